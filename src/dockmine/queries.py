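"""Protein-name normalization and boolean PubMed query assembly.

A docking target is a pair (or two multimeric groups) of proteins.  For each
interactor we collect every name under which the literature may refer to it
(the structure entry's own name, the sequence database's recommended, short
and alternative names, and the names of proteolytically cleaved chains),
normalize them into URL-encoded search terms, and assemble two boolean
queries: the *AND-query* (both interactors mentioned) and the *OR-query*
(either interactor mentioned, with the two halves kept separate so that
retrieval can record which interactor an abstract talks about).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from urllib.parse import quote

__all__ = [
    "ProteinNameSet",
    "Term",
    "BoolQuery",
    "Query",
    "normalize_name",
    "resolve_cleaved_names",
    "build_protein_query",
    "assemble_pair_queries",
    "decompose_or_query",
]

#: Minimum length (in raw symbols) for a usable name.
MIN_NAME_LENGTH = 3

#: Keyword AND-combined with names of exactly MIN_NAME_LENGTH symbols.
SHORT_NAME_KEYWORD = "protein"


@dataclass
class ProteinNameSet:
    """All query-relevant names of one interactor.

    ``pdb_name`` is the free-text molecule name from the structure entry;
    the remaining fields mirror the protein knowledgebase record.  Gene
    names, organism names, E.C. numbers and CD-antigen tags are deliberately
    not part of this set.
    """

    pdb_name: str
    recommended: str = ""
    short_names: list[str] = field(default_factory=list)
    alternative_names: list[str] = field(default_factory=list)
    cleaved_chain_names: list[str] = field(default_factory=list)
    is_generic_word: bool = False

    def __post_init__(self) -> None:
        self.pdb_name = self.pdb_name.rstrip()
        self.recommended = self.recommended.rstrip()
        self.short_names = [s.rstrip() for s in self.short_names if s.rstrip()]
        self.alternative_names = [s.rstrip() for s in self.alternative_names if s.rstrip()]
        self.cleaved_chain_names = [s.rstrip() for s in self.cleaved_chain_names if s.rstrip()]


@dataclass(frozen=True)
class Term:
    """A leaf query term: a single URL-encoded search string."""

    text: str
    provenance: frozenset[int] = frozenset()

    def serialize(self) -> str:
        return self.text


@dataclass(frozen=True)
class BoolQuery:
    """A boolean combination (AND / OR) of sub-queries."""

    op: str  # "AND" | "OR"
    children: tuple["Query", ...]
    provenance: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.op not in ("AND", "OR"):
            raise ValueError(f"unknown boolean operator {self.op!r}")
        if not self.children:
            raise ValueError("boolean query needs at least one child")

    def serialize(self) -> str:
        inner = f" {self.op} ".join(c.serialize() for c in self.children)
        return f"({inner})"

    def leaves(self) -> list[Term]:
        out: list[Term] = []
        for c in self.children:
            if isinstance(c, Term):
                out.append(c)
            else:
                out.extend(c.leaves())
        return out


Query = Term | BoolQuery


def _url_encode(name: str) -> str:
    # RFC 3986: encode everything outside the unreserved set; space -> %20.
    return quote(name, safe="")


def _hyphen_variants(name: str) -> list[str]:
    """Raw (un-encoded) hyphen variants of *name*.

    For each hyphen the variant keeps it, removes it, or replaces it with a
    space; the full cartesian product over hyphens is generated and
    deduplicated, the original form first.
    """
    positions = [i for i, ch in enumerate(name) if ch == "-"]
    if not positions:
        return [name]
    variants: list[str] = []
    for choices in itertools.product(["-", "", " "], repeat=len(positions)):
        parts: list[str] = []
        prev = 0
        for pos, repl in zip(positions, choices):
            parts.append(name[prev:pos])
            parts.append(repl)
            prev = pos + 1
        parts.append(name[prev:])
        variant = "".join(parts)
        if variant not in variants:
            variants.append(variant)
    # put the unmodified name first
    variants.sort(key=lambda v: v != name)
    return variants


def normalize_name(name: str) -> list[str]:
    """Normalize one protein name into URL-encoded query-term variants.

    Trailing spaces are removed.  Names shorter than 3 symbols are unusable
    and yield an empty list; names of exactly 3 symbols are AND-combined
    with the keyword "protein".  For hyphenated names every combination of
    keeping, removing, or replacing each hyphen with an (encoded) space is
    emitted, the original spelling first.
    """
    if not name:
        raise ValueError("name must be non-empty")
    name = name.rstrip()
    if len(name) < MIN_NAME_LENGTH:
        return []
    variants = [_url_encode(v) for v in _hyphen_variants(name)]
    seen: set[str] = set()
    unique = [v for v in variants if not (v in seen or seen.add(v))]
    if len(name) == MIN_NAME_LENGTH:
        unique = [f"({v} AND {SHORT_NAME_KEYWORD})" for v in unique]
    return unique


def _match_key(name: str) -> str:
    """Case-folded, whitespace-collapsed form used for exact matching."""
    return re.sub(r"\s+", " ", name.strip()).casefold()


def resolve_cleaved_names(pdb_name: str, name_set: ProteinNameSet) -> list[str]:
    """Decide which names enter the query when the protein is cleaved.

    Three scenarios, all based on exact (edit distance 0 after
    normalization) matching of the structure-entry name:

    1. it equals the recommended name: the structure holds every cleaved
       chain, so the recommended name plus all chain names are used;
    2. it equals exactly one cleaved chain name: the recommended name plus
       that chain name;
    3. no exact match: the recommended name plus the structure-entry name.
    """
    if not name_set.recommended:
        raise ValueError("malformed metadata: recommended name missing")
    pdb_name = pdb_name.rstrip()
    key = _match_key(pdb_name)
    if key == _match_key(name_set.recommended):
        return [name_set.recommended, *name_set.cleaved_chain_names]
    for chain_name in name_set.cleaved_chain_names:
        if key == _match_key(chain_name):
            return [name_set.recommended, chain_name]
    return [name_set.recommended, pdb_name]


def build_protein_query(
    name_set: ProteinNameSet,
    mesh_terms: list[str] | None = None,
    provenance: int = 1,
) -> Query:
    """Build the per-interactor query: OR of all variants of all names.

    Names come from :func:`resolve_cleaved_names` (when cleaved-chain names
    are present) plus short and alternative names.  When the protein name is
    a generic English word, the disjunction is AND-combined with a
    disjunction of MeSH terms to cut noise.
    """
    if name_set.cleaved_chain_names:
        names = resolve_cleaved_names(name_set.pdb_name, name_set)
    else:
        names = [n for n in (name_set.recommended, name_set.pdb_name) if n]
        if _match_key(name_set.recommended) == _match_key(name_set.pdb_name):
            names = names[:1]
    names.extend(name_set.short_names)
    names.extend(name_set.alternative_names)

    prov = frozenset({provenance})
    terms: list[Term] = []
    seen: set[str] = set()
    for name in names:
        for variant in normalize_name(name):
            if variant not in seen:
                seen.add(variant)
                terms.append(Term(variant, prov))
    if not terms:
        raise ValueError(f"no usable names for interactor {provenance}")

    query: Query = terms[0] if len(terms) == 1 else BoolQuery("OR", tuple(terms), prov)
    if name_set.is_generic_word and mesh_terms:
        mesh_leaves = tuple(Term(_url_encode(t.rstrip()), prov) for t in mesh_terms if t.rstrip())
        mesh: Query = mesh_leaves[0] if len(mesh_leaves) == 1 else BoolQuery("OR", mesh_leaves, prov)
        query = BoolQuery("AND", (query, mesh), prov)
    return query


def build_group_query(queries: list[Query], provenance: frozenset[int]) -> Query:
    """OR-combine the per-monomer queries of one multimeric interactor."""
    if not queries:
        raise ValueError("empty interactor group")
    if len(queries) == 1:
        return queries[0]
    return BoolQuery("OR", tuple(queries), provenance)


def assemble_pair_queries(q1: Query, q2: Query) -> tuple[Query, Query]:
    """Assemble the AND-query and the OR-query for an interactor pair.

    The OR-query keeps its two halves intact (children of the top OR node)
    so retrieval can submit them separately and record which interactor an
    abstract mentions.
    """
    prov = q1.provenance | q2.provenance
    and_query = BoolQuery("AND", (q1, q2), prov)
    or_query = BoolQuery("OR", (q1, q2), prov)
    return and_query, or_query


def decompose_or_query(or_query: Query) -> tuple[Query, Query]:
    """Return the two per-interactor halves of an assembled OR-query."""
    if not isinstance(or_query, BoolQuery) or or_query.op != "OR" or len(or_query.children) != 2:
        raise ValueError("not a pair OR-query")
    return or_query.children[0], or_query.children[1]
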