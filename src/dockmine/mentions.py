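"""Residue mention extraction from abstract text.

Residues are mined by a small pattern grammar: three-letter codes ("Ser4",
"Ser 4", "Ser-4", "Ser(4)") in Title/lower/UPPER case, full amino-acid
names ("serine 4") in Title/lower case, and — only when the abstract shows
mutagenesis context — one-letter ("S4A") and three-letter ("Ser4Ala",
"Ser-4Ala") mutation forms, which emit both the original and the
substituted residue.  One-letter codes outside mutation context are not
mined: deciding whether "T4" is a residue needs sentence-level parsing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "ResidueMention",
    "detect_mutagenesis_context",
    "extract_mentions",
    "MUTAGENESIS_KEYWORDS",
    "THREE_LETTER",
    "ONE_LETTER",
]

#: canonical three-letter codes of the 20 standard amino acids
THREE_LETTER = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

ONE_LETTER = dict(
    A="ALA", R="ARG", N="ASN", D="ASP", C="CYS", Q="GLN", E="GLU", G="GLY",
    H="HIS", I="ILE", L="LEU", K="LYS", M="MET", F="PHE", P="PRO", S="SER",
    T="THR", W="TRP", Y="TYR", V="VAL",
)

#: full amino-acid names (synonymous spellings of the acidic residues included)
FULL_NAMES = {
    "ALA": ["Alanine"], "ARG": ["Arginine"], "ASN": ["Asparagine"],
    "ASP": ["Aspartate", "Aspartic acid"], "CYS": ["Cysteine"],
    "GLN": ["Glutamine"], "GLU": ["Glutamate", "Glutamic acid"],
    "GLY": ["Glycine"], "HIS": ["Histidine"], "ILE": ["Isoleucine"],
    "LEU": ["Leucine"], "LYS": ["Lysine"], "MET": ["Methionine"],
    "PHE": ["Phenylalanine"], "PRO": ["Proline"], "SER": ["Serine"],
    "THR": ["Threonine"], "TRP": ["Tryptophan"], "TYR": ["Tyrosine"],
    "VAL": ["Valine"],
}

MUTAGENESIS_KEYWORDS = ("mutation", "mutagenesis", "mutagen", "mutant", "substitution")


@dataclass(frozen=True, order=True)
class ResidueMention:
    """An amino-acid / sequence-number pair mined from one abstract."""

    aa: str  # canonical three-letter code, upper case
    number: int
    pattern_kind: str = "three-letter"
    source_pmid: str = ""

    def __post_init__(self) -> None:
        if self.aa not in THREE_LETTER:
            raise ValueError(f"nonstandard residue code {self.aa!r}")
        if self.number < 1:
            raise ValueError(f"residue number must be >= 1, got {self.number}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.aa, self.number)


# --- pattern construction ---------------------------------------------------

# Residue numbers: non-zero digit followed by any number of digits.
_NUM = r"[1-9][0-9]*"
# Word boundaries on both sides so that e.g. accession-embedded "GLY2003"
# or "commutation" never match.
_LB = r"(?<![A-Za-z0-9])"
_RB = r"(?![A-Za-z0-9])"


def _case_styles(code: str) -> list[str]:
    """The three printed case styles of a three-letter code: Ala, ala, ALA."""
    return [code.capitalize(), code.lower(), code.upper()]


def _alt(forms: list[str]) -> str:
    return "(?:" + "|".join(re.escape(f) for f in forms) + ")"


_AA3 = _alt([s for code in THREE_LETTER for s in _case_styles(code)])
_FULL = _alt(
    [name for names in FULL_NAMES.values() for n in names for name in (n, n.lower())]
)
_AA1 = "[" + "".join(ONE_LETTER) + "]"

# AA directly followed by number, or separated by one space / hyphen, or
# number parenthesized (no interior spaces).
_SEP = r"(?:[ \-]?)"
_RE_THREE = re.compile(
    _LB + rf"(?P<aa>{_AA3})(?:{_SEP}(?P<num>{_NUM})|\((?P<pnum>{_NUM})\))" + _RB
)
_RE_FULL = re.compile(
    _LB + rf"(?P<aa>{_FULL})(?:{_SEP}(?P<num>{_NUM})|\((?P<pnum>{_NUM})\))" + _RB
)
# Mutations: X4Y and Ser4Ala / Ser-4Ala (no space between number and target).
_RE_MUT1 = re.compile(_LB + rf"(?P<frm>{_AA1})(?P<num>{_NUM})(?P<to>{_AA1})" + _RB)
_RE_MUT3 = re.compile(
    _LB + rf"(?P<frm>{_AA3})-?(?P<num>{_NUM})(?P<to>{_AA3})" + _RB
)

_RE_KEYWORDS = re.compile(
    r"(?<![A-Za-z])(?:" + "|".join(MUTAGENESIS_KEYWORDS) + r")(?![A-Za-z])",
    re.IGNORECASE,
)

_FULL_TO_CODE = {
    form.lower(): code
    for code, names in FULL_NAMES.items()
    for form in names
}


def _canon3(token: str) -> str:
    return token.upper()


def detect_mutagenesis_context(text: str) -> bool:
    """True iff the text contains a mutagenesis keyword as a whole word."""
    return bool(_RE_KEYWORDS.search(text))


def extract_mentions(
    text: str,
    mutagenesis: bool | None = None,
    source_pmid: str = "",
) -> list[ResidueMention]:
    """Extract residue mentions from one abstract's text.

    When ``mutagenesis`` is None it is detected from the text itself.
    Duplicate (aa, number) pairs within the abstract are removed; the list
    is returned in order of first occurrence.
    """
    if mutagenesis is None:
        mutagenesis = detect_mutagenesis_context(text)

    found: dict[tuple[str, int], ResidueMention] = {}

    def _add(aa: str, number: int, kind: str) -> None:
        key = (aa, number)
        if key not in found:
            found[key] = ResidueMention(aa, number, kind, source_pmid)

    if mutagenesis:
        # mutation forms first: "Ser4Ala" must not be read as plain "Ser4"
        for m in _RE_MUT3.finditer(text):
            num = int(m.group("num"))
            _add(_canon3(m.group("frm")), num, "three-letter-mutation")
            _add(_canon3(m.group("to")), num, "three-letter-mutation")
        for m in _RE_MUT1.finditer(text):
            num = int(m.group("num"))
            _add(ONE_LETTER[m.group("frm")], num, "one-letter-mutation")
            _add(ONE_LETTER[m.group("to")], num, "one-letter-mutation")

    for m in _RE_FULL.finditer(text):
        num = int(m.group("num") or m.group("pnum"))
        _add(_FULL_TO_CODE[m.group("aa").lower()], num, "full-word")
    for m in _RE_THREE.finditer(text):
        num = int(m.group("num") or m.group("pnum"))
        _add(_canon3(m.group("aa")), num, "three-letter")

    return list(found.values())
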