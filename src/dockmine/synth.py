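"""Synthetic corpora and toy complexes with fully recorded ground truth.

Every stage of the pipeline is testable offline against these fixtures:

* ``generate_corpus`` builds abstracts from templated sentences whose
  vocabulary follows per-class (PPI-relevant vs irrelevant) stem-frequency
  profiles, with residue mentions planted in the exact surface forms the
  extraction grammar covers (three-letter, full-name, and mutation styles
  in their printed case variants);
* ``generate_complex`` builds a two-chain toy complex on a regular grid
  with a designed contact patch, rigidly perturbed "unbound" copies, and a
  pose list holding one near-native match plus far-away decoys.

Toy chains are synthetic grid-backbone constructs with varied residue
names; they make no claim of physical realism, only of exactly known
geometry.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .corpus import AbstractRecord, TAG_AND, TAG_OR1, TAG_OR2
from .docking import DockingMatch, kabsch
from .mentions import FULL_NAMES, ONE_LETTER
from .structures import Residue, Structure

__all__ = [
    "CorpusSpec",
    "PlantedMention",
    "generate_corpus",
    "ComplexSpec",
    "ToyComplex",
    "generate_complex",
    "MENTION_STYLES",
]

# --- corpora -----------------------------------------------------------------

#: inflected vocabulary whose stems carry the PPI-relevant signal
POSITIVE_VOCAB = [
    "binding", "interaction", "interactions", "complex", "interface",
    "contact", "contacts", "conserved", "recognition", "conformation",
    "allosteric", "bound", "affinity", "association", "domain", "surface",
    "specificity", "stabilized", "induced", "mechanism",
]

#: vocabulary typical of non-PPI abstracts
NEGATIVE_VOCAB = [
    "patients", "disease", "gene", "expression", "transcription",
    "phenotype", "polymorphism", "antibody", "clinical", "diagnosis",
    "therapy", "population", "cohort", "serum", "plasma", "screening",
    "prevalence", "symptoms", "treatment", "outcome",
]

#: neutral filler that stems to neither profile
FILLER = ["study", "results", "observed", "however", "several", "analysis"]

_AA_CODES = list(FULL_NAMES)

MENTION_STYLES = (
    "three-letter-nospace",
    "three-letter-space",
    "three-letter-hyphen",
    "three-letter-paren",
    "full-nospace",
    "full-space",
    "one-letter-mutation",
    "three-letter-mutation",
)

_CASES = ("title", "lower", "upper")

_CODE_TO_ONE = {v: k for k, v in ONE_LETTER.items()}


def _case3(code: str, case: str) -> str:
    return {"title": code.capitalize(), "lower": code.lower(), "upper": code.upper()}[case]


@dataclass(frozen=True)
class PlantedMention:
    """One planted mention and the (aa, number) pairs it must yield."""

    aa: str
    number: int
    style: str
    case: str
    rendered: str
    expected: tuple[tuple[str, int], ...]
    needs_mutagenesis: bool = False


def render_mention(
    aa: str, number: int, style: str, case: str = "title", target_aa: str = "ALA"
) -> PlantedMention:
    """Render a residue mention in one of the grammar's surface forms."""
    if style == "three-letter-nospace":
        text = f"{_case3(aa, case)}{number}"
    elif style == "three-letter-space":
        text = f"{_case3(aa, case)} {number}"
    elif style == "three-letter-hyphen":
        text = f"{_case3(aa, case)}-{number}"
    elif style == "three-letter-paren":
        text = f"{_case3(aa, case)}({number})"
    elif style == "full-nospace":
        name = FULL_NAMES[aa][0]
        text = f"{name if case == 'title' else name.lower()}{number}"
    elif style == "full-space":
        name = FULL_NAMES[aa][0]
        text = f"{name if case == 'title' else name.lower()} {number}"
    elif style == "one-letter-mutation":
        text = f"{_CODE_TO_ONE[aa]}{number}{_CODE_TO_ONE[target_aa]}"
        return PlantedMention(aa, number, style, "upper", text,
                              ((aa, number), (target_aa, number)), True)
    elif style == "three-letter-mutation":
        text = f"{_case3(aa, case)}{number}{_case3(target_aa, case)}"
        return PlantedMention(aa, number, style, case, text,
                              ((aa, number), (target_aa, number)), True)
    else:
        raise ValueError(f"unknown mention style {style!r}")
    return PlantedMention(aa, number, style, case, text, ((aa, number),))


@dataclass
class CorpusSpec:
    """Study conditions for one synthetic corpus.

    ``separation`` in [0, 1] sets the class contrast: 1 means each class
    draws only from its own vocabulary; ``words_per_abstract`` is the mean
    count of profile words per abstract.
    """

    seed: int = 0
    n_pos: int = 60
    n_neg: int = 60
    separation: float = 1.0
    words_per_abstract: float = 12.0
    mentions_per_abstract: int = 2
    plant_mentions: bool = True
    and_fraction: float = 0.3  # abstracts also retrieved by the AND-query


def _abstract_text(rng, own_vocab, other_vocab, spec, planted: list[PlantedMention]) -> str:
    n_own = rng.poisson(spec.words_per_abstract * (0.5 + 0.5 * spec.separation))
    n_other = rng.poisson(spec.words_per_abstract * 0.5 * (1.0 - spec.separation))
    words = (
        [str(rng.choice(own_vocab)) for _ in range(max(1, n_own))]
        + [str(rng.choice(other_vocab)) for _ in range(n_other)]
        + [str(rng.choice(FILLER)) for _ in range(rng.integers(2, 6))]
    )
    rng.shuffle(words)
    sentences = []
    if any(p.needs_mutagenesis for p in planted):
        sentences.append("A mutation was characterized in detail.")
    for p in planted:
        sentences.append(f"Residue {p.rendered} was examined.")
    body = " ".join(words)
    sentences.append(f"In this work {body}.")
    return " ".join(sentences)


def generate_corpus(
    spec: CorpusSpec,
) -> tuple[list[AbstractRecord], dict[str, dict]]:
    """Generate a corpus and its ground-truth table.

    Returns (records, truth) where ``truth[pmid]`` holds the class label,
    the planted mentions, and the exact (aa, number) pairs extraction must
    recover.  Byte-identical output under the same spec (seeded).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[AbstractRecord] = []
    truth: dict[str, dict] = {}
    pmid_counter = 1000
    for label, n, own, other in (
        ("positive", spec.n_pos, POSITIVE_VOCAB, NEGATIVE_VOCAB),
        ("negative", spec.n_neg, NEGATIVE_VOCAB, POSITIVE_VOCAB),
    ):
        for _ in range(n):
            pmid = str(pmid_counter)
            pmid_counter += 1
            planted: list[PlantedMention] = []
            if spec.plant_mentions:
                for _ in range(spec.mentions_per_abstract):
                    aa = str(rng.choice(_AA_CODES))
                    number = int(rng.integers(1, 200))
                    style = str(rng.choice(MENTION_STYLES[:6]))
                    case = str(rng.choice(_CASES if style.startswith("three") else _CASES[:2]))
                    planted.append(render_mention(aa, number, style, case))
            text = _abstract_text(rng, own, other, spec, planted)
            tags = {TAG_AND} if rng.random() < spec.and_fraction else (
                {TAG_OR1} if rng.random() < 0.5 else {TAG_OR2}
            )
            date = _dt.date(1990, 1, 1) + _dt.timedelta(days=int(rng.integers(0, 9000)))
            records.append(
                AbstractRecord(pmid=pmid, title=f"Synthetic abstract {pmid}",
                               body=text, pub_date=date, retrieved_by=tags)
            )
            expected = sorted({pair for p in planted for pair in p.expected})
            truth[pmid] = {"label": label, "planted": planted, "expected": expected}
    return records, truth


# --- toy complexes -----------------------------------------------------------

_PALETTE = ["SER", "ARG", "HIS", "ASP", "LYS", "THR", "GLU", "ASN", "TYR", "VAL",
            "LEU", "GLN", "TRP", "PHE", "ILE", "MET", "ALA", "GLY", "PRO", "CYS"]


def _grid_residues(
    chain: str,
    shape: tuple[int, int, int],
    spacing: float,
    origin: np.ndarray,
    start_number: int = 1,
) -> list[Residue]:
    """Residues on a rectangular grid; each has N, CA, C, O, CB atoms."""
    nx, ny, nz = shape
    residues = []
    number = start_number
    offsets = {
        "N": np.array([-1.2, 0.0, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([1.2, 0.0, 0.0]),
        "O": np.array([1.2, 1.0, 0.0]),
        "CB": np.array([0.0, 1.2, 0.8]),
    }
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                ca = origin + spacing * np.array([ix, iy, iz], dtype=float)
                name = _PALETTE[(number - 1) % len(_PALETTE)]
                atom_names = list(offsets)
                if name == "GLY":
                    atom_names = ["N", "CA", "C", "O"]
                residues.append(
                    Residue(
                        chain=chain,
                        number=number,
                        icode="",
                        name=name,
                        atom_names=atom_names,
                        coords=np.vstack([ca + offsets[a] for a in atom_names]),
                        elements=[elements[a] for a in atom_names],
                    )
                )
                number += 1
    return residues


@dataclass
class ComplexSpec:
    seed: int = 0
    receptor_shape: tuple[int, int, int] = (5, 3, 2)
    ligand_shape: tuple[int, int, int] = (3, 2, 2)
    spacing: float = 5.0
    gap: float = 4.0  # facing-layer Calpha gap across the interface
    n_decoys: int = 20
    unbound_jitter: float = 0.05  # Å of coordinate noise on unbound copies


@dataclass
class ToyComplex:
    """A generated two-chain complex with every ground truth recorded."""

    bound: Structure
    receptor_chains: list[str]
    ligand_chains: list[str]
    unbound_receptor: Structure
    unbound_ligand: Structure
    interface_receptor: set  # residue ids, by brute-force distance scan
    interface_ligand: set
    near_native: DockingMatch
    decoys: list[DockingMatch] = field(default_factory=list)

    @property
    def matches(self) -> list[DockingMatch]:
        """Scan-ordered pose list: decoys first, near-native buried last."""
        return [*self.decoys, self.near_native]


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _rigid_copy(structure: Structure, rng, jitter: float) -> Structure:
    rot = _random_rotation(rng)
    tr = rng.uniform(-40.0, 40.0, size=3)
    residues = []
    for res in structure.residues():
        coords = res.coords @ rot.T + tr
        if jitter > 0:
            coords = coords + rng.normal(scale=jitter, size=coords.shape)
        residues.append(
            Residue(res.chain, res.number, res.icode, res.name,
                    list(res.atom_names), coords, list(res.elements))
        )
    return Structure(residues, name=structure.name + "_unbound")


def _brute_force_interface(res1, res2, cutoff: float):
    iface1, iface2 = set(), set()
    for r1 in res1:
        for r2 in res2:
            d = np.linalg.norm(r1.coords[:, None, :] - r2.coords[None, :, :], axis=2)
            if (d <= cutoff).any():
                iface1.add(r1.id)
                iface2.add(r2.id)
    return iface1, iface2


def generate_complex(spec: ComplexSpec) -> ToyComplex:
    """Build a toy two-chain complex plus unbound copies and a pose list.

    The ligand grid sits above the receptor's top layer at a Calpha gap of
    ``spec.gap`` Å, giving a designed contact patch; decoy poses place the
    ligand far from the receptor, so their i-RMSD exceeds 10 Å by
    construction, while the near-native pose reproduces the bound position
    of the (rigidly perturbed) unbound ligand.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.receptor_shape
    receptor_res = _grid_residues("A", spec.receptor_shape, spec.spacing, np.zeros(3))
    lig_origin = np.array(
        [
            spec.spacing * (nx - spec.ligand_shape[0]) / 2.0,
            spec.spacing * (ny - spec.ligand_shape[1]) / 2.0,
            spec.spacing * (nz - 1) + spec.gap,
        ]
    )
    ligand_res = _grid_residues("B", spec.ligand_shape, spec.spacing, lig_origin,
                                start_number=1)
    bound = Structure(receptor_res + ligand_res, name="toy_complex")

    iface_r, iface_l = _brute_force_interface(receptor_res, ligand_res, 6.0)

    unbound_receptor = _rigid_copy(bound.subset(["A"]), rng, spec.unbound_jitter)
    unbound_ligand = _rigid_copy(bound.subset(["B"]), rng, spec.unbound_jitter)

    # docking frame = unbound receptor frame: map the bound complex into it
    b_rec_ca = bound.ca_coords(["A"])
    u_rec_ca = unbound_receptor.ca_coords()
    rot_rb, tr_rb = kabsch(b_rec_ca, u_rec_ca)
    target_lig_ca = bound.ca_coords(["B"]) @ rot_rb.T + tr_rb

    # near-native pose: fit the unbound ligand onto that target position
    rot_nn, tr_nn = kabsch(unbound_ligand.ca_coords(), target_lig_ca)
    near_native = DockingMatch(rank=spec.n_decoys + 1, rotation=rot_nn, translation=tr_nn)

    decoys = []
    lig_center = unbound_ligand.ca_coords().mean(axis=0)
    nn_center = rot_nn @ lig_center + tr_nn
    for i in range(spec.n_decoys):
        rot = _random_rotation(rng)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        center = nn_center + direction * rng.uniform(30.0, 60.0)
        tr = center - rot @ lig_center
        decoys.append(DockingMatch(rank=i + 1, rotation=rot, translation=tr))

    return ToyComplex(
        bound=bound,
        receptor_chains=["A"],
        ligand_chains=["B"],
        unbound_receptor=unbound_receptor,
        unbound_ligand=unbound_ligand,
        interface_receptor=iface_r,
        interface_ligand=iface_l,
        near_native=near_native,
        decoys=decoys,
    )
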