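"""Solvent-accessible surface, interface residues, numbering mapping, and
the mention -> identified-residue filter.

Surface residues are those with >= 25% of their maximal solvent-accessible
surface area (SASA) exposed.  SASA is computed with Shrake–Rupley sphere
sampling (probe 1.4 Å, 960 points per atom by default); relative exposure
divides the per-residue SASA by a theoretical maximum-ASA reference for
that residue type (Tien et al. 2013 values).  Interface residues are those
with any heavy atom within 6 Å of any heavy atom of the partner protein in
the co-crystallized complex; the two definitions are computed
independently of each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from scipy.spatial import cKDTree

from .corpus import AbstractRecord, TAG_OR1, TAG_OR2
from .mentions import ResidueMention
from .structures import Residue, ResidueId, Structure

__all__ = [
    "MAX_ASA",
    "VDW_RADII",
    "IdentifiedResidue",
    "sasa_per_residue",
    "compute_surface",
    "compute_interface",
    "map_numbering",
    "identify_residues",
]

#: theoretical maximum ASA per residue type, Å² (Tien et al. 2013)
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: van der Waals radii by element, Å
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}
DEFAULT_VDW = 1.70

PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960
SURFACE_THRESHOLD = 0.25
INTERFACE_CUTOFF = 6.0


@dataclass
class IdentifiedResidue:
    """A mined mention matched to a surface residue of the target structure."""

    chain: str
    number: int
    icode: str
    aa: str
    side: int  # interactor side (1 or 2)
    is_interface: bool
    n_abstracts_and: int = 0
    n_abstracts_or_only: int = 0
    source_pmids: frozenset[str] = frozenset()

    @property
    def id(self) -> ResidueId:
        return (self.chain, self.number, self.icode)

    @property
    def n_abstracts(self) -> int:
        return self.n_abstracts_and + self.n_abstracts_or_only


def _unit_sphere(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa_per_residue(
    structure: Structure,
    chains: list[str] | None = None,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> dict[ResidueId, float]:
    """Per-residue SASA (Å²) of the selected chains, Shrake–Rupley sampling.

    The selection is treated as an isolated molecule: atoms outside the
    selected chains do not occlude (pass a single interactor's chains to
    get the unbound-state surface).
    """
    residues = structure.residues(chains)
    if not residues:
        raise ValueError("structure selection holds no residues")
    coords = np.vstack([r.coords for r in residues])
    radii = np.array(
        [VDW_RADII.get(el, DEFAULT_VDW) + probe for r in residues for el in r.elements]
    )
    res_index = np.repeat(np.arange(len(residues)), [len(r.coords) for r in residues])

    sphere = _unit_sphere(n_points)
    tree = cKDTree(coords)
    max_radius = radii.max()
    areas = np.zeros(len(residues))
    for i, (center, radius) in enumerate(zip(coords, radii)):
        points = center + radius * sphere
        neighbors = [j for j in tree.query_ball_point(center, radius + max_radius) if j != i]
        if neighbors:
            diff = points[:, None, :] - coords[neighbors][None, :, :]
            occluded = (
                (diff**2).sum(axis=2) < (radii[neighbors] ** 2)[None, :]
            ).any(axis=1)
            exposed_frac = 1.0 - occluded.mean()
        else:
            exposed_frac = 1.0
        areas[res_index[i]] += exposed_frac * 4.0 * np.pi * radius**2
    return {res.id: areas[i] for i, res in enumerate(residues)}


def relative_exposure(
    structure: Structure,
    chains: list[str] | None = None,
    **kwargs,
) -> dict[ResidueId, float]:
    """SASA divided by the residue type's theoretical maximum ASA."""
    sasa = sasa_per_residue(structure, chains, **kwargs)
    out: dict[ResidueId, float] = {}
    for res in structure.residues(chains):
        if res.name not in MAX_ASA:
            raise ValueError(f"no reference maximal area for residue {res.name} {res.id}")
        out[res.id] = sasa[res.id] / MAX_ASA[res.name]
    return out


def compute_surface(
    structure: Structure,
    chains: list[str] | None = None,
    exposure_threshold: float = SURFACE_THRESHOLD,
    **kwargs,
) -> set[ResidueId]:
    """Residues with relative solvent exposure >= the threshold (default 25%)."""
    rel = relative_exposure(structure, chains, **kwargs)
    return {rid for rid, x in rel.items() if x >= exposure_threshold}


def compute_interface(
    complex_structure: Structure,
    side1: list[str],
    side2: list[str],
    cutoff: float = INTERFACE_CUTOFF,
) -> tuple[set[ResidueId], set[ResidueId]]:
    """Interface residues of each interactor in the bound complex.

    A residue is at the interface iff any of its heavy atoms lies within
    ``cutoff`` (inclusive) of any heavy atom of the other interactor.
    """
    if not side1 or not side2:
        raise ValueError("both interactors need at least one chain")
    res1 = complex_structure.residues(side1)
    res2 = complex_structure.residues(side2)
    if not res1 or not res2:
        raise ValueError("empty interactor")
    tree1 = cKDTree(np.vstack([r.coords for r in res1]))
    tree2 = cKDTree(np.vstack([r.coords for r in res2]))
    idx1 = np.repeat(np.arange(len(res1)), [len(r.coords) for r in res1])
    idx2 = np.repeat(np.arange(len(res2)), [len(r.coords) for r in res2])
    pairs = tree1.query_ball_tree(tree2, cutoff)
    iface1: set[ResidueId] = set()
    iface2: set[ResidueId] = set()
    for a1, hits in enumerate(pairs):
        if hits:
            iface1.add(res1[idx1[a1]].id)
            for a2 in hits:
                iface2.add(res2[idx2[a2]].id)
    return iface1, iface2


def map_numbering(
    reference_sequence: str,
    structure: Structure,
    chain: str,
    min_identity: float = 0.9,
) -> dict[int, ResidueId]:
    """Map 1-based reference-sequence positions to structure residue ids.

    A global alignment of the reference sequence against the chain's
    sequence gives the correspondence; unaligned positions stay unmapped.
    Refuses to map when sequence identity over aligned columns falls below
    ``min_identity``.
    """
    if not reference_sequence:
        raise ValueError("empty reference sequence")
    chain_residues = structure.chains[chain]
    chain_seq = structure.sequence(chain)
    if not chain_seq:
        raise ValueError(f"chain {chain} has no residues")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(reference_sequence, chain_seq)[0]

    mapping: dict[int, ResidueId] = {}
    matches = 0
    aligned_cols = 0
    for (r0, r1), (c0, c1) in zip(*alignment.aligned):
        for offset in range(r1 - r0):
            ref_pos = r0 + offset  # 0-based
            chain_pos = c0 + offset
            aligned_cols += 1
            if reference_sequence[ref_pos] == chain_seq[chain_pos]:
                matches += 1
            mapping[ref_pos + 1] = chain_residues[chain_pos].id
    identity = matches / aligned_cols if aligned_cols else 0.0
    if identity < min_identity:
        raise ValueError(
            f"sequence identity {identity:.2f} below floor {min_identity:.2f}; refusing to map"
        )
    return mapping


def identify_residues(
    mentions_by_pmid: dict[str, list[ResidueMention]],
    records: list[AbstractRecord],
    complex_structure: Structure,
    side1: list[str],
    side2: list[str],
    query_type: str = "AND",
    numbering_maps: dict[str, dict[int, ResidueId]] | None = None,
    surface_sets: tuple[set[ResidueId], set[ResidueId]] | None = None,
    interface_sets: tuple[set[ResidueId], set[ResidueId]] | None = None,
) -> list[IdentifiedResidue]:
    """Filter mined mentions against the structure's surface residues.

    A mention survives iff both its residue name and its (optionally
    mapped) number match a surface residue.  In AND mode the check runs
    against both interactors; in OR mode only against the interactor whose
    query half retrieved the abstract (its OR tag).  Surviving residues
    are annotated with the interface truth and with per-residue abstract
    counts split into AND-retrieved and OR-only abstracts.
    """
    if query_type not in ("AND", "OR"):
        raise ValueError("query_type must be 'AND' or 'OR'")
    if surface_sets is None:
        surface_sets = (
            compute_surface(complex_structure, side1),
            compute_surface(complex_structure, side2),
        )
    if interface_sets is None:
        interface_sets = compute_interface(complex_structure, side1, side2)
    numbering_maps = numbering_maps or {}
    by_pmid = {r.pmid: r for r in records}

    # (side, residue id) -> set of contributing pmids
    hits: dict[tuple[int, ResidueId], set[str]] = {}
    resolved: dict[tuple[int, ResidueId], Residue] = {}

    for pmid, mentions in mentions_by_pmid.items():
        record = by_pmid.get(pmid)
        if record is None or not record.retrieved_by:
            continue
        if query_type == "AND":
            sides = [1, 2]
        else:
            sides = []
            if TAG_OR1 in record.retrieved_by:
                sides.append(1)
            if TAG_OR2 in record.retrieved_by:
                sides.append(2)
        for mention in mentions:
            for side in sides:
                chains = side1 if side == 1 else side2
                surface = surface_sets[side - 1]
                for chain_id in chains:
                    nmap = numbering_maps.get(chain_id)
                    if nmap is not None:
                        rid = nmap.get(mention.number)
                        res = (
                            complex_structure.find(*rid) if rid is not None else None
                        )
                    else:
                        # raw structure numbering; blank insertion code only
                        res = complex_structure.find(chain_id, mention.number, "")
                    if res is None or res.name != mention.aa:
                        continue
                    if res.id not in surface:
                        continue
                    key = (side, res.id)
                    hits.setdefault(key, set()).add(pmid)
                    resolved[key] = res

    out: list[IdentifiedResidue] = []
    for (side, rid), pmids in sorted(hits.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        res = resolved[(side, rid)]
        n_and = sum(1 for p in pmids if by_pmid[p].and_retrieved)
        out.append(
            IdentifiedResidue(
                chain=res.chain,
                number=res.number,
                icode=res.icode,
                aa=res.name,
                side=side,
                is_interface=rid in interface_sets[side - 1],
                n_abstracts_and=n_and,
                n_abstracts_or_only=len(pmids) - n_and,
                source_pmids=frozenset(pmids),
            )
        )
    return out
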