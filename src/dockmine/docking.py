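"""Docking constraints from mined residues and rescoring of docking matches.

A mined surface residue becomes a constraint with confidence

    f(R) = min(10, sum_i a_i),   a_i = 2 for an AND-retrieved abstract,
                                 a_i = 1 for an OR-only abstract,

summed over the distinct abstracts mentioning the residue.  The top five
residues per interactor are kept; when more residues tie at the cut,
those with more AND-derived contributions are preferred, and remaining
ties are removed at random (seeded).  Matches from a rigid-body docking
scan are rescored by the sum of confidences of the constraint residues
found at the model's interface (6 Å heavy-atom rule applied to the posed
model), stably re-sorted by that score.  Model quality is the ligand
interface Calpha RMSD (i-RMSD) against the unbound ligand superimposed on
the bound complex; the ligand is the smaller protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structures import ResidueId, Structure
from .surface import INTERFACE_CUTOFF, IdentifiedResidue, compute_interface

__all__ = [
    "CONFIDENCE_CAP",
    "Constraint",
    "DockingMatch",
    "residue_confidence",
    "select_constraints",
    "reference_constraints",
    "rescore",
    "kabsch",
    "superimpose",
    "irmsd",
    "success_rate",
    "read_matches",
    "write_matches",
]

CONFIDENCE_CAP = 10
TOP_K_CONSTRAINTS = 5
AND_WEIGHT = 2
OR_WEIGHT = 1


@dataclass(frozen=True)
class Constraint:
    """A mined residue with its docking confidence."""

    side: int  # 1 = receptor group, 2 = ligand group
    chain: str
    number: int
    aa: str
    confidence: int
    n_and: int = 0  # AND-abstract contributions, kept for tie preference
    icode: str = ""

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain, self.number, self.icode)


@dataclass
class DockingMatch:
    """One rigid-body pose of the ligand: x -> rotation @ x + translation."""

    rank: int  # position in the scan output
    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    tm_score: float = 0.0
    i_rmsd: float | None = None

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ np.asarray(self.rotation).T + np.asarray(self.translation)


def residue_confidence(n_and: int, n_or_only: int, cap: int = CONFIDENCE_CAP) -> int:
    """Confidence f(R) of a residue mentioned by distinct abstracts."""
    if n_and < 0 or n_or_only < 0:
        raise ValueError("abstract counts must be non-negative")
    if n_and + n_or_only < 1:
        raise ValueError("a constraint residue needs at least one abstract")
    return min(cap, AND_WEIGHT * n_and + OR_WEIGHT * n_or_only)


def constraints_from_identified(residues: list[IdentifiedResidue]) -> list[Constraint]:
    return [
        Constraint(
            side=r.side,
            chain=r.chain,
            number=r.number,
            aa=r.aa,
            confidence=residue_confidence(r.n_abstracts_and, r.n_abstracts_or_only),
            n_and=r.n_abstracts_and,
            icode=r.icode,
        )
        for r in residues
    ]


def select_constraints(
    scored: list[Constraint],
    k: int = TOP_K_CONSTRAINTS,
    seed: int = 0,
) -> list[Constraint]:
    """Top-k constraints per interactor side.

    Ordering: confidence descending; among equal confidences at the cut,
    residues with more AND-derived contributions are preferred; residues
    still tied are removed at random (deterministic under the seed).
    """
    rng = np.random.default_rng(seed)
    out: list[Constraint] = []
    for side in sorted({c.side for c in scored}):
        group = [c for c in scored if c.side == side]
        # random iid keys break exact ties reproducibly under the seed
        jitter = rng.random(len(group))
        order = sorted(
            range(len(group)),
            key=lambda i: (-group[i].confidence, -group[i].n_and, jitter[i]),
        )
        out.extend(group[i] for i in order[:k])
    return out


def reference_constraints(
    bound: Structure,
    side1: list[str],
    side2: list[str],
    n_pairs: int = 3,
    cutoff: float = INTERFACE_CUTOFF,
) -> list[tuple[Constraint, Constraint]]:
    """Reference (true-interface) constraint pairs from the bound complex.

    All cross-interface residue pairs are sorted ascending by Calpha-Calpha
    distance (exact ties broken by chain id and residue number); the top
    ``n_pairs`` are returned with the maximal confidence.  Fewer pairs are
    returned (with no error) when the interface is smaller.
    """
    iface1, iface2 = compute_interface(bound, side1, side2, cutoff)
    if not iface1 or not iface2:
        raise ValueError("empty interface: no reference constraints")

    def _with_ca(ids: set[ResidueId]):
        out = []
        for rid in sorted(ids):
            res = bound.find(*rid)
            if res is not None and res.ca is not None:
                out.append((rid, res))
        return out

    res1 = _with_ca(iface1)
    res2 = _with_ca(iface2)
    pairs = []
    for rid1, r1 in res1:
        for rid2, r2 in res2:
            d = float(np.linalg.norm(r1.ca - r2.ca))
            pairs.append((d, rid1, rid2, r1, r2))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))

    out = []
    for d, rid1, rid2, r1, r2 in pairs[:n_pairs]:
        c1 = Constraint(1, r1.chain, r1.number, r1.name, CONFIDENCE_CAP, icode=r1.icode)
        c2 = Constraint(2, r2.chain, r2.number, r2.name, CONFIDENCE_CAP, icode=r2.icode)
        out.append((c1, c2))
    return out


def _model_interface(
    receptor: Structure,
    posed_ligand_coords: np.ndarray,
    ligand: Structure,
    cutoff: float,
) -> tuple[set[ResidueId], set[ResidueId]]:
    """Interface residues of a posed model, 6 Å heavy-atom rule."""
    rec_res = receptor.residues()
    lig_res = ligand.residues()
    rec_coords = np.vstack([r.coords for r in rec_res])
    rec_idx = np.repeat(np.arange(len(rec_res)), [len(r.coords) for r in rec_res])
    lig_idx = np.repeat(np.arange(len(lig_res)), [len(r.coords) for r in lig_res])
    tree_r = cKDTree(rec_coords)
    tree_l = cKDTree(posed_ligand_coords)
    hits = tree_r.query_ball_tree(tree_l, cutoff)
    iface_r: set[ResidueId] = set()
    iface_l: set[ResidueId] = set()
    for a_r, close in enumerate(hits):
        if close:
            iface_r.add(rec_res[rec_idx[a_r]].id)
            for a_l in close:
                iface_l.add(lig_res[lig_idx[a_l]].id)
    return iface_r, iface_l


def rescore(
    matches: list[DockingMatch],
    constraints: list[Constraint],
    receptor: Structure,
    ligand: Structure,
    interface_cutoff: float = INTERFACE_CUTOFF,
) -> list[DockingMatch]:
    """Score each match by the summed confidence of constraints at its
    interface and re-sort descending (stable: equal scores keep scan order).

    With no constraints every score is zero and the scan order is
    preserved.  The input list is not mutated.
    """
    lig_coords = ligand.atom_coords()
    rescored: list[DockingMatch] = []
    for match in matches:
        rot = np.asarray(match.rotation, dtype=float)
        tr = np.asarray(match.translation, dtype=float)
        if rot.shape != (3, 3) or tr.shape != (3,):
            raise ValueError(f"malformed pose for match {match.rank}")
        if constraints:
            posed = lig_coords @ rot.T + tr
            iface_r, iface_l = _model_interface(receptor, posed, ligand, interface_cutoff)
            score = 0.0
            for c in constraints:
                at_interface = (
                    c.residue_id in iface_r if c.side == 1 else c.residue_id in iface_l
                )
                if at_interface:
                    score += c.confidence
        else:
            score = 0.0
        rescored.append(replace_score(match, score))
    rescored.sort(key=lambda m: -m.tm_score)  # stable: ties keep input order
    return rescored


def replace_score(match: DockingMatch, score: float) -> DockingMatch:
    return DockingMatch(
        rank=match.rank,
        rotation=match.rotation,
        translation=match.translation,
        tm_score=score,
        i_rmsd=match.i_rmsd,
    )


# --- i-RMSD ------------------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping mobile onto target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    tr = tc - rot @ mc
    return rot, tr


def superimpose(mobile: np.ndarray, target: np.ndarray, apply_to: np.ndarray) -> np.ndarray:
    rot, tr = kabsch(mobile, target)
    return apply_to @ rot.T + tr


def _common_ca(a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray, list[ResidueId]]:
    """Calpha coordinate pairs of residues shared (by id) between a and b."""
    ids = []
    ca_a, ca_b = [], []
    for res in a.residues():
        other = b.find(*res.id)
        if other is not None and res.ca is not None and other.ca is not None:
            ids.append(res.id)
            ca_a.append(res.ca)
            ca_b.append(other.ca)
    if not ids:
        raise ValueError("no common residues between structures")
    return np.vstack(ca_a), np.vstack(ca_b), ids


def irmsd(
    match: DockingMatch,
    bound: Structure,
    bound_receptor_chains: list[str],
    bound_ligand_chains: list[str],
    unbound_receptor: Structure,
    unbound_ligand: Structure,
    cutoff: float = INTERFACE_CUTOFF,
) -> tuple[float, int]:
    """Ligand interface Calpha RMSD of a docked pose, and the number of
    interface residues matched between bound and unbound ligand.

    The ligand interface is defined on the bound reference (6 Å heavy-atom
    rule).  The reference position is the unbound ligand superimposed on
    the bound ligand, carried into the docking frame by superimposing the
    bound receptor on the unbound receptor.  Residues missing from the
    unbound ligand are skipped; the RMSD covers the matched subset.
    """
    _, iface_lig = compute_interface(bound, bound_receptor_chains, bound_ligand_chains, cutoff)
    if not iface_lig:
        raise ValueError("bound complex has no ligand interface residues")

    # bound -> docking frame (unbound receptor coordinates)
    b_rec = bound.subset(bound_receptor_chains)
    rec_b_ca, rec_u_ca, _ = _common_ca(b_rec, unbound_receptor)
    rot_rb, tr_rb = kabsch(rec_b_ca, rec_u_ca)

    # unbound ligand -> bound ligand position, then into the docking frame
    b_lig = bound.subset(bound_ligand_chains)
    lig_u_ca, lig_b_ca, _ = _common_ca(unbound_ligand, b_lig)
    rot_lu, tr_lu = kabsch(lig_u_ca, lig_b_ca)

    ref_ca, docked_ca = [], []
    matched = 0
    for rid in sorted(iface_lig):
        res_b = bound.find(*rid)
        res_u = unbound_ligand.find(*rid)
        if res_b is None or res_u is None or res_u.ca is None:
            continue
        matched += 1
        ca_u = res_u.ca
        # reference: unbound ligand Calpha fitted onto bound, then into frame
        ca_ref = rot_rb @ (rot_lu @ ca_u + tr_lu) + tr_rb
        ref_ca.append(ca_ref)
        docked_ca.append(match.transform(ca_u[None, :])[0])
    if not matched:
        raise ValueError("no ligand interface residues matched in the unbound ligand")
    diff = np.vstack(docked_ca) - np.vstack(ref_ca)
    return float(np.sqrt((diff**2).sum(axis=1).mean())), matched


# --- success criteria --------------------------------------------------------

SUCCESS_CRITERIA = {
    "strict": (10, 5.0),  # a model with i-RMSD <= 5 Å among the top 10
    "relaxed": (100, 8.0),  # a model with i-RMSD <= 8 Å among the top 100
}


def success_rate(per_complex_irmsd: list[list[float]], criterion: str = "strict") -> float:
    """Percentage of complexes whose ranked match list satisfies the
    criterion: strict = i-RMSD <= 5 Å in the top 10, relaxed = <= 8 Å in
    the top 100 (both bounds inclusive)."""
    if criterion not in SUCCESS_CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    top_n, threshold = SUCCESS_CRITERIA[criterion]
    if not per_complex_irmsd:
        raise ValueError("no complexes")
    hits = sum(
        1 for ranked in per_complex_irmsd if ranked and min(ranked[:top_n]) <= threshold
    )
    return 100.0 * hits / len(per_complex_irmsd)


# --- pose list I/O -----------------------------------------------------------

def write_matches(matches: list[DockingMatch], path: str | Path) -> None:
    """Tabular pose list: rank, row-major rotation (9 floats), translation (3)."""
    lines = ["# rank r11 r12 r13 r21 r22 r23 r31 r32 r33 t1 t2 t3"]
    for m in matches:
        nums = list(np.asarray(m.rotation).ravel()) + list(np.asarray(m.translation))
        lines.append(str(m.rank) + " " + " ".join(f"{x:.6f}" for x in nums))
    Path(path).write_text("\n".join(lines) + "\n")


def read_matches(path: str | Path) -> list[DockingMatch]:
    matches = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 13:
            raise ValueError(f"malformed pose line: {line!r}")
        rank = int(parts[0])
        nums = [float(x) for x in parts[1:]]
        matches.append(
            DockingMatch(
                rank=rank,
                rotation=np.array(nums[:9]).reshape(3, 3),
                translation=np.array(nums[9:]),
            )
        )
    return matches
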