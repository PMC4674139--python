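"""Per-complex and dataset-level performance of the text-mining protocol.

For one complex with N abstracts containing identified residues, quality is
the fraction of correct (interface) residues among all identified residues:

    P_TM = sum_i n_int_i / sum_i (n_int_i + n_non_i)

Dataset-level metrics count complexes: coverage = L_tot / n_total (a
complex counts toward L_tot when at least one abstract yielded identified
residues), success = L_int / n_total (at least one *interface* residue
found), accuracy = L_int / L_tot.  Percentages are printed to one decimal,
half-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ComplexTMResult",
    "DatasetSummary",
    "ptm",
    "delta_ptm",
    "dataset_metrics",
    "ptm_histogram",
]


@dataclass
class ComplexTMResult:
    """Identified-residue counts for one complex.

    ``abstract_counts`` maps pmid -> (n_int, n_non): how many of the
    abstract's identified residues are at / off the reference interface.
    """

    complex_id: str
    abstract_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    residues: list = field(default_factory=list)

    @property
    def n_abstracts(self) -> int:
        return len(self.abstract_counts)

    @property
    def totals(self) -> tuple[int, int]:
        n_int = sum(c[0] for c in self.abstract_counts.values())
        n_non = sum(c[1] for c in self.abstract_counts.values())
        return n_int, n_non


@dataclass(frozen=True)
class DatasetSummary:
    l_tot: int  # complexes with >= 1 abstract containing identified residues
    l_int: int  # complexes with >= 1 interface residue identified
    n_total: int  # dataset size

    def __post_init__(self) -> None:
        if not (0 <= self.l_int <= self.l_tot <= self.n_total):
            raise ValueError("need 0 <= L_int <= L_tot <= n_total")


def ptm(result: ComplexTMResult) -> float | None:
    """Fraction of interface residues among all identified residues; None
    (undefined) when the complex has no identified residues."""
    n_int, n_non = result.totals
    total = n_int + n_non
    if total == 0:
        return None
    return n_int / total


def delta_ptm(before: ComplexTMResult, after: ComplexTMResult) -> tuple[float | None, bool]:
    """P_TM change after abstract filtering for one complex.

    Returns (after - before, all_removed); when the filter removed every
    abstract the difference is None and the flag is set.
    """
    p_before = ptm(before)
    p_after = ptm(after)
    if p_after is None:
        return None, True
    if p_before is None:
        return None, False
    return p_after - p_before, False


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def dataset_metrics(s: DatasetSummary) -> tuple[float, float | None, float | None]:
    """(coverage %, success %, accuracy %), one decimal, half-up.

    Accuracy is undefined (None) when no complex produced residues.
    """
    if s.n_total <= 0:
        raise ValueError("dataset size must be positive")
    coverage = _round1(100.0 * s.l_tot / s.n_total)
    success = _round1(100.0 * s.l_int / s.n_total)
    accuracy = _round1(100.0 * s.l_int / s.l_tot) if s.l_tot else None
    return coverage, success, accuracy


def ptm_histogram(results: list[ComplexTMResult], bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of complexes over P_TM in [0, 1], normalized by the
    number of complexes with a defined P_TM (the bins sum to 1)."""
    values = [p for p in (ptm(r) for r in results) if p is not None]
    if not values:
        raise ValueError("no complex has a defined P_TM")
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    return counts / len(values), edges
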