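"""Bag-of-words SVM filtering of abstracts for PPI relevance.

Abstracts retrieved by the AND-queries are labelled from their residue
content: with ``n_int`` interface and ``n_non`` non-interface identified
residues an abstract is *positive* when ``n_int - n_non > 4`` or
``n_non == 0 and n_int > 0``, *negative* when ``n_non - n_int > 4`` or
``n_non > 0 and n_int == 0``, otherwise unused.  Labelled abstracts are
split 80/20 per class into training and validation sets, tokenized,
stop-word-purged and Porter-stemmed; per-class normalized stem counts
f_pos(m), f_neg(m) drive feature selection (|f_pos - f_neg| > 0.02 and
f_pos + f_neg > 0.2, ranked by the contrast
delta(m) = (f_pos - f_neg) / (f_pos + f_neg)).  A support-vector machine
with a linear, polynomial (alpha x.y + c)^d or RBF exp(-gamma |x-y|^2)
kernel classifies abstracts by the sign of its score; scores within a
margin of zero are left unclassified and excluded from the metrics.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from sklearn.svm import SVC

from .stemming import DEFAULT_EXCEPTION_PREFIXES, stem

__all__ = [
    "AbstractLabel",
    "FeatureSet",
    "ConfusionMatrix",
    "SVMConfig",
    "Metrics",
    "label_abstract",
    "tokenize_stem",
    "feature_counts",
    "select_features",
    "split_train_validation",
    "vectorize",
    "RelevanceSVM",
    "train",
    "classify",
    "metrics",
    "load_stopwords",
    "load_feature_set",
    "evaluate_validation",
]

LABEL_THRESHOLD = 4
POSITIVE, NEGATIVE, UNUSED, UNCLASSIFIED = "positive", "negative", "unused", "unclassified"


# --- labelling ---------------------------------------------------------------

@dataclass(frozen=True)
class AbstractLabel:
    n_int: int
    n_non: int
    label: str


def label_abstract(n_int: int, n_non: int, threshold: int = LABEL_THRESHOLD) -> AbstractLabel:
    """Label one abstract from its interface / non-interface residue counts."""
    if n_int < 0 or n_non < 0:
        raise ValueError("residue counts must be non-negative")
    if (n_int - n_non > threshold) or (n_non == 0 and n_int > 0):
        label = POSITIVE
    elif (n_non - n_int > threshold) or (n_non > 0 and n_int == 0):
        label = NEGATIVE
    else:
        label = UNUSED
    return AbstractLabel(n_int, n_non, label)


# --- tokenization ------------------------------------------------------------

_TOKEN_RE = re.compile(r"[a-z][a-z0-9+\-]*")


def load_stopwords() -> set[str]:
    text = resources.files("dockmine.data").joinpath("stopwords.txt").read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


def tokenize_stem(
    text: str,
    stopword_list: set[str] | None = None,
    exception_map: dict[str, str] | None = None,
    extra_stop_terms: set[str] | None = None,
) -> Counter:
    """Lower-case, purge stop words (plus caller-supplied protein and
    amino-acid names), stem, and return a stem multiset."""
    stops = load_stopwords() if stopword_list is None else stopword_list
    extra = {t.lower() for t in (extra_stop_terms or set())}
    prefixes = DEFAULT_EXCEPTION_PREFIXES if exception_map is None else exception_map
    counts: Counter = Counter()
    for token in _TOKEN_RE.findall(text.lower()):
        if token in stops or token in extra:
            continue
        counts[stem(token, prefixes)] += 1
    return counts


# --- feature selection -------------------------------------------------------

@dataclass
class FeatureSet:
    """An ordered list of stems usable as bag-of-words dimensions."""

    stems: list[str]
    origin: str = "manual"  # "manual MFxx" | "automated AFxx"
    delta: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.stems)) != len(self.stems):
            raise ValueError("feature stems must be unique")

    def __len__(self) -> int:
        return len(self.stems)

    def truncate(self, n: int) -> "FeatureSet":
        """Keep the n stems of largest |delta| (the AFxx family)."""
        if not self.delta:
            raise ValueError("truncation needs per-stem delta values")
        kept = sorted(self.stems, key=lambda m: -abs(self.delta[m]))[:n]
        kept = [m for m in self.stems if m in set(kept)]  # preserve delta ordering
        return FeatureSet(kept, origin=f"automated AF{n}",
                          delta={m: self.delta[m] for m in kept})


def load_feature_set(name: str) -> FeatureSet:
    """Load a packaged stem list, e.g. ``MF50`` or ``AF143``."""
    fname = name.lower() + ".txt"
    text = resources.files("dockmine.data.feature_sets").joinpath(fname).read_text()
    stems = [line.strip() for line in text.splitlines() if line.strip()]
    origin = "manual " + name if name.upper().startswith("MF") else "automated " + name
    return FeatureSet(stems, origin=origin)


def feature_counts(training_counts: list[Counter]) -> dict[str, float]:
    """Normalized per-stem counts f_k(m) for one class's training abstracts:
    the mean over abstracts of the stem's occurrence count."""
    if not training_counts:
        raise ValueError("empty training class")
    total: Counter = Counter()
    for c in training_counts:
        total.update(c)
    n = len(training_counts)
    return {m: cnt / n for m, cnt in total.items()}


def select_features(
    f_pos: dict[str, float],
    f_neg: dict[str, float],
    diff_min: float = 0.02,
    sum_min: float = 0.2,
) -> FeatureSet:
    """Select stems with |f_pos - f_neg| > diff_min and f_pos + f_neg > sum_min,
    sorted by contrast delta descending (ties broken alphabetically)."""
    universe = sorted(set(f_pos) | set(f_neg))
    selected: list[tuple[float, str]] = []
    delta: dict[str, float] = {}
    for m in universe:
        fp, fn = f_pos.get(m, 0.0), f_neg.get(m, 0.0)
        if abs(fp - fn) > diff_min and fp + fn > sum_min:
            d = (fp - fn) / (fp + fn)
            selected.append((-d, m))
            delta[m] = d
    selected.sort()
    stems = [m for _, m in selected]
    return FeatureSet(stems, origin=f"automated AF{len(stems)}", delta=delta)


# --- train/validation split --------------------------------------------------

def split_train_validation(
    pos_ids: list, neg_ids: list, train_frac: float = 0.8, seed: int = 0
) -> tuple[list, list, list, list]:
    """Per-class randomized 80/20 split; floor(train_frac * n) per class
    goes to training.  Deterministic under the seed."""
    rng = np.random.default_rng(seed)
    out = []
    for ids in (pos_ids, neg_ids):
        ids = list(ids)
        n_train = int(len(ids) * train_frac + 1e-9)  # floor, robust to FP error
        perm = rng.permutation(len(ids))
        out.append([ids[i] for i in perm[:n_train]])
        out.append([ids[i] for i in perm[n_train:]])
    train_pos, val_pos, train_neg, val_neg = out
    return train_pos, train_neg, val_pos, val_neg


# --- SVM ---------------------------------------------------------------------

@dataclass
class SVMConfig:
    """Kernel configuration.

    linear is polynomial with d = 1; polynomial K = (alpha x.y + c)^d with
    defaults alpha = 1, c = 0; RBF K = exp(-gamma |x-y|^2).  ``margin`` is
    the half-width of the score band around zero inside which an abstract
    is left unclassified.
    """

    kernel: str = "linear"  # linear | poly | rbf
    degree: int = 1
    gamma: float = 1.0
    alpha: float = 1.0
    c: float = 0.0
    margin: float = 0.05

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "poly", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


def vectorize(counts: Counter, features: FeatureSet) -> np.ndarray:
    """Raw per-abstract stem counts J_i(m) on the feature set's dimensions."""
    return np.array([counts.get(m, 0) for m in features.stems], dtype=float)


class RelevanceSVM:
    """A margin classifier over bag-of-words vectors.

    fit() trains a support-vector machine on labelled vectors; score()
    returns the signed decision value; classify() applies the sign with
    the unclassified margin band.
    """

    def __init__(self, config: SVMConfig | None = None, features: FeatureSet | None = None):
        self.config = config or SVMConfig()
        self.features = features
        cfg = self.config
        if cfg.kernel == "linear" or (cfg.kernel == "poly" and cfg.degree == 1):
            self._svc = SVC(kernel="poly", degree=1, gamma=cfg.alpha, coef0=cfg.c)
        elif cfg.kernel == "poly":
            self._svc = SVC(kernel="poly", degree=cfg.degree, gamma=cfg.alpha, coef0=cfg.c)
        else:
            self._svc = SVC(kernel="rbf", gamma=cfg.gamma)

    def fit(self, vectors: np.ndarray, labels: list[str]) -> "RelevanceSVM":
        y = np.array([1 if lab == POSITIVE else -1 for lab in labels])
        if len(set(y)) < 2:
            raise ValueError("training set must contain both classes")
        self._svc.fit(np.asarray(vectors, dtype=float), y)
        return self

    def score(self, vectors: np.ndarray) -> np.ndarray:
        return self._svc.decision_function(np.asarray(vectors, dtype=float))

    def classify(self, vectors: np.ndarray, margin: float | None = None) -> list[str]:
        m = self.config.margin if margin is None else margin
        out = []
        for s in self.score(np.atleast_2d(vectors)):
            if abs(s) < m:
                out.append(UNCLASSIFIED)
            else:
                out.append(POSITIVE if s > 0 else NEGATIVE)
        return out


def train(config: SVMConfig, vectors: np.ndarray, labels: list[str],
          features: FeatureSet | None = None) -> RelevanceSVM:
    return RelevanceSVM(config, features).fit(vectors, labels)


def classify(classifier: RelevanceSVM, vector: np.ndarray, margin: float | None = None) -> str:
    return classifier.classify(np.atleast_2d(vector), margin)[0]


# --- metrics -----------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """Precision, recall, accuracy (fractions) and the Matthews correlation
    coefficient; a metric with zero denominator is None (undefined)."""

    precision: float | None
    recall: float | None
    accuracy: float | None
    mcc: float | None


def metrics(cm: ConfusionMatrix) -> Metrics:
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    accuracy = (tp + tn) / cm.total if cm.total else None
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / denom2**0.5 if denom2 else None
    return Metrics(precision, recall, accuracy, mcc)


def evaluate_validation(
    classifier: RelevanceSVM,
    vectors: np.ndarray,
    labels: list[str],
    margin: float | None = None,
) -> tuple[ConfusionMatrix, Metrics]:
    """Classify a validation set and compute the confusion matrix over the
    classified (non-margin) abstracts only."""
    predicted = classifier.classify(np.asarray(vectors, dtype=float), margin)
    tp = fp = tn = fn = 0
    for truth, pred in zip(labels, predicted):
        if pred == UNCLASSIFIED:
            continue
        if truth == POSITIVE:
            if pred == POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if pred == NEGATIVE:
                tn += 1
            else:
                fp += 1
    cm = ConfusionMatrix(tp, fp, tn, fn)
    return cm, metrics(cm)
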