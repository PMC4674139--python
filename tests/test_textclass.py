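"""Abstract labelling, tokenization, feature selection and the SVM filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dockmine import textclass as tc
from dockmine.stemming import porter_stem, stem


class TestLabelAbstract:
    @pytest.mark.parametrize("n_int,n_non,expected", [
        (3, 0, "positive"),     # no non-interface residues, some interface
        (10, 5, "positive"),    # difference 5 > 4
        (1, 6, "negative"),     # difference 5 > 4
        (0, 2, "negative"),     # interface-free
        (3, 2, "unused"),       # fails all four conditions
        (5, 1, "unused"),       # difference exactly 4 is not enough
        (1, 5, "unused"),
        (0, 0, "unused"),       # no residues at all
    ])
    def test_eq2_conditions(self, n_int, n_non, expected):
        assert tc.label_abstract(n_int, n_non).label == expected

    @given(st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_partition_exhaustive_and_exclusive(self, n_int, n_non):
        pos = (n_int - n_non > 4) or (n_non == 0 and n_int > 0)
        neg = (n_non - n_int > 4) or (n_non > 0 and n_int == 0)
        label = tc.label_abstract(n_int, n_non).label
        assert label in ("positive", "negative", "unused")
        assert (label == "positive") == pos
        assert (label == "negative") == (neg and not pos)


class TestStemming:
    @pytest.mark.parametrize("word,root", [
        ("binding", "bind"), ("binds", "bind"), ("bound", "bound"),
        ("interaction", "interact"), ("interactions", "interact"),
        ("conformational", "conform"), ("allosteric", "alloster"),
        ("recognition", "recognit"), ("conserved", "conserv"),
    ])
    def test_porter_reaches_table_roots(self, word, root):
        assert porter_stem(word) == root

    @pytest.mark.parametrize("word", ["include", "inclusion", "including", "inclusive"])
    def test_inclu_family_collapsed(self, word):
        assert stem(word) == "inclu"

    @pytest.mark.parametrize("word", [
        "mutant", "mutagenesis", "mutation", "mutagen", "mutated", "mutations",
    ])
    def test_muta_family_collapsed(self, word):
        assert stem(word) == "muta"


class TestTokenizeStem:
    def test_stopwords_and_case(self):
        counts = tc.tokenize_stem("The binding AND the bound complexes")
        assert counts["bind"] == 1 and counts["bound"] == 1 and counts["complex"] == 1
        assert "the" not in counts and "and" not in counts

    def test_protein_and_residue_names_excluded_via_extra_stops(self):
        counts = tc.tokenize_stem(
            "Trypsin binds serine", extra_stop_terms={"trypsin", "serine"}
        )
        assert counts == {"bind": 1}

    def test_multiset_counts(self):
        counts = tc.tokenize_stem("binding binding binds")
        assert counts["bind"] == 3


class TestFeatureCounts:
    def test_normalized_mean_count(self):
        from collections import Counter

        abstracts = [Counter({"bind": 2}) for _ in range(10)]
        assert tc.feature_counts(abstracts)["bind"] == pytest.approx(2.0)

    def test_absent_stem_is_zero(self):
        from collections import Counter

        f = tc.feature_counts([Counter({"bind": 1})])
        assert f.get("conform", 0.0) == 0.0

    def test_hand_computed_values(self):
        from collections import Counter

        # 3 abstracts: counts of "bind" are 1, 0, 5 -> f = 2.0
        abstracts = [Counter({"bind": 1}), Counter(), Counter({"bind": 5})]
        assert tc.feature_counts(abstracts)["bind"] == pytest.approx(2.0)

    def test_empty_class_is_error(self):
        with pytest.raises(ValueError):
            tc.feature_counts([])


class TestSelectFeatures:
    def test_thresholds(self):
        f_pos = {"a": 0.15, "b": 0.11, "c": 0.05}
        f_neg = {"a": 0.10, "b": 0.10, "c": 0.01}
        fs = tc.select_features(f_pos, f_neg)
        assert fs.stems == ["a"]  # b fails |diff|, c fails sum
        assert fs.delta["a"] == pytest.approx(0.2)

    def test_sorted_by_delta_descending(self):
        f_pos = {"up": 0.5, "down": 0.1, "mid": 0.3}
        f_neg = {"up": 0.1, "down": 0.5, "mid": 0.2}
        fs = tc.select_features(f_pos, f_neg)
        assert fs.stems == ["up", "mid", "down"]

    def test_invariant_to_input_ordering(self):
        f_pos = {"a": 0.3, "b": 0.4, "c": 0.5}
        f_neg = {"c": 0.1, "b": 0.1, "a": 0.1}
        a = tc.select_features(f_pos, f_neg)
        b = tc.select_features(dict(reversed(list(f_pos.items()))),
                               dict(reversed(list(f_neg.items()))))
        assert a.stems == b.stems

    def test_truncation_keeps_largest_contrast(self):
        f_pos = {"a": 0.5, "b": 0.3, "c": 0.25}
        f_neg = {"a": 0.05, "b": 0.2, "c": 0.05}
        fs = tc.select_features(f_pos, f_neg)
        small = fs.truncate(2)
        assert set(small.stems) == {"a", "c"}  # "b" has the smallest |delta|


class TestSplit:
    def test_printed_split_sizes(self):
        tr_p, tr_n, va_p, va_n = tc.split_train_validation(
            list(range(450)), list(range(855)), seed=0
        )
        assert (len(tr_p), len(tr_n)) == (360, 684)
        assert (len(va_p), len(va_n)) == (90, 171)
        assert len(va_p) + len(va_n) == 261

    def test_small_class_floor(self):
        tr_p, tr_n, va_p, va_n = tc.split_train_validation(list(range(10)), list(range(10)))
        assert len(tr_p) == len(tr_n) == 8

    def test_deterministic_under_seed_and_disjoint(self):
        a = tc.split_train_validation(list(range(50)), list(range(70)), seed=5)
        b = tc.split_train_validation(list(range(50)), list(range(70)), seed=5)
        assert a == b
        tr_p, tr_n, va_p, va_n = a
        assert set(tr_p).isdisjoint(va_p) and set(tr_n).isdisjoint(va_n)
        assert set(tr_p) | set(va_p) == set(range(50))


class TestPackagedFeatureSets:
    @pytest.mark.parametrize("name,size", [
        ("MF60", 60), ("MF50", 50), ("MF40", 40), ("MF30", 30),
        ("MF20", 20), ("MF10", 10), ("AF143", 143),
    ])
    def test_sets_load_with_printed_sizes(self, name, size):
        fs = tc.load_feature_set(name)
        assert len(fs) == size
        assert len(set(fs.stems)) == size

    def test_mf_subsets_nested_in_mf60(self):
        base = set(tc.load_feature_set("MF60").stems)
        # spelling drift in the printed smaller sets is tolerated loosely:
        # at least 90% of each subset appears verbatim in the full set
        for name in ("MF50", "MF40"):
            sub = tc.load_feature_set(name).stems
            hit = sum(1 for s in sub if s in base)
            assert hit / len(sub) >= 0.9


class TestSVM:
    def _separable(self, n=30, seed=0, loc=(2.0, -2.0)):
        rng = np.random.default_rng(seed)
        pos = rng.normal(loc=loc[0], size=(n, 4))
        neg = rng.normal(loc=loc[1], size=(n, 4))
        X = np.vstack([pos, neg])
        y = ["positive"] * n + ["negative"] * n
        return X, y

    def test_separable_data_training_mcc_is_one(self):
        X, y = self._separable()
        model = tc.train(tc.SVMConfig(kernel="linear", margin=0.0), X, y)
        cm, mets = tc.evaluate_validation(model, X, y)
        assert mets.mcc == pytest.approx(1.0)

    def test_label_flip_negates_scores(self):
        X, y = self._separable()
        flipped = ["negative" if lab == "positive" else "positive" for lab in y]
        m1 = tc.train(tc.SVMConfig(kernel="linear"), X, y)
        m2 = tc.train(tc.SVMConfig(kernel="linear"), X, flipped)
        assert np.allclose(m1.score(X), -m2.score(X), atol=1e-2)  # optimizer tolerance

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            tc.train(tc.SVMConfig(), X, ["positive"] * 4)

    @pytest.mark.parametrize("kernel,kw", [
        ("poly", {"degree": 2}), ("rbf", {"gamma": 0.5}),
    ])
    def test_nonlinear_kernels_fit(self, kernel, kw):
        # clusters on one side of the origin: a homogeneous even-degree
        # polynomial kernel cannot separate antipodal clusters
        X, y = self._separable(loc=(5.0, 1.0))
        model = tc.train(tc.SVMConfig(kernel=kernel, margin=0.0, **kw), X, y)
        _, mets = tc.evaluate_validation(model, X, y)
        assert mets.mcc > 0.9

    def test_margin_band_yields_unclassified(self):
        X, y = self._separable()
        model = tc.train(tc.SVMConfig(kernel="linear"), X, y)
        scores = model.score(X)
        wide = float(np.abs(scores).max()) + 1.0
        assert set(model.classify(X, margin=wide)) == {"unclassified"}
        assert "unclassified" not in model.classify(X, margin=0.0)

    def test_margin_monotonic(self):
        """A wider margin never classifies an abstract a narrower one left
        unclassified."""
        X, y = self._separable(seed=3)
        model = tc.train(tc.SVMConfig(kernel="linear"), X, y)
        narrow = model.classify(X, margin=0.2)
        wide = model.classify(X, margin=0.8)
        for a, b in zip(narrow, wide):
            if a == "unclassified":
                assert b == "unclassified"

    def test_unclassified_excluded_from_metrics(self):
        X, y = self._separable()
        model = tc.train(tc.SVMConfig(kernel="linear"), X, y)
        cm, _ = tc.evaluate_validation(model, X, y, margin=1e9)
        assert cm.total == 0


class TestMetrics:
    def test_undefined_metrics_are_none_not_zero(self):
        m = tc.metrics(tc.ConfusionMatrix(0, 0, 5, 0))
        assert m.precision is None and m.recall is None
        assert m.accuracy == pytest.approx(1.0)
        all_zero = tc.metrics(tc.ConfusionMatrix(0, 0, 0, 0))
        assert all_zero.accuracy is None and all_zero.mcc is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            tc.ConfusionMatrix(-1, 0, 0, 0)
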