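import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdpep import (
    PQDensityClassifier,
    classify_pq,
    pq_score,
    sweep_table,
    tune_threshold,
    window_profile,
    window_sweep,
)
from cdpep.sequences import AMINO_ACIDS

from conftest import make_dataset, random_peptide


def brute_force_profile(seq, w):
    """Independent oracle: enumerate every substring of length w."""
    return [
        sum(1 for c in seq[i : i + w] if c in "PQ") / w
        for i in range(len(seq) - w + 1)
    ]


class TestWindowProfile:
    @pytest.mark.parametrize(
        "seq,w,scores",
        [
            ("AAAAQPQPQ", 5, [0.2, 0.4, 0.6, 0.8, 1.0]),
            ("AAAAAAAAA", 3, [0.0] * 7),
            ("PPPPPPPPP", 7, [1.0] * 3),
        ],
    )
    def test_examples(self, seq, w, scores):
        prof = window_profile(seq, w)
        assert list(prof.window_scores) == pytest.approx(scores)
        assert prof.max_score == max(scores)

    def test_window_count_and_score_quantization(self):
        prof = window_profile("QPLAYACDEFGHIK", 4)
        assert len(prof.window_scores) == 14 - 4 + 1
        for s in prof.window_scores:
            assert round(s * 4) == pytest.approx(s * 4)  # k/w for integer k

    def test_window_longer_than_peptide_rejected(self):
        with pytest.raises(ValueError, match="shorten the window"):
            window_profile("ACDEF", 6)

    def test_agrees_with_brute_force(self):
        rng = random.Random(123)
        for _ in range(300):
            seq = random_peptide(rng)
            for w in range(3, 10):
                if w > len(seq):
                    continue
                assert list(window_profile(seq, w).window_scores) == pytest.approx(
                    brute_force_profile(seq, w)
                )


class TestPqScore:
    def test_two_thirds_window(self):
        # "QAP" holds 2 of 3; no 3-mer reaches 3
        assert pq_score("QAPAQAPAQ", 3) == pytest.approx(2 / 3)

    @settings(max_examples=150, derandomize=True)
    @given(st.text(alphabet=AMINO_ACIDS, min_size=5, max_size=25), st.integers(3, 5))
    def test_reversal_invariance(self, seq, w):
        assert pq_score(seq, w) == pytest.approx(pq_score(seq[::-1], w))

    @settings(max_examples=150, derandomize=True)
    @given(
        st.text(alphabet=AMINO_ACIDS, min_size=5, max_size=25),
        st.integers(3, 5),
        st.data(),
    )
    def test_monotone_under_pq_substitution(self, seq, w, data):
        pos = data.draw(st.integers(0, len(seq) - 1))
        mutated = seq[:pos] + "P" + seq[pos + 1 :]
        assert pq_score(mutated, w) >= pq_score(seq, w) - 1e-12

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet=AMINO_ACIDS, min_size=5, max_size=25))
    def test_appending_p_never_decreases(self, seq):
        assert pq_score(seq + "P", 3) >= pq_score(seq, 3)


class TestClassify:
    def test_published_operating_point(self):
        # reported w=5 operating threshold 0.410
        assert classify_pq("AAAQPQAAAA", 5, 0.410) == "positive"  # score 0.6
        assert classify_pq("AAQPAAAAAA", 5, 0.410) == "negative"  # score 0.4

    def test_boundary_is_positive(self):
        assert classify_pq("AAAAAAAAA", 5, 0.0) == "positive"


class TestTuneThreshold:
    def test_perfect_separation_selects_smallest_balanced(self):
        ds = make_dataset(["PPPPPPPPP"] * 3, "positive", "p")
        neg = make_dataset(["AAAAAAAAA", "ACDEFGHIK", "LMNRSTVWY"], "negative", "n")
        ds.records += neg.records
        t = tune_threshold(ds, 5)
        assert t.selected_threshold == pytest.approx(0.01)
        assert t.sensitivity == 100.0 and t.specificity == 100.0
        assert t.auroc == pytest.approx(1.0)

    def test_exhaustive_grid_selection(self):
        # scores: pos {1.0, 0.8}, neg {0.2, 0.0} -> first fully-separating
        # grid point is 0.21
        ds = make_dataset(["PPPPP", "PPPPA"], "positive", "p")
        ds.records += make_dataset(["PAAAA", "AAAAA"], "negative", "n").records
        t = tune_threshold(ds, 5)
        assert t.selected_threshold == pytest.approx(0.21)
        assert t.sensitivity == 100.0 and t.specificity == 100.0

    def test_single_class_rejected(self):
        ds = make_dataset(["PPPPPPPPP"] * 3, "positive")
        with pytest.raises(ValueError):
            tune_threshold(ds, 5)

    def test_selected_threshold_in_grid(self, small_ds):
        t = tune_threshold(small_ds, 5)
        assert t.selected_threshold in t.grid["threshold"].values


class TestWindowSweep:
    def test_seven_rows_default(self, small_ds):
        tunings = window_sweep(small_ds)
        table = sweep_table(tunings)
        assert list(table["window_size"]) == list(range(3, 10))
        assert ((table["threshold"] >= 0) & (table["threshold"] <= 1)).all()
        # balanced classes: accuracy between sens and spec
        lo = np.minimum(table["sensitivity"], table["specificity"])
        hi = np.maximum(table["sensitivity"], table["specificity"])
        assert ((table["accuracy"] >= lo - 1e-9) & (table["accuracy"] <= hi + 1e-9)).all()

    def test_nine_mers_never_skipped(self):
        ds = make_dataset(["PQPQPQPQP", "QPQPQPQPQ"], "positive", "p")
        ds.records += make_dataset(["ACDEFGHIK", "LMNRSTVWY"], "negative", "n").records
        for t in window_sweep(ds):
            assert t.n_skipped == 0

    def test_short_peptides_skipped_for_large_windows(self):
        ds = make_dataset(["PQPQP", "PQPQPQPQP"], "positive", "p")
        ds.records += make_dataset(["ACDEF", "ACDEFGHIK"], "negative", "n").records
        t7 = tune_threshold(ds, 7)
        assert t7.n_skipped == 2


class TestEstimator:
    def test_fixed_threshold_skips_tuning(self):
        clf = PQDensityClassifier(threshold=0.41).fit([], None)
        assert clf.threshold_ == 0.41
        assert clf.predict(["AAAAQPQPQA"]).tolist() == [1]

    def test_fit_tunes_and_predicts(self, small_ds):
        clf = PQDensityClassifier(window_size=5)
        clf.fit(small_ds.sequences(), small_ds.y())
        assert 0.0 <= clf.threshold_ <= 1.0
        proba = clf.predict_proba(small_ds.sequences()[:3])
        assert proba.shape == (3, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        clf = PQDensityClassifier(window_size=6, threshold=0.3)
        assert clone(clf).get_params() == clf.get_params()
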