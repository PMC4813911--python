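"""Tests of splitting, classifiers, metrics and the evaluation sweep."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from helpers import recount_metrics
from qsa import (
    ClassifierSpec,
    ProtocolSpec,
    SignalModelParams,
    SplitSpec,
    compute_metrics,
    derive_seed,
    generate_session,
    get_block,
    ovr_combine,
    repeated_eval,
    run_sweep,
    split,
    train_eval,
)
from qsa.sessions import ConfigError


def make_clusters(rng, n_per_class=30, spread=0.05):
    """Three well-separated Gaussian clusters in 4-D feature space."""
    centers = np.array([[0, 0, 0, 0], [5, 5, 0, 0], [0, 0, 5, 5]], dtype=float)
    X = np.vstack([
        centers[c] + spread * rng.normal(size=(n_per_class, 4)) for c in range(3)
    ])
    y = np.repeat([0, 1, 2], n_per_class)
    return X, y


class TestSplit:
    def test_stratified_30_70_on_80_segments(self):
        labels = np.array([0] * 40 + [1] * 20 + [2] * 20)
        train, val = split((None, labels), SplitSpec(seed=3), repeat_index=0)
        assert train.size == 24 and val.size == 56
        for cls in (0, 1, 2):
            assert np.count_nonzero(labels[train] == cls) >= 1
        assert np.intersect1d(train, val).size == 0
        assert np.union1d(train, val).size == 80

    def test_split_is_seed_and_repeat_deterministic(self):
        labels = np.repeat([0, 1, 2], 10)
        spec = SplitSpec(seed=9)
        a = split((None, labels), spec, repeat_index=4)
        b = split((None, labels), spec, repeat_index=4)
        np.testing.assert_array_equal(a[0], b[0])
        c = split((None, labels), spec, repeat_index=5)
        assert not np.array_equal(a[0], c[0])

    def test_full_fraction_rejected(self):
        with pytest.raises(ConfigError):
            SplitSpec(train_fraction=1.0)

    def test_missing_class_rejected(self):
        labels = np.repeat([0, 1], 10)
        with pytest.raises(ConfigError, match=r"\[2\]"):
            split((None, labels), SplitSpec(seed=0))


class TestClassifiers:
    @pytest.mark.parametrize("kind", ["dt", "knn", "svm"])
    def test_separable_clusters_classified_perfectly(self, rng, kind):
        X, y = make_clusters(rng)
        spec = SplitSpec(seed=1)
        idx = split((X, y), spec, 0)
        res = train_eval((X, y), ClassifierSpec(kind), idx, seed=1)
        assert res.acc_val == 1.0
        assert np.trace(res.confusion) == res.confusion.sum()

    def test_shuffled_labels_fall_to_chance(self, rng):
        """Permutation null: destroying the label-feature link drops the
        decision tree to the chance band, far below the separable 1.0."""
        X, y = make_clusters(rng)
        y_shuffled = rng.permutation(y)
        spec = SplitSpec(seed=2)
        accs = [
            train_eval((X, y_shuffled), ClassifierSpec("dt"),
                       split((X, y_shuffled), spec, rep), seed=rep).acc_val
            for rep in range(20)
        ]
        assert 0.15 < float(np.mean(accs)) < 0.55

    def test_degenerate_training_set_rejected(self, rng):
        X, y = make_clusters(rng, n_per_class=4)
        train = np.arange(4)  # all class 0
        val = np.arange(4, 12)
        with pytest.raises(ConfigError, match="single class"):
            train_eval((X, y), ClassifierSpec("dt"), (train, val))

    def test_same_seed_reproduces_accuracies(self, rng):
        X, y = make_clusters(rng, spread=3.0)  # overlapping: nontrivial fits
        spec = SplitSpec(seed=5)
        idx = split((X, y), spec, 0)
        a = train_eval((X, y), ClassifierSpec("dt"), idx, seed=7)
        b = train_eval((X, y), ClassifierSpec("dt"), idx, seed=7)
        assert a.acc_train == b.acc_train and a.acc_val == b.acc_val

    def test_unknown_kind_and_hyperparams_rejected(self):
        with pytest.raises(ConfigError):
            ClassifierSpec("lda")
        with pytest.raises(ConfigError, match="unrecognised"):
            ClassifierSpec("knn", {"kernel_scale": 2.0})


class TestOvrCombine:
    def test_unique_positive_machine_wins(self):
        assert ovr_combine([[2.0, -1.0, -1.0]])[0] == 0
        assert ovr_combine([[-1.0, 3.0, -1.0]])[0] == 1

    def test_zero_hot_resolves_to_least_negative(self):
        assert ovr_combine([[-3.0, -1.0, -2.0]])[0] == 1

    def test_exact_tie_goes_to_lowest_class(self):
        assert ovr_combine([[0.5, 0.5, -1.0]])[0] == 0

    def test_agrees_with_codeword_matching_for_single_positive_patterns(self):
        """Exhaustive check over sign patterns with exactly one positive
        machine: argmax equals the matching codeword."""
        for cls in range(3):
            values = np.full(3, -1.0)
            values[cls] = 1.0
            for jitter in (0.0, 0.3, -0.3):
                v = values + np.array([jitter, jitter / 2, -jitter]) * 0.1
                v[cls] = abs(v[cls])  # keep the positive machine positive
                codeword = np.argmax(np.eye(3)[cls])
                assert ovr_combine([v])[0] == codeword


class TestMetrics:
    HAND = np.array([[5, 1, 0], [2, 6, 0], [0, 1, 5]])

    def test_hand_counted_matrix(self):
        """Frozen values recounted by hand from the defining ratios."""
        rep = compute_metrics(self.HAND)
        assert rep.rt == Fraction(16, 20)
        assert rep.et == Fraction(4, 20)
        assert rep.sensitivity[0] == Fraction(5, 6)
        assert rep.specificity[0] == Fraction(11, 14)
        assert rep.accuracy[0] == Fraction(5, 7)
        assert rep.false_alarm[0] == 1 - Fraction(11, 14)
        assert rep.positive_likelihood[0] == Fraction(5, 6) / (1 - Fraction(11, 14))
        assert rep.negative_likelihood[0] == (1 - Fraction(5, 6)) / Fraction(11, 14)

    def test_hand_matrix_agrees_with_pair_recount(self):
        rep = compute_metrics(self.HAND)
        for d in range(3):
            ref = recount_metrics(self.HAND, d)
            assert float(rep.sensitivity[d]) == pytest.approx(ref["S"])
            assert float(rep.specificity[d]) == pytest.approx(ref["Sp"])
            assert float(rep.accuracy[d]) == pytest.approx(ref["A"])

    def test_perfect_classifier(self):
        rep = compute_metrics(10 * np.eye(3, dtype=int))
        assert rep.rt == 1 and rep.et == 0
        for d in range(3):
            assert rep.sensitivity[d] == 1
            assert rep.specificity[d] == 1
            assert rep.negative_likelihood[d] == 0
            assert rep.positive_likelihood[d] is None  # Sp = 1: undefined

    def test_perfect_sensitivity_forces_zero_negative_likelihood(self):
        # Row 0 fully correct while other rows spill: S_0 = 1 → NP_0 = 0.
        cm = np.array([[8, 0, 0], [3, 4, 1], [2, 1, 5]])
        rep = compute_metrics(cm)
        assert rep.sensitivity[0] == 1
        assert rep.negative_likelihood[0] == 0

    def test_undefined_flags_are_none_not_nan(self):
        # No sample of class 2 and nothing predicted as class 2.
        cm = np.array([[4, 1, 0], [1, 4, 0], [0, 0, 0]])
        rep = compute_metrics(cm)
        assert rep.sensitivity[2] is None
        assert rep.accuracy[2] is None

    def test_weighted_lr_applies_prevalence_odds(self):
        rep = compute_metrics(self.HAND)
        wrep = compute_metrics(self.HAND, weighted_lr=True)
        odds = Fraction(6, 14)  # class 0: n_0 / (N - n_0)
        assert wrep.positive_likelihood[0] == rep.positive_likelihood[0] * odds
        assert wrep.negative_likelihood[0] == rep.negative_likelihood[0] / odds

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_metrics(np.zeros((3, 3), dtype=int))

    def test_to_series_shape(self):
        series = compute_metrics(self.HAND).to_series()
        assert list(series.index[:2]) == ["RT", "ET"]
        assert len(series) == 2 + 6 * 3


@pytest.fixture(scope="module")
def tiny_session():
    proto = ProtocolSpec(cue_duration=1.5, rest_duration=1.0, n_cues=6,
                         sample_rate=32.0)
    return generate_session(proto, SignalModelParams(seed=21))


class TestSweep:
    def test_grid_cardinality_and_determinism(self, tiny_session):
        spec = SplitSpec(train_fraction=0.4, repeats=3, seed=17)
        args = (
            [("s0", tiny_session)],
            [get_block(1), get_block(2)],
            [1, 2],
            [ClassifierSpec("dt")],
            spec,
        )
        result = run_sweep(*args)
        assert len(result.frame) == 1 * 2 * 2 * 1 * 3
        again = run_sweep(*args)
        pd.testing.assert_frame_equal(result.frame, again.frame)

    def test_aggregates_recomputed_from_rows(self, tiny_session):
        spec = SplitSpec(train_fraction=0.4, repeats=3, seed=17)
        result = run_sweep([("s0", tiny_session)], [get_block(1)], [1, 2],
                           [ClassifierSpec("dt")], spec)
        by_dt = result.by_dt().set_index("dt")
        for dt in (1, 2):
            rows = result.frame[result.frame["dt"] == dt]["acc_val"]
            assert by_dt.loc[dt, "mean"] == pytest.approx(rows.mean())
            assert by_dt.loc[dt, "max"] == rows.max()
            assert by_dt.loc[dt, "min"] == rows.min()

    def test_failing_cell_recorded_and_sweep_continues(self, tiny_session):
        # Drop T7/T8 so block 2 cannot be built while block 1 still works.
        from qsa import EEGSession

        partial = EEGSession(
            tiny_session.sample_rate,
            ["FC5", "FC6", "P7", "P8"],
            tiny_session.data[:, :4],
            tiny_session.events,
        )
        spec = SplitSpec(train_fraction=0.4, repeats=2, seed=17)
        result = run_sweep([("s0", partial)], [get_block(1), get_block(2)],
                           [1], [ClassifierSpec("dt")], spec)
        ok = result.frame[result.frame["block"] == 1]
        bad = result.frame[result.frame["block"] == 2]
        assert (ok["error"] == "").all() and ok["acc_val"].notna().all()
        assert (bad["error"] != "").all() and bad["error"].str.contains("T7").all()

    def test_empty_grid_rejected(self, tiny_session):
        with pytest.raises(ConfigError, match="non-empty"):
            run_sweep([], [get_block(1)], [1], [ClassifierSpec("dt")], SplitSpec())

    def test_derive_seed_is_31_bit_and_stable(self):
        a = derive_seed(5, 1, 2, 3)
        assert a == derive_seed(5, 1, 2, 3)
        assert 0 <= a < 2**31
        assert a != derive_seed(5, 1, 2, 4)

    def test_repeated_eval_pools_all_validation_predictions(self, tiny_session):
        from qsa import QSAConfig, extract_features

        fm = extract_features(tiny_session, get_block(1), QSAConfig(dt=2))
        spec = SplitSpec(train_fraction=0.4, repeats=5, seed=3)
        frame, pooled = repeated_eval(fm, ClassifierSpec("knn"), spec)
        assert list(frame.columns) == ["repeat", "seed", "acc_train", "acc_val"]
        n_val = len(split(fm, spec, 0)[1])
        assert pooled.sum() == 5 * n_val
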