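"""Directionality scoring, permutation significance, network recovery."""

import numpy as np
import pytest

from renyite.embedding import EmbeddingSpec
from renyite.estimators import te_symbolic
from renyite.exceptions import InputError
from renyite.inference import (
    benjamini_hochberg,
    confusion_metrics,
    connectivity_matrix,
    direction_accuracy,
    directionality_index,
    network_significance,
    permutation_test,
    window_segment,
)
from renyite.simulate import kus_truth

SPEC = EmbeddingSpec(d=3, tau=1, u=1)


def symbolic_est(x, y):
    return te_symbolic(x, y, SPEC).value


def coupled_trials(rng, n_trials=12, l=300):
    """Target trials are one-sample-lagged copies of their source trials."""
    src, tgt = [], []
    for _ in range(n_trials):
        x = rng.normal(size=l + 1)
        src.append(x[1:])
        tgt.append(x[:-1] + 0.05 * rng.normal(size=l))
    return src, tgt


def independent_trials(rng, n_trials=12, l=300):
    return (
        [rng.normal(size=l) for _ in range(n_trials)],
        [rng.normal(size=l) for _ in range(n_trials)],
    )


class TestDirectionality:
    @pytest.mark.parametrize(
        "pair, expected", [((0.5, 0.2), 0.3), ((0.2, 0.5), -0.3), ((0.4, 0.4), 0.0)]
    )
    def test_index_is_a_difference(self, pair, expected):
        assert directionality_index(*pair) == pytest.approx(expected)

    def test_accuracy_counts_correct_signs(self):
        assert direction_accuracy([0.3, -0.1, 0.2], [1, -1, 1]) == 1.0
        assert direction_accuracy([0.3, 0.1], [1, -1]) == 0.5

    def test_ties_count_as_failures(self):
        assert direction_accuracy([0.0, 0.0], [1, -1]) == 0.0

    def test_chance_level_for_coin_flip_signs(self, rng):
        deltas = rng.choice([-1.0, 1.0], size=4000)
        acc = direction_accuracy(deltas, np.ones(4000, dtype=int))
        assert acc == pytest.approx(0.5, abs=0.03)

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            direction_accuracy([], [])


class TestPermutationTest:
    @pytest.mark.parametrize("scheme", ["trial_shuffle", "paired"])
    def test_constant_estimator_gives_p_one(self, rng, scheme):
        src, tgt = independent_trials(rng)
        res = permutation_test(
            src, tgt, lambda a, b: 1.0, n_perm=100, seed=0, scheme=scheme
        )
        assert res.p_value == 1.0
        assert not res.significant

    @pytest.mark.parametrize("scheme", ["trial_shuffle", "paired"])
    def test_strong_coupling_detected(self, rng, scheme):
        src, tgt = coupled_trials(rng)
        res = permutation_test(
            src, tgt, symbolic_est, n_perm=1000, seed=0, scheme=scheme
        )
        assert res.p_value <= 0.005

    def test_null_sample_count_and_p_range(self, rng):
        src, tgt = independent_trials(rng)
        res = permutation_test(src, tgt, symbolic_est, n_perm=150, seed=1)
        assert res.null_samples.shape == (150,)
        assert 0.0 < res.p_value <= 1.0

    def test_too_few_trials_rejected(self, rng):
        src, tgt = independent_trials(rng, n_trials=5)
        with pytest.raises(InputError):
            permutation_test(src, tgt, symbolic_est, n_perm=100)

    def test_false_positive_rate_is_calibrated(self, rng):
        # exactness of the permutation test: empirical FPR near the level
        hits = 0
        reps = 80
        for _ in range(reps):
            src, tgt = independent_trials(rng, n_trials=10, l=150)
            res = permutation_test(
                src, tgt, symbolic_est, n_perm=100, alpha_level=0.05,
                seed=int(rng.integers(2**31)), scheme="paired",
            )
            hits += res.significant
        assert hits / reps <= 0.12


class TestNetworkSignificance:
    def _three_channel_trials(self, rng, n_trials=12, l=250):
        trials = []
        for _ in range(n_trials):
            a = rng.normal(size=l + 1)
            b = a[:-1] + 0.05 * rng.normal(size=l)  # ch0 -> ch1, lag 1
            c = rng.normal(size=l)
            trials.append(np.vstack([a[1:], b, c]))
        return trials

    def test_detects_the_known_edge_with_clean_diagonal(self, rng):
        trials = self._three_channel_trials(rng)
        sig = network_significance(
            trials, symbolic_est, n_perm=200, seed=0, scheme="paired"
        )
        assert sig.significant[0, 1]
        assert not sig.significant.diagonal().any()
        assert np.isnan(sig.p_values.diagonal()).all()

    def test_invariant_under_channel_relabeling(self, rng):
        trials = self._three_channel_trials(rng)
        perm = np.array([2, 0, 1])
        relabeled = [t[perm] for t in trials]
        sig = network_significance(
            trials, symbolic_est, n_perm=120, seed=7, scheme="paired"
        )
        sig_rel = network_significance(
            relabeled, symbolic_est, n_perm=120, seed=7, scheme="paired"
        )
        assert np.array_equal(
            sig_rel.p_values, sig.p_values[np.ix_(perm, perm)], equal_nan=True
        )
        assert np.array_equal(
            sig_rel.significant, sig.significant[np.ix_(perm, perm)]
        )


class TestBenjaminiHochberg:
    def test_step_up_thresholds(self):
        mask = benjamini_hochberg(np.array([0.001, 0.02, 0.04, 0.8]), q=0.05)
        assert mask.tolist() == [True, True, False, False]

    def test_no_discovery_when_all_large(self):
        assert not benjamini_hochberg(np.array([0.3, 0.5, 0.9]), q=0.05).any()

    def test_discoveries_never_exceed_raw_level(self, rng):
        p = rng.random(50)
        mask = benjamini_hochberg(p, q=0.05)
        assert np.all(p[mask] <= 0.05)

    def test_raw_per_edge_option_is_less_strict(self, rng):
        trials = [rng.normal(size=(3, 200)) for _ in range(10)]
        fdr = network_significance(
            trials, symbolic_est, n_perm=100, seed=3, scheme="paired"
        )
        raw = network_significance(
            trials, symbolic_est, n_perm=100, seed=3, scheme="paired",
            correction="none",
        )
        assert np.array_equal(raw.p_values, fdr.p_values, equal_nan=True)
        assert np.all(raw.significant | ~fdr.significant)  # fdr subset of raw


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        truth = kus_truth()
        assert confusion_metrics(truth.to_matrix(), truth) == (1.0, 1.0, 1.0)

    def test_all_negative_prediction(self):
        acc, sens, spec = confusion_metrics(np.zeros((5, 5), bool), kus_truth())
        assert (acc, sens, spec) == (pytest.approx(14 / 20), 0.0, 1.0)

    def test_all_positive_prediction(self):
        pred = ~np.eye(5, dtype=bool)
        acc, sens, spec = confusion_metrics(pred, kus_truth())
        assert (acc, sens, spec) == (pytest.approx(6 / 20), 1.0, 0.0)

    def test_shape_mismatch(self):
        with pytest.raises(InputError):
            confusion_metrics(np.zeros((4, 4), bool), kus_truth())


class TestWindowing:
    def test_standard_eeg_windowing(self, rng):
        trial = rng.normal(size=(3, 1750))
        wins = window_segment(trial, 500, 0.5)
        assert len(wins) == 6
        assert all(w.shape == (3, 500) for w in wins)
        assert np.array_equal(wins[1], trial[:, 250:750])

    def test_single_window_when_exact(self, rng):
        trial = rng.normal(size=(2, 500))
        assert len(window_segment(trial, 500, 0.5)) == 1

    def test_window_longer_than_trial(self, rng):
        with pytest.raises(InputError):
            window_segment(rng.normal(size=(2, 500)), 600, 0.5)


class TestConnectivityMatrix:
    def test_two_channels(self, rng):
        w = rng.normal(size=(2, 300))
        cm = connectivity_matrix(w, symbolic_est, method="symbolic")
        assert cm.Lambda.shape == (2, 2)
        assert cm.Lambda[0, 0] == cm.Lambda[1, 1] == 0.0

    def test_failing_pair_poisons_only_its_cell(self, rng):
        w = rng.normal(size=(3, 300))

        def flaky(a, b):
            if np.array_equal(a, w[1]) and np.array_equal(b, w[2]):
                raise ValueError("boom")
            return 1.0

        with pytest.warns(UserWarning, match=r"\(1, 2\)"):
            cm = connectivity_matrix(w, flaky)
        assert np.isnan(cm.Lambda[1, 2])
        assert cm.Lambda[0, 1] == 1.0

    def test_kus_strongest_edge_is_the_direct_coupling(self):
        from renyite.simulate import simulate_kus, surrogate_eeg
        from renyite.estimators import te_kernel_alpha

        spec = EmbeddingSpec(d=3, tau=1, u=4)
        ranks = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ch = simulate_kus(surrogate_eeg(512, rng), rng)
            cm = connectivity_matrix(
                ch, lambda a, b: te_kernel_alpha(a, b, spec, 2.0).value
            )
            off = cm.Lambda[~np.eye(5, dtype=bool)]
            ranks.append(cm.Lambda[0, 1] >= np.quantile(off, 0.75))
        assert sum(ranks) >= 8  # 1 -> 2 among the largest entries
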