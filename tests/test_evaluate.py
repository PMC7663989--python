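"""Evaluation statistics: confusion, kappa, error rates, fit stats, K-S."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chubsdm import (confusion, error_rates, fit_stats, kappa, ks_test,
                     per_class_kappa)
from chubsdm.evaluate import ConfusionMatrix

# presence-absence confusion counts of the two published models
# (rows observed [absent, present], cols predicted [absent, present])
POTENTIAL_PA = np.array([[67, 76], [1, 1922]])
DISTURBANCE_PA = np.array([[95, 48], [1, 1922]])


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        obs = [0, 1, 2, 3, 2, 1]
        cm = confusion(obs, obs, labels=range(4))
        assert np.trace(cm.counts) == 6
        assert cm.counts.sum() == 6

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])

    def test_collapse_equals_direct(self):
        """Collapsing a 4-class matrix to presence-absence equals a
        direct 2-class tabulation (random instances)."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            obs = rng.integers(0, 4, 50)
            pred = rng.integers(0, 4, 50)
            via_collapse = confusion(obs, pred, labels=range(4)) \
                .presence_absence().counts
            direct = confusion((obs > 0).astype(int), (pred > 0).astype(int),
                               labels=[0, 1]).counts
            np.testing.assert_array_equal(via_collapse, direct)


class TestKappa:
    def test_published_model_kappas(self):
        assert kappa(POTENTIAL_PA) == pytest.approx(0.62, abs=0.005)
        assert kappa(DISTURBANCE_PA) == pytest.approx(0.78, abs=0.005)

    def test_identity_matrix(self):
        assert kappa(np.eye(4, dtype=int) * 5) == pytest.approx(1.0)

    def test_degenerate_marginals_signalled(self):
        with pytest.raises(ZeroDivisionError):
            kappa(np.array([[7, 0], [0, 0]]))

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.integers(0, 40), min_size=4, max_size=4),
           st.lists(st.integers(0, 40), min_size=16, max_size=16))
    def test_matches_brute_force_and_sklearn(self, cells2, cells4):
        """Oracle equivalence on random 2x2 and 4x4 matrices: direct
        agreement-minus-chance arithmetic, and scikit-learn recomputed
        from expanded label vectors."""
        from sklearn.metrics import cohen_kappa_score
        for m in (np.array(cells2).reshape(2, 2),
                  np.array(cells4).reshape(4, 4)):
            total = m.sum()
            po = np.trace(m) / total if total else 0
            pe = sum(m[i].sum() * m[:, i].sum() for i in range(len(m))) \
                / total**2 if total else 1
            if total == 0 or pe >= 1.0:
                with pytest.raises((ZeroDivisionError, ValueError)):
                    kappa(m)
                continue
            expected = (po - pe) / (1 - pe)
            assert kappa(m) == pytest.approx(expected, abs=1e-12)
            obs, pred = [], []
            for i in range(len(m)):
                for j in range(len(m)):
                    obs += [i] * m[i, j]
                    pred += [j] * m[i, j]
            if len(set(obs)) > 1 or len(set(pred)) > 1:
                assert kappa(m) == pytest.approx(
                    cohen_kappa_score(obs, pred), abs=1e-12)

    def test_bounds_and_perfect_agreement(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = rng.integers(0, 30, (3, 3))
            total = m.sum()
            if total == 0:
                continue
            pe = sum(m[i].sum() * m[:, i].sum() for i in range(3)) / total**2
            if pe >= 1.0:
                continue
            k = kappa(m)
            assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12
            assert (k == pytest.approx(1.0)) == (
                np.trace(m) == total and total > 0)

    def test_per_class_one_vs_rest(self):
        cm = ConfusionMatrix(np.array([[5, 1, 0], [2, 6, 1], [0, 1, 7]]),
                             ["a", "b", "c"])
        out = per_class_kappa(cm)
        # brute-force one-vs-rest for class "a"
        tp, fn, fp = 5, 1, 2
        tn = cm.counts.sum() - tp - fn - fp
        assert out["a"] == pytest.approx(kappa(np.array([[tn, fp], [fn, tp]])))


class TestErrorRates:
    def test_published_potential_rates(self):
        r = error_rates(POTENTIAL_PA)
        assert r["commission"] == pytest.approx(0.531, abs=0.001)
        assert r["prevalence"] == pytest.approx(0.9308, abs=0.0005)
        assert r["omission"] == pytest.approx(1 / 1923)

    def test_published_disturbance_commission(self):
        assert error_rates(DISTURBANCE_PA)["commission"] == \
            pytest.approx(0.336, abs=0.001)

    def test_zero_errors(self):
        r = error_rates(np.array([[10, 0], [0, 20]]))
        assert r["omission"] == 0 and r["commission"] == 0
        assert r["percent_correct"] == 1.0

    def test_complement_identities(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = rng.integers(1, 50, (2, 2))
            r = error_rates(m)
            assert r["omission"] + r["sensitivity"] == pytest.approx(1.0)
            assert r["commission"] + r["specificity"] == pytest.approx(1.0)

    def test_empty_observed_class_nan(self):
        r = error_rates(np.array([[0, 0], [1, 9]]))
        assert np.isnan(r["commission"])


class TestFitStats:
    def test_perfect_predictions(self):
        out = fit_stats([0, 1, 2, 3], [0, 1, 2, 3], 1)
        assert out["r2"] == 1.0 and out["r2_adj"] == 1.0 and out["mse"] == 0.0

    def test_mean_prediction_zero_r2(self):
        obs = np.array([0.0, 1.0, 2.0, 3.0])
        out = fit_stats(obs, np.full(4, obs.mean()), 1)
        assert out["r2"] == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # obs (0,1,2,3), pred (0,1,1,3): SSE = 1, SST = 5, n = 4, p = 1
        out = fit_stats([0, 1, 2, 3], [0, 1, 1, 3], 1)
        assert out["r2"] == pytest.approx(1 - 1 / 5)
        assert out["r2_adj"] == pytest.approx(1 - (1 / 5) * 3 / 2)
        assert out["mse"] == pytest.approx(1 / 4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_stats([2, 2, 2, 2], [1, 2, 3, 4], 1)


class TestKsTest:
    def test_published_oh_data(self):
        """Spring/fall presence-only collections: all observed fish in the
        high predicted classes vs 19/81 expected shares."""
        r = ks_test([0, 4835], [75 / 391, 316 / 391], n=391)
        assert r.d == pytest.approx(0.19, abs=0.005)
        assert r.critical_d == pytest.approx(0.069, abs=0.0005)
        assert r.significant  # a poorer match than chance allows

    def test_published_usgs_data(self):
        r = ks_test([0, 250], [5 / 23, 18 / 23], n=23)
        assert r.d == pytest.approx(0.22, abs=0.005)
        assert r.critical_d == pytest.approx(0.28, abs=0.005)
        assert not r.significant  # a good match

    def test_proportional_counts_zero_d(self):
        r = ks_test([19, 81], [0.19, 0.81])
        assert r.d == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance_of_d(self):
        a = ks_test([3, 7, 10], [0.2, 0.3, 0.5])
        b = ks_test([30, 70, 100], [0.2, 0.3, 0.5])
        assert a.d == pytest.approx(b.d)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ks_test([0, 0], [0.5, 0.5])
        with pytest.raises(ValueError):
            ks_test([1, 2], [0.5, 0.4])
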