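import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from bleedrisk.discrimination import (c_index, delong_compare,
                                      delong_variance, hosmer_lemeshow, idi,
                                      nri, score_to_probability)


def pair_enumeration_cindex(scores, outcome):
    """Brute-force oracle: average over all event/non-event pairs."""
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    pos = scores[outcome]
    neg = scores[~outcome]
    total = 0.0
    for a, b in itertools.product(pos, neg):
        total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (pos.size * neg.size)


class TestCIndex:
    def test_perfect_separation(self):
        assert c_index([3, 4, 5, 0, 1, 2],
                       [True, True, True, False, False, False]) == 1.0

    def test_sep8_fixture(self, fixtures):
        from bleedrisk import scores as sc
        cohort = fixtures["sep8"]
        pts = [sc.compute_hasbled(p, False).points for p in cohort.patients]
        outcome = [p.bled for p in cohort.patients]
        assert c_index(pts, outcome) == 1.0

    def test_exchangeable_near_half(self, rng):
        vals = []
        for _ in range(200):
            s = rng.random(40)
            o = np.concatenate([np.ones(20, bool), np.zeros(20, bool)])
            vals.append(c_index(s, o))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)

    def test_matches_pair_enumeration(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 31))
            s = rng.integers(0, 6, size=n).astype(float)
            o = rng.random(n) < 0.4
            if o.all() or not o.any():
                continue
            assert c_index(s, o) == pytest.approx(
                pair_enumeration_cindex(s, o), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        s = rng.random(50)
        o = rng.random(50) < 0.3
        if o.all() or not o.any():
            o[:2] = [True, False]
        assert c_index(np.exp(3 * s) + 7, o) == pytest.approx(c_index(s, o))

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            c_index([1, 2], [True, True])


class TestDeLong:
    def test_self_comparison(self, rng):
        s = rng.random(30)
        o = rng.random(30) < 0.5
        o[:2] = [True, False]
        r = delong_compare(s, s, o)
        assert r.z_statistic == 0.0 and r.p_value == 1.0

    def test_reflection(self):
        s = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.05])
        o = np.array([True, True, True, False, False, False])
        r = delong_compare(s, -s, o)
        assert r.c_index_a == pytest.approx(1.0)
        assert r.c_index_a + r.c_index_b == pytest.approx(1.0)
        assert abs(r.z_statistic) > 0

    def test_antisymmetry(self, rng):
        a, b = rng.random(40), rng.random(40)
        o = rng.random(40) < 0.4
        o[:2] = [True, False]
        r1 = delong_compare(a, b, o)
        r2 = delong_compare(b, a, o)
        assert r1.z_statistic == pytest.approx(-r2.z_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_auc_matches_c_index(self, rng):
        a, b = rng.random(60), rng.random(60)
        o = rng.random(60) < 0.4
        o[:2] = [True, False]
        r = delong_compare(a, b, o)
        assert r.c_index_a == pytest.approx(c_index(a, o))
        assert r.c_index_b == pytest.approx(c_index(b, o))

    def test_variance_against_slow_structural_oracle(self, rng):
        """Recompute the structural components by explicit double loops."""
        n = 25
        a, b = rng.random(n), rng.integers(0, 5, n).astype(float)
        o = rng.random(n) < 0.4
        o[:2] = [True, False]

        def psi(x, y):
            return 1.0 if x > y else (0.5 if x == y else 0.0)

        def components(s):
            pos, neg = s[o], s[~o]
            v10 = np.array([np.mean([psi(x, y) for y in neg]) for x in pos])
            v01 = np.array([np.mean([psi(x, y) for x in pos]) for y in neg])
            return v10, v01

        v10a, v01a = components(a)
        v10b, v01b = components(b)
        var = (np.cov(np.vstack([v10a, v10b]), ddof=1)[0, 0]
               + np.cov(np.vstack([v10a, v10b]), ddof=1)[1, 1]
               - 2 * np.cov(np.vstack([v10a, v10b]), ddof=1)[0, 1]) / v10a.size
        var += (np.cov(np.vstack([v01a, v01b]), ddof=1)[0, 0]
                + np.cov(np.vstack([v01a, v01b]), ddof=1)[1, 1]
                - 2 * np.cov(np.vstack([v01a, v01b]), ddof=1)[0, 1]) / v01a.size
        assert delong_variance(a, b, o) == pytest.approx(var, rel=1e-10)

    def test_unpaired_lengths_error(self):
        with pytest.raises(ValueError):
            delong_compare([1, 2, 3], [1, 2], [True, False, True])


class TestScoreToProbability:
    def test_constant_score_gives_prevalence(self):
        o = np.array([True, False, False, False, True] * 4)
        p = score_to_probability(np.zeros(20), o)
        np.testing.assert_allclose(p, o.mean(), atol=1e-8)

    def test_grid_search_ml_oracle(self, rng):
        x = rng.integers(0, 6, size=120).astype(float)
        y = rng.random(120) < expit(-2 + 0.5 * x)
        y[:2] = [True, False]
        p = score_to_probability(x, y)

        def nll(params):
            eta = params[0] + params[1] * x
            return -np.sum(y * eta - np.logaddexp(0, eta))

        res = minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10})
        expected = expit(res.x[0] + res.x[1] * x)
        np.testing.assert_allclose(p, expected, atol=1e-4)

    def test_fitted_mean_equals_prevalence(self, rng):
        x = rng.integers(0, 8, size=200).astype(float)
        y = rng.random(200) < expit(-1.5 + 0.3 * x)
        y[:2] = [True, False]
        p = score_to_probability(x, y)
        assert p.mean() == pytest.approx(y.mean(), abs=1e-6)

    def test_separation_error(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([False, False, True, True])
        with pytest.raises(ValueError):
            score_to_probability(x, y)


class TestNRI:
    def test_no_reclassification(self, rng):
        p = rng.random(30)
        o = rng.random(30) < 0.5
        o[:2] = [True, False]
        r = nri(p, p.copy(), o)
        assert r.nri == 0.0

    def test_maximal(self):
        o = np.array([True] * 5 + [False] * 5)
        old = np.full(10, 0.5)
        new = np.where(o, 0.9, 0.1)
        r = nri(old, new, o)
        assert r.nri == pytest.approx(2.0)
        assert r.nri_events == pytest.approx(1.0)
        assert r.nri_nonevents == pytest.approx(1.0)

    def test_twelve_subject_hand_count(self):
        # events: 4 (3 up, 1 down); non-events: 8 (2 up, 4 down, 2 same)
        o = np.array([True] * 4 + [False] * 8)
        old = np.full(12, 0.3)
        new = np.array([0.4, 0.5, 0.6, 0.2,          # events
                        0.4, 0.5, 0.2, 0.1, 0.2, 0.2, 0.3, 0.3])
        r = nri(old, new, o)
        assert r.nri_events == pytest.approx(3 / 4 - 1 / 4)
        assert r.nri_nonevents == pytest.approx(4 / 8 - 2 / 8)
        assert r.nri == pytest.approx(r.nri_events + r.nri_nonevents)

    def test_two_category_mode(self):
        o = np.array([True, True, False, False])
        old = np.array([0.1, 0.3, 0.1, 0.3])
        new = np.array([0.3, 0.1, 0.1, 0.1])
        r = nri(old, new, o, mode="two_category", category_threshold=0.2)
        assert r.nri_events == pytest.approx(0.0)   # one up, one down
        assert r.nri_nonevents == pytest.approx(0.5)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            nri([0.1, 0.2], [0.2, 0.1], [True, True])


class TestIDI:
    def test_identity_probabilities(self, rng):
        p = rng.random(20)
        o = rng.random(20) < 0.5
        o[:2] = [True, False]
        assert idi(p, p.copy(), o).idi == 0.0

    def test_hand_computed_means(self):
        o = np.array([True, True, False, False])
        old = np.array([0.5, 0.5, 0.5, 0.5])
        new = np.array([0.7, 0.9, 0.2, 0.4])
        r = idi(old, new, o)
        # slope_new = 0.8 - 0.3 = 0.5; slope_old = 0
        assert r.idi == pytest.approx(0.5)

    def test_equals_difference_of_discrimination_slopes(self, rng):
        o = rng.random(50) < 0.4
        o[:2] = [True, False]
        old = rng.random(50)
        new = rng.random(50)
        r = idi(old, new, o)
        slope = lambda p: p[o].mean() - p[~o].mean()
        assert r.idi == pytest.approx(slope(new) - slope(old), abs=1e-12)

    def test_informative_component_detected(self, rng):
        n = 2000
        x = rng.integers(0, 5, size=n).astype(float)
        z = rng.integers(0, 2, size=n).astype(float)
        y = rng.random(n) < expit(-2 + 0.4 * x + 0.8 * z)
        y[:2] = [True, False]
        p_old = score_to_probability(x, y)
        p_new = score_to_probability(x + z, y)
        r = idi(p_old, p_new, y)
        assert r.idi > 0
        assert r.p_idi < 0.05


class TestHosmerLemeshow:
    def test_exact_calibration_zero_statistic(self):
        prob = np.concatenate([np.full(10, 0.2), np.full(10, 0.5)])
        outcome = np.zeros(20, dtype=bool)
        outcome[:2] = True        # 2 of 10 at p=0.2
        outcome[10:15] = True     # 5 of 10 at p=0.5
        r = hosmer_lemeshow(prob, outcome, bins=2)
        assert r.hl_statistic == pytest.approx(0.0, abs=1e-12)
        assert r.df == 0

    def test_hand_computed_bins(self):
        prob = np.concatenate([np.full(10, 0.1), np.full(10, 0.4)])
        outcome = np.zeros(20, dtype=bool)
        outcome[:3] = True    # O=3, E=1 in bin 1
        outcome[10:14] = True  # O=4, E=4 in bin 2
        r = hosmer_lemeshow(prob, outcome, bins=2)
        expected = (3 - 1) ** 2 / (1 * (1 - 1 / 10)) + 0.0
        assert r.hl_statistic == pytest.approx(expected, rel=1e-12)

    def test_ties_kept_together(self):
        prob = np.full(30, 0.3)
        outcome = np.zeros(30, dtype=bool)
        outcome[:9] = True
        r = hosmer_lemeshow(prob, outcome, bins=10)
        assert len(r.bin_table) == 1  # all tied -> single bin

    def test_well_specified_simulation_pvalues(self, rng):
        # small-scale uniformity sanity check (full version in acceptance)
        pvals = []
        for _ in range(40):
            x = rng.integers(0, 8, size=1500).astype(float)
            y = rng.random(1500) < expit(-2 + 0.3 * x)
            if y.all() or not y.any():
                continue
            p = score_to_probability(x, y)
            pvals.append(hosmer_lemeshow(p, y).p_value)
        pvals = np.asarray(pvals)
        assert (pvals < 0.05).mean() < 0.25
        assert pvals.mean() > 0.2
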