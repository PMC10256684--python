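"""Repetition-shuffling permutation tests: enumeration oracles, null behaviour."""

import itertools

import numpy as np
import pytest

from surroundkit import perm_test_si, perm_test_slope
from surroundkit import SimulatorConfig, loom_tuning_mean

from conftest import poisson_rate_samples


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain loops, no shared code with the
# implementation)

def brute_force_si(rates_by_length):
    means = [float(np.mean(r)) for r in rates_by_length]
    peak = max(means)
    asym = sum(means[-3:]) / 3.0
    return (peak - asym) / peak


def brute_force_slope(points):
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    n = len(points)
    mx, my = sum(xs) / n, sum(ys) / n
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = sum((x - mx) ** 2 for x in xs)
    return num / den if den != 0 else float("nan")


def enumerate_si_null(a, b, sign=1.0):
    """All balanced reassignments of the pooled repetitions at each length."""
    n_len, na = a.shape
    pooled = [list(a[i]) + list(b[i]) for i in range(n_len)]
    per_length = []
    for row in pooled:
        opts = []
        for combo in itertools.combinations(range(len(row)), na):
            rest = [k for k in range(len(row)) if k not in combo]
            opts.append(([row[k] for k in combo], [row[k] for k in rest]))
        per_length.append(opts)
    null = []
    for assignment in itertools.product(*per_length):
        ra = [grp[0] for grp in assignment]
        rb = [grp[1] for grp in assignment]
        null.append(sign * (brute_force_si(ra) - brute_force_si(rb)))
    return null


def enumerate_slope_null(a, b, sign=1.0):
    n_az, na, _ = a.shape
    pooled = [[tuple(a[i, j]) for j in range(a.shape[1])]
              + [tuple(b[i, j]) for j in range(b.shape[1])] for i in range(n_az)]
    per_az = []
    for row in pooled:
        opts = []
        for combo in itertools.combinations(range(len(row)), na):
            rest = [k for k in range(len(row)) if k not in combo]
            opts.append(([row[k] for k in combo], [row[k] for k in rest]))
        per_az.append(opts)
    null = []
    for assignment in itertools.product(*per_az):
        pts_a = [(np.mean([p[0] for p in grp[0]]), np.mean([p[1] for p in grp[0]]))
                 for grp in assignment]
        pts_b = [(np.mean([p[0] for p in grp[1]]), np.mean([p[1] for p in grp[1]]))
                 for grp in assignment]
        null.append(sign * (brute_force_slope(pts_b) - brute_force_slope(pts_a)))
    return null


class TestPermTestSI:
    def test_identical_constant_conditions_give_p_one(self):
        a = np.full((4, 5), 10.0)
        res = perm_test_si(a, a.copy(), seed=0)
        assert res.p_value == 1.0
        assert res.observed == 0.0
        assert np.all(res.null_values == 0.0)

    def test_exact_mode_matches_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        a = rng.poisson(8, (4, 2)).astype(float)
        b = rng.poisson(12, (4, 2)).astype(float)
        res = perm_test_si(a, b, method="exact")
        null = enumerate_si_null(a, b)
        observed = brute_force_si(list(a)) - brute_force_si(list(b))
        p_oracle = sum(v >= observed for v in null) / len(null)
        assert res.n_perm == len(null)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_label_exchange_flips_observed_sign(self):
        rng = np.random.default_rng(5)
        a = rng.normal(20, 4, (5, 6))
        b = rng.normal(30, 4, (5, 6))
        r_ab = perm_test_si(a, b, seed=1)
        r_ba = perm_test_si(b, a, seed=1)
        assert r_ab.observed == pytest.approx(-r_ba.observed)

    def test_direction_option_flips_statistic(self):
        rng = np.random.default_rng(6)
        a = rng.normal(20, 4, (5, 6))
        b = rng.normal(30, 4, (5, 6))
        assert perm_test_si(a, b, seed=0, direction="a_minus_b").observed == \
            pytest.approx(-perm_test_si(a, b, seed=0, direction="b_minus_a").observed)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        a = rng.normal(20, 5, (5, 15))
        b = rng.normal(20, 5, (5, 15))
        r1 = perm_test_si(a, b, seed=77)
        r2 = perm_test_si(a, b, seed=77)
        np.testing.assert_array_equal(r1.null_values, r2.null_values)
        assert perm_test_si(a, b, seed=78).p_value == pytest.approx(
            r1.p_value, abs=0.08)  # different seeds: binomial MC error only

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            perm_test_si(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_nperm_must_be_positive(self):
        with pytest.raises(ValueError):
            perm_test_si(np.ones((4, 3)), np.ones((4, 3)), n_perm=0)


class TestPermTestSlope:
    def test_identical_constant_pairs_give_p_one(self):
        a = np.zeros((3, 4, 2))
        a[:, :, 0] = [[1], [2], [3]]
        a[:, :, 1] = [[2], [4], [6]]
        res = perm_test_slope(a, a.copy(), seed=0)
        assert res.p_value == 1.0

    def test_exact_mode_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        a = rng.poisson(10, (3, 2, 2)).astype(float)
        b = rng.poisson(14, (3, 2, 2)).astype(float)
        res = perm_test_slope(a, b, method="exact")
        null = enumerate_slope_null(a, b)
        pts = lambda m: [(m[i, :, 0].mean(), m[i, :, 1].mean()) for i in range(3)]
        observed = brute_force_slope(pts(b)) - brute_force_slope(pts(a))
        p_oracle = sum(v >= observed for v in null) / len(null)
        assert res.n_perm == len(null)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_pairs_shuffled_as_units(self):
        """If y = 0.5 x for every repetition pair in both conditions, every
        shuffled slope is exactly 0.5 and the null is degenerate at 0 —
        which can only happen if (x, y) pairs are never split."""
        rng = np.random.default_rng(2)
        x_a = rng.uniform(10, 100, (4, 6))
        x_b = rng.uniform(10, 100, (4, 6))
        a = np.stack([x_a, 0.5 * x_a], axis=2)
        b = np.stack([x_b, 0.5 * x_b], axis=2)
        res = perm_test_slope(a, b, seed=0)
        np.testing.assert_allclose(res.null_values, 0.0, atol=1e-12)

    def test_too_few_azimuths_rejected(self):
        with pytest.raises(ValueError):
            perm_test_slope(np.zeros((2, 4, 2)), np.zeros((2, 4, 2)))

    def test_detects_release_from_competition(self):
        """Power simulation: baseline gain 0.6 vs drug gain 1.0, 15 reps,
        Poisson-scale noise -> one-sided p <= 0.05 for most sites."""
        cfg = SimulatorConfig(competition_gain_baseline=0.6,
                              competition_gain_drug=1.0,
                              rundown_per_condition=1.0)
        az = cfg.rf_center_az + np.array([-10.0, -5.0, 0.0, 5.0, 10.0])
        rng = np.random.default_rng(100)
        n_sites, hits = 300, 0
        for _ in range(n_sites):
            pairs = {}
            for cond in ("baseline", "drug"):
                x = np.stack([poisson_rate_samples(rng, loom_tuning_mean(a, cfg, False, cond), 15)
                              for a in az])
                y = np.stack([poisson_rate_samples(rng, loom_tuning_mean(a, cfg, True, cond), 15)
                              for a in az])
                pairs[cond] = np.stack([x, y], axis=2)
            seed = int(rng.integers(2 ** 31))
            p = perm_test_slope(pairs["baseline"], pairs["drug"], seed=seed).p_value
            hits += p <= 0.05
        assert hits / n_sites >= 0.8
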