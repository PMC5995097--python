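"""RMA estimator, its CI, AICc model comparison, and grid sweeps."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allomtree import (SynthConfig, aicc_compare, ci_overlap, fit_grid,
                       fits_to_frame, generate, metrics_table, rma_fit)
from allomtree.regression import (AllometryFit, DegenerateDataError,
                                  InsufficientDataError)


class TestRmaFit:
    def test_identity_line(self):
        f = rma_fit([1, 10, 100], [1, 10, 100])
        assert f.a_hat == pytest.approx(1.0, abs=1e-12)
        assert f.b_hat == pytest.approx(0.0, abs=1e-12)
        assert f.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_exact_square_law(self):
        f = rma_fit([1, 10, 100], [1, 100, 10000])
        assert f.a_hat == pytest.approx(2.0, abs=1e-12)
        assert f.b_hat == pytest.approx(0.0, abs=1e-12)
        assert f.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_slope_equals_sd_ratio_oracle(self):
        rng = np.random.default_rng(42)
        u = rng.uniform(0, 2, size=20)
        v = 2.5 * u + rng.normal(0, 0.1, size=20)
        f = rma_fit(10.0 ** u, 10.0 ** v)
        # independent evaluation through the statistics module
        expect = math.copysign(statistics.stdev(v) / statistics.stdev(u),
                               np.corrcoef(u, v)[0, 1])
        assert f.a_hat == pytest.approx(expect, abs=1e-12)

    def test_negative_slope_sign_and_ci_order(self):
        rng = np.random.default_rng(7)
        u = rng.uniform(0, 2, size=30)
        v = -1.15 * u + 3.6 + rng.normal(0, 0.05, size=30)
        f = rma_fit(10.0 ** u, 10.0 ** v)
        assert f.a_hat < 0
        assert f.a_ci[0] < f.a_hat < f.a_ci[1]
        assert f.b_ci[0] < f.b_hat < f.b_ci[1]
        assert math.copysign(1, f.a_hat) == math.copysign(
            1, np.corrcoef(u, v)[0, 1])

    def test_nonpositive_pairs_dropped_pairwise(self):
        f = rma_fit([1, 10, 100, -5, 3], [1, 10, 100, 4, np.nan])
        assert f.n == 3
        assert f.n_dropped == 2
        assert f.a_hat == pytest.approx(1.0, abs=1e-12)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            rma_fit([1, 10], [1, 10])

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            rma_fit([5, 5, 5], [1, 2, 3])

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_scale_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.normal(0, 1, size=25)
        v = 1.7 * u + rng.normal(0, 0.3, size=25)
        x, y = 10.0 ** u, 10.0 ** v
        fxy = rma_fit(x, y)
        fyx = rma_fit(y, x)
        assert fxy.a_hat * fyx.a_hat == pytest.approx(1.0, abs=1e-9)
        scaled = rma_fit(x, 100.0 * y)
        assert scaled.a_hat == pytest.approx(fxy.a_hat, abs=1e-12)
        assert scaled.b_hat == pytest.approx(fxy.b_hat + 2.0, abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_rma_slope_brackets_ols_slope(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.normal(0, 1, size=25)
        v = 0.8 * u + rng.normal(0, 0.4, size=25)
        f = rma_fit(10.0 ** u, 10.0 ** v)
        ols = np.polyfit(u, v, 1)[0]
        assert abs(f.a_hat) >= abs(ols) - 1e-12


class TestAicc:
    def test_noiseless_linear_prefers_linear(self):
        u = np.linspace(0, 2, 30)
        res = aicc_compare(10.0 ** u, 10.0 ** (2.0 * u))
        assert res["preferred"] == "linear"

    def test_strong_curvature_prefers_quadratic(self):
        rng = np.random.default_rng(3)
        u = np.linspace(0, 2, 30)
        v = u ** 2 + rng.normal(0, 0.02, size=30)
        res = aicc_compare(10.0 ** u, 10.0 ** v)
        assert res["preferred"] == "quadratic"
        # direct residual check: the curvature term must dominate
        rss_lin = np.sum((v - np.polyval(np.polyfit(u, v, 1), u)) ** 2)
        rss_quad = np.sum((v - np.polyval(np.polyfit(u, v, 2), u)) ** 2)
        assert rss_quad < rss_lin / 10

    def test_aicc_equals_aic_plus_small_sample_correction(self):
        rng = np.random.default_rng(11)
        u = rng.uniform(0, 2, size=10)
        v = 1.3 * u + rng.normal(0, 0.2, size=10)
        res = aicc_compare(10.0 ** u, 10.0 ** v)
        # closed form for the linear model: k = 3 (slope, intercept, variance)
        n, k = 10, 3
        rss = float(np.sum((v - np.polyval(np.polyfit(u, v, 1), u)) ** 2))
        ll = -0.5 * n * (math.log(2 * math.pi * rss / n) + 1)
        aic = 2 * k - 2 * ll
        assert res["aicc_linear"] == pytest.approx(
            aic + 2 * k * (k + 1) / (n - k - 1), abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            aicc_compare([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])

    def test_linear_preferred_on_linear_truth_most_of_the_time(self):
        # data generated exactly from the linear model, sigma = 0.05,
        # n = 12 per replicate: the small-sample regime AICc is built for
        # (its extra-parameter penalty grows as n shrinks)
        wins = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(1_000 + seed)
            u = rng.uniform(0, 2, size=12)
            v = 1.5 * u + 0.2 + rng.normal(0, 0.05, size=12)
            if aicc_compare(10.0 ** u, 10.0 ** v)["preferred"] == "linear":
                wins += 1
        assert wins / reps >= 0.90


class TestCiOverlap:
    def _fit(self, lo, hi):
        mid = 0.5 * (lo + hi)
        return AllometryFit("y", "x", "subtree", "g", 10, mid, (lo, hi),
                            0.0, (0.0, 0.0), 0.9)

    @pytest.mark.parametrize("ci1, ci2, expect", [
        ((2.43, 2.55), (2.49, 2.66), True),   # cherry vs apple subtree M~D
        ((1.0, 2.0), (2.0, 3.0), True),       # shared endpoint counts
        ((1.0, 2.0), (2.01, 3.0), False),
    ])
    def test_closed_interval_intersection(self, ci1, ci2, expect):
        assert ci_overlap(self._fit(*ci1), self._fit(*ci2))["overlaps"] is expect


class TestFitGrid:
    def metrics(self, n_trees=1, **kwargs):
        trees = []
        for i in range(n_trees):
            cfg = SynthConfig(levels=6, noise_sigma=0.05, seed=100 + i,
                              tree_id=f"t{i}", **kwargs)
            trees.append(generate(cfg)[0])
        return metrics_table(trees)

    def test_cardinality(self):
        m = self.metrics()
        fits = fit_grid(m, pairs=[("length", "diameter"), ("mass", "diameter")],
                        levels=["segment", "path", "subtree"], grouping="species")
        assert len(fits) == 2 * 3 * 1

    def test_individual_grouping_one_fit_per_tree(self):
        m = self.metrics(n_trees=5)
        fits = fit_grid(m, pairs=[("length", "diameter")], levels=["segment"],
                        grouping="individual")
        assert len(fits) == 5
        per_tree = m[m.level == "segment"].groupby("tree_id").size()
        for f in fits:
            assert f.ok and f.n == per_tree[f.group]

    def test_two_species_recover_their_own_exponents(self):
        cherry = generate(SynthConfig(levels=8, beta=2 ** -0.5, gamma=2 ** -0.5,
                                      noise_sigma=0.03, seed=5,
                                      tree_id="c1", species="cherry"))[0]
        # fixed representative seeds: CI containment of the truth is itself
        # only a 95%-probability event per draw
        apple = generate(SynthConfig(levels=8, beta=2 ** -0.5,
                                     gamma=2 ** (-1 / 3), noise_sigma=0.03,
                                     seed=7, tree_id="a1", species="apple"))[0]
        m = metrics_table([cherry, apple])
        fits = {f.group: f for f in fit_grid(
            m, pairs=[("length", "diameter")], levels=["segment"],
            grouping="species")}
        assert fits["cherry"].a_ci[0] <= 1.0 <= fits["cherry"].a_ci[1]
        assert fits["apple"].a_ci[0] <= 2 / 3 <= fits["apple"].a_ci[1]

    def test_unknown_pair_is_configuration_error(self):
        with pytest.raises(ValueError, match="unknown metric"):
            fit_grid(self.metrics(), pairs=[("girth", "diameter")],
                     levels=["segment"])

    def test_failures_are_explicit_records(self):
        m = self.metrics()
        m.loc[:, "mass"] = np.nan  # no mass anywhere -> every M~D cell fails
        fits = fit_grid(m, pairs=[("mass", "diameter")], levels=["segment"])
        assert len(fits) == 1 and not fits[0].ok
        frame = fits_to_frame(fits)
        assert (frame["status"] == "failed").all()
        assert frame["reason"].iloc[0]
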