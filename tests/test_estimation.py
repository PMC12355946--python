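"""Direct Kaw estimation: grouping, QC filtering, and the weighted NLS fit."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kawfit.estimation import (
    HeadspaceKawModel,
    RatioGroup,
    VialObservation,
    fit_kaw,
    group_by_ratio,
    log10_kaw,
    qc_filter,
)
from kawfit.partition import area_model


def make_obs(ratios, areas, chemical="X", temperature=298.15):
    counter = {}
    out = []
    for r, a in zip(ratios, areas):
        counter[r] = counter.get(r, 0) + 1
        out.append(VialObservation(chemical, temperature, r, counter[r], a))
    return out


def grid_search_oracle(ratios, areas, p, n=120, passes=10):
    """Independent brute-force minimizer of the weighted SSE on a refining grid."""
    ratios = np.asarray(ratios)
    areas = np.asarray(areas)
    w = areas ** (-float(p))
    a0_lo, a0_hi = areas.max() * 0.5, areas.max() * 5.0
    k_lo, k_hi = 1e-4, 10.0

    def sse(a0_grid, k_grid):
        f = a0_grid[:, None, None] / (1.0 + k_grid[None, :, None] * ratios)
        return np.sum(w * (areas - f) ** 2, axis=2)

    for _ in range(passes):
        a0s = np.linspace(a0_lo, a0_hi, n)
        ks = np.linspace(k_lo, k_hi, n)
        s = sse(a0s, ks)
        i, j = np.unravel_index(np.argmin(s), s.shape)
        da, dk = a0s[1] - a0s[0], ks[1] - ks[0]
        a0_lo, a0_hi = a0s[i] - 2 * da, a0s[i] + 2 * da
        k_lo, k_hi = max(ks[j] - 2 * dk, 0.0), ks[j] + 2 * dk
    return a0s[i], ks[j], s[i, j]


class TestGrouping:
    def test_full_design_yields_six_triplicate_groups(self, design_ratios):
        obs = make_obs(
            list(design_ratios) * 3, np.arange(1, 19, dtype=float)
        )
        groups = group_by_ratio(obs)
        assert len(groups) == 6
        assert all(len(g.areas) == 3 for g in groups)
        assert [g.ratio for g in groups] == sorted(design_ratios)

    def test_zero_variance_group_has_zero_rsd(self):
        g = RatioGroup(1.0, (100.0, 100.0, 100.0))
        assert g.rsd == 0.0

    def test_mean_and_rsd(self):
        g = RatioGroup(1.0, (90.0, 100.0, 110.0))
        assert g.mean_area == pytest.approx(100.0)
        assert g.rsd == pytest.approx(0.10)

    def test_mixed_chemicals_rejected(self):
        obs = make_obs([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        obs[1] = VialObservation("Y", 298.15, 2.0, 1, 20.0)
        with pytest.raises(ValueError, match="mix chemicals"):
            group_by_ratio(obs)

    def test_mixed_temperatures_rejected(self):
        obs = make_obs([1.0, 2.0], [10.0, 20.0]) + make_obs(
            [3.0], [30.0], temperature=313.15
        )
        with pytest.raises(ValueError, match="mix temperatures"):
            group_by_ratio(obs)


class TestQcFilter:
    def test_zero_variance_distinct_means_keeps_everything(self):
        groups = [
            RatioGroup(r, (m, m, m))
            for r, m in [(0.1, 900.0), (1.0, 500.0), (3.0, 250.0)]
        ]
        kept, excluded = qc_filter(groups)
        assert [g.ratio for g in kept] == [0.1, 1.0, 3.0]
        assert excluded == []

    def test_noisy_group_with_close_neighbours_excluded(self):
        # middle group: rsd 0.10 but neighbour means only ~5% away
        groups = [
            RatioGroup(0.5, (1000.0, 1000.0, 1000.0)),
            RatioGroup(1.0, (855.0, 950.0, 1045.0)),  # mean 950, rsd 0.10
            RatioGroup(2.0, (1000.0, 1000.0, 1000.0)),
        ]
        kept, excluded = qc_filter(groups)
        assert [g.ratio for g in excluded] == [1.0]
        assert [g.ratio for g in kept] == [0.5, 2.0]

    def test_boundary_rsd_equal_to_neighbour_deviation_is_excluded(self):
        # terminal group: single neighbour; rel. dev of means 150 vs 100 with
        # pair-mean denominator = 50/125 = 0.4; rsd built to equal it exactly
        areas = (90.0, 150.0, 210.0)  # mean 150, sample SD 60, rsd 0.4
        assert RatioGroup(1.0, areas).rsd == 0.4
        groups = [RatioGroup(1.0, areas), RatioGroup(2.0, (100.0, 100.0, 100.0))]
        kept, excluded = qc_filter(groups)
        assert [g.ratio for g in excluded] == [1.0]

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            qc_filter([RatioGroup(1.0, (1.0,))])


class TestFit:
    def test_exact_recovery_from_noiseless_design(self, design_ratios):
        areas = [area_model(1000.0, 0.1, r) for r in design_ratios for _ in range(3)]
        ratios = [r for r in design_ratios for _ in range(3)]
        fit = HeadspaceKawModel(ratios, areas).fit()
        assert fit.converged
        assert fit.kaw_hat == pytest.approx(0.1, rel=1e-8)
        assert fit.amplitude_hat == pytest.approx(1000.0, rel=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("a0, kaw", [(5.0, 0.0), (1e6, 2.5), (300.0, 0.01)])
    @pytest.mark.parametrize("p", [0, 1, 2])
    def test_exact_recovery_any_parameters_any_weighting(self, a0, kaw, p, design_ratios):
        areas = [area_model(a0, kaw, r) for r in design_ratios]
        fit = HeadspaceKawModel(design_ratios, areas, weighting_exponent=p).fit()
        assert fit.kaw_hat == pytest.approx(kaw, rel=1e-7, abs=1e-9)
        assert fit.amplitude_hat == pytest.approx(a0, rel=1e-7)

    def test_flat_signal_gives_kaw_near_zero(self, design_ratios):
        fit = HeadspaceKawModel(design_ratios, [500.0] * 6).fit()
        assert abs(fit.kaw_hat) < 1e-10

    def test_matches_grid_search_oracle_on_noisy_data(self, design_ratios, rng):
        ratios = np.repeat(design_ratios, 3)
        truth = area_model(1000.0, 0.4, ratios)
        areas = truth * np.exp(rng.normal(0, 0.02, truth.size))
        model = HeadspaceKawModel(ratios, areas, weighting_exponent=2)
        fit = model.fit()
        a0_g, k_g, sse_g = grid_search_oracle(ratios, areas, 2)
        assert fit.kaw_hat == pytest.approx(k_g, abs=2e-6)
        assert model.weighted_sse(fit.amplitude_hat, fit.kaw_hat) <= sse_g + 1e-12

    def test_optimum_beats_wide_grid(self, design_ratios, rng):
        """Weighted SSE at the optimum is <= the minimum over a dense wide grid."""
        ratios = np.repeat(design_ratios, 3)
        areas = area_model(2000.0, 0.15, ratios) * np.exp(
            rng.normal(0, 0.05, ratios.size)
        )
        model = HeadspaceKawModel(ratios, areas, weighting_exponent=2)
        fit = model.fit()
        best = math.inf
        # 4 decades around data-driven centres, chunked over amplitude rows
        a0s = np.geomspace(areas.max() / 100.0, areas.max() * 100.0, 2000)
        ks = np.geomspace(1e-3, 10.0, 2000)
        w = areas ** (-2.0)
        for a0 in a0s:
            f = a0 / (1.0 + ks[:, None] * ratios)
            best = min(best, float(np.min(np.sum(w * (areas - f) ** 2, axis=1))))
        assert model.weighted_sse(fit.amplitude_hat, fit.kaw_hat) <= best + 1e-12

    @given(scale=st.floats(1e-3, 1e3))
    def test_area_rescaling_leaves_kaw_invariant(self, scale):
        ratios = np.repeat([19.0, 9.0, 3.0, 1.0, 1.0 / 3.0, 1.0 / 9.0], 3)
        rng = np.random.default_rng(7)
        areas = area_model(1000.0, 0.3, ratios) * np.exp(rng.normal(0, 0.02, ratios.size))
        f1 = HeadspaceKawModel(ratios, areas).fit()
        f2 = HeadspaceKawModel(ratios, areas * scale).fit()
        assert f2.kaw_hat == pytest.approx(f1.kaw_hat, rel=1e-6)
        assert f2.amplitude_hat == pytest.approx(f1.amplitude_hat * scale, rel=1e-6)

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            HeadspaceKawModel([1.0, 2.0], [10.0, 5.0])

    def test_identical_ratios_unidentifiable(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            HeadspaceKawModel([1.0, 1.0, 1.0], [10.0, 11.0, 9.0])

    def test_ci_contains_estimate_and_flags_negative_kaw(self, design_ratios, rng):
        ratios = np.repeat(design_ratios, 3)
        areas = area_model(1000.0, 0.2, ratios) * np.exp(rng.normal(0, 0.02, ratios.size))
        fit = HeadspaceKawModel(ratios, areas).fit()
        assert fit.kaw_ci95[0] < fit.kaw_hat < fit.kaw_ci95[1]
        # essentially flat data with downward noise trend -> negative slope possible
        flat = np.array([100.0, 99.5, 100.2, 100.4, 99.9, 100.1])
        f2 = HeadspaceKawModel(design_ratios, flat).fit()
        if f2.kaw_hat < 0:
            assert not f2.converged

    def test_from_observations_applies_qc_and_records_exclusions(self, design_ratios):
        obs = []
        for r in design_ratios:
            base = area_model(1000.0, 0.5, r)
            for i in range(1, 4):
                obs.append(VialObservation("X", 298.15, r, i, base))
        # corrupt the largest-ratio triplicate with huge scatter
        bad_r = max(design_ratios)
        obs = [o for o in obs if o.ratio != bad_r]
        base = area_model(1000.0, 0.5, bad_r)
        obs += [
            VialObservation("X", 298.15, bad_r, i, a)
            for i, a in enumerate([base * 0.2, base, base * 1.8], 1)
        ]
        model = HeadspaceKawModel.from_observations(obs)
        assert model.excluded_ratios == (bad_r,)
        fit = model.fit()
        assert fit.excluded_ratios == (bad_r,)
        assert fit.n_used == 15
        assert fit.kaw_hat == pytest.approx(0.5, rel=1e-6)


class TestLogScale:
    def test_log10_of_estimate_and_ci(self):
        fit = fit_kaw(
            [
                RatioGroup(r, tuple(area_model(1000.0, 0.1, r) for _ in range(3)))
                for r in [19.0, 9.0, 3.0, 1.0]
            ]
        )
        val, (lo, hi) = log10_kaw(fit)
        assert val == pytest.approx(-1.0, abs=1e-6)
        assert lo <= val <= hi

    def test_non_positive_ci_bound_not_reportable(self):
        from dataclasses import replace

        fit = fit_kaw(
            [
                RatioGroup(r, tuple(area_model(1000.0, 0.1, r) for _ in range(3)))
                for r in [19.0, 9.0, 3.0, 1.0]
            ]
        )
        broken = replace(fit, kaw_ci95=(-0.01, 0.2))
        assert not broken.reportable
        with pytest.raises(ValueError, match="not reportable"):
            log10_kaw(broken)
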