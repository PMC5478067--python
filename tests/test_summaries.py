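"""Tests for richness, benefit and posterior-summary operations.

HDI correctness is checked against an exhaustive shortest-window search;
mode and interval behaviour against analytic properties of known
distributions.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birdmix import (
    URBAN_CLASSES,
    hdi,
    posterior_mode,
    prop_above_zero,
    richness_benefit,
    richness_per_iteration,
    richness_stratum_means,
    summarize,
)


def brute_force_hdi(samples, mass):
    """Check every contiguous order-statistic window; first shortest wins."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    m = int(np.ceil(mass * n))
    best = None
    for a in range(n - m + 1):
        width = x[a + m - 1] - x[a]
        if best is None or width < best[0] - 1e-15:
            best = (width, x[a], x[a + m - 1])
    return best[1], best[2]


class TestHdi:
    def test_constant_samples(self):
        lo, hi = hdi(np.full(50, 3.25))
        assert (lo, hi) == (3.25, 3.25)

    def test_uniform_grid_tie_break(self):
        lo, hi = hdi(np.arange(1, 101, dtype=float), 0.95)
        assert (lo, hi) == (1.0, 95.0)

    @pytest.mark.parametrize("dist,n", [
        ("normal", 200), ("lognormal", 500), ("exponential", 999),
    ])
    @pytest.mark.parametrize("mass", [0.5, 0.9, 0.95])
    def test_matches_exhaustive_window_search(self, dist, n, mass, rng):
        x = getattr(rng, dist)(size=n)
        assert hdi(x, mass) == pytest.approx(brute_force_hdi(x, mass))

    def test_normal_endpoints_at_large_n(self, rng):
        x = rng.standard_normal(100_000)
        lo, hi = hdi(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    @given(st.lists(st.floats(-50, 50), min_size=20, max_size=200),
           st.floats(0.2, 0.98))
    @settings(deadline=None, max_examples=60)
    def test_window_contains_required_mass(self, xs, mass):
        x = np.asarray(xs)
        lo, hi = hdi(x, mass)
        inside = np.count_nonzero((x >= lo) & (x <= hi))
        assert inside >= int(np.ceil(mass * x.size))
        assert lo <= hi

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            hdi(np.arange(10), 0.95)


class TestPosteriorMode:
    def test_tight_cluster(self, rng):
        x = 2.0 + 1e-6 * rng.standard_normal(500)
        assert posterior_mode(x) == pytest.approx(2.0, abs=1e-3)

    def test_dominant_component_of_bimodal_mixture(self, rng):
        x = np.concatenate([rng.normal(0, 0.1, 8000), rng.normal(5, 0.1, 2000)])
        assert abs(posterior_mode(x)) < 0.5

    @given(st.lists(st.floats(-100, 100), min_size=20, max_size=100))
    @settings(deadline=None, max_examples=40)
    def test_mode_within_sample_range(self, xs):
        x = np.asarray(xs)
        m = posterior_mode(x)
        assert x.min() <= m <= x.max()


class TestPropAboveZero:
    @pytest.mark.parametrize("samples,expected", [
        ([-1.0, 1.0], 0.5),
        ([0.2, 5.0, 1e-9], 1.0),
        ([-2, -1, 0, 1, 2, 3], 0.5),  # zero is not above zero
    ])
    def test_strict_inequality_convention(self, samples, expected):
        assert prop_above_zero(samples) == expected

    def test_complement_identity(self, rng):
        x = rng.standard_normal(999)  # continuous: no exact zeros
        assert prop_above_zero(x) + prop_above_zero(-x) == pytest.approx(1.0)


class TestRichness:
    def test_all_absent(self, small_roster):
        N = np.zeros((10, 4), dtype=int)
        assert richness_per_iteration(N, small_roster).sum() == 0

    def test_hand_enumerated_mix(self):
        roster = pd.DataFrame({
            "species_id": ["a", "b", "c"],
            "urban_class": ["sensitive", "sensitive", "exploitative"],
        })
        N = np.array([[2], [0], [5]])
        rich = richness_per_iteration(N, roster)
        assert rich[0, URBAN_CLASSES.index("sensitive")] == 1
        assert rich[0, URBAN_CLASSES.index("exploitative")] == 1
        assert rich[0, URBAN_CLASSES.index("adaptable")] == 0

    def test_upper_bound_attained(self, small_roster):
        N = np.ones((10, 6), dtype=int)
        rich = richness_per_iteration(N, small_roster)
        sizes = small_roster["urban_class"].value_counts()
        for ci, cls in enumerate(URBAN_CLASSES):
            assert (rich[:, ci] == sizes[cls]).all()

    def test_stratum_means_bounded_by_class_size(self, small_design,
                                                 small_roster, rng):
        draws = rng.integers(0, 3, size=(40, 10, small_design.n_sites))
        rich = np.stack([richness_per_iteration(d, small_roster)
                         for d in draws])
        means = richness_stratum_means(rich, small_design)
        sizes = small_roster["urban_class"].value_counts()
        for name, vals in means.items():
            cls = name.split("_")[1]
            assert (vals <= sizes[cls]).all()
            assert (vals >= 0).all()


class TestRichnessBenefit:
    def _draws(self, design, rng, n_draws=30):
        return rng.integers(0, 4, size=(n_draws, design.n_sites,
                                        len(URBAN_CLASSES))).astype(float)

    def test_identical_strata_give_zero(self, small_design):
        draws = np.ones((25, small_design.n_sites, 3))
        benefit = richness_benefit(draws, small_design, "sensitive", "grass")
        assert (benefit == 0).all()

    def test_single_iteration_arithmetic(self, tiny_design):
        # craft richness so treated grass sites hold (3, 5) and untreated (1, 1)
        draws = np.zeros((1, tiny_design.n_sites, 3))
        sites = tiny_design.sites
        grass_t = np.where((sites["origin"] == "grass") & (sites["treated"] == 1))[0]
        grass_u = np.where((sites["origin"] == "grass") & (sites["treated"] == 0))[0]
        draws[0, grass_t, 0] = [3, 5]
        draws[0, grass_u, 0] = [1, 1]
        benefit = richness_benefit(draws, tiny_design, "sensitive", "grass")
        assert benefit[0] == pytest.approx(3.0)

    def test_antisymmetry_under_label_reversal(self, small_design, rng):
        draws = self._draws(small_design, rng)
        fwd = richness_benefit(draws, small_design, "adaptable", "forest")
        flipped = small_design.sites.copy()
        flipped["treated"] = 1 - flipped["treated"]
        from birdmix import SurveyDesign
        design2 = SurveyDesign(flipped, small_design.visits)
        rev = richness_benefit(draws, design2, "adaptable", "forest")
        assert np.allclose(fwd, -rev)

    def test_weed_dropout_sites_excluded(self, small_design, rng):
        draws = self._draws(small_design, rng)
        spiked = draws.copy()
        bad = np.where(small_design.sites["weed_contrast_eligible"] == 0)[0]
        assert bad.size > 0
        spiked[:, bad, :] = 99.0  # must not leak into the forest contrast
        a = richness_benefit(draws, small_design, "sensitive", "forest")
        b = richness_benefit(spiked, small_design, "sensitive", "forest")
        assert np.allclose(a, b)

    def test_direction_probability_identity(self, small_design, rng):
        draws = self._draws(small_design, rng)
        benefit = richness_benefit(draws, small_design, "exploitative", "grass")
        assert prop_above_zero(benefit) + prop_above_zero(-benefit) <= 1.0 + 1e-12


class TestSummarize:
    def test_normal_draw_summary(self, rng):
        table = summarize({"theta": rng.standard_normal(50_000)})
        row = table.iloc[0]
        assert row["parameter"] == "theta"
        assert row["prop_above_0"] == pytest.approx(0.5, abs=0.02)
        assert row["mode"] == pytest.approx(0.0, abs=0.1)
        assert row["hdi_lower"] == pytest.approx(-1.96, abs=0.07)
        assert row["hdi_upper"] == pytest.approx(1.96, abs=0.07)

    def test_constant_draws(self):
        row = summarize({"c": np.full(100, 3.0)}).iloc[0]
        assert (row["hdi_lower"], row["mode"], row["hdi_upper"],
                row["prop_above_0"]) == (3.0, 3.0, 3.0, 1.0)

    def test_one_row_per_parameter(self, rng):
        draws = {f"p{i}": rng.standard_normal(100) for i in range(7)}
        table = summarize(draws)
        assert len(table) == 7
        assert list(table.columns) == ["parameter", "hdi_lower", "mode",
                                       "hdi_upper", "prop_above_0"]
        assert (table["hdi_lower"] <= table["hdi_upper"]).all()
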