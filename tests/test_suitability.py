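import numpy as np
import pytest

from phenorisk.cohorts import make_cohorts
from phenorisk.phenology import EVENTS, run_all_cohorts
from phenorisk.suitability import (
    CAT_INSUFFICIENT,
    CAT_MODERATE,
    CAT_OK,
    CAT_SEVERE,
    StressResult,
    accumulate_stress,
    classify_stress,
    integrate_phenology_suitability,
    longest_run_below,
    multi_year_agreement,
    presence_sensitivity,
)
from phenorisk.weather import DEFAULT_TRANSFORM

from conftest import constant_weather, grid_from_arrays, seeded_weather, shift_weather


def stress_from_classes(combined, transform=DEFAULT_TRANSFORM):
    """Hand-built StressResult for combination/selection tests."""
    combined = np.asarray(combined, dtype=np.int8)
    zeros = np.zeros(combined.shape)
    return StressResult(
        cold_total=zeros, heat_total=zeros,
        cold_class=combined.copy(), heat_class=np.zeros_like(combined),
        combined_class=combined,
        missing_mask=np.zeros(combined.shape, bool),
        transform=transform,
    )


class TestClassification:
    def test_boundary_strictness(self):
        totals = np.array([80.0, 80.01, 160.0, 160.01])
        np.testing.assert_array_equal(
            classify_stress(totals, 80, 160), [0, -1, -1, -2]
        )

    def test_raising_limits_never_worsens(self):
        rng = np.random.default_rng(1)
        totals = rng.uniform(0, 300, size=200)
        base = classify_stress(totals, 80, 160)
        relaxed = classify_stress(totals, 120, 200)
        assert np.all(relaxed >= base)

    def test_order_invariance_of_totals(self, eab):
        w = seeded_weather(3, shape=(4, 4), base=-20, amplitude=18, noise_sd=3.0)
        sr = accumulate_stress(w, eab)
        perm = np.random.default_rng(0).permutation(w.n_days)
        w_shuffled = grid_from_arrays(w.tmin[perm], w.tmax[perm], year=w.year)
        sr2 = accumulate_stress(w_shuffled, eab)
        np.testing.assert_allclose(sr.cold_total, sr2.cold_total)
        np.testing.assert_allclose(sr.heat_total, sr2.heat_total)


class TestAccumulate:
    def test_benign_year_all_zero(self, eab):
        w = seeded_weather(0, shape=(5, 5), base=10, amplitude=14, noise_sd=1.0)
        sr = accumulate_stress(w, eab)
        assert np.all(sr.cold_total == 0)
        assert np.all(sr.heat_total == 0)
        assert np.all(sr.combined_class == 0)

    def test_moderate_cold(self, eab):
        # tmin=tmax=-32 for 100 days: 1 cold unit/day -> total 100 in (80, 160]
        tmin = np.full((365, 1, 1), 0.0)
        tmax = np.full((365, 1, 1), 5.0)
        tmin[:100] = tmax[:100] = -32.0
        sr = accumulate_stress(grid_from_arrays(tmin, tmax), eab)
        assert sr.cold_total[0, 0] == pytest.approx(100.0)
        assert sr.cold_class[0, 0] == -1
        assert sr.combined_class[0, 0] == -1

    def test_severe_cold_dominates_combined(self, eab):
        tmin = np.full((365, 1, 1), 0.0)
        tmax = np.full((365, 1, 1), 5.0)
        tmin[:100] = tmax[:100] = -33.0  # 2 units/day -> 200 > 160
        sr = accumulate_stress(grid_from_arrays(tmin, tmax), eab)
        assert sr.cold_total[0, 0] == pytest.approx(200.0)
        assert sr.cold_class[0, 0] == -2
        assert sr.heat_total[0, 0] == 0.0
        assert sr.combined_class[0, 0] == -2

    def test_warmer_year_stress_monotonicity(self, eab):
        w = seeded_weather(7, shape=(4, 4), base=-15, amplitude=20, noise_sd=2.0)
        warm = shift_weather(w, 2.0)
        a, b = accumulate_stress(w, eab), accumulate_stress(warm, eab)
        assert np.all(b.cold_total <= a.cold_total + 1e-9)
        assert np.all(b.heat_total >= a.heat_total - 1e-9)

    def test_masked_cells_stay_masked(self, eab):
        tmin = np.zeros((365, 2, 2))
        tmax = np.ones((365, 2, 2))
        tmin[0, 0, 0] = np.nan
        sr = accumulate_stress(grid_from_arrays(tmin, tmax), eab)
        assert np.isnan(sr.cold_total[0, 0])
        assert sr.missing_mask[0, 0]


class TestIntegration:
    def test_four_way_legend(self, eab):
        w = constant_weather(22.2, shape=(2, 2))
        events = run_all_cohorts(w, eab, make_cohorts(eab))
        stress = stress_from_classes([[0, -1], [-2, 0]])
        out = integrate_phenology_suitability(events, stress)
        doy, cat = out["adult_emergence"]
        assert cat[0, 0] == CAT_OK and not np.isnan(doy[0, 0])
        assert cat[0, 1] == CAT_MODERATE and np.isnan(doy[0, 1])
        assert cat[1, 0] == CAT_SEVERE and np.isnan(doy[1, 0])

    def test_insufficient_accumulation_label(self, eab):
        w = constant_weather(10.0, shape=(1, 1))  # no accumulation at all
        events = run_all_cohorts(w, eab, make_cohorts(eab))
        stress = stress_from_classes([[0]])
        doy, cat = integrate_phenology_suitability(events, stress)["egg_hatch"]
        assert cat[0, 0] == CAT_INSUFFICIENT
        assert np.isnan(doy[0, 0])

    def test_grid_mismatch_rejected(self, eab):
        w = constant_weather(22.2, shape=(2, 2))
        events = run_all_cohorts(w, eab, make_cohorts(eab))
        with pytest.raises(ValueError, match="mismatch"):
            integrate_phenology_suitability(events, stress_from_classes([[0]]))

    def test_all_events_present(self, eab):
        w = constant_weather(22.2, shape=(1, 1))
        events = run_all_cohorts(w, eab, make_cohorts(eab))
        out = integrate_phenology_suitability(events, stress_from_classes([[0]]))
        assert set(out) == set(EVENTS)


class TestMultiYear:
    def test_agreement_counts(self):
        years = [stress_from_classes([[0]]) for _ in range(20)]
        assert multi_year_agreement(years)[0, 0] == 20
        years[3] = stress_from_classes([[-1]])
        assert multi_year_agreement(years)[0, 0] == 19
        all_severe = [stress_from_classes([[-2]]) for _ in range(5)]
        assert multi_year_agreement(all_severe)[0, 0] == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            multi_year_agreement([])


class TestSensitivity:
    # 2x2 grid over [0,2]x[-2,0]; combined classes:
    #   (0,0)=0  (0,1)=-1
    #   (1,0)=-2 (1,1)=0
    stress = None

    def setup_method(self):
        self.stress = stress_from_classes([[0, -1], [-2, 0]])

    def test_all_in_included_cells(self):
        records = [(0.5, -0.5)] * 50
        out = presence_sensitivity(records, self.stress)
        assert out["sensitivity"] == 1.0

    def test_partial(self):
        records = [(0.5, -0.5)] * 9 + [(0.5, -1.5)]  # last one in a -2 cell
        out = presence_sensitivity(records, self.stress)
        assert out["sensitivity"] == pytest.approx(0.9)
        assert not out["included"][-1]

    def test_mode_contract(self):
        record = [(1.5, -0.5)]  # -1 cell
        both = presence_sensitivity(record, self.stress, mode="both-levels")
        severe = presence_sensitivity(record, self.stress, mode="severe-only")
        assert both["sensitivity"] == 0.0
        assert severe["sensitivity"] == 1.0

    def test_outside_reported_separately(self):
        out = presence_sensitivity([(0.5, -0.5), (99.0, -0.5)], self.stress)
        assert out["n_inside"] == 1
        assert out["outside"][1]
        assert out["sensitivity"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            presence_sensitivity([], self.stress)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            presence_sensitivity([(0.5, -0.5)], self.stress, mode="maybe")


def test_longest_run_below():
    assert longest_run_below([-35, -35, -20, -35], -31) == 2
    assert longest_run_below([0, 0, 0], -31) == 0
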