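import numpy as np
import pytest

from phenorisk.cohorts import CohortSet, make_cohorts
from phenorisk.phenology import (
    EVENTS,
    EventMaps,
    run_all_cohorts,
    run_cohort,
    stage_snapshot,
)

from conftest import assert_event_order, constant_weather, seeded_weather, shift_weather

# at constant 22.2 C every day contributes 10 DD above the 12.2 C threshold;
# chained event requirements 200/135/72/172/700 give these cumulative
# thresholds and (first day cum >= threshold) days
EXPECTED_DOYS = {
    "pupation": 20,
    "adult_emergence": 34,
    "oviposition": 41,
    "egg_hatch": 58,
    "jlarval_formation": 128,
}


class TestRunCohort:
    def test_constant_222_hand_arithmetic(self, eab, const_22_2):
        traj = run_cohort(const_22_2, eab, 200.0)
        for ev, doy in EXPECTED_DOYS.items():
            assert traj.events[ev][0, 0] == doy

    def test_below_threshold_no_events(self, eab):
        w = constant_weather(10.0)
        traj = run_cohort(w, eab, 200.0)
        assert traj.cum_dd[0, 0] == 0.0
        for ev in EVENTS:
            assert np.isnan(traj.events[ev][0, 0])

    def test_early_cohort_strictly_earlier(self, eab, const_22_2):
        fast = run_cohort(const_22_2, eab, 60.0)
        slow = run_cohort(const_22_2, eab, 350.0)
        for ev in EVENTS:
            assert fast.events[ev][0, 0] < slow.events[ev][0, 0]

    def test_completion_outside_bounds_rejected(self, eab, const_22_2):
        with pytest.raises(ValueError, match="completion_dd"):
            run_cohort(const_22_2, eab, 30.0)

    def test_masked_cells_all_missing(self, eab):
        w = constant_weather(22.2, shape=(2, 2))
        w.tmin[100, 0, 0] = np.nan
        w = type(w)(tmin=w.tmin, tmax=w.tmax, dates=w.dates)
        traj = run_cohort(w, eab, 200.0)
        for ev in EVENTS:
            assert np.isnan(traj.events[ev][0, 0])
            assert not np.isnan(traj.events[ev][1, 1])

    def test_terminal_state_after_jformation(self, eab, const_22_2):
        traj = run_cohort(const_22_2, eab, 200.0)
        assert traj.stage_index[0, 0] == 5  # DONE: no second generation

    def test_multiple_transitions_single_day(self, eab):
        # 34 C constant: 21.8 DD/day; a 10-DD cohort pupates and partially
        # completes the pupal stage on day 1 without error
        w = constant_weather(34.0)
        p = eab.replace(xdist1=5.0, distro_mean=10.0, xdist2=20.0, pupae_event_dd=10.0)
        traj = run_cohort(w, p, 6.0)
        assert traj.events["pupation"][0, 0] == 1
        assert traj.events["adult_emergence"][0, 0] == 1  # surplus cascades

    def test_degree_day_conservation(self, eab, const_22_2):
        # all EAB stages share one threshold pair, so consumed + remainder
        # must equal the plain annual accumulation
        traj = run_cohort(const_22_2, eab, 200.0)
        consumed = 200.0 + 135 + 72 + 172 + 700
        assert traj.cum_dd[0, 0] == pytest.approx(consumed + traj.within_dd[0, 0])
        # trajectory went DONE on day 128; accumulation stops there
        assert traj.cum_dd[0, 0] == pytest.approx(128 * 10.0)


class TestEventMaps:
    def test_combined_first_and_average(self):
        per = {ev: np.full((2, 1, 1), np.nan) for ev in EVENTS}
        per["adult_emergence"][0, 0, 0] = 150
        per["adult_emergence"][1, 0, 0] = 170
        maps = EventMaps(
            per_cohort=per,
            weights=np.array([0.25, 0.75]),
            missing_mask=np.zeros((1, 1), bool),
        )
        assert maps.first("adult_emergence")[0, 0] == 150
        assert maps.weighted_average("adult_emergence")[0, 0] == pytest.approx(165.0)
        # >= 50% of weight emerged only once the second cohort has
        assert maps.weighted_median("adult_emergence")[0, 0] == 170

    def test_single_cohort_first_equals_average(self, eab, const_22_2):
        cs = make_cohorts(eab, n=1)
        maps = run_all_cohorts(const_22_2, eab, cs)
        for ev in EVENTS:
            np.testing.assert_array_equal(maps.first(ev), maps.weighted_average(ev))

    def test_insufficient_accumulation_mask(self, eab):
        w = constant_weather(10.0, shape=(2, 2))
        maps = run_all_cohorts(w, eab, make_cohorts(eab))
        assert maps.insufficient_mask("egg_hatch").all()
        assert np.isnan(maps.first("egg_hatch")).all()

    def test_partial_cohort_weight_renormalized(self):
        per = {ev: np.full((2, 1, 1), np.nan) for ev in EVENTS}
        per["egg_hatch"][0, 0, 0] = 180  # only the first cohort hatched
        maps = EventMaps(
            per_cohort=per,
            weights=np.array([0.25, 0.75]),
            missing_mask=np.zeros((1, 1), bool),
        )
        assert maps.weighted_average("egg_hatch")[0, 0] == pytest.approx(180.0)
        assert not maps.insufficient_mask("egg_hatch")[0, 0]

    def test_first_le_weighted_average(self, eab):
        w = seeded_weather(seed=5, shape=(8, 8))
        maps = run_all_cohorts(w, eab, make_cohorts(eab))
        for ev in EVENTS:
            first, avg = maps.first(ev), maps.weighted_average(ev)
            both = ~np.isnan(first) & ~np.isnan(avg)
            assert np.all(first[both] <= avg[both] + 1e-9)


class TestStageSnapshot:
    def test_day1_all_overwintering(self, eab, const_22_2):
        traj = run_cohort(const_22_2, eab, 200.0)
        snap = stage_snapshot([traj], np.array([1.0]), doy=1)
        assert snap["stage_index"][0, 0, 0] == 0  # OL
        assert snap["generations"][0, 0] == 0

    def test_day25_pupa(self, eab, const_22_2):
        traj = run_cohort(const_22_2, eab, 200.0)
        snap = stage_snapshot([traj], np.array([1.0]), doy=25)
        assert snap["stage_index"][0, 0, 0] == 1  # P
        assert snap["dominant"][0, 0] == 1

    def test_terminal_generation_count(self, eab, const_22_2):
        traj = run_cohort(const_22_2, eab, 200.0)
        snap = stage_snapshot([traj], np.array([1.0]), doy=365)
        assert snap["stage_index"][0, 0, 0] == 5  # DONE
        assert snap["generations"][0, 0] == 1

    def test_date_outside_year_rejected(self, eab, const_22_2):
        traj = run_cohort(const_22_2, eab, 200.0)
        with pytest.raises(ValueError, match="doy"):
            stage_snapshot([traj], np.array([1.0]), doy=400)


class TestProperties:
    """Smaller-scale versions of the acceptance property suites."""

    @pytest.mark.parametrize("seed", range(5))
    def test_event_ordering(self, eab, seed):
        w = seeded_weather(seed, shape=(6, 6))
        for completion in (60.0, 200.0, 350.0):
            traj = run_cohort(w, eab, completion)
            assert_event_order(traj.events)

    @pytest.mark.parametrize("seed", range(3))
    def test_cohort_monotonicity(self, eab, seed):
        w = seeded_weather(seed, shape=(5, 5))
        prev = None
        for completion in (60.0, 150.0, 250.0, 350.0):
            traj = run_cohort(w, eab, completion)
            if prev is not None:
                for ev in EVENTS:
                    a, b = prev.events[ev], traj.events[ev]
                    both = ~np.isnan(a) & ~np.isnan(b)
                    assert np.all(a[both] <= b[both])
                    # later cohorts can only lose events, never gain them
                    assert not np.any(np.isnan(a) & ~np.isnan(b))
            prev = traj

    @pytest.mark.parametrize("seed", range(3))
    def test_warming_monotonicity(self, eab, seed):
        w = seeded_weather(seed, shape=(5, 5), base=10.0, noise_sd=1.0)
        warm = shift_weather(w, 1.0)  # stays well below the 36 C UDT
        base_t = run_cohort(w, eab, 200.0)
        warm_t = run_cohort(warm, eab, 200.0)
        for ev in EVENTS:
            a, b = base_t.events[ev], warm_t.events[ev]
            both = ~np.isnan(a) & ~np.isnan(b)
            assert np.all(b[both] <= a[both])
            assert not np.any(~np.isnan(a) & np.isnan(b))
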