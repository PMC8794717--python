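"""Von Bertalanffy whisker dating and segment planning."""

import math
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, strategies as st

from isoniche import (
    DensityModel,
    GrowthModel,
    WhiskerRecord,
    age_at_length,
    date_of_position,
    length_at_age,
    plan_segments,
    segment_durations,
)
from isoniche.exceptions import DomainError, InfeasiblePlanError

MODEL = GrowthModel(L_inf=100.0, k=0.01, t0=0.0)


def daily_forward_length(days: int, L_inf: float, k: float) -> float:
    """Independent oracle: step the daily growth recursion forward."""
    L = 0.0
    g = 1.0 - math.exp(-k)
    for _ in range(days):
        L = L + (L_inf - L) * g
    return L


class TestGrowthCurve:
    def test_zero_point_and_asymptote(self):
        assert length_at_age(0.0, MODEL) == 0.0
        assert MODEL.L_inf - length_at_age(20 / MODEL.k, MODEL) < 1e-6

    def test_half_saturation_closed_form_and_daily_oracle(self):
        t_half = math.log(2.0) / MODEL.k  # 100*ln2 ≈ 69.31 days
        assert length_at_age(t_half, MODEL) == pytest.approx(50.0, abs=1e-9)
        below = daily_forward_length(69, 100.0, 0.01)
        above = daily_forward_length(70, 100.0, 0.01)
        assert below < 50.0 < above

    def test_discrete_mode_matches_daily_recursion(self):
        disc = GrowthModel(100.0, 0.01, mode="daily-discrete")
        for d in (1, 10, 200):
            assert length_at_age(d, disc) == pytest.approx(
                daily_forward_length(d, 100.0, 0.01), abs=1e-9)
        with pytest.raises(DomainError):
            length_at_age(2.5, disc)

    def test_age_before_t0_rejected(self):
        model = GrowthModel(100.0, 0.01, t0=5.0)
        with pytest.raises(DomainError):
            length_at_age(4.0, model)


class TestInverse:
    def test_zero_length_and_asymptote_domain(self):
        assert age_at_length(0.0, MODEL) == MODEL.t0
        with pytest.raises(DomainError):
            age_at_length(100.0, MODEL)

    def test_round_trip_identity_on_grid(self):
        for l in np.linspace(0.0, 99.5, 200):
            assert length_at_age(age_at_length(l, MODEL), MODEL) == \
                pytest.approx(l, abs=1e-9)

    def test_half_length_age(self):
        assert age_at_length(50.0, MODEL) == pytest.approx(
            100.0 * math.log(2.0), abs=1e-9)

    @given(st.floats(0.0, 99.0), st.floats(0.0, 99.0))
    def test_monotone(self, l1, l2):
        if l1 == l2:
            return
        lo, hi = sorted((l1, l2))
        assert age_at_length(lo, MODEL) < age_at_length(hi, MODEL)

    def test_discrete_and_continuous_agree_within_a_day(self):
        for k in (0.005, 0.02, 0.05):
            cont = GrowthModel(100.0, k)
            disc = GrowthModel(100.0, k, mode="daily-discrete")
            for l in np.linspace(0.5, 90.0, 40):
                assert abs(age_at_length(l, cont)
                           - age_at_length(l, disc)) <= 1.0


WHISKER = WhiskerRecord("w1", observed_length=75.0, intradermal_length=5.0,
                        collection_date=date(2018, 9, 1))


class TestDateOfPosition:
    def test_base_is_collection_date(self):
        assert date_of_position(0.0, WHISKER, MODEL) == date(2018, 9, 1)

    def test_known_offset_from_closed_form(self):
        # material 10 mm below the base of an 80 mm whisker lay at the tip
        # when the whisker was 70 mm long: 100*(ln5 − ln(10/3)) ≈ 40.5 days
        days = 100.0 * (math.log(5.0) - math.log(10.0 / 3.0))
        expect = WHISKER.collection_date - timedelta(days=int(days))
        assert date_of_position(10.0, WHISKER, MODEL) == expect

    def test_strictly_earlier_with_depth(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            total = rng.uniform(20.0, 95.0)
            w = WhiskerRecord("r", total - 5.0, 5.0, date(2018, 9, 1))
            depths = np.sort(rng.uniform(0.0, total, size=8))
            dates = [date_of_position(d, w, MODEL) for d in depths]
            assert all(d1 >= d2 for d1, d2 in zip(dates, dates[1:]))

    def test_out_of_range_depth(self):
        with pytest.raises(DomainError):
            date_of_position(81.0, WHISKER, MODEL)


class TestSegmentPlanning:
    def test_uniform_density_cut_length(self):
        dens = DensityModel(linear_density=0.12)
        assert dens.length_for_mass(0.32, 0.0, 80.0) == \
            pytest.approx(0.32 / 0.12, abs=1e-12)

    def test_single_segment_plan(self):
        plan = plan_segments(WHISKER, MODEL, DensityModel(), n_isotope=1)
        assert len(plan.segments) == 1
        assert plan.segments[0].role == "isotope"

    def test_mass_window_and_contiguity(self):
        plan = plan_segments(WHISKER, MODEL, DensityModel(), n_isotope=3)
        iso_segs = plan.isotope_segments
        assert len(iso_segs) == 3
        for s in iso_segs:
            assert 0.2 <= s.est_mass_mg <= 0.5
        for s1, s2 in zip(plan.segments, plan.segments[1:]):
            assert s1.end_mm == pytest.approx(s2.start_mm)

    def test_default_plan_spans_roughly_one_month(self):
        # three ~2.7-day segments + two 11.3-day buffers ≈ 30 days
        w = WhiskerRecord("d", 45.0, 5.0, date(2018, 8, 15))
        gm = GrowthModel(70.0, 0.022)
        plan = plan_segments(w, gm, DensityModel(linear_density=0.30))
        span = sum(s.duration_days for s in plan.segments)
        assert 24.0 <= span <= 37.0
        for s, expect_buffer in zip(plan.segments,
                                    [False, True, False, True, False]):
            assert (s.role == "buffer") is expect_buffer
            if expect_buffer:
                assert s.duration_days == pytest.approx(11.3, abs=1e-6)

    def test_too_short_whisker_is_infeasible(self):
        w = WhiskerRecord("tiny", 2.0, 0.5, date(2018, 8, 15))
        with pytest.raises(InfeasiblePlanError):
            plan_segments(w, MODEL, DensityModel(linear_density=0.12),
                          n_isotope=3)


class TestSegmentDurations:
    def test_positive_and_monotone_toward_tip(self):
        plan = plan_segments(WHISKER, MODEL, DensityModel(), n_isotope=3)
        durations = segment_durations(plan)
        assert np.all(durations > 0)
        # deeper (older) material grew faster: fewer days per equal mass
        assert np.all(np.diff(durations) <= 1e-9)

    def test_base_slice_spans_more_days_than_mid_whisker(self):
        w = WhiskerRecord("w", 75.0, 5.0, date(2018, 9, 1))
        base = (age_at_length(80.0, MODEL) - age_at_length(79.0, MODEL))
        mid = (age_at_length(41.0, MODEL) - age_at_length(40.0, MODEL))
        assert base > mid

    def test_linear_growth_limit_gives_equal_durations(self):
        # k→0 with L_inf→∞ at fixed rate: equal lengths, equal days
        model = GrowthModel(L_inf=1e6, k=1e-6)
        w = WhiskerRecord("lin", 45.0, 5.0, date(2018, 8, 15))
        plan = plan_segments(w, model, DensityModel(linear_density=0.30),
                             n_isotope=3)
        durations = segment_durations(plan)
        assert durations == pytest.approx([durations[0]] * 3, rel=1e-3)

    def test_taper_density_integrates_to_total_mass(self):
        dens = DensityModel(profile="linear-taper", total_mass_mg=12.0,
                            taper_ratio=2.0, linear_density=None)
        assert dens.mass_between(0.0, 60.0, 60.0) == pytest.approx(12.0)
        # solving for a cut then measuring it is consistent
        length = dens.length_for_mass(0.35, 10.0, 60.0)
        assert dens.mass_between(10.0, 10.0 + length, 60.0) == \
            pytest.approx(0.35, abs=1e-9)
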