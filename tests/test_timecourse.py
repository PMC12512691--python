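import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafgas import (
    GasExchangeTimeseries,
    PhaseError,
    SteadyStateError,
    derive_iwue,
    per_stoma_series,
    per_stoma_summary,
    per_stoma_value,
    relative_normalize,
    segment_phases,
    steady_state,
    steady_states,
)
from leafgas.simulate import PAPER_SCHEDULE


def _ts(t, q, gsw, A):
    return GasExchangeTimeseries(
        pd.DataFrame({"t": t, "q_in": q, "gsw": gsw, "A": A}), {}
    )


class TestSegmentation:
    def test_paper_protocol_yields_four_labelled_phases(self, noisefree_run):
        ts, _ = noisefree_run
        phases = segment_phases(ts, schedule=list(PAPER_SCHEDULE))
        assert [p.label for p in phases] == [
            "high_light_1", "low_light", "high_light_2", "darkness",
        ]
        assert all(p.duration == 1200.0 for p in phases)
        assert all(len(p.data) == 20 for p in phases)

    def test_phases_partition_the_run(self, noisefree_run):
        ts, _ = noisefree_run
        phases = segment_phases(ts, schedule=list(PAPER_SCHEDULE))
        assert sum(len(p.data) for p in phases) == len(ts.data)
        # disjoint and ordered
        for prev, cur in zip(phases[:-1], phases[1:]):
            assert prev.t_end == cur.t_start

    def test_constant_light_is_single_phase(self, constant_ts):
        phases = segment_phases(constant_ts, detect=True)
        assert len(phases) == 1
        assert len(phases[0].data) == len(constant_ts.data)

    def test_detection_matches_schedule_on_clean_trace(self, noisefree_run):
        ts, _ = noisefree_run
        by_schedule = segment_phases(ts, schedule=list(PAPER_SCHEDULE))
        by_detect = segment_phases(ts, detect=True)
        assert len(by_detect) == len(by_schedule)
        for a, b in zip(by_schedule, by_detect):
            assert a.t_start == b.t_start
            assert len(a.data) == len(b.data)

    def test_boundary_record_belongs_to_new_phase(self, noisefree_run):
        ts, _ = noisefree_run
        phases = segment_phases(ts, schedule=list(PAPER_SCHEDULE))
        assert phases[1].data["t"].iloc[0] == phases[1].t_start

    def test_detected_count_mismatch_reports_boundaries(self, noisefree_run):
        ts, _ = noisefree_run
        with pytest.raises(PhaseError, match="boundaries"):
            segment_phases(ts, detect=True, expected_phases=3)

    def test_run_longer_than_schedule_rejected(self, noisefree_run):
        ts, _ = noisefree_run
        short = [(1000.0, 1200.0), (100.0, 1200.0)]
        with pytest.raises(PhaseError):
            segment_phases(ts, schedule=short)


class TestIwue:
    def test_proportional_series_gives_constant_iwue(self):
        t = np.arange(0, 600, 60.0)
        gsw = np.linspace(0.1, 0.3, len(t))
        ts = _ts(t, 1000.0, gsw, 70.0 * gsw)
        out = derive_iwue(ts)
        np.testing.assert_allclose(out.data["iwue"], 70.0, rtol=1e-12)

    def test_pointwise_quotient(self):
        ts = _ts([0.0, 60.0], 1000.0, [0.273, 0.273], [18.66, 18.66])
        out = derive_iwue(ts)
        assert out.data["iwue"].iloc[0] == pytest.approx(68.35, abs=0.005)

    def test_below_floor_flagged_undefined(self):
        ts = _ts([0.0, 60.0], 0.0, [0.0, 0.25], [0.1, 17.0])
        out = derive_iwue(ts)
        assert np.isnan(out.data["iwue"].iloc[0])
        assert not out.data["iwue_defined"].iloc[0]
        assert out.data["iwue_defined"].iloc[1]


class TestSteadyState:
    def test_constant_series_exact_zero_se(self, constant_ts):
        phases = segment_phases(constant_ts, detect=True)
        s = steady_state(phases[0], 300.0)
        assert s.value(phases[0].label, "gsw") == 0.25
        assert float(s.table.loc[s.table.variable == "gsw", "se"].iloc[0]) == 0.0

    def test_linear_ramp_mean_is_midpoint(self):
        # gsw = a + b t over the window: the mean of symmetric samples is the
        # value at the window's sample midpoint
        t = np.arange(0.0, 1200.0, 60.0)
        gsw = 0.1 + 1e-4 * t
        ts = _ts(t, 500.0, gsw, 10.0)
        phases = segment_phases(ts, detect=True)
        s = steady_state(phases[0], 300.0)
        window_t = t[(t >= 900.0) & (t < 1200.0)]
        expected = 0.1 + 1e-4 * window_t.mean()
        assert s.value(phases[0].label, "gsw") == pytest.approx(expected, rel=1e-12)

    def test_window_longer_than_phase_rejected(self, constant_ts):
        phases = segment_phases(constant_ts, detect=True)
        with pytest.raises(SteadyStateError):
            steady_state(phases[0], 10_000.0)

    def test_iwue_averaged_over_defined_points_only(self):
        t = np.arange(0.0, 600.0, 60.0)
        gsw = np.where(t < 300, 0.0, 0.2)  # first half undefined
        ts = derive_iwue(_ts(t, 500.0, gsw, 14.0))
        phases = segment_phases(ts, detect=True)
        s = steady_state(phases[0], 600.0)
        row = s.table[s.table.variable == "iwue"].iloc[0]
        assert row["mean"] == pytest.approx(70.0)
        assert row["n"] == 5


class TestPerStoma:
    def test_printed_convention_cases(self):
        assert round(per_stoma_value(0.273, 100.3), 2) == 2.72
        assert round(per_stoma_value(0.304, 59.6), 2) == 5.10

    def test_zero_maps_to_zero(self):
        assert per_stoma_value(0.0, 123.4) == 0.0

    def test_nonpositive_density_rejected(self, constant_ts):
        with pytest.raises(ValueError):
            per_stoma_series(constant_ts, 0.0)

    @settings(deadline=None, max_examples=50)
    @given(density=st.floats(1.0, 500.0), gsw=st.floats(1e-4, 1.0))
    def test_round_trip_inverts(self, density, gsw):
        ts = _ts([0.0, 60.0], 1000.0, [gsw] * 2, [18.0] * 2)
        per = per_stoma_series(ts, density)
        back = per.data["gsw"] * density / 1e3
        np.testing.assert_allclose(back, gsw, rtol=1e-12)

    def test_summary_scaling_applies_to_mean_and_se(self, noisefree_run):
        ts, _ = noisefree_run
        ts = derive_iwue(ts)
        phases = segment_phases(ts, schedule=list(PAPER_SCHEDULE))
        summary = steady_states(phases)
        per = per_stoma_summary(summary, 100.0)
        raw = summary.table.set_index(["phase", "variable"])
        scaled = per.table.set_index(["phase", "variable"])
        for key in [("high_light_1", "gsw"), ("low_light", "A")]:
            assert scaled.loc[key, "mean"] == pytest.approx(
                raw.loc[key, "mean"] / 100.0 * 1e3, rel=1e-12
            )
        # concentrations are not per-area fluxes and stay untouched
        assert scaled.loc[("high_light_1", "Ci"), "mean"] == raw.loc[("high_light_1", "Ci"), "mean"]


class TestRelativeNormalize:
    def test_reference_phase_mean_becomes_one(self, noisefree_run):
        ts, _ = noisefree_run
        phases = segment_phases(ts, schedule=list(PAPER_SCHEDULE))
        rel = relative_normalize(ts, phases, "high_light_1")
        rel_phases = segment_phases(rel, schedule=list(PAPER_SCHEDULE))
        s = steady_state(rel_phases[0], 300.0)
        assert s.value("high_light_1", "gsw") == pytest.approx(1.0, rel=1e-12)

    def test_scale_invariance(self, noisefree_run):
        ts, _ = noisefree_run
        phases = segment_phases(ts, schedule=list(PAPER_SCHEDULE))
        rel1 = relative_normalize(ts, phases, "high_light_1")
        doubled = ts.copy()
        doubled.data["gsw"] = doubled.data["gsw"] * 2
        phases2 = segment_phases(doubled, schedule=list(PAPER_SCHEDULE))
        rel2 = relative_normalize(doubled, phases2, "high_light_1")
        np.testing.assert_allclose(rel1.data["gsw"], rel2.data["gsw"], rtol=1e-12)

    def test_half_reference_trace_reads_half(self):
        t = np.arange(0.0, 2400.0, 60.0)
        q = np.where(t < 1200, 1000.0, 0.0)
        gsw = np.where(t < 1200, 0.2, 0.1)
        ts = _ts(t, q, gsw, 14.0)
        phases = segment_phases(ts, detect=True)
        rel = relative_normalize(ts, phases, phases[0].label)
        assert rel.data["gsw"].iloc[-1] == pytest.approx(0.5)

    def test_iwue_invariant_under_area_correction(self):
        from leafgas import ChamberGeometry, apply_area_correction

        t = np.arange(0.0, 600.0, 60.0)
        ts = _ts(t, 1000.0, np.linspace(0.1, 0.3, len(t)), 60.0 * np.linspace(0.1, 0.3, len(t)))
        geom = ChamberGeometry(chamber_area=2.0, chamber_diameter=2.0, leaf_width=0.4)
        raw = derive_iwue(ts)
        corrected = derive_iwue(apply_area_correction(ts, geom))
        np.testing.assert_allclose(raw.data["iwue"], corrected.data["iwue"], rtol=1e-12)
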