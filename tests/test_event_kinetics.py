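"""Event filtering, occupancy, release-rate fits, persistence modes, detection."""

import numpy as np
import pytest

from frit.event_kinetics import (
    KineticsWarning,
    ReleaseEvent,
    detect_events_from_trace,
    events_from_frame,
    events_to_frame,
    filter_events,
    fit_release_rates,
    occupancy_curve,
    persistence_modes,
)
from frit.simulate import DEFAULT_PERSISTENCE_MIXTURE, sample_persistence


def ev(cell_id=0, onset=10.0, persistence=20.0, **kw):
    return ReleaseEvent(cell_id=cell_id, onset=onset, persistence=persistence, **kw)


class TestFilterEvents:
    def test_histogram_keeps_single_full_length_first(self):
        events = [
            ev(0, 5, 30, full_length=False),                # censored
            ev(1, 8, 25, single=False, repeat_index=2),     # repeat
            ev(2, 12, 20),                                  # single full-length
        ]
        kept = filter_events(events, "histogram")
        assert [e.cell_id for e in kept] == [2]

    def test_histogram_identity_when_all_qualify(self):
        events = [ev(i, 5.0 * i + 1, 20) for i in range(5)]
        assert filter_events(events, "histogram") == events

    def test_censored_in_rates_not_occupancy(self):
        censored = ev(0, 5, 30, full_length=False)
        assert censored in filter_events([censored], "rates")
        assert censored not in filter_events([censored], "occupancy")

    def test_rates_sorted_by_onset(self):
        events = [ev(0, 50, 10), ev(1, 5, 10), ev(2, 25, 10)]
        assert [e.onset for e in filter_events(events, "rates")] == [5, 25, 50]

    def test_empty_result_warns(self):
        with pytest.warns(KineticsWarning):
            filter_events([ev(0, 5, 30, full_length=False)], "histogram")


class TestOccupancy:
    def test_single_event_window(self):
        occ = occupancy_curve([ev(0, 10, 20)], 100, np.arange(0, 40))
        expected = np.where((np.arange(40) >= 10) & (np.arange(40) < 30), 0.01, 0.0)
        np.testing.assert_allclose(occ.fraction_fluorescent, expected)

    def test_overlapping_events_deduplicated_per_cell(self):
        events = [ev(0, 10, 20), ev(0, 15, 20, repeat_index=2)]
        occ = occupancy_curve(events, 10, np.arange(0, 40))
        assert occ.fraction_fluorescent.max() == pytest.approx(0.1)

    def test_brute_force_oracle_equivalence(self):
        """Vectorized occupancy equals a per-minute per-cell recount."""
        rng = np.random.default_rng(11)
        events = [
            ev(int(rng.integers(0, 400)), float(rng.uniform(0, 300)), float(rng.uniform(1, 80)))
            for _ in range(1000)
        ]
        grid = np.arange(0.0, 361.0)
        occ = occupancy_curve(events, 500, grid)
        brute = np.zeros(grid.shape)
        for i, t in enumerate(grid):
            active_cells = {
                e.cell_id for e in events if e.onset <= t < e.onset + e.persistence
            }
            brute[i] = len(active_cells) / 500
        np.testing.assert_allclose(occ.fraction_fluorescent, brute)


class TestReleaseRates:
    def test_exact_on_piecewise_linear_data(self):
        """57 events over (0,30], 66 over (30,360] at 1000 cells: 1.9/0.2 permille."""
        events = [ev(i, 30.0 * (i + 1) / 57, 10) for i in range(57)]
        events += [ev(100 + j, 30.0 + 330.0 * (j + 1) / 66, 10) for j in range(66)]
        fit = fit_release_rates(events, 1000)
        assert fit.rate1 == pytest.approx(1.9, abs=1e-9)
        assert fit.rate2 == pytest.approx(0.2, abs=1e-9)
        assert fit.breakpoint == pytest.approx(30.0)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_constant_rate_gives_equal_slopes(self):
        events = [ev(i, 360.0 * (i + 1) / 120, 10) for i in range(120)]
        fit = fit_release_rates(events, 1000)
        assert fit.rate1 == pytest.approx(fit.rate2, rel=0.05)

    def test_fixed_breakpoint(self):
        events = [ev(i, 3.0 * (i + 1), 10) for i in range(20)]
        fit = fit_release_rates(events, 100, breakpoint=30.0)
        assert fit.breakpoint == 30.0

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            fit_release_rates([ev(i, i + 1.0, 5) for i in range(5)], 100)


class TestPersistenceModes:
    def test_single_mode_recovery(self):
        rng = np.random.default_rng(21)
        durations = rng.normal(24, 5, 1000)
        durations = durations[durations > 0]
        modes = persistence_modes(durations)
        assert modes.modes[0].mean == pytest.approx(24.0, abs=1.0)

    def test_three_mode_recovery(self):
        """Means of the default mixture (24/43/58 min) recovered within 3 min."""
        rng = np.random.default_rng(0)
        durations = sample_persistence(DEFAULT_PERSISTENCE_MIXTURE, 1000, rng)
        modes = persistence_modes(durations)
        top3 = sorted(m.mean for m in modes.modes[:3])
        assert top3 == pytest.approx([24.0, 43.0, 58.0], abs=3.0)

    def test_degenerate_identical_durations(self):
        with pytest.warns(KineticsWarning):
            modes = persistence_modes(np.full(50, 22.0))
        assert len(modes.modes) == 1
        assert modes.modes[0].mean == pytest.approx(22.5, abs=modes.bin_width)
        assert modes.modes[0].sd <= modes.bin_width

    def test_too_few_durations_rejected(self):
        with pytest.raises(ValueError):
            persistence_modes(np.full(10, 20.0))

    def test_accepts_release_events(self):
        rng = np.random.default_rng(22)
        events = [ev(i, 5.0, float(p)) for i, p in enumerate(rng.normal(30, 4, 200))]
        modes = persistence_modes(events)
        assert modes.modes[0].mean == pytest.approx(30.0, abs=2.0)


class TestDetectEvents:
    def test_flat_trace_no_events(self):
        times = np.arange(0.0, 100.0)
        assert detect_events_from_trace(times, np.full(100, 10.0)) == []

    def test_clean_step(self):
        """Step up at t=40, down at t=70 -> one event, onset 40, persistence 30."""
        times = np.arange(0.0, 100.0)
        mfi = np.where((times >= 40) & (times < 70), 100.0, 10.0)
        events = detect_events_from_trace(times, mfi, rise_factor=2.0, fall_factor=1.2)
        assert len(events) == 1
        assert events[0].onset == 40.0
        assert events[0].persistence == 30.0
        assert events[0].full_length

    def test_censored_event(self):
        times = np.arange(0.0, 100.0)
        mfi = np.where(times >= 60, 100.0, 10.0)
        events = detect_events_from_trace(times, mfi)
        assert len(events) == 1
        assert not events[0].full_length

    def test_repeated_events_flagged(self):
        times = np.arange(0.0, 200.0)
        mfi = np.full(200, 10.0)
        mfi[40:70] = 100.0
        mfi[120:150] = 100.0
        events = detect_events_from_trace(times, mfi)
        assert [e.repeat_index for e in events] == [1, 2]
        assert all(not e.single for e in events)
        assert [e.event_class for e in events] == ["B", "D"]


def test_event_table_csv_round_trip(tmp_path):
    events = [
        ev(0, 5, 30, depletion_duration=42.0),
        ev(1, 8, 25, depletion_duration=50.0, full_length=False, single=False,
           event_class="D", repeat_index=2),
    ]
    frame = events_to_frame(events)
    back = events_from_frame(frame)
    assert back == events
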