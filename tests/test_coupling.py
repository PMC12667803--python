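"""SO phase extraction and circular statistics."""

import numpy as np
import pandas as pd
import pytest

from sophase.coupling import (channel_phase_stats, channel_stats_table,
                              phases_at_spindles, rayleigh_test,
                              so_phase_series)
from sophase.errors import UndefinedStatisticError
from sophase.types import Recording, SPINDLE_COLUMNS

FS = 128.0


@pytest.fixture(scope="module")
def cosine_phase():
    t = np.arange(int(60 * FS)) / FS
    rec = Recording((50.0 * np.cos(2 * np.pi * 1.0 * t))[None, :], FS, ["Cz"])
    phase, valid = so_phase_series(rec)
    return t, phase[0], valid[0]


class TestSoPhaseSeries:
    def test_phase_zero_at_signal_maxima(self, cosine_phase):
        t, phase, valid = cosine_phase
        peaks = np.arange(5, 55) * int(FS)  # t = 5..54 s, cos maxima
        assert valid[peaks].all()
        assert np.abs(phase[peaks]).max() < 0.05

    def test_phase_pi_at_minima(self, cosine_phase):
        t, phase, valid = cosine_phase
        troughs = (np.arange(5, 54) + 0.5) * FS
        vals = phase[troughs.astype(int)]
        assert np.abs(np.abs(vals) - np.pi).max() < 0.05

    def test_phase_minus_half_pi_at_upgoing_zero_crossings(self, cosine_phase):
        t, phase, valid = cosine_phase
        up = (np.arange(5, 54) + 0.75) * FS  # cos up-going crossings
        vals = phase[up.astype(int)]
        assert np.abs(vals + np.pi / 2).max() < 0.05

    def test_edges_and_masked_gaps_marked_unreliable(self):
        t = np.arange(int(60 * FS)) / FS
        rec = Recording((50.0 * np.cos(2 * np.pi * t))[None, :], FS, ["Cz"])
        usable = np.ones((1, t.size), dtype=bool)
        usable[0, int(30 * FS): int(35 * FS)] = False
        phase, valid = so_phase_series(rec, usable=usable)
        assert not valid[0, :int(2 * FS)].any()          # recording edge
        assert not valid[0, int(28.5 * FS): int(37 * FS)].any()  # gap + margins
        assert valid[0, int(10 * FS)]
        assert np.isnan(phase[0, int(32 * FS)])


class TestPhasesAtSpindles:
    def _spindles(self, peaks, channel="Cz"):
        return pd.DataFrame(
            [(channel, p - 0.5, p + 0.5, p, 5.0, "zscore") for p in peaks],
            columns=SPINDLE_COLUMNS)

    def test_peak_at_so_maximum_reads_phase_zero(self, cosine_phase):
        t, phase, valid = cosine_phase
        samples = phases_at_spindles(phase[None, :], valid[None, :], FS,
                                     self._spindles([10.0, 20.0]), ["Cz"])
        assert len(samples) == 2
        assert np.abs(samples.phase).max() < 0.05
        assert (samples.source == "continuous_SO").all()
        assert (samples.position == 3).all()  # Cz is the central row

    def test_sw_gating_with_no_slow_waves_returns_empty(self, cosine_phase):
        t, phase, valid = cosine_phase
        sw = pd.DataFrame(columns=["channel", "down_zc_s", "up_zc_s",
                                   "trough_s", "envelope_peak"])
        samples = phases_at_spindles(phase[None, :], valid[None, :], FS,
                                     self._spindles([10.0]), ["Cz"], sw_events=sw)
        assert len(samples) == 0

    def test_sw_gating_keeps_only_peaks_near_a_slow_wave(self, cosine_phase):
        t, phase, valid = cosine_phase
        sw = pd.DataFrame([("Cz", 9.8, 10.4, 10.1, 50.0)],
                          columns=["channel", "down_zc_s", "up_zc_s",
                                   "trough_s", "envelope_peak"])
        # default window spans the full SW cycle: [9.2, 11.0] here
        samples = phases_at_spindles(phase[None, :], valid[None, :], FS,
                                     self._spindles([10.0, 10.9, 20.0]), ["Cz"],
                                     sw_events=sw)
        assert list(samples.event_time_s) == [10.0, 10.9]
        assert (samples.source == "SW_event").all()
        # zero margin restricts to the negative half-wave itself
        literal = phases_at_spindles(phase[None, :], valid[None, :], FS,
                                     self._spindles([10.0, 10.9, 20.0]), ["Cz"],
                                     sw_events=sw, sw_margin_half_waves=0.0)
        assert list(literal.event_time_s) == [10.0]

    def test_extracted_phases_match_injected_targets(self, short_prepared):
        """Signal-level ground truth: phases read at the true injection times
        agree with the generator's targets."""
        _, rec, usable, gt = short_prepared
        phase, valid = so_phase_series(rec, usable=usable)
        errs = []
        for ch, grp in gt.spindles.groupby("channel"):
            ci = rec.channel_labels.index(ch)
            for _, row in grp.iterrows():
                idx = int(round(row.center_s * rec.fs))
                if valid[ci, idx]:
                    errs.append(np.angle(np.exp(1j * (phase[ci, idx] - row.phase))))
        errs = np.asarray(errs)
        assert len(errs) > 100
        assert np.sqrt((errs ** 2).mean()) < 0.1


class TestCircularStats:
    def test_identical_phases_have_unit_resultant(self):
        st = channel_phase_stats(np.array([np.pi / 2, np.pi / 2]))
        assert st.mean_phase == pytest.approx(np.pi / 2)
        assert st.resultant_R == pytest.approx(1.0)

    def test_antipodal_phases_cancel_and_mean_is_undefined(self):
        st = channel_phase_stats(np.array([0.0, np.pi]))
        assert st.resultant_R == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(st.mean_phase)

    def test_empty_sample_raises(self):
        with pytest.raises(UndefinedStatisticError):
            channel_phase_stats(np.array([]))

    def test_rayleigh_p_matches_independent_implementation(self, rng):
        # pingouin uses Zar's closed-form approximation rather than the
        # exp(-Z) series; the two agree closely over the practical range
        pingouin = pytest.importorskip("pingouin")
        for n in (10, 50, 500):
            phases = rng.vonmises(0.0, 0.5, n)
            ours = rayleigh_test(phases)
            _, theirs = pingouin.circ_rayleigh(phases)
            assert ours == pytest.approx(theirs, rel=0.05, abs=5e-3)

    def test_rotation_equivariance_of_channel_stats(self, rng):
        phases = rng.vonmises(0.3, 2.0, 200)
        base = channel_phase_stats(phases)
        for c in (0.7, -2.0, np.pi):
            rot = channel_phase_stats(np.angle(np.exp(1j * (phases + c))))
            diff = np.angle(np.exp(1j * (rot.mean_phase - base.mean_phase - c)))
            assert abs(diff) < 1e-9
            assert rot.resultant_R == pytest.approx(base.resultant_R)
            assert rot.rayleigh_p == pytest.approx(base.rayleigh_p)

    def test_resultant_in_unit_interval_and_p_in_unit_interval(self, rng):
        for _ in range(50):
            st = channel_phase_stats(rng.uniform(-np.pi, np.pi,
                                                 rng.integers(2, 100)))
            assert 0.0 <= st.resultant_R <= 1.0
            assert 0.0 < st.rayleigh_p <= 1.0

    def test_montecarlo_rayleigh_agrees_with_series_approximation(self, rng):
        phases = rng.vonmises(0.0, 1.0, 40)
        p_approx = rayleigh_test(phases)
        p_mc = rayleigh_test(phases, method="montecarlo", n_sim=20000,
                             rng=np.random.default_rng(0))
        assert p_mc == pytest.approx(p_approx, abs=0.02)

    def test_stats_table_one_row_per_subject_channel(self, rng):
        df = pd.DataFrame({
            "subject_id": ["a"] * 10 + ["b"] * 10,
            "channel": (["C3"] * 5 + ["O1"] * 5) * 2,
            "position": ([3.0] * 5 + [5.0] * 5) * 2,
            "phase": rng.vonmises(0, 2, 20),
            "event_time_s": np.arange(20.0),
            "source": "continuous_SO",
        })
        table = channel_stats_table(df)
        assert len(table) == 4
        assert set(table.columns) >= {"subject_id", "channel", "position", "n",
                                      "mean_phase", "resultant_R", "rayleigh_p"}
        assert (table.n == 5).all()
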