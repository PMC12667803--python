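"""Circular-linear regression, correlation, and group/subject-level fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sophase.coupling import channel_stats_table
from sophase.errors import InsufficientDataError, UnidentifiableSlopeError
from sophase.precession import (DEFAULT_POSITION_MAP, _resultant_length,
                                assign_positions, circ_linear_corr, fit_group,
                                fit_subject, kempter_fit, phase_position_table,
                                position_for_label, slope_to_degrees,
                                unit_spacing_fraction)
from sophase.synthgen import PhaseGenConfig, generate_phase_dataset
from sophase.types import wrap_phase


def line_dataset(slope, phi0, n_per=10, positions=(1, 2, 3, 4, 5)):
    x = np.repeat(np.asarray(positions, dtype=float), n_per)
    return wrap_phase(phi0 + slope * x), x


class TestPositionMap:
    @pytest.mark.parametrize("label,pos", [("Fp1", 1), ("Fz", 2), ("Cz", 3),
                                           ("P4", 4), ("O2", 5)])
    def test_parasagittal_rows(self, label, pos):
        assert position_for_label(label) == pos

    def test_bipolar_label_maps_to_midpoint(self):
        assert position_for_label("Fp1-F3") == 1.5
        assert position_for_label("Cz-Pz") == 3.5

    def test_non_parasagittal_label_rejected(self):
        samples = pd.DataFrame({"channel": ["T3"], "phase": [0.0]})
        with pytest.raises(KeyError, match="T3"):
            assign_positions(samples)

    def test_map_covers_exactly_the_thirteen_parasagittal_channels(self):
        assert len(DEFAULT_POSITION_MAP) == 13
        assert set(DEFAULT_POSITION_MAP.values()) == {1, 2, 3, 4, 5}

    def test_position_unit_is_a_fifth_row_spacing_of_the_1020_layout(self):
        assert unit_spacing_fraction() == pytest.approx(0.20)

    def test_slope_unit_conversion_to_degrees(self):
        assert slope_to_degrees(-0.9) == pytest.approx(-51.566, abs=0.001)


class TestKempterFit:
    def test_noiseless_line_recovered_to_grid_resolution(self):
        phases, x = line_dataset(-0.5, 1.0)
        a, phi0 = kempter_fit(phases, x)
        assert a == pytest.approx(-0.5, abs=1e-3)
        assert phi0 == pytest.approx(1.0, abs=1e-3)

    def test_constant_phases_give_zero_slope_with_unit_resultant(self):
        x = np.repeat([1.0, 2.0, 3.0], 5)
        phases = np.full(15, 0.8)
        a, phi0 = kempter_fit(phases, x)
        assert a == pytest.approx(0.0, abs=1e-6)
        assert phi0 == pytest.approx(0.8, abs=1e-6)
        assert _resultant_length(phases, x, np.array([a]))[0] == pytest.approx(1.0)

    def test_noisy_fit_matches_dense_grid_oracle(self, rng):
        x = np.repeat(np.arange(1.0, 6.0), 100)
        phases = wrap_phase(rng.vonmises(1.0 - 0.9 * x, 4.0))
        a, _ = kempter_fit(phases, x)
        assert a == pytest.approx(-0.9, abs=0.1)
        dense = np.arange(-np.pi, np.pi + 5e-4, 1e-3)
        oracle = dense[np.argmax(_resultant_length(phases, x, dense))]
        assert a == pytest.approx(oracle, abs=1e-3)

    def test_identical_positions_unidentifiable(self):
        with pytest.raises(UnidentifiableSlopeError):
            kempter_fit([0.1, 0.2, 0.3], [2.0, 2.0, 2.0])

    def test_fewer_than_three_samples_insufficient(self):
        with pytest.raises(InsufficientDataError):
            kempter_fit([0.1, 0.2], [1.0, 2.0])

    def test_doubling_positions_halves_the_slope(self):
        phases, x = line_dataset(-0.4, 0.5)
        a1, _ = kempter_fit(phases, x)
        a2, _ = kempter_fit(phases, 2 * x)
        assert a2 == pytest.approx(a1 / 2, abs=2e-3)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(shift=st.floats(-np.pi, np.pi),
           seed=st.integers(0, 10_000))
    def test_phase_shift_moves_offset_only(self, shift, seed):
        rng = np.random.default_rng(seed)
        x = np.repeat(np.arange(1.0, 6.0), 20)
        phases = wrap_phase(rng.vonmises(0.5 - 0.7 * x, 3.0))
        a1, p1 = kempter_fit(phases, x)
        a2, p2 = kempter_fit(wrap_phase(phases + shift), x)
        assert a2 == pytest.approx(a1, abs=2e-3)
        assert np.angle(np.exp(1j * (p2 - p1 - shift))) == pytest.approx(0, abs=2e-2)

    def test_wrap_invariance_adding_2pi_to_a_subset(self, rng):
        x = np.repeat(np.arange(1.0, 6.0), 20)
        phases = wrap_phase(rng.vonmises(0.5 - 0.7 * x, 3.0))
        bumped = phases.copy()
        bumped[::3] += 2 * np.pi
        assert kempter_fit(phases, x) == pytest.approx(kempter_fit(bumped, x))


class TestCircLinearCorr:
    def test_independent_phases_yield_near_zero_R(self, rng):
        x = np.repeat(np.arange(1.0, 6.0), 400)
        phases = rng.uniform(-np.pi, np.pi, x.size)
        R, p = circ_linear_corr(phases, x)
        assert R < 0.1

    def test_fixed_dataset_matches_hand_coded_formula(self):
        # frozen 10-point fixture; expected value recomputed from the three
        # Pearson correlations coded independently below
        phases = np.array([0.2, -0.5, 1.1, 2.8, -3.0, 0.0, 1.9, -1.2, 2.2, 0.7])
        x = np.array([1.0, 1, 2, 2, 3, 3, 4, 4, 5, 5])

        def pearson(u, v):
            u = u - u.mean()
            v = v - v.mean()
            return (u * v).sum() / np.sqrt((u * u).sum() * (v * v).sum())

        rcx = pearson(np.cos(phases), x)
        rsx = pearson(np.sin(phases), x)
        rcs = pearson(np.cos(phases), np.sin(phases))
        expected = np.sqrt((rcx**2 + rsx**2 - 2 * rcx * rsx * rcs) / (1 - rcs**2))
        R, _ = circ_linear_corr(phases, x)
        assert R == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin_circ_corrcl(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = np.repeat(np.arange(1.0, 6.0), 30)
        phases = wrap_phase(rng.vonmises(1.0 - 0.6 * x, 2.0))
        R, p = circ_linear_corr(phases, x)
        r_pg, p_pg = pingouin.circ_corrcl(phases, x)
        assert R == pytest.approx(r_pg, abs=1e-9)
        assert p == pytest.approx(p_pg, rel=1e-6)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_R_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        x = rng.normal(size=n)
        phases = rng.uniform(-np.pi, np.pi, n)
        R, p = circ_linear_corr(phases, x)
        assert 0.0 <= R <= 1.0
        assert 0.0 < p <= 1.0

    def test_degenerate_variance_rejected(self):
        with pytest.raises(UnidentifiableSlopeError):
            circ_linear_corr([0.1, 0.1, 0.1, 0.1], [1.0, 2.0, 3.0, 4.0])


def _cohort_stats(slope, kappa, n_subjects, seed0, phase0=2.7, n_per=60):
    frames = []
    for s in range(n_subjects):
        cfg = PhaseGenConfig(slope_true=slope, phase0=phase0, kappa=kappa,
                             n_per_channel=n_per, seed=seed0 + s)
        frames.append(generate_phase_dataset(cfg, subject_id=f"s{s:03d}"))
    return channel_stats_table(pd.concat(frames, ignore_index=True))


class TestGroupAndSubjectFits:
    def test_group_fit_recovers_consistent_noiseless_slope(self):
        stats = _cohort_stats(-0.8, np.inf, n_subjects=20, seed0=100)
        fit = fit_group(stats)
        assert fit.level == "group_mean_phases"
        assert fit.slope_a == pytest.approx(-0.8, abs=0.01)
        assert fit.p_value < 0.05 and fit.significant

    def test_uniform_phases_fail_rayleigh_gate_everywhere(self):
        frames = []
        for s in range(2):
            cfg = PhaseGenConfig(slope_true=0.0, kappa=0.0, n_per_channel=40,
                                 positions={"C3": 3, "O1": 5}, seed=50 + s)
            frames.append(generate_phase_dataset(cfg, subject_id=f"u{s}"))
        stats = channel_stats_table(pd.concat(frames, ignore_index=True))
        with pytest.raises(InsufficientDataError):
            fit_group(stats)

    def test_group_slope_invariant_to_subject_offset_shifts(self):
        a = _cohort_stats(-0.9, 8.0, n_subjects=10, seed0=200, phase0=2.7)
        b = _cohort_stats(-0.9, 8.0, n_subjects=10, seed0=300, phase0=1.2)
        b["subject_id"] = "x" + b["subject_id"]
        fit = fit_group(pd.concat([a, b], ignore_index=True))
        assert fit.slope_a == pytest.approx(-0.9, abs=0.1)

    def test_subject_raw_fit_equals_group_fit_on_noiseless_data(self):
        cfg = PhaseGenConfig(slope_true=-0.6, phase0=1.0, kappa=np.inf,
                             n_per_channel=20, seed=0)
        df = generate_phase_dataset(cfg)
        sub = fit_subject(df)
        stats = _cohort_stats(-0.6, np.inf, n_subjects=5, seed0=40, phase0=1.0)
        grp = fit_group(stats)
        assert sub.slope_a == pytest.approx(grp.slope_a, abs=1e-3)
        assert sub.level == "subject_raw_phases"

    def test_raw_phase_R_lower_than_group_mean_phase_R(self):
        """Raw phases spread around the line; subject mean phases sit on it.
        The raw-level correlation is therefore lower than the group-level one
        computed from the same subjects' mean phases."""
        frames = []
        for s in range(12):
            cfg = PhaseGenConfig(slope_true=-0.9, kappa=2.0, n_per_channel=80,
                                 seed=700 + s)
            frames.append(generate_phase_dataset(cfg, subject_id=f"s{s}"))
        pooled = pd.concat(frames, ignore_index=True)
        raw_fit = fit_subject(pooled)
        grp_fit = fit_group(channel_stats_table(pooled))
        assert raw_fit.corr_R < grp_fit.corr_R

    def test_regression_line_passes_through_position_circular_means(self):
        cfg = PhaseGenConfig(slope_true=-0.9, kappa=8.0, n_per_channel=200,
                             seed=11)
        df = generate_phase_dataset(cfg)
        fit = fit_subject(df)
        for x, grp in df.groupby("position"):
            mean = np.angle(np.exp(1j * grp.phase.to_numpy()).mean())
            line = fit.phase_offset_phi0 + fit.slope_a * x
            assert abs(np.angle(np.exp(1j * (mean - line)))) < 0.15

    def test_below_sample_floor_raises(self):
        df = generate_phase_dataset(
            PhaseGenConfig(n_per_channel=1, seed=0,
                           positions={"C3": 3, "O1": 5}))
        with pytest.raises(InsufficientDataError):
            fit_subject(df, min_n=10)


class TestPhasePositionTable:
    def test_points_doubled_with_2pi_offset_and_line_through_phi0(self, rng):
        df = generate_phase_dataset(PhaseGenConfig(kappa=4.0, n_per_channel=20,
                                                   seed=5))
        fit = fit_subject(df)
        points, line = phase_position_table(fit, df)
        n = len(df)
        assert len(points) == 2 * n
        lower, upper = points.iloc[:n], points.iloc[n:]
        assert np.allclose(upper.phase.to_numpy() - lower.phase.to_numpy(),
                           2 * np.pi)
        at0 = line[(line.x == 0.0) & (line["copy"] == 0)]
        assert np.allclose(wrap_phase(at0.phase.to_numpy()),
                           wrap_phase(fit.phase_offset_phi0))
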