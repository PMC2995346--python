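"""Stimulus synthesis: grating profiles, two-stroke sequences, drift."""

import numpy as np
import pytest

from twostroke.stimulus import (
    SamplingGrid,
    StimulusSpec,
    make_drifting_grating_xt,
    make_grating_profile,
    make_repeating_xt,
    make_two_stroke_xt,
    spec_for_isi,
)


class TestGratingProfile:
    def test_amplitude_and_phase_zero(self, grid):
        spec = StimulusSpec()
        v = make_grating_profile(0.0, spec, grid)
        assert v[0] == pytest.approx(0.0, abs=1e-12)  # sin(0) = 0
        assert np.max(np.abs(v)) <= 0.5 + 1e-12
        # sampled maximum falls just short of the true peak of the sine
        assert np.max(np.abs(v)) == pytest.approx(0.5, abs=0.005)
        assert len(v) == grid.n_x

    def test_quarter_period_shift_identity(self, grid):
        # sf = 1.25 cpd: quarter period = 0.2 deg = 4 samples, and the
        # 8-deg window holds a whole number of periods, so roll is exact
        spec = StimulusSpec(spatial_frequency=1.25)
        v0 = make_grating_profile(0.0, spec, grid)
        v90 = make_grating_profile(90.0, spec, grid)
        assert np.allclose(v90, np.roll(v0, -4), atol=1e-12)

    def test_invalid_spatial_frequency_rejected(self, grid):
        with pytest.raises(ValueError):
            StimulusSpec(spatial_frequency=-1.6)


class TestTwoStroke:
    @pytest.mark.parametrize(
        "isi, n_active", [(0.0, 40), (0.085, 74), (0.315, 166)]
    )
    def test_active_duration(self, grid, isi, n_active):
        # 5 frames of 40 ms + 2 ISIs; 5 ms sampling
        stim = make_two_stroke_xt(spec_for_isi(isi, "single_cycle"), grid)
        nonzero = np.flatnonzero(np.any(stim.values != 0, axis=0))
        span = nonzero[-1] - nonzero[0] + 1
        if isi == 0:
            assert span == n_active
        else:
            assert span == n_active  # sequence ends with a grating frame
        # centred: padding split equally, extra sample after the sequence
        assert nonzero[0] == (grid.n_t - n_active) // 2

    def test_blank_epochs_are_exactly_zero(self, grid):
        stim = make_two_stroke_xt(spec_for_isi(0.085, "single_cycle"), grid)
        start = (grid.n_t - 74) // 2
        # frame = 8 samples, ISI = 17 samples: first ISI spans [8, 25)
        assert np.all(stim.values[:, start + 8 : start + 25] == 0)
        assert np.all(stim.values[:, : start] == 0)
        assert np.all(stim.values[:, start + 74 :] == 0)

    def test_psychophysical_timing_range(self):
        # display-frame analogue: 41.67 ms gratings, longest ISI 316.7 ms
        grid = SamplingGrid(dt=1.0 / 1200.0)
        frame = 5.0 / 120.0
        for isi_frames, expect_ms in [(0, 208), (38, 841)]:
            spec = StimulusSpec(frame_duration=frame, isi_duration=isi_frames / 120.0)
            stim = make_two_stroke_xt(spec, grid)
            nz = np.flatnonzero(np.any(stim.values != 0, axis=0))
            span_ms = (nz[-1] - nz[0] + 1) * grid.dt * 1000.0
            assert int(span_ms) == expect_ms

    def test_sequence_longer_than_window_rejected(self):
        grid = SamplingGrid(t_extent=0.25)
        with pytest.raises(ValueError):
            make_two_stroke_xt(spec_for_isi(0.315, "single_cycle"), grid)

    def test_zero_mean_over_whole_periods(self, grid):
        spec = StimulusSpec(isi_duration=0.125, spatial_frequency=1.25)
        stim = make_two_stroke_xt(spec, grid)
        assert np.allclose(stim.values.mean(axis=0), 0.0, atol=1e-12)

    def test_phase_step_reversal_is_spatial_mirror(self, grid):
        # sf = 1.25 cpd: reflecting about x = 1/(2*sf) = 0.4 deg maps the
        # +90-step stimulus onto the -90-step one exactly on this grid
        plus = make_two_stroke_xt(
            StimulusSpec(isi_duration=0.125, spatial_frequency=1.25, phase_step=90.0),
            grid,
        ).values
        minus = make_two_stroke_xt(
            StimulusSpec(isi_duration=0.125, spatial_frequency=1.25, phase_step=-90.0),
            grid,
        ).values
        assert np.allclose(np.roll(plus[::-1, :], 9, axis=0), minus, atol=1e-12)


class TestRepeating:
    def test_tiling_reproduces_single_cycle(self, grid):
        isi = 0.040
        rep = make_repeating_xt(spec_for_isi(isi, "repeating"), grid)
        single = make_two_stroke_xt(spec_for_isi(isi, "single_cycle"), grid)
        n_cycle = 56  # 5*8 + 2*8 samples
        start = (grid.n_t - n_cycle) // 2
        assert np.array_equal(
            rep.values[:, :n_cycle], single.values[:, start : start + n_cycle]
        )

    def test_at_least_five_full_cycles(self, grid):
        rep = make_repeating_xt(spec_for_isi(0.040, "repeating"), grid)
        n_cycle = 56
        assert grid.n_t // n_cycle >= 5
        for c in range(1, grid.n_t // n_cycle):
            assert np.array_equal(
                rep.values[:, c * n_cycle : (c + 1) * n_cycle],
                rep.values[:, :n_cycle],
            )

    def test_isi_columns_blank(self, grid):
        rep = make_repeating_xt(spec_for_isi(0.040, "repeating"), grid)
        assert np.all(rep.values[:, 8:16] == 0)  # first ISI epoch
        assert np.all(rep.values[:, 32:40] == 0)  # second ISI epoch

    def test_mode_mismatch_rejected(self, grid):
        with pytest.raises(ValueError):
            make_repeating_xt(spec_for_isi(0.040, "single_cycle"), grid)
        with pytest.raises(ValueError):
            make_two_stroke_xt(spec_for_isi(0.040, "repeating"), grid)


class TestDriftingGrating:
    def test_travelling_wave_identity(self, grid):
        # sf*dx_shift = tf*dt_shift = 0.25 cycles
        v = make_drifting_grating_xt(1.25, 5.0, +1, grid=grid).values
        assert np.allclose(v[4:, 10:], v[:-4, :-10], atol=1e-12)

    def test_stationary_grating_constant_in_time(self, grid):
        v = make_drifting_grating_xt(1.25, 0.0, +1, grid=grid).values
        assert np.allclose(v, v[:, :1], atol=1e-12)

    def test_direction_flip_is_spatial_mirror_negated(self, grid):
        # v(-x, t; +1) = -v(x, t; -1) on a whole-period window
        vp = make_drifting_grating_xt(1.25, 5.0, +1, grid=grid).values
        vm = make_drifting_grating_xt(1.25, 5.0, -1, grid=grid).values
        mirrored = np.roll(vp[::-1, :], 1, axis=0)  # index i -> -x_i mod period
        assert np.allclose(mirrored, -vm, atol=1e-10)

    @pytest.mark.parametrize("sf, tf", [(11.0, 5.0), (1.25, 120.0)])
    def test_aliased_parameters_rejected(self, grid, sf, tf):
        with pytest.raises(ValueError):
            make_drifting_grating_xt(sf, tf, +1, grid=grid)
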