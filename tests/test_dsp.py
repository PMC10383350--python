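import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radarbp import dsp
from radarbp.core import DisplacementTrace, IFFrameCube, RadarConfig
from radarbp.sim import PulseWaveformModel, generate_displacement, synthesize_if_cube


def make_cube(samples, config):
    return IFFrameCube(samples=samples, config=config)


def tone_cube(config, bin_index, n_frames=None, amplitude=1.0, phase=0.0):
    """Cube whose every frame is a pure complex tone landing on one FFT bin."""
    n = config.adc_samples_per_chirp
    m = np.arange(n)
    frame = amplitude * np.exp(1j * (2 * np.pi * bin_index * m / n + phase))
    return make_cube(np.tile(frame, (config.n_frames, 1)), config)


@pytest.fixture
def tiny_config():
    return RadarConfig(n_frames=16)


class TestRangeFFT:
    def test_tone_argmax_every_frame(self, tiny_config):
        cube = tone_cube(tiny_config, bin_index=5)
        rt = dsp.range_fft(cube, window_name="rect")
        assert np.all(np.argmax(np.abs(rt.values), axis=1) == 5)

    def test_zero_cube_gives_zero_map(self, tiny_config):
        cube = make_cube(np.zeros((16, 128), dtype=complex), tiny_config)
        rt = dsp.range_fft(cube)
        assert np.all(rt.values == 0)

    def test_two_tone_frame_against_dft_sum_oracle(self, tiny_config):
        n = 128
        m = np.arange(n)
        frame = 1.0 * np.exp(2j * np.pi * 12 * m / n) + 0.4 * np.exp(2j * np.pi * 40 * m / n)
        cube = make_cube(np.tile(frame, (16, 1)), tiny_config)
        rt = dsp.range_fft(cube, window_name="rect")
        # oracle: direct DFT sum
        oracle = np.array([np.sum(frame * np.exp(-2j * np.pi * k * m / n)) for k in range(n)])
        assert rt.values[0] == pytest.approx(oracle, rel=1e-9)
        mags = np.abs(rt.values[0])
        local_max = [
            k for k in range(1, n - 1) if mags[k] > mags[k - 1] and mags[k] > mags[k + 1]
        ]
        assert {12, 40}.issubset(local_max)

    def test_bin_spacing_matches_chirp_geometry(self, tiny_config):
        rt = dsp.range_fft(tone_cube(tiny_config, 3), zero_pad_factor=2)
        assert rt.n_range_bins == 256
        assert rt.bin_spacing_m == pytest.approx(tiny_config.range_bin_spacing_m(256))

    def test_empty_cube_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            cube = make_cube(np.zeros((16, 128), dtype=complex), tiny_config)
            cube.samples = np.zeros((0, 0), dtype=complex)
            dsp.range_fft(cube)


class TestSelectRangeBin:
    def test_synthetic_target_at_half_meter(self, small_config, chest_model):
        trace = generate_displacement(chest_model, small_config)
        cube = synthesize_if_cube(trace, small_config, target_range_m=0.5)
        rt = dsp.range_fft(cube)
        bin_index, _ = dsp.select_range_bin(rt)
        assert bin_index == round(0.5 / rt.bin_spacing_m)

    def test_uniform_map_ties_to_bin_zero_with_warning(self, tiny_config):
        rt = dsp.RangeTimeMap(
            values=np.ones((16, 8), dtype=complex),
            bin_spacing_m=0.1,
            config=tiny_config,
        )
        with pytest.warns(UserWarning, match="tie"):
            bin_index, series = dsp.select_range_bin(rt)
        assert bin_index == 0
        assert series.shape == (16,)

    def test_stronger_target_wins(self, tiny_config):
        # oracle: mean-magnitude sum per bin
        n = 128
        m = np.arange(n)
        frame = 1.0 * np.exp(2j * np.pi * 20 * m / n) + 0.3 * np.exp(2j * np.pi * 60 * m / n)
        cube = make_cube(np.tile(frame, (16, 1)), tiny_config)
        rt = dsp.range_fft(cube, window_name="rect")
        oracle_bin = int(np.argmax(np.abs(rt.values).mean(axis=0)))
        bin_index, _ = dsp.select_range_bin(rt)
        assert bin_index == oracle_bin == 20

    def test_all_zero_map_raises_no_target(self, tiny_config):
        rt = dsp.RangeTimeMap(
            values=np.zeros((16, 8), dtype=complex), bin_spacing_m=0.1, config=tiny_config
        )
        with pytest.raises(dsp.NoTargetError):
            dsp.select_range_bin(rt)


class TestDCCompensate:
    def test_exact_circle_recentered(self):
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        series = np.exp(1j * theta) + (1.0 + 0.5j)
        result = dsp.dc_compensate(series)
        assert result.ok
        assert abs(np.mean(result.series)) < 1e-10
        radii = np.abs(result.series)
        assert np.var(radii) < 1e-20
        assert result.dc_offset == pytest.approx(1.0 + 0.5j, abs=1e-10)

    def test_idempotent_on_zero_offset_input(self):
        theta = np.linspace(0.3, 2.5, 40)
        series = 2.0 * np.exp(1j * theta)
        result = dsp.dc_compensate(series)
        again = dsp.dc_compensate(result.series)
        assert np.max(np.abs(again.series - result.series)) < 1e-12 * 2.0
        assert abs(again.dc_offset) < 1e-12

    def test_quarter_arc_with_noise_against_grid_oracle(self, rng):
        # grid-search circle fit oracle on a noisy quarter arc
        theta = np.linspace(0.0, np.pi / 2, 200)
        offset = 0.3 - 0.2j
        radius = 1.0
        clean = radius * np.exp(1j * theta) + offset
        noise_sigma = radius * 10 ** (-30 / 20)  # SNR 30 dB
        noisy = clean + noise_sigma * (rng.standard_normal(200) + 1j * rng.standard_normal(200)) / np.sqrt(2)
        result = dsp.dc_compensate(noisy)
        assert result.ok
        assert abs(result.dc_offset - offset) < 0.05 * radius

        # independent oracle: coarse grid search over candidate centers
        grid = np.linspace(-0.6, 0.6, 61)
        best, best_cost = None, np.inf
        for cx in grid:
            for cy in grid:
                r = np.abs(noisy - (cx + 1j * cy))
                cost = np.var(r)
                if cost < best_cost:
                    best, best_cost = cx + 1j * cy, cost
        assert abs(result.dc_offset - best) < 0.07 * radius

    def test_collinear_points_flagged(self):
        series = np.linspace(0, 1, 20) * (1 + 1j)
        with pytest.warns(UserWarning, match="collinear"):
            result = dsp.dc_compensate(series)
        assert not result.ok
        assert np.array_equal(result.series, series)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            dsp.dc_compensate(np.ones(4, dtype=complex))

    def test_refit_residual_center_tiny_for_noiseless_arcs(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            span = rng.uniform(1.0, 2 * np.pi)
            start = rng.uniform(0, 2 * np.pi)
            theta = np.linspace(start, start + span, 100)
            offset = complex(*rng.uniform(-3, 3, 2))
            series = np.exp(1j * theta) + offset
            result = dsp.dc_compensate(series)
            refit = dsp.dc_compensate(result.series)
            assert abs(refit.dc_offset) < 1e-6 * result.radius


class TestArctanDemodulate:
    def test_constant_quarter_turn(self):
        series = np.full(16, np.exp(1j * np.pi / 2))
        assert dsp.arctan_demodulate(series) == pytest.approx(np.full(16, np.pi / 2))

    def test_lambda_over_8_phase(self):
        lam = 3.9e-3
        d = lam / 8.0
        phase = 4 * np.pi * d / lam
        series = np.exp(1j * phase) * np.ones(8)
        assert dsp.arctan_demodulate(series)[0] == pytest.approx(np.pi / 2)

    @given(st.lists(st.floats(min_value=-np.pi + 1e-9, max_value=np.pi), min_size=1, max_size=64))
    def test_round_trip_identity(self, phases):
        phases = np.asarray(phases)
        series = np.exp(1j * phases)
        assert dsp.arctan_demodulate(series) == pytest.approx(phases, abs=1e-9)

    def test_zero_magnitude_propagates_previous_phase(self):
        series = np.array([np.exp(1j * 0.7), 0.0, np.exp(1j * 0.9)])
        with pytest.warns(UserWarning, match="zero-magnitude"):
            phase = dsp.arctan_demodulate(series)
        assert phase[1] == pytest.approx(0.7)


class TestUnwrapPhase:
    def test_single_wrap(self):
        raw = np.array([0.0, np.pi - 0.1, -np.pi + 0.1])
        expected = np.array([0.0, np.pi - 0.1, np.pi + 0.1])
        assert dsp.unwrap_phase(raw) == pytest.approx(expected)

    def test_smooth_sequence_unchanged(self):
        raw = np.linspace(-1.0, 1.0, 50)
        assert np.array_equal(dsp.unwrap_phase(raw), raw)

    def test_linear_ramp_recovered(self):
        # analytic ramp oracle: wrap a straight line, unwrap, compare
        t = np.arange(2000)
        ramp = 0.05 * t
        wrapped = np.angle(np.exp(1j * ramp))
        unwrapped = dsp.unwrap_phase(wrapped)
        assert np.max(np.abs(unwrapped - ramp)) < 1e-9

    @given(
        st.lists(st.floats(min_value=-10, max_value=10), min_size=2, max_size=100)
    )
    def test_output_minus_input_is_2pi_multiple(self, values):
        raw = np.asarray(values)
        diff = dsp.unwrap_phase(raw) - raw
        k = diff / (2 * np.pi)
        assert np.max(np.abs(k - np.round(k))) < 1e-9


class TestPhaseToDisplacement:
    def test_quarter_turn_is_lambda_over_8(self):
        lam = 3.9e-3
        trace = dsp.phase_to_displacement(
            np.array([0.0, np.pi / 2]), lam, sample_period_s=5e-4, demean=False
        )
        assert trace.values_mm[1] == pytest.approx(lam * 1e3 / 8.0)
        assert trace.values_mm[1] == pytest.approx(0.4875, abs=1e-4)

    def test_zero_phase_zero_displacement(self):
        trace = dsp.phase_to_displacement(np.zeros(10), 3.9e-3, 5e-4, demean=False)
        assert np.all(trace.values_mm == 0.0)

    def test_full_chain_recovers_simulated_trace(self, small_config, chest_model):
        trace = generate_displacement(chest_model, small_config)
        cube = synthesize_if_cube(trace, small_config)
        recovered = dsp.process_cube(cube)
        truth = trace.values_mm - trace.values_mm.mean()
        assert np.max(np.abs(recovered.values_mm - truth)) < 1e-3


class TestChainProperties:
    def test_end_to_end_linearity(self, small_config):
        base = PulseWaveformModel(heart_rate_hz=1.2, pulse_amplitude_mm=0.1, pulse_width_s=0.15)
        double = PulseWaveformModel(heart_rate_hz=1.2, pulse_amplitude_mm=0.2, pulse_width_s=0.15)
        r1 = dsp.process_cube(synthesize_if_cube(generate_displacement(base, small_config), small_config))
        r2 = dsp.process_cube(synthesize_if_cube(generate_displacement(double, small_config), small_config))
        mask = np.abs(r1.values_mm) > 0.02
        ratio = r2.values_mm[mask] / r1.values_mm[mask]
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_global_gain_invariance(self, small_config, chest_model):
        trace = generate_displacement(chest_model, small_config)
        cube = synthesize_if_cube(trace, small_config)
        gained = IFFrameCube(
            samples=cube.samples * (2.5 * np.exp(0.3j)),
            config=small_config,
        )
        r1 = dsp.process_cube(cube)
        r2 = dsp.process_cube(gained)
        assert np.max(np.abs(r1.values_mm - r2.values_mm)) < 1e-9

    def test_bandpass_removes_respiration(self, small_config):
        model = PulseWaveformModel(
            heart_rate_hz=1.2,
            pulse_amplitude_mm=0.3,
            pulse_width_s=0.15,
            respiration_amplitude_mm=1.0,
            respiration_rate_hz=0.25,
        )
        trace = generate_displacement(model, small_config)
        filtered = dsp.bandpass_filter(trace)
        # respiration (0.25 Hz) energy should drop by orders of magnitude
        t = trace.times_s()
        resp = np.sin(2 * np.pi * 0.25 * t)
        raw_proj = abs(np.dot(trace.values_mm, resp)) / t.size
        filt_proj = abs(np.dot(filtered.values_mm, resp)) / t.size
        assert filt_proj < 0.02 * raw_proj
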