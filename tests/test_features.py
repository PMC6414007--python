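import math

import numpy as np
import pytest

import wheezebench as wb
from wheezebench.errors import DegenerateInputError, ParameterError
from wheezebench.features import (
    FAMILY_COUNTS,
    FEATURE_NAMES,
    FEATURE_REGISTRY,
    ase_band_edges,
    averaged_psd,
    _ase_matrix,
    cepstral_coefficients,
    entropy_features,
    extract_all,
    levinson_durbin,
    lpc_features,
    mean_crossing_irregularity,
    mfcc_features,
    misc_features,
    percentile_frequencies,
    power_ratio,
    renyi_entropy,
    timing_profile,
    tonality_index,
    wavelet_features,
)
from wheezebench.spectral import FrameConfig, modified_periodogram, spectrogram

from conftest import make_event


def _noise_event(seed, n=8000):
    rng = np.random.default_rng(seed)
    return make_event(rng.standard_normal(n))


class TestCanonicalNaming:
    def test_105_names_no_duplicates(self):
        assert len(FEATURE_NAMES) == 105
        assert len(set(FEATURE_NAMES)) == 105

    def test_registry_covers_every_name_once(self):
        assert list(FEATURE_REGISTRY) == FEATURE_NAMES

    def test_family_counts(self):
        from collections import Counter

        by_family = Counter(e.family for e in FEATURE_REGISTRY.values())
        assert dict(by_family) == FAMILY_COUNTS
        assert sum(FAMILY_COUNTS.values()) == 105

    def test_cost_classes_are_valid(self):
        assert {e.domain for e in FEATURE_REGISTRY.values()} <= {
            "time", "spectral", "cepstral", "wavelet"}


class TestAveragedPSD:
    def test_output_length(self, noise_event):
        assert averaged_psd(noise_event).shape == (32,)

    def test_tone_lands_in_band_9(self, sine_event):
        # 500 Hz lies in band 9: [487.5, 548.4375) Hz
        assert np.argmax(averaged_psd(sine_event)) == 8

    def test_white_noise_bands_statistically_flat(self):
        means = np.array([averaged_psd(_noise_event(s)) for s in range(40)])
        grand = means.mean()
        sem = means.std(axis=0, ddof=1) / np.sqrt(means.shape[0])
        assert np.all(np.abs(means.mean(axis=0) - grand) < 3.5 * sem + 1e-12)


class TestWavelet:
    def test_output_length(self, noise_event):
        assert len(wavelet_features(noise_event)) == 20

    def test_constant_signal_details_vanish(self):
        ev = make_event(np.ones(8000), scale=False)
        out = wavelet_features(ev)
        for j in range(1, 6):
            assert out[f"wt_mean_{j}"] == pytest.approx(0.0, abs=1e-8)
        assert out["wt_mean_ratio_5"] == pytest.approx(0.0, abs=1e-8)

    def test_white_noise_energy_partition(self):
        # an orthonormal DWT of white noise spreads unit power evenly
        rng = np.random.default_rng(11)
        ev = make_event(rng.standard_normal(2**15), scale=False)
        out = wavelet_features(ev)
        powers = [out[f"wt_power_{j}"] for j in range(1, 6)]
        assert np.all(np.abs(np.array(powers) - 1.0) < 0.15)

    def test_too_short_rejected(self):
        from wheezebench.features import _wavelet

        with pytest.raises(DegenerateInputError):
            _wavelet(np.ones(16))


def _naive_mfcc(power, freqs, n_filters=26, n_coef=13):
    """Independent textbook mel filterbank + DCT, all explicit loops."""

    def mel(f):
        return 2595.0 * math.log10(1.0 + f / 700.0)

    def imel(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    edges = [imel(mel(0.0) + (mel(4000.0) - mel(0.0)) * i / (n_filters + 1))
             for i in range(n_filters + 2)]
    energies = []
    for i in range(n_filters):
        lo, c, hi = edges[i], edges[i + 1], edges[i + 2]
        e = 0.0
        for f, p in zip(freqs, power):
            if lo < f < c:
                e += p * (f - lo) / (c - lo)
            elif f == c:
                e += p
            elif c < f < hi:
                e += p * (hi - f) / (hi - c)
        energies.append(e)
    floor = 1e-12 * max(energies)
    loge = [math.log(max(e, floor)) for e in energies]
    n = len(loge)
    coefs = []
    for k in range(n_coef):
        s = sum(loge[j] * math.cos(math.pi * k * (2 * j + 1) / (2 * n)) for j in range(n))
        coefs.append(s * math.sqrt((1.0 if k == 0 else 2.0) / n))
    return coefs


class TestMFCC:
    def test_output_length(self, noise_event):
        assert mfcc_features(noise_event).shape == (13,)

    def test_matches_independent_implementation(self):
        ev = _noise_event(123, n=4096)
        ps = modified_periodogram(ev.samples, ev.rate)
        expected = _naive_mfcc(ps.power, ps.freqs)
        assert np.allclose(mfcc_features(ev), expected, atol=1e-8)

    def test_constant_energies_give_zero_higher_coefficients(self):
        coefs = cepstral_coefficients(np.full(26, 3.7))
        assert coefs[0] > 0
        assert np.allclose(coefs[1:], 0.0, atol=1e-12)


class TestLPC:
    def test_output_length(self, noise_event):
        assert len(lpc_features(noise_event)) == 8

    def test_ar1_first_coefficient(self):
        rng = np.random.default_rng(2)
        e = rng.standard_normal(100_000)
        x = np.empty_like(e)
        x[0] = e[0]
        for t in range(1, x.size):
            x[t] = 0.9 * x[t - 1] + e[t]
        out = lpc_features(make_event(x))
        assert out["lpc_coef_1"] == pytest.approx(-0.9, abs=0.02)

    def test_white_noise_error_ratio_near_one(self):
        out = lpc_features(_noise_event(3, n=100_000))
        assert out["lpc_err_ratio_e0_e4"] == pytest.approx(1.0, abs=0.1)

    def test_levinson_matches_toeplitz_solve(self):
        # independent oracle: solve the Yule-Walker system directly
        from scipy.linalg import solve_toeplitz

        rng = np.random.default_rng(9)
        x = rng.standard_normal(4096)
        r = np.correlate(x, x, "full")[x.size - 1 : x.size + 6] / x.size
        a, err = levinson_durbin(r, 6)
        expected = -solve_toeplitz(r[:6], r[1:7])
        assert np.allclose(a, expected, atol=1e-10)
        assert err[6] == pytest.approx(r[0] + np.dot(a, r[1:7]), rel=1e-9)

    def test_too_short_rejected(self):
        from wheezebench.features import _lpc

        with pytest.raises(DegenerateInputError):
            _lpc(np.ones(100), 8000)


class TestPercentileFrequencies:
    def test_white_noise_uniform_spectrum_ratios(self):
        vals = [percentile_frequencies(_noise_event(s, n=16000)) for s in range(20)]
        assert np.mean([v["pfr_25_75"] for v in vals]) == pytest.approx(1 / 3, abs=0.05)
        assert np.mean([v["pfr_50_90"] for v in vals]) == pytest.approx(5 / 9, abs=0.05)

    def test_pure_tone_ratios_are_one(self, sine_event):
        out = percentile_frequencies(sine_event)
        for k in ("pfr_25_75", "pfr_25_90", "pfr_50_75", "pfr_50_90"):
            assert out[k] == pytest.approx(1.0, abs=0.01)

    def test_ordering_against_bruteforce(self):
        for seed in range(10):
            ev = _noise_event(seed, n=2048)
            out = percentile_frequencies(ev)
            ps = modified_periodogram(ev.samples, ev.rate)
            cum = np.cumsum(ps.power) / ps.power.sum()
            for pct, key in ((25, "f25"), (50, "f50"), (75, "f75"), (90, "f90")):
                idx = np.flatnonzero(cum >= pct / 100.0)[0]
                assert out[key] == ps.freqs[idx]
            assert 0 < out["pfr_25_90"] <= out["pfr_25_75"] <= 1


class TestEntropy:
    def test_stationary_periodic_signal(self):
        # 125 Hz period equals the hop, so every frame is identical
        t = np.arange(8000) / 8000.0
        ev = make_event(np.sin(2 * np.pi * 125 * t))
        out = entropy_features(ev)
        assert out["entropy_diff"] == pytest.approx(0.0, abs=1e-9)
        assert out["entropy_ratio"] == pytest.approx(1.0, abs=1e-9)

    def test_uniform_frame_entropy_is_log2_k(self):
        from wheezebench.features import _frame_entropies
        from wheezebench.spectral import Spectrogram

        sg = Spectrogram(frame_times=np.zeros(1), freqs=np.arange(16.0),
                         power=np.ones((1, 16)))
        assert _frame_entropies(sg)[0] == pytest.approx(np.log2(16))

    def test_tone_lowers_mean_entropy(self):
        t = np.arange(8000) / 8000.0
        tone = np.sin(2 * np.pi * 500 * t)
        diffs = []
        for seed in range(20):
            noise = np.random.default_rng(seed).standard_normal(8000)
            em_noise = entropy_features(make_event(noise))["entropy_mean"]
            em_tone = entropy_features(make_event(noise / 10 + tone))["entropy_mean"]
            diffs.append(em_noise - em_tone)
        assert np.mean(diffs) > 0


class TestRenyiEntropy:
    def test_uniform_histogram(self):
        # ramp filling all 100 amplitude bins equally
        ev = make_event(np.linspace(-0.9999, 0.9999, 8000), scale=False)
        assert renyi_entropy(ev) == pytest.approx(np.log(100), abs=1e-6)

    def test_single_bin(self):
        ev = make_event(np.full(8000, 0.5), scale=False)
        assert renyi_entropy(ev) == pytest.approx(0.0)

    def test_matches_direct_formula(self, noise_event):
        counts, _ = np.histogram(noise_event.samples, bins=100, range=(-1, 1))
        p = counts / noise_event.samples.size
        assert renyi_entropy(noise_event) == pytest.approx(-np.log(np.sum(p**2)), abs=1e-12)


class TestPowerRatio:
    def test_tone_in_band_dominates(self):
        t = np.arange(8000) / 8000.0
        rng = np.random.default_rng(0)
        ev = make_event(np.sin(2 * np.pi * 500 * t) + 0.01 * rng.standard_normal(8000))
        assert power_ratio(ev) > 10

    def test_out_of_band_tone_scores_lower(self):
        t = np.arange(8000) / 8000.0
        rng = np.random.default_rng(0)
        noise = 0.05 * rng.standard_normal(8000)
        in_band = power_ratio(make_event(np.sin(2 * np.pi * 500 * t) + noise))
        out_band = power_ratio(make_event(np.sin(2 * np.pi * 1500 * t) + noise))
        assert out_band < in_band


class TestASEFlux:
    def test_band_edges_and_count(self, noise_event):
        # 21 quarter-octave edges bound 20 interior bands; the below-62.5 Hz
        # and above-2000 Hz remainders complete the 22-band envelope
        edges = ase_band_edges()
        assert edges.size == 21
        assert edges[0] == 62.5 and edges[-1] == pytest.approx(2000.0)
        sg = spectrogram(noise_event.samples, 8000, FrameConfig())
        assert _ase_matrix(sg).shape[1] == 22

    def test_stationary_signal_zero_flux(self):
        t = np.arange(8000) / 8000.0
        ev = make_event(np.sin(2 * np.pi * 125 * t))
        assert wb.features.ase_flux(ev) == pytest.approx(0.0, abs=1e-9)

    def test_flux_grows_with_level_alternation(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(8192)
        fluxes = []
        for depth in (2.0, 8.0):
            mod = np.where((np.arange(8192) // 256) % 2 == 0, 1.0, 1.0 / depth)
            fluxes.append(wb.features.ase_flux(make_event(base * mod)))
        assert 0 < fluxes[0] < fluxes[1]


class TestTonality:
    def test_pure_tone_is_fully_tonal(self, sine_event):
        assert tonality_index(sine_event) == pytest.approx(1.0)

    def test_white_noise_is_noise_like(self):
        vals = [tonality_index(_noise_event(s)) for s in range(50)]
        assert np.median(vals) < 0.2

    def test_bounded(self, noise_event, sine_event):
        for ev in (noise_event, sine_event):
            assert 0.0 <= tonality_index(ev) <= 1.0


class TestMCI:
    def test_sine_has_regular_crossings(self, sine_event):
        assert mean_crossing_irregularity(sine_event) == pytest.approx(0.0)

    def test_alternating_intervals_one_three(self):
        # crossing intervals alternate {1, 3}: SD = 1, mean = 2 -> MCI = 0.5
        block = np.array([1.0, -1.0, 1.0, 1.0])
        x = np.tile(block, 200)
        from wheezebench.features import _crossing_intervals

        intervals = _crossing_intervals(x - x.mean())
        assert set(intervals) == {1.0, 3.0}
        assert intervals.std() / intervals.mean() == pytest.approx(0.5, abs=0.005)

    def test_noise_is_irregular(self, noise_event):
        assert mean_crossing_irregularity(noise_event) > 0

    def test_constant_signal_rejected(self):
        with pytest.raises(DegenerateInputError):
            mean_crossing_irregularity(make_event(np.ones(8000), scale=False))


class TestMiscFeatures:
    def test_output_length(self, noise_event):
        assert len(misc_features(noise_event)) == 20

    def test_sine_closed_forms(self, sine_event):
        out = misc_features(sine_event)
        assert out["rms"] == pytest.approx(1 / np.sqrt(2), abs=5e-3)
        assert out["zcr"] == pytest.approx(1000.0, abs=2.0)
        assert out["centroid"] == pytest.approx(500.0, abs=2.0)
        assert out["spread"] < 20.0
        assert out["crest"] > 100.0

    def test_bounds_and_monotone_rolloffs(self, noise_event):
        out = misc_features(noise_event)
        assert 0.0 <= out["brightness"] <= 1.0
        assert 0.0 < out["flatness"] <= 1.0
        assert out["f25"] <= out["f50"] <= out["f75"] <= out["rolloff_85"]
        assert out["rolloff_85"] <= out["rolloff_90"] <= out["rolloff_95"]


class TestExtractAll:
    def test_returns_105_finite_features(self, noise_event):
        fv = extract_all(noise_event)
        assert list(fv.values) == FEATURE_NAMES
        assert np.all(np.isfinite(fv.to_array()))

    def test_deterministic(self, noise_event):
        a = extract_all(noise_event).to_array()
        b = extract_all(noise_event).to_array()
        assert np.array_equal(a, b)

    def test_short_event_rejected_at_construction(self):
        # 40 ms cannot host the framed feature families
        with pytest.raises(DegenerateInputError):
            make_event(np.ones(320))

    def test_family_named_on_degenerate_input(self):
        ev = make_event(np.ones(8000), scale=False)  # never crosses its mean
        with pytest.raises(DegenerateInputError, match="family"):
            extract_all(ev)

    def test_scale_invariant_features(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(8000) * 0.1
        a = extract_all(make_event(x, scale=False))
        b = extract_all(make_event(3.0 * x, scale=False))
        for name in ("tonality_index", "flatness", "pfr_25_75", "pfr_50_90",
                     "mci", "entropy_diff", "entropy_mean"):
            assert a[name] == pytest.approx(b[name], rel=1e-9), name
        assert b["rms"] == pytest.approx(3.0 * a["rms"], rel=1e-9)
        assert b["std"] == pytest.approx(3.0 * a["std"], rel=1e-9)
        assert b["band_power"] == pytest.approx(9.0 * a["band_power"], rel=1e-9)

    def test_serialisation_roundtrip(self, noise_event, tmp_path):
        table = wb.feature_table([noise_event])
        path = tmp_path / "m.csv"
        table.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        assert list(back.columns) == ["recording_id", "label"] + FEATURE_NAMES
        assert np.allclose(back[FEATURE_NAMES].to_numpy(),
                           table[FEATURE_NAMES].to_numpy())


class TestTimingProfile:
    def test_rms_faster_than_mfcc(self, noise_event):
        prof = timing_profile([noise_event], repetitions=5,
                              features=["rms", "mfcc_01"])
        assert prof["rms"] < prof["mfcc_01"]

    def test_single_repetition(self, noise_event):
        prof = timing_profile([noise_event], repetitions=1, features=["rms"])
        assert prof["rms"] > 0

    def test_empty_events_rejected(self):
        with pytest.raises(ParameterError):
            timing_profile([], repetitions=1)
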