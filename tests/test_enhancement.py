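"""Envelope-enhancement unit and property tests.

The load-bearing identities: the critical-band analysis weights are a
partition of unity (band powers conserve bin power), the WOLA resynthesis of
unmodified spectra is exact, no energy is added at stationary segments
(a_slow > 1 forces E_peak = 0 there), and added energy is onset-locked.
"""

import numpy as np
import pytest

from assrlab import (AudioSignal, EnhancementParams, analyze_frames,
                     band_envelopes, build_band_map, enhance, peak_envelope,
                     slow_envelope, synthesize_peak_signal, wola_resynthesize)
from assrlab.enhancement import BandEnvelopeSet
from assrlab.simulate import synthetic_utterance


def _padded_spec(x, params):
    pre = params.frame_length - params.hop
    padded = np.concatenate([np.zeros(pre), x, np.zeros(params.frame_length)])
    return analyze_frames(AudioSignal(padded, params.fs_target), params), pre


# ---------------------------------------------------------------- framing

def test_frame_count_formula(params, rng):
    sig = AudioSignal(rng.standard_normal(16000), 16000.0)
    spec = analyze_frames(sig, params)
    assert spec.values.shape == (497, 65)  # (16000 - 128)//32 + 1
    assert spec.frame_rate == 500.0


def test_zero_signal_gives_zero_spectrogram(params):
    spec = analyze_frames(AudioSignal(np.zeros(1000), 16000.0), params)
    assert np.all(spec.values == 0)


def test_bin_centered_cosine_concentrates_energy(params):
    # single frame of a cosine on bin 8: Hann windowing leaks only to the
    # two adjacent bins
    n = params.frame_length
    x = np.cos(2 * np.pi * 8 * np.arange(n) / n)
    spec = analyze_frames(AudioSignal(x, 16000.0), params)
    mags = np.abs(spec.values[0])
    assert mags[8] > 0
    inside = mags[7:10].sum()
    outside = mags.sum() - inside
    assert outside < 1e-9 * inside


def test_short_signal_rejected(params):
    with pytest.raises(ValueError):
        analyze_frames(AudioSignal(np.ones(64), 16000.0), params)


# ---------------------------------------------------------------- band map

def test_band_map_covers_spectrum_with_23_bands(params):
    bm = build_band_map(params)
    assert bm.n_bands == 23
    assert bm.band_edges[0] == 0.0 and bm.band_edges[-1] == 8000.0
    assert np.all(np.diff(bm.band_edges) > 0)
    # partition of unity over bins -> exact power conservation
    assert np.allclose(bm.analysis_weights.sum(axis=0), 1.0)
    assert np.all(bm.analysis_weights >= 0)
    assert np.allclose(bm.synthesis_weights.sum(axis=1), 1.0)


def test_band_power_conservation(params, rng):
    bm = build_band_map(params)
    power = rng.random(65)
    band_power = bm.analysis_weights @ power
    assert np.isclose(band_power.sum(), power.sum())


def test_band_map_rejects_wrong_band_count():
    with pytest.raises(ValueError):
        build_band_map(EnhancementParams(n_bands=10))


# ---------------------------------------------------------------- envelopes

def test_band_envelope_is_sqrt_of_weighted_power(params):
    bm = build_band_map(params)
    values = np.zeros((3, 65), dtype=complex)
    values[:, 20] = 3.0  # 2500 Hz: interior of the 2320-2700 band (index 15)
    spec = analyze_frames(AudioSignal(np.zeros(1000), 16000.0), params)
    spec = type(spec)(values=values, frame_rate=500.0, bin_freqs=spec.bin_freqs)
    env = band_envelopes(spec, bm)
    band = np.argmax(bm.analysis_weights[:, 20])
    assert np.allclose(env.E[:, band], 3.0 * np.sqrt(bm.analysis_weights[band, 20]))
    assert np.all(env.E >= 0)


def test_slow_envelope_dc_gain(params):
    # constant envelope held long: E_slow -> a_slow * E (Butterworth DC gain 1)
    E = np.ones((2000, 23))
    env = slow_envelope(BandEnvelopeSet(E=E, frame_rate=500.0), params)
    assert np.allclose(env.E_slow[-1], 8.0, rtol=0.01)


def test_slow_envelope_lags_step(params):
    E = np.zeros((500, 23))
    E[100:] = 1.0
    env = slow_envelope(BandEnvelopeSet(E=E, frame_rate=500.0), params)
    # just after the step the filter lags: E_slow < E even with the x8 gain
    assert np.all(env.E_slow[101] < E[101])
    # long after the step the amplified slow envelope exceeds E
    assert np.all(env.E_slow[-1] > E[-1])


def test_peak_envelope_formula(params):
    E = np.full((10, 23), 2.0)
    E_slow = np.full((10, 23), 1.0)
    env = peak_envelope(BandEnvelopeSet(E=E, frame_rate=500.0, E_slow=E_slow),
                        params)
    assert np.allclose(env.E_peak, 3.5)  # (2 - 1) * a_peak
    env2 = peak_envelope(BandEnvelopeSet(E=E, frame_rate=500.0, E_slow=E),
                         params)
    assert np.all(env2.E_peak == 0)


def test_peak_envelope_requires_slow(params):
    with pytest.raises(ValueError):
        peak_envelope(BandEnvelopeSet(E=np.ones((5, 23)), frame_rate=500.0),
                      params)


# ---------------------------------------------------------------- synthesis

def test_wola_roundtrip_is_exact(params, noise_signal):
    spec, pre = _padded_spec(noise_signal.samples, params)
    y = wola_resynthesize(spec, params)
    x = noise_signal.samples
    err = np.linalg.norm(y[pre:pre + x.size] - x) / np.linalg.norm(x)
    assert err < 1e-6


def test_zero_peak_envelope_gives_zero_signal(params, noise_signal):
    spec, _ = _padded_spec(noise_signal.samples, params)
    bm = build_band_map(params)
    env = band_envelopes(spec, bm)
    env = BandEnvelopeSet(E=env.E, frame_rate=env.frame_rate,
                          E_slow=env.E, E_peak=np.zeros_like(env.E))
    p = synthesize_peak_signal(env, spec, bm, params)
    assert np.allclose(p, 0.0)


def test_impulse_peak_band_limits_output(params, noise_signal):
    # E_peak concentrated in one band -> p band-limited to that band's range
    spec, _ = _padded_spec(noise_signal.samples, params)
    bm = build_band_map(params)
    env = band_envelopes(spec, bm)
    e_peak = np.zeros_like(env.E)
    band = 16  # 2700-3150 Hz
    e_peak[200:205, band] = 1.0
    env = BandEnvelopeSet(E=env.E, frame_rate=env.frame_rate, E_slow=env.E,
                          E_peak=e_peak)
    p = synthesize_peak_signal(env, spec, bm, params)
    spec_p = np.abs(np.fft.rfft(p))
    freqs = np.fft.rfftfreq(p.size, 1 / 16000.0)
    lo, hi = bm.band_edges[band], bm.band_edges[band + 1]
    in_band = ((freqs >= lo - 150) & (freqs <= hi + 150))
    assert spec_p[in_band].sum() > 0.95 * spec_p.sum()
    # temporal localization: burst confined near the marked frames
    hop_s = params.hop
    burst = slice(195 * hop_s, 215 * hop_s)
    assert np.sum(p[burst] ** 2) > 0.99 * np.sum(p**2)


# ---------------------------------------------------------------- enhance

def test_enhance_silence(params):
    out = enhance(AudioSignal(np.zeros(16000), 16000.0), params)
    assert np.all(out.samples == 0)
    assert len(out) == 16000


def test_enhance_is_deterministic(params, noise_signal):
    a = enhance(noise_signal, params)
    b = enhance(noise_signal, params)
    assert np.array_equal(a.samples, b.samples)


def test_enhance_stationary_identity(params, noise_signal):
    # a_slow > 1 forces E_peak = 0 once the low-pass has settled, so the
    # enhanced signal equals the input outside the onset transient
    out = enhance(noise_signal, params)
    x, y = noise_signal.samples, out.samples
    settle = 8000  # 0.5 s
    rel = (np.sqrt(np.mean((y[settle:] - x[settle:]) ** 2))
           / np.sqrt(np.mean(x[settle:] ** 2)))
    assert rel < 0.05


def test_enhance_amplifies_onsets(params):
    utt, onsets = synthetic_utterance([0.3, 1.0, 1.8], [1.0, 0.8, 0.9], seed=2)
    out, inter = enhance(utt, params, return_intermediates=True)
    rate, win = 16000, int(0.05 * 16000)
    p = inter["p"]
    mask = np.zeros(p.size, dtype=bool)
    for t0 in onsets:
        i0 = int(t0 * rate)
        r_ee = np.sqrt(np.mean(out.samples[i0:i0 + win] ** 2))
        r_s = np.sqrt(np.mean(utt.samples[i0:i0 + win] ** 2))
        assert r_ee > r_s  # onset strictly amplified
        mask[i0:i0 + win] = True
    # added energy is concentrated in the 50-ms post-onset windows
    assert np.sum(p[mask] ** 2) > 0.5 * np.sum(p**2)
    # steady state untouched
    mid = slice(int(0.6 * rate), int(0.85 * rate))
    ratio = (np.sqrt(np.mean(out.samples[mid] ** 2))
             / np.sqrt(np.mean(utt.samples[mid] ** 2)))
    assert abs(ratio - 1.0) < 0.05


def test_enhance_resamples_input(params, rng):
    sig = AudioSignal(0.1 * rng.standard_normal(44100), 44100.0)
    out = enhance(sig, params)
    assert out.rate == 16000.0
    assert abs(len(out) - 16000) <= 1


def test_params_validation():
    with pytest.raises(ValueError):
        EnhancementParams(a_slow=1.0)
    with pytest.raises(ValueError):
        EnhancementParams(hop=256)
    with pytest.raises(ValueError):
        EnhancementParams(lp_cutoff=400.0)
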