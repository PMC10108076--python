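import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assrlab import (CarrierSpec, ModulatorSpec, StimulusCondition,
                     bin_locked_frequency, make_condition_stimulus,
                     measure_envelope_timing, puls_modulator, sam_modulator,
                     speech_weighted_noise)

RATE = 16000.0


def test_bin_locking():
    assert bin_locked_frequency(4.0) == 3.90625    # 4 cycles / 1.024 s
    assert bin_locked_frequency(20.0) == 19.53125  # 20 cycles / 1.024 s


def test_sam_full_depth_spans_unit_interval():
    m = sam_modulator(ModulatorSpec("SAM", 4.0), 1.024, RATE)
    assert np.isclose(m.min(), 0.0) and np.isclose(m.max(), 1.0)
    depth = (m.max() - m.min()) / (m.max() + m.min())
    assert depth == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(min_value=0.05, max_value=1.0))
def test_sam_measured_depth_equals_requested(depth):
    m = sam_modulator(ModulatorSpec("SAM", 4.0, depth=depth), 1.024, RATE)
    measured = (m.max() - m.min()) / (m.max() + m.min())
    assert measured == pytest.approx(depth, abs=1e-9)


def test_sam_exact_cycles_per_epoch():
    # bin-locked 4 Hz: exactly 4 cycles in one 1.024-s epoch
    m = sam_modulator(ModulatorSpec("SAM", 4.0), 1.024, RATE)
    spec = np.abs(np.fft.rfft(m - m.mean()))
    assert np.argmax(spec) == 4


def test_sam_rejects_nyquist_violation():
    with pytest.raises(ValueError):
        sam_modulator(ModulatorSpec("SAM", 4.0, lock_to_bin=False), 1.0, 6.0)


def test_puls_geometry_20hz():
    # 19.53125 Hz: 51.2-ms period fits 30 ms rise + 10 ms decay + 11.2 ms zero
    spec = ModulatorSpec("PULS", 20.0)
    m = puls_modulator(spec, 1.024, RATE)
    period = int(round(RATE / spec.f_m_exact))
    cycle = m[:period]
    assert np.isclose(cycle.max(), 1.0, atol=1e-3)
    zero_frac = np.mean(cycle < 1e-9)
    assert zero_frac == pytest.approx(11.2 / 51.2, abs=0.02)


def test_puls_rise_and_decay_times():
    timing = measure_envelope_timing(
        puls_modulator(ModulatorSpec("PULS", 4.0), 10.24, RATE),
        bin_locked_frequency(4.0), rate=RATE)
    assert timing["rise_ms"] == pytest.approx(30.0, abs=0.5)
    assert timing["decay_ms"] == pytest.approx(10.0, abs=0.5)
    assert timing["depth"] == pytest.approx(1.0, abs=0.02)


def test_puls_rejects_ramps_longer_than_period():
    with pytest.raises(ValueError):
        ModulatorSpec("PULS", 20.0, rise_ms=40.0, decay_ms=20.0)


@pytest.mark.parametrize("nominal", [4.0, 20.0])
def test_sam_and_puls_share_fundamental(nominal):
    f = bin_locked_frequency(nominal)
    dur = 10.24
    sam = sam_modulator(ModulatorSpec("SAM", nominal), dur, RATE)
    puls = puls_modulator(ModulatorSpec("PULS", nominal), dur, RATE)
    freqs = np.fft.rfftfreq(sam.size, 1 / RATE)
    for env in (sam, puls):
        spec = np.abs(np.fft.rfft(env - env.mean()))
        assert freqs[np.argmax(spec)] == pytest.approx(f, abs=0.01)


def test_speech_weighted_noise_deterministic_and_normalized():
    a = speech_weighted_noise(CarrierSpec(seed=3), 2.0, RATE)
    b = speech_weighted_noise(CarrierSpec(seed=3), 2.0, RATE)
    assert np.array_equal(a.samples, b.samples)
    assert np.sqrt(np.mean(a.samples**2)) == pytest.approx(1.0, rel=1e-9)


def test_flat_spectrum_model_gives_white_noise():
    flat = CarrierSpec(seed=0, ltass_breakpoints=((0.0, 0.0), (8000.0, 0.0)))
    x = speech_weighted_noise(flat, 4.0, RATE).samples
    ac = np.correlate(x, x, mode="full")[x.size - 1:] / np.sum(x**2)
    assert np.max(np.abs(ac[1:50])) < 0.05


def test_ltass_rolloff_matches_model():
    from scipy.signal import welch
    x = speech_weighted_noise(CarrierSpec(seed=1), 30.0, RATE).samples
    freqs, psd = welch(x, fs=RATE, nperseg=4096)
    carrier = CarrierSpec(seed=1)
    # compare measured vs modeled level in octave bands from 500 Hz up
    centers = np.array([700.0, 1400.0, 2800.0, 5600.0])
    for fc in centers:
        band = (freqs >= fc / np.sqrt(2)) & (freqs < fc * np.sqrt(2))
        measured = 10 * np.log10(psd[band].mean())
        ref_band = (freqs >= 250) & (freqs < 500)
        measured -= 10 * np.log10(psd[ref_band].mean())
        model = float(np.mean(carrier.levels_db(freqs[band])))
        assert measured == pytest.approx(model, abs=2.0)


def test_condition_stimulus_duration_and_normalization():
    cond = StimulusCondition(ModulatorSpec("SAM", 4.0), CarrierSpec(seed=2),
                             duration_s=10.24, rate=RATE)
    stim = make_condition_stimulus(cond)
    assert len(stim) == int(10.24 * RATE)
    assert np.max(np.abs(stim.samples)) <= 1.0


def test_condition_stimulus_envelope_depth():
    cond = StimulusCondition(ModulatorSpec("SAM", 4.0), CarrierSpec(seed=2),
                             duration_s=20.48, rate=RATE)
    stim = make_condition_stimulus(cond)
    timing = measure_envelope_timing(stim, bin_locked_frequency(4.0),
                                     is_envelope=False)
    assert timing["depth"] >= 0.95


def test_zero_duration_rejected():
    with pytest.raises(ValueError):
        StimulusCondition(ModulatorSpec("SAM", 4.0), duration_s=0.0)
    with pytest.raises(ValueError):
        speech_weighted_noise(CarrierSpec(), -1.0, RATE)


def test_timing_requires_enough_cycles():
    m = sam_modulator(ModulatorSpec("SAM", 4.0), 1.024, RATE)
    with pytest.raises(ValueError):
        measure_envelope_timing(m, 3.90625, rate=RATE)
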