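"""Amplitude-modulated speech-weighted-noise stimulus synthesis.

Two modulator families are provided at nominal rates of 4 Hz (syllable /
theta) and 20 Hz (phoneme / beta):

* SAM - sinusoidal amplitude modulation, 100% depth by default;
* PULS - pulsatile modulation with a fixed 30 ms linear rise and 10 ms
  linear decay per cycle and zero level in between, which sharpens the
  envelope rise time without changing the modulation rate.

Nominal modulation frequencies are locked to the analysis FFT grid of the
1.024-s EEG epochs (4 -> 3.90625 Hz, 20 -> 19.53125 Hz) so the steady-state
response falls in a single frequency bin. The carrier is Gaussian noise
spectrally shaped to a long-term average speech spectrum (LTASS) model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq
from scipy.signal import hilbert

from .audio import AudioSignal

EPOCH_LEN_S = 1.024


def bin_locked_frequency(nominal_hz: float, epoch_len_s: float = EPOCH_LEN_S) -> float:
    """Nearest frequency with an integer number of cycles per analysis epoch.

    >>> bin_locked_frequency(4.0)
    3.90625
    >>> bin_locked_frequency(20.0)
    19.53125
    """
    cycles = round(nominal_hz * epoch_len_s)
    if cycles < 1:
        raise ValueError("nominal frequency too low for the epoch length")
    return cycles / epoch_len_s


@dataclass(frozen=True)
class ModulatorSpec:
    """Modulation envelope description.

    ``f_m`` is the nominal rate; the generated envelope uses the bin-locked
    rate unless ``lock_to_bin=False``. Rise/decay apply to PULS only.
    """

    kind: str  # "SAM" or "PULS"
    f_m: float
    rise_ms: float = 30.0
    decay_ms: float = 10.0
    depth: float = 1.0
    lock_to_bin: bool = True

    def __post_init__(self):
        if self.kind not in ("SAM", "PULS"):
            raise ValueError("kind must be 'SAM' or 'PULS'")
        if not self.f_m > 0:
            raise ValueError("f_m must be positive")
        if not 0 < self.depth <= 1:
            raise ValueError("depth must be in (0, 1]")
        if self.kind == "PULS":
            period_ms = 1000.0 / self.f_m_exact
            if self.rise_ms + self.decay_ms > period_ms:
                raise ValueError("rise + decay exceed the modulation period")

    @property
    def f_m_exact(self) -> float:
        return bin_locked_frequency(self.f_m) if self.lock_to_bin else self.f_m


@dataclass(frozen=True)
class CarrierSpec:
    """Speech-weighted-noise carrier: an LTASS model plus an RNG seed.

    ``ltass_breakpoints`` is a piecewise-linear spectrum level model in
    (Hz, dB) pairs, linearly interpolated on a log2 frequency axis. The
    default is flat up to 500 Hz with an -8 dB/octave roll-off above,
    emulating the long-term spectrum of running female speech.
    """

    seed: int = 0
    ltass_breakpoints: tuple = ((0.0, 0.0), (500.0, 0.0), (8000.0, -32.0))

    def levels_db(self, freqs: np.ndarray) -> np.ndarray:
        pts = np.asarray(self.ltass_breakpoints, dtype=float)
        f_knots, l_knots = pts[:, 0], pts[:, 1]
        # piecewise-linear in dB on a log2 frequency axis; a zero-frequency
        # knot is floored so DC inherits the lowest knot's level
        floor = 1e-3
        xk = np.log2(np.maximum(f_knots, floor))
        x = np.log2(np.maximum(np.asarray(freqs, dtype=float), floor))
        return np.interp(x, xk, l_knots)


@dataclass(frozen=True)
class StimulusCondition:
    """One experimental condition: modulator x carrier x duration."""

    modulator: ModulatorSpec
    carrier: CarrierSpec = field(default_factory=CarrierSpec)
    duration_s: float = 532.48  # 520 epochs of 1.024 s
    rate: float = 16000.0

    def __post_init__(self):
        n_epochs = self.duration_s / EPOCH_LEN_S
        if abs(n_epochs - round(n_epochs)) > 1e-9 or self.duration_s <= 0:
            raise ValueError("duration_s must be a positive multiple of 1.024 s")


def speech_weighted_noise(carrier: CarrierSpec, duration_s: float, rate: float) -> AudioSignal:
    """Seeded Gaussian noise shaped to the carrier's LTASS model, RMS = 1."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * rate))
    rng = np.random.default_rng(carrier.seed)
    white = rng.standard_normal(n)
    spec = rfft(white)
    freqs = rfftfreq(n, 1.0 / rate)
    gains = 10.0 ** (carrier.levels_db(freqs) / 20.0)
    shaped = irfft(spec * gains, n=n)
    shaped /= np.sqrt(np.mean(shaped**2))
    return AudioSignal(shaped, rate)


def sam_modulator(spec: ModulatorSpec, duration_s: float, rate: float) -> np.ndarray:
    """Sinusoidal envelope m(t) = (1 - d cos(2 pi f t)) / (1 + d).

    At full depth (d = 1) the envelope spans [0, 1] and its measured
    modulation depth (max - min)/(max + min) equals d exactly.
    """
    if spec.kind != "SAM":
        raise ValueError("spec.kind must be SAM")
    f = spec.f_m_exact
    if f >= rate / 2:
        raise ValueError("modulation frequency at or above Nyquist")
    t = np.arange(int(round(duration_s * rate))) / rate
    return (1.0 - spec.depth * np.cos(2 * np.pi * f * t)) / (1.0 + spec.depth)


def puls_modulator(spec: ModulatorSpec, duration_s: float, rate: float) -> np.ndarray:
    """Pulsatile envelope: linear 0->1 rise, linear 1->0 decay, 0 between.

    Each modulation period starts with a ``rise_ms`` ramp to the maximum,
    immediately followed by a ``decay_ms`` ramp back to zero (no plateau);
    the envelope stays at zero for the remainder of the period, preserving
    100% modulation depth at the same fundamental frequency as SAM.
    """
    if spec.kind != "PULS":
        raise ValueError("spec.kind must be PULS")
    f = spec.f_m_exact
    t = np.arange(int(round(duration_s * rate))) / rate
    phase_t = np.mod(t, 1.0 / f)  # seconds into the current period
    rise, decay = spec.rise_ms / 1000.0, spec.decay_ms / 1000.0
    env = np.zeros_like(t)
    up = phase_t < rise
    env[up] = phase_t[up] / rise
    down = (phase_t >= rise) & (phase_t < rise + decay)
    env[down] = 1.0 - (phase_t[down] - rise) / decay
    return env * spec.depth + (1 - spec.depth) / 2 if spec.depth < 1 else env


def make_condition_stimulus(cond: StimulusCondition) -> AudioSignal:
    """Carrier times modulator, peak-normalized to 0.99 full scale."""
    carrier = speech_weighted_noise(cond.carrier, cond.duration_s, cond.rate)
    if cond.modulator.kind == "SAM":
        env = sam_modulator(cond.modulator, cond.duration_s, cond.rate)
    else:
        env = puls_modulator(cond.modulator, cond.duration_s, cond.rate)
    x = carrier.samples * env
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.99 * x / peak
    return AudioSignal(x, cond.rate)


def _cycle_average(envelope: np.ndarray, rate: float, f_m: float) -> np.ndarray:
    """Fold an envelope on the exact modulation period and average per phase bin."""
    n_bins = int(rate / f_m)
    t = np.arange(envelope.size) / rate
    bins = (np.mod(t * f_m, 1.0) * n_bins).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    sums = np.bincount(bins, weights=envelope, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    return sums / np.maximum(counts, 1)


def measure_envelope_timing(stimulus, f_m: float, rate: float | None = None,
                            is_envelope: bool | None = None) -> dict:
    """Measure rise time, decay time and modulation depth of a stimulus.

    The (Hilbert) envelope is folded on the modulation period and
    cycle-averaged; rise time is the 5%-95% crossing interval rescaled to the
    full ramp (divided by 0.9), decay time likewise on the falling flank, and
    depth is (max - min)/(max + min) of the folded cycle.

    ``stimulus`` may be an :class:`AudioSignal` (envelope extracted via the
    Hilbert transform) or a raw non-negative envelope array with ``rate``
    given. Requires at least 10 modulation cycles.
    """
    if isinstance(stimulus, AudioSignal):
        x, rate = stimulus.samples, stimulus.rate
        if is_envelope is None:
            is_envelope = bool(np.all(x >= 0))
    else:
        if rate is None:
            raise ValueError("rate required for a bare array")
        x = np.asarray(stimulus, dtype=float)
        if is_envelope is None:
            is_envelope = bool(np.all(x >= 0))
    if x.size / rate * f_m < 10:
        raise ValueError("need at least 10 modulation cycles")
    env = x if is_envelope else np.abs(hilbert(x))
    cyc = _cycle_average(env, rate, f_m)
    n = cyc.size
    dt_ms = 1000.0 / rate * (rate / f_m) / n  # ms per phase bin
    i_min, i_max = int(np.argmin(cyc)), int(np.argmax(cyc))
    lo, hi = cyc[i_min], cyc[i_max]
    depth = (hi - lo) / (hi + lo) if hi + lo > 0 else 0.0
    # rotate so the cycle starts at the minimum
    cyc = np.roll(cyc, -i_min)
    i_pk = int(np.argmax(cyc))
    thr05, thr95 = lo + 0.05 * (hi - lo), lo + 0.95 * (hi - lo)
    rising = cyc[: i_pk + 1]
    above = np.nonzero(rising >= thr95)[0]
    t95 = above[0] if above.size else i_pk
    below = np.nonzero(rising[: t95 + 1] <= thr05)[0]
    t05 = below[-1] if below.size else 0
    rise_ms = (t95 - t05) * dt_ms / 0.9
    falling = cyc[i_pk:]
    under = np.nonzero(falling <= thr05)[0]
    f05 = under[0] if under.size else falling.size - 1
    over = np.nonzero(falling[: f05 + 1] >= thr95)[0]
    f95 = over[-1] if over.size else 0
    decay_ms = (f05 - f95) * dt_ms / 0.9
    return {"rise_ms": float(rise_ms), "decay_ms": float(decay_ms),
            "depth": float(depth)}
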