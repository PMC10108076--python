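"""Mono audio container and basic I/O.

Amplitudes are dimensionless with a nominal full-scale range of [-1, 1];
sampling rates are in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly


@dataclass(frozen=True)
class AudioSignal:
    """A mono sampled waveform.

    Parameters
    ----------
    samples : ndarray
        1-D float array of amplitudes.
    rate : float
        Sampling frequency in Hz.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "rate", float(self.rate))

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.rate

    def __len__(self) -> int:
        return self.samples.size


def resample_audio(signal: AudioSignal, target_rate: float) -> AudioSignal:
    """Resample to ``target_rate`` with a polyphase anti-aliased resampler.

    Identity when the rates already match. Duration is preserved to within
    one sample period.
    """
    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if target_rate == signal.rate:
        return signal
    ratio = Fraction(target_rate / signal.rate).limit_denominator(10_000)
    out = resample_poly(signal.samples, ratio.numerator, ratio.denominator)
    return AudioSignal(out, target_rate)


def read_wav(path) -> AudioSignal:
    """Read a mono PCM-16 or float32 WAV file, scaled to [-1, 1] floats."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    if data.dtype == np.int16:
        data = data / 32768.0
    elif data.dtype == np.int32:
        data = data / 2147483648.0
    return AudioSignal(np.asarray(data, dtype=np.float64), float(rate))


def write_wav(path, signal: AudioSignal, dtype: str = "float32") -> None:
    """Write a mono WAV file as float32 (default) or PCM-16."""
    if dtype == "float32":
        wavfile.write(path, int(signal.rate), signal.samples.astype(np.float32))
    elif dtype == "int16":
        clipped = np.clip(signal.samples, -1.0, 1.0)
        wavfile.write(path, int(signal.rate), (clipped * 32767).astype(np.int16))
    else:
        raise ValueError("dtype must be 'float32' or 'int16'")
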