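"""Seeded synthetic EEG cohorts and audio fixtures.

The EEG simulator embodies the signal model the extraction pipeline assumes:
each parieto-occipital electrode carries independent pink (1/f) background
noise plus a hemisphere-specific steady-state sinusoid at the bin-locked
modulation frequency; Cz carries noise only. Sporadic high-amplitude artifact
bursts contaminate a random subset of epochs. Cohorts draw per-subject
response amplitudes around group means with a unit-mean log-normal
multiplier shared across hemispheres, so each subject's lateralization
difference scales with their overall response size.

Default group means encode the reported hemispheric asymmetries: typical
readers (TR) show R - L = +0.20 uV for 4 Hz SAM and L - R = +0.27 uV for
4 Hz PULS; dyslexic readers (DR) are symmetric at 4 Hz and show
R - L = +0.04 uV at 20 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .audio import AudioSignal
from .pipeline import (LEFT_ELECTRODES, RIGHT_ELECTRODES, ConditionTag,
                       Recording)

EPOCH_LEN_S = 1.024
DEFAULT_RATE = 1000.0          # Hz; one epoch = exactly 1024 samples
SAMPLES_PER_EPOCH = 1024
DEFAULT_N_EPOCHS = 520         # 532.48 s per condition

CONDITIONS = (ConditionTag("SAM", 4.0), ConditionTag("PULS", 4.0),
              ConditionTag("SAM", 20.0), ConditionTag("PULS", 20.0))

#: Group mean (left, right) response amplitudes in microvolts per condition.
DEFAULT_GROUP_EFFECTS = {
    "TR": {("SAM", 4.0): (0.50, 0.70),   # R - L = +0.20
           ("PULS", 4.0): (0.77, 0.50),  # L - R = +0.27
           ("SAM", 20.0): (0.20, 0.20),
           ("PULS", 20.0): (0.20, 0.20)},
    "DR": {("SAM", 4.0): (0.60, 0.60),
           ("PULS", 4.0): (0.60, 0.60),
           ("SAM", 20.0): (0.18, 0.22),  # R - L = +0.04
           ("PULS", 20.0): (0.18, 0.22)},
}


# 1/f "pinking" IIR approximation (Paul Kellett's economy filter rewritten
# as a rational transfer function); accurate to a fraction of a dB over
# roughly three decades of normalized frequency. An IIR-filtered stream is
# mixing, so successive analysis epochs decorrelate the way real EEG
# background activity does — a strictly periodic frequency-domain synthesis
# would instead stay phase-coherent at epoch-commensurate bins and mimic a
# steady-state response.
_PINK_B = np.array([0.049922035, -0.095993537, 0.050612699, -0.004408786])
_PINK_A = np.array([1.0, -2.494956002, 2.017265875, -0.522189400])
_PINK_WARMUP = 4096  # samples discarded while the filter state settles


def pink_noise(n_samples: int, rms: float, seed) -> np.ndarray:
    """Gaussian 1/f noise, exactly normalized to the requested RMS.

    White Gaussian noise passed through a pinking IIR filter (warm-up
    discarded). ``seed`` may be an int or a Generator.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_samples + _PINK_WARMUP)
    x = lfilter(_PINK_B, _PINK_A, white)[_PINK_WARMUP:]
    return rms * x / np.sqrt(np.mean(x**2))


def _pink_noise_multi(n_channels: int, n_samples: int, rms: float, rng) -> np.ndarray:
    """Independent pink noise for several channels at once."""
    white = rng.standard_normal((n_channels, n_samples + _PINK_WARMUP))
    x = lfilter(_PINK_B, _PINK_A, white, axis=1)[:, _PINK_WARMUP:]
    x *= rms / np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x


@dataclass(frozen=True)
class SubjectSpec:
    """Everything needed to simulate one subject's recordings.

    ``amplitudes`` maps (stimulus, nominal f_m) to the injected
    (left, right) response amplitudes in microvolts. ``artifact_rate`` is the
    fraction of epochs receiving a burst; capped at 0.12 so at least 448 of
    520 epochs stay clean.
    """

    subject_id: str
    group: str
    amplitudes: dict
    phase: float = 0.0
    noise_rms: float = 20.0
    artifact_rate: float = 0.05
    artifact_amp: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.artifact_rate <= 0.12:
            raise ValueError("artifact_rate must lie in [0, 0.12]")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be non-negative")
        if any(a < 0 for pair in self.amplitudes.values() for a in pair):
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design: group sizes, effect table and nuisance parameters."""

    n_per_group: dict = field(default_factory=lambda: {"TR": 52, "DR": 26})
    group_effects: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_GROUP_EFFECTS.items()})
    between_subject_sd: float = 0.3   # log-scale SD of the subject multiplier
    noise_rms: float = 20.0
    artifact_rate: float = 0.05
    artifact_amp: float = 300.0
    conditions: tuple = CONDITIONS
    master_seed: int = 0


def simulate_recording(spec: SubjectSpec, condition: ConditionTag,
                       n_epochs: int = DEFAULT_N_EPOCHS,
                       rate: float = DEFAULT_RATE) -> Recording:
    """Simulate one 19-channel recording (18 montage electrodes + Cz).

    Left/right electrodes carry the hemisphere's injected sinusoid at the
    bin-locked modulation frequency plus independent pink noise; Cz carries
    noise only. ``spec.artifact_rate`` of the epochs receive a 100-ms uniform
    burst of amplitude ``spec.artifact_amp`` on every channel.
    """
    key = (condition.stimulus, condition.f_m)
    if key not in spec.amplitudes:
        raise KeyError(f"no injected amplitude for condition {key}")
    a_left, a_right = spec.amplitudes[key]
    if round(spec.artifact_rate * n_epochs) > n_epochs - 448:
        raise ValueError("artifact_rate leaves fewer than 448 clean epochs")
    rng = np.random.default_rng(spec.seed)
    labels = list(LEFT_ELECTRODES) + list(RIGHT_ELECTRODES) + ["Cz"]
    spe = int(round(rate * EPOCH_LEN_S))
    n = n_epochs * spe
    t = np.arange(n) / rate
    f = condition.f_m_exact
    carrier = np.cos(2 * np.pi * f * t + spec.phase)
    data = np.zeros((len(labels), n))
    if spec.noise_rms > 0:
        data += _pink_noise_multi(len(labels), n, spec.noise_rms, rng)
    data[: len(LEFT_ELECTRODES)] += a_left * carrier
    data[len(LEFT_ELECTRODES): len(LEFT_ELECTRODES) + len(RIGHT_ELECTRODES)] += (
        a_right * carrier)
    n_art = int(round(spec.artifact_rate * n_epochs))
    if n_art > 0:
        burst_len = int(round(0.100 * rate))
        art_epochs = rng.choice(n_epochs, size=n_art, replace=False)
        for e in art_epochs:
            start = e * spe + rng.integers(0, spe - burst_len + 1)
            data[:, start: start + burst_len] += rng.uniform(
                -spec.artifact_amp, spec.artifact_amp,
                size=(len(labels), burst_len))
    return Recording(channel_labels=labels, data=data, rate=rate,
                     condition=condition)


@dataclass
class CohortSimulation:
    """Subject specs plus the injected ground truth; recordings are lazy."""

    spec: CohortSpec
    subjects: list            # of SubjectSpec
    ground_truth: pd.DataFrame
    n_epochs: int = DEFAULT_N_EPOCHS
    rate: float = DEFAULT_RATE

    def recordings(self):
        """Yield (subject_spec, condition, Recording) lazily to bound memory."""
        for subj in self.subjects:
            for cond in self.spec.conditions:
                # per-condition child seed, derived deterministically
                child = np.random.default_rng(
                    [subj.seed, int(cond.f_m), 0 if cond.stimulus == "SAM" else 1]
                ).integers(0, 2**31 - 1)
                rec_spec = SubjectSpec(
                    subject_id=subj.subject_id, group=subj.group,
                    amplitudes=subj.amplitudes, phase=subj.phase,
                    noise_rms=subj.noise_rms, artifact_rate=subj.artifact_rate,
                    artifact_amp=subj.artifact_amp, seed=int(child))
                yield subj, cond, simulate_recording(
                    rec_spec, cond, self.n_epochs, self.rate)


def simulate_cohort(spec: CohortSpec = CohortSpec()) -> CohortSimulation:
    """Draw a cohort of subject specs around the group means.

    Each subject gets one unit-mean log-normal amplitude multiplier
    (``sigma = between_subject_sd`` on the log scale) applied to both
    hemispheres and all conditions, a uniform random response phase, and a
    deterministic child seed spawned from ``master_seed``.
    """
    rng = np.random.default_rng(spec.master_seed)
    subjects = []
    rows = []
    for group, n_subj in spec.n_per_group.items():
        if group not in spec.group_effects:
            raise KeyError(f"no effect table for group {group!r}")
        effects = spec.group_effects[group]
        for i in range(n_subj):
            sd = spec.between_subject_sd
            mult = float(np.exp(rng.normal(-0.5 * sd**2, sd))) if sd > 0 else 1.0
            phase = float(rng.uniform(-np.pi, np.pi))
            seed = int(rng.integers(0, 2**31 - 1))
            sid = f"{group}{i:03d}"
            amplitudes = {key: (mult * l, mult * r)
                          for key, (l, r) in effects.items()}
            subjects.append(SubjectSpec(
                subject_id=sid, group=group, amplitudes=amplitudes,
                phase=phase, noise_rms=spec.noise_rms,
                artifact_rate=spec.artifact_rate,
                artifact_amp=spec.artifact_amp, seed=seed))
            for (stim, fm), (l, r) in amplitudes.items():
                rows.append({"subject_id": sid, "group": group,
                             "stimulus_type": stim, "f_m": fm,
                             "true_left_uV": l, "true_right_uV": r,
                             "phase_rad": phase})
    truth = pd.DataFrame(rows)
    return CohortSimulation(spec=spec, subjects=subjects, ground_truth=truth)


def synthetic_utterance(onset_times, segment_levels, rate: float = 16000.0,
                        seed: int = 0, gap_s: float = 0.1,
                        tail_s: float = 0.5) -> tuple[AudioSignal, np.ndarray]:
    """Noise bursts with abrupt onsets at known times (speech-like fixture).

    Each segment starts at its onset time with a near-instant rise to the
    requested level and runs until ``gap_s`` before the next onset (the last
    segment lasts ``tail_s``); the signal is silent between segments, so
    every onset is a genuine envelope rise. Returns the signal and the
    ground-truth onset times.
    """
    onset_times = np.asarray(onset_times, dtype=float)
    segment_levels = np.asarray(segment_levels, dtype=float)
    if onset_times.size != segment_levels.size:
        raise ValueError("one level per onset required")
    if np.any(np.diff(onset_times) <= 0):
        raise ValueError("onset times must be strictly increasing")
    ends = np.empty_like(onset_times)
    ends[:-1] = onset_times[1:] - gap_s
    ends[-1] = onset_times[-1] + tail_s
    if np.any(ends <= onset_times):
        raise ValueError("segments overlap: decrease gap_s or space onsets")
    n = int(round((ends[-1] + gap_s) * rate))
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    for t0, t1, lev in zip(onset_times, ends, segment_levels):
        i0, i1 = int(round(t0 * rate)), int(round(t1 * rate))
        x[i0:i1] = lev * rng.standard_normal(i1 - i0) * 0.3
    return AudioSignal(x, rate), onset_times
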