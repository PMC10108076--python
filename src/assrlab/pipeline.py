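"""EEG preprocessing and ASSR estimation.

The chain, applied in this order to a multichannel recording:

1. causal 2nd-order Butterworth high-pass at 2 Hz (DC removal);
2. averaging into artificial LEFT / RIGHT hemisphere channels over nine
   parieto-occipital electrodes each, with Cz carried along;
3. segmentation into non-overlapping 1.024-s epochs;
4. adaptive amplitude-based artifact rejection down to exactly 448 epochs
   (the smallest peak-amplitude threshold leaving that many epochs);
5. re-referencing to Cz;
6. per-epoch FFT, keeping the complex value at the modulation-frequency bin
   in single-sided amplitude scaling (2 |X| / N, microvolts);
7. vector averaging across epochs for response amplitude and phase, an
   across-epoch noise floor, and a one-sample Hotelling T2 test on the
   (real, imaginary) components for response detection.

Amplitudes are in microvolts throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, lfilter
from scipy.stats import f as f_dist

EPOCH_LEN_S = 1.024

LEFT_ELECTRODES = ("TP7", "P1", "P3", "P5", "P7", "P9", "PO3", "PO7", "O1")
RIGHT_ELECTRODES = ("TP8", "P2", "P4", "P6", "P8", "P10", "PO4", "PO8", "O2")


@dataclass(frozen=True)
class ConditionTag:
    """Stimulus condition of a recording: modulator kind and nominal rate."""

    stimulus: str  # "SAM" or "PULS"
    f_m: float     # nominal modulation frequency (4 or 20 Hz)

    def __post_init__(self):
        if self.stimulus not in ("SAM", "PULS"):
            raise ValueError("stimulus must be 'SAM' or 'PULS'")

    @property
    def f_m_exact(self) -> float:
        cycles = round(self.f_m * EPOCH_LEN_S)
        return cycles / EPOCH_LEN_S


@dataclass
class Recording:
    """Multichannel EEG: channels x samples in microvolts."""

    channel_labels: list
    data: np.ndarray
    rate: float
    condition: ConditionTag

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("label count does not match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.rate > 2 * self.condition.f_m:
            raise ValueError("sampling rate too low for the modulation frequency")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")


@dataclass(frozen=True)
class MontageSpec:
    """Hemisphere electrode groups and the reference electrode."""

    left_channels: tuple = LEFT_ELECTRODES
    right_channels: tuple = RIGHT_ELECTRODES
    reference: str = "Cz"

    def __post_init__(self):
        if set(self.left_channels) & set(self.right_channels):
            raise ValueError("left and right electrode sets must be disjoint")
        if self.reference in self.left_channels + self.right_channels:
            raise ValueError("reference must not belong to a hemisphere set")


@dataclass
class EpochSet:
    """Epoched data: n_epochs x channels x samples_per_epoch."""

    epochs: np.ndarray
    channel_labels: list
    rate: float
    condition: ConditionTag
    retained_index: np.ndarray  # original epoch indices, strictly increasing

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass(frozen=True)
class ComplexBinSeries:
    """Per-epoch complex spectral values at the modulation bin (one channel)."""

    values: np.ndarray  # complex, single-sided amplitude scaling, microvolts
    bin_index: int
    f_m: float


@dataclass(frozen=True)
class ResponseEstimate:
    """Vector-averaged response with noise floor and Hotelling T2 detection."""

    amplitude: float
    phase: float
    noise_amplitude: float
    t2: float
    f_stat: float
    p_value: float
    significant: bool
    n_epochs: int

    def snr_db(self) -> float:
        """Response-to-noise-floor ratio in dB."""
        if self.noise_amplitude == 0:
            return np.inf
        return 20 * np.log10(self.amplitude / self.noise_amplitude)


@dataclass(frozen=True)
class PipelineConfig:
    target_epochs: int = 448
    alpha: float = 0.05
    hp_cutoff: float = 2.0
    hp_order: int = 2
    montage: MontageSpec = field(default_factory=MontageSpec)


def highpass(rec: Recording, cutoff: float = 2.0, order: int = 2) -> Recording:
    """Causal Butterworth high-pass per channel (DC removal)."""
    if cutoff >= rec.rate / 2:
        raise ValueError("cutoff at or above Nyquist")
    b, a = butter(order, cutoff, btype="highpass", fs=rec.rate)
    return replace(rec, data=lfilter(b, a, rec.data, axis=1))


def hemisphere_channels(rec: Recording, montage: MontageSpec = MontageSpec()) -> Recording:
    """Average electrodes into LEFT and RIGHT channels; pass Cz through."""
    index = {lab: i for i, lab in enumerate(rec.channel_labels)}
    for lab in montage.left_channels + montage.right_channels + (montage.reference,):
        if lab not in index:
            raise KeyError(f"electrode {lab!r} missing from recording")
    left = rec.data[[index[l] for l in montage.left_channels]].mean(axis=0)
    right = rec.data[[index[l] for l in montage.right_channels]].mean(axis=0)
    cz = rec.data[index[montage.reference]]
    return replace(rec, channel_labels=["LEFT", "RIGHT", montage.reference],
                   data=np.vstack([left, right, cz]))


def epoch(rec: Recording, epoch_len_s: float = EPOCH_LEN_S) -> EpochSet:
    """Cut into consecutive non-overlapping epochs; drop the short tail."""
    spe_f = rec.rate * epoch_len_s
    spe = int(round(spe_f))
    if abs(spe_f - spe) > 1e-6:
        raise ValueError(
            f"epoch length {epoch_len_s} s is not an integer number of samples "
            f"at {rec.rate} Hz")
    n = rec.data.shape[1] // spe
    if n < 1:
        raise ValueError("recording shorter than one epoch")
    eps = rec.data[:, : n * spe].reshape(rec.data.shape[0], n, spe)
    return EpochSet(epochs=np.swapaxes(eps, 0, 1).copy(),
                    channel_labels=list(rec.channel_labels), rate=rec.rate,
                    condition=rec.condition, retained_index=np.arange(n))


def reject_artifacts(eps: EpochSet, target_epochs: int = 448) -> EpochSet:
    """Adaptive amplitude rejection: keep the ``target_epochs`` epochs with
    the smallest peak absolute amplitude across all channels.

    Equivalent to raising an amplitude threshold until exactly
    ``target_epochs`` remain; ties are broken toward the earlier epoch.
    Original temporal order is preserved.
    """
    if eps.n_epochs < target_epochs:
        raise ValueError(
            f"only {eps.n_epochs} epochs available, need {target_epochs}")
    peaks = np.abs(eps.epochs).max(axis=(1, 2))
    keep = np.sort(np.argsort(peaks, kind="stable")[:target_epochs])
    return replace(eps, epochs=eps.epochs[keep],
                   retained_index=eps.retained_index[keep])


def rereference(eps: EpochSet, montage: MontageSpec = MontageSpec()) -> EpochSet:
    """Subtract the Cz reference from every other channel and drop Cz."""
    if montage.reference not in eps.channel_labels:
        raise KeyError(f"reference {montage.reference!r} missing")
    ref_i = eps.channel_labels.index(montage.reference)
    others = [i for i in range(len(eps.channel_labels)) if i != ref_i]
    data = eps.epochs[:, others, :] - eps.epochs[:, ref_i: ref_i + 1, :]
    return replace(eps, epochs=data,
                   channel_labels=[eps.channel_labels[i] for i in others])


def epoch_spectra(eps: EpochSet, f_m: float) -> dict:
    """Complex value at the modulation bin, per channel and epoch.

    Single-sided amplitude scaling 2 X[k] / N so a cosine of amplitude A
    (microvolts) and phase phi at the bin yields exactly A e^{i phi}.
    """
    spe = eps.epochs.shape[2]
    bin_f = f_m * spe / eps.rate
    bin_index = int(round(bin_f))
    if abs(bin_f - bin_index) > 1e-6:
        raise ValueError(
            f"f_m={f_m} Hz does not fall on an FFT bin of the "
            f"{spe / eps.rate:.3f}-s epoch")
    basis = np.exp(-2j * np.pi * bin_index * np.arange(spe) / spe)
    vals = 2.0 * (eps.epochs @ basis) / spe  # (n_epochs, channels)
    return {lab: ComplexBinSeries(values=vals[:, i].copy(), bin_index=bin_index,
                                  f_m=f_m)
            for i, lab in enumerate(eps.channel_labels)}


def vector_average(series: ComplexBinSeries) -> tuple[float, float]:
    """(amplitude, phase) of the across-epoch mean complex value."""
    if series.values.size < 1:
        raise ValueError("empty series")
    m = series.values.mean()
    return float(np.abs(m)), float(np.angle(m))


def noise_floor(series: ComplexBinSeries) -> float:
    """Across-epoch complex standard deviation divided by sqrt(n).

    The complex SD uses squared moduli of deviations from the mean with an
    n - 1 denominator; the 1/sqrt(n) factor converts per-epoch variability
    into the residual noise of the vector average.
    """
    n = series.values.size
    if n < 2:
        raise ValueError("need at least 2 epochs")
    z = series.values
    sd = np.sqrt(np.sum(np.abs(z - z.mean()) ** 2) / (n - 1))
    return float(sd / np.sqrt(n))


def hotelling_t2(series: ComplexBinSeries, alpha: float = 0.05) -> tuple:
    """One-sample Hotelling T2 on the (Re, Im) components of the bin values.

    T2 = n xbar' S^{-1} xbar with S the sample covariance;
    F = T2 (n - 2) / (2 (n - 1)) on (2, n - 2) degrees of freedom. When the
    covariance is singular (all epochs identical): p -> 0 for a non-zero
    mean, p = 1 for an all-zero series.

    Returns ``(t2, f_stat, p_value, significant)``.
    """
    z = series.values
    n = z.size
    if n < 3:
        raise ValueError("need at least 3 epochs")
    x = np.column_stack([z.real, z.imag])
    xbar = x.mean(axis=0)
    dev = x - xbar
    S = dev.T @ dev / (n - 1)
    det = np.linalg.det(S)
    if det <= np.finfo(float).tiny * max(1.0, float(np.trace(S)) ** 2):
        if np.allclose(xbar, 0.0):
            return 0.0, 0.0, 1.0, False
        return np.inf, np.inf, 0.0, True
    t2 = float(n * xbar @ np.linalg.solve(S, xbar))
    f_stat = t2 * (n - 2) / (2 * (n - 1))
    p = float(f_dist.sf(f_stat, 2, n - 2))
    return t2, float(f_stat), p, p < alpha


def estimate_response(series: ComplexBinSeries, alpha: float = 0.05) -> ResponseEstimate:
    """Bundle vector average, noise floor and Hotelling detection."""
    amp, phase = vector_average(series)
    noise = noise_floor(series)
    t2, f_stat, p, sig = hotelling_t2(series, alpha)
    return ResponseEstimate(amplitude=amp, phase=phase, noise_amplitude=noise,
                            t2=t2, f_stat=f_stat, p_value=p, significant=sig,
                            n_epochs=series.values.size)


def run_condition(rec: Recording, config: PipelineConfig = PipelineConfig()) -> dict:
    """Full chain on one recording; returns {'LEFT': ..., 'RIGHT': ...}."""
    rec = highpass(rec, config.hp_cutoff, config.hp_order)
    rec = hemisphere_channels(rec, config.montage)
    eps = epoch(rec)
    eps = reject_artifacts(eps, config.target_epochs)
    eps = rereference(eps, config.montage)
    spectra = epoch_spectra(eps, rec.condition.f_m_exact)
    return {lab: estimate_response(s, config.alpha) for lab, s in spectra.items()}


def electrode_sensitivity(results, criterion: float = 0.70) -> tuple[bool, float]:
    """Proportion of significant responses; pass if strictly above criterion."""
    results = list(results)
    if not results:
        raise ValueError("no results")
    prop = sum(r.significant for r in results) / len(results)
    return prop > criterion, float(prop)


# ---------------------------------------------------------------------------
# I/O helpers

def save_recording(path, rec: Recording) -> None:
    """Save a recording to the package's .npz container."""
    np.savez_compressed(
        path, data=rec.data, labels=np.array(rec.channel_labels), rate=rec.rate,
        stimulus=rec.condition.stimulus, f_m=rec.condition.f_m)


def load_recording(path) -> Recording:
    with np.load(path, allow_pickle=False) as z:
        return Recording(channel_labels=[str(l) for l in z["labels"]],
                         data=z["data"], rate=float(z["rate"]),
                         condition=ConditionTag(str(z["stimulus"]),
                                                float(z["f_m"])))


def read_recording_edf(path, condition: ConditionTag, target_rate: float = 1000.0) -> Recording:
    """Read an EDF/BDF file (requires mne) and resample so that a 1.024-s
    epoch is an integer number of samples. Data are converted to microvolts.
    """
    import mne  # optional dependency

    raw = mne.io.read_raw(path, preload=True, verbose="error")
    if raw.info["sfreq"] != target_rate:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = raw.resample(target_rate)
    return Recording(channel_labels=list(raw.ch_names),
                     data=raw.get_data() * 1e6, rate=target_rate,
                     condition=condition)


def results_to_json(path, results: dict) -> None:
    """Write {hemisphere: ResponseEstimate} to a JSON file."""
    payload = {}
    for lab, r in results.items():
        payload[lab] = {
            "amplitude_uV": r.amplitude, "phase_rad": r.phase,
            "noise_amplitude_uV": r.noise_amplitude, "t2": r.t2,
            "f_stat": r.f_stat, "p_value": r.p_value,
            "significant": bool(r.significant), "n_epochs": r.n_epochs,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
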