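"""Cohort aggregation and hemispheric-lateralization statistics.

Per-subject response estimates are collected into a tidy long-format table
(one row per subject x test phase x condition x hemisphere). Lateralization
is tested per group x modulation frequency x stimulus type with a paired
sign-flip permutation test on the within-subject right-minus-left amplitude
differences, with Holm step-down correction applied within each
group x frequency family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

TABLE_COLUMNS = ["subject_id", "group", "test_phase", "f_m", "stimulus_type",
                 "hemisphere", "response_amplitude", "noise_amplitude",
                 "significant", "n_epochs"]


def aggregate(records) -> pd.DataFrame:
    """Build the long-format cohort table from per-subject result records.

    ``records`` is an iterable of mappings with the :data:`TABLE_COLUMNS`
    keys (``test_phase`` defaults to "pre" when absent). Missing conditions
    are simply absent rows; duplicated subject-condition-hemisphere rows are
    an error.
    """
    rows = []
    for rec in records:
        row = dict(rec)
        row.setdefault("test_phase", "pre")
        rows.append(row)
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    key = ["subject_id", "test_phase", "f_m", "stimulus_type", "hemisphere"]
    if table.duplicated(subset=key).any():
        dup = table[table.duplicated(subset=key)].iloc[0]
        raise ValueError(f"duplicate row for {dict(dup[key])}")
    if (table["response_amplitude"] < 0).any() or (table["noise_amplitude"] < 0).any():
        raise ValueError("amplitudes must be non-negative")
    return table


def response_record(subject_id, group, f_m, stimulus_type, hemisphere,
                    estimate, test_phase="pre") -> dict:
    """One cohort-table row from a pipeline ResponseEstimate."""
    return {"subject_id": subject_id, "group": group, "test_phase": test_phase,
            "f_m": f_m, "stimulus_type": stimulus_type,
            "hemisphere": hemisphere,
            "response_amplitude": estimate.amplitude,
            "noise_amplitude": estimate.noise_amplitude,
            "significant": bool(estimate.significant),
            "n_epochs": estimate.n_epochs}


@dataclass(frozen=True)
class ContrastResult:
    """A paired right-minus-left contrast with permutation inference."""

    label: str
    effect: float          # mean paired difference, microvolts
    p_raw: float
    p_adjusted: float
    n_subjects: int


def paired_signflip_test(diffs: np.ndarray, n_perm: int = 5000,
                         seed: int = 0) -> float:
    """Two-sided sign-flip permutation p-value for mean(diffs) = 0.

    Under the exchangeable null the sign of each paired difference is
    arbitrary; the p-value is (b + 1) / (n_perm + 1) where b counts sign
    assignments whose |mean| reaches the observed one, so the smallest
    attainable p is 1 / (n_perm + 1).
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    if n < 3:
        raise ValueError("need at least 3 paired differences")
    rng = np.random.default_rng(seed)
    t_obs = abs(diffs.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_null = np.abs((signs * diffs).mean(axis=1))
    b = int(np.sum(t_null >= t_obs - 1e-12))
    return (b + 1) / (n_perm + 1)


def lateralization_contrast(table: pd.DataFrame, group: str, f_m: float,
                            stimulus_type: str, n_perm: int = 5000,
                            seed: int = 0, test_phase=None) -> ContrastResult:
    """Mean right-minus-left response difference with a sign-flip p-value.

    Subjects contribute only if both hemispheres are present for the cell.
    ``p_adjusted`` is filled with the raw p; Holm adjustment across a family
    happens in :func:`group_report` (or via :func:`holm_adjust`).
    """
    sel = table[(table["group"] == group) & (table["f_m"] == f_m)
                & (table["stimulus_type"] == stimulus_type)]
    if test_phase is not None:
        sel = sel[sel["test_phase"] == test_phase]
    wide = sel.pivot_table(index="subject_id", columns="hemisphere",
                           values="response_amplitude", aggfunc="mean")
    if not {"LEFT", "RIGHT"}.issubset(wide.columns):
        raise ValueError("both hemispheres required")
    wide = wide.dropna(subset=["LEFT", "RIGHT"])
    if len(wide) < 3:
        raise ValueError("need at least 3 subjects with both hemispheres")
    diffs = (wide["RIGHT"] - wide["LEFT"]).to_numpy()
    p = paired_signflip_test(diffs, n_perm=n_perm, seed=seed)
    label = f"{group} {stimulus_type} {f_m:g} Hz R-L"
    return ContrastResult(label=label, effect=float(diffs.mean()), p_raw=p,
                          p_adjusted=p, n_subjects=len(wide))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass(frozen=True)
class GroupReport:
    """Cell means, detection proportions and Holm-adjusted contrasts."""

    cell_means: pd.DataFrame
    detection: pd.DataFrame
    contrasts: pd.DataFrame

    def to_csv(self, means_path, detection_path, contrasts_path) -> None:
        self.cell_means.to_csv(means_path, index=False)
        self.detection.to_csv(detection_path, index=False)
        self.contrasts.to_csv(contrasts_path, index=False)


def group_report(table: pd.DataFrame, n_perm: int = 5000, seed: int = 0) -> GroupReport:
    """Summarize a cohort table.

    * cell means of response and noise amplitudes per
      group x f_m x stimulus x hemisphere;
    * proportion of significant (Hotelling) responses per condition — the
      electrode-sensitivity statistic;
    * all right-minus-left lateralization contrasts, Holm-corrected within
      each group x modulation-frequency family.

    Groups with no usable hemisphere pairs are omitted with a warning.
    Deterministic given (table, n_perm, seed).
    """
    if table.empty:
        raise ValueError("empty cohort table")
    cell_means = (table.groupby(["group", "f_m", "stimulus_type", "hemisphere"],
                                as_index=False)
                  .agg(response_amplitude=("response_amplitude", "mean"),
                       noise_amplitude=("noise_amplitude", "mean"),
                       n=("response_amplitude", "size")))
    detection = (table.groupby(["group", "f_m", "stimulus_type"], as_index=False)
                 .agg(prop_significant=("significant", "mean"),
                      n=("significant", "size")))
    contrasts = []
    for (group, f_m), _ in table.groupby(["group", "f_m"]):
        family = []
        stim_types = sorted(table[(table["group"] == group)
                                  & (table["f_m"] == f_m)]["stimulus_type"].unique())
        for k, stim in enumerate(stim_types):
            try:
                res = lateralization_contrast(table, group, f_m, stim,
                                              n_perm=n_perm,
                                              seed=seed + 97 * k)
            except ValueError as err:
                warnings.warn(f"skipping {group} {stim} {f_m:g} Hz: {err}")
                continue
            family.append(res)
        if family:
            adj = holm_adjust([r.p_raw for r in family])
            contrasts.extend(replace(r, p_adjusted=float(a))
                             for r, a in zip(family, adj))
        else:
            warnings.warn(f"group {group!r} at {f_m:g} Hz omitted: no contrasts")
    cdf = pd.DataFrame([{"label": c.label, "effect_uV": c.effect,
                         "p_raw": c.p_raw, "p_holm": c.p_adjusted,
                         "n_subjects": c.n_subjects} for c in contrasts])
    return GroupReport(cell_means=cell_means, detection=detection, contrasts=cdf)
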