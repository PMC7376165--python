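"""Contamination and interference quality control.

The platelet index (PI) flags platelet contamination of a plasma sample:
per (sample, particle) it is the median natural-log intensity of a
platelet-signature protein list divided by the median natural-log
intensity of all other observed proteins. The per-sample overall PI
averages the column-standardized per-particle PIs across particles (and
depleted plasma, when present as a pseudo-particle column).

Note the PI is a ratio of ln-medians, so it is *not* invariant to global
intensity rescaling (both medians shift additively in ln space); it is
meaningful only within a fixed intensity scale.

Interference robustness compares a control against a perturbed tensor:
lipid interference should leave IDs and intensities untouched, hemolysate
adds new proteins but should leave overlapping proteins correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .matrixio import IntensityTensor


@dataclass
class PlateletIndexReport:
    """per_particle: samples × particles PI matrix (NaN where undefined);
    overall: per-sample mean of standardized per-particle PIs (set by
    overall_pi)."""

    per_particle: pd.DataFrame
    overall: pd.Series | None = None
    n_undefined: pd.Series | None = None


def platelet_index(tensor: IntensityTensor, signature) -> PlateletIndexReport:
    """Per-(sample, particle) platelet index.

    Intensities must be linear-scale positive; per protein the median over
    replicates (observed values only) is taken before the ln transform.
    Cells with no observed signature or no observed non-signature protein
    are reported as NaN.
    """
    signature = frozenset(signature)
    if not signature:
        raise ValueError("signature protein set must be non-empty")
    if tensor.scale != "linear":
        raise ValueError("platelet index expects linear-scale intensities")
    cells: dict[tuple, float] = {}
    for (np_id, _condition, sample), frame in tensor.replicate_groups():
        med = frame.median(axis=1, skipna=True).dropna()
        is_sig = med.index.isin(signature)
        sig_med = np.median(np.log(med[is_sig])) if is_sig.any() else np.nan
        non_med = np.median(np.log(med[~is_sig])) if (~is_sig).any() else np.nan
        key = (sample, np_id)
        cells[key] = sig_med / non_med if np.isfinite(sig_med) and np.isfinite(non_med) and non_med != 0 else np.nan
    frame = pd.Series(cells).unstack()
    frame.index.name = "sample"
    frame.columns.name = "particle"
    return PlateletIndexReport(per_particle=frame)


def overall_pi(report: PlateletIndexReport) -> pd.Series:
    """Per-sample overall PI: each particle column standardized to mean 0 /
    sample-sd 1 across samples, then averaged across particles per sample.

    Zero-variance columns contribute 0 after centering; undefined cells are
    excluded from the mean (excluded counts in report.n_undefined). Needs
    at least two samples.
    """
    pp = report.per_particle
    if len(pp.index) < 2:
        raise ValueError("overall PI needs >= 2 samples to standardize")
    standardized = {}
    for particle in pp.columns:
        col = pp[particle]
        sd = col.std(ddof=1)
        centered = col - col.mean()
        standardized[particle] = centered / sd if sd > 0 else centered * 0.0
    z = pd.DataFrame(standardized)
    overall = z.mean(axis=1, skipna=True)
    report.overall = overall.rename("overall_pi")
    report.n_undefined = pp.isna().sum(axis=1).rename("n_undefined")
    return report.overall


@dataclass
class InterferenceSummary:
    pearson_r: float
    jaccard: float
    delta_ids: int  # perturbed minus control detected-ID count
    n_shared: int


def interference_check(
    control: IntensityTensor,
    perturbed: IntensityTensor,
    min_replicates: int = 1,
) -> InterferenceSummary:
    """Robustness of detection and quantification to an interference.

    A protein counts as detected if observed in >= ``min_replicates``
    columns of the whole tensor. Over proteins detected in both tensors,
    the Pearson correlation of log10 median intensities is computed,
    alongside the Jaccard of the detected sets and the ID-count change.
    """
    def detected_and_levels(t: IntensityTensor):
        counts = t.data.notna().sum(axis=1)
        det = counts[counts >= min_replicates].index
        levels = t.data.loc[det].median(axis=1, skipna=True)
        return frozenset(det), levels

    det_c, lev_c = detected_and_levels(control)
    det_p, lev_p = detected_and_levels(perturbed)
    shared = sorted(det_c & det_p)
    if not shared:
        raise InsufficientDataError("control and perturbed tensors share no detected protein")
    x = np.log10(lev_c.loc[shared].to_numpy(dtype=float))
    y = np.log10(lev_p.loc[shared].to_numpy(dtype=float))
    if len(shared) > 1 and np.std(x) > 0 and np.std(y) > 0:
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        r = np.nan
    return InterferenceSummary(
        pearson_r=r,
        jaccard=len(det_c & det_p) / len(det_c | det_p),
        delta_ids=len(det_p) - len(det_c),
        n_shared=len(shared),
    )
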