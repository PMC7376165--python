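"""Detection counting, replicate-CV precision and dynamic-range compression.

Detection follows the full-assay-replicate rule: a protein counts as
identified for a (particle, condition) only if it is observed in at least
``min_replicates_present`` replicates (default: all of them, the 3/3 rule).
CVs are computed on linear-scale intensities as sample-sd/mean per protein,
restricted to proteins passing the valid-value filter. Compression is
quantified by ordinary least squares of log10 measured intensity on log10
reference abundance: a slope below 1 means the corona narrows the measured
span relative to the true span.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InsufficientDataError
from .matrixio import IntensityTensor, ReferenceAbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class DetectionRule:
    """Minimum number of replicates a protein must be observed in."""

    min_replicates_present: int = 3

    def __post_init__(self) -> None:
        if self.min_replicates_present < 1:
            raise ValueError("min_replicates_present must be >= 1")


def detect(tensor: IntensityTensor, rule: DetectionRule) -> dict:
    """Per-(particle, condition) detected protein-ID sets.

    A protein is detected for (np, condition) if, within at least one
    sample of that group, it is observed in >= rule.min_replicates_present
    replicates.
    """
    if rule.min_replicates_present > tensor.n_replicates:
        raise ValueError(
            f"rule requires {rule.min_replicates_present} replicates, tensor "
            f"has at most {tensor.n_replicates}"
        )
    detected: dict[tuple, frozenset] = {}
    for (np_id, condition, _sample), frame in tensor.replicate_groups():
        present = frame.notna().sum(axis=1) >= rule.min_replicates_present
        key = (np_id, condition)
        ids = frozenset(frame.index[present])
        detected[key] = detected.get(key, frozenset()) | ids
    return detected


@dataclass
class CVReport:
    """Per-protein replicate CVs (long table: protein_id, np_id, condition,
    sample, n_valid, cv) plus per-particle medians."""

    table: pd.DataFrame

    @property
    def median_cv_per_np(self) -> pd.Series:
        if self.table.empty:
            return pd.Series(dtype=float, name="median_cv")
        return self.table.groupby("np_id", sort=False)["cv"].median().rename("median_cv")

    @property
    def mean_of_medians(self) -> float:
        """Arithmetic mean of the per-particle median CVs (the panel-level
        precision summary)."""
        return float(self.median_cv_per_np.mean())


def cv_report(tensor: IntensityTensor, min_valid: int | None = None) -> CVReport:
    """Replicate CV per protein per (particle, condition, sample) group.

    CV = sample sd / mean of linear-scale intensities across replicates;
    only proteins with >= ``min_valid`` observed replicates are included
    (default: all replicates of the group — the "three out of three valid
    values" filter).
    """
    if tensor.scale != "linear":
        raise ValueError("CVs are computed on linear-scale intensities")
    rows = []
    for (np_id, condition, sample), frame in tensor.replicate_groups():
        n_reps = frame.shape[1]
        if n_reps < 2:
            raise ValueError(f"group {(np_id, condition, sample)} has fewer than 2 replicates")
        need = n_reps if min_valid is None else min_valid
        counts = frame.notna().sum(axis=1)
        keep = frame.loc[counts >= max(need, 2)]
        if keep.empty:
            continue
        mean = keep.mean(axis=1, skipna=True)
        sd = keep.std(axis=1, ddof=1, skipna=True)
        rows.append(
            pd.DataFrame(
                {
                    "protein_id": keep.index,
                    "np_id": np_id,
                    "condition": condition,
                    "sample": sample,
                    "n_valid": counts.loc[keep.index].to_numpy(),
                    "cv": (sd / mean).to_numpy(),
                }
            )
        )
    if not rows:
        warnings.warn("no protein passed the valid-value filter; CV report is empty")
        return CVReport(pd.DataFrame(
            columns=["protein_id", "np_id", "condition", "sample", "n_valid", "cv"]
        ))
    return CVReport(pd.concat(rows, ignore_index=True))


def count_cv_below(report: CVReport, threshold: float = 0.20,
                   best_per_protein: bool = False) -> int:
    """Number of (proteins | entries) with CV below ``threshold``.

    With ``best_per_protein`` each protein contributes its minimum CV
    across particles before thresholding — the particle one would actually
    assay that protein on; otherwise every (protein, particle) entry is
    counted separately.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    if report.table.empty:
        raise ValueError("empty CV report")
    if best_per_protein:
        best = report.table.groupby("protein_id")["cv"].min()
        return int((best < threshold).sum())
    return int((report.table["cv"] < threshold).sum())


@dataclass
class CompressionFit:
    """OLS fit of log10 measured intensity on log10 reference abundance."""

    np_id: str
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r2_adj: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise InsufficientDataError(f"{self.np_id}: need >= 3 points, got {self.n}")
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError("confidence interval must contain the slope")


def _ols_loglog(x_log10: np.ndarray, y_log10: np.ndarray, np_id: str) -> CompressionFit:
    X = sm.add_constant(x_log10)
    fit = sm.OLS(y_log10, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return CompressionFit(
        np_id=np_id,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        r2_adj=float(fit.rsquared_adj),
        n=int(fit.nobs),
    )


def compression_fit(
    tensor: IntensityTensor,
    reference: ReferenceAbundanceTable,
    aggregate: str = "max",
    protein_subset=None,
) -> dict:
    """Per-particle compression fit versus a reference abundance table.

    Intensities are aggregated per protein over all of a particle's columns
    (``max`` by default, ``median`` as alternative); the fit uses proteins
    shared between the tensor and the reference (optionally restricted to
    ``protein_subset`` so two particles can be compared on identical
    proteins).
    """
    if aggregate not in ("max", "median"):
        raise ValueError("aggregate must be 'max' or 'median'")
    if tensor.scale != "linear":
        raise ValueError("compression fit expects linear-scale intensities")
    fits = {}
    for np_id in tensor.np_ids:
        sub = tensor.select(np_id=np_id).data
        agg = sub.max(axis=1, skipna=True) if aggregate == "max" else sub.median(axis=1, skipna=True)
        agg = agg.dropna()
        shared = agg.index.intersection(reference.protein_ids)
        if protein_subset is not None:
            shared = shared.intersection(pd.Index(list(protein_subset)))
        if len(shared) < 3:
            raise InsufficientDataError(
                f"{np_id}: only {len(shared)} proteins shared with the reference"
            )
        x = np.log10(reference.table.loc[shared, "intensity"].to_numpy(dtype=float))
        y = np.log10(agg.loc[shared].to_numpy(dtype=float))
        fits[np_id] = _ols_loglog(x, y, np_id)
    return fits


def coverage_vs_reference(
    detected: dict,
    reference: ReferenceAbundanceTable,
    marker_list=None,
) -> pd.DataFrame:
    """Depth-of-coverage summary per detected set.

    For each key of ``detected``: number of reference proteins matched, the
    deepest (largest) matched rank, the number of reference proteins ranked
    below that deepest match (how much of the low-abundance tail remains
    unseen), and the overlap with an optional marker list.
    """
    n_ref = len(reference)
    rows = []
    for key, ids in detected.items():
        matched = [p for p in ids if p in reference.protein_ids]
        deepest = max((reference.rank_of(p) for p in matched), default=None)
        row = {
            "key": key,
            "n_matched": len(matched),
            "deepest_rank": deepest,
            "n_below_deepest": (n_ref - deepest) if deepest is not None else None,
        }
        if marker_list is not None:
            row["n_markers"] = len(set(matched) & set(marker_list))
        rows.append(row)
    return pd.DataFrame(rows).set_index("key")
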