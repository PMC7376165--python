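"""Spike-recovery linearity: log-log response of measured intensity to
known concentration, plus a null slope distribution from unchanging
features.

A perfectly linear platform yields slope 1 when regressing log10(MS
intensity) on log10(spiked concentration); features that were not spiked
should show slopes centered at 0 across the same samples. Intensities
missing at low spike levels (below the limit of detection) are dropped,
not imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError


@dataclass
class SpikeSeries:
    """Known concentrations per spike level and measured intensities per
    feature (rows) per level (columns); NaN marks undetectable."""

    concentrations: pd.Series  # index: level label, value: known concentration
    intensities: pd.DataFrame  # features x levels

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(~(c > 0)):
            raise ValueError("concentrations must be strictly positive")
        if len(np.unique(c)) != len(c):
            raise ValueError("concentrations must be distinct")
        missing = set(self.intensities.columns) - set(self.concentrations.index)
        if missing:
            raise ValueError(f"levels without a concentration: {sorted(missing)}")


@dataclass
class RegressionFit:
    slope: float
    ci_low: float
    ci_high: float
    r2_adj: float
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError("confidence interval must contain the slope")


def fit_spike_response(series: SpikeSeries, pool_features: bool = True,
                       robust: bool = False) -> RegressionFit:
    """OLS of log10(intensity) on log10(concentration) over all observed
    (feature, level) pairs.

    With ``pool_features`` a single slope is fit with per-feature
    intercepts (offsets absorb abundance differences between peptides);
    otherwise one common intercept. ``robust`` switches to a Theil–Sen
    slope on within-feature-centered data for outlier resilience.
    """
    long = (
        series.intensities.stack()
        .rename("intensity")
        .reset_index()
        .set_axis(["feature", "level", "intensity"], axis=1)
    )
    long["log_conc"] = np.log10(series.concentrations.loc[long["level"]].to_numpy(dtype=float))
    long["log_int"] = np.log10(long["intensity"].to_numpy(dtype=float))
    if len(long) < 3:
        raise InsufficientDataError(f"need >= 3 observed points, got {len(long)}")

    if robust:
        if pool_features:
            # center x and y within feature; Theil-Sen on the pooled residuals
            for col in ("log_conc", "log_int"):
                long[col] -= long.groupby("feature")[col].transform("mean")
        res = stats.theilslopes(long["log_int"], long["log_conc"], alpha=0.95)
        return RegressionFit(float(res.slope), float(res.low_slope),
                             float(res.high_slope), np.nan, len(long))

    y = long["log_int"].to_numpy()
    x = long["log_conc"].to_numpy()
    if pool_features and long["feature"].nunique() > 1:
        dummies = pd.get_dummies(long["feature"], drop_first=True, dtype=float)
        X = np.column_stack([np.ones(len(long)), x, dummies.to_numpy()])
    else:
        X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionFit(
        slope=float(fit.params[1]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        r2_adj=float(fit.rsquared_adj),
        n=int(fit.nobs),
    )


@dataclass
class NullSlopeResult:
    """Per-feature slopes of nonspiked features plus a summary fit of their
    mean (t-interval); for truly unchanging features the distribution is
    centered near 0."""

    slopes: pd.Series
    mean_slope: float
    ci_low: float
    ci_high: float

    @property
    def n_features(self) -> int:
        return len(self.slopes)


def null_feature_slopes(
    intensities: pd.DataFrame,
    concentrations: pd.Series,
    spiked_feature_ids=(),
    min_present: int = 4,
) -> NullSlopeResult:
    """Slopes of nonspiked features against the spike concentration axis.

    ``intensities``: features × samples (NaN = missing); features observed
    in fewer than ``min_present`` samples (default 4, of the 5-sample spike
    design) are excluded, as are the spiked features themselves.
    """
    keep = intensities.drop(index=[f for f in spiked_feature_ids if f in intensities.index])
    keep = keep.loc[keep.notna().sum(axis=1) >= min_present]
    if len(keep) < 2:
        raise InsufficientDataError(
            f"only {len(keep)} nonspiked features observed in >= {min_present} samples"
        )
    log_c_all = np.log10(concentrations.loc[keep.columns].to_numpy(dtype=float))
    slopes = {}
    for feature, row in keep.iterrows():
        mask = row.notna().to_numpy()
        x = log_c_all[mask]
        y = np.log10(row.to_numpy(dtype=float)[mask])
        slopes[feature] = float(np.polyfit(x, y, 1)[0])
    s = pd.Series(slopes, name="slope")
    mean = float(s.mean())
    if len(s) > 1 and s.std(ddof=1) > 0:
        half = float(stats.t.ppf(0.975, len(s) - 1) * s.std(ddof=1) / np.sqrt(len(s)))
    else:
        half = 0.0
    return NullSlopeResult(s, mean, mean - half, mean + half)
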