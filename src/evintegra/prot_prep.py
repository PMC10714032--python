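"""Proteomics preprocessing: missingness filtering, left-censored imputation
and variance stabilization.

The stage order is fixed — log2 transform, group-wise missingness filter,
MinProb-style Gaussian imputation, variance-stabilizing normalization — and
is asserted through the provenance flags carried on the matrix.

Missing label-free intensities are concentrated at the low end of the
expression distribution (left-censored / MNAR), which motivates imputing
them from a Gaussian centred at the observed matrix minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import IntensityMatrix

STAGE_LOG2 = "log2"
STAGE_FILTERED = "filtered"
STAGE_IMPUTED = "imputed"
STAGE_VST = "vst"


def log2_transform(raw: pd.DataFrame, groups: pd.Series) -> IntensityMatrix:
    """Log2-transform a raw (linear-scale) intensity matrix.

    Non-positive raw entries are treated as missing.
    """
    vals = raw.where(raw > 0)
    return IntensityMatrix(values=np.log2(vals), groups=groups, stages=(STAGE_LOG2,))


def _require_stage(m: IntensityMatrix, stage: str, op: str) -> None:
    if stage not in m.stages:
        raise ValueError(f"{op} requires a matrix that has passed stage {stage!r}; "
                         f"got stages {m.stages}")


def filter_missing(m: IntensityMatrix, max_missing_per_group: int = 2) -> IntensityMatrix:
    """Remove features with more than ``max_missing_per_group`` missing values
    in any experimental group. Idempotent; feature order is preserved."""
    if max_missing_per_group < 0:
        raise ValueError("max_missing_per_group must be >= 0")
    _require_stage(m, STAGE_LOG2, "filter_missing")
    keep = pd.Series(True, index=m.feature_ids)
    for g in m.group_levels:
        cols = m.group_samples(g)
        keep &= m.mask[cols].sum(axis=1) <= max_missing_per_group
    if not keep.any():
        warnings.warn("filter_missing removed every feature")
    out = m.values.loc[keep]
    stage = () if STAGE_FILTERED in m.stages else (STAGE_FILTERED,)
    return IntensityMatrix(values=out, groups=m.groups,
                           original_mask=None if m.original_mask is None
                           else m.original_mask.loc[keep],
                           stages=m.stages + stage)


@dataclass
class ImputationParams:
    """Gaussian parameters for MinProb-style left-censored imputation.

    mu is the 0.0-th quantile (minimum) of the observed log2 intensities;
    sigma is the median of the per-feature standard deviations among features
    observed in more than half of the samples.
    """

    mu: float
    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @classmethod
    def estimate(cls, m: IntensityMatrix, seed: int = 0) -> "ImputationParams":
        obs = m.values.to_numpy()
        observed = ~np.isnan(obs)
        if not observed.any():
            raise ValueError("matrix has no observed values")
        mu = float(np.nanmin(obs))
        frac_obs = observed.mean(axis=1)
        eligible = frac_obs > 0.5
        if not eligible.any():
            raise ValueError(
                "sigma undefined: no feature observed in more than half of the samples"
            )
        sds = np.nanstd(obs[eligible], axis=1, ddof=1)
        sigma = float(np.nanmedian(sds))
        return cls(mu=mu, sigma=sigma, seed=seed)


def impute_minprob(m: IntensityMatrix, params: ImputationParams) -> IntensityMatrix:
    """Replace every missing entry by an independent draw from
    Gaussian(mu, sigma); observed entries are untouched. The pre-imputation
    mask is retained as provenance."""
    _require_stage(m, STAGE_FILTERED, "impute_minprob")
    mask = m.mask
    rng = np.random.default_rng(params.seed)
    vals = m.values.to_numpy().copy()
    miss = np.isnan(vals)
    vals[miss] = rng.normal(params.mu, params.sigma, size=int(miss.sum()))
    out = pd.DataFrame(vals, index=m.feature_ids, columns=m.samples)
    return IntensityMatrix(values=out, groups=m.groups, original_mask=mask,
                           stages=m.stages + (STAGE_IMPUTED,))


def _trend_slope(means: np.ndarray, sds: np.ndarray) -> float:
    """Slope of the lowess-smoothed SD-vs-mean trend (least-squares slope of
    the fitted trend against the mean)."""
    fitted = lowess(sds, means, frac=0.6, return_sorted=True)
    x, y = fitted[:, 0], fitted[:, 1]
    if np.ptp(x) == 0:
        return 0.0
    return float(np.polyfit(x, y, 1)[0])


def vst_normalize(m: IntensityMatrix, trend_tol: float = 0.05,
                  max_iter: int = 3) -> IntensityMatrix:
    """Variance-stabilizing normalization of a complete matrix.

    Two steps: (1) per-sample affine calibration — median-centering and
    MAD-scaling each sample to the pooled reference — and (2) if the
    lowess-estimated SD-vs-mean trend still has |slope| above ``trend_tol``,
    a monotone transform h(x) = integral of 1/sd_hat(u) du (numerically
    integrated along the trend) applied identically to all samples, which
    flattens the trend while preserving within-sample rank order.
    """
    if m.mask.to_numpy().any():
        raise ValueError("vst_normalize requires a complete (imputed) matrix")
    vals = m.values.to_numpy().astype(float).copy()

    def _affine(x: np.ndarray) -> np.ndarray:
        med = np.median(x, axis=0)
        mad = np.median(np.abs(x - med), axis=0)
        if (mad == 0).any():
            raise ValueError("constant sample encountered during calibration")
        ref_med = np.median(x)
        ref_mad = np.median(np.abs(x - np.median(x, axis=0)))
        return (x - med) / mad * ref_mad + ref_med

    vals = _affine(vals)
    for _ in range(max_iter):
        means = vals.mean(axis=1)
        sds = vals.std(axis=1, ddof=1)
        slope = _trend_slope(means, sds)
        if abs(slope) < trend_tol:
            break
        fitted = lowess(sds, means, frac=0.6, return_sorted=True)
        grid, sd_hat = fitted[:, 0], np.maximum(fitted[:, 1], 1e-8)
        # h(x) = cumulative integral of 1/sd_hat: strictly increasing
        h_grid = np.concatenate([[0.0], np.cumsum(np.diff(grid) / (0.5 * (sd_hat[1:] + sd_hat[:-1])))])
        span = np.ptp(grid)
        h_span = np.ptp(h_grid)
        if h_span == 0 or span == 0:
            break
        # rescale so h stays on the original intensity scale
        scale = span / h_span
        lo = grid[0]
        flat = np.interp(vals, grid, h_grid * scale + lo)
        # linear extension beyond the grid keeps monotonicity
        below = vals < grid[0]
        above = vals > grid[-1]
        flat[below] = lo + (vals[below] - grid[0]) * scale / sd_hat[0]
        flat[above] = h_grid[-1] * scale + lo + (vals[above] - grid[-1]) * scale / sd_hat[-1]
        vals = _affine(flat)

    out = pd.DataFrame(vals, index=m.feature_ids, columns=m.samples)
    return IntensityMatrix(values=out, groups=m.groups, original_mask=m.original_mask,
                           stages=m.stages + (STAGE_VST,))


def preprocess(m: IntensityMatrix, max_missing_per_group: int = 2,
               seed: int = 0) -> IntensityMatrix:
    """Full preprocessing chain: filter -> impute -> vst."""
    filtered = filter_missing(m, max_missing_per_group)
    params = ImputationParams.estimate(filtered, seed=seed)
    imputed = impute_minprob(filtered, params)
    return vst_normalize(imputed)
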