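"""Two-group differential expression with empirical-Bayes variance moderation.

The per-feature residual variances of a two-group linear model are shrunk
toward a pooled prior by an inverse-chi-square empirical Bayes step: the
posterior variance is ``(d0*s0^2 + d*s^2) / (d0 + d)`` and the moderated t
statistic is referred to a t distribution on ``d0 + d`` degrees of freedom.
The prior (d0, s0^2) is estimated by a method of moments on log s^2
(trigamma matching), the standard estimator for this model family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import IntensityMatrix


@dataclass
class ModerationParams:
    """Empirical-Bayes prior: d0 prior degrees of freedom (may be ``inf``),
    s0_sq prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0 (or inf)")
        if self.s0_sq < 0:
            raise ValueError("s0_sq must be >= 0")


def fit_two_group(m: IntensityMatrix, allow_missing: bool = False) -> pd.DataFrame:
    """Per-feature two-group fit.

    Returns a DataFrame with ``logFC`` (case - control group mean
    difference), pooled within-group variance ``s2``, per-feature residual
    degrees of freedom ``df``, per-feature sample counts ``n1``/``n2`` and
    the group means. With ``allow_missing`` the fit is NaN-aware: each
    feature uses its observed samples (features with fewer than two observed
    samples in either group are dropped with a warning); otherwise missing
    values are an error.
    """
    ctrl_label, case_label = m.group_levels
    ctrl = m.values[m.group_samples(ctrl_label)].to_numpy()
    case = m.values[m.group_samples(case_label)].to_numpy()
    if ctrl.shape[1] < 2 or case.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples for a pooled variance")
    if not allow_missing and (np.isnan(ctrl).any() or np.isnan(case).any()):
        raise ValueError("fit_two_group requires a complete matrix "
                         "(use allow_missing=True for a NaN-aware fit)")
    n1 = (~np.isnan(ctrl)).sum(axis=1)
    n2 = (~np.isnan(case)).sum(axis=1)
    ok = (n1 >= 2) & (n2 >= 2)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} features dropped: fewer than 2 "
                      "observed samples in a group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_c = np.nanmean(ctrl, axis=1)
        mean_t = np.nanmean(case, axis=1)
        ss = np.nansum((ctrl - mean_c[:, None]) ** 2, axis=1) + \
             np.nansum((case - mean_t[:, None]) ** 2, axis=1)
    df = n1 + n2 - 2
    fits = pd.DataFrame({
        "logFC": mean_t - mean_c,
        "s2": np.where(ok, ss / np.maximum(df, 1), np.nan),
        "df": df.astype(float),
        "n1": n1,
        "n2": n2,
        "mean_control": mean_c,
        "mean_case": mean_t,
    }, index=m.feature_ids).loc[ok]
    fits.attrs["n1"] = int(ctrl.shape[1])
    fits.attrs["n2"] = int(case.shape[1])
    return fits


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float | np.ndarray) -> ModerationParams:
    """Method-of-moments prior estimation on log s^2 (trigamma matching).

    ``df`` may be a scalar or a per-feature vector (NaN-aware fits). Zero
    variances are excluded from moment estimation (they carry no scale
    information); if fewer than 2 positive variances remain the prior falls
    back to d0 = 0 (no moderation).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    pos = s2 > 0
    if len(s2) < 10:
        warnings.warn("fewer than 10 features: prior estimation is unstable")
    if pos.sum() < 2:
        warnings.warn("not enough positive variances to estimate a prior; "
                      "falling back to d0=0 (ordinary t)")
        return ModerationParams(d0=0.0, s0_sq=float(s2[pos].mean()) if pos.any() else 1.0)
    z = np.log(s2[pos])
    dfp = df[pos]
    e = z - special.digamma(dfp / 2.0) + np.log(dfp / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, dfp / 2.0).mean()
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(e_mean)
    return ModerationParams(d0=float(d0), s0_sq=float(s0_sq))


def ebayes_moderate(fits: pd.DataFrame,
                    params: ModerationParams | None = None) -> pd.DataFrame:
    """Moderate the per-feature t statistics and attach p-values.

    With ``params=None`` the prior is estimated from the data. Degrees of
    freedom of the reference t distribution are ``d0 + df``; the d0 = inf
    limit uses the normal distribution. Features whose posterior variance is
    exactly zero get infinite t and are flagged in the ``infinite_t`` column.
    Benjamini-Hochberg adjustment is applied across all tested features.
    """
    if "n1" in fits.columns:
        n1 = fits["n1"].to_numpy(dtype=float)
        n2 = fits["n2"].to_numpy(dtype=float)
    else:
        n1, n2 = fits.attrs.get("n1"), fits.attrs.get("n2")
        if n1 is None or n2 is None:
            raise ValueError("fits must carry n1/n2 (use fit_two_group)")
    s2 = fits["s2"].to_numpy()
    df = fits["df"].to_numpy(dtype=float)
    if params is None:
        params = estimate_prior(s2, df)
    d0, s0_sq = params.d0, params.s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    logfc = fits["logFC"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / np.where(se > 0, se, 1.0),
                     np.sign(logfc) * np.inf)
    t = np.where((se == 0) & (logfc == 0), 0.0, t)
    infinite = ~np.isfinite(t)
    if infinite.any():
        warnings.warn(f"{int(infinite.sum())} features have zero posterior variance "
                      "(infinite moderated t); their p-values are set to 0")
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(infinite, 0.0, p)
    out = fits.copy()
    out["t_mod"] = t
    out["p"] = p
    out["p_adj"] = bh_adjust(p)
    out["infinite_t"] = infinite
    out.attrs.update(fits.attrs)
    out.attrs["d0"] = float(d0)
    out.attrs["s0_sq"] = float(s0_sq)
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def de_two_group(m: IntensityMatrix,
                 params: ModerationParams | None = None) -> pd.DataFrame:
    """Convenience wrapper: fit, moderate, return the full DE table."""
    return ebayes_moderate(fit_two_group(m), params)


def top_table(de: pd.DataFrame, p_cut: float = 0.05,
              lfc_cut: float = 0.0) -> pd.DataFrame:
    """Features with p < p_cut and |logFC| > lfc_cut (strict inequalities),
    sorted by p ascending. Up/down counts are stored in ``attrs``."""
    if p_cut < 0 or lfc_cut < 0:
        raise ValueError("thresholds must be >= 0")
    sel = de[(de["p"] < p_cut) & (de["logFC"].abs() > lfc_cut)]
    sel = sel.sort_values("p", kind="stable")
    sel.attrs["n_up"] = int((sel["logFC"] > 0).sum())
    sel.attrs["n_down"] = int((sel["logFC"] < 0).sum())
    return sel
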