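"""Cell-of-origin deconvolution of bulk EV cargo by support-vector regression.

Following the CIBERSORT-style procedure, each mixture is regressed on the
signature columns with a linear nu-SVR over a small nu grid; the fit with
the lowest reconstruction RMSE wins, negative coefficients are clamped to
zero and the remainder renormalized to sum to one. Group shifts in the
per-sample proportions are tested per cell type with a two-sided Welch t
test and BH adjustment.

The regression runs on the linear intensity scale, with both matrices bound
to [0,1] by the *signature's* gene-wise min-max transformation. Sharing one
gene-wise transform is what keeps the convex-mixture identity intact
(``scaled_mixture = sum_k p_k * scaled_signature_k`` exactly, because the
fractions sum to one) while still calibrating away per-gene unit differences
between the proteomic mixture and the transcriptomic signature. Genes that
are constant across cell types carry no compositional signal; they stay in
the regression (scaled by the median gene span) where they anchor the
intercept, which would otherwise be confounded with a uniform shift of all
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import NuSVR

from .containers import IntensityMatrix
from .modstats import bh_adjust
from .signatures import match_features, minmax_scale


@dataclass
class DeconConfig:
    """Settings for SVR deconvolution.

    nu_grid: candidate nu values (support fraction) for the linear nu-SVR;
    the fit with the lowest reconstruction RMSE is selected.
    min_shared_features: required size of the mixture/signature feature
    intersection.
    """

    nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    C: float = 1.0
    min_shared_features: int = 50

    def __post_init__(self) -> None:
        if not all(0 < nu <= 1 for nu in self.nu_grid):
            raise ValueError("nu values must lie in (0, 1]")


@dataclass
class ProportionVector:
    """Per-sample cell-type fractions (non-negative, summing to one)."""

    fractions: pd.Series
    reconstruction_rmse: float
    nu: float = field(default=np.nan)


def scale_mixture_to_signature(bulk_log2: pd.DataFrame, sig_log2: pd.DataFrame
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared gene-wise [0,1] scaling of signature and mixture, on the linear
    intensity scale.

    The signature is min-max scaled gene-wise (:func:`minmax_scale` on
    ``2**sig``); the mixture is mapped with the *same* per-gene min/max so the
    convex-mixture identity is preserved. Genes constant across cell types
    (degenerate rows) are scaled by the median positive gene span instead,
    keeping their (signal-free) residuals on a comparable scale.
    """
    sig_lin = pd.DataFrame(np.power(2.0, sig_log2.to_numpy()),
                           index=sig_log2.index, columns=sig_log2.columns)
    scaled = minmax_scale(sig_lin)
    span = (scaled.x_max - scaled.x_min).to_numpy()
    positive = span[span > 0]
    if positive.size == 0:
        raise ValueError("signature is constant across cell types for every gene")
    safe_span = np.where(span > 0, span, np.median(positive))
    bulk_lin = np.power(2.0, bulk_log2.to_numpy())
    bulk_scaled = (bulk_lin - scaled.x_min.to_numpy()[:, None]) / safe_span[:, None]
    sig_scaled = (sig_lin.to_numpy() - scaled.x_min.to_numpy()[:, None]) / safe_span[:, None]
    return (pd.DataFrame(sig_scaled, index=sig_log2.index, columns=sig_log2.columns),
            pd.DataFrame(bulk_scaled, index=bulk_log2.index, columns=bulk_log2.columns))


def deconvolve_sample(mixture: np.ndarray | pd.Series, sig: pd.DataFrame,
                      cfg: DeconConfig | None = None) -> ProportionVector:
    """Deconvolve one scaled mixture vector against a scaled signature matrix.

    ``mixture`` and ``sig`` must share an identical, ordered feature universe
    (take the intersection upstream; see :func:`deconvolve_cohort`).
    """
    cfg = cfg or DeconConfig()
    y = np.asarray(mixture, dtype=float)
    X = sig.to_numpy(dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("mixture and signature feature universes differ")
    if len(y) < cfg.min_shared_features:
        raise ValueError(
            f"only {len(y)} shared features; need >= {cfg.min_shared_features}")
    best: tuple[float, np.ndarray, float] | None = None
    for nu in cfg.nu_grid:
        model = NuSVR(kernel="linear", nu=nu, C=cfg.C)
        model.fit(X, y)
        coef = model.coef_.ravel()
        rmse = float(np.sqrt(np.mean((model.predict(X) - y) ** 2)))
        if best is None or rmse < best[0]:
            best = (rmse, coef, nu)
    rmse, coef, nu = best
    coef = np.clip(coef, 0.0, None)
    total = coef.sum()
    if total <= 0:
        raise ValueError("all SVR coefficients non-positive: proportions undefined")
    fractions = pd.Series(coef / total, index=sig.columns)
    return ProportionVector(fractions=fractions, reconstruction_rmse=rmse, nu=nu)


def deconvolve_cohort(m: IntensityMatrix, sig: pd.DataFrame,
                      cfg: DeconConfig | None = None,
                      markers: dict[str, list[str]] | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deconvolve every sample of a preprocessed cohort and test group shifts.

    The bulk matrix and the signature matrix are intersected on uppercase
    feature symbols (restricted to the union of ``markers`` when that still
    leaves at least ``cfg.min_shared_features`` features), independently
    min-max scaled feature-wise, and deconvolved sample by sample.

    Returns
    -------
    proportions : DataFrame
        samples x cell types, plus ``rmse`` and ``nu`` columns.
    summary : DataFrame
        per cell type: mean proportion per group (as percentages), Welch t
        p-value and BH-adjusted p-value.
    """
    cfg = cfg or DeconConfig()
    if m.mask.to_numpy().any():
        raise ValueError("deconvolve_cohort requires a complete (preprocessed) matrix")
    bulk, sig_m = match_features(m.values, sig)
    if markers:
        union = {g.upper() for genes in markers.values() for g in genes}
        keep = np.array([f.upper() in union for f in bulk.index])
        # fall back to all shared features when too few markers overlap
        if int(keep.sum()) >= cfg.min_shared_features:
            bulk, sig_m = bulk.loc[keep], sig_m.loc[keep]
    if len(bulk) < cfg.min_shared_features:
        raise ValueError(
            f"feature overlap {len(bulk)} below minimum {cfg.min_shared_features}")
    sig_scaled, bulk_scaled = scale_mixture_to_signature(bulk, sig_m)
    rows = {}
    for sample in bulk_scaled.columns:
        pv = deconvolve_sample(bulk_scaled[sample], sig_scaled, cfg)
        rows[sample] = pd.concat([pv.fractions,
                                  pd.Series({"rmse": pv.reconstruction_rmse,
                                             "nu": pv.nu})])
    props = pd.DataFrame(rows).T
    props.index.name = "sample"

    ctrl_label, case_label = m.group_levels
    ctrl_rows = props.loc[m.group_samples(ctrl_label), sig.columns]
    case_rows = props.loc[m.group_samples(case_label), sig.columns]
    pvals = []
    for ct in sig.columns:
        res = stats.ttest_ind(case_rows[ct], ctrl_rows[ct], equal_var=False)
        pvals.append(res.pvalue if np.isfinite(res.pvalue) else 1.0)
    summary = pd.DataFrame({
        "cell_type": list(sig.columns),
        "mean_control_pct": 100.0 * ctrl_rows.mean().to_numpy(),
        "mean_case_pct": 100.0 * case_rows.mean().to_numpy(),
        "p": pvals,
        "p_adj": bh_adjust(np.asarray(pvals)),
    }).set_index("cell_type")
    return props, summary
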