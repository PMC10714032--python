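"""OpenArray/qPCR Ct processing and the miRNA origin classifier.

Ct values are cycle thresholds (log2-scale of inverse abundance: a drop of
one Ct corresponds to a doubling of expression). The stages are: reliability
filtering against Ct ceiling and amplification-score cutoffs, one of three
normalizations (rank-invariant features, scale-invariant features, or
sample means — the geometric-mean equivalent on the log-scale Ct),
comparative-Ct (delta-delta-Ct) quantification, moderated differential
expression on sign-inverted Ct values, and a rule-based classifier deciding
whether a glial miRNA is endogenously produced or exogenously imported,
combining a DICER-knockout contrast (a cell lacking DICER cannot mature its
own miRNA) with primary/precursor transcript evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, CtMatrix, IntensityMatrix
from .modstats import ModerationParams, de_two_group

RANK_SD_BAND = 1.0   # max cross-sample rank SD for a rank-invariant feature
CV_MAX = 0.02        # max coefficient of variation for a scale-invariant feature


def unreliable_mask(m: CtMatrix) -> pd.DataFrame:
    """Entries failing the Ct ceiling or amplification-score cutoff."""
    return (m.ct > m.thresholds.ct_max) | (m.amp_score < m.thresholds.amp_min) | m.ct.isna()


def filter_unreliable(m: CtMatrix) -> CtMatrix:
    """Drop miRNAs with more than ``max_unreliable`` unreliable Cts; set the
    remaining unreliable entries to missing."""
    bad = unreliable_mask(m)
    keep = bad.sum(axis=1) <= m.thresholds.max_unreliable
    n_removed = int((~keep).sum())
    if n_removed:
        warnings.warn(
            f"filter_unreliable removed {n_removed} miRNAs "
            f"(ct_max={m.thresholds.ct_max}, amp_min={m.thresholds.amp_min}, "
            f"max_unreliable={m.thresholds.max_unreliable})")
    ct = m.ct.loc[keep].mask(bad.loc[keep])
    return CtMatrix(ct=ct, amp_score=m.amp_score.loc[keep], groups=m.groups,
                    thresholds=m.thresholds)


def _rle(ct: pd.DataFrame) -> pd.Series:
    """Per-sample median relative log expression (Ct minus row median)."""
    rle = ct.sub(ct.median(axis=1), axis=0)
    return rle.median(axis=0)


def normalize_ct(m: CtMatrix, method: str = "geomean",
                 rank_sd_band: float = RANK_SD_BAND,
                 cv_max: float = CV_MAX) -> tuple[CtMatrix, pd.DataFrame]:
    """Normalize Ct values; returns the normalized matrix and diagnostics.

    ``geomean``
        Subtract each sample's mean Ct (the geometric-mean equivalent, Ct
        being log-scale) and re-center at the global mean.
    ``rank_invariant``
        Normalize to the mean Ct of features whose cross-sample rank SD is
        within ``rank_sd_band`` (computed on fully observed features).
    ``scale_invariant``
        Same, using features with coefficient of variation <= ``cv_max``.

    When no invariant feature qualifies, falls back to ``geomean`` with a
    warning. Diagnostics report the per-sample median relative log
    expression before and after.
    """
    if method not in {"geomean", "rank_invariant", "scale_invariant"}:
        raise ValueError(f"unknown normalization method {method!r}")
    ct = m.ct
    before = _rle(ct)
    if method == "geomean":
        ref = ct.mean(axis=0)
    else:
        complete = ct.dropna(axis=0)
        if complete.empty:
            chosen = pd.Index([])
        elif method == "rank_invariant":
            ranks = complete.rank(axis=0)
            chosen = complete.index[ranks.std(axis=1, ddof=1) <= rank_sd_band]
        else:
            cv = complete.std(axis=1, ddof=1) / complete.mean(axis=1)
            chosen = complete.index[cv <= cv_max]
        if len(chosen) == 0:
            warnings.warn(f"no invariant features found for {method}; "
                          "falling back to geomean")
            ref = ct.mean(axis=0)
        else:
            ref = ct.loc[chosen].mean(axis=0)
    normalized = ct.sub(ref, axis=1) + ref.mean()
    out = CtMatrix(ct=normalized, amp_score=m.amp_score, groups=m.groups,
                   thresholds=m.thresholds)
    diagnostics = pd.DataFrame({"rle_before": before, "rle_after": _rle(normalized)})
    return out, diagnostics


def ddct_percent(target_ct: pd.Series, reference_ct: pd.Series,
                 groups: pd.Series) -> float:
    """Comparative-Ct percent change of the case group relative to control.

    delta Ct = Ct_target - Ct_reference per sample; delta-delta Ct is the
    case-minus-control difference of group means; the result is
    ``2^(-ddCt) * 100`` (identical groups -> 100%).
    """
    groups = pd.Series(groups)
    dct = target_ct - reference_ct
    for g in (CONTROL, CASE):
        if not (groups == g).any():
            raise ValueError(f"group {g!r} absent")
    mean_case = dct[groups.index[groups == CASE]].mean()
    mean_ctrl = dct[groups.index[groups == CONTROL]].mean()
    if np.isnan(mean_case) or np.isnan(mean_ctrl):
        raise ValueError("a group has no observed delta-Ct values")
    ddct = mean_case - mean_ctrl
    return float(2.0 ** (-ddct) * 100.0)


def ct_differential_expression(m: CtMatrix,
                               params: ModerationParams | None = None
                               ) -> pd.DataFrame:
    """Moderated DE on Ct values, reported on the abundance scale.

    Ct values are sign-inverted before model fitting so that a positive
    logFC means higher expression in the case group (lower Ct). The fit is
    NaN-aware: each miRNA uses its reliable samples; miRNAs with fewer than
    two reliable samples in a group are dropped.
    """
    from .modstats import ebayes_moderate, fit_two_group

    expr = IntensityMatrix(values=-m.ct, groups=m.groups, stages=("log2",))
    fits = fit_two_group(expr, allow_missing=True)
    return ebayes_moderate(fits, params)


@dataclass
class OriginEvidence:
    """Evidence for one miRNA's origin call.

    dicer_ko_logfc / dicer_ko_p: abundance-scale contrast of DICER-knockout
    vs wild-type glia. pri_detected: primary transcript detected in the glial
    cell (only the producing cell can raise it). pre_changed: precursor
    transcript significantly changed between conditions.
    """

    dicer_ko_logfc: float
    dicer_ko_p: float
    pri_detected: bool = False
    pre_changed: bool = False
    alpha: float = 0.05


@dataclass
class OriginCall:
    glia_mature_logfc: float | None
    dicer_ko_logfc: float
    dicer_ko_significant: bool
    pri_detected: bool
    pre_changed: bool
    call: str  # endogenous | exogenous | indeterminate


def classify_origin(evidence: OriginEvidence,
                    glia_mature_logfc: float | None = None) -> OriginCall:
    """Classify a glial miRNA as endogenously produced or exogenously imported.

    Endogenous: significantly downregulated in the DICER knockout (the cell
    was producing it) OR its primary transcript is detected. Exogenous:
    knockout shows upregulation or no significant change AND no primary
    transcript AND no precursor change. Anything else is indeterminate.
    The mapping is total: every evidence combination yields exactly one call.
    """
    sig = evidence.dicer_ko_p < evidence.alpha
    ko_down = sig and evidence.dicer_ko_logfc < 0
    if ko_down or evidence.pri_detected:
        call = "endogenous"
    elif (evidence.dicer_ko_logfc > 0 or not sig) and not evidence.pre_changed:
        call = "exogenous"
    else:
        call = "indeterminate"
    return OriginCall(glia_mature_logfc=glia_mature_logfc,
                      dicer_ko_logfc=evidence.dicer_ko_logfc,
                      dicer_ko_significant=sig,
                      pri_detected=evidence.pri_detected,
                      pre_changed=evidence.pre_changed,
                      call=call)


def classify_origin_table(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Vectorized origin calls for a table with columns ``dicer_ko_logfc``,
    ``dicer_ko_p`` and optional ``pri_detected`` / ``pre_changed``."""
    out = table.copy()
    calls = []
    for _, row in table.iterrows():
        ev = OriginEvidence(
            dicer_ko_logfc=float(row["dicer_ko_logfc"]),
            dicer_ko_p=float(row["dicer_ko_p"]),
            pri_detected=bool(row.get("pri_detected", False)),
            pre_changed=bool(row.get("pre_changed", False)),
            alpha=alpha,
        )
        calls.append(classify_origin(ev).call)
    out["call"] = calls
    return out
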