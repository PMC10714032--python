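"""Self-contained recovery experiments on synthetic data.

Each function simulates inputs with :mod:`evintegra.syndata`, runs the
corresponding pipeline stage, and measures how well known ground truth is
recovered. They are used both by the test suite and by the acceptance
script; every one takes an explicit seed and is deterministic given it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import syndata
from .containers import CASE, CONTROL, IntensityMatrix
from .ctarray import filter_unreliable, unreliable_mask
from .decon import DeconConfig, deconvolve_cohort
from .modstats import ModerationParams, de_two_group, ebayes_moderate, fit_two_group
from .prot_prep import ImputationParams, filter_missing, impute_minprob

DEFAULT_PROPS_CONTROL = (0.40, 0.30, 0.15, 0.10, 0.05)
DEFAULT_PROPS_CASE = (0.25, 0.25, 0.15, 0.10, 0.25)
# mirrors the study's control-to-degeneration glial shift (2.6% -> 22.2%)
SHIFT_PROPS_CONTROL = (0.45, 0.27, 0.15, 0.10, 0.03)
SHIFT_PROPS_CASE = (0.30, 0.23, 0.15, 0.10, 0.22)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s % (2 ** 31)) for s in np.random.SeedSequence(seed).generate_state(n)]


def _simulate_cohort(seed: int, control_props, case_props, noise_sd: float,
                     dropout_rate: float, n_genes: int = 500,
                     n_samples_per_group: int = 5):
    s_sig, s_truth, s_imp = _child_seeds(seed, 3)
    sig, _ = syndata.gen_cell_signatures(n_genes, len(control_props), 60, 3.0,
                                         seed=s_sig)
    truth = syndata.make_truth(sig.columns, control_props, case_props,
                               n_samples_per_group, dropout_rate=dropout_rate,
                               noise_sd=noise_sd, seed=s_truth)
    m = syndata.gen_ev_proteome(sig, truth)
    filtered = filter_missing(m)
    imputed = impute_minprob(filtered, ImputationParams.estimate(filtered, seed=s_imp))
    return sig, truth, imputed


def decon_recovery(n_seeds: int = 20, seed: int = 0, noise_sd: float = 0.1,
                   dropout_rate: float = 0.1) -> dict[str, float]:
    """Deconvolution parameter recovery over replicate simulated cohorts.

    Five cell types, five samples per group, additive log2 noise and MNAR
    dropout; each cohort is filtered, imputed and deconvolved against the
    reference signature. Reports the mean absolute proportion error per type
    (worst type), and the Pearson correlation between true and estimated
    proportions pooled over all samples, types and seeds.
    """
    per_type_errors = []
    truths, estimates = [], []
    for s in _child_seeds(seed, n_seeds):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sig, truth, imputed = _simulate_cohort(
                s, DEFAULT_PROPS_CONTROL, DEFAULT_PROPS_CASE, noise_sd, dropout_rate)
            props, _ = deconvolve_cohort(imputed, sig, DeconConfig())
        est = props[sig.columns]
        true = truth.proportions.loc[est.index]
        per_type_errors.append((est - true).abs().mean(axis=0))
        truths.append(true.to_numpy().ravel())
        estimates.append(est.to_numpy().ravel())
    errs = pd.concat(per_type_errors, axis=1)  # types x seeds
    corr = float(np.corrcoef(np.concatenate(truths), np.concatenate(estimates))[0, 1])
    return {
        "mean_abs_error": float(errs.mean(axis=1).mean()),
        "max_type_mean_abs_error": float(errs.mean(axis=1).max()),
        "truth_estimate_correlation": corr,
        "n": n_seeds,
    }


def shift_detection(n_seeds: int = 20, seed: int = 0, noise_sd: float = 0.1,
                    dropout_rate: float = 0.1, alpha: float = 0.05) -> dict[str, float]:
    """Planted group-shift recovery: the fifth cell type's fraction moves from
    3% (control) to 22% (case). Reports in how many replicate cohorts the
    shifted type is significant at BH-adjusted alpha, plus the average
    estimated group means for that type."""
    detected = 0
    ctrl_means, case_means = [], []
    for s in _child_seeds(seed, n_seeds):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sig, truth, imputed = _simulate_cohort(
                s, SHIFT_PROPS_CONTROL, SHIFT_PROPS_CASE, noise_sd, dropout_rate)
            _, summary = deconvolve_cohort(imputed, sig, DeconConfig())
        shifted = sig.columns[-1]
        if summary.loc[shifted, "p_adj"] < alpha:
            detected += 1
        ctrl_means.append(summary.loc[shifted, "mean_control_pct"])
        case_means.append(summary.loc[shifted, "mean_case_pct"])
    return {
        "detected": detected,
        "detection_rate": detected / n_seeds,
        "mean_control_pct": float(np.mean(ctrl_means)),
        "mean_case_pct": float(np.mean(case_means)),
        "n": n_seeds,
    }


def _null_matrix(n_features: int, n_per_group: int, rng: np.random.Generator
                 ) -> IntensityMatrix:
    samples = [f"ctrl_{i}" for i in range(n_per_group)] + \
              [f"case_{i}" for i in range(n_per_group)]
    groups = pd.Series([CONTROL] * n_per_group + [CASE] * n_per_group, index=samples)
    vals = pd.DataFrame(rng.normal(0.0, 1.0, size=(n_features, 2 * n_per_group)),
                        index=[f"G{i:05d}" for i in range(n_features)], columns=samples)
    return IntensityMatrix(values=vals, groups=groups)


def type1_error(n_seeds: int = 10, seed: int = 0, n_features: int = 2000,
                n_per_group: int = 5, alpha: float = 0.05) -> dict[str, float]:
    """Moderated-t calibration on pure-null Gaussian data: fraction of raw
    p-values below alpha, pooled over replicate simulations."""
    rejections, total = 0, 0
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            de = de_two_group(_null_matrix(n_features, n_per_group, rng))
        rejections += int((de["p"] < alpha).sum())
        total += len(de)
    return {"type1_error": rejections / total, "n": total}


def moderation_reduces_to_ordinary_t(seed: int = 0, n_features: int = 200,
                                     n_per_group: int = 5) -> float:
    """Max |t_mod - pooled t| when the prior weight d0 is set to zero."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    m = _null_matrix(n_features, n_per_group, rng)
    fits = fit_two_group(m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        de = ebayes_moderate(fits, ModerationParams(d0=0.0, s0_sq=1.0))
    ctrl = m.values[m.group_samples(CONTROL)].to_numpy()
    case = m.values[m.group_samples(CASE)].to_numpy()
    t_ref = stats.ttest_ind(case, ctrl, axis=1, equal_var=True).statistic
    return float(np.max(np.abs(de["t_mod"].to_numpy() - t_ref)))


def spikein_power(n_seeds: int = 20, seed: int = 0, lfc: float = 1.5,
                  sd: float = 0.5, n_features: int = 500, n_spiked: int = 50,
                  n_per_group: int = 5, alpha: float = 0.05) -> dict[str, float]:
    """Power to detect spiked features at BH-adjusted alpha on Gaussian data."""
    hits, total = 0, 0
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        m = _null_matrix(n_features, n_per_group, rng)
        vals = m.values * sd
        spiked = list(vals.index[:n_spiked])
        vals.loc[spiked, m.group_samples(CASE)] += lfc
        m = IntensityMatrix(values=vals, groups=m.groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            de = de_two_group(m)
        hits += int((de.loc[spiked, "p_adj"] < alpha).sum())
        total += n_spiked
    return {"power": hits / total, "n": total}


def imputation_moments(seed: int = 0, n_features: int = 1000,
                       n_samples: int = 12, target_missing: int = 10000
                       ) -> dict[str, float]:
    """Moments of the imputed entries versus the MinProb Gaussian parameters.

    Builds a matrix with ~``target_missing`` missing entries (missing
    completely at random within the eligible region so the observed-value
    parameters stay estimable), imputes, and reports the standardized
    deviation of the imputed mean from mu and the relative deviation of the
    imputed SD from sigma.
    """
    rng = np.random.default_rng(seed)
    n_features = max(n_features, int(np.ceil(target_missing / (n_samples // 3))))
    samples = [f"ctrl_{i}" for i in range(n_samples // 2)] + \
              [f"case_{i}" for i in range(n_samples // 2)]
    groups = pd.Series([CONTROL] * (n_samples // 2) + [CASE] * (n_samples // 2),
                       index=samples)
    vals = rng.normal(20.0, 2.0, size=(n_features, n_samples))
    # drop entries in at most a third of the columns so every feature stays
    # observed in >50% of samples
    k = n_samples // 3
    miss = np.zeros_like(vals, dtype=bool)
    rows = rng.choice(n_features, size=target_missing // k, replace=False)
    for r in rows:
        miss[r, rng.choice(n_samples, size=k, replace=False)] = True
    vals = np.where(miss, np.nan, vals)
    m = IntensityMatrix(values=pd.DataFrame(vals, columns=samples), groups=groups,
                        stages=("log2", "filtered"))
    params = ImputationParams.estimate(m, seed=int(rng.integers(2 ** 31)))
    imputed = impute_minprob(m, params)
    drawn = imputed.values.to_numpy()[miss]
    n_imputed = int(miss.sum())
    mean_dev_se = abs(drawn.mean() - params.mu) / (params.sigma / np.sqrt(n_imputed))
    sd_rel_dev = abs(drawn.std(ddof=1) - params.sigma) / params.sigma
    observed_unchanged = np.array_equal(
        imputed.values.to_numpy()[~miss], np.asarray(
            pd.DataFrame(vals).to_numpy())[~miss])
    return {"mean_dev_se": float(mean_dev_se), "sd_rel_dev": float(sd_rel_dev),
            "observed_unchanged": bool(observed_unchanged), "n": n_imputed}


def ddct_exact() -> float:
    """Percent change for an exactly planted delta-delta-Ct of -1."""
    from .ctarray import ddct_percent

    samples = ["ctrl_1", "ctrl_2", "ctrl_3", "case_1", "case_2", "case_3"]
    groups = pd.Series([CONTROL] * 3 + [CASE] * 3, index=samples)
    reference = pd.Series([20.0] * 6, index=samples)
    target = pd.Series([25.0, 26.0, 27.0, 24.0, 25.0, 26.0], index=samples)
    return ddct_percent(target, reference, groups)


def ct_filter_matches_oracle(seed: int = 0, n_mirna: int = 200,
                             n_samples_per_group: int = 6) -> dict[str, float]:
    """Compare the Ct reliability filter against brute-force per-row counting."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ct, _ = syndata.gen_ct_array(n_mirna, n_samples_per_group, 10, -1.0,
                                     0.08, seed=seed)
        kept = set(filter_unreliable(ct).ct.index)
    bad = unreliable_mask(ct)
    expected = {m for m in ct.ct.index
                if int(bad.loc[m].sum()) <= ct.thresholds.max_unreliable}
    return {"agreement": float(kept == expected), "n_kept": len(kept),
            "n": len(ct.ct.index)}


def gsea_enumeration_sweep(max_n: int = 8, max_s: int = 3) -> dict[str, float]:
    """Exhaustive-enumeration agreement sweep for the enrichment p-value.

    For every universe size N <= max_n and set size |S| <= min(max_s, N-1),
    and for every placement of the set, the exact-mode permutation p must
    equal the tail fraction computed by an independent brute-force
    enumeration of the running-sum statistic. Returns the max |difference|.
    """
    from itertools import combinations

    from .enrich import gsea_preranked

    def brute_es(n: int, positions: tuple[int, ...], metric: np.ndarray) -> float:
        hits = np.zeros(n)
        w = np.abs(metric[list(positions)])
        hits[list(positions)] = (w / w.sum()) if w.sum() > 0 else 1.0 / len(positions)
        running = np.cumsum(hits) - np.arange(1, n + 1) / n
        return running[np.argmax(np.abs(running))]

    max_diff = 0.0
    n_checked = 0
    for n in range(2, max_n + 1):
        metric = np.linspace(2.0, 1.0, n)
        genes = [f"g{i}" for i in range(n)]
        ranked = pd.Series(metric, index=genes)
        for s in range(1, min(max_s, n - 1) + 1):
            all_es = {pos: brute_es(n, pos, metric)
                      for pos in combinations(range(n), s)}
            for pos, es in all_es.items():
                expected_p = np.mean([abs(e) >= abs(es) - 1e-12
                                      for e in all_es.values()])
                res = gsea_preranked(ranked, [genes[i] for i in pos],
                                     permutations="exact")
                max_diff = max(max_diff, abs(res.p - expected_p),
                               abs(res.es - es))
                n_checked += 1
    return {"max_abs_diff": max_diff, "n": n_checked}


def ora_closed_form() -> dict[str, float]:
    """Hypergeometric ORA on the textbook instance N=10, K=5, n=4, k=4."""
    from .enrich import ora_hypergeom

    universe = [f"u{i}" for i in range(10)]
    p, k = ora_hypergeom(universe[:4], universe[:5], universe)
    return {"p": p, "expected": 5.0 / 210.0, "overlap": k, "n": 10}
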