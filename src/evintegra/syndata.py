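"""Synthetic-data generators with known ground truth.

Every generator is a pure function of its parameters and an explicit seed
(one ``numpy.random.Generator`` stream per call, no global state), so
repeated calls are bit-identical. The generators emulate the processed
matrices of an EV multiomics study: cell-type expression signatures, convex
EV proteome mixtures with additive noise and intensity-dependent (MNAR)
dropout, negative-binomial single-cell counts, qPCR Ct arrays with
amplification-score reliability flags, and a toy ligand-receptor database.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, CellMatrix, CtMatrix, CtThresholds, IntensityMatrix, SimTruth

# Baseline log2 expression is drawn from a Gaussian on the log2 scale
# (log-normal intensities): mean 5, sd 1.5. Arbitrary but configurable.
BASELINE_MEAN = 5.0
BASELINE_SD = 1.5

# Logistic width (log2 units) of the MNAR dropout curve.
MNAR_SCALE = 1.0


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def gen_cell_signatures(
    n_genes: int,
    n_celltypes: int,
    n_markers_per_type: int,
    marker_log2fc: float,
    seed: int,
    baseline_mean: float = BASELINE_MEAN,
    baseline_sd: float = BASELINE_SD,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Simulate cell-type signature profiles with planted, disjoint markers.

    Each cell type's column equals a shared log-normal baseline (Gaussian on
    the log2 scale) with exactly ``n_markers_per_type`` genes elevated by
    ``marker_log2fc``. Returns the genes x cell-types signature matrix
    (log2 units) and the planted marker sets.
    """
    if n_markers_per_type * n_celltypes > n_genes:
        raise ValueError(
            f"cannot allocate {n_celltypes} disjoint marker sets of size "
            f"{n_markers_per_type} among {n_genes} genes"
        )
    if marker_log2fc < 0:
        raise ValueError("marker_log2fc must be >= 0")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    types = [f"CT{k + 1}" for k in range(n_celltypes)]
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    sig = np.tile(baseline[:, None], (1, n_celltypes))
    order = rng.permutation(n_genes)
    markers: dict[str, list[str]] = {}
    for k, ct in enumerate(types):
        idx = order[k * n_markers_per_type:(k + 1) * n_markers_per_type]
        sig[idx, k] += marker_log2fc
        markers[ct] = sorted(genes[i] for i in idx)
    return pd.DataFrame(sig, index=genes, columns=types), markers


def make_truth(
    celltypes: Sequence[str],
    control_props: Sequence[float],
    case_props: Sequence[float],
    n_samples_per_group: int,
    de_features: Mapping[str, float] | None = None,
    dropout_rate: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SimTruth:
    """Assemble a :class:`SimTruth` for a two-group cohort with fixed
    per-group cell-type proportions."""
    samples = [f"ctrl_{i + 1}" for i in range(n_samples_per_group)] + \
              [f"case_{i + 1}" for i in range(n_samples_per_group)]
    rows = [list(control_props)] * n_samples_per_group + \
           [list(case_props)] * n_samples_per_group
    props = pd.DataFrame(rows, index=samples, columns=list(celltypes), dtype=float)
    return SimTruth(proportions=props, de_features=dict(de_features or {}),
                    dropout_rate=dropout_rate, noise_sd=noise_sd, seed=seed)


def truth_groups(truth: SimTruth) -> pd.Series:
    """Group labels implied by the sample naming convention of
    :func:`make_truth` (``ctrl_*`` -> control, everything else -> case)."""
    return pd.Series(
        {s: (CONTROL if s.startswith("ctrl") else CASE) for s in truth.proportions.index}
    )


def _mnar_dropout_probs(noiseless: np.ndarray, dropout_rate: float,
                        scale: float = MNAR_SCALE) -> np.ndarray:
    """Logistic MNAR dropout probabilities, decreasing in log2 intensity.

    The logistic midpoint sits at the lower quartile of the noiseless matrix
    and the curve amplitude is tuned so the expected global missing rate
    equals ``dropout_rate`` (a width-only tuning cannot reach low global
    rates, so the amplitude is the tuned knob).
    """
    if dropout_rate == 0:
        return np.zeros_like(noiseless)
    midpoint = np.quantile(noiseless, 0.25)
    logistic = 1.0 / (1.0 + np.exp((noiseless - midpoint) / scale))
    amplitude = dropout_rate / logistic.mean()
    probs = amplitude * logistic
    if probs.max() > 1.0:
        # extremely high requested rates: cap and warn, rate becomes approximate
        warnings.warn("dropout_rate too high for logistic MNAR shape; capping probabilities at 1")
        probs = np.minimum(probs, 1.0)
    return probs


def gen_ev_proteome(
    signatures: pd.DataFrame,
    truth: SimTruth,
    groups: pd.Series | None = None,
) -> IntensityMatrix:
    """Simulate a bulk EV proteome as convex mixtures of cell-type signatures.

    Each sample's log2 intensity is ``log2(sum_k p_k * 2^signature_k)`` plus a
    group effect on the spiked features (case samples only) plus Gaussian
    noise, after which entries are dropped to missing with probability
    decreasing in intensity (logistic MNAR; see :func:`_mnar_dropout_probs`).
    """
    props = truth.proportions
    missing_types = [c for c in props.columns if c not in signatures.columns]
    if missing_types:
        raise ValueError(f"truth references unknown cell types: {missing_types}")
    if groups is None:
        groups = truth_groups(truth)
    rng = np.random.default_rng(truth.seed)
    linear = np.power(2.0, signatures[props.columns].to_numpy())  # genes x types
    mix = linear @ props.to_numpy().T  # genes x samples
    log2mix = np.log2(mix)
    values = pd.DataFrame(log2mix, index=signatures.index, columns=props.index)
    case_samples = [s for s in props.index if groups[s] == CASE]
    for feat, lfc in truth.de_features.items():
        if feat not in values.index:
            raise ValueError(f"de feature {feat!r} not in signature gene universe")
        values.loc[feat, case_samples] += lfc
    noiseless = values.to_numpy().copy()
    if truth.noise_sd > 0:
        values += rng.normal(0.0, truth.noise_sd, size=values.shape)
    probs = _mnar_dropout_probs(noiseless, truth.dropout_rate)
    drop = rng.random(values.shape) < probs
    out = values.mask(drop)
    return IntensityMatrix(values=out, groups=groups, stages=("log2",))


def gen_single_cell_counts(
    signatures: pd.DataFrame,
    cells_per_type: int,
    library_size: float,
    dispersion: float,
    seed: int,
) -> CellMatrix:
    """Draw negative-binomial single-cell counts around the signature profiles.

    Per-gene mean in a cell of type *k* is the signature column (on the linear
    scale) rescaled to sum to ``library_size``. ``dispersion`` is the
    NB overdispersion alpha (variance = mu + alpha * mu^2); alpha = 0 falls
    back to Poisson sampling.
    """
    if cells_per_type < 2:
        raise ValueError("cells_per_type must be >= 2 so every label has >= 2 cells")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    genes = signatures.index
    blocks, cells, labels = [], [], []
    for ct in signatures.columns:
        lin = np.power(2.0, signatures[ct].to_numpy())
        mu = library_size * lin / lin.sum()
        mu_block = np.tile(mu[:, None], (1, cells_per_type))
        if dispersion == 0:
            counts = rng.poisson(mu_block)
        else:
            r = 1.0 / dispersion
            # NB as gamma-Poisson mixture, vectorized
            lam = rng.gamma(shape=r, scale=mu_block / r)
            counts = rng.poisson(lam)
        blocks.append(counts)
        ids = [f"{ct}_c{i + 1}" for i in range(cells_per_type)]
        cells.extend(ids)
        labels.extend([ct] * cells_per_type)
    counts = pd.DataFrame(np.hstack(blocks), index=genes, columns=cells)
    return CellMatrix(counts=counts, labels=pd.Series(labels, index=cells),
                      dispersion=pd.Series(dispersion, index=genes))


def gen_ct_array(
    n_mirna: int,
    n_samples_per_group: int,
    n_de: int,
    de_delta_ct: float,
    unreliable_fraction: float,
    seed: int,
    baseline_range: tuple[float, float] = (22.0, 32.0),
    ct_sd: float = 0.25,
    sample_offset_sd: float = 0.5,
    thresholds: CtThresholds | None = None,
    include_reference: bool = True,
) -> tuple[CtMatrix, dict[str, float]]:
    """Simulate an OpenArray-style Ct matrix with reliability flags.

    Ct values are Gaussian around per-miRNA baselines plus a per-sample
    loading offset (``sample_offset_sd``, emulating input-amount differences
    that normalization must remove); ``n_de`` miRNAs are shifted by
    ``de_delta_ct`` in the case group (negative delta = higher expression).
    A ``unreliable_fraction`` of entries is flagged by either a
    low amplification score or a Ct above the ceiling. When
    ``include_reference`` a stable reference assay ``U6`` (never DE, never
    unreliable) is appended for delta-delta-Ct use. Returns the matrix and the
    map of DE miRNA -> planted delta Ct.
    """
    if n_de > n_mirna:
        raise ValueError("n_de must be <= n_mirna")
    if not 0 <= unreliable_fraction <= 1:
        raise ValueError("unreliable_fraction must lie in [0, 1]")
    thresholds = thresholds or CtThresholds()
    rng = np.random.default_rng(seed)
    mirnas = [f"mir-{i + 1:04d}" for i in range(n_mirna)]
    samples = [f"ctrl_{i + 1}" for i in range(n_samples_per_group)] + \
              [f"case_{i + 1}" for i in range(n_samples_per_group)]
    groups = pd.Series([CONTROL] * n_samples_per_group + [CASE] * n_samples_per_group,
                       index=samples)
    baseline = rng.uniform(*baseline_range, size=n_mirna)
    offsets = rng.normal(0.0, sample_offset_sd, size=2 * n_samples_per_group)
    ct = baseline[:, None] + offsets[None, :] + \
        rng.normal(0.0, ct_sd, size=(n_mirna, 2 * n_samples_per_group))
    de_idx = rng.choice(n_mirna, size=n_de, replace=False)
    case_cols = np.arange(n_samples_per_group, 2 * n_samples_per_group)
    ct[np.ix_(de_idx, case_cols)] += de_delta_ct
    de_map = {mirnas[i]: float(de_delta_ct) for i in sorted(de_idx)}

    # amplification scores: reliable entries comfortably above the default cutoff
    amp = rng.normal(1.6, 0.08, size=ct.shape)
    bad = rng.random(ct.shape) < unreliable_fraction
    # half of flagged entries get a failing AmpScore, half a Ct above ceiling
    amp_fail = bad & (rng.random(ct.shape) < 0.5)
    ct_fail = bad & ~amp_fail
    amp[amp_fail] = rng.normal(1.0, 0.08, size=int(amp_fail.sum()))
    amp[amp_fail] = np.minimum(amp[amp_fail], thresholds.amp_min - 1e-3)
    ct[ct_fail] = thresholds.ct_max + rng.uniform(1.0, 4.0, size=int(ct_fail.sum()))

    ct_df = pd.DataFrame(ct, index=mirnas, columns=samples)
    amp_df = pd.DataFrame(amp, index=mirnas, columns=samples)
    if include_reference:
        ref_ct = 20.0 + offsets + rng.normal(0.0, 0.05, size=2 * n_samples_per_group)
        ct_df.loc["U6"] = ref_ct
        amp_df.loc["U6"] = 1.8
    return CtMatrix(ct=ct_df, amp_score=amp_df, groups=groups,
                    thresholds=thresholds), de_map


def gen_lr_database(
    n_ligands: int,
    receptors_per_ligand: int | Sequence[int],
    shared_receptor_fraction: float,
    seed: int,
) -> pd.DataFrame:
    """Generate a toy bipartite ligand-receptor interaction table.

    The table has one row per (ligand, receptor) pair. The total number of
    rows equals the sum of per-ligand receptor slots; a
    ``shared_receptor_fraction`` of those slots reuse receptors already
    assigned to other ligands, so the distinct-receptor count is
    ``total_slots - round(fraction * total_slots)``.
    """
    if n_ligands <= 0:
        raise ValueError("n_ligands must be positive")
    if isinstance(receptors_per_ligand, int):
        rpl = [receptors_per_ligand] * n_ligands
    else:
        rpl = list(receptors_per_ligand)
        if len(rpl) != n_ligands:
            raise ValueError("receptors_per_ligand list must have length n_ligands")
    if any(r <= 0 for r in rpl):
        raise ValueError("receptors_per_ligand must be positive")
    if not 0 <= shared_receptor_fraction < 1:
        raise ValueError("shared_receptor_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    total = sum(rpl)
    n_distinct = total - int(round(shared_receptor_fraction * total))
    n_distinct = max(n_distinct, max(rpl))  # each ligand needs enough distinct receptors
    receptors = [f"R{i + 1:03d}" for i in range(n_distinct)]
    ligands = [f"LIG{i + 1}" for i in range(n_ligands)]
    rows: list[tuple[str, str]] = []
    fresh = iter(receptors)
    used: list[str] = []
    for lig, k in zip(ligands, rpl):
        mine: list[str] = []
        for _ in range(k):
            nxt = next(fresh, None)
            if nxt is not None:
                mine.append(nxt)
            else:
                pool = [r for r in used if r not in mine]
                mine.append(pool[rng.integers(len(pool))])
        used.extend(r for r in mine if r not in used)
        rows.extend((lig, r) for r in mine)
    table = pd.DataFrame(rows, columns=["ligand", "receptor"])
    return table.drop_duplicates(ignore_index=True)
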