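"""Preranked gene-set enrichment, over-representation analysis, and
cell-type-specificity enrichment grids.

The enrichment statistic is a running sum over the ranked gene list: each
gene-set member at rank *i* contributes ``|metric_i|^weight`` (normalized so
the hit contributions sum to one over the set) and every rank carries a
uniform position penalty of ``1/N``. The enrichment score (ES) is the signed
maximum deviation of this bridge from zero, so ``|ES| <= 1``; a set
concentrated in the top ranks yields ES near ``1 - |S|/N``. P-values come
from gene-label permutations with an add-one correction (or exhaustive
enumeration of all placements when requested), and the leading edge is the
set members ranked at or before (after, for negative ES) the extremum.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EnrichmentResult
from .modstats import bh_adjust

_EXACT_LIMIT = 2_000_000


def rank_genes(metric: pd.Series) -> pd.Series:
    """Order a gene -> metric map descending by metric, breaking ties by
    gene id for determinism. Duplicate gene ids are rejected."""
    if metric.index.has_duplicates:
        raise ValueError("ranked list contains duplicate gene ids")
    order = sorted(metric.index, key=lambda g: (-metric[g], g))
    return metric.loc[order]


def _es_from_positions(metric_abs_w: np.ndarray, positions: np.ndarray) -> tuple[float, int]:
    """ES (signed max deviation) and extremum index for hit positions in a
    ranked list. ``metric_abs_w`` is |metric|^weight over the full list."""
    n = len(metric_abs_w)
    hits = np.zeros(n)
    weights = metric_abs_w[positions]
    total = weights.sum()
    if total > 0:
        hits[positions] = weights / total
    else:  # all-zero metric over the set: uniform hit increments
        hits[positions] = 1.0 / len(positions)
    running = np.cumsum(hits) - np.arange(1, n + 1) / n
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx


def gsea_preranked(ranked: pd.Series, gene_set: Iterable[str],
                   n_perm: int = 1000, weight: float = 1.0,
                   seed: int | None = None,
                   permutations: str = "random") -> EnrichmentResult:
    """Preranked gene-set enrichment with permutation p-values.

    Parameters
    ----------
    ranked
        gene -> metric map; re-ranked internally (descending, gene-id
        tie-break).
    gene_set
        Gene ids; genes absent from the ranked list are ignored, an empty
        intersection is an error.
    n_perm, seed
        Number of random gene-label permutations and RNG seed
        (``permutations="random"``).
    permutations
        ``"random"`` (default) or ``"exact"`` — enumerate all placements of
        the set over the list (feasible for small problems only).

    Notes
    -----
    The permutation p is ``(1 + #{|ES_perm| >= |ES|}) / (n_perm + 1)`` in
    random mode, so it never falls below ``1/(n_perm+1)``; in exact mode it
    is the exact tail fraction over all placements. NES is ES divided by the
    mean |ES_perm| of same-signed permutations (NaN when no permutation has
    the observed sign).
    """
    ranked = rank_genes(pd.Series(ranked))
    genes = list(ranked.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    members = sorted({g for g in gene_set if g in gene_pos})
    if not members:
        raise ValueError("gene set does not intersect the ranked list")
    n = len(genes)
    s = len(members)
    degenerate = s == n
    metric_abs_w = np.abs(ranked.to_numpy(dtype=float)) ** weight
    positions = np.array(sorted(gene_pos[g] for g in members))
    es, ext_idx = _es_from_positions(metric_abs_w, positions)

    if permutations == "exact":
        from math import comb
        if comb(n, s) > _EXACT_LIMIT:
            raise ValueError("exact enumeration infeasible for this problem size")
        perm_es = np.array([
            _es_from_positions(metric_abs_w, np.array(p))[0]
            for p in combinations(range(n), s)
        ])
        n_used = len(perm_es)
        p = float(np.mean(np.abs(perm_es) >= abs(es) - 1e-12))
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        perm_es = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.choice(n, size=s, replace=False)
            perm_es[i] = _es_from_positions(metric_abs_w, np.sort(perm))[0]
        n_used = n_perm
        p = (1.0 + float(np.sum(np.abs(perm_es) >= abs(es) - 1e-12))) / (n_perm + 1.0)

    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    nes = es / float(np.mean(np.abs(same_sign))) if len(same_sign) else float("nan")

    if es >= 0:
        leading = [g for g in members if gene_pos[g] <= ext_idx]
    else:
        leading = [g for g in members if gene_pos[g] >= ext_idx]
    return EnrichmentResult(es=es, nes=float(nes), p=float(p),
                            leading_edge=leading, n_perm=n_used, size=s,
                            degenerate=degenerate)


def ora_hypergeom(hits: Iterable[str], gene_set: Iterable[str],
                  universe: Iterable[str]) -> tuple[float, int]:
    """Hypergeometric over-representation p-value (exact upper tail).

    Returns ``P(X >= k)`` for the overlap ``k`` between ``hits`` and
    ``gene_set`` inside ``universe``, and the overlap count.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    hits = set(hits) & universe
    gene_set = set(gene_set) & universe
    k = len(hits & gene_set)
    n_univ, n_set, n_hits = len(universe), len(gene_set), len(hits)
    p = float(stats.hypergeom.sf(k - 1, n_univ, n_set, n_hits))
    return p, k


def celltype_specificity_ranking(profiles: pd.DataFrame, cell_type: str) -> pd.Series:
    """Rank metric for one cell type: per-gene z-score of that type's
    expression across cell types (constant genes get z = 0)."""
    x = profiles.to_numpy(dtype=float)
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    col = profiles[cell_type].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (col - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.Series(z, index=profiles.index)


def celltype_target_enrichment(target_sets: Mapping[str, Iterable[str]],
                               profiles: pd.DataFrame, n_perm: int = 1000,
                               weight: float = 0.0,
                               seed: int | None = None) -> pd.DataFrame:
    """Enrichment of each target set in each cell type's specificity ranking.

    For every cell type, genes are ranked by their expression z-score of that
    type across types and each target set is scored with
    :func:`gsea_preranked`; BH adjustment is applied across the whole
    (set x cell type) grid. Sets that do not intersect the profile genes
    raise upstream; the grid has exactly |target_sets| x |cell types| rows.

    The default is the unweighted running sum (``weight=0``): its permutation
    null does not depend on the ranking metric, so NES values are comparable
    across cell types and "which type has the maximal NES" is meaningful.
    """
    seeds = np.random.SeedSequence(seed).generate_state(
        len(target_sets) * len(profiles.columns))
    rankings = {ct: celltype_specificity_ranking(profiles, ct)
                for ct in profiles.columns}
    rows = []
    i = 0
    for set_name, genes in target_sets.items():
        genes = list(genes)
        for ct in profiles.columns:
            res = gsea_preranked(rankings[ct], genes, n_perm=n_perm, weight=weight,
                                 seed=int(seeds[i] % (2 ** 31)))
            i += 1
            rows.append({"set": set_name, "cell_type": ct, "es": res.es,
                         "nes": res.nes, "p": res.p, "size": res.size,
                         "leading_edge": ",".join(res.leading_edge)})
    grid = pd.DataFrame(rows)
    grid["p_adj"] = bh_adjust(grid["p"].to_numpy())
    return grid
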