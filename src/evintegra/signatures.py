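"""Cell-type marker derivation, signature matrices and [0,1] scaling.

Markers are the top-n genes per cell type ranked by one-vs-rest log2 fold
change of mean counts-per-million (pseudocount 1) — a deterministic,
test-free ranking. Before deconvolution both the bulk matrix and the
signature matrix are bound to the [0,1] interval feature-wise:
``x_scaled = (x - x_min) / (x_max - x_min)``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CellMatrix, ScaledMatrix


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization per cell (column)."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("cells with zero total counts cannot be CPM-normalized")
    return counts * (1e6 / totals)


def derive_markers(cells: CellMatrix, n: int = 100,
                   min_detection: float = 0.1) -> dict[str, list[str]]:
    """Top-n one-vs-rest markers per cell type.

    Genes are ranked per type by log2((mean CPM in type + 1) /
    (mean CPM in rest + 1)), requiring detection (count > 0) in at least
    ``min_detection`` of the type's cells. Ties break by higher detection
    fraction, then lexicographic gene id.
    """
    types = cells.cell_types
    if len(types) < 2:
        raise ValueError("derive_markers needs >= 2 cell types")
    norm = cpm(cells.counts)
    markers: dict[str, list[str]] = {}
    for ct in types:
        mine = cells.cells_of(ct)
        rest = [c for c in cells.counts.columns if c not in set(mine)]
        mean_in = norm[mine].mean(axis=1)
        mean_out = norm[rest].mean(axis=1)
        lfc = np.log2(mean_in + 1.0) - np.log2(mean_out + 1.0)
        detection = (cells.counts[mine] > 0).mean(axis=1)
        tab = pd.DataFrame({"lfc": lfc, "detection": detection})
        tab = tab[tab["detection"] >= min_detection]
        tab = tab[tab["lfc"] > 0]
        if tab.empty:
            warnings.warn(f"no qualifying marker genes for cell type {ct!r}")
            markers[ct] = []
            continue
        tab = tab.reset_index(names="gene").sort_values(
            ["lfc", "detection", "gene"], ascending=[False, False, True],
            kind="stable")
        markers[ct] = list(tab["gene"].iloc[:n])
    return markers


def build_signature_matrix(cells: CellMatrix,
                           markers: dict[str, list[str]] | None = None,
                           celltype_order: list[str] | None = None) -> pd.DataFrame:
    """Genes x cell-types signature of mean normalized expression.

    Entries are log2(mean CPM + 1) of each gene in each cell type, restricted
    to the union of marker genes (all genes when ``markers`` is None).
    """
    types = celltype_order or cells.cell_types
    for ct in types:
        if len(cells.cells_of(ct)) < 2:
            warnings.warn(f"cell type {ct!r} has a single cell; its signature "
                          "equals that cell's profile")
    norm = cpm(cells.counts)
    if markers is not None:
        union = sorted(set(g for genes in markers.values() for g in genes))
        absent = [g for g in union if g not in norm.index]
        if absent:
            raise ValueError(f"marker genes absent from count matrix: {absent[:5]}")
        norm = norm.loc[union]
    cols = {ct: np.log2(norm[cells.cells_of(ct)].mean(axis=1) + 1.0) for ct in types}
    return pd.DataFrame(cols)[types]


def minmax_scale(matrix: pd.DataFrame, axis: str = "feature") -> ScaledMatrix:
    """Bound a matrix to [0,1] via (x - min)/(max - min).

    ``axis='feature'`` scales each row over its columns (the gene-wise
    transformation used before deconvolution). Rows with max == min map to
    all-zeros and are flagged degenerate. Invariant to positive affine
    transforms of the input rows.
    """
    if axis != "feature":
        raise ValueError("only feature-wise scaling is defined")
    if matrix.isna().to_numpy().any():
        raise ValueError("minmax_scale requires a complete matrix")
    x = matrix.to_numpy(dtype=float)
    x_min = x.min(axis=1)
    x_max = x.max(axis=1)
    span = x_max - x_min
    degenerate = span == 0
    safe = np.where(degenerate, 1.0, span)
    scaled = (x - x_min[:, None]) / safe[:, None]
    scaled[degenerate] = 0.0
    return ScaledMatrix(
        X_scaled=pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns),
        x_min=pd.Series(x_min, index=matrix.index),
        x_max=pd.Series(x_max, index=matrix.index),
        degenerate=pd.Series(degenerate, index=matrix.index),
    )


def match_features(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersect two matrices on exact uppercase feature-symbol match,
    preserving the order of ``a``. Unmatched features are dropped with a
    logged count."""
    a_up = {f.upper(): f for f in a.index}
    b_up = {f.upper(): f for f in b.index}
    shared = [u for u in a_up if u in b_up]
    dropped = (len(a.index) - len(shared), len(b.index) - len(shared))
    if any(dropped):
        warnings.warn(f"feature matching dropped {dropped[0]} bulk and "
                      f"{dropped[1]} signature features")
    return a.loc[[a_up[u] for u in shared]], b.loc[[b_up[u] for u in shared]]
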