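"""Ligand-receptor analysis of differentially expressed EV proteins.

DE proteins are joined against a curated ligand-receptor table supplied by
the user (never downloaded); the receptors of up- and downregulated ligands
form two receptor modules whose expression is scored across cell types with
the preranked enrichment machinery (or a mean z-score alternative).
Multi-subunit receptor complexes written as underscore-joined symbols
(e.g. ``ITGAV_ITGB1``) are expanded to individual subunit genes for module
membership.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import ReceptorModule
from .enrich import celltype_specificity_ranking, celltype_target_enrichment
from .modstats import bh_adjust


def validate_lr_table(lr: pd.DataFrame) -> pd.DataFrame:
    """Uppercase gene symbols and drop duplicate (ligand, receptor) pairs."""
    if not {"ligand", "receptor"} <= set(lr.columns):
        raise ValueError("LR table needs 'ligand' and 'receptor' columns")
    out = lr.copy()
    out["ligand"] = out["ligand"].str.upper()
    out["receptor"] = out["receptor"].str.upper()
    return out.drop_duplicates(subset=["ligand", "receptor"], ignore_index=True)


def extract_de_ligands(de: pd.DataFrame, lr: pd.DataFrame,
                       p_cut: float = 0.05,
                       lfc_cut: float = 0.5) -> tuple[list[str], list[str]]:
    """Ligands among the DE features (p < p_cut, |logFC| > lfc_cut, strict),
    split by fold-change sign. Returns (up, down) sorted ligand lists."""
    lr = validate_lr_table(lr)
    ligands = set(lr["ligand"])
    sig = de[(de["p"] < p_cut) & (de["logFC"].abs() > lfc_cut)]
    feats = {str(f).upper(): lfc for f, lfc in zip(sig.index, sig["logFC"])}
    up = sorted(f for f, lfc in feats.items() if f in ligands and lfc > 0)
    down = sorted(f for f, lfc in feats.items() if f in ligands and lfc < 0)
    return up, down


def map_receptors(ligands: Iterable[str], lr: pd.DataFrame
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """All (ligand, receptor) rows whose ligand is in the input, plus summary
    counts of distinct ligands, distinct receptors and interactions."""
    lr = validate_lr_table(lr)
    wanted = {l.upper() for l in ligands}
    rows = lr[lr["ligand"].isin(wanted)].reset_index(drop=True)
    summary = {
        "n_ligands": int(rows["ligand"].nunique()),
        "n_distinct_receptors": int(rows["receptor"].nunique()),
        "n_interactions": int(len(rows)),
    }
    return rows, summary


def _expand_complexes(receptors: Iterable[str]) -> list[str]:
    out: list[str] = []
    for r in receptors:
        out.extend(r.split("_"))
    return sorted(set(out))


def build_receptor_modules(up: Iterable[str], down: Iterable[str],
                           lr: pd.DataFrame) -> dict[str, ReceptorModule]:
    """Union the receptors of each direction's ligands into two modules,
    expanding receptor complexes to subunit genes."""
    modules = {}
    for direction, ligs in (("up", list(up)), ("down", list(down))):
        rows, _ = map_receptors(ligs, lr)
        modules[direction] = ReceptorModule(
            direction=direction,
            receptors=_expand_complexes(rows["receptor"]),
            source_ligands=sorted({l.upper() for l in ligs}),
        )
    return modules


def score_modules(modules: Mapping[str, ReceptorModule], profiles: pd.DataFrame,
                  n_perm: int = 1000, seed: int | None = None,
                  method: str = "gsea") -> pd.DataFrame:
    """Score each receptor module's expression across cell types.

    ``method="gsea"`` (default) delegates to the preranked enrichment grid on
    the cell-type specificity rankings. ``method="zscore"`` reports the mean
    specificity z-score of module genes per cell type with a gene-label
    permutation p-value. Modules with no receptor present in the profiles are
    skipped with a warning.
    """
    import warnings

    profile_genes = {g.upper() for g in profiles.index}
    usable = {}
    for name, mod in modules.items():
        present = [r for r in mod.receptors if r.upper() in profile_genes]
        if not present:
            warnings.warn(f"module {name!r} has no receptors in the profiles; skipped")
            continue
        usable[name] = present
    if not usable:
        return pd.DataFrame(columns=["set", "cell_type", "es", "nes", "p",
                                     "size", "leading_edge", "p_adj"])
    if method == "gsea":
        return celltype_target_enrichment(usable, profiles, n_perm=n_perm, seed=seed)
    if method != "zscore":
        raise ValueError(f"unknown scoring method {method!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for name, genes in usable.items():
        for ct in profiles.columns:
            z = celltype_specificity_ranking(profiles, ct)
            members = [g for g in profiles.index if g.upper() in {x.upper() for x in genes}]
            obs = float(z.loc[members].mean())
            null = np.array([
                z.iloc[rng.choice(len(z), size=len(members), replace=False)].mean()
                for _ in range(n_perm)])
            p = (1.0 + float(np.sum(np.abs(null) >= abs(obs)))) / (n_perm + 1.0)
            rows.append({"set": name, "cell_type": ct, "es": obs,
                         "nes": obs / (null.std(ddof=1) or np.nan),
                         "p": p, "size": len(members), "leading_edge": ""})
    grid = pd.DataFrame(rows)
    grid["p_adj"] = bh_adjust(grid["p"].to_numpy())
    return grid
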