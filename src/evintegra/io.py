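"""Plain-text readers and writers for every fixture format.

Dialects: intensity matrices are TSV with the feature id in the first column
and ``NA`` for missing entries; group assignments are a two-column TSV
(sample_id, group); single-cell counts are MatrixMarket plus gene/cell/label
TSVs; Ct and AmpScore matrices are CSV; gene sets are GMT; ligand-receptor
tables are TSV; simulation ground truth is a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CellMatrix, CtMatrix, CtThresholds, IntensityMatrix, SimTruth


def write_intensity_tsv(m: IntensityMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_intensity_tsv(path: str | Path, groups: pd.Series,
                       stages: tuple[str, ...] = ("log2",)) -> IntensityMatrix:
    df = _read_rectangular(path, sep="\t")
    return IntensityMatrix(values=df, groups=groups, stages=stages)


def _read_rectangular(path: str | Path, sep: str) -> pd.DataFrame:
    """Read a matrix file, failing fast with file and line on ragged rows."""
    path = Path(path)
    with open(path) as fh:
        widths = [len(line.rstrip("\n").split(sep)) for line in fh if line.strip()]
    if len(set(widths)) > 1:
        bad = next(i for i, w in enumerate(widths) if w != widths[0])
        raise ValueError(f"{path}:{bad + 1}: ragged row "
                         f"({widths[bad]} fields, expected {widths[0]})")
    return pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"])


def write_groups_tsv(groups: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False)


def read_groups_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["group"].values, index=df["sample_id"].values)


def write_cells(cells: CellMatrix, outdir: str | Path, prefix: str = "cells") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / f"{prefix}.mtx", sparse.csr_matrix(cells.counts.to_numpy()))
    pd.Series(cells.counts.index).to_csv(outdir / f"{prefix}_genes.tsv",
                                         sep="\t", index=False, header=["gene"])
    pd.DataFrame({"cell": cells.counts.columns,
                  "label": cells.labels.values}).to_csv(
        outdir / f"{prefix}_labels.tsv", sep="\t", index=False)


def read_cells(outdir: str | Path, prefix: str = "cells") -> CellMatrix:
    outdir = Path(outdir)
    counts = spio.mmread(outdir / f"{prefix}.mtx").toarray().astype(int)
    genes = pd.read_csv(outdir / f"{prefix}_genes.tsv", sep="\t")["gene"]
    labels_df = pd.read_csv(outdir / f"{prefix}_labels.tsv", sep="\t")
    counts_df = pd.DataFrame(counts, index=genes, columns=labels_df["cell"])
    labels = pd.Series(labels_df["label"].values, index=labels_df["cell"].values)
    return CellMatrix(counts=counts_df, labels=labels)


def write_ct(m: CtMatrix, ct_path: str | Path, amp_path: str | Path) -> None:
    ct = m.ct.copy()
    ct.index.name = "mirna"
    ct.to_csv(ct_path, na_rep="NA")
    amp = m.amp_score.copy()
    amp.index.name = "mirna"
    amp.to_csv(amp_path, na_rep="NA")


def read_ct(ct_path: str | Path, amp_path: str | Path, groups: pd.Series,
            thresholds: CtThresholds | None = None) -> CtMatrix:
    ct = _read_rectangular(ct_path, sep=",")
    amp = _read_rectangular(amp_path, sep=",")
    return CtMatrix(ct=ct, amp_score=amp.loc[ct.index, ct.columns],
                    groups=groups, thresholds=thresholds or CtThresholds())


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path,
              description: str = "evintegra") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_lr_tsv(lr: pd.DataFrame, path: str | Path) -> None:
    lr.to_csv(path, sep="\t", index=False)


def read_lr_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_json(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)


def read_truth_json(path: str | Path) -> SimTruth:
    with open(path) as fh:
        return SimTruth.from_dict(json.load(fh))


def write_signature_tsv(sig: pd.DataFrame, path: str | Path) -> None:
    sig = sig.copy()
    sig.index.name = "gene"
    sig.to_csv(path, sep="\t")


def read_signature_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_de_tsv(de: pd.DataFrame, path: str | Path) -> None:
    out = de.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_de_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def sha256_file(path: str | Path) -> str:
    import hashlib
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
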