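"""End-to-end orchestration from a single config, with a JSON manifest.

A single top-level seed is expanded deterministically (via
``numpy.random.SeedSequence``) into per-stage seeds, so one number reproduces
every stochastic stage. All outputs are plain TSV/CSV/JSON/GMT. The manifest
records the package version, every per-stage seed and threshold, and a
SHA-256 hash of each output file; re-running the same config reproduces the
deterministic stages bit-identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as evio
from .containers import IntensityMatrix
from .ctarray import ct_differential_expression, filter_unreliable, normalize_ct
from .decon import DeconConfig, deconvolve_cohort
from .enrich import celltype_target_enrichment
from .lrnet import build_receptor_modules, extract_de_ligands, map_receptors, score_modules
from .modstats import de_two_group, top_table
from .prot_prep import ImputationParams, filter_missing, impute_minprob, vst_normalize
from .signatures import build_signature_matrix, derive_markers
from . import syndata

STAGE_ORDER = ("simulate", "prep", "de", "signatures", "decon", "enrich", "lr", "ct")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``stages`` maps stage name -> dict of options; a stage runs when its dict
    contains ``enabled: true``. Thresholds live inside the stage dicts.
    """

    seed: int = 0
    outdir: str = "evintegra_out"
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw.get("stages", {})) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages in config: {sorted(unknown)}")
        return cls(seed=int(raw.get("seed", 0)), outdir=raw.get("outdir", "evintegra_out"),
                   stages=raw.get("stages", {}))

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, {}).get("enabled", False))

    def opts(self, stage: str) -> dict:
        return {k: v for k, v in self.stages.get(stage, {}).items() if k != "enabled"}


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from one top-level seed."""
    states = np.random.SeedSequence(seed).generate_state(len(STAGE_ORDER))
    return {s: int(v % (2 ** 31)) for s, v in zip(STAGE_ORDER, states)}


def demo_config(outdir: str | Path, seed: int = 0) -> RunConfig:
    """Packaged synthetic demo: simulate a 5-type cohort with a planted
    Müller-like shift, run preprocessing, DE, signature derivation,
    deconvolution and ligand-receptor scoring."""
    return RunConfig(seed=seed, outdir=str(outdir), stages={
        "simulate": {"enabled": True, "n_genes": 400, "n_celltypes": 5,
                     "n_markers_per_type": 60, "marker_log2fc": 3.0,
                     "n_samples_per_group": 5, "noise_sd": 0.05,
                     "dropout_rate": 0.05,
                     "control_props": [0.45, 0.25, 0.15, 0.10, 0.05],
                     "case_props": [0.25, 0.20, 0.15, 0.10, 0.30]},
        "prep": {"enabled": True, "max_missing_per_group": 2},
        "de": {"enabled": True, "p_cut": 0.05, "lfc_cut": 0.0},
        "signatures": {"enabled": True, "n_markers": 60},
        "decon": {"enabled": True},
        "lr": {"enabled": True, "n_ligands": 6,
               "receptors_per_ligand": [7, 7, 7, 7, 6, 6],
               "shared_receptor_fraction": 0.2, "n_perm": 200},
    })


def _validate_inputs(cfg: RunConfig) -> None:
    """Fail-fast input resolution before any stage executes."""
    for stage in STAGE_ORDER:
        if not cfg.enabled(stage):
            continue
        opts = cfg.opts(stage)
        for key in ("matrix", "groups", "cells_dir", "gmt", "lrdb", "ct_csv",
                    "amp_csv", "signature"):
            path = opts.get(key)
            if path and not Path(path).exists():
                raise FileNotFoundError(f"stage {stage!r}: input {key}={path!r} not found")
    needs_sim = {"prep": "matrix", "signatures": "cells_dir"}
    for stage, key in needs_sim.items():
        if cfg.enabled(stage) and not cfg.opts(stage).get(key) and not cfg.enabled("simulate"):
            raise ValueError(f"stage {stage!r} needs {key!r} or an enabled simulate stage")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and write a manifest.

    Returns the manifest dict (also written to ``<outdir>/manifest.json``).
    """
    _validate_inputs(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    from . import __version__
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "stage_seeds": seeds, "stages": {}, "outputs": {}}

    ctx: dict = {}

    def record(stage: str, name: str, path: Path) -> None:
        manifest["outputs"][f"{stage}/{name}"] = {
            "path": str(path), "sha256": evio.sha256_file(path)}

    if cfg.enabled("simulate"):
        o = cfg.opts("simulate")
        sig, markers = syndata.gen_cell_signatures(
            o.get("n_genes", 400), o.get("n_celltypes", 5),
            o.get("n_markers_per_type", 60), o.get("marker_log2fc", 3.0),
            seed=seeds["simulate"])
        truth = syndata.make_truth(
            sig.columns, o["control_props"], o["case_props"],
            o.get("n_samples_per_group", 5), dropout_rate=o.get("dropout_rate", 0.0),
            noise_sd=o.get("noise_sd", 0.0), seed=seeds["simulate"])
        matrix = syndata.gen_ev_proteome(sig, truth)
        cells = syndata.gen_single_cell_counts(
            sig, cells_per_type=o.get("cells_per_type", 40),
            library_size=o.get("library_size", 20000.0),
            dispersion=o.get("dispersion", 0.3), seed=seeds["simulate"] + 1)
        evio.write_intensity_tsv(matrix, outdir / "simulated_proteome.tsv")
        evio.write_groups_tsv(matrix.groups, outdir / "samples.tsv")
        evio.write_truth_json(truth, outdir / "truth.json")
        evio.write_cells(cells, outdir)
        evio.write_gmt(markers, outdir / "planted_markers.gmt")
        for name in ("simulated_proteome.tsv", "samples.tsv", "truth.json",
                     "planted_markers.gmt"):
            record("simulate", name, outdir / name)
        ctx.update(matrix=matrix, truth=truth, cells=cells,
                   planted_signature=sig, planted_markers=markers)
        manifest["stages"]["simulate"] = {"seed": seeds["simulate"], **o}

    if cfg.enabled("prep"):
        o = cfg.opts("prep")
        if "matrix" in o:
            groups = evio.read_groups_tsv(o["groups"])
            matrix = evio.read_intensity_tsv(o["matrix"], groups)
        else:
            matrix = ctx["matrix"]
        filtered = filter_missing(matrix, o.get("max_missing_per_group", 2))
        params = ImputationParams.estimate(filtered, seed=seeds["prep"])
        imputed = impute_minprob(filtered, params)
        prepped = vst_normalize(imputed)
        evio.write_intensity_tsv(prepped, outdir / "prepped.tsv")
        record("prep", "prepped.tsv", outdir / "prepped.tsv")
        # variance-stabilized values feed model fitting; deconvolution uses the
        # imputed matrix in original log2 intensity units
        ctx["prepped"] = prepped
        ctx["imputed"] = imputed
        manifest["stages"]["prep"] = {
            "seed": seeds["prep"], "mu": params.mu, "sigma": params.sigma, **o}

    if cfg.enabled("de"):
        o = cfg.opts("de")
        de = de_two_group(ctx["prepped"])
        top = top_table(de, o.get("p_cut", 0.05), o.get("lfc_cut", 0.0))
        evio.write_de_tsv(de, outdir / "de.tsv")
        record("de", "de.tsv", outdir / "de.tsv")
        ctx["de"] = de
        manifest["stages"]["de"] = {
            **o, "n_significant": int(len(top)),
            "n_up": top.attrs["n_up"], "n_down": top.attrs["n_down"],
            "d0": de.attrs["d0"], "s0_sq": de.attrs["s0_sq"]}

    if cfg.enabled("signatures"):
        o = cfg.opts("signatures")
        cells = evio.read_cells(o["cells_dir"]) if "cells_dir" in o else ctx["cells"]
        markers = derive_markers(cells, n=o.get("n_markers", 100))
        sig = build_signature_matrix(cells, markers)
        evio.write_gmt(markers, outdir / "markers.gmt")
        evio.write_signature_tsv(sig, outdir / "signature.tsv")
        record("signatures", "markers.gmt", outdir / "markers.gmt")
        record("signatures", "signature.tsv", outdir / "signature.tsv")
        ctx.update(markers=markers, signature=sig)
        manifest["stages"]["signatures"] = {**o}

    if cfg.enabled("decon"):
        o = cfg.opts("decon")
        # the reference signature plays the role of an external single-cell
        # atlas; when the demo simulator ran, its reference profiles are used
        if "signature" in o:
            sig = evio.read_signature_tsv(o["signature"])
        else:
            sig = ctx.get("planted_signature", ctx.get("signature"))
        # all shared features are used: genes that are constant across cell
        # types anchor the regression intercept (see decon module notes)
        props, summary = deconvolve_cohort(ctx.get("imputed", ctx["prepped"]), sig,
                                           DeconConfig())
        props.to_csv(outdir / "proportions.tsv", sep="\t")
        summary.to_csv(outdir / "decon_summary.tsv", sep="\t")
        record("decon", "proportions.tsv", outdir / "proportions.tsv")
        record("decon", "decon_summary.tsv", outdir / "decon_summary.tsv")
        ctx.update(proportions=props, decon_summary=summary)
        manifest["stages"]["decon"] = {**o}

    if cfg.enabled("enrich"):
        o = cfg.opts("enrich")
        sets = evio.read_gmt(o["gmt"]) if "gmt" in o else ctx["markers"]
        grid = celltype_target_enrichment(sets, ctx["signature"],
                                          n_perm=o.get("n_perm", 1000),
                                          seed=seeds["enrich"])
        grid.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        record("enrich", "enrichment.tsv", outdir / "enrichment.tsv")
        manifest["stages"]["enrich"] = {"seed": seeds["enrich"], **o}

    if cfg.enabled("lr"):
        o = cfg.opts("lr")
        if "lrdb" in o:
            lrdb = evio.read_lr_tsv(o["lrdb"])
        else:
            lrdb = syndata.gen_lr_database(
                o.get("n_ligands", 6), o.get("receptors_per_ligand", 6),
                o.get("shared_receptor_fraction", 0.2), seed=seeds["lr"])
            # tie the toy database to simulated features so the join is non-empty
            de_feats = list(ctx["de"].sort_values("p").index)
            lig_map = {lig: de_feats[i] for i, lig in
                       enumerate(pd.unique(lrdb["ligand"]))}
            rec_feats = [f for f in ctx["signature"].index if f not in lig_map.values()]
            rec_map = {r: rec_feats[i % len(rec_feats)] for i, r in
                       enumerate(pd.unique(lrdb["receptor"]))}
            lrdb = pd.DataFrame({"ligand": lrdb["ligand"].map(lig_map),
                                 "receptor": lrdb["receptor"].map(rec_map)})
        up, down = extract_de_ligands(ctx["de"], lrdb, o.get("p_cut", 0.05),
                                      o.get("lfc_cut", 0.0))
        rows, summary = map_receptors(up + down, lrdb)
        modules = build_receptor_modules(up, down, lrdb)
        grid = score_modules(modules, ctx["signature"],
                             n_perm=o.get("n_perm", 1000), seed=seeds["lr"])
        evio.write_lr_tsv(rows, outdir / "interactions.tsv")
        grid.to_csv(outdir / "module_scores.tsv", sep="\t", index=False)
        record("lr", "interactions.tsv", outdir / "interactions.tsv")
        record("lr", "module_scores.tsv", outdir / "module_scores.tsv")
        manifest["stages"]["lr"] = {"seed": seeds["lr"], **{k: v for k, v in o.items()},
                                    **summary}

    if cfg.enabled("ct"):
        o = cfg.opts("ct")
        groups = evio.read_groups_tsv(o["groups"])
        ct = evio.read_ct(o["ct_csv"], o["amp_csv"], groups)
        filtered = filter_unreliable(ct)
        normalized, diag = normalize_ct(filtered, method=o.get("method", "geomean"))
        de = ct_differential_expression(normalized)
        evio.write_ct(normalized, outdir / "ct_normalized.csv", outdir / "ct_amp.csv")
        evio.write_de_tsv(de, outdir / "ct_de.tsv")
        record("ct", "ct_normalized.csv", outdir / "ct_normalized.csv")
        record("ct", "ct_de.tsv", outdir / "ct_de.tsv")
        manifest["stages"]["ct"] = {**o, "rle_after_max_abs":
                                    float(diag["rle_after"].abs().max())}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
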