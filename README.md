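# evintegra

Multiomic integration toolkit for linking extracellular-vesicle (EV) cargo
to the cell types that produced — or receive — it, built around the retina
as a model CNS tissue.

In degenerating neural tissue, EV shuttle proteins and miRNA between neurons
and glia. Working out *which* cell types drive a bulk EV proteome, *where*
a miRNA's target module is active, *which* receptors its surface ligands can
engage, and *whether* a glial miRNA was produced locally or imported
requires stitching together proteomics, single-cell transcriptomics and
qPCR panels. `evintegra` implements that analysis arc as a tested Python
library for computational biologists:

- **`syndata`** — simulators for every input (signatures, EV mixtures with
  MNAR dropout, negative-binomial single-cell counts, Ct panels, toy
  ligand–receptor tables) with known ground truth.
- **`prot_prep`** — proteomics preprocessing: group-wise missingness filter,
  left-censored (MinProb-style) Gaussian imputation with
  μ = min(observed), σ = median per-feature SD, variance stabilization.
- **`modstats`** — two-group DE with empirical-Bayes moderated t:
  s̃² = (d₀s₀² + d·s²)/(d₀+d), t = logFC/(s̃·√(1/n₁+1/n₂)) on d₀+d df, with
  (d₀, s₀²) estimated by trigamma moment matching; BH adjustment.
- **`signatures`** — top-n one-vs-rest markers, signature matrices, and the
  gene-wise [0,1] scaling x_scaled = (x − x_min)/(x_max − x_min).
- **`decon`** — CIBERSORT-style cell-of-origin deconvolution: linear ν-SVR
  over ν ∈ {0.25, 0.5, 0.75}, best reconstruction RMSE, clamp-and-normalize;
  Welch tests for group shifts in the estimated fractions.
- **`enrich`** — preranked running-sum enrichment (ES = signed max deviation
  of a bridge with hit increments ∝ |metric|^w and position penalty 1/N),
  gene-label permutation p-values with leading-edge extraction, exact
  hypergeometric over-representation, and per-cell-type enrichment grids.
- **`lrnet`** — joins DE proteins to a curated ligand–receptor table, builds
  up/down receptor modules and scores them across cell types.
- **`ctarray`** — OpenArray/qPCR Ct reliability filtering, three
  normalizations, ΔΔCt percent change (2^(−ΔΔCt)·100%), moderated DE on Ct,
  and the endogenous/exogenous miRNA origin classifier driven by a
  DICER-knockout contrast and pri/pre-miRNA evidence.
- **`pipeline`** — one-config orchestration with per-stage seeds and a
  hash-carrying manifest; a thin `evintegra` CLI wraps the library.

## Worked example

`examples/03_deconvolution.py` simulates a degeneration-style cohort in
which the fifth cell type's contribution to EV cargo rises from 3% to 22%,
preprocesses it and deconvolves each sample:

```
per-cell-type group means (percent of EV cargo) and Welch test:
           mean_control_pct  mean_case_pct      p  p_adj
cell_type
CT1                  44.686         30.189  0.000  0.000
CT2                  26.765         23.063  0.000  0.000
CT3                  15.468         14.959  0.068  0.085
CT4                  10.206          9.840  0.299  0.299
CT5                   2.875         21.949  0.000  0.000

planted shift for CT5: 3.0% -> 22.0%; estimated 2.9% -> 21.9% (p_adj=2.08e-12)
```

Each row is a cell type's mean share of the EV proteome per group; the
Welch p-values test whether that share shifted between control and
degeneration. The deconvolution recovers the planted composition to within
a fraction of a percentage point and flags exactly the shifted glial type —
the computational signature of a neuronal-to-glial shift in EV origin.

The other scripts in `examples/` walk through preprocessing, moderated DE,
enrichment grids, ligand–receptor module scoring, Ct/origin analysis, and
the end-to-end pipeline (`evintegra run --config run.yaml` from the shell).

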