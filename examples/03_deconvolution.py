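"""Recover cell-type contributions to EV cargo by SVR deconvolution.

Simulates a cohort in which the fifth cell type's contribution rises from 3%
(control) to 22% (degeneration) — the kind of glial shift deconvolution is
meant to expose — and compares estimated group means against the truth.
"""

from evintegra import syndata
from evintegra.decon import DeconConfig, deconvolve_cohort
from evintegra.prot_prep import ImputationParams, filter_missing, impute_minprob

sig, _ = syndata.gen_cell_signatures(500, 5, 60, 3.0, seed=1)
truth = syndata.make_truth(
    sig.columns, control_props=(0.45, 0.27, 0.15, 0.10, 0.03),
    case_props=(0.30, 0.23, 0.15, 0.10, 0.22), n_samples_per_group=5,
    dropout_rate=0.1, noise_sd=0.1, seed=2)
m = syndata.gen_ev_proteome(sig, truth)

filtered = filter_missing(m)
imputed = impute_minprob(filtered, ImputationParams.estimate(filtered, seed=3))
proportions, summary = deconvolve_cohort(imputed, sig, DeconConfig())

print("per-cell-type group means (percent of EV cargo) and Welch test:")
print(summary.round(3).to_string())
shifted = sig.columns[-1]
print(f"\nplanted shift for {shifted}: 3.0% -> 22.0%; "
      f"estimated {summary.loc[shifted, 'mean_control_pct']:.1f}% -> "
      f"{summary.loc[shifted, 'mean_case_pct']:.1f}% "
      f"(p_adj={summary.loc[shifted, 'p_adj']:.2e})")
# a significant p_adj for the shifted type means the comparative shift
# analysis attributes the changed EV cargo to that cell type
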