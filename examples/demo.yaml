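# Synthetic end-to-end demo: simulate a four-genotype cohort plus DE tables
# for three tissues, then run the synergy time-course, GSEA against the
# planted gene sets, the transcript-length imbalance and the cross-tissue
# core signature.  Run with:
#   kosynergy run --config examples/demo.yaml --outdir results/demo
outdir: results/demo
seed: 5
horizons: [100, 200, 300, 400]
n_boot: 500
n_perm: 499
incidence_method: crude
gsea_weight: 1.0
gsea_min_size: 10
gsea_max_size: 500
simulate:
  n_per_genotype: 40
  followup_days: 400
  n_genes: 2000
  frac_up: 0.05
  frac_down: 0.05
  effect_log2fc: 2.0
  length_shift: 0.4
  noise_sd: 0.3
  dispersion: 0.1
  n_samples_per_group: 4
  seed: 5
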