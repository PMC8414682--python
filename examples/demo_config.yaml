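# End-to-end demo: simulate a 96-sample whole-blood cohort, normalize to
# RPKM, run the DEG cascade, score the 7-transcript composite panel, and
# compute enrichment tables. `bloodtrac run examples/demo_config.yaml`
seed: 1
outdir: bloodtrac_demo
stages: [simulate, normalize, deg, score, enrich, report]
simulate:
  n_transcripts: 2000
  n_low: 48
  n_mid: 48
  trac_fold: 1.7
analysis:
  min_rpkm: 0.01
  min_fraction: 0.70
  deg_p: 0.001
  deg_fc: 1.5
  percentile_cut: 20
  parent_fc: 1.4
score:
  panel: TRAC_PANEL7
enrich:
  universe: 20000
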