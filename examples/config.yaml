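# Desk-scale end-to-end run:
#   adforecast simulate --config examples/config.yaml --out-dir out
#   adforecast validate out/panel.csv --config examples/config.yaml --out-dir out
#   adforecast report out/scores.csv --out out/report.txt
seed: 1
generator:
  n_patients: 30
  n_days: 100
min_days: 10
variants: [none, "single:temp"]
refit_stride: 7
min_train_days: 21
quad_order: 9
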