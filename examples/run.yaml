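# A desk-scale run with a planted dose effect: drug 0 raises the monthly
# odds of urinary retention; drug 1 raises electrolyte imbalances.
output_dir: runs/demo
seeds: {data: 1, match: 2, split: 3, model: 4, attribution: 5}
synthetic:
  n_patients: 2000
  n_drugs: 8
  months_simulated: 24
  hazard_model:
    dose_coefs:
      "0": {"0": 0.03}
      "2": {"1": 0.01}
    recency_coefs:
      "5": {"0": 0.02}
model: {hidden_size: 8}
train: {max_epochs: 120, patience: 120}
attribution: {n_samples: 100, background_size: 80, max_patients: 80}
clogit: {top_k: 10}
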