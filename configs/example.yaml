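# Desk-scale pipeline run on the built-in synthetic scaffold.
seed: 1
output_dir: runs/example
scaffold: builtin:mini_barrel

n_sequences: 2000
top_candidates: 30
top_models: 12

insertion_spec:
  fragment_span: [80, 110]   # the 31-residue beta-alpha-beta fragment
  loop_span: [91, 94]        # the replaced beta-alpha loop (Asp91..Asp94)
  insert_len_min: 8
  insert_len_max: 19

motif_filter:
  helix_min: 4
  helix_max: 8
  flank_min: 2
  flank_max: 3

predictor:
  method: propensity
  window: 7

folding:
  mode: simulate        # "external" + models_dir to ingest real folding output
  n_decoys: 50
  noise_sigma_min: 0.05
  noise_sigma_max: 1.0

graft:
  anchor_rmsd_threshold: 2.0
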