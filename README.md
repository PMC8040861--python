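# helixgraft

Fragment-based design tooling for inserting a *de novo* helix into a
βα-loop of a TIM-barrel scaffold — the computational side of a
"screen, fold, rank, graft, evaluate" protocol for extending a minimal
(βα)₈-barrel with an extra secondary-structure element on its catalytic
face.

## What it does

Designing a helical extension without a predefined backbone is tackled as
a sub-problem: a 31-residue βαβ super-secondary fragment around the target
site stands in for the whole barrel. The package implements every desk
stage of that protocol:

* **screen** — generate random insert sequences (8–19 residues), splice
  each into the fragment sequence in place of the 4-residue βα-loop
  (yielding 35–46-residue candidates), predict per-residue secondary
  structure, and accept only candidates whose predicted labels contain a
  helix run of length 4–8 immediately flanked by coil runs of length 2–3
  at the insertion site; rank survivors by prediction score and keep the
  top 30;
* **fold hand-off** — emit candidate FASTAs for an external folding
  engine and ingest its model ensembles (a built-in Gaussian-noise decoy
  generator stands in for the engine at desk scale);
* **rank** — sort fragment models by the CA-RMSD of the fragment core
  (insert excluded) after Kabsch superposition onto the parent barrel and
  keep the top 12;
* **graft** — rigidly transplant the winning model's helix into the full
  scaffold over anchor residues, renumber, and report junction gaps and
  clashes (never auto-fixed: that is the hand-off contract to a
  downstream relaxation step);
* **re-filter** — re-predict the grafted full-length sequence and apply
  the motif filter again;
* **evaluate** — compare a design model against an experimental
  structure: region RMSDs, per-residue CA deviations, α vs 3₁₀ helix
  typing from backbone H-bond patterns (i→i+4 vs i→i+3), B-factor
  statistics, and polar contacts.

The geometric core is standard: Kabsch (SVD) superposition with proper
rotations, `rmsd = sqrt(Σ‖R xᵢ + t − yᵢ‖²/N)` minimized over rigid
transforms; backbone torsions by the four-atom dihedral; ideal backbones
built in internal coordinates (NeRF) from canonical torsions
(α: φ=−57°, ψ=−47°; 3₁₀: φ=−49°, ψ=−26°); helix typing by DSSP-style
electrostatic H-bond energy with a geometrically placed amide H.

Secondary structure comes either from a built-in, transparent
propensity-window predictor (Chou–Fasman-type scales, center-weighted
window, normalized to per-residue H/E/C probability triples) or from
standard PSIPRED output files (`.ss2` vertical and `.horiz` horizontal
formats), interchangeable behind one interface.

No external data is needed: a fixtures module builds an idealized
mini-barrel scaffold, βαβ fragments, candidate models and decoy ensembles
programmatically.

## Worked example

```sh
helixgraft run -c configs/example.yaml
```

screens 2,000 random inserts against the built-in scaffold, simulates a
50-model decoy ensemble for the best candidate, ranks, grafts and
evaluates, printing:

```
setup: completed (2 outputs)
screen: completed (3 outputs)
fold: completed (51 outputs)
rank: completed (1 outputs)
graft: completed (2 outputs)
refilter: completed (1 outputs)
evaluate: completed (2 outputs)
```

`runs/example/screen/top_candidates.tsv` then holds the accepted
candidates, best first — e.g. insert `PAQMEMIH` (8 residues, score
0.402), whose assembled 35-residue sequence is predicted as
`...CCHHHHHHHCC...` at the insertion site: a 7-residue helix flanked by
2-residue coils, which satisfies the motif filter. The graft report
(`runs/example/graft/report.json`) shows what a relaxation step would
need to fix:

```
anchor_rmsd: 0.069        # Å, fragment anchors onto the barrel
junction_gaps: [[98, 4.09]]  # open C-side junction, Å
clashes: 1
```

and the evaluation report classifies the inserted helix residue by
residue (`alpha` at every interior position of this candidate) while the
scaffold outside the replaced loop is untouched (global mapped-residue
RMSD 0.0 Å). Inspect any model with `helixgraft info
runs/example/graft/grafted.pdb` (124 residues: the 120-residue scaffold
grew by 8 − 4 = 4).

Individual stages are also exposed: `helixgraft screen`, `helixgraft
rank-models`, `helixgraft graft`, `helixgraft compare`, `helixgraft
predict`, `helixgraft rmsd`, `helixgraft info`, `helixgraft fixtures`,
`helixgraft validate-config`.

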