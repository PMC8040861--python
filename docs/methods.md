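# Methods

This note records the models, conventions and design choices behind
helixgraft, in the order the pipeline uses them.

## Coordinate model and conventions

Structures are chain → residue → atom hierarchies with author (PDB)
residue numbering, 1-based; every residue span in configs and signatures
is inclusive on both ends, so the replaced loop `(91, 94)` names four
residues. Index spans into sequences are 0-based inclusive. Angles are
degrees everywhere (crystallographic convention), distances Å, B-factors
Å².

Parsing and writing of fixed-column PDB goes through gemmi. Alternate
locations are resolved at read time to the highest-occupancy conformer
(ties → first in file order), so all geometry downstream sees a single
conformer. Multi-MODEL files are read as their first model with a
warning; the intended inputs are X-ray single-conformer models. Waters
and other HETATM records are kept but flagged, and the protein residue
count excludes them. Coordinates survive a write/read round trip to
0.001 Å and B-factors to 0.01 Å² (format field widths). Residue numbers
above 9999 do not fit the format and are rejected rather than silently
wrapped.

## Superposition and RMSD

Rigid superposition is the Kabsch algorithm via SVD of the covariance of
centered point sets, with the smallest singular direction sign-corrected
so the rotation is always proper (det = +1): chirality is never
mirrored, even when a reflection would fit better. Collinear point sets
are flagged with a warning but still return a (non-unique) solution.
The test suite checks the solver against an independent quaternion
key-matrix eigenvalue solver on a thousand random instances (agreement
to 1e-6 Å) plus rigid-motion invariance and symmetry properties.

Model ranking uses CA atoms only: fast, and robust to sidechain
rebuilds in folding-engine output. Evaluation reports can select any
atom set (`name N,CA,C,O`) through the selection mini-language
(`chain A resi 60-90 name CA`). Which atom set the original protocol
used for its fragment-onto-barrel RMSD is not recorded; both choices are
supported and the default is documented, with no claim of matching any
engine's internal value.

## Backbone construction

Ideal backbones are built in internal coordinates (natural-extension
reference frame placement) from per-residue (φ, ψ, ω) with fixed bond
geometry: N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å; N-CA-C 111.2°,
CA-C-N 116.2°, C-N-CA 121.7°, CA-C-O 120.8°. These values are tabulated
once (`geometry.IDEAL_BACKBONE`) and used by every builder. Canonical
helix torsions are α (−57, −47) and 3₁₀ (−49, −26); building then
measuring recovers the inputs to well under 0.5° at interior residues,
and an ideal α-helix shows the expected 3.80 Å CA–CA spacing and
~1.5 Å rise per residue.

## Secondary-structure prediction

The built-in predictor is a propensity-window method, deliberately
transparent rather than a neural-network re-implementation: per-residue
helix/strand/coil weights (a classic Chou–Fasman scale shipped as a
versioned TSV) are averaged over a centred window (default 7, truncated
at termini) and normalized to a probability triple; the label is the
argmax. The window average is center-weighted (triangular) by default:
a flat mean over 7 residues smears state transitions so heavily that
coil-flanked helix motifs almost never survive in random-sequence
libraries, which would starve the screen; the triangular weighting keeps
transitions sharp while remaining a pure propensity method
(`weighting="flat"` restores the plain mean). Predictors are
interchangeable behind a `sequence -> SSPrediction` callable, and
readers for PSIPRED's `.ss2` (vertical) and `.horiz` (horizontal)
formats produce the same container: `.ss2` score triples are
renormalized to sum to one; `.horiz` confidence digits d map to
probability (d + 0.5)/10 for the predicted state with the remainder
split evenly — monotone and bounded.

The candidate score is the mean confidence of the predicted state over
the insert region (configurable to min). "Flexible residues" in the
motif are read as coil (C): a 3-state alphabet offers no other reading.
Whether low-confidence H/E positions should also count as flexible is
not decidable from the protocol description; they do not here.

## The screen

Insert libraries are i.i.d.: lengths uniform on [8, 19], letters uniform
over a 19-letter alphabet that excludes cysteine (the scaffold is a
cysteine-free variant; configurable). Duplicates are kept — the
protocol has no deduplication step — and the seed is mandatory: no
silent entropy anywhere in the package.

The motif filter accepts a label string iff it contains a **maximal**
H-run of length 4–8 immediately flanked on both sides by maximal C-runs
of length 2–3: an H-run of 9 does not pass via a sub-run, because
"a helix of length 4–8" describes the helix, not a substring of it. The
filter is evaluated on the insert region padded by `flank_max` on each
side — the tightest window that can contain the motif. It is compiled
to a single regular expression with look-arounds enforcing run
maximality; an expert raw-regex override exists. Exhaustive enumeration
(all 3-state strings to length 12, all H/C strings to length 14, plus
random 46-mers) pins the matcher to an independent run-length oracle.

Top-k selection sorts by descending score with ties broken by candidate
id, making the selection a deterministic, permutation-invariant function
of the candidate multiset.

## Folding hand-off, decoys and ranking

The pipeline never shells out to a folding engine: it writes candidate
FASTAs and ingests a directory of models (`folding.mode: external`).
For self-contained runs, `mode: simulate` builds a designed fragment
model — scaffold coordinates kept verbatim outside the loop, the insert
built as a capped helix (two coil residues each end for inserts of ≥7)
continuing the chain from the N-side junction — and perturbs it with
i.i.d. Gaussian coordinate noise, one σ per decoy from a schedule.
Coordinate noise (not torsion noise) is chosen because its expected
pre-superposition displacement is analytic (≈ σ√3 per atom), which makes
the ranking fixtures predictable; realized-order assertions use
geometric σ schedules and frozen seeds so the realized core RMSDs are
strictly ordered. The simulated C-side junction is generally open; see
grafting below.

Ranking superposes each model's core (fragment minus insert) onto the
parent scaffold by CA-Kabsch and sorts ascending; unparseable or
incomplete models are logged and skipped rather than aborting the
ensemble.

## Grafting

The fragment model is superposed onto the barrel over paired anchor CAs
(default: everything in the fragment except the replaced loop — the two
strands and the C-terminal helix). Anchor CA superposition, rather than
all-backbone, is robust to perturbed loop geometry in folding output.
A graft is refused when the anchor RMSD exceeds 2.0 Å — at that point
the model does not recover the scaffold geometry and transplantation is
meaningless. The barrel's loop residues are deleted, the transformed
insert residues spliced in (sidechains carried verbatim, no repacking),
and the chain renumbered sequentially from the barrel's first residue
with the old→new map recorded (keys are tagged `barrel:`/`insert:`
because the two numbering schemes may overlap).

Junction C–N distances outside 1.33 ± 0.2 Å and steric clashes
(heavy-atom pairs under 2.5 Å, same/adjacent residues excluded — a
permissive cutoff for pre-relaxation backbones) are measured and
reported, never auto-corrected: closing the junction is the job of a
downstream relaxation step, and the report is the machine-readable
hand-off to it. The identity graft (fragment extracted from the barrel,
grafted straight back) is a fixed point to 1e-6 Å, and residues outside
the replaced span are bit-identical before and after any graft.

## Evaluation

Helix typing finds backbone H-bonds O(i)…N(i+k), k ∈ {3, 4, 5}, with
two criteria both required: O…N ≤ 3.5 Å, and DSSP-style electrostatic
energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5
kcal/mol, with the amide H placed geometrically 1.01 Å from N along the
external bisector of the preceding carbonyl C and the residue's own CA
(X-ray models usually lack hydrogens). Runs of ≥2 consecutive bonds of
one offset label the residues between the first donor and the run's
last acceptor: i→i+4 → α, i→i+3 → 3₁₀, i→i+5 → π, with precedence
α > 3₁₀ > π where patterns overlap; isolated bonds mark turns. Both
thresholds and the precedence are config keys; ideal helices of lengths
6–20 round-trip to their own type at every interior residue, with no
cross-talk between the i+3 and i+4 patterns at canonical torsions.

Per-residue deviation is the CA–CA distance after a single global
superposition over mapped residue pairs (superposition set
configurable). Numbering differences between a design model and a
crystal structure are handled only by an explicit residue mapping —
never by silent offset detection, since deposited structures may carry
tag residues or renumbered chains. B-factor statistics (mean/max/median
over heavy atoms) are reported per named region with a whole-structure
baseline for contrast, as a flexibility proxy. Polar contacts are
N/O–N/O pairs across two selections within 3.5 Å (configurable),
excluding same-residue and adjacent backbone–backbone pairs, sorted by
distance. The aggregated comparison report is versioned JSON that
round-trips losslessly, plus a human-readable table.

## Pipeline orchestration

Stages communicate through files under the run directory, which makes
the pipeline resumable: a stage re-runs only if its recorded outputs are
missing or changed, the configuration hash changed, or an upstream stage
re-ran. The manifest contains the config hash, per-stage status, a
SHA-256 for every produced file, and tool versions — and nothing
non-deterministic: wall-clock timings and the seeds actually used go to
a JSON-lines log, so identical configuration and seed give byte-identical
manifests. The post-graft re-filter re-predicts the grafted full-length
sequence and applies the motif filter again, mirroring the final
prediction check of the protocol. The original protocol's manual
low-energy candidate choice cannot be automated faithfully; rank-order
selection replaces it.

## Synthetic fixtures and their limits

The mini-barrel (120 residues) and βαβ-fragment (31 residues, loop
sequence Asp-Ala-Thr-Asp at 91–94) are torsion-built geometric
stand-ins: a single chain of helix/strand/loop segments with realistic
mixed-polarity sequences, continuous backbone, clash-free at 2.5 Å, and
the canonical fragment span (80–110) embedded at the expected numbering.
One transition residue takes coil torsions at each helix→strand
junction, otherwise the abrupt torsion switch collides carbonyls. The
fixtures do not close a barrel, pack sidechains (backbone-only, no CB)
or model tertiary contacts — so passing tests demonstrate the
pipeline's contracts (arithmetic, determinism, ranking, grafting,
classification), not biological validity of any particular design.
Fixture sequences were chosen once so the propensity screen accepts a
realistic ~1% of random inserts; they are not tuned per test.

## Problem sizes and determinism

The shipped end-to-end configuration screens 2,000 sequences and
simulates 50 decoys — large enough that every stage runs on a seed-robust
candidate pool, small enough that the whole pipeline finishes in about a
second; the acceptance script additionally ranks a 1,000-model ensemble.
Every stochastic step takes an explicit seed (numpy Generator); fixture
builders are seed-deterministic and byte-stable on one platform,
coordinate-stable to 1e-9 across platforms.

## Known limitations

* The propensity predictor is far weaker than a profile-based neural
  predictor; its acceptance statistics, not its accuracy, are what the
  desk-scale screen exercises. Real screens should feed PSIPRED files in.
* Junction closure, relaxation, sidechain repacking and any energy
  function are out of scope by design; grafts are reported with open
  junctions where geometry demands them.
* Only single-model PDB input is supported; mmCIF is not written.
* The evaluation module trusts the user's residue mapping; there is no
  sequence alignment fallback.
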