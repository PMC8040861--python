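"""Synthetic inputs for desk-scale pipeline runs and tests.

Everything the pipeline consumes is generated here programmatically: an
idealized βαβ-fragment, a mini-barrel scaffold that embeds it, candidate
fragment models carrying a helical insert, Gaussian-noise decoy ensembles
standing in for folding-engine output, and PSIPRED-format prediction files.

The mini-barrel is a geometric stand-in built from ideal backbone torsions
— a single chain laying out helix/strand/loop segments with the canonical
fragment (residues 80–110, replaced loop 91–94 with sequence DATD) embedded
at the numbering the design conventions expect.  It is not a model of a
real barrel: tests assert pipeline contracts on it, never biological
realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, HelixgraftError
from .geometry import (
    CANONICAL_HELIX_TORSIONS,
    build_chain_from_torsions,
    detect_clashes,
    extend_backbone,
)
from .sspredict import SSPrediction, write_ss2
from .structure_io import Structure

__all__ = [
    "FixtureSpec",
    "TORSIONS",
    "make_bab_fragment",
    "make_mini_barrel",
    "make_candidate_fragment_model",
    "make_decoy_ensemble",
    "make_ss2_fixture",
]

# Segment torsions (phi, psi), degrees.
TORSIONS = {
    "helix": CANONICAL_HELIX_TORSIONS["alpha"],
    "three10": CANONICAL_HELIX_TORSIONS["three10"],
    "strand": (-120.0, 130.0),
    "coil": (-75.0, 150.0),
}

# Mini-barrel layout: (segment kind, length, sequence pattern).  The target
# fragment occupies residues 80-110; the replaced loop 91-94 is DATD.
_BARREL_LAYOUT = [
    ("helix", 10, "AEELKKLAEE"),
    ("coil", 4, "GSDG"),
    ("strand", 11, "KTVEVIV"),
    ("coil", 4, "GNSG"),
    ("helix", 11, "AEELKKLAEE"),
    ("coil", 5, "GSDNG"),
    ("strand", 11, "KTVEVIV"),
    ("coil", 4, "GSDG"),
    ("helix", 11, "AEELKKLAEE"),
    ("coil", 8, "GSDNG"),
    ("strand", 11, "KTVEVIVELTS"),  # 80-90: fragment N-terminal strand
    ("loop", 4, "DATD"),            # 91-94: the replaced beta-alpha loop
    ("helix", 10, "SNEELLKKAE"),    # 95-104: fragment helix
    ("strand", 6, "EVTVKV"),        # 105-110: fragment C-terminal strand
    ("coil", 3, "GSG"),
    ("helix", 7, "AEELKKL"),
]

DEFAULT_FRAGMENT_SPAN = (80, 110)
DEFAULT_LOOP_SPAN = (91, 94)


@dataclass
class FixtureSpec:
    """Declarative fixture request (kind, seed and size parameters)."""

    kind: str = "mini_barrel"
    seed: int = 0
    strand_length: int = 11
    helix_length: int = 10
    n_decoys: int = 20
    noise_sigma: float = 0.5


def _segment_sequence(pattern: str, length: int) -> str:
    if len(pattern) == length:
        return pattern
    return (pattern * (length // len(pattern) + 1))[:length]


def _torsion_schedule(layout):
    seq, phis, psis = [], [], []
    prev_kind = None
    for kind, length, pattern in layout:
        t = TORSIONS["coil"] if kind == "loop" else TORSIONS[kind]
        seq.append(_segment_sequence(pattern, length))
        seg_phi = [t[0]] * length
        seg_psi = [t[1]] * length
        # a strand directly after a helix needs one transition residue,
        # otherwise the abrupt torsion switch collides the carbonyls
        if kind == "strand" and prev_kind == "helix":
            seg_phi[0], seg_psi[0] = TORSIONS["coil"]
        phis.extend(seg_phi)
        psis.extend(seg_psi)
        prev_kind = kind
    return "".join(seq), phis, psis


def make_mini_barrel(spec: FixtureSpec | None = None) -> Structure:
    """Build the mini-barrel scaffold (120 residues, chain A, numbered 1–120).

    Deterministic: the layout is fixed and the builder is torsion-driven;
    the seed plays no role here.
    """
    seq, phis, psis = _torsion_schedule(_BARREL_LAYOUT)
    st = build_chain_from_torsions(seq, phis, psis, start_seq_id=1,
                                   structure_id="mini_barrel")
    return st


def make_bab_fragment(spec: FixtureSpec | None = None) -> Structure:
    """The idealized βαβ-fragment: strand–loop–helix–strand, 31 residues,
    numbered 80–110, clash-free at the default cutoff."""
    spec = spec or FixtureSpec(kind="bab_fragment")
    if spec.strand_length < 3 or spec.helix_length < 3:
        raise ConfigError("strand and helix lengths must be >= 3")
    layout = [
        ("strand", spec.strand_length, "KTVEVIVELTS"),
        ("loop", 4, "DATD"),
        ("helix", spec.helix_length, "SNEELLKKAE"),
        ("strand", 31 - spec.strand_length - 4 - spec.helix_length, "EVTVKV"),
    ]
    if layout[-1][1] < 1:
        raise ConfigError("strand/helix lengths exceed the 31-residue fragment")
    seq, phis, psis = _torsion_schedule(layout)
    st = build_chain_from_torsions(seq, phis, psis,
                                   start_seq_id=DEFAULT_FRAGMENT_SPAN[0],
                                   structure_id="bab_fragment")
    if detect_clashes(st):
        raise HelixgraftError("fixture geometry parameters produce a self-clash")
    return st


def make_candidate_fragment_model(barrel: Structure, insert_seq: str,
                                  fragment_span=DEFAULT_FRAGMENT_SPAN,
                                  loop_span=DEFAULT_LOOP_SPAN,
                                  helix_type: str = "alpha") -> Structure:
    """A designed fragment model: scaffold coordinates outside the loop are
    kept verbatim, and the insert is built as a capped helix continuing the
    chain from the N-terminal junction.

    The insert's first and last two residues get coil torsions (the
    "flexible" flanks of the motif), the middle is an ideal helix.  The
    C-terminal junction is generally left open — exactly the gap a
    downstream relaxation step would close; the graft report measures it.

    Numbering: prefix keeps barrel numbers; insert continues sequentially
    from the loop start; the suffix is shifted so numbering stays strictly
    increasing.
    """
    from .grafting import extract_fragment

    chain = barrel.first_chain_id()
    f0, f1 = fragment_span
    l0, l1 = loop_span
    L = len(insert_seq)
    prefix = extract_fragment(barrel, (f0, l0 - 1), chain)
    suffix = extract_fragment(barrel, (l1 + 1, f1), chain)

    n_cap = 2 if L >= 7 else min(1, (L - 3) // 2) if L > 3 else 0
    ht = TORSIONS["helix"] if helix_type == "alpha" else TORSIONS["three10"]
    ct = TORSIONS["coil"]
    phis = [ct[0]] * n_cap + [ht[0]] * (L - 2 * n_cap) + [ct[0]] * n_cap
    psis = [ct[1]] * n_cap + [ht[1]] * (L - 2 * n_cap) + [ct[1]] * n_cap

    prev = prefix.chains[chain][-1]
    insert_residues = extend_backbone(prev, insert_seq, phis, psis,
                                      psi_prev=ct[1], start_seq_id=l0)
    model = Structure(id=f"candidate_{insert_seq[:6]}")
    for r in prefix.chains[chain]:
        model.add_residue(chain, r.copy())
    for r in insert_residues:
        model.add_residue(chain, r)
    shift = L - (l1 - l0 + 1)
    for r in suffix.chains[chain]:
        rc = r.copy()
        rc.seq_id += shift
        model.add_residue(chain, rc)
    return model


def make_decoy_ensemble(reference: Structure, n: int,
                        noise_sigma_schedule, seed: int,
                        out_dir=None) -> list[tuple[Structure, float]]:
    """Decoy models: the reference perturbed by i.i.d. Gaussian coordinate
    noise (σ per decoy from the schedule, cycled/broadcast to ``n``).

    A stand-in for a folding engine's model ensemble with analytically
    predictable expected RMSD (≈ σ√3 per atom before superposition).
    Optionally writes ``decoy_####.pdb`` files.  Deterministic given seed.
    """
    from .structure_io import write_pdb

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    schedule = np.resize(np.asarray(noise_sigma_schedule, float), n)
    if np.any(schedule < 0):
        raise ValueError("noise sigmas must be >= 0")
    decoys = []
    for i, sigma in enumerate(schedule):
        st = reference.copy()
        st.id = f"decoy_{i:04d}"
        for _c, _r, a in st.iter_atoms():
            a.pos = a.pos + rng.normal(0.0, sigma, size=3) if sigma > 0 else a.pos
        decoys.append((st, float(sigma)))
        if out_dir is not None:
            write_pdb(st, f"{out_dir}/decoy_{i:04d}.pdb")
    return decoys


def make_ss2_fixture(prediction: SSPrediction, path) -> None:
    """Write a prediction as a .ss2 file that parses back equal."""
    prediction.validate(strict_argmax=False)
    write_ss2(prediction, path)
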