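"""The in-silico screen: random insert libraries, candidate assembly, the
secondary-structure motif filter, score-based selection and core-RMSD
ranking of folded models.

The screen mirrors a fragment-based design protocol for inserting a helix
into a βαβ super-secondary fragment of a TIM barrel: random insert
sequences (8–19 residues by default) replace the 4-residue βα-loop, the
assembled fragment sequences (35–46 residues) are predicted, and only
candidates whose predicted labels show a helix of length 4–8 flanked on
both sides by 2–3 coil residues at the insertion site are accepted.
Surviving candidates are ranked by prediction score; folded models of the
winners are ranked by the RMSD of the fragment core (insert excluded)
against the parent scaffold.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, HelixgraftError
from .geometry import kabsch_superpose
from .sspredict import SSPrediction
from .structure_io import Structure, read_pdb

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ALPHABET",
    "InsertionSpec",
    "MotifFilter",
    "Candidate",
    "generate_insert_sequences",
    "assemble_candidate",
    "compile_motif_filter",
    "MotifMatcher",
    "apply_filter",
    "select_top",
    "rank_models_by_core_rmsd",
]

# 19 letters: the scaffold is a cysteine-free barrel variant, so the random
# library excludes C by default (configurable).
DEFAULT_ALPHABET = "ADEFGHIKLMNPQRSTVWY"


@dataclass
class InsertionSpec:
    """The design problem: which loop of which scaffold fragment is replaced
    and how long the random inserts may be.  Residue spans are author
    numbering, inclusive."""

    scaffold_id: str = "mini_barrel"
    fragment_span: tuple[int, int] = (80, 110)   # 31 residues
    loop_span: tuple[int, int] = (91, 94)        # the four replaced residues
    insert_len_min: int = 8
    insert_len_max: int = 19
    alphabet: str = DEFAULT_ALPHABET

    def __post_init__(self):
        f0, f1 = self.fragment_span
        l0, l1 = self.loop_span
        if not (f0 <= l0 <= l1 <= f1):
            raise ConfigError("loop_span must lie within fragment_span")
        if self.insert_len_min > self.insert_len_max:
            raise ConfigError("insert_len_min must be <= insert_len_max")
        if not self.alphabet:
            raise ConfigError("alphabet must be non-empty")
        bad = set(self.alphabet) - set("ACDEFGHIKLMNPQRSTVWY")
        if bad:
            raise ConfigError(f"non-canonical letters in alphabet: {sorted(bad)}")

    @property
    def fragment_length(self) -> int:
        return self.fragment_span[1] - self.fragment_span[0] + 1

    @property
    def loop_length(self) -> int:
        return self.loop_span[1] - self.loop_span[0] + 1

    @property
    def loop_local_span(self) -> tuple[int, int]:
        """The loop as 0-based inclusive indices within the fragment."""
        off = self.fragment_span[0]
        return (self.loop_span[0] - off, self.loop_span[1] - off)


@dataclass
class MotifFilter:
    """Run-length motif over predicted labels: a maximal H-run of length
    [helix_min, helix_max] immediately flanked on both sides by maximal
    C-runs of length [flank_min, flank_max]."""

    helix_min: int = 4
    helix_max: int = 8
    flank_min: int = 2
    flank_max: int = 3
    raw_regex: str | None = None  # expert override; searched verbatim

    def __post_init__(self):
        if not (1 <= self.helix_min <= self.helix_max):
            raise ConfigError("need 1 <= helix_min <= helix_max")
        if not (0 <= self.flank_min <= self.flank_max):
            raise ConfigError("need 0 <= flank_min <= flank_max")


@dataclass
class Candidate:
    """One screened sequence: the insert, its assembled fragment context and
    (once computed) its prediction, score and filter verdict."""

    id: str
    insert_seq: str
    assembled_seq: str
    insert_region: tuple[int, int]  # 0-based inclusive within assembled_seq
    prediction: SSPrediction | None = None
    score: float | None = None
    passed_filter: bool | None = None

    def __post_init__(self):
        start, end = self.insert_region
        if end - start + 1 != len(self.insert_seq):
            raise HelixgraftError(
                f"candidate {self.id}: insert_region does not match insert length")
        if self.assembled_seq[start:end + 1] != self.insert_seq:
            raise HelixgraftError(
                f"candidate {self.id}: assembled_seq does not contain the insert at insert_region")


def generate_insert_sequences(spec: InsertionSpec, n: int, seed: int) -> list[str]:
    """Draw ``n`` random insert sequences: lengths uniform over
    [insert_len_min, insert_len_max], letters i.i.d. uniform over the
    alphabet.  Reproducible given the seed; duplicates are permitted."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    alphabet = np.array(sorted(spec.alphabet))
    lengths = rng.integers(spec.insert_len_min, spec.insert_len_max + 1, size=n)
    return ["".join(alphabet[rng.integers(0, len(alphabet), size=L)]) for L in lengths]


def assemble_candidate(fragment_seq: str, loop_local_span: tuple[int, int],
                       insert_seq: str, candidate_id: str = "cand") -> Candidate:
    """Splice an insert into the fragment sequence, replacing the loop.

    ``loop_local_span`` is 0-based inclusive within ``fragment_seq``.  The
    assembled length is fragment − loop + insert.
    """
    start, end = loop_local_span
    if not insert_seq:
        raise HelixgraftError("insert sequence must be non-empty")
    if not (0 <= start <= end < len(fragment_seq)):
        raise HelixgraftError(f"loop span {loop_local_span} out of bounds")
    assembled = fragment_seq[:start] + insert_seq + fragment_seq[end + 1:]
    region = (start, start + len(insert_seq) - 1)
    return Candidate(candidate_id, insert_seq, assembled, region)


class MotifMatcher:
    """Compiled motif filter: accepts an H/E/C label string iff it contains
    the coil–helix–coil run-length motif.  Runs are maximal: an H-run of 9
    does not satisfy helix_max = 8 via a sub-run."""

    def __init__(self, filt: MotifFilter):
        self.filter = filt
        if filt.raw_regex is not None:
            self._re = re.compile(filt.raw_regex)
        else:
            f = filt
            # Maximal-run semantics: the H-run is bounded by the C flanks;
            # the flanks themselves must not extend (lookarounds), with the
            # string edges counting as run boundaries.
            self._re = re.compile(
                f"(?<!C)C{{{f.flank_min},{f.flank_max}}}"
                f"H{{{f.helix_min},{f.helix_max}}}"
                f"C{{{f.flank_min},{f.flank_max}}}(?!C)"
            )

    def matches(self, labels: str, scope: tuple[int, int] | None = None) -> bool:
        if scope is not None:
            s, e = scope
            labels = labels[max(0, s):e + 1]
        return self._re.search(labels) is not None

    __call__ = matches


def compile_motif_filter(filt: MotifFilter) -> MotifMatcher:
    return MotifMatcher(filt)


def apply_filter(candidates: list[Candidate], matcher: MotifMatcher,
                 predictor) -> list[Candidate]:
    """Predict (where needed), evaluate the motif filter on the insert region
    padded by flank_max on each side, and record scores and verdicts.

    ``predictor`` is any ``sequence -> SSPrediction`` callable.
    """
    from .sspredict import prediction_score

    pad = matcher.filter.flank_max
    for cand in candidates:
        if cand.prediction is None:
            cand.prediction = predictor(cand.assembled_seq)
        if len(cand.prediction) != len(cand.assembled_seq):
            raise HelixgraftError(
                f"candidate {cand.id}: prediction length {len(cand.prediction)} "
                f"!= sequence length {len(cand.assembled_seq)}")
        start, end = cand.insert_region
        window = (max(0, start - pad), min(len(cand.assembled_seq) - 1, end + pad))
        cand.passed_filter = matcher.matches(cand.prediction.labels, scope=window)
        cand.score = prediction_score(cand.prediction, cand.insert_region)
    return candidates


def select_top(candidates: list[Candidate], k: int) -> list[Candidate]:
    """Top-k candidates by descending score; ties broken by id for
    determinism.  Permutation-invariant in the input order."""
    if k < 0:
        raise ValueError("k must be >= 0")
    for cand in candidates:
        if cand.score is None:
            raise HelixgraftError(f"candidate {cand.id} is unscored")
    ordered = sorted(candidates, key=lambda c: (-c.score, c.id))
    if k > len(ordered):
        warnings.warn(f"requested top {k} but only {len(ordered)} candidates available")
    return ordered[:k]


def rank_models_by_core_rmsd(models, reference: Structure,
                             core_pairs: list[tuple[int, int]],
                             k: int | None = None,
                             chain_model: str | None = None,
                             chain_ref: str | None = None) -> list[tuple[str, float]]:
    """Rank folded fragment models by CA-RMSD of the core onto the parent.

    ``models`` is a list of PDB paths or ``Structure`` objects.
    ``core_pairs`` pairs model residue numbers with reference residue
    numbers (the insert region is excluded by construction of the pairing).
    Unparseable or incomplete models are logged and skipped; ranking is
    ascending RMSD.
    """
    scored: list[tuple[str, float]] = []
    n_failed = 0
    for m in models:
        try:
            st = m if isinstance(m, Structure) else read_pdb(m)
            name = st.id if isinstance(m, Structure) else str(m)
            cm = chain_model or st.first_chain_id()
            cr = chain_ref or reference.first_chain_id()
            pa, pb = [], []
            for rid_m, rid_r in core_pairs:
                rm = st.get_residue(cm, rid_m)
                rr = reference.get_residue(cr, rid_r)
                if rm is None or rr is None or rm.atom("CA") is None or rr.atom("CA") is None:
                    raise HelixgraftError(f"core residue pair ({rid_m}, {rid_r}) unresolvable")
                pa.append(rm.atom("CA").pos)
                pb.append(rr.atom("CA").pos)
            rmsd = kabsch_superpose(np.array(pa), np.array(pb)).rmsd
            scored.append((name, rmsd))
        except Exception as exc:  # per-model failures are not fatal
            n_failed += 1
            logger.warning("skipping model %s: %s", m, exc)
    if not scored:
        raise HelixgraftError("no model could be scored")
    scored.sort(key=lambda t: (t[1], t[0]))
    if k is not None:
        scored = scored[:k]
    return scored
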