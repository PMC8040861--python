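"""Per-residue 3-state (H/E/C) secondary-structure prediction.

Two sources of predictions share one container:

* a built-in, transparent propensity-window predictor (Chou–Fasman-style
  per-residue scales, window-averaged and normalized to a probability
  triple) — deterministic, dependency-free, adequate for screening
  synthetic libraries at desk scale;
* readers for the standard PSIPRED output formats (``.ss2`` vertical and
  ``.horiz`` horizontal), so externally computed predictions drop into the
  same pipeline.

The built-in method is a propensity-window scorer in the Chou–Fasman
tradition, not a neural-network predictor; predictors are interchangeable
behind the ``sequence -> SSPrediction`` callable interface.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, HelixgraftError, SequenceValidationError

__all__ = [
    "SSPrediction",
    "PropensityTable",
    "load_propensity_table",
    "predict_ss",
    "PropensityPredictor",
    "read_psipred_ss2",
    "read_psipred_horiz",
    "write_ss2",
    "prediction_score",
]

STATES = ("H", "E", "C")
_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SSPrediction:
    """Sequence, per-residue H/E/C labels and (pH, pE, pC) confidences."""

    sequence: str
    labels: str
    confidence: np.ndarray  # (n, 3) rows summing to 1, columns H, E, C

    def __post_init__(self):
        self.confidence = np.asarray(self.confidence, float)

    def validate(self, strict_argmax: bool = True) -> None:
        n = len(self.sequence)
        if len(self.labels) != n or self.confidence.shape != (n, 3):
            raise HelixgraftError("prediction lengths are inconsistent")
        if not set(self.labels) <= set(STATES):
            raise HelixgraftError(f"unknown state letters in {self.labels!r}")
        sums = self.confidence.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise HelixgraftError("confidence triples must sum to 1")
        if strict_argmax:
            arg = [STATES[i] for i in self.confidence.argmax(axis=1)]
            mismatches = [i for i, (a, b) in enumerate(zip(arg, self.labels)) if a != b]
            if mismatches:
                raise HelixgraftError(
                    f"label != argmax(confidence) at positions {mismatches[:5]}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PropensityTable:
    """Per-amino-acid helix/strand/coil weights (all 20 canonical residues)."""

    weights: dict[str, tuple[float, float, float]]

    def __post_init__(self):
        missing = _CANONICAL - set(self.weights)
        if missing:
            raise ConfigError(f"propensity table missing residues {sorted(missing)}")
        for aa, w in self.weights.items():
            if len(w) != 3 or any(x <= 0 for x in w):
                raise ConfigError(f"propensities for {aa} must be three positive weights")


def load_propensity_table(path=None) -> PropensityTable:
    """Load the shipped (or a user-supplied) propensity TSV."""
    if path is None:
        ref = importlib.resources.files("helixgraft.data") / "propensities.tsv"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    weights = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("aa\t"):
            continue
        aa, h, e, c = line.split("\t")
        weights[aa] = (float(h), float(e), float(c))
    return PropensityTable(weights)


def predict_ss(sequence: str, table: PropensityTable | None = None,
               window: int = 7, weighting: str = "triangular") -> SSPrediction:
    """Window-averaged propensity prediction.

    Each residue's (helix, strand, coil) propensities are averaged over a
    centred window (truncated at the termini), then normalized to a
    probability triple; the label is the argmax.  The default window is a
    triangular (center-weighted) average, which keeps state transitions
    sharp enough for run-length motifs; ``weighting="flat"`` gives the
    plain mean.  Deterministic in (sequence, table, window, weighting).
    """
    if not sequence:
        raise SequenceValidationError("empty sequence")
    bad = [(i, c) for i, c in enumerate(sequence) if c not in _CANONICAL]
    if bad:
        raise SequenceValidationError(
            f"non-canonical letters at positions {[i for i, _ in bad]}",
            offending=[c for _, c in bad])
    if window < 1 or window % 2 == 0:
        raise ConfigError(f"window must be a positive odd integer, got {window}")
    if weighting not in ("triangular", "flat"):
        raise ConfigError(f"unknown weighting {weighting!r}")
    if table is None:
        table = load_propensity_table()
    raw = np.array([table.weights[c] for c in sequence], float)
    half = window // 2
    if weighting == "triangular":
        w = np.array([half + 1 - abs(k) for k in range(-half, half + 1)], float)
    else:
        w = np.ones(window)
    n = len(sequence)
    conf = np.empty((n, 3))
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        ww = w[lo - i + half: hi - i + half]
        m = (raw[lo:hi] * ww[:, None]).sum(axis=0) / ww.sum()
        conf[i] = m / m.sum()
    labels = "".join(STATES[i] for i in conf.argmax(axis=1))
    pred = SSPrediction(sequence, labels, conf)
    pred.validate()
    return pred


class PropensityPredictor:
    """The built-in predictor as a reusable ``sequence -> SSPrediction``
    callable, fixing a table and window."""

    def __init__(self, table: PropensityTable | None = None, window: int = 7,
                 weighting: str = "triangular"):
        self.table = table if table is not None else load_propensity_table()
        self.window = window
        self.weighting = weighting

    def __call__(self, sequence: str) -> SSPrediction:
        return predict_ss(sequence, self.table, self.window, self.weighting)


# ---------------------------------------------------------------------------
# PSIPRED output readers / writer
# ---------------------------------------------------------------------------

def read_psipred_ss2(path) -> SSPrediction:
    """Read PSIPRED vertical (.ss2) output.

    Lines: index, residue, state, then coil/helix/strand scores.  States and
    scores are taken verbatim; score triples are renormalized to sum to 1.
    """
    seq, labels, conf = [], [], []
    expected = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 6:
                raise HelixgraftError(f"{path}:{lineno}: malformed ss2 line")
            idx = int(parts[0])
            if idx != expected:
                raise HelixgraftError(
                    f"{path}:{lineno}: index discontinuity ({idx}, expected {expected})")
            expected += 1
            state = parts[2]
            if state not in STATES:
                raise HelixgraftError(f"{path}:{lineno}: unknown state {state!r}")
            c, h, e = (float(x) for x in parts[3:6])
            seq.append(parts[1])
            labels.append(state)
            conf.append((h, e, c))
    if not seq:
        raise HelixgraftError(f"{path}: empty prediction")
    conf = np.array(conf)
    sums = conf.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise HelixgraftError(f"{path}: non-positive score triple")
    conf = conf / sums
    pred = SSPrediction("".join(seq), "".join(labels), conf)
    pred.validate(strict_argmax=False)
    return pred


def write_ss2(prediction: SSPrediction, path) -> None:
    """Write a prediction in PSIPRED vertical (.ss2) format."""
    if len(prediction) == 0:
        raise HelixgraftError("refusing to write an empty prediction")
    with open(path, "w") as fh:
        fh.write("# PSF format file (helixgraft)\n\n")
        for i, (aa, state) in enumerate(zip(prediction.sequence, prediction.labels), 1):
            h, e, c = prediction.confidence[i - 1]
            fh.write(f"{i:4d} {aa} {state}  {c:6.3f} {h:6.3f} {e:6.3f}\n")


def read_psipred_horiz(path) -> SSPrediction:
    """Read PSIPRED horizontal (.horiz) output: Conf/Pred/AA blocks.

    A confidence digit d for the predicted state maps to probability
    (d + 0.5)/10, with the remainder split equally between the other two
    states — a monotone, bounded reading of the 0–9 scale.
    """
    conf_s, pred_s, aa_s = [], [], []
    block = {}
    blockno = 0

    def flush():
        nonlocal blockno
        if not block:
            return
        blockno += 1
        widths = {len(block.get(k, "")) for k in ("Conf", "Pred", "AA")}
        if len(widths) != 1:
            raise HelixgraftError(f"{path}: misaligned block {blockno}")
        conf_s.append(block.get("Conf", ""))
        pred_s.append(block.get("Pred", ""))
        aa_s.append(block.get("AA", ""))
        block.clear()

    with open(path) as fh:
        for line in fh:
            s = line.rstrip("\n")
            if ":" in s:
                key, _, val = s.partition(":")
                key = key.strip()
                if key in ("Conf", "Pred", "AA"):
                    if key in block:
                        flush()
                    block[key] = val.strip()
            elif not s.strip() and len(block) == 3:
                flush()
    flush()
    conf_str, pred_str, aa_str = "".join(conf_s), "".join(pred_s), "".join(aa_s)
    if not aa_str:
        raise HelixgraftError(f"{path}: empty prediction")
    if not (len(conf_str) == len(pred_str) == len(aa_str)):
        raise HelixgraftError(f"{path}: misaligned Conf/Pred/AA lengths")
    conf = np.empty((len(aa_str), 3))
    for i, (d, state) in enumerate(zip(conf_str, pred_str)):
        if state not in STATES:
            raise HelixgraftError(f"{path}: unknown state {state!r} at position {i}")
        p = (int(d) + 0.5) / 10.0
        rest = (1.0 - p) / 2.0
        triple = [rest, rest, rest]
        triple[STATES.index(state)] = p
        conf[i] = triple
    pred = SSPrediction(aa_str, pred_str, conf)
    pred.validate(strict_argmax=False)
    return pred


def prediction_score(pred: SSPrediction, region: tuple[int, int],
                     method: str = "mean") -> float:
    """Aggregate predicted-state confidence over a 0-based inclusive region.

    ``mean`` (default) averages each residue's confidence in its own
    predicted state; ``min`` takes the weakest residue.  Higher is better.
    """
    start, end = region
    if start < 0 or end >= len(pred) or start > end:
        raise HelixgraftError(f"region {region} out of bounds for length {len(pred)}")
    vals = [pred.confidence[i, STATES.index(pred.labels[i])] for i in range(start, end + 1)]
    if method == "mean":
        return float(np.mean(vals))
    if method == "min":
        return float(np.min(vals))
    raise ConfigError(f"unknown score method {method!r}")
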