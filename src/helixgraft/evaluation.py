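"""Compare a design model against an experimental structure.

The comparisons mirror how a designed helical extension is judged against
its crystal structure: global and per-region RMSD, per-residue CA deviation
after one global superposition, helix typing from backbone hydrogen-bond
patterns (α: i→i+4, 3₁₀: i→i+3, π: i→i+5 — the distinction that matters
when a designed α-helix crystallizes as a 3₁₀ helix), per-region B-factor
statistics (a flexibility proxy), and polar donor/acceptor contacts.

Hydrogen bonds are detected from heavy atoms only: the amide H is placed
geometrically (X-ray models typically omit hydrogens) and a bond requires
both an O…N distance within cutoff and a DSSP-style electrostatic energy
below threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import HelixgraftError, SelectionError
from .geometry import kabsch_superpose
from .selection import parse_selection, select_residues
from .structure_io import Structure

__all__ = [
    "HBond",
    "HelixClassification",
    "classify_helix",
    "per_residue_deviation",
    "bfactor_stats",
    "polar_contacts",
    "ComparisonReport",
    "compare_model_to_structure",
]

# H-bond acceptance: O...N distance cutoff (Å) and DSSP-style energy
# threshold (kcal/mol).  Both configurable at call sites.
DEFAULT_ON_CUTOFF = 3.5
DEFAULT_ENERGY_CUTOFF = -0.5
_DSSP_Q = 0.084 * 332.0  # coupled partial charges * electrostatic constant
_NH_LENGTH = 1.01

# Pattern offset -> helix type, in precedence order (alpha wins overlaps).
_PATTERNS = (("alpha", 4), ("three10", 3), ("pi", 5))


@dataclass
class HBond:
    donor_seq_id: int      # residue providing N-H
    acceptor_seq_id: int   # residue providing C=O
    distance_on: float     # O...N, Å
    pattern: str           # "i->i+3" | "i->i+4" | "i->i+5"
    energy: float          # kcal/mol


@dataclass
class HelixClassification:
    seq_ids: list[int]
    labels: list[str]  # per-residue: alpha | three10 | pi | turn | none
    hbonds: list[HBond]

    def label_of(self, seq_id: int) -> str:
        return self.labels[self.seq_ids.index(seq_id)]


def _amide_h(n_pos, c_prev, ca_self) -> np.ndarray:
    """Geometric amide H: 1.01 Å from N along the external bisector (away
    from the midpoint of the preceding carbonyl C and this residue's CA)."""
    mid = 0.5 * (c_prev + ca_self)
    v = n_pos - mid
    return n_pos + _NH_LENGTH * v / np.linalg.norm(v)


def _hbond_energy(c, o, n, h) -> float:
    """DSSP electrostatic model of a backbone C=O ... H-N hydrogen bond."""
    def d(a, b):
        return float(np.linalg.norm(a - b))
    return _DSSP_Q * (1.0 / d(o, n) + 1.0 / d(c, h) - 1.0 / d(o, h) - 1.0 / d(c, n))


def classify_helix(structure: Structure, region: tuple[int, int] | None = None,
                   chain_id: str | None = None,
                   on_cutoff: float = DEFAULT_ON_CUTOFF,
                   energy_cutoff: float = DEFAULT_ENERGY_CUTOFF) -> HelixClassification:
    """Assign per-residue helix types from backbone H-bond patterns.

    A bond O(i)…N(i+k) (k = 3, 4, 5) is accepted when the O…N distance is
    within ``on_cutoff`` and the DSSP-style energy (with a geometrically
    placed amide H) is below ``energy_cutoff``.  Runs of at least two
    consecutive bonds of the same offset define helical residues; where
    patterns overlap, alpha takes precedence over three10 over pi.
    Isolated bonds mark turns.
    """
    import warnings

    if chain_id is None:
        chain_id = structure.first_chain_id()
    residues = structure.chains[chain_id]
    if region is not None:
        lo, hi = region
        residues = [r for r in residues if lo <= r.seq_id <= hi]
    n = len(residues)
    labels = ["none"] * n

    def pos(i, name):
        a = residues[i].atom(name)
        return None if a is None else a.pos

    missing_o = [residues[i].seq_id for i in range(n) if pos(i, "O") is None]
    if missing_o:
        warnings.warn(f"missing carbonyl O atoms at residues {missing_o}; labeled none")

    bonds: dict[int, set[int]] = {k: set() for _, k in _PATTERNS}
    hbonds: list[HBond] = []
    for i in range(n):
        C, O = pos(i, "C"), pos(i, "O")
        if C is None or O is None:
            continue
        for tname, k in _PATTERNS:
            j = i + k
            if j >= n:
                continue
            # acceptor numbering must actually be i+k in sequence
            if residues[j].seq_id != residues[i].seq_id + k:
                continue
            N = pos(j, "N")
            if N is None:
                continue
            d_on = float(np.linalg.norm(O - N))
            if d_on > on_cutoff:
                continue
            Cprev, CAj = pos(j - 1, "C"), pos(j, "CA")
            if Cprev is None or CAj is None:
                continue
            H = _amide_h(N, Cprev, CAj)
            e = _hbond_energy(C, O, N, H)
            if e < energy_cutoff:
                bonds[k].add(i)
                hbonds.append(HBond(residues[j].seq_id, residues[i].seq_id,
                                    d_on, f"i->i+{k}", e))

    # Helical runs: >= 2 consecutive bond starts of the same offset label
    # residues strictly between the first donor turn and the run's last
    # acceptor; precedence alpha > three10 > pi.
    turn_starts: set[int] = set()
    for tname, k in _PATTERNS:
        starts = sorted(bonds[k])
        run: list[int] = []
        for s in starts + [None]:
            if run and (s is None or s != run[-1] + 1):
                if len(run) >= 2:
                    for idx in range(run[0] + 1, run[-1] + k):
                        if labels[idx] == "none":
                            labels[idx] = tname
                else:
                    turn_starts.add((run[0], k))
                run = []
            if s is not None:
                run.append(s)
    for (s, k) in turn_starts:
        for idx in range(s + 1, min(s + k, n)):
            if labels[idx] == "none":
                labels[idx] = "turn"
    return HelixClassification([r.seq_id for r in residues], labels, hbonds)


def per_residue_deviation(model: Structure, xray: Structure,
                          mapping: list[tuple[int, int]] | None = None,
                          superpose_pairs: list[tuple[int, int]] | None = None,
                          chain_model: str | None = None,
                          chain_xray: str | None = None) -> dict[int, float]:
    """CA–CA distance per mapped residue after one global superposition.

    ``mapping`` pairs model residue numbers with xray residue numbers; by
    default residues are paired by identical number.  ``superpose_pairs``
    optionally restricts the superposition set (default: all mapped pairs).
    Returns {model residue number: deviation Å}; unmapped residues are
    excluded with a warning.
    """
    import warnings

    cm = chain_model or model.first_chain_id()
    cx = chain_xray or xray.first_chain_id()
    res_m = {r.seq_id: r for r in model.chains[cm]}
    res_x = {r.seq_id: r for r in xray.chains[cx]}
    if mapping is None:
        mapping = [(i, i) for i in res_m if i in res_x]
    usable = []
    for a, b in mapping:
        ra, rb = res_m.get(a), res_x.get(b)
        if ra is None or rb is None or ra.atom("CA") is None or rb.atom("CA") is None:
            warnings.warn(f"residue pair ({a}, {b}) unmapped or lacking CA; excluded")
            continue
        usable.append((a, b))
    if len(usable) < 3:
        raise HelixgraftError("fewer than 3 mapped CA pairs")
    sup_pairs = superpose_pairs if superpose_pairs is not None else usable
    P = np.array([res_m[a].atom("CA").pos for a, _ in sup_pairs])
    Q = np.array([res_x[b].atom("CA").pos for _, b in sup_pairs])
    sup = kabsch_superpose(P, Q)
    out: dict[int, float] = {}
    for a, b in usable:
        pa = sup.apply(res_m[a].atom("CA").pos[None, :])[0]
        out[a] = float(np.linalg.norm(pa - res_x[b].atom("CA").pos))
    return out


def bfactor_stats(structure: Structure, regions: dict[str, str]) -> dict[str, dict[str, float]]:
    """Heavy-atom B-factor mean/max/median per named selection, plus an
    ``overall`` baseline over all heavy atoms for contrast."""
    out: dict[str, dict[str, float]] = {}
    all_b = [a.bfactor for _, _, a in structure.iter_atoms(heavy_only=True)]
    if not all_b:
        raise HelixgraftError("structure has no heavy atoms")
    out["overall"] = _bstats(all_b)
    for name, sel_text in regions.items():
        sel = parse_selection(sel_text)
        vals = [a.bfactor
                for cid, r in select_residues(structure, sel)
                for a in r.atoms
                if not a.is_hydrogen and sel.matches_atom(a.name)]
        if not vals:
            raise HelixgraftError(f"region {name!r} ({sel_text!r}) selects no atoms")
        out[name] = _bstats(vals)
    return out


def _bstats(vals) -> dict[str, float]:
    arr = np.asarray(vals, float)
    return {"mean": float(arr.mean()), "max": float(arr.max()),
            "median": float(np.median(arr)), "n_atoms": int(arr.size)}


def polar_contacts(structure: Structure, region_a: str, region_b: str,
                   cutoff: float = 3.5) -> list[dict]:
    """N/O–N/O atom pairs across two selections within ``cutoff`` Å.

    Backbone–backbone pairs of the same or adjacent residues are excluded
    (those are covalent neighbourhood, not contacts).  Sorted by distance.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    def gather(sel_text):
        sel = parse_selection(sel_text)
        items = []
        for cid, r in select_residues(structure, sel):
            for a in r.atoms:
                if a.element.upper() in ("N", "O") and sel.matches_atom(a.name):
                    items.append((cid, r, a))
        return items

    atoms_a, atoms_b = gather(region_a), gather(region_b)
    if not atoms_a or not atoms_b:
        return []
    tree = cKDTree(np.array([a.pos for _, _, a in atoms_b]))
    contacts = []
    backbone = {"N", "O", "C", "CA"}
    seen = set()
    for ca_, ra, aa in atoms_a:
        for j in tree.query_ball_point(aa.pos, cutoff):
            cb_, rb, ab = atoms_b[j]
            if ca_ == cb_ and ra.key == rb.key:
                continue
            if (ca_ == cb_ and abs(ra.seq_id - rb.seq_id) <= 1
                    and aa.name in backbone and ab.name in backbone):
                continue
            key = tuple(sorted([(ca_, ra.seq_id, aa.name), (cb_, rb.seq_id, ab.name)]))
            if key in seen:
                continue
            seen.add(key)
            d = float(np.linalg.norm(aa.pos - ab.pos))
            contacts.append({
                "residue_a": [ca_, ra.seq_id, ra.name],
                "residue_b": [cb_, rb.seq_id, rb.name],
                "atom_a": aa.name, "atom_b": ab.name,
                "distance": d,
            })
    contacts.sort(key=lambda c: (c["distance"], str(c["residue_a"]), c["atom_a"]))
    return contacts


@dataclass
class ComparisonReport:
    """Aggregated model-vs-experiment comparison; JSON-serializable."""

    global_rmsd: float
    region_rmsds: dict[str, float]
    per_residue_deviation: dict[int, float]
    bfactor_stats: dict[str, dict[str, float]]
    polar_contacts: list[dict]
    helix_class_model: HelixClassification | None = None
    helix_class_xray: HelixClassification | None = None
    schema_version: int = 1

    def to_dict(self) -> dict:
        def hc(h):
            if h is None:
                return None
            return {"seq_ids": h.seq_ids, "labels": h.labels,
                    "hbonds": [[b.donor_seq_id, b.acceptor_seq_id, b.distance_on,
                                b.pattern, b.energy] for b in h.hbonds]}
        return {
            "schema_version": self.schema_version,
            "global_rmsd": self.global_rmsd,
            "region_rmsds": self.region_rmsds,
            "per_residue_deviation": {str(k): v for k, v in self.per_residue_deviation.items()},
            "bfactor_stats": self.bfactor_stats,
            "polar_contacts": self.polar_contacts,
            "helix_class_model": hc(self.helix_class_model),
            "helix_class_xray": hc(self.helix_class_xray),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonReport":
        def hc(x):
            if x is None:
                return None
            return HelixClassification(
                x["seq_ids"], x["labels"],
                [HBond(b[0], b[1], b[2], b[3], b[4]) for b in x["hbonds"]])
        return cls(
            global_rmsd=d["global_rmsd"],
            region_rmsds=d["region_rmsds"],
            per_residue_deviation={int(k): v for k, v in d["per_residue_deviation"].items()},
            bfactor_stats=d["bfactor_stats"],
            polar_contacts=d["polar_contacts"],
            helix_class_model=hc(d["helix_class_model"]),
            helix_class_xray=hc(d["helix_class_xray"]),
            schema_version=d.get("schema_version", 1),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def summary_table(self) -> str:
        lines = [f"global CA-RMSD: {self.global_rmsd:.3f} Å"]
        for name, v in sorted(self.region_rmsds.items()):
            lines.append(f"region {name}: RMSD {v:.3f} Å")
        for name, st in sorted(self.bfactor_stats.items()):
            lines.append(
                f"B-factors {name}: mean {st['mean']:.1f} max {st['max']:.1f} "
                f"median {st['median']:.1f} Å² ({st['n_atoms']} atoms)")
        lines.append(f"polar contacts: {len(self.polar_contacts)}")
        return "\n".join(lines)


def compare_model_to_structure(model: Structure, xray: Structure,
                               config: dict | None = None) -> ComparisonReport:
    """Run the full comparison.

    ``config`` keys (all optional): ``mapping`` (list of [model_res,
    xray_res] pairs; default pair-by-number), ``regions`` ({name: selection}
    evaluated on both structures for region RMSD), ``helix_region``
    ((lo, hi) span for helix typing, model numbering = xray numbering via
    mapping), ``contacts`` ({region_a, region_b, cutoff} evaluated on the
    xray structure), ``bfactor_regions`` ({name: selection} on the xray
    structure).
    """
    config = config or {}
    mapping = config.get("mapping")
    if mapping is not None:
        mapping = [tuple(p) for p in mapping]
    dev = per_residue_deviation(model, xray, mapping=mapping)
    glob = rmsd_pairs = None
    cm, cx = model.first_chain_id(), xray.first_chain_id()
    if mapping is None:
        ids_m = {r.seq_id for r in model.chains[cm]}
        ids_x = {r.seq_id for r in xray.chains[cx]}
        mapping = [(i, i) for i in sorted(ids_m & ids_x)]
    res_m = {r.seq_id: r for r in model.chains[cm]}
    res_x = {r.seq_id: r for r in xray.chains[cx]}
    P = np.array([res_m[a].atom("CA").pos for a, b in mapping
                  if res_m.get(a) and res_x.get(b)
                  and res_m[a].atom("CA") is not None and res_x[b].atom("CA") is not None])
    Q = np.array([res_x[b].atom("CA").pos for a, b in mapping
                  if res_m.get(a) and res_x.get(b)
                  and res_m[a].atom("CA") is not None and res_x[b].atom("CA") is not None])
    glob = kabsch_superpose(P, Q).rmsd

    region_rmsds: dict[str, float] = {}
    for name, sel_text in (config.get("regions") or {}).items():
        sel = parse_selection(sel_text)
        sub = [(a, b) for a, b in mapping
               if res_m.get(a) is not None and sel.matches_residue(cm, res_m[a])]
        if len(sub) < 3:
            raise SelectionError(f"region {name!r} ({sel_text!r}) maps fewer than 3 residues")
        Pr = np.array([res_m[a].atom("CA").pos for a, _ in sub])
        Qr = np.array([res_x[b].atom("CA").pos for _, b in sub])
        region_rmsds[name] = kabsch_superpose(Pr, Qr).rmsd

    helix_region = config.get("helix_region")
    hc_m = hc_x = None
    if helix_region is not None:
        lo, hi = helix_region
        hc_m = classify_helix(model, (lo, hi))
        xmap = dict(mapping)
        xlo, xhi = xmap.get(lo, lo), xmap.get(hi, hi)
        hc_x = classify_helix(xray, (xlo, xhi))

    contacts_cfg = config.get("contacts") or {}
    contacts = []
    if contacts_cfg:
        contacts = polar_contacts(xray, contacts_cfg["region_a"],
                                  contacts_cfg["region_b"],
                                  cutoff=contacts_cfg.get("cutoff", 3.5))

    bstats = bfactor_stats(xray, config.get("bfactor_regions") or {})
    return ComparisonReport(
        global_rmsd=glob,
        region_rmsds=region_rmsds,
        per_residue_deviation=dev,
        bfactor_stats=bstats,
        polar_contacts=contacts,
        helix_class_model=hc_m,
        helix_class_xray=hc_x,
    )
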