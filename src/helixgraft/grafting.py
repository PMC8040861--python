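"""Transfer a designed helix from a folded fragment model into the full
scaffold.

The fragment model is rigidly superposed onto the barrel over paired anchor
residues (by default the fragment's strands and C-terminal helix, i.e.
everything except the replaced loop), the barrel's loop residues are
deleted, the fragment's insert residues are copied in, and the chain is
renumbered sequentially.  Junction gaps and steric clashes are measured and
reported — never auto-fixed: closing them is the job of a downstream
relaxation step outside this package, and the report is the hand-off
contract to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import GraftError, HelixgraftError
from .geometry import IDEAL_BACKBONE, detect_clashes, kabsch_superpose, Clash
from .structure_io import Residue, Structure, transform_structure

__all__ = ["GraftSpec", "GraftResult", "extract_fragment", "graft_insert", "renumber"]


@dataclass
class GraftSpec:
    """How to transplant: paired anchor residue numbers (fragment vs
    barrel, 1:1 in order), the fragment span holding the new helix, and the
    barrel span it replaces."""

    anchor_residues_fragment: list[int]
    anchor_residues_barrel: list[int]
    insert_span_fragment: tuple[int, int]
    replace_span_barrel: tuple[int, int] = (91, 94)
    anchor_rmsd_threshold: float = 2.0
    clash_cutoff: float = 2.5

    def __post_init__(self):
        if len(self.anchor_residues_fragment) != len(self.anchor_residues_barrel):
            raise HelixgraftError("anchor lists must pair 1:1")
        lo, hi = self.insert_span_fragment
        if any(lo <= r <= hi for r in self.anchor_residues_fragment):
            raise HelixgraftError("insert span must be disjoint from the anchors")


@dataclass
class GraftResult:
    model: Structure
    anchor_rmsd: float
    junction_gaps: list[tuple[int, float]]  # (new residue number before gap, C-N distance)
    clashes: list[Clash]
    renumbering_map: dict[str, int]  # "barrel:<old>" / "insert:<old>" -> new number

    def report_dict(self) -> dict:
        return {
            "anchor_rmsd": self.anchor_rmsd,
            "junction_gaps": [[p, d] for p, d in self.junction_gaps],
            "clashes": [
                {"a": [c.a.chain, c.a.seq_id, c.a.atom_name],
                 "b": [c.b.chain, c.b.seq_id, c.b.atom_name],
                 "distance": c.distance}
                for c in self.clashes
            ],
            "renumbering_map": {str(k): v for k, v in self.renumbering_map.items()},
        }

    def write_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report_dict(), fh, indent=2, sort_keys=True)


def extract_fragment(barrel: Structure, fragment_span: tuple[int, int],
                     chain_id: str | None = None) -> Structure:
    """Copy a residue span (author numbering, inclusive) into a new
    structure, preserving numbering."""
    if chain_id is None:
        chain_id = barrel.first_chain_id()
    lo, hi = fragment_span
    wanted = list(range(lo, hi + 1))
    present = {r.seq_id: r for r in barrel.chains[chain_id]}
    missing = [i for i in wanted if i not in present]
    if missing:
        raise HelixgraftError(f"fragment span missing residues {missing}")
    out = Structure(id=f"{barrel.id}_frag_{lo}_{hi}")
    for i in wanted:
        out.add_residue(chain_id, present[i].copy())
    return out


def renumber(structure: Structure, start: int = 1,
             chain_id: str | None = None) -> tuple[Structure, dict[int, int]]:
    """Renumber one chain sequentially from ``start``; insertion codes are
    cleared.  Returns the renumbered copy and the old→new map."""
    if chain_id is None:
        chain_id = structure.first_chain_id()
    out = structure.copy()
    mapping: dict[int, int] = {}
    for offset, r in enumerate(out.chains[chain_id]):
        mapping[r.seq_id] = start + offset
        r.seq_id = start + offset
        r.insertion_code = ""
    return out, mapping


def graft_insert(barrel: Structure, fragment_model: Structure,
                 spec: GraftSpec) -> GraftResult:
    """Graft the fragment model's insert into the barrel.

    Steps: Kabsch on paired anchor CAs (fragment → barrel frame); reject if
    the anchor RMSD exceeds the threshold; delete the barrel's replaced
    span; splice in the transformed insert residues; renumber sequentially
    from the barrel's first residue number.  Barrel residues outside the
    replaced span keep their coordinates bit-identically (the transform is
    applied to the fragment only).
    """
    cb = barrel.first_chain_id()
    cf = fragment_model.first_chain_id()
    frag_res = {r.seq_id: r for r in fragment_model.chains[cf]}
    barrel_res = {r.seq_id: r for r in barrel.chains[cb]}
    pa, pb = [], []
    for rf, rb in zip(spec.anchor_residues_fragment, spec.anchor_residues_barrel):
        if rf not in frag_res or rb not in barrel_res:
            raise GraftError(f"anchor pair ({rf}, {rb}) unresolvable")
        af, ab = frag_res[rf].atom("CA"), barrel_res[rb].atom("CA")
        if af is None or ab is None:
            raise GraftError(f"anchor pair ({rf}, {rb}) lacks CA atoms")
        pa.append(af.pos)
        pb.append(ab.pos)
    sup = kabsch_superpose(np.array(pa), np.array(pb))
    if sup.rmsd > spec.anchor_rmsd_threshold:
        raise GraftError(
            f"anchor RMSD {sup.rmsd:.2f} Å exceeds threshold "
            f"{spec.anchor_rmsd_threshold:.2f} Å — fragment model does not "
            f"recover the scaffold geometry")
    placed = transform_structure(fragment_model, sup.rotation, sup.translation)

    lo_i, hi_i = spec.insert_span_fragment
    insert_residues = [r.copy() for r in placed.chains[cf] if lo_i <= r.seq_id <= hi_i]
    if not insert_residues:
        raise GraftError(f"insert span {spec.insert_span_fragment} empty in fragment model")

    # Rebuild the chain in order: before-loop, insert, after-loop, then
    # renumber sequentially from the barrel's first residue number.  The
    # renumbering map is keyed "barrel:<old>" / "insert:<fragment old>"
    # because barrel and fragment-model numbering may overlap.
    lo_r, hi_r = spec.replace_span_barrel
    new = Structure(id=f"{barrel.id}_grafted")
    before = [r.copy() for r in barrel.chains[cb] if r.seq_id < lo_r]
    after = [r.copy() for r in barrel.chains[cb] if r.seq_id > hi_r]
    combined = before + insert_residues + after
    n_before, n_insert = len(before), len(insert_residues)
    start = barrel.chains[cb][0].seq_id
    mapping: dict[str, int] = {}
    for offset, r in enumerate(combined):
        new_id = start + offset
        origin = "insert" if n_before <= offset < n_before + n_insert else "barrel"
        mapping[f"{origin}:{r.seq_id}"] = new_id
        r.seq_id = new_id
        r.insertion_code = ""
        new.add_residue(cb, r)

    # Junction C-N distances at the two splice points.
    gaps: list[tuple[int, float]] = []
    for idx in (n_before - 1, n_before + n_insert - 1):
        if 0 <= idx < len(combined) - 1:
            c = combined[idx].atom("C")
            nn = combined[idx + 1].atom("N")
            if c is not None and nn is not None:
                d = float(np.linalg.norm(c.pos - nn.pos))
                if abs(d - IDEAL_BACKBONE["C-N"]) > 0.2:
                    gaps.append((combined[idx].seq_id, d))

    insert_ids = {r.seq_id for r in insert_residues}
    clashes = [c for c in detect_clashes(new, cutoff=spec.clash_cutoff)
               if c.a.seq_id in insert_ids or c.b.seq_id in insert_ids]
    return GraftResult(model=new, anchor_rmsd=sup.rmsd, junction_gaps=gaps,
                       clashes=clashes, renumbering_map=mapping)
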