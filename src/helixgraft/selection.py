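"""Tiny residue/atom selection mini-language.

Grammar (whitespace-separated clauses, all optional, each at most once)::

    chain <id>[,<id>...] resi <n>[-<m>][,<n>[-<m>]...] name <atom>[,<atom>...]

Example: ``chain A resi 60-90 name CA``.  Residue ranges are author
numbering, inclusive on both ends.  An empty string selects everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SelectionError
from .structure_io import Residue, Structure

__all__ = ["Selection", "parse_selection", "select_residues", "select_atoms"]


@dataclass
class Selection:
    chains: set[str] | None = None
    resi_ranges: list[tuple[int, int]] | None = None
    names: set[str] | None = None

    def matches_residue(self, chain_id: str, residue: Residue) -> bool:
        if self.chains is not None and chain_id not in self.chains:
            return False
        if self.resi_ranges is not None:
            if not any(lo <= residue.seq_id <= hi for lo, hi in self.resi_ranges):
                return False
        return True

    def matches_atom(self, name: str) -> bool:
        return self.names is None or name in self.names


def parse_selection(text: str | None) -> Selection:
    if not text or not text.strip():
        return Selection()
    tokens = text.split()
    sel = Selection()
    i = 0
    while i < len(tokens):
        key = tokens[i].lower()
        if i + 1 >= len(tokens):
            raise SelectionError(f"selection clause {key!r} missing its argument")
        arg = tokens[i + 1]
        if key == "chain":
            sel.chains = set(arg.split(","))
        elif key == "resi":
            ranges = []
            for part in arg.split(","):
                if "-" in part[1:]:  # allow negative lower bound
                    lo_s, hi_s = part.rsplit("-", 1)
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError as exc:
                        raise SelectionError(f"bad residue range {part!r}") from exc
                else:
                    try:
                        lo = hi = int(part)
                    except ValueError as exc:
                        raise SelectionError(f"bad residue number {part!r}") from exc
                if lo > hi:
                    raise SelectionError(f"inverted residue range {part!r}")
                ranges.append((lo, hi))
            sel.resi_ranges = ranges
        elif key == "name":
            sel.names = set(arg.split(","))
        else:
            raise SelectionError(f"unknown selection clause {key!r}")
        i += 2
    return sel


def select_residues(structure: Structure, selection: Selection | str | None):
    """Yield ``(chain_id, residue)`` pairs matching the selection, in order."""
    if not isinstance(selection, Selection):
        selection = parse_selection(selection)
    for cid, residues in structure.chains.items():
        for r in residues:
            if selection.matches_residue(cid, r):
                yield cid, r


def select_atoms(structure: Structure, selection: Selection | str | None):
    """Yield ``(chain_id, residue, atom)`` triples matching the selection."""
    if not isinstance(selection, Selection):
        selection = parse_selection(selection)
    for cid, r in select_residues(structure, selection):
        for a in r.atoms:
            if selection.matches_atom(a.name):
                yield cid, r, a
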