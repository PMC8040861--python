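"""Rigid-body superposition, RMSD, dihedrals, ideal-backbone construction,
clash and continuity checks.

This is the geometric engine behind model ranking (core-RMSD sorting of
decoy ensembles), grafting (anchor superposition) and evaluation (deviation
maps, helix typing).  Angles are degrees everywhere, matching
crystallographic convention; distances are Å.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import PairingError
from .selection import Selection, parse_selection, select_residues
from .structure_io import AA_1TO3, Atom, Residue, Structure

__all__ = [
    "IDEAL_BACKBONE",
    "CANONICAL_HELIX_TORSIONS",
    "SuperpositionResult",
    "DihedralProfile",
    "IdealHelixParams",
    "kabsch_superpose",
    "rmsd_after_superposition",
    "dihedral",
    "backbone_dihedrals",
    "place_atom",
    "build_chain_from_torsions",
    "extend_backbone",
    "build_ideal_helix",
    "detect_clashes",
    "check_backbone_continuity",
]

# Ideal peptide backbone geometry — single source of truth for every builder.
# Bond lengths in Å, angles in degrees (standard Engh/Huber-style values).
IDEAL_BACKBONE = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C-O": 1.231,
    "N-CA-C": 111.2,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "CA-C-O": 120.8,
}

# Canonical backbone torsions (phi, psi) for ideal helices, degrees.
CANONICAL_HELIX_TORSIONS = {
    "alpha": (-57.0, -47.0),
    "three10": (-49.0, -26.0),
}


@dataclass
class SuperpositionResult:
    """Optimal rigid transform ``x -> R x + t`` of mobile onto reference."""

    rotation: np.ndarray  # 3x3, proper (det = +1)
    translation: np.ndarray  # 3-vector, Å
    rmsd: float  # Å
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch_superpose(coords_mobile: np.ndarray, coords_ref: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch, SVD-based).

    Returns the proper rotation and translation minimizing the RMSD of
    ``R x + t`` over the reference; reflections are excluded by sign
    correction of the smallest singular direction, preserving chirality.
    """
    P = np.asarray(coords_mobile, float)
    Q = np.asarray(coords_ref, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate arrays must both be N x 3")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs at least 3 points, got {n}")
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(Q))):
        raise ValueError("coordinates must be finite")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2 or np.linalg.matrix_rank(Q0, tol=1e-8) < 2:
        warnings.warn("degenerate (collinear) point set; superposition is not unique")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def _paired_coords(structure_a: Structure, structure_b: Structure,
                   selection: Selection | str | None,
                   atom_names: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Resolve a selection in both structures and pair atoms by
    (chain, seq_id, icode, atom name)."""
    sel = selection if isinstance(selection, Selection) else parse_selection(selection)
    keys_a = {(c, r.seq_id, r.insertion_code): r for c, r in select_residues(structure_a, sel)}
    keys_b = {(c, r.seq_id, r.insertion_code): r for c, r in select_residues(structure_b, sel)}
    only_a = sorted(set(keys_a) - set(keys_b))
    only_b = sorted(set(keys_b) - set(keys_a))
    if only_a or only_b:
        raise PairingError(
            f"unpaired residues: {only_a + only_b}", mismatches=only_a + only_b
        )
    pa, pb = [], []
    for key in keys_a:
        ra, rb = keys_a[key], keys_b[key]
        for name in atom_names:
            aa, ab = ra.atom(name), rb.atom(name)
            if aa is not None and ab is not None:
                pa.append(aa.pos)
                pb.append(ab.pos)
    if not pa:
        raise PairingError("selection resolved to no paired atoms")
    return np.array(pa), np.array(pb)


def rmsd_after_superposition(structure_a: Structure, structure_b: Structure,
                             selection: Selection | str | None = None,
                             atom_names: tuple[str, ...] = ("CA",)) -> float:
    """Optimal-superposition RMSD over paired selected atoms (default CA)."""
    pa, pb = _paired_coords(structure_a, structure_b, selection, atom_names)
    return kabsch_superpose(pa, pb).rmsd


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign, range (-180, 180]."""
    b0 = np.asarray(p1, float) - np.asarray(p2, float)
    b1 = np.asarray(p3, float) - np.asarray(p2, float)
    b2 = np.asarray(p4, float) - np.asarray(p3, float)
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


@dataclass
class DihedralProfile:
    """Per-residue phi/psi/omega (degrees); ``None`` marks angles undefined
    at termini or where backbone atoms are missing."""

    seq_ids: list[int]
    phi: list[float | None]
    psi: list[float | None]
    omega: list[float | None]


def backbone_dihedrals(structure: Structure, chain_id: str | None = None) -> DihedralProfile:
    """Backbone torsions for one chain.

    ``omega[i]`` is the peptide torsion CA(i-1)-C(i-1)-N(i)-CA(i), i.e. the
    bond preceding residue *i* (near ±180 for trans peptides).
    """
    if chain_id is None:
        chain_id = structure.first_chain_id()
    residues = [r for r in structure.chains[chain_id]]
    n = len(residues)
    phi: list[float | None] = [None] * n
    psi: list[float | None] = [None] * n
    omega: list[float | None] = [None] * n

    def bb(i: int, name: str):
        a = residues[i].atom(name)
        return None if a is None else a.pos

    for i in range(n):
        N, CA, C = bb(i, "N"), bb(i, "CA"), bb(i, "C")
        if i > 0:
            Cp, CAp = bb(i - 1, "C"), bb(i - 1, "CA")
            if all(p is not None for p in (Cp, N, CA, C)):
                phi[i] = dihedral(Cp, N, CA, C)
            if all(p is not None for p in (CAp, Cp, N, CA)):
                omega[i] = dihedral(CAp, Cp, N, CA)
        if i < n - 1:
            Nn = bb(i + 1, "N")
            if all(p is not None for p in (N, CA, C, Nn)):
                psi[i] = dihedral(N, CA, C, Nn)
    return DihedralProfile([r.seq_id for r in residues], phi, psi, omega)


# ---------------------------------------------------------------------------
# Backbone construction (NeRF internal-coordinate placement)
# ---------------------------------------------------------------------------

def place_atom(a, b, c, bond_length: float, bond_angle_deg: float,
               torsion_deg: float) -> np.ndarray:
    """Place atom d with |c-d| = bond_length, angle(b,c,d) = bond_angle and
    torsion(a,b,c,d) = torsion (natural extension reference frame)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    nv = np.cross(b - a, bc)
    nv /= np.linalg.norm(nv)
    mv = np.cross(nv, bc)
    theta = math.radians(bond_angle_deg)
    chi = math.radians(torsion_deg)
    d_local = bond_length * np.array([
        -math.cos(theta),
        math.sin(theta) * math.cos(chi),
        math.sin(theta) * math.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * mv + d_local[2] * nv


def _residue_from_backbone(seq_id: int, one_letter: str, N, CA, C, O,
                           bfactor: float) -> Residue:
    name3 = AA_1TO3.get(one_letter, "UNK")
    atoms = [
        Atom("N", "N", N, 1.0, bfactor),
        Atom("CA", "C", CA, 1.0, bfactor),
        Atom("C", "C", C, 1.0, bfactor),
        Atom("O", "O", O, 1.0, bfactor),
    ]
    return Residue(seq_id, name3, atoms)


def build_chain_from_torsions(sequence: str,
                              phi: list[float],
                              psi: list[float],
                              omega: list[float] | None = None,
                              start_seq_id: int = 1,
                              chain_id: str = "A",
                              structure_id: str = "built",
                              bfactor: float = 20.0) -> Structure:
    """Build an ideal-geometry backbone (N, CA, C, O) from torsion lists.

    ``phi[0]`` and ``omega[0]`` are undefined for the first residue and are
    ignored; ``psi[-1]`` only orients the final carbonyl.  Bond lengths and
    angles come from :data:`IDEAL_BACKBONE`.
    """
    n = len(sequence)
    if not (len(phi) == len(psi) == n):
        raise ValueError("phi/psi lists must match the sequence length")
    if omega is None:
        omega = [180.0] * n
    g = IDEAL_BACKBONE
    # First residue laid flat in the xy-plane.
    N0 = np.zeros(3)
    CA0 = np.array([g["N-CA"], 0.0, 0.0])
    ang = math.pi - math.radians(g["N-CA-C"])
    C0 = CA0 + g["CA-C"] * np.array([math.cos(ang), math.sin(ang), 0.0])
    Ns, CAs, Cs = [N0], [CA0], [C0]
    for i in range(1, n):
        Ni = place_atom(Ns[-1], CAs[-1], Cs[-1], g["C-N"], g["CA-C-N"], psi[i - 1])
        CAi = place_atom(CAs[-1], Cs[-1], Ni, g["N-CA"], g["C-N-CA"], omega[i])
        Ci = place_atom(Cs[-1], Ni, CAi, g["CA-C"], g["N-CA-C"], phi[i])
        Ns.append(Ni)
        CAs.append(CAi)
        Cs.append(Ci)
    st = Structure(id=structure_id)
    for i in range(n):
        O = place_atom(Ns[i], CAs[i], Cs[i], g["C-O"], g["CA-C-O"], psi[i] + 180.0)
        st.add_residue(chain_id, _residue_from_backbone(
            start_seq_id + i, sequence[i], Ns[i], CAs[i], Cs[i], O, bfactor))
    return st


def extend_backbone(prev_residue: Residue, sequence: str,
                    phi: list[float], psi: list[float],
                    psi_prev: float,
                    omega: list[float] | None = None,
                    start_seq_id: int = 1,
                    bfactor: float = 20.0) -> list[Residue]:
    """Continue a backbone from an existing residue by NeRF placement.

    ``psi_prev`` is the psi torsion assigned to the junction residue (it
    orients the first new N).  Returns the new residues only.
    """
    n = len(sequence)
    if omega is None:
        omega = [180.0] * n
    g = IDEAL_BACKBONE
    Np, CAp, Cp = (prev_residue.atom(x).pos for x in ("N", "CA", "C"))
    Ns, CAs, Cs = [], [], []
    for i in range(n):
        psi_before = psi_prev if i == 0 else psi[i - 1]
        Ni = place_atom(Np, CAp, Cp, g["C-N"], g["CA-C-N"], psi_before)
        CAi = place_atom(CAp, Cp, Ni, g["N-CA"], g["C-N-CA"], omega[i])
        Ci = place_atom(Cp, Ni, CAi, g["CA-C"], g["N-CA-C"], phi[i])
        Ns.append(Ni)
        CAs.append(CAi)
        Cs.append(Ci)
        Np, CAp, Cp = Ni, CAi, Ci
    out = []
    for i in range(n):
        O = place_atom(Ns[i], CAs[i], Cs[i], g["C-O"], g["CA-C-O"], psi[i] + 180.0)
        out.append(_residue_from_backbone(
            start_seq_id + i, sequence[i], Ns[i], CAs[i], Cs[i], O, bfactor))
    return out


@dataclass
class IdealHelixParams:
    """Parameters for an ideal helix: type (alpha | three10), torsions and
    length.  Defaults to the canonical textbook torsions for the type."""

    helix_type: str = "alpha"
    n_residues: int = 11
    phi: float | None = None
    psi: float | None = None

    def __post_init__(self):
        if self.helix_type not in CANONICAL_HELIX_TORSIONS:
            from .errors import ConfigError
            raise ConfigError(f"unknown helix type {self.helix_type!r}")
        if self.n_residues < 4:
            raise ValueError("a helix needs at least 4 residues")
        ph, ps = CANONICAL_HELIX_TORSIONS[self.helix_type]
        if self.phi is None:
            self.phi = ph
        if self.psi is None:
            self.psi = ps


def build_ideal_helix(params: IdealHelixParams, sequence: str | None = None) -> Structure:
    """Build an ideal α- or 3₁₀-helix backbone from canonical torsions."""
    if sequence is None:
        sequence = "A" * params.n_residues
    if len(sequence) != params.n_residues:
        raise ValueError("sequence length must equal n_residues")
    n = params.n_residues
    return build_chain_from_torsions(
        sequence, [params.phi] * n, [params.psi] * n,
        structure_id=f"ideal_{params.helix_type}_{n}")


# ---------------------------------------------------------------------------
# Clash and continuity checks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRef:
    chain: str
    seq_id: int
    insertion_code: str
    atom_name: str


@dataclass
class Clash:
    a: AtomRef
    b: AtomRef
    distance: float


def detect_clashes(structure: Structure, cutoff: float = 2.5,
                   exclude_bonded_within: int = 1) -> list[Clash]:
    """All heavy-atom pairs closer than ``cutoff`` Å.

    Pairs on the same chain whose residue indices (position in chain order)
    differ by at most ``exclude_bonded_within`` are excluded — by default
    same and adjacent residues, which covers covalent neighbours.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    refs: list[AtomRef] = []
    coords = []
    chain_pos: list[tuple[str, int]] = []  # (chain id, residue index in chain)
    for cid, residues in structure.chains.items():
        for idx, r in enumerate(residues):
            for a in r.atoms:
                if a.is_hydrogen:
                    continue
                refs.append(AtomRef(cid, r.seq_id, r.insertion_code, a.name))
                coords.append(a.pos)
                chain_pos.append((cid, idx))
    if not coords:
        return []
    tree = cKDTree(np.array(coords))
    clashes = []
    for i, j in sorted(tree.query_pairs(cutoff)):
        ci, cj = chain_pos[i], chain_pos[j]
        if ci[0] == cj[0] and abs(ci[1] - cj[1]) <= exclude_bonded_within:
            continue
        d = float(np.linalg.norm(np.asarray(coords[i]) - np.asarray(coords[j])))
        clashes.append(Clash(refs[i], refs[j], d))
    return clashes


@dataclass
class ContinuityIssue:
    seq_id_a: int
    seq_id_b: int
    distance: float | None  # None when unassessable
    kind: str  # "break" | "unassessable"


def check_backbone_continuity(structure: Structure, chain_id: str | None = None,
                              tolerance: float = 0.2) -> list[ContinuityIssue]:
    """Flag consecutive residue pairs whose C(i)-N(i+1) distance deviates
    from the ideal peptide bond (1.33 Å) by more than ``tolerance``.

    Pairs missing a C or N atom are reported as unassessable, not breaks.
    """
    if chain_id is None:
        chain_id = structure.first_chain_id()
    residues = structure.chains[chain_id]
    ideal = IDEAL_BACKBONE["C-N"]
    issues = []
    for r1, r2 in zip(residues, residues[1:]):
        c, n = r1.atom("C"), r2.atom("N")
        if c is None or n is None:
            issues.append(ContinuityIssue(r1.seq_id, r2.seq_id, None, "unassessable"))
            continue
        d = float(np.linalg.norm(c.pos - n.pos))
        if abs(d - ideal) > tolerance:
            issues.append(ContinuityIssue(r1.seq_id, r2.seq_id, d, "break"))
    return issues
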