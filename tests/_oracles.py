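"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the RMSD
oracle solves the superposition problem via the quaternion
characteristic-polynomial eigenvalue method instead of SVD, and the motif
oracle checks run-lengths by explicit run-length encoding instead of a
regular expression.
"""

import itertools

import numpy as np


def quaternion_rmsd(P, Q):
    """Minimal RMSD of paired point sets via the largest eigenvalue of the
    quaternion key matrix (Theobald-style formulation)."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    n = P.shape[0]
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    M = P0.T @ Q0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    g = (P0 ** 2).sum() + (Q0 ** 2).sum()
    return float(np.sqrt(max(g - 2.0 * lam, 0.0) / n))


def runs(labels):
    """Run-length encoding: [(char, length), ...]."""
    return [(c, len(list(g))) for c, g in itertools.groupby(labels)]


def motif_oracle(labels, helix_min=4, helix_max=8, flank_min=2, flank_max=3):
    """Direct run-length check of the coil-helix-coil motif with maximal-run
    semantics (independent of the regex matcher)."""
    r = runs(labels)
    for i in range(1, len(r) - 1):
        c, n = r[i]
        if c != "H" or not (helix_min <= n <= helix_max):
            continue
        (cl, nl), (cr, nr) = r[i - 1], r[i + 1]
        if cl == "C" and cr == "C" and flank_min <= nl <= flank_max \
                and flank_min <= nr <= flank_max:
            return True
    return False


def brute_force_close_pairs(coords, cutoff):
    """All index pairs (i < j) with distance < cutoff, by full O(n²) scan."""
    coords = np.asarray(coords, float)
    out = set()
    for i in range(len(coords)):
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        for j in np.nonzero(d < cutoff)[0]:
            out.add((i, i + 1 + int(j)))
    return out
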