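"""Rigid superposition and TM-score structural similarity.

Mode alignment compares deformation vector fields of two proteins placed in
a common frame, so every structure pair is superposed first.  The route here
is sequence-guided: a global alignment of the C-alpha sequences seeds a
residue correspondence, Kabsch least-squares fitting and distance-based
pruning of the correspondence are iterated with a shrinking cutoff, and the
transform with the best TM-score across iterations is kept.  Rotation
matrices produced by external structure-alignment tools can be imported
instead (:func:`load_external_superposition`).

TM-score is normalised here by the shorter structure's C-alpha count, giving
a single symmetric scalar per pair:

    TM = (1/L) * sum_i 1 / (1 + (d_i/d0)^2),   d0 = 1.24 (L-15)^(1/3) - 1.8

with d0 floored at 0.5 Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import NodeModel


class SuperpositionError(Exception):
    """Base class for superposition failures."""


class DegenerateSuperpositionError(SuperpositionError):
    """Fewer than 3 corresponded pairs, or collinear points."""


class SuperpositionFailure(SuperpositionError):
    """Iterative superposition collapsed: structurally dissimilar inputs."""


@dataclass
class Superposition:
    """A proper rigid transform mapping structure A onto structure B.

    ``transform`` applies ``x -> x @ rotation.T + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    correspondence: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    rmsd: float = np.nan
    tm_score: float = np.nan

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.correspondence = np.asarray(self.correspondence, dtype=int).reshape(-1, 2)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-4):
            raise DegenerateSuperpositionError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise DegenerateSuperpositionError("improper rotation (det = -1)")

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Superposition":
        return cls(np.eye(3), np.zeros(3), rmsd=0.0, tm_score=1.0)


# ---------------------------------------------------------------------------
# sequence alignment (seed correspondence)
# ---------------------------------------------------------------------------

def align_sequences(seq_a: str, seq_b: str, match: float = 1.0,
                    mismatch: float = 0.0, gap: float = -0.5) -> np.ndarray:
    """Global alignment with a linear gap penalty; returns matched columns.

    Ties in the traceback prefer diagonal, then up (gap in B), then left.
    The result is an (m, 2) array of index pairs, strictly increasing in
    both coordinates.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    na, nb = len(seq_a), len(seq_b)
    H = np.empty((na + 1, nb + 1))
    H[0, :] = gap * np.arange(nb + 1)
    H[:, 0] = gap * np.arange(na + 1)
    sub = np.empty((na, nb))
    a_arr = np.frombuffer(seq_a.encode("latin1"), dtype=np.uint8)
    b_arr = np.frombuffer(seq_b.encode("latin1"), dtype=np.uint8)
    eq = a_arr[:, None] == b_arr[None, :]
    sub[:] = np.where(eq, match, mismatch)
    for i in range(1, na + 1):
        H[i, 1:] = H[i - 1, :-1] + sub[i - 1]
        np.maximum(H[i, 1:], H[i - 1, 1:] + gap, out=H[i, 1:])
        # left moves depend on earlier cells of the same row: scalar pass
        row = H[i]
        for j in range(1, nb + 1):
            left = row[j - 1] + gap
            if left > row[j]:
                row[j] = left
    pairs = []
    i, j = na, nb
    while i > 0 and j > 0:
        if H[i, j] == H[i - 1, j - 1] + sub[i - 1, j - 1]:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    return np.array(pairs[::-1], dtype=int).reshape(-1, 2)


# ---------------------------------------------------------------------------
# Kabsch and TM-score
# ---------------------------------------------------------------------------

def kabsch(coords_a: np.ndarray, coords_b: np.ndarray,
           correspondence: np.ndarray) -> Superposition:
    """Least-squares proper rigid transform of A onto B over corresponded pairs."""
    corr = np.asarray(correspondence, dtype=int).reshape(-1, 2)
    if len(corr) < 3:
        raise DegenerateSuperpositionError("need >= 3 corresponded pairs")
    A = np.asarray(coords_a, dtype=float)[corr[:, 0]]
    B = np.asarray(coords_b, dtype=float)[corr[:, 1]]
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    s = np.linalg.svd(A0, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise DegenerateSuperpositionError("corresponded points are collinear")
    U, _, Vt = np.linalg.svd(B0.T @ A0)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    t = cb - R @ ca
    rmsd = float(np.sqrt(np.mean(np.sum((A0 @ R.T - B0) ** 2, axis=1))))
    return Superposition(R, t, corr, rmsd=rmsd)


def tm_d0(l_norm: int) -> float:
    """TM-score distance scale d0 for normalisation length l_norm."""
    if l_norm < 1:
        raise ValueError("l_norm must be >= 1")
    return max(0.5, 1.24 * np.cbrt(l_norm - 15.0) - 1.8)


def tm_score(coords_a: np.ndarray, coords_b: np.ndarray,
             correspondence: np.ndarray, superposition: Superposition | None,
             l_norm: int) -> float:
    """TM-score of the corresponded pairs under the given transform."""
    corr = np.asarray(correspondence, dtype=int).reshape(-1, 2)
    A = np.asarray(coords_a, dtype=float)[corr[:, 0]]
    if superposition is not None:
        A = superposition.transform(A)
    B = np.asarray(coords_b, dtype=float)[corr[:, 1]]
    d0 = tm_d0(l_norm)
    d2 = np.sum((A - B) ** 2, axis=1)
    return float(np.sum(1.0 / (1.0 + d2 / d0**2)) / l_norm)


# ---------------------------------------------------------------------------
# iterative superposition
# ---------------------------------------------------------------------------

def superpose_iterative(nodes_a: NodeModel, nodes_b: NodeModel,
                        max_iter: int = 20, cutoff_start: float = 8.0,
                        cutoff_end: float = 4.0) -> Superposition:
    """Sequence-seeded iterative Kabsch superposition maximising TM-score.

    The seed correspondence comes from a global sequence alignment of the
    C-alpha nodes; each iteration refits on the current pair subset and
    keeps seed pairs within a linearly shrinking distance cutoff
    (``cutoff_start`` -> ``cutoff_end`` Å).  The transform with the highest
    TM-score (normalised by the shorter C-alpha count) is returned.
    """
    ca_a = np.flatnonzero(nodes_a.ca_mask)
    ca_b = np.flatnonzero(nodes_b.ca_mask)
    if len(ca_a) < 7 or len(ca_b) < 7:
        raise DegenerateSuperpositionError("need >= 7 C-alpha nodes per structure")
    seed = align_sequences(nodes_a.sequence(), nodes_b.sequence())
    if len(seed) < 3:
        raise SuperpositionFailure("seed correspondence below 3 pairs")
    seed_global = np.column_stack([ca_a[seed[:, 0]], ca_b[seed[:, 1]]])
    A, B = nodes_a.coords, nodes_b.coords
    l_norm = min(len(ca_a), len(ca_b))
    cutoffs = np.linspace(cutoff_start, cutoff_end, max_iter)
    corr = seed_global
    best: Superposition | None = None
    for cut in cutoffs:
        if len(corr) < 3:
            break
        sup = kabsch(A, B, corr)
        tm = tm_score(A, B, seed_global, sup, l_norm)
        if best is None or tm > best.tm_score:
            sup.tm_score = tm
            best = sup
        d = np.linalg.norm(sup.transform(A[seed_global[:, 0]])
                           - B[seed_global[:, 1]], axis=1)
        new_corr = seed_global[d <= cut]
        if len(new_corr) == len(corr) and np.array_equal(new_corr, corr) \
                and cut == cutoffs[-1]:
            break
        corr = new_corr
    if best is None:
        raise SuperpositionFailure(
            "correspondence collapsed below 3 pairs; inputs are structurally "
            "too dissimilar to superpose")
    return best


# ---------------------------------------------------------------------------
# external transforms
# ---------------------------------------------------------------------------

def save_superposition(sup: Superposition, path) -> None:
    """Write the transform as 3 rows of ``t_i r_i1 r_i2 r_i3`` (full precision)."""
    with open(path, "w") as fh:
        for i in range(3):
            fh.write("%.17g %.17g %.17g %.17g\n" % (
                sup.translation[i], *sup.rotation[i]))


def load_external_superposition(path) -> Superposition:
    """Read a rotation-matrix file in the ``t_i r_i1 r_i2 r_i3`` layout.

    Validates orthonormality and det = +1 (within 1e-4); the returned
    superposition is transform-only (empty correspondence).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                continue
            try:
                rows.append([float(v) for v in fields[:4]])
            except ValueError as exc:
                raise SuperpositionError(
                    f"malformed matrix line in {path}: {line!r}") from exc
    if len(rows) != 3:
        raise SuperpositionError(
            f"{path}: expected 3 numeric rows 't r1 r2 r3', got {len(rows)}")
    m = np.array(rows)
    rot, trans = m[:, 1:4], m[:, 0]
    if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-4):
        raise SuperpositionError(f"{path}: rotation is not orthonormal")
    if np.linalg.det(rot) < 1.0 - 1e-4:
        raise SuperpositionError(f"{path}: improper rotation (det != +1)")
    return Superposition(rot, trans)
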