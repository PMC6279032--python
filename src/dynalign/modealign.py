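"""Local alignment of slow modes and the dynamics similarity score (DSS).

Two superposed proteins A and B are compared through their slowest n
non-trivial ANM modes.  For a mode pair (k of A, l of B) every residue pair
(i, j) is scored by the cosine of the angle between the two deformation
vectors, shifted by a similarity threshold C:

    S_ij = u_ik . v_jl / (|u_ik| |v_jl|) - C            (0 <= C <= 1)

and, with distance constraints enabled (the default, appropriate for
homologous or identical proteins), S_ij is clamped to -1 whenever the
superposed inter-node distance r_ij exceeds a cutoff R_c:

    S_ij = cosine - C   if r_ij <= R_c,   else  -1

From each mode-pair score matrix the best non-overlapping gapless diagonal
segments ("matches") of length >= 7 with positive total score are extracted
greedily, up to 200 per matrix.  Mode sign is arbitrary, so each pair is
aligned with both orientations of the second mode and the better one kept.
The 2n best-scoring matches over all n x n mode combinations are pooled; for
each residue and mode combination the best covered score is kept, summed
into per-residue similarity profiles, and the mean profile of both proteins,
averaged, is the scalar DSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from .anm import ModeSet


class ModeAlignError(Exception):
    """Contract violation in mode alignment."""


@dataclass
class AlignParams:
    """Tunable mode-alignment parameters.

    C: cosine similarity threshold subtracted from every cosine.
    r_c: distance constraint in Å (superposed inter-node distance).
    n_modes: number of slowest non-trivial modes aligned (n).
    min_len: minimal gapless match length in residues.
    max_matches_per_pair: cap on matches kept per mode-pair matrix.
    use_distance_constraint: apply the R_c clamp (disable for
        non-homologous comparisons).
    sign_rule: how the orientation of the second mode is chosen —
        "best_match" compares the best single match of each orientation,
        "total" compares summed match scores.
    """

    C: float = 0.7
    r_c: float = 10.0
    n_modes: int = 12
    min_len: int = 7
    max_matches_per_pair: int = 200
    use_distance_constraint: bool = True
    sign_rule: str = "best_match"

    def __post_init__(self):
        if not 0.0 <= self.C <= 1.0:
            raise ValueError("C must be in [0, 1]")
        if self.min_len < 1 or self.n_modes < 1:
            raise ValueError("min_len and n_modes must be >= 1")
        if self.sign_rule not in ("best_match", "total"):
            raise ValueError("sign_rule must be 'best_match' or 'total'")


@dataclass
class ScoreMatrix:
    """S_ij over all node pairs for one mode combination and sign."""

    matrix: np.ndarray
    mode_k: int = 0
    mode_l: int = 0
    sign: int = 1


@dataclass
class Match:
    """A gapless diagonal segment of a mode-pair score matrix."""

    mode_k: int
    mode_l: int
    sign: int
    i_start: int
    j_start: int
    length: int
    cell_scores: np.ndarray
    score: float
    selected: bool = False


@dataclass
class DssResult:
    """Selected matches, per-residue similarity profiles, and the scalar DSS."""

    matches: list
    profile_a: np.ndarray
    profile_b: np.ndarray
    dss: float
    params: AlignParams = field(default_factory=AlignParams)

    @property
    def selected_matches(self) -> list:
        return [m for m in self.matches if m.selected]


# ---------------------------------------------------------------------------
# per-cell scores
# ---------------------------------------------------------------------------

def residue_score(u: np.ndarray, v: np.ndarray, C: float = 0.7) -> float:
    """Cosine-minus-threshold score of two deformation vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ModeAlignError("zero-length deformation vector has no direction")
    return float(np.dot(u, v) / (nu * nv) - C)


def constrained_score(u: np.ndarray, v: np.ndarray, r_ij: float,
                      C: float = 0.7, r_c: float = 10.0) -> float:
    """Distance-constrained score: -1 beyond R_c, else the plain score."""
    if r_ij < 0:
        raise ValueError("distance must be non-negative")
    if r_ij > r_c:
        return -1.0
    return residue_score(u, v, C)


def score_matrix(mode_a: np.ndarray, mode_b: np.ndarray,
                 coords_a: np.ndarray, coords_b: np.ndarray,
                 sign: int = 1, params: AlignParams | None = None,
                 mode_k: int = 0, mode_l: int = 0) -> ScoreMatrix:
    """S_ij over all node pairs for one mode combination and sign.

    ``mode_a``/``mode_b`` are (N, 3) per-node deformation fields; coordinates
    must already be in the common superposed frame.  Nodes with a zero
    deformation vector score -1 against everything (unalignable direction).
    """
    params = params or AlignParams()
    Ua = np.asarray(mode_a, dtype=float)
    Vb = np.asarray(mode_b, dtype=float) * sign
    ca = np.asarray(coords_a, dtype=float)
    cb = np.asarray(coords_b, dtype=float)
    if Ua.shape != ca.shape or Vb.shape != cb.shape:
        raise ModeAlignError("mode and coordinate shapes disagree")
    na_norm = np.linalg.norm(Ua, axis=1)
    nb_norm = np.linalg.norm(Vb, axis=1)
    za, zb = na_norm == 0.0, nb_norm == 0.0
    Ua_hat = np.divide(Ua, np.where(za, 1.0, na_norm)[:, None])
    Vb_hat = np.divide(Vb, np.where(zb, 1.0, nb_norm)[:, None])
    S = Ua_hat @ Vb_hat.T - params.C
    if za.any():
        S[za, :] = -1.0
    if zb.any():
        S[:, zb] = -1.0
    if params.use_distance_constraint:
        S[cdist(ca, cb) > params.r_c] = -1.0
    return ScoreMatrix(matrix=S, mode_k=mode_k, mode_l=mode_l, sign=sign)


# ---------------------------------------------------------------------------
# gapless match extraction
# ---------------------------------------------------------------------------

@njit(cache=True)
def _best_segment(S, row_masked, col_masked, min_len):  # pragma: no cover
    """Best positive diagonal segment of unmasked cells, length >= min_len.

    Ties broken by smallest (i0, j0) lexicographically, then shortest.
    Returns (score, i0, j0, length); length 0 when no qualifying segment.
    """
    na, nb = S.shape
    lmax = min(na, nb)
    P = np.empty(lmax + 1)
    best_score = 0.0
    bi = -1
    bj = -1
    bl = 0
    found = False
    for d in range(-(na - 1), nb):
        if d >= 0:
            i0, j0 = 0, d
        else:
            i0, j0 = -d, 0
        t = 0
        while i0 + t < na and j0 + t < nb:
            if row_masked[i0 + t] or col_masked[j0 + t]:
                t += 1
                continue
            rs = t
            P[0] = 0.0
            L = 0
            while (i0 + t < na and j0 + t < nb and
                   not row_masked[i0 + t] and not col_masked[j0 + t]):
                P[L + 1] = P[L] + S[i0 + t, j0 + t]
                L += 1
                t += 1
            if L < min_len:
                continue
            minP = P[0]
            min_s = 0
            for e in range(min_len, L + 1):
                s_new = e - min_len
                if P[s_new] < minP:
                    minP = P[s_new]
                    min_s = s_new
                sc = P[e] - minP
                if sc <= 0.0:
                    continue
                ci = i0 + rs + min_s
                cj = j0 + rs + min_s
                cl = e - min_s
                if (not found) or sc > best_score or (
                        sc == best_score and
                        (ci < bi or (ci == bi and
                                     (cj < bj or (cj == bj and cl < bl))))):
                    best_score = sc
                    bi = ci
                    bj = cj
                    bl = cl
                    found = True
    return best_score, bi, bj, bl


def extract_matches(S, params: AlignParams | None = None) -> list[Match]:
    """Greedy extraction of the best non-overlapping gapless matches.

    Repeatedly takes the highest-scoring diagonal segment (length >=
    ``min_len``, total score > 0; ties by smallest (i0, j0), then shortest)
    and masks its rows and columns, until no qualifying segment remains or
    ``max_matches_per_pair`` is reached.  Matches are returned sorted by
    total score descending (stable, so extraction order breaks ties).
    """
    params = params or AlignParams()
    if isinstance(S, ScoreMatrix):
        mat, mk, ml, sign = S.matrix, S.mode_k, S.mode_l, S.sign
    else:
        mat, mk, ml, sign = np.asarray(S, dtype=float), 0, 0, 1
    na, nb = mat.shape
    row_masked = np.zeros(na, dtype=np.bool_)
    col_masked = np.zeros(nb, dtype=np.bool_)
    matches: list[Match] = []
    while len(matches) < params.max_matches_per_pair:
        score, i0, j0, length = _best_segment(mat, row_masked, col_masked,
                                              params.min_len)
        if length == 0:
            break
        cells = mat[np.arange(i0, i0 + length), np.arange(j0, j0 + length)].copy()
        matches.append(Match(mk, ml, sign, int(i0), int(j0), int(length),
                             cells, float(score)))
        row_masked[i0:i0 + length] = True
        col_masked[j0:j0 + length] = True
    matches.sort(key=lambda m: -m.score)
    return matches


def align_mode_pair(mode_a: np.ndarray, mode_b: np.ndarray,
                    coords_a: np.ndarray, coords_b: np.ndarray,
                    params: AlignParams | None = None,
                    mode_k: int = 0, mode_l: int = 0) -> tuple[int, list[Match]]:
    """Align one mode pair with both orientations of the second mode.

    The orientation whose best single match scores higher (or, with
    ``sign_rule="total"``, whose matches sum higher) is kept; ties keep +1.
    """
    params = params or AlignParams()
    results = {}
    for sign in (1, -1):
        sm = score_matrix(mode_a, mode_b, coords_a, coords_b, sign=sign,
                          params=params, mode_k=mode_k, mode_l=mode_l)
        results[sign] = extract_matches(sm, params)
    if params.sign_rule == "best_match":
        key = {s: (ms[0].score if ms else 0.0) for s, ms in results.items()}
    else:
        key = {s: sum(m.score for m in ms) for s, ms in results.items()}
    sign = 1 if key[1] >= key[-1] else -1
    return sign, results[sign]


# ---------------------------------------------------------------------------
# DSS
# ---------------------------------------------------------------------------

def _mode_vectors(modes, n: int) -> np.ndarray:
    if isinstance(modes, ModeSet):
        if modes.n_modes < n:
            raise ModeAlignError(
                f"need >= {n} non-trivial modes, have {modes.n_modes}")
        return modes.vectors[:n]
    arr = np.asarray(modes, dtype=float)
    if arr.shape[0] < n:
        raise ModeAlignError(f"need >= {n} non-trivial modes, have {arr.shape[0]}")
    return arr[:n]


def _canonical_key(vectors: np.ndarray, coords: np.ndarray) -> tuple:
    return (coords.shape[0], coords.tobytes(), vectors.tobytes())


def compute_dss(modes_a, modes_b, coords_a: np.ndarray, coords_b: np.ndarray,
                params: AlignParams | None = None) -> DssResult:
    """Dynamics similarity score between two superposed proteins.

    All n x n mode combinations are aligned; the 2n matches with the highest
    total score are selected from the global pool (ties by (k, l, i0, j0));
    for each mode combination and residue the best covered S_ij is kept and
    summed into per-residue profiles r1 (protein A) and r2 (protein B);
    residues covered by no selected match contribute 0.  DSS is
    (mean r1 + mean r2) / 2.

    The computation is argument-order canonicalised internally, so
    DSS(A, B) == DSS(B, A) exactly even when score ties occur.
    """
    params = params or AlignParams()
    n = params.n_modes
    va = _mode_vectors(modes_a, n)
    vb = _mode_vectors(modes_b, n)
    ca = np.ascontiguousarray(coords_a, dtype=float)
    cb = np.ascontiguousarray(coords_b, dtype=float)
    swapped = _canonical_key(vb, cb) < _canonical_key(va, ca)
    if swapped:
        va, vb, ca, cb = vb, va, cb, ca

    pool: list[Match] = []
    for k in range(n):
        for l in range(n):
            _, ms = align_mode_pair(va[k], vb[l], ca, cb, params,
                                    mode_k=k, mode_l=l)
            pool.extend(ms)
    pool.sort(key=lambda m: (-m.score, m.mode_k, m.mode_l, m.i_start, m.j_start))
    for m in pool:
        m.selected = False
    for m in pool[:2 * n]:
        m.selected = True

    na, nb = len(ca), len(cb)
    r1 = np.zeros(na)
    r2 = np.zeros(nb)
    # per combination, best covered cell per residue (−inf = uncovered)
    best1: dict[tuple, np.ndarray] = {}
    best2: dict[tuple, np.ndarray] = {}
    for m in pool[:2 * n]:
        key = (m.mode_k, m.mode_l)
        b1 = best1.setdefault(key, np.full(na, -np.inf))
        b2 = best2.setdefault(key, np.full(nb, -np.inf))
        rows = np.arange(m.i_start, m.i_start + m.length)
        cols = np.arange(m.j_start, m.j_start + m.length)
        np.maximum.at(b1, rows, m.cell_scores)
        np.maximum.at(b2, cols, m.cell_scores)
    for b1 in best1.values():
        r1 += np.where(np.isfinite(b1), b1, 0.0)
    for b2 in best2.values():
        r2 += np.where(np.isfinite(b2), b2, 0.0)
    dss = float((r1.mean() + r2.mean()) / 2.0)

    matches = pool
    if swapped:
        matches = [Match(m.mode_l, m.mode_k, m.sign, m.j_start, m.i_start,
                         m.length, m.cell_scores, m.score, m.selected)
                   for m in pool]
        r1, r2 = r2, r1
    return DssResult(matches=matches, profile_a=r1, profile_b=r2, dss=dss,
                     params=params)


def residue_profiles(result: DssResult, nodes_a=None, nodes_b=None):
    """Per-residue similarity tables for both proteins as DataFrames."""
    import pandas as pd

    def table(profile, nodes):
        if nodes is not None:
            return pd.DataFrame({"chain": nodes.chain_ids,
                                 "residue": nodes.res_labels,
                                 "kind": nodes.kinds,
                                 "r_score": profile})
        return pd.DataFrame({"node": np.arange(len(profile)),
                             "r_score": profile})

    return table(result.profile_a, nodes_a), table(result.profile_b, nodes_b)


def write_match_table(result: DssResult, path) -> None:
    """Match table TSV: mode_k, mode_l, sign, i_start, j_start, length, score, selected."""
    import pandas as pd
    pd.DataFrame([{"mode_k": m.mode_k, "mode_l": m.mode_l, "sign": m.sign,
                   "i_start": m.i_start, "j_start": m.j_start,
                   "length": m.length, "score": m.score,
                   "selected": int(m.selected)} for m in result.matches]
                 ).to_csv(path, sep="\t", index=False, float_format="%.6f")
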