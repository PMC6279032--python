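"""Anisotropic network model: Hessian construction and slow-mode extraction.

Each node is a unit mass connected by uniform springs (force constant
``gamma``) to every node within a distance cutoff (default 15 Å).  The
3N x 3N Hessian uses the distance-normalised projector convention: the
off-diagonal super-element for a connected pair i, j is

    H_ij = -(gamma / d_ij^2) * outer(r_ij, r_ij)

and diagonal super-elements are the negated sums of their row's
off-diagonals, which enforces translation invariance.  A connected,
non-collinear network has exactly six zero (rigid-body) eigenvalues; the
slowest non-trivial eigenvectors are the collective motions that mode
alignment compares.  The downstream similarity score normalises every
per-residue deformation vector, so the spring-constant convention does not
affect it — it is fixed here only so eigenvalues are testable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structure_io import EmptySelectionError, NodeModel

#: Relative tolerance below which an eigenvalue counts as a rigid-body mode.
TRIVIAL_TOL = 1e-8


class AnmError(Exception):
    """Base class for elastic-network failures."""


class DegenerateGeometryError(AnmError):
    """Coincident nodes make the spring network ill-defined."""


class DisconnectedNetworkError(AnmError):
    """More than 6 near-zero eigenvalues: disconnected or degenerate network."""


@dataclass
class Hessian:
    """Sparse ANM Hessian with its construction parameters."""

    matrix: sp.csr_matrix
    cutoff: float
    gamma: float
    n_nodes: int
    nodes: NodeModel

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


@dataclass
class ModeSet:
    """Slowest non-trivial modes: eigenvalues ascending, unit eigenvectors.

    ``vectors`` has shape (n_modes, N, 3): per-node deformation 3-vectors of
    each full unit-norm eigenvector.
    """

    eigenvalues: np.ndarray
    vectors: np.ndarray
    nodes: NodeModel
    n_trivial_removed: int = 6

    def __post_init__(self):
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 3:
            raise AnmError("vectors must have shape (n_modes, N, 3)")

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def take(self, n: int) -> "ModeSet":
        """The n slowest modes of this set."""
        if n > self.n_modes:
            raise AnmError(f"requested {n} modes, have {self.n_modes}")
        return replace(self, eigenvalues=self.eigenvalues[:n],
                       vectors=self.vectors[:n])


def _contact_pairs(coords: np.ndarray, cutoff: float) -> np.ndarray:
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs.reshape(-1, 2)


def build_hessian(nodes: NodeModel, cutoff: float = 15.0,
                  gamma: float = 1.0) -> Hessian:
    """Assemble the sparse ANM Hessian over all node pairs within ``cutoff``."""
    coords = nodes.coords
    n = len(coords)
    if n < 2:
        raise AnmError("need at least 2 nodes")
    pairs = _contact_pairs(coords, cutoff)
    rvec = coords[pairs[:, 1]] - coords[pairs[:, 0]]
    d2 = np.sum(rvec**2, axis=1)
    if np.any(d2 < 1e-12):
        bad = pairs[d2 < 1e-12][0]
        raise DegenerateGeometryError(
            f"coincident nodes {bad[0]} and {bad[1]} (distance < 1e-6 A)")
    # super-element blocks, one (3,3) per contact
    blocks = -(gamma / d2)[:, None, None] * (rvec[:, :, None] * rvec[:, None, :])
    m = len(pairs)
    ii = np.repeat(pairs[:, 0] * 3, 9) + np.tile(np.repeat(np.arange(3), 3), m)
    jj = np.repeat(pairs[:, 1] * 3, 9) + np.tile(np.tile(np.arange(3), 3), m)
    data = blocks.reshape(-1)
    rows = np.concatenate([ii, jj])  # symmetric: (i,j) and (j,i)
    cols = np.concatenate([jj, ii])
    vals = np.concatenate([data, data])
    # diagonal blocks: negated sums of the row's off-diagonal blocks
    diag = np.zeros((n, 3, 3))
    np.add.at(diag, pairs[:, 0], -blocks)
    np.add.at(diag, pairs[:, 1], -blocks)
    di = np.repeat(np.arange(n) * 3, 9) + np.tile(np.repeat(np.arange(3), 3), n)
    dj = np.repeat(np.arange(n) * 3, 9) + np.tile(np.tile(np.arange(3), 3), n)
    rows = np.concatenate([rows, di])
    cols = np.concatenate([cols, dj])
    vals = np.concatenate([vals, diag.reshape(-1)])
    H = sp.coo_matrix((vals, (rows, cols)), shape=(3 * n, 3 * n)).tocsr()
    return Hessian(matrix=H, cutoff=cutoff, gamma=gamma, n_nodes=n, nodes=nodes)


def check_connectivity(nodes: NodeModel, cutoff: float = 15.0) -> np.ndarray:
    """Connected-component label per node under the cutoff contact graph."""
    n = len(nodes)
    pairs = _contact_pairs(nodes.coords, cutoff)
    adj = sp.coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                        shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def slow_modes(hessian: Hessian, n_keep: int = 40,
               method: str = "auto") -> ModeSet:
    """Extract the ``n_keep`` slowest non-trivial modes.

    ``method``: "dense" (full eigendecomposition), "lanczos" (shift-invert
    partial solver), or "auto" (dense below 3N = 900).  Exactly six
    eigenvalues must fall below the trivial-mode tolerance; more indicates a
    disconnected or degenerate network and raises.
    """
    H = hessian.matrix
    dim = H.shape[0]
    k = n_keep + 6
    if k > dim:
        raise AnmError(f"n_keep + 6 = {k} exceeds 3N = {dim}")
    if method == "auto":
        method = "dense" if dim <= 900 else "lanczos"
    if method == "dense" or k == dim:
        evals, evecs = np.linalg.eigh(H.toarray())
        evals, evecs = evals[:k], evecs[:, :k]
    elif method == "lanczos":
        scale = float(np.abs(H.diagonal()).max())
        try:
            evals, evecs = sp.linalg.eigsh(H.tocsc(), k=k, sigma=-1e-4 * scale,
                                           which="LM")
        except sp.linalg.ArpackNoConvergence as exc:
            raise AnmError(f"partial eigensolver did not converge: {exc}") from exc
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]
    else:
        raise ValueError(f"unknown method {method!r}")
    tol = TRIVIAL_TOL * float(evals[-1])
    n_trivial = int(np.sum(evals < tol))
    if n_trivial != 6:
        raise DisconnectedNetworkError(
            f"expected exactly 6 trivial modes, found {n_trivial}: "
            "network is disconnected or degenerate")
    evals = evals[6:]
    evecs = evecs[:, 6:]
    evecs = evecs / np.linalg.norm(evecs, axis=0)
    return ModeSet(eigenvalues=evals,
                   vectors=evecs.T.reshape(n_keep, hessian.n_nodes, 3),
                   nodes=hessian.nodes, n_trivial_removed=6)


def restrict_modes(modes: ModeSet, chains) -> ModeSet:
    """Keep only the mode components on the given chain(s).

    Eigenvalues and mode identity are preserved and the clipped vectors are
    deliberately NOT re-normalised: the similarity score normalises each
    per-residue 3-vector, so global vector scale is irrelevant, while
    re-normalising would silently change exported mode amplitudes.
    """
    mask = modes.nodes.chain_mask(chains)
    if not mask.any():
        raise EmptySelectionError(f"no nodes on chains {chains!r}")
    scope = ",".join([chains] if isinstance(chains, str) else list(chains))
    return ModeSet(eigenvalues=modes.eigenvalues.copy(),
                   vectors=modes.vectors[:, mask, :],
                   nodes=modes.nodes.subset(mask, scope=scope),
                   n_trivial_removed=modes.n_trivial_removed)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_nmd(modes: ModeSet, path, name: str = "dynalign") -> None:
    """Write modes in NMD format for molecular-viewer animation."""
    nodes = modes.nodes
    with open(path, "w") as fh:
        fh.write(f"nmwiz_load {path}\n")
        fh.write(f"name {name}\n")
        fh.write("resnames " + " ".join(nodes.res_names) + "\n")
        fh.write("chainids " + " ".join(nodes.chain_ids) + "\n")
        fh.write("resids " + " ".join(nodes.res_labels) + "\n")
        fh.write("coordinates " +
                 " ".join("%.3f" % v for v in nodes.coords.reshape(-1)) + "\n")
        for i, (lam, vec) in enumerate(zip(modes.eigenvalues, modes.vectors), 1):
            fh.write(f"mode {i} {lam:.6g} " +
                     " ".join("%.5f" % v for v in vec.reshape(-1)) + "\n")


def write_eigenvalues(modes: ModeSet, path) -> None:
    import pandas as pd
    pd.DataFrame({"mode": np.arange(1, modes.n_modes + 1),
                  "eigenvalue": modes.eigenvalues}).to_csv(
        path, sep="\t", index=False)
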