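"""Dataset-level pipeline: DSS matrices, clustering, scans and maps.

For every unordered pair of dataset entries the compared scopes are
superposed, ANM slow modes are computed on each full structure as provided
(the biological unit is whatever coordinates the entry carries), modes are
restricted to the entry's chain scope where one is set, and the DSS is
computed.  The resulting similarity matrix is converted to a distance
matrix (d = DSS_max - DSS, an affine rank-preserving transform) and fed to
standard agglomerative clustering.  The module also provides the mode-count
selection scan (Pearson correlation between DSS matrices at successive mode
counts), the two-reference-state map (mean DSS of every entry against two
reference sets), and the DSS-versus-TM-score pair table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .anm import ModeSet, build_hessian, restrict_modes, slow_modes
from .modealign import AlignParams, compute_dss
from .structure_io import NodeModel, StructureModel, extract_nodes, read_structure
from .superpose import Superposition, SuperpositionError, superpose_iterative

logger = logging.getLogger(__name__)

LINKAGES = ("complete", "average", "single")


@dataclass
class DatasetEntry:
    """One dataset member: a structure and the scope compared.

    ``structure`` is a StructureModel or a file path; ``scope`` is None for
    the whole assembly or a chain id (modes are still computed on the whole
    structure and then restricted to the chain).
    """

    label: str
    structure: StructureModel | str
    scope: str | None = None


@dataclass
class DatasetSpec:
    entries: list[DatasetEntry]
    params: AlignParams = field(default_factory=AlignParams)
    cutoff: float = 15.0
    include_heme: bool = True

    def __post_init__(self):
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("dataset labels must be unique")

    @classmethod
    def from_structures(cls, items, **kwargs) -> "DatasetSpec":
        """Build from (label, structure, scope) tuples."""
        return cls(entries=[DatasetEntry(*it) for it in items], **kwargs)


@dataclass
class DssMatrix:
    """Pairwise DSS over a dataset with companion TM-scores."""

    labels: list[str]
    dss: np.ndarray
    tm: np.ndarray
    failures: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dss, index=self.labels, columns=self.labels)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f")


@dataclass
class Dendrogram:
    """Agglomerative merge tree over dataset labels (scipy linkage matrix)."""

    linkage_matrix: np.ndarray
    labels: list[str]

    def cut(self, n_clusters: int) -> np.ndarray:
        return sch.fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")


# ---------------------------------------------------------------------------
# pairwise DSS
# ---------------------------------------------------------------------------

def _prepare_entry(entry: DatasetEntry, cutoff: float,
                   include_heme: bool) -> tuple[NodeModel, str | None]:
    st = entry.structure
    if isinstance(st, (str,)) or hasattr(st, "__fspath__"):
        st = read_structure(st)
    nodes = extract_nodes(st, include_heme=include_heme)
    return nodes, entry.scope


def _scoped(nodes: NodeModel, scope: str | None) -> NodeModel:
    if scope is None:
        return nodes
    return nodes.subset(nodes.chain_mask(scope), scope=scope)


def pair_context(nodes_a: NodeModel, scope_a: str | None,
                 nodes_b: NodeModel, scope_b: str | None,
                 n_modes: int, cutoff: float = 15.0):
    """Superpose the compared scopes and compute scope-restricted modes.

    Returns (modes_a, modes_b, coords_a, coords_b, tm_score) with A already
    placed in B's frame: the superposition is applied to A's coordinates
    before the Hessian is built, so A's mode vectors are expressed in the
    common frame.
    """
    sa, sb = _scoped(nodes_a, scope_a), _scoped(nodes_b, scope_b)
    sup = superpose_iterative(sa, sb)
    nodes_a_t = nodes_a.with_coords(sup.transform(nodes_a.coords))
    ma = slow_modes(build_hessian(nodes_a_t, cutoff=cutoff), n_keep=n_modes)
    mb = slow_modes(build_hessian(nodes_b, cutoff=cutoff), n_keep=n_modes)
    if scope_a is not None:
        ma = restrict_modes(ma, scope_a)
    if scope_b is not None:
        mb = restrict_modes(mb, scope_b)
    return ma, mb, ma.nodes.coords, mb.nodes.coords, sup.tm_score


def _self_context(nodes: NodeModel, scope: str | None, n_modes: int,
                  cutoff: float):
    m = slow_modes(build_hessian(nodes, cutoff=cutoff), n_keep=n_modes)
    if scope is not None:
        m = restrict_modes(m, scope)
    return m, m, m.nodes.coords, m.nodes.coords, 1.0


def dss_matrix(dataset: DatasetSpec, n_keep: int | None = None) -> DssMatrix:
    """Pairwise DSS and TM-score over a dataset.

    Each unordered pair is computed once; pair-level superposition failures
    are recorded in ``failures`` and yield NaN entries rather than aborting
    the run.  The diagonal holds self-DSS values.
    """
    if len(dataset.entries) < 2:
        raise ValueError("need at least 2 entries")
    n_modes = n_keep or dataset.params.n_modes
    prepared = [_prepare_entry(e, dataset.cutoff, dataset.include_heme)
                for e in dataset.entries]
    K = len(prepared)
    dss = np.full((K, K), np.nan)
    tm = np.full((K, K), np.nan)
    failures = []
    for i in range(K):
        ctx = _self_context(*prepared[i], n_modes, dataset.cutoff)
        res = compute_dss(ctx[0], ctx[1], ctx[2], ctx[3], dataset.params)
        dss[i, i], tm[i, i] = res.dss, 1.0
        for j in range(i + 1, K):
            try:
                ma, mb, ca, cb, t = pair_context(
                    prepared[i][0], prepared[i][1],
                    prepared[j][0], prepared[j][1], n_modes, dataset.cutoff)
                res = compute_dss(ma, mb, ca, cb, dataset.params)
                dss[i, j] = dss[j, i] = res.dss
                tm[i, j] = tm[j, i] = t
            except SuperpositionError as exc:
                failures.append((dataset.entries[i].label,
                                 dataset.entries[j].label, str(exc)))
                logger.warning("pair (%s, %s) failed: %s",
                               dataset.entries[i].label,
                               dataset.entries[j].label, exc)
    return DssMatrix(labels=[e.label for e in dataset.entries],
                     dss=dss, tm=tm, failures=failures)


# ---------------------------------------------------------------------------
# distance transform and clustering
# ---------------------------------------------------------------------------

def to_distance(m: DssMatrix | np.ndarray, transform: str = "shift") -> np.ndarray:
    """Convert a DSS matrix into a distance matrix.

    ``shift`` (default): d_ij = max(DSS) - DSS_ij off-diagonal, d_ii = 0 —
    affine and strictly rank-reversing.  ``reciprocal``: 1/(1 + DSS).
    Missing (NaN) pairs are imputed at the maximum distance with a warning.
    """
    dss = m.dss if isinstance(m, DssMatrix) else np.asarray(m, dtype=float)
    if transform == "shift":
        d = np.nanmax(dss) - dss
    elif transform == "reciprocal":
        d = 1.0 / (1.0 + dss)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    if np.isnan(d).any():
        logger.warning("imputing %d missing pairs at maximum distance",
                       int(np.isnan(d).sum()) // 2)
        d = np.where(np.isnan(d), np.nanmax(d), d)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def hierarchical_cluster(d: np.ndarray, labels=None,
                         linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of a distance matrix (default complete linkage)."""
    d = np.asarray(d, dtype=float)
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9) or (d < 0).any():
        raise ValueError("distance matrix must be symmetric and non-negative")
    Z = sch.linkage(squareform(d, checks=False), method=linkage)
    if labels is None:
        labels = [str(i) for i in range(d.shape[0])]
    return Dendrogram(linkage_matrix=Z, labels=list(labels))


def _newick_label(label: str) -> str:
    if any(c in label for c in " ()[]:;,'\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Dendrogram, path=None) -> str:
    """Render the dendrogram as a Newick string with ultrametric branch lengths.

    A node's branch length is (parent height - node height) / 2, so leaf
    depths equal half the merge heights (a two-leaf tree merged at height h
    renders as ``(A:h/2,B:h/2);``).
    """
    root = sch.to_tree(tree.linkage_matrix)

    def render(node, parent_dist):
        bl = (parent_dist - node.dist) / 2.0
        if node.is_leaf():
            return f"{_newick_label(tree.labels[node.id])}:{bl:.10g}"
        inner = ",".join(render(c, node.dist) for c in (node.left, node.right))
        return f"({inner}):{bl:.10g}"

    inner = ",".join(render(c, root.dist) for c in (root.left, root.right))
    s = f"({inner});\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


# ---------------------------------------------------------------------------
# scans, maps, tables
# ---------------------------------------------------------------------------

def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def modecount_scan(dataset: DatasetSpec,
                   n_values=(2, 4, 6, 8, 10, 12, 14, 16, 18, 20)) -> pd.DataFrame:
    """Pearson correlation between DSS matrices at successive mode counts.

    For each n the pairwise DSS matrix is computed; strict upper triangles
    are flattened and correlated between successive n.  Each row is labelled
    by the larger n of its pair.  Rows with a zero-variance vector are
    flagged with NaN correlation.
    """
    n_values = sorted(n_values)
    if len(dataset.entries) < 3:
        raise ValueError("need >= 3 entries for a correlation scan")
    n_max = n_values[-1]
    prepared = [_prepare_entry(e, dataset.cutoff, dataset.include_heme)
                for e in dataset.entries]
    K = len(prepared)
    contexts = {}
    for i in range(K):
        contexts[(i, i)] = _self_context(*prepared[i], n_max, dataset.cutoff)
        for j in range(i + 1, K):
            contexts[(i, j)] = pair_context(
                prepared[i][0], prepared[i][1],
                prepared[j][0], prepared[j][1], n_max, dataset.cutoff)
    from dataclasses import replace
    vectors = {}
    for n in n_values:
        params = replace(dataset.params, n_modes=n)
        mat = np.zeros((K, K))
        for i in range(K):
            for j in range(i + 1, K):
                ma, mb, ca, cb, _ = contexts[(i, j)]
                mat[i, j] = mat[j, i] = compute_dss(
                    ma.take(n), mb.take(n), ca, cb, params).dss
        vectors[n] = _upper(mat)
    rows = []
    for n_small, n_large in zip(n_values[:-1], n_values[1:]):
        x, y = vectors[n_small], vectors[n_large]
        if np.std(x) == 0.0 and np.std(y) == 0.0 and np.allclose(x, y):
            r = 1.0  # identical constant vectors: perfectly reproducible
        elif np.std(x) == 0.0 or np.std(y) == 0.0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"n_modes": n_large, "n_modes_prev": n_small,
                     "correlation": r})
    return pd.DataFrame(rows)


def reference_map(m: DssMatrix, refs_a, refs_b) -> pd.DataFrame:
    """Mean DSS of every entry against two reference label sets.

    Self-pairs are excluded from the mean when the entry is itself a
    reference, mirroring how end-state representatives are mapped.
    """
    refs_a, refs_b = list(refs_a), list(refs_b)
    if not refs_a or not refs_b:
        raise ValueError("reference sets must be non-empty")
    idx = {lab: i for i, lab in enumerate(m.labels)}
    for r in refs_a + refs_b:
        if r not in idx:
            raise ValueError(f"reference label {r!r} not in dataset")

    def mean_vs(i, refs):
        vals = [m.dss[i, idx[r]] for r in refs if idx[r] != i]
        return float(np.mean(vals)) if vals else np.nan

    return pd.DataFrame([
        {"label": lab,
         "mean_dss_refs_a": mean_vs(i, refs_a),
         "mean_dss_refs_b": mean_vs(i, refs_b)}
        for i, lab in enumerate(m.labels)])


def dss_vs_tmscore(m: DssMatrix) -> pd.DataFrame:
    """One row per unordered pair: (label_i, label_j, TM-score, DSS)."""
    rows = []
    for i in range(len(m.labels)):
        for j in range(i + 1, len(m.labels)):
            rows.append({"label_i": m.labels[i], "label_j": m.labels[j],
                         "tm_score": m.tm[i, j], "dss": m.dss[i, j]})
    return pd.DataFrame(rows)
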