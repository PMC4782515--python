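"""Gene regulatory network inference and expression clustering.

The network skeleton is recovered by a path-consistency algorithm driven by
Gaussian (conditional) mutual information: starting from the complete graph,
edges whose MI falls below a threshold theta are removed at order 0, and at
order L >= 1 an edge (x, y) is removed when the maximum CMI over all size-L
conditioning subsets of the common neighbours of x and y stays below theta.
Communities are read off the inferred graph with Markov clustering (MCL), and
cell-type-specific expression clusters are chosen by K-means with the number
of clusters selected by a leave-one-condition-out figure of merit (FOM).

All information quantities are in nats.  For jointly Gaussian vectors,

    MI(X, Y)       = 1/2 ln( |C(X)| |C(Y)| / |C(X, Y)| )
    CMI(X, Y | Z)  = 1/2 ln( |C(X, Z)| |C(Y, Z)| / (|C(Z)| |C(X, Y, Z)|) )

with |C(.)| the determinant of the sample covariance of the stacked vectors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


class DegenerateSignalError(ValueError):
    """A covariance matrix required by an estimator is singular."""


@dataclass
class GRNConfig:
    theta: float = 0.03  # CMI threshold, nats
    max_order: int = 1  # largest conditioning-set size

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.max_order < 0:
            raise ValueError("max_order must be >= 0")


@dataclass
class Community:
    community_id: int
    genes: list[str] = field(default_factory=list)


def _as_2d(vectors) -> np.ndarray:
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def _logdet(cov: np.ndarray) -> float:
    cov = np.atleast_2d(cov)
    sign, ld = np.linalg.slogdet(cov)
    if sign <= 0 or not np.isfinite(ld):
        raise DegenerateSignalError("singular or indefinite covariance")
    return ld


def mutual_information_gaussian(x, y) -> float:
    """Gaussian mutual information of two sample vectors, in nats."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    cov = np.cov(np.vstack([x, y]))
    if cov[0, 0] <= 0 or cov[1, 1] <= 0:
        raise DegenerateSignalError("zero-variance input")
    mi = 0.5 * (np.log(cov[0, 0]) + np.log(cov[1, 1]) - _logdet(cov))
    return max(mi, 0.0)


def conditional_mutual_information_gaussian(x, y, Z=()) -> float:
    """Gaussian CMI(X, Y | Z) in nats; with empty Z this is exactly the MI."""
    Zarr = _as_2d(Z) if len(Z) else np.empty((0, len(np.asarray(x))))
    if Zarr.shape[0] == 0:
        return mutual_information_gaussian(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    data = np.vstack([x, y, Zarr])
    if not np.isfinite(data).all():
        raise ValueError("inputs must be finite")
    cov = np.cov(data)
    k = Zarr.shape[0]
    iz = list(range(2, 2 + k))
    ld_xz = _logdet(cov[np.ix_([0] + iz, [0] + iz)])
    ld_yz = _logdet(cov[np.ix_([1] + iz, [1] + iz)])
    ld_z = _logdet(cov[np.ix_(iz, iz)])
    ld_xyz = _logdet(cov)
    return max(0.5 * (ld_xz + ld_yz - ld_z - ld_xyz), 0.0)


def _cmi_from_cov(cov: np.ndarray, i: int, j: int, K: tuple[int, ...]) -> float:
    """CMI(i, j | K) from a precomputed covariance matrix (same formulas)."""
    if not K:
        ld = _logdet(cov[np.ix_([i, j], [i, j])])
        return max(0.5 * (np.log(cov[i, i]) + np.log(cov[j, j]) - ld), 0.0)
    iz = list(K)
    ld_xz = _logdet(cov[np.ix_([i] + iz, [i] + iz)])
    ld_yz = _logdet(cov[np.ix_([j] + iz, [j] + iz)])
    ld_z = _logdet(cov[np.ix_(iz, iz)])
    all_ix = [i, j] + iz
    ld_xyz = _logdet(cov[np.ix_(all_ix, all_ix)])
    return max(0.5 * (ld_xz + ld_yz - ld_z - ld_xyz), 0.0)


def pca_cmi(expression: pd.DataFrame, config: GRNConfig | None = None) -> nx.Graph:
    """Path-consistency GRN skeleton from a genes x samples expression table.

    Adjacency is frozen within each sweep so that removals inside a sweep
    cannot destroy the conditioning sets of edges tested later in the same
    sweep; sweeps repeat at each order until no edge is removed.  Returned
    edges carry their final (C)MI value as the ``score`` attribute.
    """
    config = config or GRNConfig()
    if not isinstance(expression, pd.DataFrame):
        expression = pd.DataFrame(np.asarray(expression, dtype=float))
        expression.index = [f"g{i}" for i in range(len(expression))]
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if expression.shape[0] < 2:
        raise ValueError("need at least 2 genes")

    variances = expression.var(axis=1, ddof=1)
    degenerate = variances[variances <= 1e-300].index.tolist()
    if degenerate:
        warnings.warn(f"excluding zero-variance genes: {degenerate}")
    genes = [g for g in expression.index if g not in set(degenerate)]
    X = expression.loc[genes].to_numpy(dtype=float)
    n = len(genes)
    cov = np.cov(X)

    graph = nx.Graph()
    graph.add_nodes_from(genes)
    score: dict[tuple[int, int], float] = {}
    # order 0: complete graph minus low-MI edges
    for i in range(n):
        for j in range(i + 1, n):
            mi = _cmi_from_cov(cov, i, j, ())
            if mi >= config.theta:
                score[(i, j)] = mi

    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in score:
        adj[i].add(j)
        adj[j].add(i)

    for order in range(1, config.max_order + 1):
        while True:
            removed = []
            frozen = {i: set(s) for i, s in adj.items()}
            for (i, j) in list(score):
                common = sorted(frozen[i] & frozen[j])
                if len(common) < order:
                    continue
                best = -np.inf
                for K in itertools.combinations(common, order):
                    try:
                        best = max(best, _cmi_from_cov(cov, i, j, K))
                    except DegenerateSignalError:
                        continue
                if best == -np.inf:
                    continue
                if best < config.theta:
                    removed.append((i, j))
                else:
                    score[(i, j)] = best
            for (i, j) in removed:
                del score[(i, j)]
                adj[i].discard(j)
                adj[j].discard(i)
            if not removed:
                break

    for (i, j), s in score.items():
        graph.add_edge(genes[i], genes[j], score=float(s))
    return graph


def mcl_communities(
    grn: nx.Graph,
    inflation: float = 2.0,
    weighted: bool = True,
    self_loop: float = 1.0,
    prune: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> list[Community]:
    """Markov clustering of a GRN into communities.

    Expansion (matrix squaring) alternates with inflation (elementwise power
    and column renormalisation) on the column-stochastic transition matrix
    with unit self-loops, until the matrix stops changing.  Communities are
    the connected components of the converged non-zero structure; they
    partition the node set.
    """
    if grn.number_of_nodes() == 0:
        raise ValueError("GRN is empty")
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    nodes = sorted(grn.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for u, v, d in grn.edges(data=True):
        w = float(d.get("score", d.get("weight", 1.0))) if weighted else 1.0
        M[index[u], index[v]] = M[index[v], index[u]] = abs(w)
    M[np.diag_indices(n)] = self_loop
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        new = M @ M
        new = new**inflation
        new /= new.sum(axis=0, keepdims=True)
        new[new < prune] = 0.0
        colsum = new.sum(axis=0, keepdims=True)
        new /= np.where(colsum == 0, 1.0, colsum)
        residual = np.abs(new - M).max()
        M = new
        if residual < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"MCL did not converge in {max_iter} iterations "
                           f"(last residual {residual:.3g})")

    structure = nx.Graph()
    structure.add_nodes_from(range(n))
    rows, cols = np.nonzero(M)
    structure.add_edges_from(zip(rows.tolist(), cols.tolist()))
    comps = sorted(nx.connected_components(structure), key=lambda c: sorted(c)[0])
    return [
        Community(community_id=k, genes=sorted(nodes[i] for i in comp))
        for k, comp in enumerate(comps)
    ]


def _fom_for_k(X: np.ndarray, k: int, seed: int) -> float:
    """Leave-one-condition-out figure of merit, adjusted by sqrt(n/(n-k))."""
    n_genes, n_cond = X.shape
    total = 0.0
    for e in range(n_cond):
        rest = np.delete(X, e, axis=1)
        if k == 1:
            labels = np.zeros(n_genes, dtype=int)
        else:
            labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(rest)
        dev = 0.0
        for c in np.unique(labels):
            mask = labels == c
            held = X[mask, e]
            dev += float(((held - held.mean()) ** 2).sum())
        total += np.sqrt(dev / n_genes)
    return total * np.sqrt(n_genes / (n_genes - k))


def kmeans_fom(
    expression: pd.DataFrame, k_range: tuple[int, int], seed: int = 0
) -> tuple[int, pd.Series, pd.DataFrame]:
    """K-means clustering of genes with FOM-selected number of clusters.

    The FOM curve is computed for every k in ``k_range`` (plus a k=1 baseline
    anchoring the curve's range); the chosen k is the smallest one whose
    further improvement at k+1 drops below 10% of the total FOM range, ties
    resolved toward the smallest k.  Returns (chosen_k, assignment, curve).
    """
    X = expression.to_numpy(dtype=float)
    n_genes, n_cond = X.shape
    k_min, k_max = int(k_range[0]), int(k_range[1])
    if k_min < 2 or k_max >= n_genes:
        raise ValueError("k_range must lie within [2, n_genes - 1]")
    if k_min > k_max:
        raise ValueError("k_range must be ordered")
    if n_cond < 2:
        raise ValueError("need at least 2 conditions")

    ks = list(range(k_min, k_max + 1))
    fom = {k: _fom_for_k(X, k, seed) for k in [1] + ks}
    total_range = max(fom.values()) - min(fom.values())

    chosen = k_max
    if total_range <= 1e-12:
        chosen = k_min
    else:
        for k in ks[:-1]:
            if fom[k] - fom[k + 1] < 0.10 * total_range:
                chosen = k
                break

    labels = KMeans(n_clusters=chosen, n_init=10, random_state=seed).fit_predict(X)
    assignment = pd.Series(labels, index=expression.index, name="cluster")
    curve = pd.DataFrame({"k": ks, "fom": [fom[k] for k in ks]})
    return chosen, assignment, curve


def write_grn(grn: nx.Graph, path) -> None:
    rows = [(u, v, d.get("score", 1.0)) for u, v, d in sorted(grn.edges(data=True))]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).to_csv(
        path, sep="\t", index=False
    )


def read_grn(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(row.iloc[0], row.iloc[1], score=float(row.iloc[2]))
    return g
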