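"""Statistical core of the meta-analysis.

Four families of analysis live here:

* co-expression graphs thresholded on the Pearson correlation of log2FC
  profiles across experiments (default r >= 0.95, signed), and the
  extraction of "fully connected subnetworks" (clique components);
* hierarchical clustering of experiments (Euclidean distance, Ward
  variance-minimizing linkage), used to group experiments with similar
  transcriptomic responses;
* PCA of the gene x experiment matrix with experiments as variables:
  eigenvalues, gene/experiment contributions (percent of each dimension's
  variance), dimension selection by a cumulative-variance threshold plus a
  scree-inflection diagnostic, and ranking of the genes contributing most to
  the retained dimensions;
* nonparametric bias-corrected and accelerated (BCa) bootstrap confidence
  intervals, and the per-gene-per-cluster specificity call: a gene behaves
  specifically in a cluster when the global mean log2FC falls outside the
  BCa interval of the gene's log2FC over that cluster's experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import norm

from .degmat import DEGMatrix

__all__ = [
    "CorrelationGraph",
    "ClusterAssignment",
    "PCAResult",
    "BCaInterval",
    "SpecificityCall",
    "DimensionSelection",
    "correlation_graph",
    "fully_connected_subnetworks",
    "cluster_experiments",
    "pca_contributions",
    "select_dimensions",
    "top_contributing_genes",
    "bca_interval",
    "cluster_specificity",
]


# ---------------------------------------------------------------------------
# correlation subnetworks


@dataclass
class CorrelationGraph:
    genes: list[str]
    edges: set[tuple[str, str, float]]  # (a, b, r), a < b
    threshold: float
    signed: bool
    zero_variance: list[str] = field(default_factory=list)

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {g: set() for g in self.genes}
        for a, b, _ in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj


def correlation_graph(
    matrix: DEGMatrix,
    genes: Iterable[str],
    r_min: float = 0.95,
    signed: bool = True,
) -> CorrelationGraph:
    """Threshold the pairwise Pearson correlations of log2FC profiles.

    Correlations are computed across all experiments on the matrix values as
    filled (including fill-policy zeros).  An edge is stored when r >= r_min
    (``signed=True``) or |r| >= r_min.  Genes with zero variance cannot
    correlate and are listed in ``zero_variance`` instead.
    """
    genes = sorted(set(genes))
    gidx = matrix.gene_index
    missing = [g for g in genes if g not in gidx]
    if missing:
        raise ValueError(f"genes not in matrix: {missing[:5]}")
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    X = matrix.lfc[[gidx[g] for g in genes], :]
    sd = X.std(axis=1)
    live = sd > 0
    zero_var = [g for g, ok in zip(genes, live) if not ok]
    live_genes = [g for g, ok in zip(genes, live) if ok]
    edges: set[tuple[str, str, float]] = set()
    if len(live_genes) >= 2:
        R = np.corrcoef(X[live])
        n = len(live_genes)
        for i in range(n):
            for j in range(i + 1, n):
                r = float(R[i, j])
                keep = r >= r_min if signed else abs(r) >= r_min
                if keep:
                    edges.add((live_genes[i], live_genes[j], r))
    return CorrelationGraph(genes=genes, edges=edges, threshold=r_min,
                            signed=signed, zero_variance=zero_var)


def fully_connected_subnetworks(
    graph: CorrelationGraph,
) -> tuple[set[str], list[set[str]]]:
    """Split a correlation graph into the any-correlation set and cliques.

    ``connected_genes`` is every gene with at least one correlation edge.
    ``clique_components`` are the connected components of size >= 2 in which
    every pair of members is directly adjacent — the reported co-expression
    module.  Components that are merely connected (not complete) are
    excluded from the clique list.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from((a, b) for a, b, _ in graph.edges)
    connected = {n for n in g if g.degree(n) >= 1}
    cliques = []
    for comp in nx.connected_components(g):
        k = len(comp)
        if k >= 2 and g.subgraph(comp).number_of_edges() == k * (k - 1) // 2:
            cliques.append(set(comp))
    cliques.sort(key=lambda c: (-len(c), min(c)))
    return connected, cliques


# ---------------------------------------------------------------------------
# experiment clustering


@dataclass
class ClusterAssignment:
    experiments: list[str]
    labels: dict[str, int]     # experiment -> 1..k
    k: int
    linkage_matrix: np.ndarray
    method: str = "ward"
    metric: str = "euclidean"

    def members(self, label: int) -> list[str]:
        return [e for e in self.experiments if self.labels[e] == label]

    @property
    def cluster_labels(self) -> list[int]:
        return sorted(set(self.labels.values()))


def cluster_experiments(matrix: DEGMatrix, k: int = 4) -> ClusterAssignment:
    """Ward/Euclidean hierarchical clustering of experiment profiles.

    Experiments are clustered on their log2FC column vectors with the
    variance-minimizing (Ward.D2) update and cut into ``k`` clusters.
    Labels are renumbered 1..k by first appearance in experiment order, so
    the assignment is deterministic for a given matrix.
    """
    n = len(matrix.experiments)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} experiments")
    X = matrix.lfc.T  # experiments as observations
    Z = linkage(X, method="ward", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for e, r in zip(matrix.experiments, raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[e] = relabel[r]
    return ClusterAssignment(experiments=list(matrix.experiments),
                             labels=labels, k=k, linkage_matrix=Z)


# ---------------------------------------------------------------------------
# PCA contributions


@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # variance per dimension, non-increasing
    gene_scores: np.ndarray          # genes x dims
    experiment_loadings: np.ndarray  # experiments x dims
    gene_contrib: np.ndarray         # percent, genes x dims
    experiment_contrib: np.ndarray   # percent, experiments x dims
    genes: list[str]
    experiments: list[str]
    total_variance: float
    scaled: bool = False


def pca_contributions(matrix: DEGMatrix, scale: bool = False) -> PCAResult:
    """PCA of the gene x experiment matrix, experiments as variables.

    Columns (experiments) are mean-centered; with ``scale=True`` they are
    additionally standardized to unit variance.  Genes act as observations,
    so gene scores are the principal-component coordinates and experiment
    loadings the unit eigenvectors of the column covariance matrix.  The
    contribution of gene g to dimension d is
    ``100 * score[g, d]**2 / sum_h score[h, d]**2`` (analogous for
    experiments on loadings), the convention of contribution biplots.
    """
    G, E = matrix.lfc.shape
    if G < 2 or E < 2:
        raise ValueError("need at least 2 genes and 2 experiments")
    X = matrix.lfc.astype(float)
    Xc = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        flat = [e for e, s in zip(matrix.experiments, sd) if s == 0]
        if flat:
            raise ValueError(
                f"cannot scale constant experiment column(s): {flat}"
            )
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|.| loading entry positive per dimension
    for d in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[d]))
        if Vt[d, pivot] < 0:
            Vt[d] *= -1.0
            U[:, d] *= -1.0
    eigenvalues = S**2 / (G - 1)
    scores = U * S
    loadings = Vt.T
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = 100.0 * scores**2 / np.maximum((scores**2).sum(axis=0), 1e-300)
        ec = 100.0 * loadings**2 / np.maximum((loadings**2).sum(axis=0), 1e-300)
    total_var = float(Xc.var(axis=0, ddof=1).sum())
    return PCAResult(
        eigenvalues=eigenvalues,
        gene_scores=scores,
        experiment_loadings=loadings,
        gene_contrib=gc,
        experiment_contrib=ec,
        genes=list(matrix.genes),
        experiments=list(matrix.experiments),
        total_variance=total_var,
        scaled=scale,
    )


class DimensionSelection(NamedTuple):
    dims: list[int]          # 1-based dimension indices, 1..D
    n_variance: int          # smallest D with cumulative fraction > threshold
    inflection: int          # scree inflection diagnostic (1-based)


def select_dimensions(
    result: PCAResult, var_threshold: float = 0.70
) -> DimensionSelection:
    """Choose how many leading dimensions to analyse.

    D is the smallest depth whose cumulative variance fraction exceeds
    ``var_threshold``; the scree inflection (argmax of the second difference
    of the eigenvalue sequence, first index on ties) is reported as a
    diagnostic and, when it exceeds D, extends the selection.
    """
    if not (0 < var_threshold < 1):
        raise ValueError("var_threshold must be in (0, 1)")
    lam = np.asarray(result.eigenvalues, dtype=float)
    frac = lam / lam.sum()
    cum = np.cumsum(frac)
    D = int(np.argmax(cum > var_threshold)) + 1
    if len(lam) >= 3:
        second = lam[:-2] - 2 * lam[1:-1] + lam[2:]
        inflection = int(np.argmax(second)) + 2  # interior index, 1-based
    else:
        inflection = 1
    depth = max(D, inflection)
    return DimensionSelection(dims=list(range(1, depth + 1)),
                              n_variance=D, inflection=inflection)


def top_contributing_genes(
    result: PCAResult,
    dims: Sequence[int],
    n: int = 100,
) -> list[tuple[str, float]]:
    """Rank genes by eigenvalue-weighted mean contribution over ``dims``.

    The multi-dimension contribution of gene g is
    ``sum_d ctr[g, d] * lambda_d / sum_d lambda_d`` over the selected
    dimensions (1-based), the convention of contribution-plot tooling.
    Ties break lexicographically by gene id.
    """
    if not dims:
        raise ValueError("dims must be non-empty")
    if n > len(result.genes):
        raise ValueError(f"n={n} exceeds the {len(result.genes)} genes")
    idx = [d - 1 for d in dims]
    if min(idx) < 0 or max(idx) >= len(result.eigenvalues):
        raise ValueError(f"dimension out of range: {dims}")
    lam = result.eigenvalues[idx]
    scores = result.gene_contrib[:, idx] @ lam / lam.sum()
    order = sorted(zip(result.genes, scores), key=lambda t: (-t[1], t[0]))
    return [(g, float(s)) for g, s in order[:n]]


# ---------------------------------------------------------------------------
# BCa bootstrap


@dataclass
class BCaInterval:
    estimate: float
    lower: float
    upper: float
    z0: float
    a: float
    B: int
    alpha: float
    degenerate: bool = False

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def bca_interval(
    values: Sequence[float],
    B: int = 10_000,
    alpha: float = 0.05,
    statistic: Callable[[np.ndarray], float] | None = None,
    seed: int | np.random.Generator | None = None,
) -> BCaInterval:
    """Bias-corrected and accelerated bootstrap interval of a statistic.

    Nonparametric bootstrap with ``B`` resamples drawn with replacement.
    The bias correction is ``z0 = Phi^-1(p)`` with
    ``p = (#{theta* < theta_hat} + 0.5 * #{theta* = theta_hat}) / B``
    (ties count half); the acceleration comes from the leave-one-out
    jackknife, ``a = sum d_i^3 / (6 * (sum d_i^2)^1.5)`` with
    ``d_i = mean(theta_(i)) - theta_(i)``.  Interval endpoints are the
    adjusted-percentile empirical quantiles of the bootstrap distribution
    (linear, type-7 interpolation).  Degenerate inputs (all values equal, or
    zero jackknife variance) yield the point interval [theta_hat, theta_hat].
    When every bootstrap replicate falls on one side of the estimate, p is
    clamped to (1/(2B), 1 - 1/(2B)) to keep z0 finite.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 values, got {n}")
    if B < 1:
        raise ValueError("B must be >= 1")
    stat = statistic if statistic is not None else np.mean
    theta = float(stat(x))

    def _degenerate() -> BCaInterval:
        return BCaInterval(theta, theta, theta, 0.0, 0.0, B, alpha,
                           degenerate=True)

    if np.ptp(x) == 0:
        return _degenerate()

    # leave-one-out jackknife acceleration
    if stat is np.mean:
        jack = (x.sum() - x) / (n - 1)
    else:
        jack = np.array([stat(np.delete(x, i)) for i in range(n)])
    d = jack.mean() - jack
    ss = float((d**2).sum())
    if ss == 0.0:
        return _degenerate()
    a = float((d**3).sum() / (6.0 * ss**1.5))

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    idx = rng.integers(0, n, size=(B, n))
    if stat is np.mean:
        boot = x[idx].mean(axis=1)
    else:
        boot = np.array([stat(x[row]) for row in idx])

    p = (np.count_nonzero(boot < theta)
         + 0.5 * np.count_nonzero(boot == theta)) / B
    p = min(max(p, 1.0 / (2 * B)), 1.0 - 1.0 / (2 * B))
    z0 = float(norm.ppf(p))
    z_lo, z_hi = norm.ppf(alpha / 2.0), norm.ppf(1.0 - alpha / 2.0)
    a1 = float(norm.cdf(z0 + (z0 + z_lo) / (1.0 - a * (z0 + z_lo))))
    a2 = float(norm.cdf(z0 + (z0 + z_hi) / (1.0 - a * (z0 + z_hi))))
    lower, upper = np.quantile(boot, [a1, a2], method="linear")
    return BCaInterval(theta, float(lower), float(upper), z0, a, B, alpha)


@dataclass
class SpecificityCall:
    gene_id: str
    cluster: int
    interval: BCaInterval
    global_mean: float
    flagged: bool
    direction: str  # "above" | "below" | "none"


def cluster_specificity(
    matrix: DEGMatrix,
    genes: Sequence[str],
    clusters: "ClusterAssignment",
    B: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[SpecificityCall]:
    """Per gene x cluster BCa intervals against the global mean log2FC.

    The global mean is the mean log2FC over the supplied genes across all
    experiments.  For each gene and cluster, a BCa interval of the gene's
    mean log2FC over that cluster's experiments is computed; the gene is
    flagged as cluster-specific when the global mean falls outside the
    interval, with ``direction="above"`` when the cluster values sit above
    the global mean.  Bootstrap streams are derived per (gene, cluster) from
    ``seed``, so results do not depend on iteration order.
    """
    genes = [g[0] if isinstance(g, tuple) else g for g in genes]
    gidx = matrix.gene_index
    missing = [g for g in genes if g not in gidx]
    if missing:
        raise ValueError(f"genes not in matrix: {missing[:5]}")
    eidx = matrix.experiment_index
    members: dict[int, list[int]] = {}
    for label in clusters.cluster_labels:
        cols = [eidx[e] for e in clusters.members(label) if e in eidx]
        if len(cols) < 2:
            raise ValueError(
                f"cluster {label} has {len(cols)} experiment(s) in the "
                "matrix; need at least 2 for a bootstrap"
            )
        members[label] = cols

    rows = [gidx[g] for g in genes]
    global_mean = float(matrix.lfc[rows, :].mean())
    calls: list[SpecificityCall] = []
    for ci, (label, cols) in enumerate(sorted(members.items())):
        for gi, g in enumerate(genes):
            values = matrix.lfc[gidx[g], cols]
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(ci, gi))
            )
            iv = bca_interval(values, B=B, alpha=alpha, seed=rng)
            flagged = not iv.contains(global_mean)
            if not flagged:
                direction = "none"
            elif global_mean < iv.lower:
                direction = "above"
            else:
                direction = "below"
            calls.append(SpecificityCall(g, label, iv, global_mean,
                                         flagged, direction))
    return calls
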