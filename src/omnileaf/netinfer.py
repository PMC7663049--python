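"""Co-expression network inference, inverse-rank-product aggregation, backbone.

Several inference methods score every gene pair; scores are symmetrised by
keeping the larger of each directed pair, per-method edge ranks (1 = best,
average on ties) are combined by the geometric mean (the rank product), and
the aggregate edge weight is the inverse rank product. Edges are then pruned
with a strength-based noise-corrected null: each unit of total weight T
lands on edge (i, j) with probability ``p_ij = s_i s_j / T^2`` and an edge is
kept iff its binomial z-score exceeds ``sigma`` (default 2.32, a one-sided
normal tail of roughly 1%).

Partitioning is greedy modularity maximisation within connected components
(a documented substitute for a map-equation optimizer); cluster labels are
formatted ``component:cluster`` with components indexed by size rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import LedoitWolf

__all__ = [
    "EdgeScoreSet",
    "AggregatedNetwork",
    "filter_and_adjust",
    "infer",
    "aggregate_irp",
    "backbone",
    "partition",
    "centralities",
    "summary_stats",
    "INFERENCE_METHODS",
]

INFERENCE_METHODS = ("pearson", "spearman", "clr", "pcor")


@dataclass
class EdgeScoreSet:
    """Symmetric upper-triangular edge scores for one inference method."""

    method: str
    genes: list[str]
    scores: np.ndarray  # condensed upper-triangular vector
    higher_is_stronger: bool = True

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class AggregatedNetwork:
    genes: list[str]
    edges: pd.DataFrame  # gene_a, gene_b, per-method ranks, rank_product, irp_score
    backbone_edges: pd.DataFrame | None = None
    partition_labels: pd.Series | None = None
    centrality_table: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def graph(self, backbone_only: bool = True) -> nx.Graph:
        df = self.backbone_edges if backbone_only and self.backbone_edges is not None \
            else self.edges
        G = nx.Graph()
        G.add_nodes_from(
            set(df["gene_a"]).union(df["gene_b"])
        )
        for a, b, w in zip(df["gene_a"], df["gene_b"], df["irp_score"]):
            G.add_edge(a, b, weight=float(w))
        return G


# ---------------------------------------------------------------------------
# expression preprocessing
# ---------------------------------------------------------------------------


def filter_and_adjust(
    counts: pd.DataFrame,
    min_nonzero: int | None = None,
    var_min: float = 0.05,
    n_pcs: int = 0,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Normalise, log-transform, filter, and optionally remove leading PCs.

    Counts are divided by size factors (median-of-ratios if not given) and
    transformed as ``log2(normalized + 1)`` -- a stand-in for a
    variance-stabilising transform. Genes with fewer than ``min_nonzero``
    nonzero samples (default: 10% of samples) or log-scale variance <=
    ``var_min`` are dropped. If ``n_pcs > 0`` the top principal components
    are regressed out and residuals returned.
    """

    from omnileaf.degx import size_factors as mor_size_factors

    n_samples = counts.shape[1]
    if min_nonzero is None:
        min_nonzero = max(1, int(round(0.1 * n_samples)))
    if n_pcs >= n_samples:
        raise ValueError("n_pcs must be smaller than the number of samples")
    sf = size_factors if size_factors is not None else mor_size_factors(counts)
    norm = counts.to_numpy(dtype=float) / sf.to_numpy(dtype=float)[None, :]
    logx = np.log2(norm + 1.0)
    nonzero = (counts.to_numpy() > 0).sum(axis=1)
    keep = (nonzero >= min_nonzero) & (logx.var(axis=1, ddof=1) > var_min)
    logx = logx[keep]
    out = pd.DataFrame(logx, index=counts.index[keep], columns=counts.columns)
    if n_pcs > 0:
        X = out.to_numpy()
        Xc = X - X.mean(axis=1, keepdims=True)
        # PCs over samples: right singular vectors of the gene x sample matrix
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        V = Vt[:n_pcs].T  # samples x n_pcs, orthonormal
        resid = Xc - (Xc @ V) @ V.T
        out = pd.DataFrame(resid, index=out.index, columns=out.columns)
    return out


# ---------------------------------------------------------------------------
# inference methods
# ---------------------------------------------------------------------------


def _condense(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def _corr_scores(X: np.ndarray, rank_first: bool) -> np.ndarray:
    if rank_first:
        X = np.apply_along_axis(stats.rankdata, 1, X)
    sd = X.std(axis=1, ddof=1)
    const = sd == 0
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.where(sd > 0, sd * np.sqrt(X.shape[1] - 1), 1.0)
    Xn = Xc / denom[:, None]
    C = Xn @ Xn.T
    C[const, :] = 0.0
    C[:, const] = 0.0
    np.fill_diagonal(C, 0.0)
    return np.abs(np.clip(C, -1.0, 1.0))


def _mutual_information(X: np.ndarray) -> np.ndarray:
    """Pairwise MI by equal-frequency binning with ceil(sqrt(n)) bins."""

    g, n = X.shape
    nbins = int(np.ceil(np.sqrt(n)))
    # equal-frequency bin assignment per gene
    B = np.empty((g, n), dtype=np.int32)
    for i in range(g):
        ranks = stats.rankdata(X[i], method="ordinal") - 1
        B[i] = (ranks * nbins) // n
    MI = np.zeros((g, g))
    logn = np.log(n)
    for i in range(g):
        bi = B[i]
        for j in range(i + 1, g):
            joint = np.zeros((nbins, nbins))
            np.add.at(joint, (bi, B[j]), 1.0)
            pj = joint / n
            pi_m = pj.sum(axis=1, keepdims=True)
            pj_m = pj.sum(axis=0, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = pj * (np.log(pj) - np.log(pi_m) - np.log(pj_m))
            MI[i, j] = MI[j, i] = np.nansum(term)
    return MI


def _clr_scores(X: np.ndarray) -> np.ndarray:
    MI = _mutual_information(X)
    mu = MI.mean(axis=1, keepdims=True)
    sd = MI.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (MI - mu) / sd
    zi = np.maximum(Z, 0.0)
    S = np.sqrt(zi**2 + zi.T**2)
    np.fill_diagonal(S, 0.0)
    return S


def _pcor_scores(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=1, ddof=1)
    const = sd == 0
    Xs = np.where(
        sd[:, None] > 0,
        (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None],
        0.0,
    )
    lw = LedoitWolf().fit(Xs.T)
    prec = np.linalg.pinv(lw.covariance_)
    d = np.sqrt(np.abs(np.diag(prec)))
    P = -prec / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    P[const, :] = 0.0
    P[:, const] = 0.0
    return np.abs(P)


def infer(expr: pd.DataFrame, method: str) -> EdgeScoreSet:
    """Score all gene pairs with one inference method (higher = stronger).

    Methods: ``pearson``/``spearman`` (absolute correlation), ``clr``
    (equal-frequency-binned mutual information with background z-score
    combination), ``pcor`` (shrinkage partial correlation magnitude).
    Constant genes get zero scores on all their edges.
    """

    if expr.shape[1] < 10:
        raise ValueError("need at least 10 samples for network inference")
    X = expr.to_numpy(dtype=float)
    if method == "pearson":
        M = _corr_scores(X, rank_first=False)
    elif method == "spearman":
        M = _corr_scores(X, rank_first=True)
    elif method == "clr":
        M = _clr_scores(X)
    elif method == "pcor":
        M = _pcor_scores(X)
    else:
        raise ValueError(f"unknown inference method: {method!r}")
    M = np.maximum(M, M.T)  # keep the higher score of each directed pair
    return EdgeScoreSet(method, list(expr.index), _condense(M))


# ---------------------------------------------------------------------------
# aggregation and backbone
# ---------------------------------------------------------------------------


def aggregate_irp(score_sets: list[EdgeScoreSet]) -> AggregatedNetwork:
    """Inverse-rank-product aggregation across inference methods.

    Per method, edges are ranked 1 = strongest with average ranks on ties;
    the rank product is the geometric mean of per-method ranks and the
    aggregate score its inverse. Edges are returned sorted by rank product.
    """

    if not score_sets:
        raise ValueError("need at least one score set")
    genes = score_sets[0].genes
    for s in score_sets[1:]:
        if s.genes != genes:
            raise ValueError("score sets cover different gene universes")
    n = len(genes)
    iu = np.triu_indices(n, k=1)
    n_edges = iu[0].size
    log_rp = np.zeros(n_edges)
    ranks = {}
    for s in score_sets:
        sc = s.scores if s.higher_is_stronger else -s.scores
        r = stats.rankdata(-sc, method="average")  # 1 = best
        ranks[s.method] = r
        log_rp += np.log(r)
    log_rp /= len(score_sets)
    rp = np.exp(log_rp)
    edges = pd.DataFrame(
        {
            "gene_a": [genes[i] for i in iu[0]],
            "gene_b": [genes[j] for j in iu[1]],
            **{f"rank_{m}": r for m, r in ranks.items()},
            "rank_product": rp,
            "irp_score": 1.0 / rp,
        }
    )
    edges = edges.sort_values("rank_product", kind="stable").reset_index(drop=True)
    return AggregatedNetwork(genes=genes, edges=edges,
                             meta={"methods": [s.method for s in score_sets]})


def backbone(
    network: AggregatedNetwork, sigma: float = 2.32, unit: str = "min"
) -> AggregatedNetwork:
    """Noise-corrected backbone filter at the given z threshold.

    Null: each of the T total weight units falls on edge (i, j) with
    probability ``p_ij = s_i s_j / T^2``; keep the edge iff
    ``(w_ij - T p_ij) / sqrt(T p_ij (1 - p_ij)) >= sigma``.

    The z statistic is weight-unit dependent (a global rescale by c scales z
    by sqrt(c)), so weights must be expressed in a count-like unit.
    ``unit="min"`` (default) divides by the smallest positive weight, making
    the weakest edge one observation unit; ``unit="raw"`` uses weights as
    given. The variance uses the binomial form of the null.
    """

    edges = network.edges
    w = edges["irp_score"].to_numpy(dtype=float)
    if np.any(w < 0):
        raise ValueError("backbone filter requires nonnegative edge weights")
    if unit == "min" and (w > 0).any():
        w = w / w[w > 0].min()
    elif unit not in ("min", "raw"):
        raise ValueError("unit must be 'min' or 'raw'")
    T = w.sum()
    if T == 0:
        network.backbone_edges = edges.iloc[0:0].assign(backbone_z=[])
        return network
    strength: dict[str, float] = {}
    for a, b, wv in zip(edges["gene_a"], edges["gene_b"], w):
        strength[a] = strength.get(a, 0.0) + wv
        strength[b] = strength.get(b, 0.0) + wv
    s_a = np.array([strength[a] for a in edges["gene_a"]])
    s_b = np.array([strength[b] for b in edges["gene_b"]])
    p = s_a * s_b / T**2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (w - T * p) / np.sqrt(T * p * (1.0 - p))
    z = np.where(np.isfinite(z), z, -np.inf)
    out = edges.assign(backbone_z=z)
    network.edges = out
    network.backbone_edges = out[out["backbone_z"] >= sigma].reset_index(drop=True)
    network.meta["sigma"] = sigma
    return network


# ---------------------------------------------------------------------------
# partitioning, centralities, summaries
# ---------------------------------------------------------------------------


def partition(network: AggregatedNetwork, seed: int = 0) -> pd.Series:
    """Cluster labels ``component:cluster`` on the backbone graph.

    Components are indexed by size rank (1 = largest); within each component
    clusters come from greedy modularity maximisation (weighted), a
    documented substitute for a map-equation optimizer. Deterministic.
    """

    G = network.graph(backbone_only=True)
    labels = {}
    comps = sorted(nx.connected_components(G), key=lambda c: (-len(c), sorted(c)[0]))
    comp_of = {}
    for ci, comp in enumerate(comps, start=1):
        for node in comp:
            comp_of[node] = ci
    if G.number_of_edges() > 0:
        communities = nx.community.greedy_modularity_communities(
            G, weight="weight"
        )
    else:
        communities = [frozenset([n]) for n in G]
    communities = sorted(communities, key=lambda c: (-len(c), sorted(c)[0]))
    counters: dict[int, int] = {}
    for community in communities:
        ci = comp_of[next(iter(community))]  # communities never span components
        counters[ci] = counters.get(ci, 0) + 1
        for node in community:
            labels[node] = f"{ci}:{counters[ci]}"
    out = pd.Series(labels, name="cluster")
    network.partition_labels = out
    return out


def centralities(network: AggregatedNetwork) -> pd.DataFrame:
    """Node centrality table on the backbone graph.

    Columns: degree, strength, pagerank (damping 0.85, tol 1e-9),
    betweenness (exact), eigenvector, katz (alpha = 0.9 / lambda_max),
    hub, authority.
    """

    G = network.graph(backbone_only=True)
    if G.number_of_nodes() == 0:
        return pd.DataFrame(
            columns=["degree", "strength", "pagerank", "betweenness",
                     "eigenvector", "katz", "hub", "authority"]
        )
    degree = dict(G.degree())
    strength = dict(G.degree(weight="weight"))
    pr = nx.pagerank(G, alpha=0.85, tol=1e-9, max_iter=1000, weight="weight")
    bt = nx.betweenness_centrality(G, weight=None)
    try:
        ev = nx.eigenvector_centrality_numpy(G, weight="weight")
    except Exception:
        ev = {n: np.nan for n in G}
    A = nx.to_numpy_array(G, weight="weight")
    lam_max = float(np.max(np.abs(np.linalg.eigvalsh(A)))) if A.size else 0.0
    alpha = 0.9 / lam_max if lam_max > 0 else 0.1
    try:
        kt = nx.katz_centrality_numpy(G, alpha=alpha, weight="weight")
    except Exception:
        kt = {n: np.nan for n in G}
    try:
        hubs, auth = nx.hits(G, max_iter=1000)
    except Exception:
        hubs = auth = {n: np.nan for n in G}
    df = pd.DataFrame(
        {
            "degree": degree, "strength": strength, "pagerank": pr,
            "betweenness": bt, "eigenvector": ev, "katz": kt,
            "hub": hubs, "authority": auth,
        }
    )
    network.centrality_table = df
    return df


def top_central_genes(cent: pd.DataFrame, k: int = 5) -> dict[str, list[str]]:
    """Per-metric top-k gene report."""

    return {c: cent[c].nlargest(k).index.tolist() for c in cent.columns}


def scale_free_fit(G: nx.Graph) -> float:
    """R^2 of the least-squares line on the log-log degree distribution."""

    degs = np.array([d for _, d in G.degree()])
    degs = degs[degs > 0]
    if degs.size == 0:
        return 0.0
    vals, counts = np.unique(degs, return_counts=True)
    if vals.size < 3:
        return 0.0
    x, y = np.log10(vals), np.log10(counts / counts.sum())
    slope, intercept, r, _, _ = stats.linregress(x, y)
    return float(r**2)


def summary_stats(network: AggregatedNetwork) -> dict:
    """Whole-network summary on the backbone graph.

    Path metrics use 1/weight as edge length and are computed on the largest
    connected component.
    """

    G = network.graph(backbone_only=True)
    if G.number_of_nodes() == 0:
        return {
            "n_nodes": 0, "n_edges": 0, "n_components": 0,
            "clustering_coefficient": 0.0, "scale_free_fit": 0.0,
            "average_degree": 0.0, "average_weighted_degree": 0.0,
            "diameter": 0.0, "average_path_length": 0.0,
        }
    for a, b, d in G.edges(data=True):
        d["length"] = 1.0 / d["weight"] if d["weight"] > 0 else np.inf
    comps = list(nx.connected_components(G))
    largest = G.subgraph(max(comps, key=len))
    ecc = nx.eccentricity(
        largest, sp=dict(nx.all_pairs_dijkstra_path_length(largest, weight="length"))
    )
    diameter = max(ecc.values()) if ecc else 0.0
    apl = (
        nx.average_shortest_path_length(largest, weight="length")
        if largest.number_of_nodes() > 1
        else 0.0
    )
    return {
        "n_nodes": G.number_of_nodes(),
        "n_edges": G.number_of_edges(),
        "n_components": len(comps),
        "clustering_coefficient": float(nx.transitivity(G)),
        "scale_free_fit": scale_free_fit(G),
        "average_degree": float(np.mean([d for _, d in G.degree()])),
        "average_weighted_degree": float(
            np.mean([d for _, d in G.degree(weight="weight")])
        ),
        "diameter": float(diameter),
        "average_path_length": float(apl),
    }
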