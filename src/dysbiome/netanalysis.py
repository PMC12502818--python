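"""Co-abundance network inference and comparison.

Networks are inferred per cohort subset by sparse neighbourhood selection on
CLR-transformed abundances: each taxon is lasso-regressed on all others over
a log-spaced penalty path, the penalty is chosen by stability selection
(StARS) over subsamples, and an edge is kept if selected in either
direction.  Topology is summarised by node centralities, global stability
metrics including natural connectivity, and the exact frequency profile of
the nine connected 2-4-node graphlets; networks are compared by graphlet
frequency correlation distance and edge-sharing (Jaccard) distance, which
feed the ordination/PERMANOVA machinery.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm, spearmanr
from sklearn.linear_model import lasso_path

from .coredata import CountTable, DysbiomeError, clr_transform
from .ecostats import DistanceMatrix

GRAPHLET_NAMES = (
    "G0_edge", "G1_path3", "G2_triangle", "G3_path4", "G4_claw",
    "G5_cycle4", "G6_paw", "G7_diamond", "G8_complete4",
)


@dataclass
class CoabundanceNetwork:
    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise DysbiomeError("self-loops are not allowed")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def adjacency(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, weight=None)

    def to_edge_tsv(self, path) -> None:
        rows = [
            (u, v, d.get("sign", 1), d.get("weight", 1.0))
            for u, v, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "sign", "weight"]
                     ).to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


@dataclass
class GraphletProfile:
    counts: np.ndarray  # the 9 connected 2-4 node graphlet counts

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (9,):
            raise DysbiomeError("graphlet profile must have 9 entries")
        if (self.counts < 0).any():
            raise DysbiomeError("graphlet counts must be non-negative")

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(GRAPHLET_NAMES))

    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.astype(float)


@dataclass
class GlobalNetworkStats:
    n_nodes: int
    n_edges: int
    density: float
    clustering: float
    assortativity: float
    diameter: float
    radius: float
    natural_connectivity: float


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def infer_network(
    counts: CountTable,
    seed: int = 0,
    n_lambda: int = 20,
    n_subsamples: int = 30,
    subsample_fraction: float = 0.8,
    instability_target: float = 0.05,
    stability_threshold: float = 0.8,
    pseudocount: float = 0.5,
) -> CoabundanceNetwork:
    """Sparse neighbourhood-selection network with StARS penalty choice.

    The penalty path is log-spaced below the smallest penalty that zeroes
    every neighbourhood; edge instability at each penalty is the mean
    Bernoulli variance of edge selection across subsamples of size
    ``subsample_fraction * n``, and the chosen penalty is the densest one
    whose monotonised instability stays at or below ``instability_target``.
    The reported edges are those selected (OR rule) in at least
    ``stability_threshold`` of the subsamples at that penalty, so unstable
    noise edges near the instability boundary are excluded; signs and
    weights come from the full-data fit.
    """
    if counts.n_samples < 50:
        warnings.warn("fewer than 50 samples: network inference is unstable")
    Z_full = clr_transform(counts, pseudocount=pseudocount).values()
    sds = Z_full.std(axis=0)
    keep = sds > 1e-12
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} constant taxa dropped")
    taxa = [t for t, k in zip(counts.taxon_ids, keep) if k]
    Z_full = Z_full[:, keep]
    n, p = Z_full.shape
    Zs = (Z_full - Z_full.mean(axis=0)) / Z_full.std(axis=0)

    lam_max = max(
        np.max(np.abs(Zs[:, [j for j in range(p) if j != i]].T @ Zs[:, i])) / n
        for i in range(p)
    )
    lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-2), n_lambda)

    def selection_tensor(Z):
        """(n_lambda, p, p) boolean OR-rule adjacency for one data matrix."""
        m = Z.shape[0]
        sel = np.zeros((n_lambda, p, p), dtype=bool)
        for i in range(p):
            others = [j for j in range(p) if j != i]
            _, coefs, _ = lasso_path(Z[:, others], Z[:, i], alphas=lambdas)
            nz = coefs != 0  # (p-1, n_lambda)
            for a in range(n_lambda):
                idx = np.array(others)[nz[:, a]]
                sel[a, i, idx] = True
        return sel | sel.transpose(0, 2, 1)

    rng = np.random.default_rng(seed)
    m = int(np.floor(subsample_fraction * n))
    freq = np.zeros((n_lambda, p, p))
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=m, replace=False)
        freq += selection_tensor(Zs[idx])
    freq /= n_subsamples
    iu = np.triu_indices(p, 1)
    instab = np.array([
        (2.0 * freq[a][iu] * (1.0 - freq[a][iu])).mean() for a in range(n_lambda)
    ])
    instab = np.maximum.accumulate(instab)  # monotonise from sparse side
    ok = np.where(instab <= instability_target)[0]
    chosen = int(ok[-1]) if len(ok) else 0

    # final fit on the full data at the chosen penalty; keep stable edges
    g = nx.Graph()
    g.add_nodes_from(taxa)
    coef_mat = np.zeros((p, p))
    lam = lambdas[chosen]
    for i in range(p):
        others = [j for j in range(p) if j != i]
        _, coefs, _ = lasso_path(Zs[:, others], Zs[:, i], alphas=[lam])
        coef_mat[i, others] = coefs[:, 0]
    stable = freq[chosen] >= stability_threshold
    for i, j in zip(*iu):
        if not stable[i, j]:
            continue
        cij, cji = coef_mat[i, j], coef_mat[j, i]
        c = cij if abs(cij) >= abs(cji) else cji
        g.add_edge(taxa[i], taxa[j], weight=float(abs(c)),
                   sign=int(np.sign(c)) if c != 0 else 1)
    return CoabundanceNetwork(g, provenance={
        "method": "neighborhood_selection", "lambda": float(lam),
        "instability_target": instability_target,
        "n_subsamples": n_subsamples, "n_samples": n, "seed": seed,
    })


# --------------------------------------------------------------------------
# node and global statistics
# --------------------------------------------------------------------------

def node_centralities(net: CoabundanceNetwork) -> pd.DataFrame:
    """Degree, betweenness, PageRank (damping 0.85), eigenvector centrality
    and mean nearest-neighbour degree on the unweighted skeleton."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise DysbiomeError("empty graph")
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=False)
    pagerank = nx.pagerank(g, alpha=0.85)
    try:
        eigen = nx.eigenvector_centrality_numpy(g)
    except Exception:
        eigen = {v: 0.0 for v in g}
    knn = nx.average_neighbor_degree(g)
    return pd.DataFrame({
        "degree": pd.Series(degree, dtype=float),
        "betweenness": pd.Series(betweenness),
        "pagerank": pd.Series(pagerank),
        "eigenvector": pd.Series(eigen),
        "knn_degree": pd.Series(knn),
    }).loc[net.nodes]


def natural_connectivity(adj: np.ndarray) -> float:
    """ln of the average eigenvalue-exponential of the adjacency matrix."""
    n = adj.shape[0]
    if n == 0:
        return 0.0
    lam = np.linalg.eigvalsh(adj)
    return float(logsumexp(lam) - np.log(n))


def global_network_stats(net: CoabundanceNetwork) -> GlobalNetworkStats:
    """Global topology metrics; diameter and radius are computed on the
    largest connected component."""
    g = net.graph
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if n == 0 or m == 0:
        return GlobalNetworkStats(n, m, 0.0, 0.0, float("nan"),
                                  0.0, 0.0, 0.0)
    density = nx.density(g)
    clustering = nx.average_clustering(g)
    try:
        assort = nx.degree_assortativity_coefficient(g)
    except Exception:
        assort = float("nan")
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    diameter = float(nx.diameter(sub)) if len(comp) > 1 else 0.0
    radius = float(nx.radius(sub)) if len(comp) > 1 else 0.0
    nc = natural_connectivity(nx.to_numpy_array(g, weight=None))
    return GlobalNetworkStats(n, m, density, clustering, float(assort),
                              diameter, radius, nc)


# --------------------------------------------------------------------------
# centrality null test
# --------------------------------------------------------------------------

def centrality_null_test(
    net: CoabundanceNetwork,
    n_perm: int = 10000,
    seed: int = 0,
    metric: str = "betweenness",
) -> pd.DataFrame:
    """Per-node one-sided Z-test of a centrality against a degree-preserving
    rewired ensemble (double-edge swaps); falls back to an Erdos-Renyi
    ensemble when the graph is too sparse to rewire."""
    if n_perm < 100:
        raise DysbiomeError("n_perm must be >= 100")
    g = net.graph
    nodes = net.nodes
    obs = node_centralities(net)[metric].to_numpy()
    rng = np.random.default_rng(seed)
    m = g.number_of_edges()
    use_er = m < 2 or g.number_of_nodes() < 4
    if use_er:
        warnings.warn("graph too sparse for rewiring; Erdos-Renyi null used")
    null = np.empty((n_perm, len(nodes)))
    for b in range(n_perm):
        if use_er:
            h = nx.gnm_random_graph(len(nodes), m, seed=int(rng.integers(2 ** 31)))
            h = nx.relabel_nodes(h, dict(enumerate(nodes)))
        else:
            h = g.copy()
            try:
                nx.double_edge_swap(h, nswap=4 * m, max_tries=100 * m,
                                    seed=int(rng.integers(2 ** 31)))
            except nx.NetworkXError:
                pass  # too few successful swaps: keep partial rewiring
        vals = node_centralities(CoabundanceNetwork(h))[metric]
        null[b] = vals.loc[nodes].to_numpy()
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs - mean) / sd, np.nan)
    p = norm.sf(z)
    return pd.DataFrame({
        "node": nodes, "observed": obs, "null_mean": mean, "null_sd": sd,
        "z": z, "p_one_sided": p, "degenerate_null": sd == 0,
    }).set_index("node")


# --------------------------------------------------------------------------
# graphlets
# --------------------------------------------------------------------------

def graphlet_profile(net: CoabundanceNetwork) -> GraphletProfile:
    """Exact counts of the nine connected 2-4-node induced graphlets.

    Non-induced subgraph counts come from closed-form degree / adjacency
    identities; induced counts follow by Moebius inversion over the 4-node
    graph lattice.  Validated against brute-force enumeration in the tests.
    """
    A = net.adjacency()
    n = A.shape[0]
    if n == 0:
        return GraphletProfile(np.zeros(9, dtype=np.int64))
    d = A.sum(axis=1)
    m = int(round(d.sum() / 2))
    A2 = A @ A
    # triangles
    tri_total = int(round(np.trace(A2 @ A) / 6.0))
    tri_per_node = np.diag(A2 @ A) / 2.0
    # induced P3: open 2-paths
    p3 = int(round((d * (d - 1) / 2).sum())) - 3 * tri_total

    iu = np.triu_indices(n, 1)
    edge_mask = A[iu] > 0
    cn = A2[iu][edge_mask]  # common neighbours per edge
    du = d[iu[0]][edge_mask]
    dv = d[iu[1]][edge_mask]

    # non-induced 4-node subgraph counts
    paths4 = int(round(((du - 1) * (dv - 1) - cn).sum()))
    claws = int(round((d * (d - 1) * (d - 2) / 6).sum()))
    trA4 = float(np.trace(A2 @ A2))
    cycles4 = int(round((trA4 - 2 * m - 2 * (d * (d - 1)).sum()) / 8.0))
    paws = int(round((tri_per_node * (d - 2)).sum()))
    diamonds = int(round((cn * (cn - 1) / 2).sum()))
    # K4: edges among common neighbours, summed per edge
    k4 = 0
    ui, vi = iu[0][edge_mask], iu[1][edge_mask]
    for u, v in zip(ui, vi):
        nbrs = np.where((A[u] > 0) & (A[v] > 0))[0]
        if len(nbrs) >= 2:
            k4 += int(A[np.ix_(nbrs, nbrs)].sum() / 2)
    k4 //= 6

    ind_k4 = k4
    ind_diamond = diamonds - 6 * ind_k4
    ind_c4 = cycles4 - ind_diamond - 3 * ind_k4
    ind_paw = paws - 4 * ind_diamond - 12 * ind_k4
    ind_claw = claws - ind_paw - 2 * ind_diamond - 4 * ind_k4
    ind_p4 = (paths4 - 2 * ind_paw - 4 * ind_c4 - 6 * ind_diamond
              - 12 * ind_k4)
    return GraphletProfile(np.array([
        m, p3, tri_total, ind_p4, ind_claw, ind_c4, ind_paw, ind_diamond,
        ind_k4,
    ]))


def graphlet_profile_bruteforce(net: CoabundanceNetwork) -> GraphletProfile:
    """Independent oracle: enumerate all 2-4-node vertex subsets and classify
    the induced subgraph.  Only feasible for small graphs."""
    g = net.graph
    nodes = list(g.nodes)
    counts = np.zeros(9, dtype=np.int64)
    counts[0] = g.number_of_edges()
    for trio in itertools.combinations(nodes, 3):
        e = g.subgraph(trio).number_of_edges()
        if e == 2:
            counts[1] += 1
        elif e == 3:
            counts[2] += 1
    for quad in itertools.combinations(nodes, 4):
        sub = g.subgraph(quad)
        e = sub.number_of_edges()
        if e < 3 or not nx.is_connected(sub):
            continue
        degs = sorted(dict(sub.degree()).values())
        if e == 3:
            counts[3 if degs == [1, 1, 2, 2] else 4] += 1
        elif e == 4:
            counts[5 if degs == [2, 2, 2, 2] else 6] += 1
        elif e == 5:
            counts[7] += 1
        else:
            counts[8] += 1
    return GraphletProfile(counts)


# --------------------------------------------------------------------------
# between-network distances
# --------------------------------------------------------------------------

def network_distance(
    nets: list[CoabundanceNetwork],
    metric: str = "graphlet_correlation",
    ids: list[str] | None = None,
) -> DistanceMatrix:
    """Pairwise distances between networks.

    ``graphlet_correlation``: 1 - Spearman correlation of graphlet frequency
    vectors.  ``edge_sharing``: 1 - Jaccard index of edge sets (requires a
    shared node universe).
    """
    if len(nets) < 2:
        raise DysbiomeError("need at least 2 networks")
    if ids is None:
        ids = [f"net{i + 1}" for i in range(len(nets))]
    n = len(nets)
    dm = np.zeros((n, n))
    if metric == "graphlet_correlation":
        profiles = [graphlet_profile(net).frequencies() for net in nets]
        for i, j in itertools.combinations(range(n), 2):
            if profiles[i].sum() == 0 or profiles[j].sum() == 0:
                warnings.warn("all-zero graphlet vector: pair undefined")
                dm[i, j] = dm[j, i] = np.nan
                continue
            rho = spearmanr(profiles[i], profiles[j]).statistic
            dm[i, j] = dm[j, i] = max(0.0, 1.0 - float(rho))
    elif metric == "edge_sharing":
        universe = set(nets[0].nodes)
        for net in nets[1:]:
            if set(net.nodes) != universe:
                raise DysbiomeError("edge_sharing requires a shared node universe")
        edge_sets = [net.edges for net in nets]
        for i, j in itertools.combinations(range(n), 2):
            union = edge_sets[i] | edge_sets[j]
            if not union:
                dm[i, j] = dm[j, i] = 0.0
                continue
            jac = len(edge_sets[i] & edge_sets[j]) / len(union)
            dm[i, j] = dm[j, i] = 1.0 - jac
    else:
        raise DysbiomeError(f"unknown network distance metric {metric!r}")
    return DistanceMatrix(dm, ids, metric)
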