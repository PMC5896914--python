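"""Subpopulation-level population graphs.

Each sampling site becomes a node; an edge is kept between two sites only
when their multilocus allele frequencies are *conditionally dependent*
given all other sites, in the Gaussian-graphical-model sense.  The fitting
procedure follows the Population Graphs construction: individuals are
encoded as multilocus allele-count vectors, sites are summarised by their
centroids, the among-site covariance is obtained by double-centering the
squared-distance matrix of centroids (Gower transform), and each edge is
screened with the Edge Exclusion Deviance

    EED_ij = -n * ln(1 - rho_ij^2),

where ``rho_ij`` is the partial correlation from the (pseudo-)inverse
covariance and ``n`` the number of genotyped individuals; an edge is kept
when EED exceeds the chi-square(1) critical value.  Retained edges carry a
length on the genetic-distance scale (the centroid distance
``sqrt(s_ii + s_jj - 2 s_ij)``), so that

* the conditional genetic distance (cGD) between two sites is the
  shortest-path length between them in the pruned graph,
* communities of sites are found by leading-eigenvector (spectral)
  modularity maximisation, with edge affinities given by the positive part
  of the among-site correlation (sites whose allele-frequency profiles
  co-vary strongly attract each other; the inverse edge length is
  available as an alternative affinity but has much weaker contrast), and
* gene-flow centrality is the current-flow (random-walk) betweenness with
  edge conductances 1/length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from scipy.stats import chi2

from .genotypes import MISSING, GenotypeTable
from .differentiation import DistanceMatrix
from .netstruct import CommunityPartition

__all__ = [
    "PopulationGraph",
    "encode_populations",
    "fit_population_graph",
    "graph_from_covariance",
    "conditional_genetic_distance",
    "spectral_communities",
    "random_walk_betweenness",
    "key_subpopulation_report",
]


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def encode_populations(
    table: GenotypeTable,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Encode sites as centroids of multilocus allele-count vectors.

    Each individual becomes a vector with one coordinate per allele per
    locus (value 0/1/2 copies), the most common pooled allele of every
    locus being dropped as the reference to avoid the within-locus sum
    constraint.  Missing genotypes are imputed with their site's mean
    vector, so they contribute nothing to the within-site variance.

    Returns
    -------
    centroids : (K, P) site mean vectors
    within_var : (K,) mean squared distance of members to their centroid
        (NaN for single-individual sites, with a warning)
    site_ids : site order of the rows
    """
    sites = table.sites
    if len(sites) < 3:
        raise ValueError("population graphs need at least 3 sites")
    idx = table.site_index()
    n = table.n_individuals

    blocks = []
    for l in range(table.n_loci):
        pairs = table.calls[:, l, :]
        obs = (pairs != MISSING).all(axis=1)
        alleles, counts = np.unique(pairs[obs], return_counts=True)
        ref = alleles[np.argmax(counts)]  # reference allele: most common pooled
        kept = [a for a in alleles if a != ref]
        amap = {a: k for k, a in enumerate(kept)}
        X = np.zeros((n, len(kept)))
        for i in np.flatnonzero(obs):
            for col in range(2):
                a = pairs[i, col]
                if a in amap:
                    X[i, amap[a]] += 1
        # impute missing rows with the site mean of observed rows
        for s in sites:
            members = idx[s]
            m_obs = members[obs[members]]
            m_mis = members[~obs[members]]
            if len(m_mis) and len(m_obs):
                X[m_mis] = X[m_obs].mean(axis=0)
        blocks.append(X)
    X = np.hstack(blocks)

    K = len(sites)
    centroids = np.zeros((K, X.shape[1]))
    within = np.zeros(K)
    for k, s in enumerate(sites):
        members = idx[s]
        centroids[k] = X[members].mean(axis=0)
        if len(members) < 2:
            warnings.warn(f"site {s!r} has one individual; within-site variance undefined")
            within[k] = math.nan
        else:
            within[k] = float(((X[members] - centroids[k]) ** 2).sum(axis=1).mean())
    return centroids, within, sites


# ---------------------------------------------------------------------------
# the graph
# ---------------------------------------------------------------------------

@dataclass
class PopulationGraph:
    """Pruned conditional-dependence graph over sampling sites."""

    site_ids: list[str]
    covariance: np.ndarray  # (K, K) among-site covariance (Gower)
    correlation: np.ndarray  # (K, K) among-site correlation
    partial_corr: np.ndarray  # (K, K)
    eed: np.ndarray  # (K, K) edge exclusion deviance
    adjacency: np.ndarray  # (K, K) bool, retained edges
    lengths: np.ndarray  # (K, K) edge lengths (NaN where no edge)
    within_variance: np.ndarray  # (K,) node attribute
    n: int  # sample size used in the deviance
    alpha: float

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, k=1).sum())

    def edges(self) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(ii.tolist(), jj.tolist()))

    def is_connected(self) -> bool:
        if self.n_sites == 0:
            return False
        return nx.is_connected(self.to_networkx())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for k, s in enumerate(self.site_ids):
            g.add_node(s, within_variance=float(self.within_variance[k]))
        for i, j in self.edges():
            L = float(self.lengths[i, j])
            g.add_edge(
                self.site_ids[i],
                self.site_ids[j],
                length=L,
                conductance=1.0 / L,
                eed=float(self.eed[i, j]),
                partial_corr=float(self.partial_corr[i, j]),
            )
        return g

    def to_igraph(self, affinity: str = "correlation") -> ig.Graph:
        """igraph view with edge ``weight`` set to the chosen affinity
        (``"correlation"``: positive among-site correlation;
        ``"inverse_length"``: 1/length)."""
        g = ig.Graph(n=self.n_sites, edges=self.edges())
        g.vs["name"] = self.site_ids
        g.es["length"] = [float(self.lengths[i, j]) for i, j in self.edges()]
        if affinity == "correlation":
            g.es["weight"] = [
                max(float(self.correlation[i, j]), 1e-6) for i, j in self.edges()
            ]
        elif affinity == "inverse_length":
            g.es["weight"] = [1.0 / float(self.lengths[i, j]) for i, j in self.edges()]
        else:
            raise ValueError(f"unknown affinity {affinity!r}")
        return g

    def write_graphml(self, path, extra_node_attrs: pd.DataFrame | None = None) -> None:
        g = self.to_networkx()
        if extra_node_attrs is not None:
            for col in extra_node_attrs.columns:
                nx.set_node_attributes(
                    g, {s: float(v) for s, v in extra_node_attrs[col].items()}, col
                )
        nx.write_graphml(g, path)


def graph_from_covariance(
    cov: np.ndarray,
    n: int,
    alpha: float = 0.05,
    site_ids: list[str] | None = None,
    within_variance: np.ndarray | None = None,
    bonferroni: bool = False,
) -> PopulationGraph:
    """Prune a site covariance matrix into a conditional-dependence graph.

    The covariance is inverted (Moore–Penrose pseudo-inverse when
    rank-deficient, which is the rule for Gower-centred matrices; the
    condition number is reported in a warning), partial correlations are
    ``-w_ij / sqrt(w_ii w_jj)``, and edge (i, j) is retained when
    ``EED = -n ln(1 - rho^2)`` exceeds the chi-square(1) critical value at
    ``alpha`` (Bonferroni-corrected over the K(K-1)/2 edges on request).
    Edge length is ``sqrt(s_ii + s_jj - 2 s_ij)``.
    """
    cov = np.asarray(cov, dtype=float)
    K = cov.shape[0]
    if site_ids is None:
        site_ids = [f"site_{k + 1:02d}" for k in range(K)]
    if within_variance is None:
        within_variance = np.full(K, math.nan)
    sv = np.linalg.svd(cov, compute_uv=False)
    rank = int((sv > sv[0] * 1e-10).sum()) if sv.size else 0
    if rank < K:
        warnings.warn(
            f"covariance is rank-deficient (rank {rank} < {K}); using the "
            f"pseudo-inverse (condition number of retained spectrum "
            f"{sv[0] / sv[rank - 1]:.3g})"
        )
    omega = np.linalg.pinv(cov, rcond=1e-10, hermitian=True)
    d = np.sqrt(np.clip(np.diag(omega), 1e-300, None))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    rho2 = np.clip(rho**2, 0.0, 1.0 - 1e-12)
    eed = -n * np.log1p(-rho2)
    m_tests = K * (K - 1) // 2
    level = alpha / m_tests if bonferroni else alpha
    crit = chi2.ppf(1.0 - level, df=1)
    adjacency = eed > crit
    np.fill_diagonal(adjacency, False)

    diag = np.diag(cov)
    with np.errstate(invalid="ignore"):
        lengths = np.sqrt(np.clip(diag[:, None] + diag[None, :] - 2.0 * cov, 0.0, None))
    lengths = np.where(adjacency, lengths, np.nan)
    dd = np.sqrt(np.clip(diag, 1e-300, None))
    corr = cov / np.outer(dd, dd)
    graph = PopulationGraph(
        list(site_ids), cov, corr, rho, eed, adjacency, lengths,
        np.asarray(within_variance, dtype=float), n, alpha,
    )
    if not graph.is_connected():
        warnings.warn("pruned population graph is disconnected; cGD will be partial")
    return graph


def fit_population_graph(
    table: GenotypeTable, alpha: float = 0.05, bonferroni: bool = False
) -> PopulationGraph:
    """Full Population-Graphs fit from a genotype table."""
    centroids, within, sites = encode_populations(table)
    d2 = ((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    K = d2.shape[0]
    J = np.eye(K) - np.ones((K, K)) / K
    cov = -0.5 * J @ d2 @ J
    cov = (cov + cov.T) / 2.0
    return graph_from_covariance(
        cov, n=table.n_individuals, alpha=alpha, site_ids=sites,
        within_variance=within, bonferroni=bonferroni,
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def conditional_genetic_distance(graph: PopulationGraph) -> DistanceMatrix:
    """All-pairs shortest-path lengths over retained edges (Dijkstra).

    Disconnected pairs are infinite (with a warning); if every pair is
    disconnected an error is raised.
    """
    K = graph.n_sites
    W = np.where(graph.adjacency, np.nan_to_num(graph.lengths, nan=0.0), 0.0)
    d = dijkstra(W, directed=False)
    np.fill_diagonal(d, 0.0)
    off = d[np.triu_indices(K, k=1)]
    if np.isinf(off).all():
        raise ValueError("population graph has no connected site pairs")
    if np.isinf(off).any():
        warnings.warn("disconnected site pairs have infinite cGD")
    return DistanceMatrix(d, list(graph.site_ids), "cgd")


def spectral_communities(
    graph: PopulationGraph, affinity: str = "correlation"
) -> CommunityPartition:
    """Leading-eigenvector (spectral) modularity communities of the pruned
    graph.  The default edge affinity is the positive among-site
    correlation, which separates genetically coherent groups far more
    sharply than the inverse edge length (also available)."""
    import random as _random

    g = graph.to_igraph(affinity=affinity)
    if g.ecount() == 0:
        raise ValueError("population graph has no edges; communities undefined")
    # ARPACK inside the leading-eigenvector routine consumes igraph's
    # global RNG; seed it locally so the partition is a deterministic
    # function of the graph.  Occasional non-convergence for a given start
    # vector is retried with the next seed (still deterministic).
    last_error: Exception | None = None
    clustering = None
    for attempt in range(5):
        try:
            ig.set_random_number_generator(_random.Random(attempt))
            clustering = g.community_leading_eigenvector(weights="weight")
            break
        except ig.InternalError as exc:  # ARPACK did not converge
            last_error = exc
        finally:
            ig.set_random_number_generator(_random)
    if clustering is None:
        raise RuntimeError(f"leading-eigenvector decomposition failed: {last_error}")
    q = g.modularity(clustering.membership, weights="weight")
    membership = {g.vs[i]["name"]: int(c) for i, c in enumerate(clustering.membership)}
    return CommunityPartition(membership, float(q))


def random_walk_betweenness(graph: PopulationGraph) -> pd.Series:
    """Current-flow (random-walk) betweenness centrality per site.

    Unit current is injected between every source-target pair; a node's
    score is the mean over pairs (excluding pairs that contain it) of the
    net current flowing through it, i.e. normalised by (n-1)(n-2)/2, so
    scores lie in [0, 1].  Edge conductance is 1/length.  On a
    disconnected graph scores are computed per component (components
    smaller than 3 nodes score 0) with a warning.
    """
    g = graph.to_networkx()
    scores = pd.Series(0.0, index=list(graph.site_ids), name="RWB")
    components = [g.subgraph(c).copy() for c in nx.connected_components(g)]
    if len(components) > 1:
        warnings.warn("disconnected graph: RWB computed per component")
    for comp in components:
        if comp.number_of_nodes() < 3:
            continue
        cfb = nx.current_flow_betweenness_centrality(
            comp, normalized=True, weight="conductance"
        )
        for node, val in cfb.items():
            scores[node] = float(val)
    return scores


def key_subpopulation_report(
    graph: PopulationGraph,
    scores: pd.Series,
    summary,
    communities: CommunityPartition | None = None,
) -> pd.DataFrame:
    """Per-site conservation-relevance table: diversity (Ho, AR), gene-flow
    centrality (RWB), community membership and the two rankings.  No
    composite score is computed: diversity hotspots and gene-flow hubs are
    distinct, equally legitimate priorities."""
    sites = list(graph.site_ids)
    if sorted(scores.index) != sorted(sites) or sorted(summary.table.index) != sorted(sites):
        raise ValueError("graph, centrality scores and diversity summary must cover the same sites")
    out = pd.DataFrame(index=pd.Index(sites, name="site"))
    out["Ho"] = summary.table["Ho"]
    out["AR"] = summary.table["AR"]
    out["RWB"] = scores
    out["within_variance"] = graph.within_variance
    if communities is not None:
        out["community"] = [communities.membership.get(s, -1) for s in sites]
    out["rank_diversity"] = out["Ho"].rank(ascending=False, method="min").astype(int)
    out["rank_AR"] = out["AR"].rank(ascending=False, method="min").astype(int)
    out["rank_RWB"] = out["RWB"].rank(ascending=False, method="min").astype(int)
    return out
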