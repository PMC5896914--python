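"""Individual-level genetic-similarity networks.

Individuals are nodes; edge weights are allele-sharing similarities in
[0, 1].  Removing edges below increasing similarity thresholds exposes
progressively finer population structure; at each threshold communities
are detected by greedy modularity maximisation (FastGreedy) and tested for
association with sampling sites using Fisher's exact test on the
community x site contingency table.  Following a conservative
all-thresholds rule, site structure is declared only when the association
is significant at every threshold that yields a testable network.

Two similarity weightings are available for a pair (i, j): with
``m_a = min(copies of allele a in i, copies in j)`` at a locus,

* ``uniform``:    ``s = sum_a m_a / 2`` (plain allele sharing);
* ``frequency``:  ``s = sum_a (m_a / 2) (1 - f_a)`` with ``f_a`` the pooled
  allele frequency, so sharing a rare allele counts for more.

The per-pair similarity is the mean of ``s`` over the loci scorable in
both individuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import fisher_exact, random_table

from .genotypes import GenotypeTable
from .differentiation import _allele_count_masks
from .permutation import TestResult, mc_pvalue

__all__ = [
    "IndividualNetwork",
    "CommunityPartition",
    "SweepResult",
    "similarity_matrix",
    "apply_threshold",
    "fast_greedy_communities",
    "site_association_test",
    "threshold_sweep",
]


@dataclass
class IndividualNetwork:
    """Weighted genetic-similarity graph over individuals."""

    node_ids: list[str]
    site_labels: list[str]
    weights: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    threshold: float | None = None  # None: base network (no edges removed)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T):
            raise ValueError("similarity matrix must be symmetric")
        if (w < -1e-9).any() or (w > 1 + 1e-9).any():
            raise ValueError("similarities must lie in [0, 1]")
        np.fill_diagonal(w, 0.0)
        self.weights = np.clip(w, 0.0, 1.0)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def edge_mask(self) -> np.ndarray:
        """Upper-triangle boolean mask of present edges (weight > 0)."""
        mask = np.triu(self.weights > 0, k=1)
        return mask

    @property
    def n_edges(self) -> int:
        return int(self.edge_mask().sum())

    def degrees(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=1)

    def connected_nodes(self) -> np.ndarray:
        """Indices of nodes with at least one incident edge."""
        return np.flatnonzero(self.degrees() > 0)

    def to_igraph(self, nodes: np.ndarray | None = None) -> ig.Graph:
        if nodes is None:
            nodes = np.arange(self.n_nodes)
        sub = self.weights[np.ix_(nodes, nodes)]
        ii, jj = np.nonzero(np.triu(sub > 0, k=1))
        g = ig.Graph(n=len(nodes), edges=list(zip(ii.tolist(), jj.tolist())))
        g.es["weight"] = sub[ii, jj].tolist()
        g.vs["name"] = [self.node_ids[i] for i in nodes]
        g.vs["site"] = [self.site_labels[i] for i in nodes]
        return g

    def to_edge_list(self) -> pd.DataFrame:
        ii, jj = np.nonzero(self.edge_mask())
        return pd.DataFrame(
            {
                "source": [self.node_ids[i] for i in ii],
                "target": [self.node_ids[j] for j in jj],
                "weight": self.weights[ii, jj],
            }
        )


@dataclass
class CommunityPartition:
    """Node -> community assignment with the modularity of the partition."""

    membership: dict[str, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


@dataclass
class SweepResult:
    """Outcome of an edge-removal threshold sweep (one row per threshold)."""

    table: pd.DataFrame  # threshold, n_communities, n_connected, p_value, tested
    alpha: float
    reject: bool  # all-thresholds rule over the tested thresholds


def similarity_matrix(
    table: GenotypeTable, weighting: str = "frequency"
) -> IndividualNetwork:
    """Genetic-similarity network over all individuals of a genotype table."""
    if table.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if weighting not in ("uniform", "frequency"):
        raise ValueError(f"unknown weighting {weighting!r}")
    n = table.n_individuals
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for b1, b2, obs, freq in _allele_count_masks(table):
        w = 0.5 * (1.0 - freq) if weighting == "frequency" else np.full(freq.size, 0.5)
        s = (b1 * w) @ b1.T + (b2 * w) @ b2.T
        both = np.outer(obs, obs).astype(float)
        num += s * both
        den += both
    with np.errstate(invalid="ignore"):
        sim = num / den
    no_shared = den == 0
    np.fill_diagonal(no_shared, False)
    if no_shared.any():
        warnings.warn(
            f"{int(no_shared.sum() // 2)} individual pairs share no scorable "
            "locus; their similarity is set to 0"
        )
        sim[no_shared] = 0.0
    all_missing = table.missing_mask().all(axis=1)
    if all_missing.any():
        dropped = [table.individual_ids[i] for i in np.flatnonzero(all_missing)]
        warnings.warn(f"individuals missing at all loci excluded: {dropped}")
        keep = np.flatnonzero(~all_missing)
        return IndividualNetwork(
            [table.individual_ids[i] for i in keep],
            [table.site_ids[i] for i in keep],
            sim[np.ix_(keep, keep)],
        )
    np.fill_diagonal(sim, 0.0)
    return IndividualNetwork(list(table.individual_ids), list(table.site_ids), sim)


def apply_threshold(net: IndividualNetwork, t: float) -> IndividualNetwork:
    """Remove edges with weight below ``t`` (weights >= t are kept)."""
    if t < 0:
        raise ValueError("threshold must be non-negative")
    w = net.weights.copy()
    w[w < t] = 0.0
    return IndividualNetwork(list(net.node_ids), list(net.site_labels), w, threshold=t)


def fast_greedy_communities(net: IndividualNetwork) -> CommunityPartition:
    """Greedy agglomerative modularity maximisation (Clauset–Newman–Moore)
    on the weighted network; isolated nodes are excluded."""
    nodes = net.connected_nodes()
    if len(nodes) == 0 or net.n_edges == 0:
        raise ValueError("network has no edges; communities undefined")
    g = net.to_igraph(nodes)
    dendro = g.community_fastgreedy(weights="weight")
    clustering = dendro.as_clustering()
    q = g.modularity(clustering.membership, weights="weight")
    membership = {
        g.vs[i]["name"]: int(c) for i, c in enumerate(clustering.membership)
    }
    return CommunityPartition(membership, float(q))


def _log_table_prob(tab: np.ndarray, lgr: float, lgc: float, lgn: float) -> np.ndarray:
    """Log multivariate-hypergeometric probability of tables with fixed
    margins; ``tab`` is (..., r, c)."""
    return lgr + lgc - lgn - gammaln(tab + 1.0).sum(axis=(-2, -1))


def site_association_test(
    partition: CommunityPartition,
    site_labels: dict[str, str],
    n_mc: int = 100_000,
    seed: int = 0,
    force_mc: bool = False,
) -> TestResult:
    """Fisher's exact test of independence between detected communities
    and sampling sites.

    2x2 tables use the exact two-sided hypergeometric p; larger tables use
    a Monte-Carlo Fisher test: random tables with the observed margins are
    sampled and the p-value is the fraction with probability at most that
    of the observed table (+1 smoothing).
    """
    nodes = list(partition.membership)
    comm = pd.Series({v: partition.membership[v] for v in nodes})
    site = pd.Series({v: site_labels[v] for v in nodes})
    tab = pd.crosstab(comm, site).to_numpy()
    method = "fisher_exact"
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return TestResult(math.nan, None, 0, seed, method, "untestable: degenerate table")
    if tab.shape == (2, 2) and not force_mc:
        _, p = fisher_exact(tab, alternative="two-sided")
        return TestResult(float(tab[0, 0]), float(p), 0, seed, method)
    r_marg = tab.sum(axis=1)
    c_marg = tab.sum(axis=0)
    lgr = gammaln(r_marg + 1.0).sum()
    lgc = gammaln(c_marg + 1.0).sum()
    lgn = gammaln(tab.sum() + 1.0)
    obs = _log_table_prob(tab.astype(float), lgr, lgc, lgn)
    rng = np.random.default_rng(seed)
    sampler = random_table(r_marg, c_marg)
    n_exceed = 0
    batch = 20_000
    remaining = n_mc
    while remaining > 0:
        b = min(batch, remaining)
        draws = sampler.rvs(b, random_state=rng)
        lp = _log_table_prob(draws.astype(float), lgr, lgc, lgn)
        n_exceed += int((lp <= obs + 1e-9).sum())
        remaining -= b
    return TestResult(
        float(obs), mc_pvalue(n_exceed, n_mc), n_mc, seed, "fisher_exact_mc"
    )


def default_threshold_grid(net: IndividualNetwork, n: int = 20, quantile: float = 0.9) -> np.ndarray:
    """Evenly spaced thresholds from 0 to the ``quantile`` of positive
    edge weights."""
    pos = net.weights[np.triu(net.weights > 0, k=1)]
    if pos.size == 0:
        raise ValueError("network has no positive edge weights")
    top = float(np.quantile(pos, quantile))
    return np.linspace(0.0, top, n)


def threshold_sweep(
    net: IndividualNetwork,
    thresholds: np.ndarray | None = None,
    n_mc: int = 100_000,
    seed: int = 0,
    alpha: float = 0.05,
    min_connected_frac: float = 0.5,
) -> SweepResult:
    """Run the full edge-removal sweep and apply the all-thresholds rule.

    A threshold is *tested* only if at least ``min_connected_frac`` of the
    nodes remain connected and at least two communities are found; the
    overall null (no community-site association) is rejected only when
    ``p < alpha`` at every tested threshold.
    """
    if thresholds is None:
        thresholds = default_threshold_grid(net)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0 or (np.diff(thresholds) < 0).any():
        raise ValueError("thresholds must be a non-empty ascending list")
    if thresholds[0] != 0:
        raise ValueError("the first threshold must be 0 (no edges removed)")
    site_map = dict(zip(net.node_ids, net.site_labels))
    rng = np.random.default_rng(seed)
    rows = []
    for t in thresholds:
        sub = apply_threshold(net, float(t))
        n_connected = int(len(sub.connected_nodes()))
        if sub.n_edges == 0:
            rows.append((t, 0, 0, math.nan, False))
            continue
        part = fast_greedy_communities(sub)
        res = site_association_test(part, site_map, n_mc=n_mc, seed=int(rng.integers(2**31)))
        tested = (
            res.testable
            and n_connected >= min_connected_frac * net.n_nodes
            and part.n_communities >= 2
        )
        rows.append((t, part.n_communities, n_connected, res.p_value, tested))
    df = pd.DataFrame(
        rows, columns=["threshold", "n_communities", "n_connected", "p_value", "tested"]
    )
    tested = df[df["tested"]]
    if tested.empty:
        raise ValueError("no testable thresholds in the sweep")
    reject = bool((tested["p_value"] < alpha).all())
    return SweepResult(df, alpha, reject)
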