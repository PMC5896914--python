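"""Between-subpopulation differentiation.

The workhorse estimator is a two-level AMOVA (among / within sampling
sites) on gene copies: each diploid contributes two allele copies, the
squared distance between two copies is 0 when they are the same allele
and 1 otherwise, variance components follow the standard AMOVA sums of
squares (summed over loci), and ``Fst = sigma2_among / (sigma2_among +
sigma2_within)``.  This is the classical codominant AMOVA whose Fst is on
the Weir–Cockerham theta scale.  Significance is assessed by permuting
*individuals* (keeping their two copies together) across sites.  A
Weir–Cockerham theta estimator is provided as an independent cross-check.

Because microsatellites are highly polymorphic, the attainable range of
Fst-type statistics is far below [0, 1]; ``fst_upper_bounds`` computes the
maximum Gst-form Fst compatible with the pooled frequency of the most
common allele (M) and with the pooled homozygosity, per locus, so that an
observed Fst can be judged against its true ceiling.

Isolation by distance is tested with a one-tailed Mantel permutation test
between a genetic distance matrix (linearised Fst, or the conditional
genetic distance from a population graph) and great-circle geographic
distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genotypes import MISSING, AlleleFrequencyTable, GenotypeTable, SiteTable
from .permutation import TestResult, mc_pvalue

__all__ = [
    "DistanceMatrix",
    "AmovaResult",
    "FstBounds",
    "amova",
    "pairwise_fst",
    "weir_cockerham_theta",
    "fst_upper_bounds",
    "max_fst_given_M",
    "max_fst_given_homozygosity",
    "linearize_fst",
    "geographic_distances",
    "mantel_test",
]

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Site-indexed symmetric distance matrix with a kind label."""

    values: np.ndarray
    ids: list[str]
    kind: str  # fst | linearized_fst | cgd | geographic_km

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, float_format="%.6g")


# ---------------------------------------------------------------------------
# genotype mismatch distances
# ---------------------------------------------------------------------------

def _allele_count_masks(table: GenotypeTable) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Per locus: (B1, B2, observed, pooled frequency vector).

    ``B1[i, a]`` is 1 when individual i carries at least one copy of allele
    a, ``B2`` when homozygous; with counts in {0, 1, 2} the shared-allele
    count between i and j is ``B1 B1' + B2 B2'``.
    """
    out = []
    for l in range(table.n_loci):
        pairs = table.calls[:, l, :]
        obs = (pairs != MISSING).all(axis=1)
        alleles = np.unique(pairs[obs])
        amap = {a: k for k, a in enumerate(alleles)}
        n, A = table.n_individuals, len(alleles)
        counts = np.zeros((n, A), dtype=np.float64)
        for col in range(2):
            for i in np.flatnonzero(obs):
                counts[i, amap[pairs[i, col]]] += 1
        b1 = (counts >= 1).astype(np.float64)
        b2 = (counts >= 2).astype(np.float64)
        total = counts[obs].sum()
        freq = counts[obs].sum(axis=0) / total if total else np.zeros(A)
        out.append((b1, b2, obs, freq))
    return out


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _locus_counts(table: GenotypeTable) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per locus: (C, m) with ``C[i, a]`` = copies of allele a carried by
    individual i (0/1/2, zero row when missing) and ``m[i]`` the number of
    scorable copies (0 or 2)."""
    out = []
    for l in range(table.n_loci):
        pairs = table.calls[:, l, :]
        obs = (pairs != MISSING).all(axis=1)
        alleles = np.unique(pairs[obs])
        amap = {a: k for k, a in enumerate(alleles)}
        C = np.zeros((table.n_individuals, len(alleles)))
        for i in np.flatnonzero(obs):
            for col in range(2):
                C[i, amap[pairs[i, col]]] += 1
        m = np.where(obs, 2.0, 0.0)
        out.append((C, m))
    return out


def _ss_from_counts(allele_counts: np.ndarray, n_copies: float) -> float:
    """Sum of squared 0/1 distances within a group of gene copies, divided
    by the group size: ``(n^2 - sum_a c_a^2) / (2 n)``."""
    if n_copies <= 0:
        return 0.0
    return float((n_copies**2 - (allele_counts**2).sum()) / (2.0 * n_copies))


def _amova_from_counts(
    locus_counts: list[tuple[np.ndarray, np.ndarray]],
    groups: list[np.ndarray],
) -> tuple[float, float, int, int, float, float, float]:
    """Variance components summed over loci for a grouping of individuals."""
    ss_a_sum = ss_w_sum = 0.0
    df_a_sum = df_w_sum = 0
    sigma_a_sum = sigma_w_sum = 0.0
    for C, m in locus_counts:
        sizes = np.array([m[g].sum() for g in groups])
        present = sizes > 0
        k = int(present.sum())
        if k < 2:
            continue
        n_tot = sizes.sum()
        ss_t = _ss_from_counts(C.sum(axis=0), n_tot)
        ss_w = sum(
            _ss_from_counts(C[g].sum(axis=0), sizes[gi])
            for gi, g in enumerate(groups)
            if present[gi]
        )
        ss_a = ss_t - ss_w
        df_a, df_w = k - 1, int(n_tot) - k
        if df_w <= 0:
            continue
        ms_w = ss_w / df_w
        ms_a = ss_a / df_a
        n0 = (n_tot - (sizes[present] ** 2).sum() / n_tot) / df_a
        sigma_a_sum += (ms_a - ms_w) / n0
        sigma_w_sum += ms_w
        ss_a_sum += ss_a
        ss_w_sum += ss_w
        df_a_sum += df_a
        df_w_sum += df_w
    denom = max(sigma_a_sum, 0.0) + sigma_w_sum
    fst = max(sigma_a_sum, 0.0) / denom if denom > 0 else 0.0
    return ss_a_sum, ss_w_sum, df_a_sum, df_w_sum, sigma_a_sum, sigma_w_sum, fst

@dataclass
class AmovaResult:
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma2_among: float  # raw estimate, may be negative
    sigma2_within: float
    fst: float  # negative component clamped to 0
    p_value: float | None
    n_permutations: int
    seed: int | None = None

    @property
    def negative_component(self) -> bool:
        return self.sigma2_among < 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": [self.df_among, self.df_within],
                "SS": [self.ss_among, self.ss_within],
                "variance": [self.sigma2_among, self.sigma2_within],
            },
            index=["among_sites", "within_sites"],
        )


def amova(
    table: GenotypeTable,
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """Two-level AMOVA (among / within sampling sites) on gene copies.

    ``p`` is the fraction of ``n_perm`` random permutations of individuals
    across sites with Fst at least the observed value (+1 smoothing); pass
    ``n_perm=0`` to skip the permutation test.
    """
    table.validate_multisite()
    idx = table.site_index()
    for s, g in idx.items():
        if len(g) < 2:
            raise ValueError(f"site {s!r} has fewer than 2 individuals")
    locus_counts = _locus_counts(table)
    groups = list(idx.values())
    ss_a, ss_w, df_a, df_w, s_a, s_w, fst = _amova_from_counts(locus_counts, groups)

    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        n = table.n_individuals
        sizes = [len(g) for g in groups]
        edges = np.cumsum([0] + sizes)
        n_exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            pg = [perm[edges[i] : edges[i + 1]] for i in range(len(sizes))]
            fst_p = _amova_from_counts(locus_counts, pg)[6]
            if fst_p >= fst - 1e-12:
                n_exceed += 1
        p = mc_pvalue(n_exceed, n_perm)
    return AmovaResult(ss_a, ss_w, df_a, df_w, s_a, s_w, fst, p, n_perm, seed)


def pairwise_fst(
    table: GenotypeTable,
    n_perm: int = 999,
    seed: int = 0,
    estimator: str = "amova",
) -> tuple[DistanceMatrix, pd.DataFrame]:
    """Pairwise Fst for every pair of sites, with permutation p-values.

    Pairs involving a site with fewer than 2 individuals are flagged NaN.
    ``estimator`` is ``"amova"`` (default, two-site AMOVA) or
    ``"weir_cockerham"`` (theta; no permutation p in that mode).
    """
    table.validate_multisite()
    sites = table.sites
    idx = table.site_index()
    K = len(sites)
    fst = np.zeros((K, K))
    pvals = np.full((K, K), np.nan)
    locus_counts = _locus_counts(table) if estimator == "amova" else None
    rng = np.random.default_rng(seed)
    for i in range(K):
        for j in range(i + 1, K):
            gi, gj = idx[sites[i]], idx[sites[j]]
            if len(gi) < 2 or len(gj) < 2:
                fst[i, j] = fst[j, i] = np.nan
                continue
            if estimator == "weir_cockerham":
                sub = table.subset(np.concatenate([gi, gj]))
                val = weir_cockerham_theta(sub)
                fst[i, j] = fst[j, i] = val
                continue
            sel = np.concatenate([gi, gj])
            sub_counts = [(C[sel], m[sel]) for C, m in locus_counts]
            groups = [np.arange(len(gi)), np.arange(len(gi), len(sel))]
            obs = _amova_from_counts(sub_counts, groups)[6]
            fst[i, j] = fst[j, i] = obs
            if n_perm > 0:
                n = len(sel)
                n_exceed = 0
                for _ in range(n_perm):
                    perm = rng.permutation(n)
                    pg = [perm[: len(gi)], perm[len(gi) :]]
                    if _amova_from_counts(sub_counts, pg)[6] >= obs - 1e-12:
                        n_exceed += 1
                pvals[i, j] = pvals[j, i] = mc_pvalue(n_exceed, n_perm)
    dm = DistanceMatrix(np.nan_to_num(fst, nan=0.0), sites, "fst")
    # keep NaN flags accessible on the raw array
    dm.values = fst
    np.fill_diagonal(dm.values, 0.0)
    pdf = pd.DataFrame(pvals, index=sites, columns=sites)
    return dm, pdf


def combined_fst_p_table(fst: DistanceMatrix, pvals: pd.DataFrame) -> pd.DataFrame:
    """Square table with Fst below the diagonal and p-values above."""
    out = pd.DataFrame(np.nan, index=fst.ids, columns=fst.ids)
    v = fst.values
    for i, a in enumerate(fst.ids):
        for j, b in enumerate(fst.ids):
            if i > j:
                out.loc[a, b] = v[i, j]
            elif i < j:
                out.loc[a, b] = pvals.iloc[i, j]
    return out


# ---------------------------------------------------------------------------
# Weir-Cockerham theta (independent cross-check estimator)
# ---------------------------------------------------------------------------

def weir_cockerham_theta(table: GenotypeTable) -> float:
    """Multi-allele, multi-locus Weir–Cockerham theta (ratio of sums)."""
    table.validate_multisite()
    idx = table.site_index()
    sites = table.sites
    r = len(sites)
    num = 0.0
    den = 0.0
    for l in range(table.n_loci):
        pairs = table.calls[:, l, :]
        obs = (pairs != MISSING).all(axis=1)
        n_i = np.array([(obs[idx[s]]).sum() for s in sites], dtype=float)
        if (n_i < 1).any():
            continue
        alleles = np.unique(pairs[obs])
        nbar = n_i.mean()
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        for a in alleles:
            p_ia = np.array(
                [
                    (pairs[idx[s]][obs[idx[s]]] == a).sum() / (2.0 * (obs[idx[s]]).sum())
                    for s in sites
                ]
            )
            h_ia = np.array(
                [
                    (
                        ((pairs[idx[s]][obs[idx[s]]] == a).sum(axis=1) == 1).sum()
                        / (obs[idx[s]]).sum()
                    )
                    for s in sites
                ]
            )
            pbar = (n_i * p_ia).sum() / (r * nbar)
            s2 = (n_i * (p_ia - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_ia).sum() / (r * nbar)
            a_comp = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
            )
            b_comp = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c_comp = hbar / 2.0
            num += a_comp
            den += a_comp + b_comp + c_comp
    return num / den if den != 0 else math.nan


# ---------------------------------------------------------------------------
# Fst upper bounds (bounded-by-diversity theory)
# ---------------------------------------------------------------------------

def max_fst_given_M(M: float, K: int) -> float:
    """Maximum Gst-form Fst over K equal-sized subpopulations when the
    pooled frequency of the most common allele is ``M``.

    For ``M >= 1/K`` the extremal configuration fixes ``floor(K*M)``
    subpopulations on the most common allele, gives one subpopulation the
    fractional remainder (rest of its mass on a single private allele) and
    fixes the remaining subpopulations on distinct private alleles.  For
    ``M < 1/K`` no subpopulation can be fixed; the optimum spreads private
    alleles at within-subpopulation frequency ``K*M``.
    """
    if not 0 < M <= 1:
        raise ValueError("M must lie in (0, 1]")
    if M == 1.0:
        return math.nan  # monomorphic: bound undefined
    if K < 2:
        raise ValueError("need K >= 2 subpopulations")
    if M * K >= 1.0:
        j = int(math.floor(K * M + 1e-12))
        x = K * M - j
        if x <= 1e-12:
            return 1.0
        j_s = 1.0 - 2.0 * x * (1.0 - x) / K
        j_t = M * M + (1.0 - x) ** 2 / K**2 + (K - j - 1) / K**2
        return (j_s - j_t) / (1.0 - j_t)
    # all-private regime: per subpopulation, floor(1/(K*M)) alleles at K*M
    q = K * M
    full = int(math.floor(1.0 / q + 1e-12))
    rem = 1.0 - full * q
    j_s = full * q * q + rem * rem
    j_t = j_s / K
    return (j_s - j_t) / (1.0 - j_t)


def max_fst_given_homozygosity(J_T: float, K: int) -> float:
    """Maximum Gst-form Fst over K equal-sized subpopulations when the
    pooled homozygosity is ``J_T`` (i.e. total heterozygosity
    ``H_T = 1 - J_T``).

    For ``J_T <= 1/K`` the bound is ``J_T (K - 1) / (1 - J_T)`` (attained
    with all alleles private, since pooled homozygosity can be no less
    than 1/K of the mean within-subpopulation homozygosity).  Above 1/K
    the extremal configurations fix subpopulations on shared alleles, with
    one partially mixed subpopulation interpolating between lattice
    points, where the bound touches 1.
    """
    if not 0 < J_T < 1:
        raise ValueError("pooled homozygosity must lie in (0, 1)")
    if K < 2:
        raise ValueError("need K >= 2 subpopulations")
    if J_T <= 1.0 / K:
        return J_T * (K - 1) / (1.0 - J_T)

    best = 0.0
    for j in range(1, K):
        lo = (j * j + K - j) / K**2
        hi = ((j + 1) ** 2 + K - j - 1) / K**2
        if not (lo - 1e-12 <= J_T <= hi + 1e-12):
            continue

        def t_of_x(x: float, j: int = j) -> float:
            return ((j + x) ** 2 + (1 - x) ** 2 + (K - j - 1)) / K**2

        f = lambda x: t_of_x(x) - J_T
        roots = []
        # t_of_x is a parabola in x; scan both monotone branches
        x_vertex = (1 - j) / 2.0
        for a, b in ((0.0, 1.0),):
            if x_vertex <= a or x_vertex >= b:
                if f(a) * f(b) <= 0:
                    roots.append(brentq(f, a, b, xtol=1e-12))
            else:
                for aa, bb in ((a, x_vertex), (x_vertex, b)):
                    if f(aa) * f(bb) <= 0:
                        roots.append(brentq(f, aa, bb, xtol=1e-12))
        for x in roots:
            j_s = 1.0 - 2.0 * x * (1.0 - x) / K
            best = max(best, (j_s - J_T) / (1.0 - J_T))
    return best


@dataclass
class FstBounds:
    per_locus: pd.DataFrame  # columns: locus, M, H_T, bound_M, bound_HT
    K: int

    @property
    def mean_bound_M(self) -> float:
        return float(self.per_locus["bound_M"].mean(skipna=True))

    @property
    def mean_bound_HT(self) -> float:
        return float(self.per_locus["bound_HT"].mean(skipna=True))


def fst_upper_bounds(freqs: AlleleFrequencyTable, K: int) -> FstBounds:
    """Per-locus Fst ceilings from pooled allele frequencies.

    ``freqs`` may be per-site (it is pooled internally) or already pooled.
    Monomorphic loci have undefined bounds and are excluded from the
    averages.
    """
    if K < 2:
        raise ValueError("need K >= 2 subpopulations")
    pooled = freqs.pooled() if len(freqs.sites) > 1 else freqs
    site = pooled.sites[0]
    rows = []
    for locus in pooled.locus_names:
        f = np.array(list(pooled.frequencies(site, locus).values()))
        if f.size == 0:
            continue
        M = float(f.max())
        j_t = float((f**2).sum())
        if M >= 1.0 - 1e-12:
            rows.append((locus, M, 1.0 - j_t, math.nan, math.nan))
            continue
        rows.append(
            (
                locus,
                M,
                1.0 - j_t,
                max_fst_given_M(M, K),
                max_fst_given_homozygosity(j_t, K),
            )
        )
    df = pd.DataFrame(rows, columns=["locus", "M", "H_T", "bound_M", "bound_HT"])
    return FstBounds(df, K)


# ---------------------------------------------------------------------------
# linearised Fst, geography, Mantel
# ---------------------------------------------------------------------------

def linearize_fst(m: DistanceMatrix, on_unity: str = "error") -> DistanceMatrix:
    """Entrywise ``Fst / (1 - Fst)``; small negative estimates are clamped
    to 0 first.  ``on_unity`` controls entries equal to 1 ("error" or
    "inf")."""
    if m.kind != "fst":
        raise ValueError(f"expected an fst matrix, got kind={m.kind!r}")
    v = m.values.copy()
    if (v < 0).any():
        warnings.warn("negative Fst entries clamped to 0 before linearisation")
        v = np.clip(v, 0.0, None)
    if (v >= 1.0).any():
        if on_unity == "error":
            raise ValueError("Fst = 1 linearises to infinity")
        v = np.where(v >= 1.0, np.inf, v)
    out = np.divide(v, 1.0 - v, out=np.full_like(v, np.inf), where=(1.0 - v) > 0)
    return DistanceMatrix(out, m.ids, "linearized_fst")


def geographic_distances(sites: SiteTable) -> DistanceMatrix:
    """Great-circle (haversine) distances in km, Earth radius 6371 km."""
    coords = sites.coordinates()
    if np.isnan(coords).any():
        bad = [s for s, c in zip(sites.site_ids, coords) if np.isnan(c).any()]
        raise ValueError(f"missing coordinates for sites: {bad}")
    lat = np.radians(coords[:, 0])[:, None]
    lon = np.radians(coords[:, 1])[:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    h = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    return DistanceMatrix(d, sites.site_ids, "geographic_km")


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> TestResult:
    """One-tailed Mantel permutation test (positive association).

    ``r`` is the Pearson correlation over the upper-triangle pairs; the
    null distribution is built by simultaneous row/column permutation of
    the second matrix.
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices must share the same site ordering")
    n = len(d1.ids)
    if n < 4:
        raise ValueError("Mantel test requires at least 4 sites")
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    y = d2.values[iu]
    finite = np.isfinite(x) & np.isfinite(y)
    if not finite.all():
        warnings.warn("non-finite distance pairs excluded from Mantel test")
    if x[finite].std() == 0 or y[finite].std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")

    def corr(mat: np.ndarray) -> float:
        yy = mat[iu]
        f = finite & np.isfinite(yy)
        return float(np.corrcoef(x[f], yy[f])[0, 1])

    r_obs = corr(d2.values)
    rng = np.random.default_rng(seed)
    n_exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(d2.values[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            n_exceed += 1
    return TestResult(r_obs, mc_pvalue(n_exceed, n_perm), n_perm, seed, "mantel_one_tailed")
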