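"""Per-site genetic diversity statistics and Hardy–Weinberg / linkage tests.

Statistics follow the conventions of the classic microsatellite toolchain:
observed heterozygosity is the fraction of scorable genotypes that are
heterozygous, expected heterozygosity is Nei's gene diversity
``He = 1 - sum_a f_a^2`` (biased form; an unbiased small-sample correction
is available), the fixation index is ``F = (He - Ho) / He``, and allelic
richness is rarefied to a common number of gene copies so that sites with
different sample sizes are comparable.

Exact tests are Monte-Carlo randomisation tests: Hardy–Weinberg via random
re-pairing of the observed gene copies (Levene's conditional distribution),
genotypic linkage disequilibrium via a permutation G-test on the
genotype x genotype contingency table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeTable,
    allele_frequencies,
)
from .permutation import TestResult, mc_pvalue

__all__ = [
    "heterozygosity_stats",
    "allelic_richness",
    "private_alleles",
    "hwe_exact_test",
    "genotypic_ld_test",
    "diversity_table",
    "DiversitySummary",
]


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------

def heterozygosity_stats(
    calls: np.ndarray, unbiased: bool = False
) -> tuple[float, float, float]:
    """Observed/expected heterozygosity and fixation index for one
    site x locus cell.

    Parameters
    ----------
    calls
        ``(m, 2)`` allele pairs; rows with the missing sentinel are ignored.
    unbiased
        Apply the ``2n / (2n - 1)`` small-sample correction to He.

    Returns
    -------
    (Ho, He, F); ``F`` is NaN when the locus is monomorphic (He = 0).
    """
    calls = np.asarray(calls)
    ok = (calls != MISSING).all(axis=1)
    calls = calls[ok]
    if calls.shape[0] == 0:
        raise ValueError("no scorable genotypes")
    ho = float((calls[:, 0] != calls[:, 1]).mean())
    copies = calls.ravel()
    _, counts = np.unique(copies, return_counts=True)
    freqs = counts / copies.size
    he = 1.0 - float((freqs**2).sum())
    if unbiased and copies.size > 1:
        he *= copies.size / (copies.size - 1)
    f = (he - ho) / he if he > 0 else math.nan
    return ho, he, f


# ---------------------------------------------------------------------------
# rarefied allelic richness
# ---------------------------------------------------------------------------

def allelic_richness(allele_counts, g: int) -> float:
    """Expected number of distinct alleles in a subsample of ``g`` gene
    copies (hurlbert-style rarefaction).

    ``AR = sum_a [1 - C(N - N_a, g) / C(N, g)]`` where ``N`` is the total
    number of gene copies and ``N_a`` the copies of allele ``a``.
    """
    counts = np.asarray(
        list(allele_counts.values()) if isinstance(allele_counts, dict) else allele_counts,
        dtype=np.int64,
    )
    counts = counts[counts > 0]
    n = int(counts.sum())
    if g < 1:
        raise ValueError("rarefaction size g must be >= 1")
    if g > n:
        raise ValueError(
            f"rarefaction size g={g} exceeds the {n} available gene copies; "
            "lower g (e.g. to the smallest cell's gene-copy count)"
        )

    def log_comb(a: np.ndarray, b: int) -> np.ndarray:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    rest = n - counts
    term = np.zeros(counts.size)
    feasible = rest >= g
    if feasible.any():
        term[feasible] = np.exp(log_comb(rest[feasible], g) - log_comb(np.array(n), g))
    return float((1.0 - term).sum())


# ---------------------------------------------------------------------------
# private alleles
# ---------------------------------------------------------------------------

def private_alleles(
    freqs: AlleleFrequencyTable, scope: list[str] | None = None
) -> pd.Series:
    """Private alleles per locus for every site in ``scope``.

    An allele is private to a site when it occurs there and nowhere else
    within the scope.  The returned value is the count of private alleles
    divided by the number of loci (the per-locus mean).
    """
    sites = list(scope) if scope is not None else list(freqs.sites)
    if len(sites) < 2:
        raise ValueError("private alleles are undefined for fewer than 2 sites")
    df = freqs.df[freqs.df["site"].isin(sites)]
    counts = pd.Series(0.0, index=sites, name="Np")
    occupancy = df.groupby(["locus", "allele"])["site"].nunique()
    singles = occupancy[occupancy == 1].index
    if len(singles):
        owner = df.set_index(["locus", "allele"]).loc[singles, "site"]
        per_site = owner.value_counts()
        counts.loc[per_site.index] = per_site.astype(float)
    return counts / len(freqs.locus_names)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte-Carlo, Levene's conditional distribution)
# ---------------------------------------------------------------------------

def _genotype_log_prob_terms(pairs: np.ndarray) -> np.ndarray:
    """Variable part of the log conditional probability of genotype arrays.

    ``pairs`` is ``(reps, m, 2)`` with each pair sorted.  Given fixed
    allele counts, ``log P(array) = const + h*ln2 - sum_g ln(n_g!)`` where
    ``h`` is the number of heterozygotes and ``n_g`` the genotype counts.
    """
    reps, m, _ = pairs.shape
    het = (pairs[:, :, 0] != pairs[:, :, 1]).sum(axis=1)
    base = int(pairs.max()) + 1
    codes = pairs[:, :, 0] * base + pairs[:, :, 1]
    codes = np.sort(codes, axis=1)
    idx = np.arange(m)
    new_run = np.ones((reps, m), dtype=bool)
    new_run[:, 1:] = codes[:, 1:] != codes[:, :-1]
    start_idx = np.where(new_run, idx, 0)
    last_start = np.maximum.accumulate(start_idx, axis=1)
    pos_in_run = idx - last_start + 1
    sum_log_fact = np.log(pos_in_run).sum(axis=1)
    return het * math.log(2.0) - sum_log_fact


def hwe_exact_test(
    calls: np.ndarray, n_reps: int = 10_000, seed: int = 0
) -> TestResult:
    """Monte-Carlo exact test of Hardy–Weinberg proportions for one
    site x locus cell.

    The observed gene copies are randomly re-paired into diploids
    ``n_reps`` times; the p-value is the fraction of pairings whose
    conditional probability under HWE is at most that of the observed
    genotype array (+1 smoothing).
    """
    calls = np.asarray(calls)
    ok = (calls != MISSING).all(axis=1)
    calls = np.sort(calls[ok], axis=1)
    m = calls.shape[0]
    method = "hwe_exact_mc"
    if m < 5:
        return TestResult(math.nan, None, 0, seed, method, "skipped: fewer than 5 genotypes")
    copies = calls.ravel()
    alleles, inv = np.unique(copies, return_inverse=True)
    if alleles.size < 2:
        return TestResult(math.nan, None, 0, seed, method, "skipped: monomorphic")
    obs = _genotype_log_prob_terms(np.sort(calls[None, :, :], axis=2))[0]
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(inv, (n_reps, 1)), axis=1).reshape(n_reps, m, 2)
    perms = np.sort(perms, axis=2)
    sim = _genotype_log_prob_terms(perms)
    n_exceed = int((sim <= obs + 1e-9).sum())
    return TestResult(float(obs), mc_pvalue(n_exceed, n_reps), n_reps, seed, method)


# ---------------------------------------------------------------------------
# genotypic linkage disequilibrium (permutation G-test)
# ---------------------------------------------------------------------------

def _g_statistics(joint: np.ndarray, row_marg: np.ndarray, col_marg: np.ndarray) -> np.ndarray:
    """Log-likelihood-ratio G for a stack of contingency tables with
    common margins.  ``joint`` is ``(reps, r, c)``."""
    n = row_marg.sum()
    expected = np.outer(row_marg, col_marg) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = joint * (np.log(joint) - np.log(expected))
    contrib = np.where(joint > 0, contrib, 0.0)
    return 2.0 * contrib.sum(axis=(1, 2))


def genotypic_ld_test(
    calls_a: np.ndarray,
    calls_b: np.ndarray,
    n_reps: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Permutation G-test of genotypic association between two loci at one
    site.  Genotypes of the second locus are shuffled across individuals to
    build the null distribution."""
    calls_a = np.sort(np.asarray(calls_a), axis=1)
    calls_b = np.sort(np.asarray(calls_b), axis=1)
    ok = ((calls_a != MISSING).all(axis=1)) & ((calls_b != MISSING).all(axis=1))
    calls_a, calls_b = calls_a[ok], calls_b[ok]
    m = calls_a.shape[0]
    method = "genotypic_ld_g_perm"
    if m < 5:
        return TestResult(math.nan, None, 0, seed, method, "skipped: fewer than 5 individuals")

    def codes(calls: np.ndarray) -> np.ndarray:
        base = int(calls.max()) + 1
        _, inv = np.unique(calls[:, 0] * base + calls[:, 1], return_inverse=True)
        return inv

    ga, gb = codes(calls_a), codes(calls_b)
    ka, kb = ga.max() + 1, gb.max() + 1
    if ka < 2 or kb < 2:
        return TestResult(
            math.nan, None, 0, seed, method, "skipped: fewer than 2 genotypes at a locus"
        )
    row_marg = np.bincount(ga, minlength=ka)
    col_marg = np.bincount(gb, minlength=kb)
    obs_joint = np.zeros((1, ka, kb))
    np.add.at(obs_joint[0], (ga, gb), 1)
    g_obs = _g_statistics(obs_joint, row_marg, col_marg)[0]

    rng = np.random.default_rng(seed)
    perm_b = rng.permuted(np.tile(gb, (n_reps, 1)), axis=1)
    flat = (np.arange(n_reps)[:, None] * (ka * kb)) + ga[None, :] * kb + perm_b
    joint = np.bincount(flat.ravel(), minlength=n_reps * ka * kb).reshape(n_reps, ka, kb)
    g_sim = _g_statistics(joint, row_marg, col_marg)
    n_exceed = int((g_sim >= g_obs - 1e-9).sum())
    return TestResult(float(g_obs), mc_pvalue(n_exceed, n_reps), n_reps, seed, method)


# ---------------------------------------------------------------------------
# the per-site summary table
# ---------------------------------------------------------------------------

@dataclass
class DiversitySummary:
    """Per-site diversity statistics, each a mean over loci with its
    standard error (over loci)."""

    table: pd.DataFrame  # indexed by site
    g: int  # gene copies used for rarefaction

    def mean_row(self) -> pd.Series:
        return self.table.mean(numeric_only=True)

    def with_mean_row(self) -> pd.DataFrame:
        out = self.table.copy()
        out.loc["Mean"] = self.mean_row()
        return out

    def to_csv(self, path, sites=None) -> None:
        """Write the report, optionally merged with site metadata."""
        out = self.with_mean_row().reset_index(names="site")
        if sites is not None:
            meta_cols = [c for c in ("site", "country", "lat", "lon", "elevation") if c in sites.data.columns]
            out = sites.data[meta_cols].merge(out, on="site", how="right")
        out.to_csv(path, index=False, float_format="%.6g")


def default_rarefaction_g(table: GenotypeTable) -> int:
    """Default rarefaction size: twice the smallest number of scorable
    individuals over all site x locus cells (the smallest cell's gene-copy
    count)."""
    miss = table.missing_mask()
    idx = table.site_index()
    m = min(
        int((~miss[ind, l]).sum())
        for ind in idx.values()
        for l in range(table.n_loci)
    )
    if m < 1:
        raise ValueError("a site x locus cell has no scorable genotypes")
    return 2 * m


def diversity_table(table: GenotypeTable, g: int | None = None) -> DiversitySummary:
    """Per-site diversity summary (mean over loci, SE over loci).

    Columns: ``n`` (individuals), ``N`` (alleles per locus), ``Np``
    (private alleles per locus), ``AR`` (rarefied allelic richness),
    ``Ho``, ``He``, ``F`` — each statistic except ``n`` and ``Np``
    accompanied by a standard-error column.
    """
    table.validate_multisite()
    if g is None:
        g = default_rarefaction_g(table)
    freqs = allele_frequencies(table)
    np_series = private_alleles(freqs)
    idx = table.site_index()
    L = table.n_loci

    def mean_se(vals: list[float]) -> tuple[float, float]:
        arr = np.asarray([v for v in vals if not math.isnan(v)], dtype=float)
        if arr.size == 0:
            return math.nan, math.nan
        se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
        return float(arr.mean()), se

    rows = {}
    for site, ind in idx.items():
        n_alleles, ar, ho, he, f = [], [], [], [], []
        for l, locus in enumerate(table.locus_names):
            counts = freqs.counts(site, locus)
            if not counts:
                n_alleles.append(math.nan)
                ar.append(math.nan)
                ho.append(math.nan)
                he.append(math.nan)
                f.append(math.nan)
                continue
            n_alleles.append(float(len(counts)))
            ar.append(allelic_richness(counts, g))
            h_o, h_e, f_l = heterozygosity_stats(table.calls[ind, l, :])
            ho.append(h_o)
            he.append(h_e)
            f.append(f_l)
        row = {"n": float(len(ind))}
        for name, vals in (("N", n_alleles), ("AR", ar), ("Ho", ho), ("He", he), ("F", f)):
            row[name], row[f"{name}_se"] = mean_se(vals)
        row["Np"] = float(np_series[site])
        rows[site] = row

    cols = ["n", "N", "N_se", "Np", "AR", "AR_se", "Ho", "Ho_se", "He", "He_se", "F", "F_se"]
    df = pd.DataFrame.from_dict(rows, orient="index")[cols]
    df.index.name = "site"
    return DiversitySummary(df, g)
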