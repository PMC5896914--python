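"""Core containers for diploid codominant genotype data.

Genotypes are stored as an ``(n_individuals, n_loci, 2)`` integer array of
allele identifiers.  Allele identifiers are positive integers (for
microsatellites, fragment lengths in base pairs); ``0`` is the missing-data
sentinel.  A half-called genotype (one allele known, one missing) is
normalised to fully missing for that locus, the usual convention for
codominant markers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeTable",
    "SiteTable",
    "AlleleFrequencyTable",
    "allele_frequencies",
    "POOLED",
]

#: Sentinel allele identifier for missing data.
MISSING = 0

#: Pseudo-site label used for frequencies pooled over all sites.
POOLED = "__pooled__"


class GenotypeTableError(ValueError):
    """Raised when a genotype table violates its invariants."""


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls with site assignments.

    Parameters
    ----------
    individual_ids
        One label per individual (unique).
    site_ids
        Sampling-site label per individual.
    locus_names
        One label per locus.
    calls
        Integer array ``(n, n_loci, 2)``; 0 encodes missing.  Within a
        locus the allele pair is unordered; calls are stored sorted so that
        equality is well defined.
    """

    individual_ids: list[str]
    site_ids: list[str]
    locus_names: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [str(x) for x in self.individual_ids]
        self.site_ids = [str(x) for x in self.site_ids]
        self.locus_names = [str(x) for x in self.locus_names]
        calls = np.asarray(self.calls, dtype=np.int64)
        n, n_loci = len(self.individual_ids), len(self.locus_names)
        if calls.shape != (n, n_loci, 2):
            raise GenotypeTableError(
                f"calls shape {calls.shape} does not match "
                f"({n} individuals, {n_loci} loci, 2)"
            )
        if len(self.site_ids) != n:
            raise GenotypeTableError("one site_id required per individual")
        if len(set(self.individual_ids)) != n:
            raise GenotypeTableError("individual_ids must be unique")
        if (calls < 0).any():
            raise GenotypeTableError("allele identifiers must be non-negative")
        # half-missing genotypes collapse to fully missing
        half = (calls == MISSING).any(axis=2)
        calls[half] = MISSING
        calls.sort(axis=2)
        self.calls = calls

    # -- basic properties -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def sites(self) -> list[str]:
        """Unique site labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.site_ids:
            seen.setdefault(s)
        return list(seen)

    def site_index(self) -> dict[str, np.ndarray]:
        """Map site label -> integer index array of its individuals."""
        arr = np.asarray(self.site_ids)
        return {s: np.flatnonzero(arr == s) for s in self.sites}

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, n_loci)`` mask of missing genotypes."""
        return (self.calls == MISSING).all(axis=2)

    def subset(self, indices: np.ndarray) -> "GenotypeTable":
        indices = np.asarray(indices)
        return GenotypeTable(
            [self.individual_ids[i] for i in indices],
            [self.site_ids[i] for i in indices],
            list(self.locus_names),
            self.calls[indices].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.site_ids == other.site_ids
            and self.locus_names == other.locus_names
            and np.array_equal(self.calls, other.calls)
        )

    def validate_multisite(self) -> None:
        """Require >= 2 sites and >= 1 locus (multi-site analyses)."""
        if len(self.sites) < 2:
            raise GenotypeTableError("multi-site analysis requires >= 2 sites")
        if self.n_loci < 1:
            raise GenotypeTableError("at least one locus required")


@dataclass
class SiteTable:
    """Sampling-site metadata (coordinates in decimal degrees WGS84)."""

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("site", "lat", "lon")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"site table missing required column {col!r}")
        if df["site"].duplicated().any():
            dupes = df.loc[df["site"].duplicated(), "site"].tolist()
            raise ValueError(f"duplicate site ids: {dupes}")
        lat = df["lat"].astype(float)
        lon = df["lon"].astype(float)
        if ((lat < -90) | (lat > 90)).any():
            raise ValueError("latitude out of [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise ValueError("longitude out of [-180, 180]")
        df = df.copy()
        df["lat"] = lat
        df["lon"] = lon
        self.data = df.reset_index(drop=True)

    @property
    def site_ids(self) -> list[str]:
        return [str(s) for s in self.data["site"]]

    def coordinates(self) -> np.ndarray:
        """``(n_sites, 2)`` array of (lat, lon)."""
        return self.data[["lat", "lon"]].to_numpy(float)

    def __len__(self) -> int:
        return len(self.data)


class AlleleFrequencyTable:
    """Per-(site, locus) allele counts and frequencies.

    Backed by a tidy DataFrame with columns
    ``site, locus, allele, count, freq`` plus the gene-copy totals.  A
    site x locus cell with no scorable gene copies is simply absent from the
    table and reported by :meth:`is_empty`.
    """

    def __init__(self, df: pd.DataFrame, sites: list[str], locus_names: list[str]):
        self.df = df.reset_index(drop=True)
        self.sites = list(sites)
        self.locus_names = list(locus_names)
        self._by_cell = {
            key: grp for key, grp in self.df.groupby(["site", "locus"], sort=False)
        }

    def counts(self, site: str, locus: str) -> dict[int, int]:
        grp = self._by_cell.get((site, locus))
        if grp is None:
            return {}
        return dict(zip(grp["allele"].astype(int), grp["count"].astype(int)))

    def frequencies(self, site: str, locus: str) -> dict[int, float]:
        grp = self._by_cell.get((site, locus))
        if grp is None:
            return {}
        return dict(zip(grp["allele"].astype(int), grp["freq"].astype(float)))

    def n_copies(self, site: str, locus: str) -> int:
        grp = self._by_cell.get((site, locus))
        return 0 if grp is None else int(grp["count"].sum())

    def is_empty(self, site: str, locus: str) -> bool:
        return (site, locus) not in self._by_cell

    def alleles(self, locus: str) -> list[int]:
        """All alleles observed at a locus across sites, sorted."""
        sub = self.df[self.df["locus"] == locus]
        return sorted(sub["allele"].astype(int).unique())

    def pooled(self) -> "AlleleFrequencyTable":
        """Collapse sites into a single pooled population."""
        agg = (
            self.df.groupby(["locus", "allele"], sort=False)["count"]
            .sum()
            .reset_index()
        )
        agg["site"] = POOLED
        totals = agg.groupby("locus")["count"].transform("sum")
        agg["freq"] = agg["count"] / totals
        agg = agg[["site", "locus", "allele", "count", "freq"]]
        return AlleleFrequencyTable(agg, [POOLED], self.locus_names)


def allele_frequencies(table: GenotypeTable) -> AlleleFrequencyTable:
    """Count allele copies per (site, locus) and derive frequencies.

    Missing genotypes contribute no gene copies; the frequency denominator
    for a cell is its number of scorable gene copies (2 x non-missing
    individuals there).
    """
    rows = []
    idx = table.site_index()
    for site, ind in idx.items():
        for l, locus in enumerate(table.locus_names):
            alleles = table.calls[ind, l, :].ravel()
            alleles = alleles[alleles != MISSING]
            if alleles.size == 0:
                continue
            counts = Counter(alleles.tolist())
            total = alleles.size
            for a in sorted(counts):
                rows.append((site, locus, int(a), counts[a], counts[a] / total))
    df = pd.DataFrame(rows, columns=["site", "locus", "allele", "count", "freq"])
    return AlleleFrequencyTable(df, table.sites, table.locus_names)
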