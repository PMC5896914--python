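"""Built-in reference tables for the motivating study system.

The package was developed around the *Acacia tortilis* population at the
northern edge of the species' range (Dead Sea region, Arava Valley and
Gulf of Eilat/Aqaba, Israel and Jordan, plus two sites from the species'
core range in Egypt and Sudan).  The raw genotypes of that survey are not
publicly available, so the synthetic generators in
:mod:`msatnet.simulate` stand in for them; what *is* available is the
per-site summary below — coordinates, sample sizes, and the per-site
diversity and centrality statistics (mean over six microsatellite loci) —
which serves as the reference layout for presets, worked examples and
consistency checks.

Columns: ``site, country, lat, lon, elevation, n`` and the per-site means
``N`` (alleles per locus), ``Np`` (private alleles per locus), ``AR``
(rarefied allelic richness), ``Ho``, ``He``, ``F`` (fixation index) and
``RWB`` (random-walk betweenness; defined only for the 14 northern-edge
sites that form the population graph).
"""

from __future__ import annotations

import io

import pandas as pd

from .genotypes import SiteTable

__all__ = ["arava_reference_table", "arava_sites", "NORTHERN_EDGE_SITES"]

_TABLE_CSV = """\
site,country,lat,lon,elevation,n,N,Np,AR,Ho,He,F,RWB
Ein Gedi,Israel,31.45,35.39,-371,21,6.83,0.17,5.26,0.73,0.71,-0.02,0.26
Zeelim,Israel,31.35,35.38,-343,24,7.00,0.17,5.33,0.80,0.72,-0.12,0.26
Jordan_DS,Jordan,31.21,35.53,-362,24,9.33,0,6.67,0.79,0.78,-0.01,0.30
Hemar,Israel,31.13,35.37,-344,20,7.33,0.17,6.22,0.78,0.76,-0.02,0.31
Peres,Israel,30.99,35.33,-301,15,5.83,0,5.26,0.70,0.71,0.02,0.34
Saif,Israel,30.85,35.23,-88,17,7.83,0,6.35,0.83,0.76,-0.10,0.26
Gidron,Israel,30.79,35.27,-148,20,7.67,0,6.04,0.74,0.76,0.03,0.32
Sheizaf,Israel,30.72,35.27,-137,24,8.33,0,6.12,0.78,0.77,-0.01,0.28
Zofar,Israel,30.56,35.16,24,21,7.17,0.33,5.61,0.79,0.73,-0.08,0.36
Yotveta,Israel,29.89,35.05,71,23,8.50,0.67,6.49,0.81,0.77,-0.04,0.29
Qatar,Jordan,29.81,35.07,72,20,9.17,0.17,6.87,0.73,0.76,0.04,0.36
Roded,Israel,29.61,34.99,27,21,9.00,0.50,6.73,0.73,0.79,0.07,0.27
Shlomo,Israel,29.53,34.92,171,18,6.67,0.17,5.35,0.63,0.64,0.01,0.25
Tala Bay,Jordan,29.42,34.99,70,24,9.50,0.33,6.81,0.76,0.76,0.00,0.25
Egypt,Egypt,24.40,35.10,156,14,6.33,1.83,5.62,0.53,0.71,0.26,
Sudan,Sudan,18.99,30.86,253,12,9.00,1.5,7.98,0.72,0.81,0.11,
"""

#: The 14 sites of the northern-edge population (Israel/Jordan); the two
#: core-range sites (Egypt, Sudan) are outgroups in most analyses.
NORTHERN_EDGE_SITES = [
    "Ein Gedi", "Zeelim", "Jordan_DS", "Hemar", "Peres", "Saif", "Gidron",
    "Sheizaf", "Zofar", "Yotveta", "Qatar", "Roded", "Shlomo", "Tala Bay",
]


def arava_reference_table(northern_edge_only: bool = False) -> pd.DataFrame:
    """Per-site reference summary of the motivating acacia survey."""
    df = pd.read_csv(io.StringIO(_TABLE_CSV))
    if northern_edge_only:
        df = df[df["site"].isin(NORTHERN_EDGE_SITES)].reset_index(drop=True)
    return df


def arava_sites(northern_edge_only: bool = True) -> SiteTable:
    """Site metadata (coordinates, elevation) as a :class:`SiteTable`."""
    df = arava_reference_table(northern_edge_only)
    return SiteTable(df[["site", "country", "lat", "lon", "elevation"]])
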