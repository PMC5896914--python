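"""GenePop file input/output and site-metadata reading.

GenePop is the de-facto exchange format for codominant microsatellite
genotypes: a title line, one locus name per line (or comma separated), and
``Pop`` separators between samples, each individual line being
``label ,  AABB AABB ...`` with 2- or 3-digit allele codes and all-zero
codes for missing data.  Parsing is delegated to Biopython's GenePop
reader; this module adds strict width validation with line numbers, site
naming, and a writer that round-trips :class:`~msatnet.genotypes.GenotypeTable`
objects exactly.

GenePop has no population-name field.  The writer records site names in
the title line as ``pops=<name>,<name>,...``; the reader uses that list
when present and otherwise falls back to the first individual label of
each Pop block (or generic ``pop_<k>`` labels), selectable via
``site_names``.
"""

from __future__ import annotations

import io
import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PopGen.GenePop import read as _biopython_read

from .genotypes import MISSING, GenotypeTable, SiteTable

__all__ = ["read_genepop", "write_genepop", "read_site_table", "GenePopFormatError"]

_POPS_RE = re.compile(r"pops=([^;]+)")


class GenePopFormatError(ValueError):
    """Malformed GenePop content (message includes the offending line)."""


def _validate_widths(lines: list[str]) -> int:
    """Check genotype-token width consistency; return the allele digit width.

    Raises :class:`GenePopFormatError` naming the first inconsistent line.
    """
    width = None
    in_pops = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if stripped.lower() == "pop":
            in_pops = True
            continue
        if not in_pops or not stripped:
            continue
        if "," not in stripped:
            raise GenePopFormatError(
                f"line {lineno}: individual line lacks the ',' after its label"
            )
        _, _, geno = stripped.partition(",")
        for tok in geno.split():
            if not tok.isdigit():
                raise GenePopFormatError(
                    f"line {lineno}: genotype token {tok!r} is not numeric"
                )
            if len(tok) not in (4, 6):
                raise GenePopFormatError(
                    f"line {lineno}: genotype token {tok!r} has width "
                    f"{len(tok)}; expected 4 (2-digit) or 6 (3-digit)"
                )
            w = len(tok) // 2
            if width is None:
                width = w
            elif w != width:
                raise GenePopFormatError(
                    f"line {lineno}: allele-code width {w} conflicts with "
                    f"width {width} used earlier in the file"
                )
    if width is None:
        raise GenePopFormatError("no genotype rows found (missing 'Pop' blocks?)")
    return width


def read_genepop(path: str | Path, site_names: str | list[str] = "auto") -> GenotypeTable:
    """Read a GenePop file into a :class:`GenotypeTable`.

    Parameters
    ----------
    path
        GenePop file (2- or 3-digit allele coding).
    site_names
        ``"auto"`` (title-line ``pops=`` list if present, else first
        individual label per Pop block), ``"first_label"``, ``"generic"``
        (``pop_1``, ``pop_2``, ...), or an explicit list with one name per
        Pop block.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    if len(lines) < 3:
        raise GenePopFormatError("file too short to be GenePop (need title, loci, Pop)")
    _validate_widths(lines)
    try:
        record = _biopython_read(io.StringIO(text))
    except Exception as exc:  # pragma: no cover - biopython message passthrough
        raise GenePopFormatError(f"GenePop parse failed: {exc}") from exc

    loci = [str(l) for l in record.loci_list]
    header_pops = None
    m = _POPS_RE.search(record.comment_line or "")
    if m:
        header_pops = [s.strip() for s in m.group(1).split(",")]

    individual_ids: list[str] = []
    site_ids: list[str] = []
    calls = []
    pop_first_labels = []
    seen: dict[str, int] = {}
    for k, pop in enumerate(record.populations):
        pop_first_labels.append(str(pop[0][0]).strip())
        for label, genos in pop:
            # repeated labels (files often label every row with the site
            # name) are made unique with a positional suffix
            label = str(label).strip()
            if label in seen:
                seen[label] += 1
                label = f"{label}_{seen[label]}"
            else:
                seen[label] = 0
            individual_ids.append(label)
            site_ids.append(str(k))  # placeholder, resolved below
            row = []
            for g in genos:
                if g is None:
                    g = (None, None)
                a1 = MISSING if g[0] in (None, 0) else int(g[0])
                a2 = MISSING if (len(g) < 2 or g[1] in (None, 0)) else int(g[1])
                row.append((a1, a2))
            calls.append(row)

    n_pops = len(record.populations)
    if isinstance(site_names, (list, tuple)):
        if len(site_names) != n_pops:
            raise GenePopFormatError(
                f"{len(site_names)} site names given for {n_pops} Pop blocks"
            )
        names = [str(s) for s in site_names]
    elif site_names == "generic":
        names = [f"pop_{k + 1}" for k in range(n_pops)]
    elif site_names == "first_label":
        names = pop_first_labels
    elif site_names == "auto":
        if header_pops is not None and len(header_pops) == n_pops:
            names = header_pops
        else:
            names = pop_first_labels
    else:
        raise ValueError(f"unknown site_names mode {site_names!r}")

    resolved = [names[int(s)] for s in site_ids]
    return GenotypeTable(individual_ids, resolved, loci, np.asarray(calls))


def write_genepop(table: GenotypeTable, path: str | Path, title: str = "msatnet export") -> None:
    """Write a :class:`GenotypeTable` as a GenePop file.

    Allele coding width is 2 digits when every allele identifier is <= 99,
    otherwise 3 digits; identifiers above 999 cannot be represented and
    raise a ``ValueError``.  Site names are embedded in the title line
    (``pops=...``) so that :func:`read_genepop` round-trips exactly.
    """
    max_allele = int(table.calls.max()) if table.calls.size else 0
    if max_allele > 999:
        raise ValueError(
            f"allele identifier {max_allele} exceeds the 3-digit GenePop coding"
        )
    width = 3 if max_allele > 99 else 2

    sites = table.sites
    idx = table.site_index()
    out = [f"{title}; pops={','.join(sites)}"]
    out.extend(table.locus_names)
    for site in sites:
        out.append("Pop")
        for i in idx[site]:
            toks = []
            for a1, a2 in table.calls[i]:
                toks.append(f"{a1:0{width}d}{a2:0{width}d}")
            out.append(f"{table.individual_ids[i]}, " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


def read_site_table(path: str | Path) -> SiteTable:
    """Read site metadata from a delimited text file.

    Requires a header with at least ``site, lat, lon``; ``country``,
    ``elevation`` and ``truth_community`` columns are carried through when
    present.  Coordinate ranges and site-id uniqueness are validated.
    """
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    return SiteTable(df)


def write_site_table(sites: SiteTable, path: str | Path) -> None:
    sites.data.to_csv(path, index=False)
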