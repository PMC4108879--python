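"""Spatial distribution of candidate relevant SNPs along chromosomes.

The r-scan statistic tests whether locus positions are uniformly
distributed: the r-scan lengths are the distances between each position
and its r-th successor, and their minimum (maximum) is small (large)
when loci clump (spread regularly).  P-values come either from seeded
Monte-Carlo sampling of uniform positions or, for the clumped
alternative, from the extreme-value approximation

    P(min r-scan <= x) ~ 1 - exp(-n^(r+1) * (x/L)^r / r!).

Loci are additionally grouped into 1-D single-linkage clusters and
classified against gene annotation (exon > UTR > intron > upstream-2kb
> intergenic, strand aware).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "RScanResult",
    "SNPCluster",
    "rscan_lengths",
    "rscan_test",
    "cluster_snps",
    "read_annotation",
    "classify_snps",
    "FUNCTIONAL_CLASSES",
]

FUNCTIONAL_CLASSES = ["exon", "UTR", "intron", "upstream_2kb", "intergenic"]
UPSTREAM_BP = 2000


@dataclass(frozen=True)
class RScanResult:
    chrom: str | None
    r: int
    statistic: float
    p_value: float
    alternative: str
    method: str
    n_points: int


@dataclass(frozen=True)
class SNPCluster:
    chrom: str | None
    start: int
    end: int
    n_snps: int
    gene: str | None = None


def rscan_lengths(positions: Sequence[float], r: int = 1) -> np.ndarray:
    """Distances x_(i+r) - x_(i) over the sorted positions."""
    pos = np.asarray(positions, dtype=float)
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted ascending")
    if len(pos) <= r:
        raise ValueError(f"need more than r={r} positions")
    return pos[r:] - pos[:-r]


def rscan_test(
    positions: Sequence[float],
    chrom_length: float,
    r: int = 1,
    alternative: str = "clumped",
    method: str = "monte_carlo",
    B: int = 10_000,
    seed: int | None = None,
    chrom: str | None = None,
) -> RScanResult:
    """Test uniformity of positions on [1, chrom_length] via r-scan extremes.

    ``clumped`` uses the minimum r-scan length (clumping makes the
    minimum unusually small), ``regular`` the maximum (even spacing
    makes the maximum unusually small, so both alternatives reject in
    the lower tail of their statistic).  The
    Monte-Carlo p carries the standard +1/(B+1) correction and is hence
    floored at 1/(B+1); the asymptotic method (clumped only) can report
    arbitrarily small p for tight clumps.  Duplicate positions are
    tolerated (minimum length 0 gives the smallest attainable p).
    """
    pos = np.sort(np.asarray(positions, dtype=float))
    n = len(pos)
    if n <= r:
        raise ValueError(f"need more than r={r} positions")
    if pos[0] < 0 or pos[-1] > chrom_length:
        raise ValueError("positions must lie within [0, chrom_length]")
    if alternative not in ("clumped", "regular"):
        raise ValueError("alternative must be 'clumped' or 'regular'")
    lengths = pos[r:] - pos[:-r]
    stat = float(lengths.min() if alternative == "clumped" else lengths.max())

    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        sim = np.sort(rng.random((B, n)) * chrom_length, axis=1)
        sim_lengths = sim[:, r:] - sim[:, :-r]
        if alternative == "clumped":
            exceed = (sim_lengths.min(axis=1) <= stat).sum()
        else:
            exceed = (sim_lengths.max(axis=1) <= stat).sum()
        p = (exceed + 1.0) / (B + 1.0)
    elif method == "asymptotic":
        if alternative != "clumped":
            raise NotImplementedError(
                "asymptotic approximation is available for the clumped "
                "alternative only; use method='monte_carlo'"
            )
        lam = n ** (r + 1) * (stat / chrom_length) ** r / math.factorial(r)
        p = 1.0 - math.exp(-lam)
    else:
        raise ValueError("method must be 'monte_carlo' or 'asymptotic'")
    return RScanResult(chrom, r, stat, float(min(p, 1.0)), alternative, method, n)


def cluster_snps(
    positions: Sequence[float],
    gap: float,
    chrom: str | None = None,
) -> list[SNPCluster]:
    """Single-linkage 1-D clustering: spacings <= gap join one cluster."""
    pos = np.asarray(positions, dtype=float)
    if len(pos) == 0:
        return []
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted ascending")
    breaks = np.flatnonzero(np.diff(pos) > gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(pos) - 1]])
    return [
        SNPCluster(chrom, int(pos[i]), int(pos[j]), int(j - i + 1))
        for i, j in zip(starts, ends)
    ]


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            key, val = part.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def read_annotation(path) -> pd.DataFrame:
    """Read gene/exon/UTR intervals from BED6 or GFF3 into a uniform frame.

    Returned columns: chrom, start, end (1-based inclusive), strand,
    feature (gene/exon/UTR), name.  BED input uses the name column for
    the feature type, optionally ``type|gene_name``; GFF3 recognises
    the gene, exon and *_UTR feature types.  Malformed lines raise with
    their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) >= 9 and fields[3].isdigit() and fields[4].isdigit():
                    # GFF3: seqid source type start end score strand frame attrs
                    ftype = fields[2].lower()
                    if ftype == "gene":
                        feature = "gene"
                    elif ftype == "exon":
                        feature = "exon"
                    elif ftype.endswith("utr"):
                        feature = "UTR"
                    else:
                        continue
                    attrs = _parse_gff_attributes(fields[8])
                    name = attrs.get("Name") or attrs.get("gene_id") or attrs.get("ID") or ""
                    rows.append(
                        {
                            "chrom": fields[0],
                            "start": int(fields[3]),
                            "end": int(fields[4]),
                            "strand": fields[6],
                            "feature": feature,
                            "name": name,
                        }
                    )
                elif len(fields) >= 6:
                    # BED6, 0-based half-open; name column = feature[|gene]
                    name_field = fields[3]
                    feature, _, gene = name_field.partition("|")
                    feature_norm = {"gene": "gene", "exon": "exon", "utr": "UTR"}[
                        feature.lower()
                    ]
                    rows.append(
                        {
                            "chrom": fields[0],
                            "start": int(fields[1]) + 1,
                            "end": int(fields[2]),
                            "strand": fields[5],
                            "feature": feature_norm,
                            "name": gene,
                        }
                    )
                else:
                    raise ValueError("expected BED6 or GFF3 fields")
            except (ValueError, KeyError, IndexError) as exc:
                raise ValueError(f"malformed annotation at line {lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "feature", "name"])


def classify_snps(
    snps: pd.DataFrame,
    annotation: pd.DataFrame,
) -> tuple[pd.Series, pd.Series]:
    """Assign one functional class per SNP against gene annotation.

    ``snps`` needs chrom and pos (1-based) columns.  Precedence:
    exon > UTR > intron (inside a gene but outside exon/UTR) >
    upstream-2kb (strand-aware, 5' of the gene start) > intergenic.
    Returns (per-SNP class Series, class->count Series over all classes).
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for row in annotation.itertuples():
        key = (row.chrom, row.feature)
        trees.setdefault(key, IntervalTree()).addi(row.start, row.end + 1, row.name)
    upstream: dict[str, IntervalTree] = {}
    for row in annotation.itertuples():
        if row.feature != "gene":
            continue
        if row.strand == "-":
            lo, hi = row.end + 1, row.end + UPSTREAM_BP
        else:
            lo, hi = max(1, row.start - UPSTREAM_BP), row.start - 1
        if hi >= lo:
            upstream.setdefault(row.chrom, IntervalTree()).addi(lo, hi + 1, row.name)

    def classify_one(chrom: str, pos: int) -> str:
        if trees.get((chrom, "exon"), IntervalTree()).overlaps_point(pos):
            return "exon"
        if trees.get((chrom, "UTR"), IntervalTree()).overlaps_point(pos):
            return "UTR"
        if trees.get((chrom, "gene"), IntervalTree()).overlaps_point(pos):
            return "intron"
        if upstream.get(chrom, IntervalTree()).overlaps_point(pos):
            return "upstream_2kb"
        return "intergenic"

    classes = pd.Series(
        [classify_one(r.chrom, int(r.pos)) for r in snps.itertuples()],
        index=snps.index,
        name="functional_class",
    )
    counts = classes.value_counts().reindex(FUNCTIONAL_CLASSES, fill_value=0)
    return classes, counts
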