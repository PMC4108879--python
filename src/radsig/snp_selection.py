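"""Candidate relevant SNP selection by perfect segregation between strain groups.

With 14 inbred strains split into a radiosensitive and a regular-responder
group, per-SNP association testing has no power after multiple-testing
control over millions of loci.  The most conservative selection rule is
used instead: a locus is a *candidate relevant SNP* iff the allele is
identical within each group and differs between the groups.

Because inbred strains are homozygous, each strain contributes a single
allele call per locus.  The number of such loci expected by chance under
independent strains, with variant-allele population frequency p and a
split of n_s sensitive vs n_r regular strains, is

    E = p^n_s * (1 - p)^n_r * N

for the "variant in sensitive, reference in regular" configuration over N
loci.  Per-chromosome over/under-representation of observed counts
relative to this expectation is assessed with a one-sided Fisher exact
test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "FreqTable",
    "MISSING",
    "is_relevant",
    "select_relevant",
    "variant_frequencies",
    "weighted_overall_frequency",
    "expected_by_chance",
    "fisher_enrichment",
    "enrichment_table",
    "relevant_to_bed",
]

MISSING = "."
META_COLS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Strains x loci allele calls with genomic coordinates.

    ``table`` holds one row per locus with columns (chrom, pos, ref, alt)
    followed by one allele column per strain; alleles are strings, with
    ``.`` marking a missing call.  Rows are kept sorted by (chrom, pos).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLS if c not in self.table.columns]
        if missing:
            raise ValueError(f"genotype table is missing columns: {missing}")
        if len(self.strains) != len(set(self.strains)):
            raise ValueError("strain labels must be unique")
        t = self.table.copy()
        t[self.strains] = t[self.strains].astype(object).fillna(MISSING)
        self.table = t.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    @property
    def strains(self) -> list[str]:
        return [c for c in self.table.columns if c not in META_COLS]

    @property
    def loci(self) -> pd.DataFrame:
        return self.table[META_COLS]

    @property
    def alleles(self) -> pd.DataFrame:
        return self.table[self.strains]

    def __len__(self) -> int:
        return len(self.table)

    def subset_strains(self, strains: Sequence[str]) -> "GenotypeMatrix":
        unknown = set(strains) - set(self.strains)
        if unknown:
            raise KeyError(f"unknown strains: {sorted(unknown)}")
        return GenotypeMatrix(self.table[META_COLS + list(strains)])

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read a minimal uncompressed VCF: GT calls, haploid or
        homozygous diploid; heterozygous or missing GTs become missing.
        Multi-allelic records are collapsed to ref vs first alt with a
        warning."""
        import pysam

        rows = []
        with pysam.VariantFile(str(path)) as vcf:
            samples = list(vcf.header.samples)
            for rec in vcf:
                alts = rec.alts or ()
                if len(alts) > 1:
                    warnings.warn(
                        f"multi-allelic locus {rec.chrom}:{rec.pos} collapsed "
                        "to ref/non-ref"
                    )
                row = {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": alts[0] if alts else MISSING,
                }
                for s in samples:
                    gt = rec.samples[s].get("GT") or ()
                    calls = {a for a in gt if a is not None}
                    if len(calls) == 1:
                        idx = calls.pop()
                        row[s] = rec.ref if idx == 0 else (alts[0] if alts else MISSING)
                    else:
                        row[s] = MISSING
                rows.append(row)
        return cls(pd.DataFrame(rows))


def is_relevant(
    alleles: dict[str, str],
    sensitive: Sequence[str],
    regular: Sequence[str],
) -> bool:
    """Perfect-segregation rule for one locus.

    True iff the allele is uniform within each group, non-missing
    everywhere, and differs between the groups.
    """
    try:
        a_s = [alleles[s] for s in sensitive]
        a_r = [alleles[s] for s in regular]
    except KeyError as exc:
        raise KeyError(f"strain {exc} not present at this locus") from exc
    if MISSING in a_s or MISSING in a_r:
        return False
    return len(set(a_s)) == 1 and len(set(a_r)) == 1 and a_s[0] != a_r[0]


def select_relevant(
    gm: GenotypeMatrix,
    sensitive: Sequence[str],
    regular: Sequence[str],
) -> pd.DataFrame:
    """All loci passing the perfect-segregation rule, in genome order.

    Returns the matching rows of the genotype table (meta columns plus
    the allele carried by each group).
    """
    for group in (sensitive, regular):
        unknown = set(group) - set(gm.strains)
        if unknown:
            raise KeyError(f"unknown strains: {sorted(unknown)}")
    a_s = gm.table[list(sensitive)].to_numpy(object)
    a_r = gm.table[list(regular)].to_numpy(object)
    uniform_s = (a_s == a_s[:, :1]).all(axis=1) & (a_s != MISSING).all(axis=1)
    uniform_r = (a_r == a_r[:, :1]).all(axis=1) & (a_r != MISSING).all(axis=1)
    mask = uniform_s & uniform_r & (a_s[:, 0] != a_r[:, 0])
    out = gm.loci[mask].copy()
    out["sensitive_allele"] = a_s[mask, 0]
    out["regular_allele"] = a_r[mask, 0]
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class FreqTable:
    """Per-chromosome variant-allele frequency bookkeeping.

    ``per_chrom`` columns: n_loci, n_polymorphic,
    polymorphic_variant_freq_pct (share of variant calls among
    strain x polymorphic-locus cells), overall_variant_freq_pct
    (= polymorphic freq * n_polymorphic / n_loci).  ``genome_wide_pct``
    is the n_loci-weighted mean of the overall frequencies.
    """

    per_chrom: pd.DataFrame
    genome_wide_pct: float


def variant_frequencies(gm: GenotypeMatrix) -> FreqTable:
    if len(gm) == 0:
        raise ValueError("empty genotype matrix")
    alleles = gm.alleles.to_numpy(object)
    ref = gm.table["ref"].to_numpy(object)[:, None]
    non_missing = alleles != MISSING
    is_var = non_missing & (alleles != ref)
    poly = is_var.any(axis=1)

    rows = []
    for chrom, idx in gm.table.groupby("chrom", sort=False).indices.items():
        p = poly[idx]
        n_loci = len(idx)
        n_poly = int(p.sum())
        cells = non_missing[idx][p].sum()
        var_calls = is_var[idx][p].sum()
        freq_poly = 100.0 * var_calls / cells if cells else 0.0
        overall = freq_poly * n_poly / n_loci
        rows.append(
            {
                "chrom": chrom,
                "n_loci": n_loci,
                "n_polymorphic": n_poly,
                "polymorphic_variant_freq_pct": freq_poly,
                "overall_variant_freq_pct": overall,
            }
        )
    per_chrom = pd.DataFrame(rows)
    return FreqTable(per_chrom, weighted_overall_frequency(per_chrom))


def weighted_overall_frequency(
    per_chrom: pd.DataFrame,
    freq_col: str = "overall_variant_freq_pct",
    weight_col: str = "n_loci",
) -> float:
    """n_loci-weighted mean of per-chromosome overall variant frequencies."""
    w = per_chrom[weight_col].to_numpy(float)
    return float((per_chrom[freq_col].to_numpy(float) * w).sum() / w.sum())


def expected_by_chance(
    p: float,
    n_sens: int,
    n_reg: int,
    n_loci: int,
    both_directions: bool = False,
) -> float:
    """Expected count of perfectly segregating loci under independence.

    Counts the "variant allele in every sensitive strain, reference in
    every regular strain" configuration, p^n_sens * (1-p)^n_reg * N.
    ``both_directions=True`` adds the mirrored configuration.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a fraction in [0, 1]")
    e = p**n_sens * (1.0 - p) ** n_reg * n_loci
    if both_directions:
        e += (1.0 - p) ** n_sens * p**n_reg * n_loci
    return e


def fisher_enrichment(found: int, expected: float, n_loci: int) -> float:
    """One-sided Fisher exact p-value for found vs expected counts.

    The 2x2 table compares [found, N - found] against
    [round(expected), N - round(expected)]; the test direction follows
    the observed deviation.  Exact hypergeometric computation via
    scipy's Fisher test.
    """
    if not 0 <= found <= n_loci:
        raise ValueError("found must lie in [0, n_loci]")
    if expected < 0:
        raise ValueError("expected must be non-negative")
    e = int(round(expected))
    if e == found:
        # no deviation; includes the expected-rounds-to-0, found=0 case
        return 1.0 if e == 0 else float(
            stats.fisher_exact(
                [[found, n_loci - found], [e, n_loci - e]], alternative="greater"
            ).pvalue
        )
    alternative = "greater" if found > e else "less"
    table = [[found, n_loci - found], [e, n_loci - e]]
    return float(stats.fisher_exact(table, alternative=alternative).pvalue)


def enrichment_table(
    gm: GenotypeMatrix,
    sensitive: Sequence[str],
    regular: Sequence[str],
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-chromosome found vs expected candidate relevant SNP counts.

    The chance expectation uses each chromosome's overall variant-allele
    frequency from :func:`variant_frequencies`.  P-values are raw
    one-sided Fisher tests; an optional Bonferroni column multiplies by
    the number of chromosomes.
    """
    freqs = variant_frequencies(gm).per_chrom.set_index("chrom")
    found = select_relevant(gm, sensitive, regular)
    found_counts = found["chrom"].value_counts()
    rows = []
    for chrom, row in freqs.iterrows():
        n = int(row["n_loci"])
        p = row["overall_variant_freq_pct"] / 100.0
        exp = expected_by_chance(p, len(sensitive), len(regular), n)
        obs = int(found_counts.get(chrom, 0))
        rows.append(
            {
                "chrom": chrom,
                "n_loci": n,
                "variant_freq_pct": row["overall_variant_freq_pct"],
                "expected_by_chance": exp,
                "found": obs,
                "p_value": fisher_enrichment(obs, exp, n),
            }
        )
    out = pd.DataFrame(rows)
    if bonferroni:
        out["p_bonferroni"] = np.minimum(out["p_value"] * len(out), 1.0)
    return out


def relevant_to_bed(relevant: pd.DataFrame, path=None) -> str:
    """Candidate relevant SNPs as BED lines (0-based half-open, width 1)."""
    lines = [
        f"{r.chrom}\t{r.pos - 1}\t{r.pos}\t{r.ref}>{r.alt}"
        for r in relevant.itertuples()
    ]
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
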