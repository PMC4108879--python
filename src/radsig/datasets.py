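"""Bundled reference tables from the 14-strain mouse radiosensitivity study.

Small published summary tables ship with the package so that the
analytic bookkeeping — chance expectations, frequency identities,
mixture thresholds and the strain classification — can be recomputed
without any external download:

* ``load_strain_kinetics`` — per-strain gain k, time constant T and AUF
  fitted from the G2 chromosomal radiosensitivity assay, with replicate
  counts.
* ``load_chromosome_snp_counts`` — genotyped locus counts per mouse
  chromosome.
* ``load_variant_frequencies`` — per-chromosome polymorphic-locus counts
  and variant-allele frequencies.
* ``load_enrichment_table`` — published per-chromosome expected/found
  candidate relevant SNP counts with Fisher-test p-values (kept verbatim,
  including a chromosome-9 frequency that disagrees with the frequency
  table by 0.09 points; the frequency table is the one used for
  recomputation).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_strain_kinetics",
    "load_chromosome_snp_counts",
    "load_variant_frequencies",
    "load_enrichment_table",
    "STUDY_N_SENSITIVE",
    "STUDY_N_REGULAR",
    "STUDY_TOTAL_LOCI",
]

# 14 strains split 3 radiosensitive / 11 regular; genome-wide genotyped loci
STUDY_N_SENSITIVE = 3
STUDY_N_REGULAR = 11
STUDY_TOTAL_LOCI = 7_849_649


def _read(name: str) -> pd.DataFrame:
    with resources.files("radsig.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def load_strain_kinetics() -> pd.DataFrame:
    """Columns: strain, n_replicates, k, T, auf."""
    return _read("g2cr_kinetics.tsv")


def load_chromosome_snp_counts() -> pd.DataFrame:
    """Columns: chrom, n_snps."""
    return _read("chromosome_snp_counts.tsv")


def load_variant_frequencies() -> pd.DataFrame:
    """Columns: chrom, n_snps, n_polymorphic, polymorphic_variant_freq_pct,
    overall_variant_freq_pct."""
    return _read("variant_frequencies.tsv")


def load_enrichment_table() -> pd.DataFrame:
    """Columns: chrom, n_snps, variant_freq_pct, expected_by_chance, found,
    p_value (string; 'ns' and '<1e-6' appear as published)."""
    return _read("relevant_snp_enrichment.tsv")
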