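import numpy as np
import pandas as pd
import pytest

from radsig import datasets
from radsig.snp_selection import GenotypeMatrix


@pytest.fixture(scope="session")
def strain_kinetics() -> pd.DataFrame:
    """Bundled per-strain k/T/AUF table from the 14-strain study."""
    return datasets.load_strain_kinetics()


@pytest.fixture(scope="session")
def variant_freq_table() -> pd.DataFrame:
    return datasets.load_variant_frequencies()


@pytest.fixture(scope="session")
def enrichment_table() -> pd.DataFrame:
    return datasets.load_enrichment_table()


def make_genotype_matrix(allele_rows, strains, chrom="1", ref="A", alt="G",
                         start_pos=100, spacing=10) -> GenotypeMatrix:
    """Build a small genotype matrix from a list of per-locus allele lists."""
    rows = []
    for i, alleles in enumerate(allele_rows):
        row = {"chrom": chrom, "pos": start_pos + i * spacing, "ref": ref, "alt": alt}
        row.update(dict(zip(strains, alleles)))
        rows.append(row)
    columns = ["chrom", "pos", "ref", "alt"] + list(strains)
    return GenotypeMatrix(pd.DataFrame(rows, columns=columns))


@pytest.fixture
def small_gm() -> GenotypeMatrix:
    """Four strains, five loci, one perfectly segregating locus (the 3rd)."""
    strains = ["S1", "S2", "R1", "R2"]
    return make_genotype_matrix(
        [
            ["A", "A", "A", "A"],  # monomorphic
            ["G", "A", "A", "A"],  # polymorphic, not segregating
            ["G", "G", "A", "A"],  # perfectly segregating S vs R
            ["G", "G", "A", "."],  # missing call blocks selection
            ["A", "A", "G", "G"],  # segregating in the mirrored direction
        ],
        strains,
    )
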