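"""Synthetic time-course and genotype generators with planted structure.

Every downstream stage of the pipeline is testable without external
data: time courses are drawn around the exponential decay model with
additive truncated-Gaussian noise, and genotype matrices are drawn with
per-chromosome variant-allele frequencies, independent loci, and an
exact number of *planted* loci that perfectly segregate between the
sensitive and regular strain groups (positioned uniformly or clumped
into a narrow window, the alternative the r-scan test is meant to
detect).  Both generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import TimeCourse, predict
from .snp_selection import MISSING, GenotypeMatrix

__all__ = [
    "TimeCourseSpec",
    "GenotypeSpec",
    "gen_timecourses",
    "gen_genotypes",
    "gen_similarity_panel",
    "timecourses_to_frame",
]

DEFAULT_TIMEPOINTS = (1.0, 2.0, 3.0, 4.0, 5.0)
REF_ALLELE = "A"
VAR_ALLELE = "G"


@dataclass(frozen=True)
class TimeCourseSpec:
    """Parameters of one strain's simulated aberration time courses.

    ``noise_model`` selects between constant-variance noise
    (``additive``: every timepoint gets sd ``noise_sd``) and
    signal-proportional noise (``proportional``: the sd at time t is
    ``noise_sd * exp(-t/T)``, i.e. ``noise_sd`` is the sd at t=0 and the
    coefficient of variation is constant, as for count-derived yields).
    """

    strain_id: str
    n_replicates: int
    true_k: float
    true_T: float
    noise_sd: float
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    noise_model: str = "additive"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_k <= 0 or self.true_T <= 0:
            raise ValueError("true_k and true_T must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_model not in ("additive", "proportional"):
            raise ValueError("noise_model must be 'additive' or 'proportional'")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        t = np.asarray(self.timepoints, float)
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be positive and strictly increasing")


@dataclass(frozen=True)
class GenotypeSpec:
    """Parameters of a simulated strain x locus genotype matrix.

    ``n_loci`` gives the background locus count per chromosome; planted
    loci are added on top of it and exactly satisfy the
    perfect-segregation rule (variant in every sensitive strain,
    reference in every regular one).
    """

    n_strains_sensitive: int
    n_strains_regular: int
    chrom_lengths: Mapping[str, int]
    per_chrom_variant_freq: Mapping[str, float]
    n_loci: Mapping[str, int]
    n_planted_relevant: int = 0
    planted_layout: str = "uniform"
    clump_width: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains_sensitive < 1 or self.n_strains_regular < 1:
            raise ValueError("both strain groups must be non-empty")
        for chrom, f in self.per_chrom_variant_freq.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"variant frequency for {chrom} outside [0, 1]")
        if set(self.per_chrom_variant_freq) != set(self.chrom_lengths) or set(
            self.n_loci
        ) != set(self.chrom_lengths):
            raise ValueError("chromosome maps must share the same keys")
        if self.planted_layout not in ("uniform", "clumped"):
            raise ValueError("planted_layout must be 'uniform' or 'clumped'")
        total = sum(self.chrom_lengths.values())
        if self.n_planted_relevant > total:
            raise ValueError("more planted loci than base pairs available")
        if self.n_planted_relevant < 0:
            raise ValueError("n_planted_relevant must be >= 0")

    @property
    def sensitive_strains(self) -> list[str]:
        return [f"SENS{i + 1}" for i in range(self.n_strains_sensitive)]

    @property
    def regular_strains(self) -> list[str]:
        return [f"REG{i + 1}" for i in range(self.n_strains_regular)]


def gen_timecourses(spec: TimeCourseSpec) -> list[TimeCourse]:
    """Simulate replicates of y(t) = k*exp(-t/T) + N(0, sd^2), clipped at 0."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.timepoints, float)
    mean = predict(spec.true_k, spec.true_T, t)
    if spec.noise_model == "proportional":
        sd = spec.noise_sd * mean / spec.true_k
    else:
        sd = np.full_like(t, spec.noise_sd)
    out = []
    for rep in range(spec.n_replicates):
        noise = rng.normal(0.0, sd) if spec.noise_sd else 0.0
        out.append(
            TimeCourse(
                strain_id=spec.strain_id,
                replicate_id=f"rep{rep + 1}",
                times=t,
                yields=np.clip(mean + noise, 0.0, None),
            )
        )
    return out


def timecourses_to_frame(tcs: Sequence[TimeCourse]) -> pd.DataFrame:
    """Long-format (strain, replicate, time_h, yield) frame."""
    return pd.DataFrame(
        [
            {"strain": tc.strain_id, "replicate": tc.replicate_id,
             "time_h": t, "yield": y}
            for tc in tcs
            for t, y in zip(tc.times, tc.yields)
        ]
    )


def _sample_positions(length: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """n distinct sorted 1-based positions on [1, length], memory-bounded."""
    if n > length:
        raise ValueError(f"cannot place {n} distinct loci on {length} bp")
    if 4 * n >= length:
        return np.sort(rng.permutation(length)[:n] + 1)
    # collisions are rare when n << length: over-draw, deduplicate, top up
    out = np.unique(rng.integers(1, length + 1, size=n + n // 8 + 16))
    while len(out) < n:
        more = rng.integers(1, length + 1, size=(n - len(out)) * 2 + 16)
        out = np.unique(np.concatenate([out, more]))
    return np.sort(rng.permutation(out)[:n])


def _planted_positions(spec: GenotypeSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Spread planted loci across chromosomes, uniform or clumped layout."""
    chroms = list(spec.chrom_lengths)
    counts = np.bincount(
        rng.integers(0, len(chroms), size=spec.n_planted_relevant),
        minlength=len(chroms),
    )
    rows = []
    for chrom, count in zip(chroms, counts):
        if count == 0:
            continue
        length = spec.chrom_lengths[chrom]
        if spec.planted_layout == "clumped":
            width = min(spec.clump_width, length)
            if count > width:
                raise ValueError(
                    f"clump_width {width} too narrow for {count} planted loci"
                )
            start = int(rng.integers(1, length - width + 2))
            pos = _sample_positions(width, count, rng) + start - 1
        else:
            pos = _sample_positions(length, count, rng)
        rows.extend({"chrom": chrom, "pos": int(p)} for p in pos)
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def gen_genotypes(spec: GenotypeSpec) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate the genotype matrix plus the planted ground truth.

    Background loci carry the variant allele independently per strain at
    the chromosome's variant frequency; planted loci are variant in all
    sensitive strains and reference in all regular strains.  Returns
    (matrix, planted truth frame of chrom/pos).
    """
    rng = np.random.default_rng(spec.seed)
    strains = spec.sensitive_strains + spec.regular_strains
    frames = []
    for chrom, length in spec.chrom_lengths.items():
        n = spec.n_loci[chrom]
        if n == 0:
            continue
        pos = _sample_positions(length, n, rng)
        p = spec.per_chrom_variant_freq[chrom]
        calls = rng.random((n, len(strains))) < p
        frame = pd.DataFrame(
            np.where(calls, VAR_ALLELE, REF_ALLELE), columns=strains
        )
        frame.insert(0, "alt", VAR_ALLELE)
        frame.insert(0, "ref", REF_ALLELE)
        frame.insert(0, "pos", pos)
        frame.insert(0, "chrom", chrom)
        frames.append(frame)

    planted = _planted_positions(spec, rng)
    if len(planted):
        frame = pd.DataFrame(
            {
                "chrom": planted["chrom"],
                "pos": planted["pos"],
                "ref": REF_ALLELE,
                "alt": VAR_ALLELE,
            }
        )
        for s in spec.sensitive_strains:
            frame[s] = VAR_ALLELE
        for s in spec.regular_strains:
            frame[s] = REF_ALLELE
        frames.append(frame)
    if not frames:
        raise ValueError("spec generates no loci at all")
    table = pd.concat(frames, ignore_index=True)
    # planted positions may collide with a background locus; keep the planted call
    table = table.drop_duplicates(subset=["chrom", "pos"], keep="last")
    return GenotypeMatrix(table), planted


def gen_similarity_panel(
    pattern_alleles: np.ndarray,
    planted_identities: Sequence[float],
    n_background: int,
    background_identity: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Query-strain allele vectors with controlled pattern identity.

    Background strains match the pattern allele independently with
    probability ``background_identity``; each planted strain matches at
    an exact rounded fraction of loci.  Alleles are two-state: the
    pattern allele or its flip.
    """
    rng = np.random.default_rng(seed)
    pat = np.asarray(pattern_alleles, dtype=object)
    flip = np.where(pat == VAR_ALLELE, REF_ALLELE, VAR_ALLELE)
    n_loci = len(pat)
    cols = {}
    for i in range(n_background):
        match = rng.random(n_loci) < background_identity
        cols[f"BG{i + 1}"] = np.where(match, pat, flip)
    for j, ident in enumerate(planted_identities):
        if not 0.0 <= ident <= 1.0:
            raise ValueError("identities must be fractions in [0, 1]")
        n_match = int(round(ident * n_loci))
        idx = rng.choice(n_loci, size=n_match, replace=False)
        alleles = flip.copy()
        alleles[idx] = pat[idx]
        cols[f"PLANTED{j + 1}"] = alleles
    return pd.DataFrame(cols)
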