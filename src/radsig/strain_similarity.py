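"""In-silico prediction of radiosensitive strains from the SNP signature.

Strains without a measured aberration time course are scored against the
*radiosensitive pattern* — the allele carried by every radiosensitive
strain at each candidate relevant SNP.  The similarity score is the
percentage of pattern loci at which a query strain carries the pattern
allele (missing calls excluded from the denominator).  Because the score
distribution over a strain panel is typically skewed, high-similarity
strains are flagged with the Hubert-Vandervieren adjusted boxplot, whose
fences are tilted by the medcouple robust skewness measure:

    MC >= 0:  [Q1 - 1.5*exp(-4*MC)*IQR,  Q3 + 1.5*exp(+3*MC)*IQR]
    MC <  0:  [Q1 - 1.5*exp(-3*MC)*IQR,  Q3 + 1.5*exp(+4*MC)*IQR]

Relationships among all strains restricted to the candidate relevant
SNPs are summarised by a UPGMA tree on Jukes-Cantor distances
d = -(3/4) ln(1 - (4/3) p) computed from pairwise mismatch fractions p.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.stattools import medcouple as _sm_medcouple

from .snp_selection import MISSING, GenotypeMatrix

__all__ = [
    "Pattern",
    "TreeNode",
    "pattern_from_genotypes",
    "similarity_score",
    "score_strains",
    "medcouple",
    "adjusted_boxplot_outliers",
    "jukes_cantor",
    "jc_distance_matrix",
    "upgma",
    "write_newick",
]


@dataclass(frozen=True)
class Pattern:
    """The radiosensitive allele at each candidate relevant SNP."""

    loci: pd.DataFrame  # chrom, pos
    alleles: np.ndarray  # parallel to loci rows

    def __post_init__(self) -> None:
        keys = list(zip(self.loci["chrom"], self.loci["pos"]))
        if len(keys) != len(set(keys)):
            raise ValueError("pattern loci must be unique")
        if len(self.alleles) != len(self.loci):
            raise ValueError("alleles and loci must be parallel")
        if any(a == MISSING for a in self.alleles):
            raise ValueError("pattern alleles must be non-missing")

    def __len__(self) -> int:
        return len(self.alleles)


def pattern_from_genotypes(
    gm: GenotypeMatrix,
    relevant: pd.DataFrame,
    sensitive: Sequence[str],
) -> Pattern:
    """Extract the allele shared by all sensitive strains at the relevant loci."""
    merged = gm.table.merge(relevant[["chrom", "pos"]], on=["chrom", "pos"])
    alleles = merged[list(sensitive)].to_numpy(object)
    if not ((alleles == alleles[:, :1]).all(axis=1).all() and (alleles != MISSING).all()):
        raise ValueError("sensitive strains do not share one non-missing allele "
                         "at every relevant locus")
    return Pattern(merged[["chrom", "pos"]].reset_index(drop=True), alleles[:, 0])


def similarity_score(strain_alleles: Sequence[str], pattern: Pattern) -> tuple[float, int]:
    """Percentage of non-missing pattern loci with the pattern allele.

    Returns (score, n_loci_used); the score is NaN when every call is
    missing.
    """
    if len(pattern) == 0:
        raise ValueError("pattern must be non-empty")
    a = np.asarray(strain_alleles, dtype=object)
    if a.shape != pattern.alleles.shape:
        raise ValueError("strain alleles must align with the pattern loci")
    use = a != MISSING
    n_used = int(use.sum())
    if n_used == 0:
        return float("nan"), 0
    score = 100.0 * float((a[use] == pattern.alleles[use]).sum()) / n_used
    return score, n_used


def score_strains(gm: GenotypeMatrix, pattern: Pattern) -> pd.DataFrame:
    """Similarity score for every strain in the matrix, aligned to the pattern."""
    merged = pattern.loci.merge(gm.table, on=["chrom", "pos"], how="left")
    rows = []
    for strain in gm.strains:
        alleles = merged[strain].fillna(MISSING).to_numpy(object)
        score, n_used = similarity_score(alleles, pattern)
        rows.append({"strain": strain, "score": score, "n_loci_used": n_used})
    return pd.DataFrame(rows)


def medcouple(values: Sequence[float]) -> float:
    """Robust skewness in [-1, 1]: the median of the kernel
    h = ((x_j - med) - (med - x_i)) / (x_j - x_i) over pairs
    x_i <= med <= x_j, with the signed -1/0/+1 convention for pairs tied
    at the median.  Constant samples return 0."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("medcouple needs at least 3 observations")
    if np.ptp(x) == 0:
        return 0.0
    return float(_sm_medcouple(x))


def _quartiles(x: np.ndarray) -> tuple[float, float]:
    return tuple(np.percentile(x, [25, 75]))  # type: ignore[return-value]


def adjusted_boxplot_outliers(
    scores: pd.DataFrame | Sequence[float],
) -> pd.DataFrame:
    """Flag outliers with the medcouple-adjusted boxplot.

    Accepts the frame produced by :func:`score_strains` (or a bare
    sequence of scores) and returns it with columns medcouple,
    fence_lower, fence_upper, outlier, and side ('high'/'low'/'').
    High-side outliers are the candidate radiosensitive strains.
    """
    if not isinstance(scores, pd.DataFrame):
        scores = pd.DataFrame({"strain": range(len(scores)), "score": list(scores)})
    out = scores.copy()
    x = out["score"].to_numpy(float)
    x = x[~np.isnan(x)]
    if len(x) < 5:
        raise ValueError("adjusted boxplot needs at least 5 scores")
    q1, q3 = _quartiles(x)
    iqr = q3 - q1
    mc = medcouple(x)
    if iqr == 0:
        lo, hi = q1, q3
    elif mc >= 0:
        lo = q1 - 1.5 * math.exp(-4.0 * mc) * iqr
        hi = q3 + 1.5 * math.exp(3.0 * mc) * iqr
    else:
        lo = q1 - 1.5 * math.exp(-3.0 * mc) * iqr
        hi = q3 + 1.5 * math.exp(4.0 * mc) * iqr
    s = out["score"].to_numpy(float)
    out["medcouple"] = mc
    out["fence_lower"] = lo
    out["fence_upper"] = hi
    out["outlier"] = (s < lo) | (s > hi)
    out["side"] = np.where(s > hi, "high", np.where(s < lo, "low", ""))
    return out


def jukes_cantor(
    alleles_i: Sequence[str],
    alleles_j: Sequence[str],
) -> float:
    """JC69 distance from the mismatch fraction over shared non-missing loci.

    Alleles here are two-state characters; mismatch fractions >= 3/4 lie
    outside the JC69 domain and yield +inf with a warning.
    """
    a = np.asarray(alleles_i, dtype=object)
    b = np.asarray(alleles_j, dtype=object)
    if a.shape != b.shape:
        raise ValueError("allele vectors must have equal length")
    use = (a != MISSING) & (b != MISSING)
    if not use.any():
        raise ValueError("no shared non-missing loci")
    p = float((a[use] != b[use]).mean())
    if p >= 0.75:
        warnings.warn(f"mismatch fraction {p:.3f} >= 3/4: JC distance undefined")
        return float("inf")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_distance_matrix(gm: GenotypeMatrix, loci: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pairwise Jukes-Cantor distances between strains, optionally restricted
    to the (chrom, pos) loci given (the candidate relevant SNPs)."""
    table = gm.table
    if loci is not None:
        table = table.merge(loci[["chrom", "pos"]], on=["chrom", "pos"])
    strains = gm.strains
    d = pd.DataFrame(0.0, index=strains, columns=strains)
    cols = {s: table[s].to_numpy(object) for s in strains}
    for i, si in enumerate(strains):
        for sj in strains[i + 1:]:
            dist = jukes_cantor(cols[si], cols[sj])
            d.loc[si, sj] = d.loc[sj, si] = dist
    return d


@dataclass(frozen=True)
class TreeNode:
    """Node of a rooted ultrametric tree; leaves have height 0."""

    height: float
    name: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        return [n for c in self.children for n in c.leaf_names()]


def upgma(dist: pd.DataFrame) -> TreeNode:
    """Average-linkage agglomeration into a rooted ultrametric tree.

    At each step the closest pair of clusters merges at a node of height
    d/2; distances to the merged cluster are size-weighted arithmetic
    means.  Ties break deterministically on the lexicographically
    smallest pair of cluster labels (a cluster is labelled by its
    smallest leaf).
    """
    m = dist.to_numpy(float)
    labels = list(dist.index)
    if not np.allclose(m, m.T) or np.any(np.diag(m) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if np.any(np.isnan(m)) or np.any(m < 0):
        raise ValueError("distance matrix must be non-negative and NaN-free")
    if len(labels) == 1:
        return TreeNode(0.0, name=labels[0])

    clusters: dict[str, tuple[TreeNode, int]] = {
        lab: (TreeNode(0.0, name=lab), 1) for lab in labels
    }
    d: dict[frozenset, float] = {
        frozenset((labels[i], labels[j])): m[i, j]
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    while len(clusters) > 1:
        best = min(
            d.items(),
            key=lambda kv: (kv[1], tuple(sorted(kv[0]))),
        )
        (pair, dist_ij) = best
        li, lj = sorted(pair)
        (node_i, ni), (node_j, nj) = clusters.pop(li), clusters.pop(lj)
        merged = TreeNode(dist_ij / 2.0, children=(node_i, node_j))
        for other in clusters:
            dio = d.pop(frozenset((li, other)))
            djo = d.pop(frozenset((lj, other)))
            d[frozenset((li, other))] = (ni * dio + nj * djo) / (ni + nj)
        del d[pair]
        # re-key the merged cluster under its smallest leaf label (= li)
        clusters[li] = (merged, ni + nj)
    (root, _), = clusters.values()
    return root


def write_newick(tree: TreeNode, path=None) -> str:
    """Newick serialisation with branch lengths = parent - child height."""

    def fmt(node: TreeNode, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{node.name}:{length:.10g}"
        inner = ",".join(fmt(c, node.height) for c in node.children)
        return f"({inner}):{length:.10g}"

    if tree.is_leaf:
        text = f"{tree.name}:0;"
    else:
        inner = ",".join(fmt(c, tree.height) for c in tree.children)
        text = f"({inner});"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
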