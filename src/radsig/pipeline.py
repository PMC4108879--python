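"""End-to-end orchestration of the radiosensitivity signature pipeline.

Stage order: kinetics -> subpopulation classification -> candidate
relevant SNP selection -> along-chromosome distribution -> similarity
scoring of unphenotyped strains.  A run is fully described by a
:class:`PipelineConfig`; outputs land in one directory together with a
JSON manifest (package version, seeds, derived thresholds) that
suffices to replay the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, datasets, genome_distribution, kinetics, snp_selection
from . import strain_similarity as sim
from . import subpopulations

logger = logging.getLogger("radsig")

__all__ = ["PipelineConfig", "run_all", "reproduce_tables"]


@dataclass
class PipelineConfig:
    """All paths and tuning knobs of one pipeline run."""

    genotypes: str
    out_dir: str
    timecourses: str | None = None
    kinetic_params: str | None = None  # skip fitting, use precomputed k/T/auf
    annotation: str | None = None
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    t_end: float = 5.0
    g_max: int = 3
    seed: int = 17
    n_restarts: int = 50
    r: int = 1
    B: int = 10_000
    gap: int = 250_000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        for name in ("timecourses", "kinetic_params", "genotypes", "annotation"):
            value = getattr(cfg, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} file does not exist: {value}")
        return cfg


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


@_stage("kinetics")
def _run_kinetics(cfg: PipelineConfig) -> pd.DataFrame:
    if cfg.kinetic_params is not None:
        params = pd.read_csv(cfg.kinetic_params)
        if "auf" not in params.columns and {"k", "T"} <= set(params.columns):
            params["auf"] = [
                kinetics.auf(k, T, cfg.t_end) for k, T in zip(params["k"], params["T"])
            ]
        return params
    if cfg.timecourses is None:
        raise ValueError("config needs either timecourses or kinetic_params")
    df = pd.read_csv(cfg.timecourses)
    return kinetics.fit_strains(df, t_end=cfg.t_end)


@_stage("subpopulations")
def _run_classification(cfg: PipelineConfig, params: pd.DataFrame):
    rule, models = subpopulations.derive_rule(
        params, g_max=cfg.g_max, seed=cfg.seed, n_restarts=cfg.n_restarts
    )
    classes = subpopulations.classify(params, rule)
    return rule, models, classes


@_stage("snp_selection")
def _run_selection(cfg: PipelineConfig, gm, sensitive, regular):
    phenotyped = gm.subset_strains(sensitive + regular)
    relevant = snp_selection.select_relevant(phenotyped, sensitive, regular)
    freqs = snp_selection.variant_frequencies(phenotyped)
    enrich = snp_selection.enrichment_table(phenotyped, sensitive, regular)
    return relevant, freqs, enrich


@_stage("genome_distribution")
def _run_spatial(cfg: PipelineConfig, relevant: pd.DataFrame):
    results = []
    clusters = []
    for chrom, grp in relevant.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(float)
        if len(pos) <= cfg.r:
            logger.warning("chromosome %s has too few relevant SNPs for r-scan", chrom)
            continue
        length = cfg.chrom_lengths.get(str(chrom), float(pos.max()))
        res = genome_distribution.rscan_test(
            pos, length, r=cfg.r, method="monte_carlo", B=cfg.B,
            seed=cfg.seed, chrom=str(chrom),
        )
        results.append(res)
        clusters.extend(genome_distribution.cluster_snps(pos, cfg.gap, chrom=str(chrom)))
    rscan_df = pd.DataFrame([asdict(r) for r in results])
    cluster_df = pd.DataFrame([asdict(c) for c in clusters])
    if cfg.annotation:
        ann = genome_distribution.read_annotation(cfg.annotation)
        classes, _ = genome_distribution.classify_snps(relevant, ann)
        func_df = relevant[["chrom", "pos"]].assign(functional_class=classes)
    else:
        logger.warning("no annotation provided; functional classification skipped")
        func_df = None
    return rscan_df, cluster_df, func_df


@_stage("strain_similarity")
def _run_similarity(cfg: PipelineConfig, gm, relevant, sensitive, phenotyped):
    pattern = sim.pattern_from_genotypes(gm, relevant, sensitive)
    query = [s for s in gm.strains if s not in phenotyped]
    out = {}
    if query:
        scores = sim.score_strains(gm.subset_strains(query), pattern)
        out["scores"] = sim.adjusted_boxplot_outliers(scores)
    dist = sim.jc_distance_matrix(gm, relevant)
    tree = sim.upgma(dist)
    out["distances"] = dist
    out["newick"] = sim.write_newick(tree)
    return out


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage; write stage outputs plus a manifest to out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    params = _run_kinetics(cfg)
    gm = snp_selection.GenotypeMatrix.from_tsv(cfg.genotypes)

    missing = sorted(set(params["strain"]) - set(gm.strains))
    if missing:
        raise ValueError(
            "strains with time courses but no genotypes: " + ", ".join(missing)
        )

    rule, models, classes = _run_classification(cfg, params)
    sensitive = sorted(classes.loc[classes["label"] == "radiosensitive", "strain"])
    regular = sorted(classes.loc[classes["label"] == "regular", "strain"])
    if not sensitive or not regular:
        raise ValueError("classification produced an empty strain group; "
                         "cannot select segregating SNPs")

    relevant, freqs, enrich = _run_selection(cfg, gm, sensitive, regular)
    rscan_df, cluster_df, func_df = _run_spatial(cfg, relevant)

    classes_out = classes.sort_values("strain").reset_index(drop=True)
    similarity = _run_similarity(cfg, gm, relevant, sensitive, set(params["strain"]))

    params.sort_values("strain").to_csv(out / "kinetic_params.csv", index=False)
    classes_out.to_csv(out / "classes.csv", index=False)
    relevant.to_csv(out / "relevant_snps.tsv", sep="\t", index=False)
    snp_selection.relevant_to_bed(relevant, out / "relevant_snps.bed")
    freqs.per_chrom.to_csv(out / "variant_frequencies.tsv", sep="\t", index=False)
    enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    rscan_df.to_csv(out / "rscan.tsv", sep="\t", index=False)
    cluster_df.to_csv(out / "clusters.tsv", sep="\t", index=False)
    if func_df is not None:
        func_df.to_csv(out / "functional_classes.tsv", sep="\t", index=False)
    similarity["distances"].to_csv(out / "jc_distances.csv")
    (out / "tree.nwk").write_text(similarity["newick"] + "\n")
    if "scores" in similarity:
        similarity["scores"].to_csv(out / "similarity_scores.tsv", sep="\t", index=False)

    manifest = {
        "radsig_version": __version__,
        "seed": cfg.seed,
        "t_end": cfg.t_end,
        "g_max": cfg.g_max,
        "n_restarts": cfg.n_restarts,
        "r": cfg.r,
        "B": cfg.B,
        "gap": cfg.gap,
        "threshold_k": rule.threshold_k,
        "threshold_auf": rule.threshold_auf,
        "n_components": {p: m.n_components for p, m in models.items()},
        "radiosensitive": sensitive,
        "n_relevant_snps": int(len(relevant)),
        "genome_wide_variant_freq_pct": freqs.genome_wide_pct,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "params": params,
        "rule": rule,
        "classes": classes_out,
        "relevant": relevant,
        "freqs": freqs,
        "enrichment": enrich,
        "rscan": rscan_df,
        "clusters": cluster_df,
        "similarity": similarity,
        "manifest": manifest,
    }


def reproduce_tables(out_dir=None) -> dict[str, pd.DataFrame]:
    """Recompute the analytic columns of the bundled summary tables.

    From the bundled per-chromosome variant frequencies this rebuilds the
    genome-wide weighted frequency, each chromosome's overall-frequency
    identity, and the per-chromosome and genome-wide chance expectations,
    then diffs them against the published values.  The chromosome-9
    frequency disagreement between the two bundled tables is surfaced in
    the diff rather than hidden.
    """
    freq = datasets.load_variant_frequencies()
    enrich = datasets.load_enrichment_table()
    ns, nr = datasets.STUDY_N_SENSITIVE, datasets.STUDY_N_REGULAR

    freq_check = freq.copy()
    freq_check["overall_recomputed_pct"] = (
        freq["polymorphic_variant_freq_pct"] * freq["n_polymorphic"] / freq["n_snps"]
    )
    freq_check["overall_diff_pct"] = (
        freq_check["overall_recomputed_pct"] - freq["overall_variant_freq_pct"]
    )

    merged = enrich.merge(
        freq[["chrom", "overall_variant_freq_pct"]], on="chrom"
    )
    merged["freq_diff_pct"] = (
        merged["variant_freq_pct"] - merged["overall_variant_freq_pct"]
    )
    merged["expected_recomputed"] = [
        snp_selection.expected_by_chance(f / 100.0, ns, nr, int(n))
        for f, n in zip(merged["variant_freq_pct"], merged["n_snps"])
    ]
    merged["expected_diff"] = (
        merged["expected_recomputed"].round() - merged["expected_by_chance"]
    )

    weighted = snp_selection.weighted_overall_frequency(
        freq, freq_col="overall_variant_freq_pct", weight_col="n_snps"
    )
    genome = pd.DataFrame(
        {
            "genome_wide_variant_freq_pct": [weighted],
            "n_loci": [int(freq["n_snps"].sum())],
            "expected_by_chance": [
                snp_selection.expected_by_chance(
                    round(weighted, 2) / 100.0, ns, nr, int(freq["n_snps"].sum())
                )
            ],
        }
    )
    tables = {"frequencies": freq_check, "enrichment": merged, "genome": genome}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"reproduced_{name}.tsv", sep="\t", index=False)
    return tables
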