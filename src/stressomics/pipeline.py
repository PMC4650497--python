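"""End-to-end pipeline stages over a working directory.

Each ``run_*`` stage reads the outputs of the stages before it from the
output directory, writes its own TSV outputs, and appends a structured entry
(stage name, parameters, input-file hashes) to ``pipeline_log.jsonl``.  A
missing upstream artifact raises :class:`PipelineError` naming the stage to
run first.  ``run_all`` chains every stage on synthetic data; with a fixed
seed the whole directory is byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as cl
from . import differential as de
from . import enrichment as enr
from . import mixedmodel as mm
from . import multilevel as ml
from . import preprocess as pp
from . import simulate as sim
from .config import PipelineConfig
from .containers import LongitudinalMatrix

__all__ = [
    "PipelineError",
    "run_simulate",
    "run_preprocess",
    "run_decompose",
    "run_de",
    "run_cluster",
    "run_lmm",
    "run_spls",
    "run_enrich",
    "run_all",
]


class PipelineError(RuntimeError):
    pass


def _stage_seed(config: PipelineConfig, stage_index: int) -> int:
    return int((config.seed * 1_000_003 + stage_index) % 2**31)


def _require(outdir: Path, filename: str, produced_by: str) -> Path:
    path = outdir / filename
    if not path.exists():
        raise PipelineError(
            f"missing {filename!r}: run {produced_by} first"
        )
    return path


def _log(outdir: Path, stage: str, params: dict, inputs: list[Path]) -> None:
    hashes = {}
    for path in inputs:
        hashes[path.name] = hashlib.md5(path.read_bytes()).hexdigest()
    entry = {"stage": stage, "params": params, "input_hashes": hashes}
    with open(outdir / "pipeline_log.jsonl", "a") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


# --------------------------------------------------------------------------- #
def run_simulate(config: PipelineConfig, outdir: str | Path) -> dict:
    """Generate the synthetic study: biological arm, transcriptome arm and a
    synthetic annotation table for the enrichment stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sexes = {
        i: ("F" if i < round(0.525 * config.n_animals_bio) else "M")
        for i in range(config.n_animals_bio)
    }
    bio_design = sim.StudyDesign(
        n_animals=config.n_animals_bio,
        n_batches=config.n_batches_bio,
        sex_assignment=sexes,
        seed=_stage_seed(config, 0),
    )
    bio, bio_truth = sim.generate_biological(bio_design)
    bio.write_tsv(outdir / "bio.tsv")
    _write(bio_truth.effects, outdir / "bio_truth_effects.tsv")

    expr_design = sim.StudyDesign(
        n_animals=config.n_animals_expr,
        n_batches=config.n_batches_expr,
        seed=_stage_seed(config, 1),
    )
    truth = sim.ExpressionTruth.default(
        cluster_sizes=config.cluster_sizes,
        n_null=config.n_null_genes,
        probes_per_gene=config.probes_per_gene,
        effect_size=config.effect_size,
        probe_noise_sd=config.probe_noise_sd,
        n_controls=config.n_control_probes,
    )
    expression, sample_map, probe_map = sim.generate_expression(expr_design, truth)
    _write(expression, outdir / "expression.tsv")
    _write(sample_map, outdir / "sample_map.tsv")
    _write(probe_map, outdir / "probe_map.tsv")

    annotation = _synthetic_annotation(truth, seed=_stage_seed(config, 2))
    annotation.write_tsv(outdir / "annotation.tsv")

    _log(outdir, "simulate", {"seed": config.seed}, [outdir / "bio.tsv", outdir / "expression.tsv"])
    return {"bio": bio, "expression": expression}


def _synthetic_annotation(truth: sim.ExpressionTruth, seed: int) -> enr.AnnotationTable:
    """Terms aligned with the planted clusters plus random background terms."""
    rng = np.random.default_rng(seed)
    genes = list(truth.gene_clusters)
    null_genes = [g for g, c in truth.gene_clusters.items() if c == 0]
    mapping, names = {}, {}
    clusters = sorted({c for c in truth.gene_clusters.values() if c != 0})
    for c in clusters:
        members = [g for g, cc in truth.gene_clusters.items() if cc == c]
        extra = list(rng.choice(null_genes, size=min(10, len(null_genes)), replace=False))
        mapping[f"SYN:{c:04d}"] = set(members) | set(extra)
        names[f"SYN:{c:04d}"] = f"synthetic process {c}"
    for j in range(20):
        size = int(rng.integers(5, 40))
        mapping[f"BG:{j:04d}"] = set(rng.choice(genes, size=size, replace=False))
        names[f"BG:{j:04d}"] = f"background process {j}"
    return enr.AnnotationTable.from_mapping(mapping, names)


# --------------------------------------------------------------------------- #
def run_preprocess(config: PipelineConfig, outdir: str | Path) -> dict:
    """Clean both arms: outlier masking, k-NN imputation, transforms and
    batch alignment for the biological arm; median alignment, within-animal
    quantile normalization and probe filtering for the transcriptome arm."""
    outdir = Path(outdir)
    bio_path = _require(outdir, "bio.tsv", "run_simulate")
    expr_path = _require(outdir, "expression.tsv", "run_simulate")
    probe_map = pd.read_csv(_require(outdir, "probe_map.tsv", "run_simulate"),
                            sep="\t", index_col=0)
    sample_map = pd.read_csv(_require(outdir, "sample_map.tsv", "run_simulate"),
                             sep="\t", index_col=0)

    log = pp.ProvenanceLog()
    bio = LongitudinalMatrix.read_tsv(bio_path)
    bio = pp.mask_outliers(bio, z_threshold=config.outlier_z, log=log)
    bio = pp.impute_knn(bio, k=config.knn_k, weighting=config.knn_weighting, log=log)
    bio = pp.apply_transforms(bio, pp.TransformSpec.acth_default(), log=log)
    bio = pp.align_batch_medians(bio, log=log)
    bio.write_tsv(outdir / "bio_clean.tsv")

    expression = pd.read_csv(expr_path, sep="\t", index_col=0)
    expr = sim.expression_to_matrix(expression, sample_map)
    # within-array median alignment: one group spanning all arrays
    expr = pp.quantile_normalize_within_group(
        expr, group=np.zeros(expr.n_samples, dtype=int), mode="median", log=log
    )
    expr = pp.quantile_normalize_within_group(expr, mode="quantile", log=log)
    filtered, report = pp.filter_probes(
        expr.values.T,
        probe_map,
        threshold_mode="control" if config.n_control_probes else "none",
        min_expressed_fraction=config.min_expressed_fraction,
        log=log,
    )
    _write(filtered, outdir / "expr_clean.tsv")
    log.write(outdir / "preprocess_provenance.jsonl")
    _log(outdir, "preprocess", {"knn_k": config.knn_k, **report}, [bio_path, expr_path])
    return {"bio": bio, "expression": filtered}


# --------------------------------------------------------------------------- #
def _load_bio_clean(outdir: Path) -> LongitudinalMatrix:
    return LongitudinalMatrix.read_tsv(_require(outdir, "bio_clean.tsv", "run_preprocess"))


def _load_expr_clean(outdir: Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    expr = pd.read_csv(_require(outdir, "expr_clean.tsv", "run_preprocess"),
                       sep="\t", index_col=0)
    sample_map = pd.read_csv(_require(outdir, "sample_map.tsv", "run_simulate"),
                             sep="\t", index_col=0)
    probe_map = pd.read_csv(_require(outdir, "probe_map.tsv", "run_simulate"),
                            sep="\t", index_col=0)
    return expr, sample_map, probe_map


def run_decompose(config: PipelineConfig, outdir: str | Path) -> dict:
    """Write the within-animal components of both cleaned arms."""
    outdir = Path(outdir)
    bio = _load_bio_clean(outdir)
    expr, sample_map, _ = _load_expr_clean(outdir)

    bio_within = ml.decompose(bio).within_matrix
    bio_within.write_tsv(outdir / "bio_within.tsv")
    expr_m = sim.expression_to_matrix(expr, sample_map)
    expr_within = ml.decompose(expr_m).within_matrix
    _write(expr_within.values.T, outdir / "expr_within.tsv")
    _log(outdir, "decompose", {}, [outdir / "bio_clean.tsv", outdir / "expr_clean.tsv"])
    return {"bio_within": bio_within, "expr_within": expr_within}


# --------------------------------------------------------------------------- #
def run_de(config: PipelineConfig, outdir: str | Path) -> dict:
    """Univariate stage: time ANOVA, sex ANOVA and anchor correlations for
    the biological arm; paired tests, Bonferroni control and duplicate-probe
    consolidation for the transcriptome arm."""
    outdir = Path(outdir)
    bio = _load_bio_clean(outdir)
    expr, sample_map, probe_map = _load_expr_clean(outdir)

    anova = de.rm_anova(bio, adjust_method=config.bio_adjust)
    _write(anova, outdir / "bio_anova.tsv")
    responding = anova.index[anova["adj_p"] < config.alpha].tolist()
    bio_paired = de.paired_tests(
        bio.subset_features(responding) if responding else bio,
        adjust_method=config.bio_adjust, alpha=config.alpha,
    )
    _write(bio_paired, outdir / "bio_paired.tsv", index=False)
    sex = de.two_way_anova_sex(bio, adjust_method=config.bio_adjust)
    _write(sex, outdir / "bio_sex.tsv")

    # anchor correlations of biological variables to the cortisol peak
    bio_within = ml.decompose(bio).within_matrix
    anchor = bio_within.at_time(config.anchor_time)[config.anchor_variable]
    others = [v for v in bio.values.columns if v != config.anchor_variable]
    bio_anchor = de.correlate_to_anchor(
        bio_within.subset_features(others), anchor, adjust_method=config.bio_adjust,
        alpha=config.alpha,
    )
    _write(bio_anchor, outdir / "bio_anchor.tsv", index=False)

    expr_m = sim.expression_to_matrix(expr, sample_map)
    expr_paired = de.paired_tests(
        expr_m, adjust_method=config.transcript_adjust, alpha=config.alpha
    )
    _write(expr_paired, outdir / "expr_paired.tsv", index=False)
    consolidation, unannotated = de.consolidate_probes(
        expr_paired, expr, probe_map,
        min_fraction=config.min_fraction, min_corr=config.min_corr, alpha=config.alpha,
    )
    _write(consolidation, outdir / "consolidation.tsv")
    _write(unannotated, outdir / "unannotated_probes.tsv")
    de_genes = consolidation.index[consolidation["passes"]].tolist()
    (outdir / "de_genes.txt").write_text("\n".join(de_genes) + "\n")

    # anchor correlations of DE genes (within-subject) to the cortisol peak
    reps = consolidation.loc[de_genes, "representative"]
    gene_expr = expr_m.subset_features(reps.tolist())
    gene_expr.values.columns = list(reps.index)
    expr_anchor_animals = gene_expr.animals
    expr_within = ml.decompose(gene_expr).within_matrix
    anchor_expr = anchor.loc[[a for a in expr_anchor_animals]]
    expr_anchor = de.correlate_to_anchor(
        expr_within, anchor_expr, adjust_method="BH", alpha=config.alpha
    )
    _write(expr_anchor, outdir / "expr_anchor.tsv", index=False)

    _log(outdir, "de",
         {"n_responding_bio": len(responding), "n_de_genes": len(de_genes)},
         [outdir / "bio_clean.tsv", outdir / "expr_clean.tsv"])
    return {"anova": anova, "consolidation": consolidation, "de_genes": de_genes}


def _gene_level_within(config, outdir):
    """Within-animal matrix of DE genes (representative probe per gene)."""
    expr, sample_map, _ = _load_expr_clean(outdir)
    consolidation = pd.read_csv(_require(outdir, "consolidation.tsv", "run_de"),
                                sep="\t", index_col=0)
    de_genes = consolidation.index[consolidation["passes"]].tolist()
    if not de_genes:
        raise PipelineError("no DE genes passed consolidation; nothing to cluster")
    reps = consolidation.loc[de_genes, "representative"]
    expr_m = sim.expression_to_matrix(expr, sample_map)
    gene_m = expr_m.subset_features(reps.tolist())
    gene_m.values.columns = list(reps.index)
    within = ml.decompose(gene_m).within_matrix
    return gene_m, within, consolidation


def run_cluster(config: PipelineConfig, outdir: str | Path) -> dict:
    """Ward clustering of DE genes into kinetic clusters plus per-cluster tests."""
    outdir = Path(outdir)
    _, within, _ = _gene_level_within(config, outdir)
    distance = cl.gene_distance(within, mode=config.distance_mode)
    result = cl.hac_ward(distance, k=config.k_clusters, within=within,
                         distance_mode=config.distance_mode)
    _write(result.assignments.to_frame(), outdir / "gene_clusters.tsv")
    _write(pd.DataFrame(result.linkage,
                        columns=["left", "right", "height", "size"]),
           outdir / "linkage.tsv", index=False)
    _write(result.profiles, outdir / "cluster_profiles.tsv")
    (outdir / "dendrogram.nwk").write_text(result.to_newick() + "\n")
    tests = cl.cluster_time_tests(result, within, alpha=config.alpha)
    _write(tests, outdir / "cluster_tests.tsv", index=False)
    _log(outdir, "cluster",
         {"k": config.k_clusters, "sizes": result.cluster_sizes.to_dict()},
         [outdir / "consolidation.tsv"])
    return {"clustering": result, "tests": tests}


def run_lmm(config: PipelineConfig, outdir: str | Path) -> dict:
    """Mixed-model adjustment of DE genes for the L/G ratio."""
    outdir = Path(outdir)
    gene_m, _, consolidation = _gene_level_within(config, outdir)
    bio = _load_bio_clean(outdir)

    # L/G ratio of the transcriptome animals at the matching animal x time
    bio_long = bio.to_long()
    lut = bio_long.pivot_table(index=["animal", "time"], columns="variable",
                               values="value", aggfunc="first")
    lg_all = mm.lg_ratio_from_counts(lut["lymphocytes"], lut["granulocytes"],
                                     log=config.lg_log)
    keys = list(zip(gene_m.animal.values, gene_m.time.values))
    lg = pd.Series([lg_all.loc[k] for k in keys], index=gene_m.values.index,
                   name="lg_ratio")

    sample_map = pd.DataFrame({"animal": gene_m.animal, "time": gene_m.time})
    fits = mm.fit_genes(gene_m.values.T, lg, sample_map)
    _write(fits, outdir / "lmm_fits.tsv")
    time_tests = mm.test_time_effect(fits, alpha=config.alpha)
    _write(time_tests, outdir / "lmm_time_tests.tsv", index=False)
    lg_tests = mm.test_lg_effect(fits, alpha=config.alpha)
    _write(lg_tests, outdir / "lmm_lg_tests.tsv")
    _log(outdir, "lmm",
         {"n_genes": len(fits), "n_lg_significant": int(lg_tests["significant"].sum())},
         [outdir / "consolidation.tsv", outdir / "bio_clean.tsv"])
    return {"fits": fits, "time_tests": time_tests, "lg_tests": lg_tests}


def run_spls(config: PipelineConfig, outdir: str | Path) -> dict:
    """Multilevel sparse PLS of DE-gene expression against biological variables."""
    outdir = Path(outdir)
    gene_m, _, _ = _gene_level_within(config, outdir)
    bio = _load_bio_clean(outdir)

    # biological arm restricted to the transcriptome animals, row-aligned
    expr_animals = set(gene_m.animals)
    mask = bio.animal.isin(expr_animals).values
    bio_sub = LongitudinalMatrix(
        values=bio.values.loc[mask].copy(),
        animal=bio.animal[mask],
        time=bio.time[mask],
        batch=bio.batch[mask],
        sex=None if bio.sex is None else bio.sex[mask],
    )
    key = {(a, t): i for i, (a, t) in
           enumerate(zip(bio_sub.animal.values, bio_sub.time.values))}
    order = [key[(a, t)] for a, t in zip(gene_m.animal.values, gene_m.time.values)]
    bio_aligned = LongitudinalMatrix(
        values=bio_sub.values.iloc[order].set_axis(gene_m.values.index),
        animal=pd.Series(bio_sub.animal.values[order]),
        time=pd.Series(bio_sub.time.values[order]),
        batch=pd.Series(bio_sub.batch.values[order]),
    )

    result = ml.multilevel_pls(
        gene_m, bio_aligned,
        n_components=config.n_components,
        keep_x=min(config.keep_x, gene_m.n_features),
        keep_y=bio_aligned.n_features,
        mode=config.pls_mode,
        scale_x=config.scale_expr,
        scale_y=config.scale_bio,
    )
    result.write_dir(outdir / "spls")
    _log(outdir, "spls", {"keep_x": config.keep_x, "mode": config.pls_mode},
         [outdir / "consolidation.tsv", outdir / "bio_clean.tsv"])
    return {"spls": result}


def run_enrich(config: PipelineConfig, outdir: str | Path) -> dict:
    """Fisher over-representation of each kinetic cluster and of the
    L/G-driven gene set against the expressed-gene reference."""
    outdir = Path(outdir)
    annotation = enr.AnnotationTable.read_tsv(
        _require(outdir, "annotation.tsv", "run_simulate"))
    clusters = pd.read_csv(_require(outdir, "gene_clusters.tsv", "run_cluster"),
                           sep="\t", index_col=0)["cluster"]
    probe_map = pd.read_csv(_require(outdir, "probe_map.tsv", "run_simulate"),
                            sep="\t", index_col=0)
    reference = sorted(set(probe_map.loc[~probe_map["is_control"].astype(bool), "gene"]))

    tables = {}
    for c in sorted(clusters.unique()):
        query = clusters.index[clusters == c].tolist()
        table, _warn = enr.fisher_enrichment(
            query, reference, annotation,
            min_genes=config.enrich_min_genes, fdr=config.enrich_fdr,
        )
        _write(table, outdir / f"enrichment_cluster{c}.tsv", index=False)
        tables[c] = table
    lg_path = outdir / "lmm_lg_tests.tsv"
    if lg_path.exists():
        lg = pd.read_csv(lg_path, sep="\t", index_col=0)
        query = lg.index[lg["significant"].astype(bool)].tolist()
        if query:
            table, _warn = enr.fisher_enrichment(
                query, reference, annotation,
                min_genes=config.enrich_min_genes, fdr=config.enrich_fdr,
            )
            _write(table, outdir / "enrichment_lg.tsv", index=False)
            tables["lg"] = table
    _log(outdir, "enrich", {"n_terms": len(annotation.terms)},
         [outdir / "gene_clusters.tsv"])
    return tables


STAGES = [
    ("simulate", run_simulate),
    ("preprocess", run_preprocess),
    ("decompose", run_decompose),
    ("de", run_de),
    ("cluster", run_cluster),
    ("lmm", run_lmm),
    ("spls", run_spls),
    ("enrich", run_enrich),
]


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in order on synthetic data."""
    results = {}
    for name, stage in STAGES:
        results[name] = stage(config, outdir)
    return results
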