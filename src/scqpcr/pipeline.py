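"""End-to-end pipeline: preprocessing -> stage dynamics -> lineage.

``run_pipeline`` composes the analysis steps in order and emits a
machine-readable report of what was removed, classified and called at
each step, together with every threshold applied.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    ExpressionMatrix,
    FateCalls,
    MarkerSets,
    PCAResult,
    PipelineError,
    RawPlate,
)
from .lineage import DEFAULT_ANCHORS, MarkerSetFinder, FateCaller
from .preprocessing import CtNormalizer
from .stage_dynamics import BranchClusterer, ExpressionPCA, ThresholdGeneClassifier

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunable constants of the analysis, with conventional defaults.

    Thresholds follow the standard BioMark workflow: Ct baseline 30,
    detection threshold -10 on the normalized log2 scale, three
    endogenous reference genes identified by the gene metadata.
    """

    baseline: float = 30.0
    expression_threshold: float | None = -10.0
    min_ref_level: float = 3.0
    nondetect_floor: float = -14.0
    pool_late_stages: bool = False
    # branch clustering
    n_branches: int = 3
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "ward"
    trend_cutoff: float = 0.3
    flat_range: float = 2.0
    # marker discovery
    min_within: float = 0.2
    max_between: float = 0.0
    alpha: float = 0.05
    correlation_k: int | None = None
    anchor_genes: tuple[str, ...] = DEFAULT_ANCHORS
    # fate calling
    fate_mode: str = "score"
    fate_thresholds: tuple[float, float] | str = "terciles"
    # PCA
    n_components: int = 2
    seed: int = 0


@dataclass
class PipelineResult:
    expression: ExpressionMatrix
    threshold_classes: pd.Series
    per_stage_mean: pd.DataFrame
    branches: pd.Series
    global_pca: PCAResult
    blastomere_pca: PCAResult
    marker_sets: MarkerSets
    fate_calls: FateCalls
    report: dict = field(default_factory=dict)


def _stage(name: str):
    """Decorator-free error context helper."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise PipelineError(f"[{name}] {exc}") from exc
    return _Ctx()


def run_pipeline(plate: RawPlate, sample_meta: pd.DataFrame,
                 gene_meta: pd.DataFrame,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run preprocessing, stage dynamics and lineage analysis in order."""
    cfg = config or PipelineConfig()

    with _stage("preprocessing"):
        norm = CtNormalizer(baseline=cfg.baseline,
                            min_ref_level=cfg.min_ref_level,
                            floor=cfg.nondetect_floor)
        expr = norm.fit_transform(plate, gene_meta=gene_meta)
        meta = sample_meta.loc[expr.samples]

    with _stage("stage_dynamics"):
        clf = ThresholdGeneClassifier(threshold=cfg.expression_threshold,
                                      pool_late_stages=cfg.pool_late_stages)
        clf.fit(expr, sample_meta=meta)
        brancher = BranchClusterer(n_branches=cfg.n_branches,
                                   metric=cfg.cluster_metric,
                                   linkage_method=cfg.cluster_linkage,
                                   trend_cutoff=cfg.trend_cutoff,
                                   flat_range=cfg.flat_range)
        brancher.fit(expr, sample_meta=meta)
        global_pca = ExpressionPCA(n_components=cfg.n_components).fit(expr).result_()

    with _stage("lineage"):
        finder = MarkerSetFinder(min_within=cfg.min_within,
                                 max_between=cfg.max_between,
                                 alpha=cfg.alpha, k=cfg.correlation_k,
                                 anchors=tuple(cfg.anchor_genes))
        finder.fit(expr, sample_meta=meta)
        sets = finder.marker_sets_
        caller = FateCaller(mode=cfg.fate_mode, thresholds=cfg.fate_thresholds)
        caller.fit(expr, sets=sets, sample_meta=meta)
        fates = caller.result_()
        from .lineage import select_blastomeres
        blast_pca = ExpressionPCA(n_components=cfg.n_components).fit(
            select_blastomeres(expr, meta)).result_()

    class_counts = clf.labels_.value_counts().to_dict()
    branch_counts = brancher.labels_.value_counts().to_dict()
    fate_counts = fates.fate.value_counts().to_dict()
    report = {
        "n_genes_in": int(len(plate.genes)),
        "n_samples_in": int(len(plate.samples)),
        "n_genes_removed": int(len(norm.removed_genes_)),
        "n_samples_removed": int(len(norm.removed_samples_)),
        "removed_samples": dict(sorted(norm.removed_samples_.items())),
        "n_genes_analysed": int(len(expr.genes)),
        "n_samples_analysed": int(len(expr.samples)),
        "reference_ids": list(expr.reference_ids),
        "thresholds": {
            "baseline": cfg.baseline,
            "expression_threshold": clf.threshold_,
            "min_ref_level": cfg.min_ref_level,
            "nondetect_floor": cfg.nondetect_floor,
            "fate_thresholds": list(fates.thresholds),
        },
        "threshold_class_counts": {k: int(v) for k, v in sorted(class_counts.items())},
        "branch_counts": {k: int(v) for k, v in sorted(branch_counts.items())},
        "branch_trends": {k: round(float(v), 6)
                          for k, v in sorted(brancher.branch_trend_.items())},
        "marker_set_sizes": {"icm": len(sets.icm), "te": len(sets.te)},
        "marker_sets": {"icm": list(sets.icm), "te": list(sets.te)},
        "marker_set_rho": {
            "within_icm": round(sets.within_icm_mean_rho, 6),
            "within_te": round(sets.within_te_mean_rho, 6),
            "between": round(sets.between_mean_rho, 6),
        },
        "fate_counts": {k: int(v) for k, v in sorted(fate_counts.items())},
        "pca_variance_explained": [round(float(v), 6)
                                   for v in global_pca.variance_explained],
    }
    for key, value in report["thresholds"].items():
        logger.info("threshold %s = %s", key, value)

    return PipelineResult(
        expression=expr,
        threshold_classes=clf.labels_,
        per_stage_mean=clf.per_stage_mean_,
        branches=brancher.labels_,
        global_pca=global_pca,
        blastomere_pca=blast_pca,
        marker_sets=sets,
        fate_calls=fates,
        report=report,
    )
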