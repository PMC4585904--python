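"""Stage-resolved expression dynamics.

Threshold-based maternal/zygotic gene classification, hierarchical
clustering of mean-centred expression profiles into maternal /
ubiquitous / zygotic branches, and PCA of the cell population.

The detection threshold (default -10 on the normalized log2 scale)
separates the censoring-floor peak of the pooled value distribution from
the expressed mode; gene classes are defined on per-stage mean signals:

* exclusively zygotic: silent in MII oocytes, detected at some later stage;
* exclusively maternal: detected in MII but silent in both 16- and
  32-cell blastomeres;
* not expressed: silent at every stage;
* expressed throughout: everything else.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde, spearmanr
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA as _SKPCA

from .data import (
    BLASTOMERE_STAGES,
    ESC,
    STAGE_ORDER,
    ExpressionMatrix,
    PCAResult,
    PipelineError,
    check_sample_meta,
)

__all__ = [
    "ThresholdGeneClassifier",
    "BranchClusterer",
    "ExpressionPCA",
    "detection_threshold",
    "classify_threshold",
    "center_genes",
    "cluster_branches",
    "pca",
    "top_loading_genes",
]


def detection_threshold(expr: ExpressionMatrix,
                        fixed: float | None = -10.0) -> float:
    """Expression threshold from the pooled normalized-value distribution.

    When ``fixed`` is given (the default, -10) it is returned unchanged.
    Otherwise the threshold is estimated as the antimode of the pooled
    value density between the censoring-floor peak and the next expressed
    mode to its right.
    """
    if expr.values.size == 0:
        raise PipelineError("empty expression matrix")
    if fixed is not None:
        return float(fixed)
    pooled = expr.values.to_numpy().ravel()
    kde = gaussian_kde(pooled)
    grid = np.linspace(pooled.min(), pooled.max(), 512)
    dens = kde(grid)
    maxima = list(argrelextrema(dens, np.greater)[0])
    # The censoring-floor peak sits at the lower grid edge; interior-only
    # extrema would miss it.
    if dens[0] > dens[1]:
        maxima.insert(0, 0)
    if dens[-1] > dens[-2]:
        maxima.append(len(dens) - 1)
    # Keep modes carrying non-trivial mass to ignore KDE ripple.
    maxima = [i for i in sorted(maxima) if dens[i] > 0.05 * dens.max()]
    if len(maxima) < 2:
        raise PipelineError(
            "pooled value distribution looks unimodal; no antimode to "
            "estimate — pass a fixed threshold (the conventional value is -10)"
        )
    left = maxima[0]            # floor peak (lowest-value major mode)
    right = maxima[1]           # nearest expressed mode to its right
    antimode = grid[left + int(np.argmin(dens[left:right + 1]))]
    return float(antimode)


def center_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean across samples (row-centring).

    The censoring mask is carried through unchanged.  Idempotent.
    """
    values = expr.values.sub(expr.values.mean(axis=1), axis=0)
    return ExpressionMatrix(values=values, censored=expr.censored.copy(),
                            reference_ids=list(expr.reference_ids),
                            floor=expr.floor)


def _stage_means(values: pd.DataFrame, sample_meta: pd.DataFrame,
                 stages: list[str]) -> pd.DataFrame:
    """Per-gene mean expression for each requested stage (genes x stages)."""
    meta = check_sample_meta(sample_meta).loc[values.columns]
    out = {}
    for stage in stages:
        cols = meta.index[meta["stage"] == stage]
        if len(cols):
            out[stage] = values[cols].mean(axis=1)
    return pd.DataFrame(out)


class ThresholdGeneClassifier(BaseEstimator):
    """Classify genes as maternal/zygotic/silent by stage-mean thresholds.

    Parameters
    ----------
    threshold:
        Detection threshold on the normalized log2 scale; ``None``
        estimates it from the pooled value distribution.
    pool_late_stages:
        If True, the "silent late" test for exclusively-maternal genes
        uses the pooled 16+32-cell mean; otherwise each of the two stages
        must be below threshold separately (the default reading).
    include_esc:
        ESC control samples are excluded from stage means by default;
        the maternal/zygotic definitions refer to embryonic stages only.

    Fitted attributes
    -----------------
    threshold_ : float, the threshold applied
    labels_ : pandas Series gene -> threshold class
    per_stage_mean_ : DataFrame genes x stages of mean normalized signal
    """

    def __init__(self, threshold: float | None = -10.0,
                 pool_late_stages: bool = False, include_esc: bool = False):
        self.threshold = threshold
        self.pool_late_stages = pool_late_stages
        self.include_esc = include_esc

    def fit(self, X: ExpressionMatrix, y=None, *, sample_meta: pd.DataFrame):
        meta = check_sample_meta(sample_meta).loc[X.samples]
        stages_present = set(meta["stage"])
        if "MII" not in stages_present:
            raise PipelineError("threshold classification requires MII samples")
        late = [s for s in BLASTOMERE_STAGES if s in stages_present]
        if not late:
            raise PipelineError(
                "threshold classification requires 16cell and/or 32cell samples"
            )
        stages = [s for s in STAGE_ORDER if s in stages_present]
        if self.include_esc and ESC in stages_present:
            stages.append(ESC)
        values = X.values
        if not self.include_esc:
            keep = meta.index[meta["stage"] != ESC]
            values = values[keep]
        self.threshold_ = detection_threshold(X, fixed=self.threshold)
        means = _stage_means(values, meta, stages)
        t = self.threshold_

        emb = means[[s for s in means.columns if s != ESC]]
        mii = means["MII"]
        if self.pool_late_stages:
            cols = [c for c in X.samples
                    if meta.loc[c, "stage"] in BLASTOMERE_STAGES]
            late_silent = values[cols].mean(axis=1) < t
        else:
            late_silent = pd.Series(True, index=means.index)
            for s in late:
                late_silent &= means[s] < t

        labels = pd.Series("expressed_throughout", index=means.index)
        labels[(mii < t) & (emb.ge(t).any(axis=1))] = "exclusively_zygotic"
        labels[(mii >= t) & late_silent] = "exclusively_maternal"
        labels[emb.lt(t).all(axis=1)] = "not_expressed"
        self.labels_ = labels
        self.per_stage_mean_ = means
        return self

    def predict(self, X: ExpressionMatrix, *, sample_meta: pd.DataFrame):
        return self.fit(X, sample_meta=sample_meta).labels_


class BranchClusterer(ClusterMixin, BaseEstimator):
    """Hierarchical clustering of centred gene profiles into named branches.

    Gene rows are clustered (default: Euclidean distance, Ward linkage)
    and the tree is cut into ``n_branches`` groups.  Each branch is named
    from its mean per-stage profile: a branch whose profile spans less
    than ``flat_range`` log2 units (or whose Spearman trend against
    developmental stage order is weaker than ``trend_cutoff``) is
    "ubiquitous"; otherwise a decreasing trend is "maternal" and an
    increasing one "zygotic".  The dynamic-range test matters because
    rank correlation is scale-free: a flat branch measured with noise
    draws an arbitrary rho.

    Fitted attributes
    -----------------
    labels_ : Series gene -> branch name
    branch_trend_ : dict branch name -> Spearman trend statistic
    linkage_ : the scipy linkage matrix
    """

    def __init__(self, n_branches: int = 3, metric: str = "euclidean",
                 linkage_method: str = "ward", trend_cutoff: float = 0.3,
                 flat_range: float = 2.0):
        self.n_branches = n_branches
        self.metric = metric
        self.linkage_method = linkage_method
        self.trend_cutoff = trend_cutoff
        self.flat_range = flat_range

    def fit(self, X: ExpressionMatrix, y=None, *, sample_meta: pd.DataFrame,
            assume_centered: bool = False):
        expr = X if assume_centered else center_genes(X)
        values = expr.values
        if len(values) < self.n_branches:
            raise PipelineError(
                f"need at least {self.n_branches} genes, got {len(values)}"
            )
        if self.n_branches == 1:
            raw = np.ones(len(values), dtype=int)
            self.linkage_ = None
        else:
            self.linkage_ = linkage(values.to_numpy(), method=self.linkage_method,
                                    metric=self.metric)
            raw = fcluster(self.linkage_, t=self.n_branches, criterion="maxclust")

        meta = check_sample_meta(sample_meta).loc[values.columns]
        stages = [s for s in STAGE_ORDER if (meta["stage"] == s).any()]
        name_of, trends = {}, {}
        for c in np.unique(raw):
            profile = values[raw == c].mean(axis=0)
            stage_prof = _stage_means(profile.to_frame().T, meta, stages).iloc[0]
            with warnings.catch_warnings():
                # a perfectly flat profile has no defined trend; treat as 0
                warnings.simplefilter("ignore")
                rho = spearmanr(np.arange(len(stage_prof)),
                                stage_prof.to_numpy()).statistic
            rho = 0.0 if np.isnan(rho) else float(rho)
            trends[c] = rho
            span = float(stage_prof.max() - stage_prof.min())
            if span < self.flat_range or abs(rho) < self.trend_cutoff:
                name_of[c] = "ubiquitous"
            else:
                name_of[c] = "maternal" if rho < 0 else "zygotic"
        names = list(name_of.values())
        if len(set(names)) < len(names):
            raise PipelineError(
                "two branches received the same name; trend statistics: "
                + ", ".join(f"cluster {c}: rho={trends[c]:+.3f}" for c in trends)
            )
        self.labels_ = pd.Series([name_of[c] for c in raw], index=values.index,
                                 name="branch")
        self.branch_trend_ = {name_of[c]: trends[c] for c in trends}
        return self


class ExpressionPCA(BaseEstimator):
    """PCA of samples on gene-centred expression.

    Genes are mean-centred internally (no unit-variance scaling); samples
    are the observations.  Per-component sign is fixed by forcing the
    largest-magnitude loading positive, making results deterministic.

    Fitted attributes
    -----------------
    scores_ : DataFrame samples x components
    loadings_ : DataFrame genes x components
    variance_explained_ : ndarray of variance fractions
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X: ExpressionMatrix, y=None):
        values = X.values
        n_genes, n_samples = values.shape
        if n_samples < 2:
            raise PipelineError("PCA requires at least two samples")
        centered = values.sub(values.mean(axis=1), axis=0)
        rank = min(n_genes, n_samples - 1)
        k = rank if self.n_components is None else self.n_components
        if k > rank:
            raise PipelineError(
                f"n_components={k} exceeds the matrix rank bound {rank}"
            )
        model = _SKPCA(n_components=k, svd_solver="full")
        scores = model.fit_transform(centered.T.to_numpy())  # samples x k
        loadings = model.components_.T                       # genes x k
        for j in range(k):
            i = np.argmax(np.abs(loadings[:, j]))
            if loadings[i, j] < 0:
                loadings[:, j] *= -1
                scores[:, j] *= -1
        comp = [f"PC{j + 1}" for j in range(k)]
        self.scores_ = pd.DataFrame(scores, index=values.columns, columns=comp)
        self.loadings_ = pd.DataFrame(loadings, index=values.index, columns=comp)
        self.variance_explained_ = model.explained_variance_ratio_.copy()
        return self

    def result_(self) -> PCAResult:
        return PCAResult(scores=self.scores_, loadings=self.loadings_,
                         variance_explained=self.variance_explained_)


def top_loading_genes(pca_result: PCAResult, n: int) -> list[str]:
    """Genes ranked by distance from the origin in the PC1/PC2 loading plane.

    Ties are broken by gene id (lexicographic).  Asking for more genes
    than exist returns the full ranking with a warning.
    """
    if pca_result.loadings.shape[1] < 2:
        raise PipelineError("loading ranking requires at least two components")
    load = pca_result.loadings.iloc[:, :2]
    norm = np.hypot(load.iloc[:, 0], load.iloc[:, 1])
    ranked = sorted(load.index, key=lambda g: (-norm[g], g))
    if n > len(ranked):
        warnings.warn(
            f"requested {n} genes but only {len(ranked)} available; "
            "returning the full ranking"
        )
        return ranked
    return ranked[:n]


# -- functional wrappers ---------------------------------------------------

def classify_threshold(expr: ExpressionMatrix, sample_meta: pd.DataFrame,
                       threshold: float | None = -10.0,
                       pool_late_stages: bool = False):
    """Per-gene threshold classes and per-stage means.

    Returns ``(labels, per_stage_mean)``.
    """
    clf = ThresholdGeneClassifier(threshold=threshold,
                                  pool_late_stages=pool_late_stages)
    clf.fit(expr, sample_meta=sample_meta)
    return clf.labels_, clf.per_stage_mean_


def cluster_branches(expr: ExpressionMatrix, sample_meta: pd.DataFrame,
                     k: int = 3, metric: str = "euclidean",
                     linkage_method: str = "ward",
                     assume_centered: bool = False) -> pd.Series:
    """Branch labels (maternal/ubiquitous/zygotic) per gene."""
    model = BranchClusterer(n_branches=k, metric=metric,
                            linkage_method=linkage_method)
    model.fit(expr, sample_meta=sample_meta, assume_centered=assume_centered)
    return model.labels_


def pca(expr: ExpressionMatrix, n_components: int | None = None) -> PCAResult:
    """PCA scores, loadings and variance fractions of the cell population."""
    return ExpressionPCA(n_components=n_components).fit(expr).result_()
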