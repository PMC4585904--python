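"""ICM/trophectoderm lineage analysis of 16/32-cell blastomeres.

Marker discovery proceeds from the pairwise Spearman correlation matrix
of gene expression across blastomeres: hierarchical clustering of
``1 - rho`` dissimilarities exposes two mutually anti-correlated gene
clusters (the inner-cell-mass and trophectoderm programmes).  Each
blastomere then receives a lineage score

    L = mean(ICM-marker expression) - mean(TE-marker expression)

and a fate call (ICM / TE / n.d.) from low/mid/high score thresholds,
by default the terciles of the observed distribution.
"""
from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata, spearmanr
from sklearn.base import BaseEstimator
from sklearn.metrics import silhouette_score

from .data import (
    BLASTOMERE_STAGES,
    CorrelationMatrix,
    ExpressionMatrix,
    FateCalls,
    MarkerSets,
    PipelineError,
    check_sample_meta,
)

__all__ = [
    "MarkerSetFinder",
    "FateCaller",
    "spearman_matrix",
    "exact_spearman_pvalue",
    "cluster_correlation",
    "extract_marker_sets",
    "lineage_score",
    "assign_fate",
    "evaluate_panel",
    "select_blastomeres",
]

DEFAULT_ANCHORS = ("Pou5f1", "Sox2", "Klf2", "Klf4")
#: Reduced marker panel shown to suffice for fate assignment.
FOUR_GENE_PANEL = ("Ezh1", "Prdm14", "Scmh1", "Tet1")


def select_blastomeres(expr: ExpressionMatrix,
                       sample_meta: pd.DataFrame) -> ExpressionMatrix:
    """Restrict an expression matrix to 16/32-cell blastomeres."""
    meta = check_sample_meta(sample_meta).loc[expr.samples]
    cols = meta.index[meta["stage"].isin(BLASTOMERE_STAGES)]
    return expr.subset_samples(cols)


def exact_spearman_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-tailed exact permutation p-value for the Spearman correlation.

    Enumerates all n! orderings of ``y`` and counts those whose absolute
    rank correlation is at least the observed one.  Intended for n <= 7.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rx = rankdata(x)
    ry = rankdata(y)
    rx_c = rx - rx.mean()
    sx = np.sqrt((rx_c ** 2).sum())

    def rho_of(r):
        r_c = r - r.mean()
        sy = np.sqrt((r_c ** 2).sum())
        if sx == 0 or sy == 0:
            return np.nan
        return float(rx_c @ r_c / (sx * sy))

    obs = rho_of(ry)
    if np.isnan(obs):
        return 1.0
    hits = total = 0
    for perm in permutations(ry):
        total += 1
        if abs(rho_of(np.asarray(perm))) >= abs(obs) - 1e-12:
            hits += 1
    return hits / total


def spearman_matrix(expr: ExpressionMatrix | pd.DataFrame,
                    sample_meta: pd.DataFrame | None = None,
                    exact_cutoff: int = 7,
                    min_detected: float = 0.5) -> CorrelationMatrix:
    """Pairwise Spearman rho and two-tailed p-values over blastomeres.

    ``expr`` is restricted to 16/32-cell samples when metadata is given;
    otherwise all columns are used (they must already be blastomeres).
    P-values use the t approximation, or full permutation enumeration
    when the number of cells is at most ``exact_cutoff``.  Genes constant
    across cells get rho 0, p 1, and are listed in ``constant_genes``;
    likewise genes detected (non-censored) in less than ``min_detected``
    of the cells, whose ranks are dominated by limit-of-detection ties
    and reflect shared measurement structure rather than co-expression
    (listed in ``low_detection_genes``).
    """
    if isinstance(expr, ExpressionMatrix):
        if sample_meta is not None:
            expr = select_blastomeres(expr, sample_meta)
        values = expr.values
        detected = 1.0 - expr.censored.to_numpy().mean(axis=1)
    else:
        values = expr
        detected = np.ones(len(values))
    n = values.shape[1]
    if n < 4:
        raise PipelineError(f"need at least 4 blastomeres, got {n}")

    X = values.to_numpy(float)
    low_det = detected < min_detected
    const = (np.ptp(X, axis=1) == 0) | low_det
    constant_genes = list(values.index[np.ptp(X, axis=1) == 0])
    low_detection_genes = list(values.index[low_det])

    if n <= exact_cutoff:
        g = len(values)
        rho = np.eye(g)
        pval = np.full((g, g), np.nan)
        np.fill_diagonal(pval, 1.0)
        ranks = np.apply_along_axis(rankdata, 1, X)
        for i in range(g):
            for j in range(i + 1, g):
                if const[i] or const[j]:
                    r = 0.0
                    p = 1.0
                else:
                    ri = ranks[i] - ranks[i].mean()
                    rj = ranks[j] - ranks[j].mean()
                    r = float(ri @ rj / np.sqrt((ri @ ri) * (rj @ rj)))
                    p = exact_spearman_pvalue(X[i], X[j])
                rho[i, j] = rho[j, i] = r
                pval[i, j] = pval[j, i] = p
    else:
        g = len(values)
        rho = np.zeros((g, g))
        pval = np.ones((g, g))
        idx = np.flatnonzero(~const)  # scipy degenerates on constant rows
        if len(idx) >= 2:
            with np.errstate(invalid="ignore", divide="ignore"):
                res = spearmanr(X[idx], axis=1)
            r = np.asarray(res.statistic, float)
            p = np.asarray(res.pvalue, float)
            if r.ndim == 0:  # scipy collapses the 2-variable case to a scalar
                r = np.array([[1.0, float(r)], [float(r), 1.0]])
                p = np.array([[1.0, float(p)], [float(p), 1.0]])
            rho[np.ix_(idx, idx)] = np.nan_to_num(r, nan=0.0)
            pval[np.ix_(idx, idx)] = np.where(np.isnan(p), 1.0, p)
        np.fill_diagonal(rho, 1.0)
        np.fill_diagonal(pval, 1.0)
    # p-values live in (0, 1]; clamp the t-approximation's occasional 0.
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)

    idx = values.index
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        pvalue=pd.DataFrame(pval, index=idx, columns=idx),
        n=n,
        constant_genes=constant_genes,
        low_detection_genes=low_detection_genes,
    )


def _correlation_distance(corr: CorrelationMatrix) -> np.ndarray:
    d = 1.0 - corr.rho.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    return (d + d.T) / 2


def _silhouette_ranked_cuts(Z, d: np.ndarray,
                            k_range: tuple[int, int]) -> list[tuple[int, np.ndarray]]:
    """Tree cuts for each k, ordered by decreasing mean silhouette."""
    g = d.shape[0]
    scored = []
    for kk in range(max(2, k_range[0]), min(k_range[1], g - 1) + 1):
        cand = fcluster(Z, t=kk, criterion="maxclust")
        if len(np.unique(cand)) < 2:
            continue
        s = silhouette_score(d, cand, metric="precomputed")
        scored.append((s, kk, cand))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [(kk, cand) for _, kk, cand in scored]


def cluster_correlation(corr: CorrelationMatrix, k: int | None = None,
                        k_range: tuple[int, int] = (2, 10),
                        linkage_method: str = "ward") -> pd.Series:
    """Cluster genes on the ``1 - rho`` dissimilarity.

    ``k=None`` selects the cluster count maximizing the mean silhouette
    over ``k_range`` (capped at the number of genes).  Ward linkage is
    the default: under ``1 - rho`` anti-correlated gene sets are
    maximally distant, and variance-minimizing merges keep each coherent
    set intact instead of absorbing it into the uncorrelated background.
    """
    genes = corr.rho.index
    g = len(genes)
    if g == 1:
        return pd.Series([1], index=genes, name="cluster")
    d = _correlation_distance(corr)
    Z = linkage(squareform(d, checks=False), method=linkage_method)
    if k is not None:
        labels = fcluster(Z, t=min(k, g), criterion="maxclust")
    else:
        cuts = _silhouette_ranked_cuts(Z, d, k_range)
        labels = cuts[0][1] if cuts else fcluster(Z, t=2, criterion="maxclust")
    return pd.Series(labels, index=genes, name="cluster")


def _offdiag_mean(rho: pd.DataFrame, a: list[str], b: list[str] | None = None) -> float:
    if b is None:
        if len(a) < 2:
            return 1.0 if len(a) == 1 else np.nan
        block = rho.loc[a, a].to_numpy()
        iu = np.triu_indices(len(a), k=1)
        return float(block[iu].mean())
    return float(rho.loc[a, b].to_numpy().mean())


class MarkerSetFinder(BaseEstimator):
    """Discover anti-correlated ICM/TE marker sets from blastomeres.

    The blastomere Spearman matrix is clustered; among cluster pairs with
    within-cluster mean rho at least ``min_within`` on both sides, the
    pair with the most negative between-cluster mean rho (at most
    ``max_between``) is taken.  Genes whose median p-value against their
    own set exceeds ``alpha`` are trimmed.  The set containing the anchor
    genes (pluripotency factors by default) is labelled ICM.

    Fitted attributes
    -----------------
    correlation_ : CorrelationMatrix over blastomeres
    clusters_ : Series gene -> cluster id
    marker_sets_ : MarkerSets
    """

    def __init__(self, min_within: float = 0.2, max_between: float = 0.0,
                 alpha: float = 0.05, k: int | None = None,
                 anchors: tuple[str, ...] = DEFAULT_ANCHORS,
                 exact_cutoff: int = 7):
        self.min_within = min_within
        self.max_between = max_between
        self.alpha = alpha
        self.k = k
        self.anchors = anchors
        self.exact_cutoff = exact_cutoff

    def fit(self, X: ExpressionMatrix, y=None,
            *, sample_meta: pd.DataFrame | None = None):
        corr = spearman_matrix(X, sample_meta, exact_cutoff=self.exact_cutoff)
        self.correlation_ = corr

        def extract(clusters):
            return extract_marker_sets(
                clusters, corr, min_within=self.min_within,
                max_between=self.max_between, alpha=self.alpha,
                anchors=self.anchors)

        if self.k is not None:
            self.clusters_ = cluster_correlation(corr, k=self.k)
            self.marker_sets_ = extract(self.clusters_)
            return self
        # Automatic cluster count: examine every tree cut in the k range
        # and keep the one whose extracted pair is most strongly
        # anti-correlated.  A coarse cut can bury one marker set inside
        # the weakly-coherent background (which may still squeak past the
        # within-cluster bound), diluting the between-set signal; the cut
        # that isolates both programmes maximizes the anti-correlation.
        d = _correlation_distance(corr)
        Z = linkage(squareform(d, checks=False), method="ward")
        cuts = _silhouette_ranked_cuts(Z, d, (2, 10))
        best: tuple[float, float, MarkerSets, pd.Series] | None = None
        last_err: Exception | None = None
        for _, cand in cuts:
            clusters = pd.Series(cand, index=corr.rho.index, name="cluster")
            try:
                sets = extract(clusters)
            except PipelineError as exc:
                if last_err is None:
                    last_err = exc
                continue
            key = (sets.between_mean_rho,
                   -min(sets.within_icm_mean_rho, sets.within_te_mean_rho))
            if best is None or key < best[:2]:
                best = (*key, sets, clusters)
        if best is None:
            raise last_err if last_err is not None else PipelineError(
                "correlation matrix yields no clusters to extract markers from")
        self.marker_sets_ = best[2]
        self.clusters_ = best[3]
        return self


def extract_marker_sets(clusters: pd.Series, corr: CorrelationMatrix,
                        min_within: float = 0.2, max_between: float = 0.0,
                        alpha: float = 0.05,
                        anchors: tuple[str, ...] = DEFAULT_ANCHORS) -> MarkerSets:
    """Pick the anti-correlated cluster pair and trim weak members."""
    ids = sorted(clusters.unique())
    if len(ids) < 2:
        raise PipelineError("marker extraction requires at least 2 clusters")
    members = {c: list(clusters.index[clusters == c]) for c in ids}
    within = {c: _offdiag_mean(corr.rho, members[c]) for c in ids}

    best_pair, best_between = None, np.inf
    stats = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            between = _offdiag_mean(corr.rho, members[a], members[b])
            stats.append((a, b, within[a], within[b], between))
            if within[a] >= min_within and within[b] >= min_within \
                    and between <= max_between and between < best_between:
                best_pair, best_between = (a, b), between
    if best_pair is None:
        a, b, wa, wb, bt = min(stats, key=lambda s: s[4])
        raise PipelineError(
            "no cluster pair is mutually anti-correlated with coherent "
            f"within-cluster signal; best candidate ({a}, {b}): "
            f"within {wa:.3f}/{wb:.3f}, between {bt:.3f}"
        )

    def trim(genes: list[str]) -> list[str]:
        if len(genes) < 2:
            return list(genes)
        kept = []
        for g in genes:
            others = [h for h in genes if h != g]
            if float(corr.pvalue.loc[g, others].median()) <= alpha:
                kept.append(g)
        return kept or list(genes)

    set_a = trim(members[best_pair[0]])
    set_b = trim(members[best_pair[1]])

    anchors_in_a = len(set(anchors) & set(set_a))
    anchors_in_b = len(set(anchors) & set(set_b))
    anchored = anchors_in_a != anchors_in_b
    if anchors_in_b > anchors_in_a:
        set_a, set_b = set_b, set_a

    return MarkerSets(
        icm=sorted(set_a), te=sorted(set_b),
        within_icm_mean_rho=_offdiag_mean(corr.rho, set_a),
        within_te_mean_rho=_offdiag_mean(corr.rho, set_b),
        between_mean_rho=_offdiag_mean(corr.rho, set_a, set_b),
        anchored=anchored,
    )


def _set_mean(values: pd.DataFrame, genes: list[str], label: str) -> pd.Series:
    missing = [g for g in genes if g not in values.index]
    if missing:
        raise PipelineError(f"{label} gene(s) missing from matrix: {missing}")
    if not genes:
        raise PipelineError(f"{label} gene set is empty")
    return values.loc[genes].mean(axis=0)


def lineage_score(expr: ExpressionMatrix, sets: MarkerSets) -> pd.Series:
    """Per-cell lineage score: mean ICM-set minus mean TE-set expression."""
    icm = _set_mean(expr.values, sets.icm, "ICM")
    te = _set_mean(expr.values, sets.te, "TE")
    return (icm - te).rename("lineage_score")


def _tercile_thresholds(x: pd.Series, how: str = "range") -> tuple[float, float]:
    """Low/high boundaries cutting values into low, mid and high thirds.

    ``how="range"`` (default) uses equal-width thirds of the observed
    value range, trimmed to the 5th-95th percentiles so that a handful of
    censoring-floored outliers cannot stretch the bands: for a bimodal
    score distribution the mid band then falls into the gap between the
    two modes, and cells are only left undefined when their signal
    genuinely sits between the lineage levels.  ``how="quantile"`` uses
    the empirical 1/3 and 2/3 quantiles instead.
    """
    v = x.to_numpy(dtype=float)
    if how == "quantile":
        lo, hi = np.percentile(v, [100 / 3, 200 / 3])
    else:
        v0, v1 = np.percentile(v, [5, 95])
        span = v1 - v0
        lo, hi = v0 + span / 3, v1 - span / 3
    if not lo < hi:  # degenerate (e.g. constant values): nudge apart
        eps = 1e-9 + 1e-9 * abs(hi)
        lo, hi = lo - eps, hi + eps
    return float(lo), float(hi)


def _call_from_levels(level: pd.Series, thresholds,
                      high_label: str, low_label: str) -> tuple[pd.Series, tuple]:
    if thresholds is None or thresholds in ("terciles", "range"):
        thresholds = _tercile_thresholds(level, "range")
    elif thresholds == "quantile":
        thresholds = _tercile_thresholds(level, "quantile")
    low, high = thresholds
    if not low < high:
        raise PipelineError(f"thresholds must satisfy low < high, got {thresholds}")
    fate = pd.Series("n.d.", index=level.index, name="fate")
    fate[level >= high] = high_label
    fate[level <= low] = low_label
    return fate, (float(low), float(high))


class FateCaller(BaseEstimator):
    """Call blastomere fates from marker-set expression.

    ``mode="score"`` thresholds the lineage score L (ICM if L >= high,
    TE if L <= low, else n.d.).  ``mode="set_means"`` reproduces the
    per-set low/mid/high rule: a cell is ICM when its ICM-set mean is
    high and its TE-set mean is low, TE in the converse case, else n.d.
    Default thresholds are the terciles of the observed distributions.

    Fitted attributes
    -----------------
    score_ : Series cell -> lineage score
    fate_ : Series cell -> {ICM, TE, n.d.}
    thresholds_ : (low, high) applied to the score (score mode)
    """

    def __init__(self, mode: str = "score",
                 thresholds: tuple[float, float] | str = "terciles"):
        self.mode = mode
        self.thresholds = thresholds

    def fit(self, X: ExpressionMatrix, y=None, *, sets: MarkerSets,
            sample_meta: pd.DataFrame | None = None):
        expr = X if sample_meta is None else select_blastomeres(X, sample_meta)
        if expr.values.shape[1] == 0:
            raise PipelineError("no blastomeres to assign fates to")
        score = lineage_score(expr, sets)
        if self.mode == "score":
            fate, thr = _call_from_levels(score, self.thresholds, "ICM", "TE")
        elif self.mode == "set_means":
            icm_mean = _set_mean(expr.values, sets.icm, "ICM")
            te_mean = _set_mean(expr.values, sets.te, "TE")
            icm_call, _ = _call_from_levels(icm_mean, self.thresholds, "high", "low")
            te_call, _ = _call_from_levels(te_mean, self.thresholds, "high", "low")
            fate = pd.Series("n.d.", index=score.index, name="fate")
            fate[(icm_call == "high") & (te_call == "low")] = "ICM"
            fate[(icm_call == "low") & (te_call == "high")] = "TE"
            thr = _tercile_thresholds(score) if isinstance(self.thresholds, str) \
                else tuple(map(float, self.thresholds))
        else:
            raise PipelineError(f"unknown fate-calling mode {self.mode!r}")
        self.score_ = score
        self.fate_ = fate
        self.thresholds_ = thr
        return self

    def result_(self) -> FateCalls:
        return FateCalls(score=self.score_, fate=self.fate_,
                         thresholds=self.thresholds_)


def assign_fate(expr: ExpressionMatrix, sets: MarkerSets,
                mode: str = "score",
                thresholds: tuple[float, float] | str = "terciles",
                sample_meta: pd.DataFrame | None = None) -> FateCalls:
    """Lineage scores and ICM/TE/n.d. fate calls for blastomeres."""
    caller = FateCaller(mode=mode, thresholds=thresholds)
    return caller.fit(expr, sets=sets, sample_meta=sample_meta).result_()


def evaluate_panel(expr: ExpressionMatrix, panel: list[str],
                   reference_calls: FateCalls, sets: MarkerSets | None = None,
                   side: str | None = None) -> float:
    """Concordance of a reduced marker panel with reference fate calls.

    The panel mean per blastomere is cut into low/mid/high terciles; a
    high panel mean calls the lineage the panel belongs to (``side``,
    inferred from marker-set membership or, failing that, from the sign
    of the correlation between panel mean and reference lineage score).
    Returns the fraction of reference-called (non-n.d.) blastomeres whose
    panel call agrees.
    """
    if not panel:
        raise PipelineError("panel is empty")
    cells = reference_calls.fate.index
    level = _set_mean(expr.values[cells], list(panel), "panel")
    if side is None and sets is not None:
        in_icm = len(set(panel) & set(sets.icm))
        in_te = len(set(panel) & set(sets.te))
        if in_icm != in_te:
            side = "ICM" if in_icm > in_te else "TE"
    if side is None:
        r = np.corrcoef(level.to_numpy(), reference_calls.score[cells].to_numpy())[0, 1]
        side = "ICM" if (np.isnan(r) or r >= 0) else "TE"
    other = "TE" if side == "ICM" else "ICM"
    call, _ = _call_from_levels(level, "terciles", side, other)
    defined = reference_calls.fate != "n.d."
    if not defined.any():
        raise PipelineError("reference calls contain no defined fates")
    return float((call[defined] == reference_calls.fate[defined]).mean())
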