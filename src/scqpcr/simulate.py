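"""Synthetic single-cell qPCR experiment generator.

Emulates a Fluidigm BioMark-style profiling run over mouse preimplantation
development: 192 assays (3 endogenous reference genes, a fraction of
non-specific assays discarded at QC) measured in single oocytes and
blastomeres from MII through the 32-cell blastocyst, plus ESC controls.

The generative model is deliberately the simplest one that reproduces the
statistical structure the downstream analysis relies on:

* each gene has a deterministic stage-profile of *normalized* log2
  expression (maternal decay, zygotic activation, flat, silent, or
  lineage-bifurcating in 16/32-cell blastomeres);
* the raw inverted-Ct signal of a reaction is the normalized level plus a
  per-cell reference level (total-RNA proxy) plus Gaussian noise;
* reactions drop out (non-detects) with a probability that decreases
  logistically in the raw signal, with midpoint at the Ct baseline.

Ground-truth labels for every planted structure are returned so that the
full pipeline can be scored as a recovery problem.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import BLASTOMERE_STAGES, ESC, STAGE_ORDER, PipelineError, RawPlate

__all__ = ["SimConfig", "TruthLabels", "default_config", "simulate_experiment"]

REFERENCE_GENES = ["Hnrnpr", "Ssu72", "Ube2e1"]
# Per-reference offsets from the cell's reference mean; sum to zero so the
# per-cell mean of the three references equals the cell's reference level.
REFERENCE_OFFSETS = [-0.5, 0.0, 0.5]

# Curated symbol pools per planted class.  Genes intended to be silent in
# MII oocytes (hence "exclusively zygotic" by the threshold rule) come
# first in the zygotic-like pools; genes intended to decay fully come
# first in the maternal pool.
_ICM_POOL = ["Tet1", "Nanog", "Esrrb", "Pou5f1", "Sox2", "Klf2", "Klf4",
             "Prdm14", "Ezh1", "Scmh1", "Tbx3", "Pecam1"]
_TE_POOL = ["Elf5", "Hand1", "Gata3", "Cdx2", "Id2", "Krt8", "Tead4",
            "Tspan8", "Dnmt3b", "Kdm1b"]
_ZYG_POOL = ["Smyd1", "Suv39h1", "Cbx6", "Xist", "Fgf4", "Fgfr3", "Ring1",
             "Kdm4c", "Zfp42", "Nr0b1", "Mll1", "Smyd2", "Smyd5", "Kdm5a",
             "Krt18", "Eif1a", "Pdgfra", "Gata4", "Sox17", "Kdm6b"]
_MAT_POOL = ["Dazl", "Mecom", "Prdm6", "Scml2", "Zp3", "Brdt", "Bmi1",
             "Smyd3", "Smyd4", "Suv39h2", "Tet3", "Dnmt3a", "Mll2", "Dppa1",
             "Pcgf1", "Phf19", "Kdm1a", "Npm2", "Padi6", "Mater"]
_UBI_POOL = ["Ezh2", "Eed", "Suz12", "Trim28", "Hdac1", "Hdac2", "Dnmt1",
             "Chd1", "Smarca4", "Smarca5", "Ssrp1", "Supt16"]
_SILENT_POOL = ["Olfr151", "Gfap"]

_CATEGORIES = ["histone methyltransferase", "histone demethylase",
               "chromatin remodeller", "DNA modification",
               "transcription factor", "signalling", "histone chaperone",
               "chromatin binding"]


@dataclass
class SimConfig:
    """Design constants of a simulated profiling run.

    Expression parameters are on the normalized log2 scale (inverted Ct
    minus per-cell reference mean); ``ref_raw_mean`` is on the raw
    inverted-Ct scale.
    """

    n_genes: int = 192
    n_reference: int = 3
    stage_design: list[tuple[str, int]] = field(default_factory=lambda: [
        ("MII", 26), ("zygote", 20), ("2cell", 24), ("4cell", 24),
        ("8cell", 28), ("16cell", 34), ("32cell", 35), (ESC, 3),
    ])
    class_fractions: dict[str, float] = field(default_factory=lambda: {
        "maternal": 31 / 153, "ubiquitous": 62 / 153, "zygotic": 36 / 153,
        "icm_marker": 12 / 153, "te_marker": 10 / 153, "silent": 2 / 153,
    })
    expr_high: float = 2.0       # normalized level of an expressed gene
    expr_low: float = -14.0      # fully silent / decayed level
    expr_partial: float = -6.0   # weak ("predominant" rather than exclusive) level
    lineage_effect: float = 6.0  # ICM-TE log2 separation for marker genes
    noise_sd: float = 0.8        # per-reaction Gaussian sd, log2 units
    dropout_rate: float = 1.0    # ceiling of the logistic dropout curve
    dropout_midpoint: float = 0.0  # raw inverted-Ct at 50% of ceiling (Ct = baseline)
    dropout_scale: float = 1.5
    nonspecific_fraction: float = 36 / 192
    ref_raw_mean: float = 10.0   # raw inverted-Ct level of reference genes
    cell_sd: float = 1.0         # per-cell total-RNA (reference level) sd
    embryo_sd: float = 0.0       # embryo-of-origin random effect sd
    baseline: float = 30.0
    n_exclusive_maternal: int = 7   # maternal genes decaying below detection
    n_exclusive_zygotic: int = 16   # zygotic-like genes silent in MII
    n_low_quality_cells: int = 5    # planted cells failing the reference QC
    low_quality_ref_level: float = -2.0  # raw reference level of those cells
    icm_fraction: float = 0.5    # ICM share of 16/32-cell blastomeres
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise PipelineError(f"class_fractions sum to {total}, expected 1")
        if self.n_genes <= 0 or self.n_reference <= 0:
            raise PipelineError("gene counts must be strictly positive")
        if any(n <= 0 for _, n in self.stage_design):
            raise PipelineError("stage cell counts must be strictly positive")
        known = set(STAGE_ORDER) | {ESC}
        bad = [s for s, _ in self.stage_design if s not in known]
        if bad:
            raise PipelineError(f"unknown stages in design: {bad}")
        if self.expr_high - self.expr_low < 4 * self.noise_sd:
            raise PipelineError(
                "expr_high - expr_low = "
                f"{self.expr_high - self.expr_low:g} < 4*noise_sd = "
                f"{4 * self.noise_sd:g}: planted structure unrecoverable by design"
            )


@dataclass
class TruthLabels:
    """Planted ground truth for recovery scoring."""

    gene_class: pd.Series          # planted class per gene (incl. reference/nonspecific)
    threshold_class: pd.Series     # expected threshold class per retained gene
    branch: pd.Series              # expected branch per retained gene
    cell_fate: pd.Series           # ICM/TE for every 16/32-cell sample
    censored: pd.DataFrame         # boolean mask over all reactions
    low_quality_cells: list[str]   # samples planted to fail the reference QC


def default_config(seed: int = 0) -> SimConfig:
    """Configuration mirroring the published study's scale.

    192 assays (three shared reference genes), ~190 cells spanning MII
    oocytes through 32-cell blastocysts plus three ESC control samples,
    36/192 assays non-specific, and gene-class counts yielding the
    published maternal/ubiquitous/zygotic structure after QC.
    """
    return SimConfig(seed=seed)


def _apportion(fractions: dict[str, float], total: int) -> dict[str, int]:
    """Largest-remainder apportionment of `total` items over fractions."""
    raw = {k: v * total for k, v in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _names(pool: list[str], n: int, prefix: str, used: set[str]) -> list[str]:
    names = [g for g in pool if g not in used][:n]
    counter = itertools.count(1)
    while len(names) < n:
        cand = f"{prefix}{next(counter):03d}"
        if cand not in used and cand not in names:
            names.append(cand)
    used.update(names)
    return names


def _build_gene_table(cfg: SimConfig) -> pd.DataFrame:
    """Gene metadata plus planted-class bookkeeping columns."""
    n_nonspecific = int(round(cfg.nonspecific_fraction * cfg.n_genes))
    n_assay = cfg.n_genes - cfg.n_reference - n_nonspecific
    if n_assay <= 0:
        raise PipelineError("config leaves no specific assay genes")
    counts = _apportion(cfg.class_fractions, n_assay)

    used: set[str] = set()
    refs = _names(REFERENCE_GENES, cfg.n_reference, "Ref", used)
    rows: list[dict] = []
    for i, g in enumerate(refs):
        rows.append(dict(gene_id=g, gene_class="reference", exclusive=False,
                         is_reference=True, specific=True,
                         offset=REFERENCE_OFFSETS[i % len(REFERENCE_OFFSETS)]))

    pools = {"maternal": _MAT_POOL, "ubiquitous": _UBI_POOL,
             "zygotic": _ZYG_POOL, "icm_marker": _ICM_POOL,
             "te_marker": _TE_POOL, "silent": _SILENT_POOL}
    prefixes = {"maternal": "Matg", "ubiquitous": "Ubig", "zygotic": "Zygg",
                "icm_marker": "Icmg", "te_marker": "Teg", "silent": "Silg"}

    # MII-silent ("exclusively zygotic") genes are apportioned over the
    # three zygotic-like classes proportionally to their sizes.
    zyg_like = {k: counts.get(k, 0) for k in ("zygotic", "icm_marker", "te_marker")}
    n_excl_z = min(cfg.n_exclusive_zygotic, sum(zyg_like.values()))
    tot = sum(zyg_like.values()) or 1
    excl_z = _apportion({k: v / tot for k, v in zyg_like.items()}, n_excl_z)

    for cls in ("maternal", "ubiquitous", "zygotic", "icm_marker",
                "te_marker", "silent"):
        n = counts.get(cls, 0)
        names = _names(pools[cls], n, prefixes[cls], used)
        if cls == "maternal":
            n_excl = min(cfg.n_exclusive_maternal, n)
        elif cls in excl_z:
            n_excl = min(excl_z[cls], n)
        else:
            n_excl = 0
        for j, g in enumerate(names):
            rows.append(dict(gene_id=g, gene_class=cls, exclusive=j < n_excl,
                             is_reference=False, specific=True, offset=0.0))

    ns_names = _names([], n_nonspecific, "Nsg", used)
    for g in ns_names:
        rows.append(dict(gene_id=g, gene_class="nonspecific", exclusive=False,
                         is_reference=False, specific=False, offset=0.0))

    table = pd.DataFrame(rows).set_index("gene_id")
    table["category"] = [_CATEGORIES[i % len(_CATEGORIES)]
                         for i in range(len(table))]
    return table


_STAGE_IDX = {s: i for i, s in enumerate(STAGE_ORDER)}


def _profile_level(cls: str, exclusive: bool, stage: str, fate: str | None,
                   cfg: SimConfig) -> float:
    """Deterministic normalized log2 level of a gene class at a stage."""
    hi, lo, part = cfg.expr_high, cfg.expr_low, cfg.expr_partial
    if cls in ("ubiquitous", "reference"):
        return hi
    if cls == "silent":
        return lo
    if cls == "maternal":
        target = lo if exclusive else part
        if stage == ESC:
            return target
        i = _STAGE_IDX[stage]
        if i <= 1:  # MII, zygote: full maternal load
            return hi
        if i >= 5:  # 16cell on: decayed
            return target
        return hi + (target - hi) * (i - 1) / 4  # linear decay zygote->16cell
    # zygotic-like classes (plain zygotic and lineage markers)
    start = lo if exclusive else part
    if cls == "zygotic":
        if stage == ESC:
            return hi
        i = _STAGE_IDX[stage]
        if i <= 1:
            return start
        if i >= 4:  # fully activated from 8cell
            return hi
        return start + (hi - start) * (i - 1) / 3  # ramp zygote->8cell
    # lineage markers: zygotic ramp to an intermediate level, then bifurcate
    pre = hi - cfg.lineage_effect / 2
    own = "ICM" if cls == "icm_marker" else "TE"
    if stage == ESC:  # ESC expresses the pluripotency (ICM) programme
        return hi if cls == "icm_marker" else hi - cfg.lineage_effect
    i = _STAGE_IDX[stage]
    if i <= 1:
        return start
    if i <= 3:
        return start + (pre - start) * (i - 1) / 3
    if i == 4:
        return pre
    return hi if fate == own else hi - cfg.lineage_effect


def _dropout_prob(raw: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """P(non-detect) as a function of the raw inverted-Ct signal."""
    if cfg.dropout_rate <= 0:
        return np.zeros_like(raw)
    z = (raw - cfg.dropout_midpoint) / cfg.dropout_scale
    return cfg.dropout_rate / (1.0 + np.exp(z))


def simulate_experiment(
    config: SimConfig | None = None, seed: int | None = None
) -> tuple[RawPlate, pd.DataFrame, pd.DataFrame, TruthLabels]:
    """Simulate one profiling run.

    Returns the raw Ct plate, sample metadata (stage, embryo id), gene
    metadata (category, reference and specificity flags) and the planted
    truth labels.  Deterministic given ``(config, seed)``; ``seed``
    overrides ``config.seed`` when given.
    """
    cfg = config if config is not None else default_config()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = _build_gene_table(cfg)

    # --- samples ----------------------------------------------------------
    sample_rows: list[dict] = []
    embryo_size = {"2cell": 2, "4cell": 4, "8cell": 4, "16cell": 4, "32cell": 4}
    for stage, n in cfg.stage_design:
        for i in range(n):
            if stage in embryo_size:
                emb = f"{stage}_e{i // embryo_size[stage] + 1:02d}"
            else:
                emb = f"{stage}_e{i + 1:02d}"
            sample_rows.append(dict(
                sample_id=f"{stage}_c{i + 1:03d}", stage=stage, embryo_id=emb))
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    # ICM/TE fates: balanced split within each blastomere stage.
    fate = pd.Series(index=samples.index, dtype=object)
    for stage in BLASTOMERE_STAGES:
        ids = samples.index[samples["stage"] == stage]
        n_icm = int(round(cfg.icm_fraction * len(ids)))
        perm = rng.permutation(len(ids))
        fates = np.array(["TE"] * len(ids), dtype=object)
        fates[perm[:n_icm]] = "ICM"
        fate.loc[ids] = fates
    cell_fate = fate.dropna()

    # Planted low-quality cells: low total RNA, drawn from pre-blastomere
    # embryonic stages so the blastomere complement stays intact.
    early = samples.index[samples["stage"].isin(STAGE_ORDER[:5])]
    n_lq = min(cfg.n_low_quality_cells, len(early))
    low_quality = list(rng.choice(early, size=n_lq, replace=False))

    # --- signal -----------------------------------------------------------
    n_g, n_s = len(genes), len(samples)
    cell_ref = cfg.ref_raw_mean + rng.normal(0.0, cfg.cell_sd, size=n_s)
    cell_ref[samples.index.get_indexer(low_quality)] = cfg.low_quality_ref_level
    embryo_ids = samples["embryo_id"].to_numpy()
    if cfg.embryo_sd > 0:
        uniq = pd.unique(embryo_ids)
        eff = dict(zip(uniq, rng.normal(0.0, cfg.embryo_sd, size=len(uniq))))
        embryo_eff = np.array([eff[e] for e in embryo_ids])
    else:
        embryo_eff = np.zeros(n_s)

    mu = np.empty((n_g, n_s))
    stage_arr = samples["stage"].to_numpy()
    fate_arr = fate.reindex(samples.index).to_numpy()
    nonspecific_base = rng.uniform(-4.0, 4.0, size=n_g)
    for gi, (g, row) in enumerate(genes.iterrows()):
        if row.gene_class == "nonspecific":
            mu[gi, :] = nonspecific_base[gi]
            continue
        if row.gene_class == "reference":
            mu[gi, :] = row.offset
            continue
        for si in range(n_s):
            mu[gi, si] = _profile_level(row.gene_class, row.exclusive,
                                        stage_arr[si], fate_arr[si], cfg)

    noise = rng.normal(0.0, cfg.noise_sd, size=(n_g, n_s)) if cfg.noise_sd > 0 \
        else np.zeros((n_g, n_s))
    # Non-specific assays are noisier: their signal is primer-dimer junk.
    ns_mask = (genes["gene_class"] == "nonspecific").to_numpy()
    noise[ns_mask, :] *= 2.0
    raw = mu + cell_ref[None, :] + embryo_eff[None, :] + noise

    p_fail = _dropout_prob(raw, cfg)
    censored = rng.uniform(size=(n_g, n_s)) < p_fail

    ct = cfg.baseline - raw
    ct[censored] = np.nan
    # Guard the RawPlate contract: passing Ct must be positive.
    ct[~censored & (ct <= 0)] = 0.01

    values = pd.DataFrame(ct, index=genes.index, columns=samples.index)
    call = pd.DataFrame(~censored, index=genes.index, columns=samples.index)
    plate = RawPlate(values=values, call=call, baseline=cfg.baseline)

    # --- truth ------------------------------------------------------------
    retained = genes.index[genes["specific"]]
    thr_class, branch = {}, {}
    for g in retained:
        cls, excl = genes.loc[g, "gene_class"], genes.loc[g, "exclusive"]
        if cls == "silent":
            thr_class[g], branch[g] = "not_expressed", "ubiquitous"
        elif cls in ("ubiquitous", "reference"):
            thr_class[g], branch[g] = "expressed_throughout", "ubiquitous"
        elif cls == "maternal":
            thr_class[g] = "exclusively_maternal" if excl else "expressed_throughout"
            branch[g] = "maternal"
        else:
            thr_class[g] = "exclusively_zygotic" if excl else "expressed_throughout"
            branch[g] = "zygotic"

    truth = TruthLabels(
        gene_class=genes["gene_class"].copy(),
        threshold_class=pd.Series(thr_class, name="threshold_class"),
        branch=pd.Series(branch, name="branch"),
        cell_fate=cell_fate,
        censored=pd.DataFrame(censored, index=genes.index, columns=samples.index),
        low_quality_cells=sorted(low_quality),
    )

    gene_meta = genes[["category", "is_reference", "specific"]].copy()
    return plate, samples, gene_meta, truth
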