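"""Recovery-scoring helpers shared by unit and acceptance tests."""
from __future__ import annotations

import numpy as np
import pandas as pd

import scqpcr as sq


def branch_recovery(result, truth) -> float:
    tb = truth.branch
    return float((result.branches.loc[tb.index] == tb).mean())


def threshold_recovery(result, truth) -> float:
    tc = truth.threshold_class
    return float((result.threshold_classes.loc[tc.index] == tc).mean())


def marker_purities(result, truth) -> tuple[float, float]:
    sets = result.marker_sets
    icm_t = set(truth.gene_class.index[truth.gene_class == "icm_marker"])
    te_t = set(truth.gene_class.index[truth.gene_class == "te_marker"])
    return (len(set(sets.icm) & icm_t) / len(sets.icm),
            len(set(sets.te) & te_t) / len(sets.te))


def fate_accuracy(result, truth) -> tuple[float, int, int]:
    """(accuracy among called, n called, n total)."""
    fc = result.fate_calls
    called = fc.fate[fc.fate != "n.d."]
    acc = float((called == truth.cell_fate.loc[called.index]).mean())
    return acc, len(called), len(fc.fate)


def panel_concordance(result, smeta, panel) -> float:
    blast = sq.select_blastomeres(result.expression,
                                  smeta.loc[result.expression.samples])
    return sq.evaluate_panel(blast, list(panel), result.fate_calls,
                             sets=result.marker_sets)


def brute_spearman(X: np.ndarray) -> np.ndarray:
    """Independent oracle: rank each row (mid-ranks), then Pearson."""
    from scipy.stats import rankdata

    ranks = np.apply_along_axis(rankdata, 1, X)
    return np.corrcoef(ranks)
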