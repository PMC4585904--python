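"""File formats: BioMark-style long CSV, wide TSV matrices, metadata,
YAML configuration and JSON reports.

The long export has one row per reaction chamber with the fixed columns
``SampleName, AssayName, CtValue, CtCall`` and call vocabulary
``Pass``/``Fail``.  Failed reactions are non-detects; their CtValue is
written as the sentinel 999.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ExpressionMatrix, PipelineError, RawPlate

LONG_COLUMNS = ["SampleName", "AssayName", "CtValue", "CtCall"]
FAIL_SENTINEL = 999.0


def read_biomark_long(path) -> tuple[RawPlate, pd.DataFrame]:
    """Read a BioMark-style long CSV into a plate and a metadata skeleton.

    Rows with ``CtCall == Fail`` (or the 999 sentinel) become censored
    reactions.  Duplicate (sample, assay) chambers and missing columns
    are errors.
    """
    df = pd.read_csv(path)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise PipelineError(f"{path}: missing required column(s) {missing}")
    ct = pd.to_numeric(df["CtValue"], errors="coerce")
    bad = df.index[ct.isna() & df["CtValue"].notna()]
    if len(bad):
        raise PipelineError(
            f"{path}: unparseable CtValue at row(s) {[int(i) + 2 for i in bad]}"
        )
    dup = df.duplicated(subset=["SampleName", "AssayName"])
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup]]
        raise PipelineError(f"{path}: duplicate (sample, assay) chamber at row(s) {rows}")

    passing = (df["CtCall"] == "Pass") & ct.notna() & (ct != FAIL_SENTINEL)
    values = df.assign(_ct=ct.where(passing)).pivot(
        index="AssayName", columns="SampleName", values="_ct")
    call = df.assign(_ok=passing).pivot(
        index="AssayName", columns="SampleName", values="_ok").fillna(False).astype(bool)
    plate = RawPlate(values=values, call=call)
    sample_meta = pd.DataFrame(index=values.columns)
    sample_meta.index.name = "sample_id"
    return plate, sample_meta


def write_biomark_long(plate: RawPlate, path) -> None:
    rows = []
    for g in plate.genes:
        for s in plate.samples:
            ok = bool(plate.call.loc[g, s])
            ct = plate.values.loc[g, s] if ok else FAIL_SENTINEL
            rows.append((s, g, float(ct), "Pass" if ok else "Fail"))
    pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(path, index=False)


def write_wide_tsv(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", float_format="%.6f")


def read_wide_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_plate_wide(path) -> RawPlate:
    """Wide genes x samples Ct TSV; empty cells are failed reactions."""
    values = read_wide_tsv(path)
    call = values.notna()
    return RawPlate(values=values, call=call)


def write_meta_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t")


def read_sample_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("is_reference", "specific"):
        if col in meta.columns and meta[col].dtype == object:
            meta[col] = meta[col].astype(str).str.lower().isin(("true", "1", "yes"))
    return meta


def write_expression(expr: ExpressionMatrix, path) -> None:
    """Expression TSV plus a sidecar JSON with mask and normalization info."""
    path = Path(path)
    write_wide_tsv(expr.values, path)
    sidecar = {
        "reference_ids": list(expr.reference_ids),
        "floor": expr.floor,
        "censored": {
            s: [g for g in expr.genes if bool(expr.censored.loc[g, s])]
            for s in expr.samples
            if expr.censored[s].any()
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True))


def read_expression(path) -> ExpressionMatrix:
    path = Path(path)
    values = read_wide_tsv(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    censored = pd.DataFrame(False, index=values.index, columns=values.columns)
    for s, genes in sidecar["censored"].items():
        censored.loc[genes, s] = True
    return ExpressionMatrix(values=values, censored=censored,
                            reference_ids=sidecar["reference_ids"],
                            floor=sidecar["floor"])


def write_config_yaml(config, path) -> None:
    d = dataclasses.asdict(config)
    d = {k: _to_plain(v) for k, v in d.items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _to_plain(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (list, tuple)):
        return [_to_plain(x) for x in v]
    if isinstance(v, dict):
        return {k: _to_plain(x) for k, x in v.items()}
    return v


def read_config_yaml(cls, path):
    d = yaml.safe_load(Path(path).read_text())
    if "stage_design" in d and d["stage_design"] is not None:
        d["stage_design"] = [tuple(x) for x in d["stage_design"]]
    return cls(**d)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(_to_plain(report), indent=1, sort_keys=True))
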