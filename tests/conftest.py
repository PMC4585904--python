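"""Shared fixtures: simulated experiments at study scale and the tiny
hand-checkable plate fixture."""
from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import pytest

import scqpcr as sq

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def default_sim():
    """Study-scale simulation with default noise, seed 1."""
    return sq.simulate_experiment(seed=1)


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Full pipeline result on the default simulation."""
    plate, smeta, gmeta, truth = default_sim
    result = sq.run_pipeline(plate, smeta, gmeta)
    return result, smeta, truth


@pytest.fixture(scope="session")
def noiseless_sim():
    """Deterministic simulation: no reaction noise, no dropout."""
    cfg = replace(sq.default_config(3), noise_sd=0.0, dropout_rate=0.0,
                  cell_sd=0.0)
    return sq.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def noiseless_run(noiseless_sim):
    plate, smeta, gmeta, truth = noiseless_sim
    result = sq.run_pipeline(plate, smeta, gmeta)
    return result, smeta, truth


@pytest.fixture(scope="session")
def tiny_paths():
    return {
        "plate": DATA / "tiny_plate_long.csv",
        "sample_meta": DATA / "tiny_sample_meta.tsv",
        "gene_meta": DATA / "tiny_gene_meta.tsv",
    }
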