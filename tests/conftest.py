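"""Shared fixtures: hand-built CNV tables and scaled-down simulated worlds."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cnvset.simulate import SimConfig, StratumSpec, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_call(
    sample_id="s1",
    chrom="chr1",
    start=1_000_000,
    end=1_100_000,
    copy_state="deletion",
    n_probes=20,
    study="STUDY1",
    chip="chipA",
    phenotype=1,
):
    return dict(
        sample_id=sample_id, chrom=chrom, start=start, end=end,
        copy_state=copy_state, n_probes=n_probes, study=study, chip=chip,
        phenotype=phenotype,
    )


def calls_frame(calls: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(calls)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


@pytest.fixture(scope="session")
def small_world():
    """A small simulated world: 1,000 CNVs, 2 strata, 20 sets, 400 genes."""
    cfg = SimConfig(
        seed=42,
        chrom_lengths={"chr1": 15_000_000, "chr2": 10_000_000},
        n_genes=400,
        n_sets=20,
        hub_size=60,
        set_size_max=120,
        strata=[
            StratumSpec("A", "chip1", 280, 320),
            StratumSpec("B", "chip2", 180, 220),
        ],
    )
    rows, genes, sets, probes, lcr, truth = simulate_dataset(cfg)
    return dict(
        cfg=cfg, rows=rows, genes=genes, sets=sets, probes=probes,
        lcr=lcr, truth=truth,
    )


@pytest.fixture(scope="session")
def null_world():
    """The default stated world (no embedded set effects, ~4,000 CNVs)."""
    cfg = SimConfig(seed=7)
    rows, genes, sets, probes, lcr, truth = simulate_dataset(cfg)
    return dict(
        cfg=cfg, rows=rows, genes=genes, sets=sets, probes=probes,
        lcr=lcr, truth=truth,
    )
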