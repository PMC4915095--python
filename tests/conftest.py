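"""Shared fixtures: tiny genomes/populations for unit tests and one
session-scoped mini-scale replicate reused by the slower checks."""

from __future__ import annotations

import numpy as np
import pytest

from ssgwas import genome_sim as gs
from ssgwas.workflow import ExperimentConfig, ScaleParams, simulate_replicate

# a deliberately tiny problem scale for fast orchestration tests
MICRO = ScaleParams(
    n_chromosomes=5, total_length=40.0,
    n_sim_markers=900, n_sim_qtl=60,
    n_markers=200, n_qtl=20, maf_min=0.02,
    hist_constant_size=60, hist_n_constant=40, hist_final_size=30,
    hist_decline_hld=80, hist_decline_lld=40,
    exp_generations=2, offspring_per_dam=5,
    sel_generations=2, n_sires=6, n_dams=60, replacement_rate=0.2,
    n_genotyped=40, genotyped_last_k=2, blend=0.05,
    bc_chain=600, bc_burnin=100, bc_thin=5,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_genome(rng):
    """Small multi-chromosome genome with markers and QTLs."""
    return gs.GenomeSpec.random(rng, n_chromosomes=3, total_length=60.0,
                                n_markers=150, n_qtl=30)


@pytest.fixture
def tiny_population(tiny_genome, rng):
    sched = gs.PopSchedule.historical(constant_size=60, n_constant=30,
                                      final_size=40, ld="lld", n_decline=20)
    return gs.simulate_historical(tiny_genome, sched, rng)


def micro_config(ld="hld", seed=1, **kw):
    return ExperimentConfig(ld_level=ld, scale="mini", base_seed=seed,
                            params=MICRO, **kw)


@pytest.fixture(scope="session")
def mini_replicate():
    """One mini-scale HLD replicate shared across slow tests."""
    cfg = ExperimentConfig(ld_level="hld", scale="mini", base_seed=1)
    return cfg, simulate_replicate(cfg, 0)
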