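"""Shared fixtures: small simulated families reused across test modules.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import pytest

from ddradmap.pipeline import PipelineResult, run_pipeline
from ddradmap.simulate import SimConfig, TruthTable, emit_reads, simulate_family


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    return SimConfig(n_loci=40, n_progeny=12, n_chromosomes=3, seed=7)


@pytest.fixture(scope="session")
def tiny_truth(tiny_config: SimConfig) -> TruthTable:
    return simulate_family(tiny_config)


@pytest.fixture(scope="session")
def tiny_reads(tiny_truth: TruthTable):
    return emit_reads(tiny_truth)


@pytest.fixture(scope="session")
def tiny_result(tiny_reads) -> PipelineResult:
    return run_pipeline(tiny_reads)


@pytest.fixture(scope="session")
def clean_config() -> SimConfig:
    """Error-free family at depths where missing data is (numerically)
    impossible: exact-recovery oracles hold."""
    return SimConfig(
        n_loci=30,
        n_progeny=15,
        n_chromosomes=3,
        depth_parent=60.0,
        depth_progeny=30.0,
        error_rate=0.0,
        plastid_copy_factor=0.0,
        repeat_families=(),
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_truth(clean_config: SimConfig) -> TruthTable:
    return simulate_family(clean_config)


@pytest.fixture(scope="session")
def clean_result(clean_truth: TruthTable) -> PipelineResult:
    return run_pipeline(emit_reads(clean_truth))
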