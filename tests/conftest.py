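"""Shared fixtures: one miniature simulated study reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from methylrescue import simulate


@pytest.fixture(scope="session")
def small_cfg():
    return simulate.SimulationConfig(
        seed=11,
        n_contigs=1,
        contig_length=20_000,
        n_islands=2,
        n_genes=6,
        n_dmr_sites=15,
        coverage=12.0,
    )


@pytest.fixture(scope="session")
def small_reference(small_cfg):
    return simulate.generate_reference(small_cfg)


@pytest.fixture(scope="session")
def units():
    return simulate.make_design(0)


@pytest.fixture(scope="session")
def small_truth(small_cfg, small_reference, units):
    return simulate.assign_methylation(small_reference, units, small_cfg)


@pytest.fixture(scope="session")
def small_fragments(small_cfg, small_reference):
    return simulate.size_select(
        simulate.digest_mspi(small_reference.contigs), small_cfg.size_range
    )


@pytest.fixture(scope="session")
def small_unit_reads(small_cfg, small_reference, small_truth, small_fragments, units):
    """Reads for the first SAL-n6 unit, deterministic."""
    unit = units[0]
    rng = np.random.default_rng(np.random.SeedSequence([small_cfg.seed, 12, 0]))
    reads = simulate.simulate_reads(
        small_fragments, small_truth, unit, small_cfg, small_reference, rng
    )
    return unit, reads
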