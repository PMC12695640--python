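"""Shared fixtures: small codebooks and seeded synthetic populations."""

import numpy as np
import pytest
from hypothesis import settings

import chromtrace as ct

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def codebook():
    """Full-size panel: 473 regions over 19 autosomes."""
    return ct.synthetic_codebook()


@pytest.fixture(scope="session")
def small_codebook():
    """Small panel for fast oracle tests: 60 regions over 4 chromosomes."""
    return ct.synthetic_codebook(n_regions=60, n_chroms=4)


@pytest.fixture(scope="session")
def wt_population(codebook):
    """Default-parameter single-state population (150 cells)."""
    state = ct.StateParams(label="WT", n_cells=150)
    return ct.simulate_population([state], codebook, seed=101)


@pytest.fixture(scope="session")
def two_state_population(codebook):
    """Adenoma-like (0.8x compaction) vs normal-like states, 120 cells each."""
    states = [
        ct.StateParams(label="normal", n_cells=120),
        ct.StateParams(label="adenoma", n_cells=120,
                       compaction_scale=1200.0, heterogeneity_sd=0.15),
    ]
    return ct.simulate_population(states, codebook, seed=202)


def make_cell(cell_id, state, loci_by_trace, codebook):
    """Build a CellRecord from {(chrom, copy): [(region_index, x, y, z)]}."""
    traces = []
    for (chrom, copy_id), loci in loci_by_trace.items():
        traces.append(ct.ChromatinTrace(
            chrom=chrom, copy_id=copy_id,
            loci=[ct.Locus3D(region_index=ri, x=x, y=y, z=z)
                  for ri, x, y, z in loci]))
    return ct.CellRecord(cell_id=cell_id, state=state, traces=traces)
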