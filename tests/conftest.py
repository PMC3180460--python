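"""Shared fixtures: a toy single-chromosome genome, the study-scale synthetic
genome, and a simulated cohort reused by the heavier tests."""

import numpy as np
import pandas as pd
import pytest

from tetrascope import event_calling, meiosis_sim
from tetrascope.genome_io import Chromosome, GenomeMap


@pytest.fixture()
def toy_genome():
    """One 100-kb chromosome with 8 markers at 10-kb spacing."""
    chrom = Chromosome("1", 100_000, 50_000)
    pos = np.arange(10_000, 90_001, 10_000)
    markers = pd.DataFrame({
        "chrom": "1", "pos": pos,
        "marker_id": [f"m{i + 1}" for i in range(len(pos))],
    })
    return GenomeMap([chrom], markers)


@pytest.fixture(scope="session")
def study_genome():
    """Study-scale synthetic map: 16 chromosomes, ~2,965 markers, ~77%
    covered."""
    return meiosis_sim.synthetic_genome()


@pytest.fixture(scope="session")
def study_cohort(study_genome):
    """60 simulated tetrads at default study conditions, with truth log."""
    cfg = meiosis_sim.SimulationConfig(seed=11)
    tetrads, truth = meiosis_sim.simulate_cohort(study_genome, cfg, 60)
    return tetrads, truth


@pytest.fixture(scope="session")
def study_events(study_genome, study_cohort):
    tetrads, _ = study_cohort
    events, summary = event_calling.call_all_events(tetrads, study_genome)
    return events, summary


def make_tetrad(n_sets, n_markers=None, tetrad_id="t1"):
    """Build a TetradGenotypes from per-marker N-carrying spore sets.

    Each element of ``n_sets`` is an iterable of spore indices carrying the N
    allele, or None for an all-missing marker.
    """
    from tetrascope.genome_io import CALL_MISSING, CALL_N, CALL_S, TetradGenotypes

    m = n_markers or len(n_sets)
    spores = np.full((4, m), CALL_S, dtype=np.int8)
    for j, nset in enumerate(n_sets):
        if nset is None:
            spores[:, j] = CALL_MISSING
        else:
            for s in nset:
                spores[s, j] = CALL_N
    return TetradGenotypes(tetrad_id, spores)
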