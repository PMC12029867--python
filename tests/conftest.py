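"""Shared fixtures: small simulated studies reused across the suite."""

import pytest

from microsnv.synthetic_data import (SimulationConfig, demo_config,
                                     simulate_study)


@pytest.fixture(scope="session")
def demo_study():
    """Seconds-fast demo study: 2 species x 6 kb, 2 replicates per cell."""
    return simulate_study(demo_config(seed=11))


@pytest.fixture(scope="session")
def clean_study():
    """Full-scale clean study (5 species x 50 kb, depth 150, planted frequency
    0.6, no sequencing error) under which recovery is exact."""
    return simulate_study(SimulationConfig(seed=5))


@pytest.fixture(scope="session")
def clean_calls(clean_study):
    """Per-sample SNV calls for the clean study at the default thresholds."""
    from microsnv.snv_profiler import CallerParams, call_snvs

    params = CallerParams()
    by_sample = {m.sample_id: [] for m in clean_study.samples}
    for m in clean_study.samples:
        for g in clean_study.genomes:
            pileup = clean_study.pileup_for(m.sample_id, g.species_id)
            by_sample[m.sample_id].extend(
                call_snvs(pileup, g, params, sample_id=m.sample_id))
    return by_sample
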