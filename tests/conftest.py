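"""Shared fixtures: one moderately sized simulation reused across modules."""

from __future__ import annotations

import pytest

from grainfill import STAGES
from grainfill.annotation import CollapsedRead, classify_all
from grainfill.synthetic import (
    SimulationConfig,
    simulate_dge,
    simulate_genome,
    simulate_libraries,
)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(
        genome_length=40_000,
        n_known_mirnas=4,
        n_novel_hairpins=4,
        n_target_genes=4,
        n_decoy_genes=3,
        library_depths={s: 2500 for s in STAGES},
        seed=11,
    )


@pytest.fixture(scope="session")
def simulation(sim_config):
    genome, tracks, truth = simulate_genome(sim_config)
    return genome, tracks, truth


@pytest.fixture(scope="session")
def libraries(simulation, sim_config):
    genome, tracks, truth = simulation
    return simulate_libraries(genome, tracks, truth, sim_config)


@pytest.fixture(scope="session")
def collapsed(libraries):
    merged: dict[str, dict[str, int]] = {}
    for stage in STAGES:
        for read in libraries[stage]:
            merged.setdefault(read.sequence, {})[stage] = read.counts[stage]
    return [CollapsedRead(seq, counts) for seq, counts in merged.items()]


@pytest.fixture(scope="session")
def classified(collapsed, simulation):
    genome, tracks, _ = simulation
    return classify_all(collapsed, genome, tracks)


@pytest.fixture(scope="session")
def library_maps(libraries):
    return {
        stage: {r.sequence: r.counts[stage] for r in libraries[stage]}
        for stage in STAGES
    }


@pytest.fixture(scope="session")
def report(classified, simulation, library_maps, sim_config):
    """Novel-miRNA discovery run over the shared simulation."""
    from grainfill.hairpin import discover

    genome, tracks, truth = simulation
    unann = [c for c in classified if c.category == "no_annotation"]
    totals = {s: sim_config.library_depths[s] for s in STAGES}
    known_iv = [(p.start, p.end) for p in tracks.mirna_precursors]
    return discover(unann, genome, library_maps, totals, known_iv)


@pytest.fixture(scope="session")
def dge_data(simulation, sim_config):
    genome, tracks, truth = simulation
    profiles = {
        m.planted_id: sim_config.profile_templates[m.profile_label]
        for m in truth.planted_mirnas
    }
    transcripts, tag_libraries = simulate_dge(truth, profiles, sim_config, coupling=-1.0)
    return transcripts, tag_libraries, profiles
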