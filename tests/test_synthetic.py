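"""Simulation tests: determinism, planted structure, noise contracts."""

from __future__ import annotations

import numpy as np
import pytest

from grainfill import STAGES
from grainfill.annotation import CollapsedRead
from grainfill.fold import fold_window
from grainfill.hairpin import build_candidate, check_duplex_criteria
from grainfill.synthetic import (
    ConfigError,
    PlacementError,
    SimulationConfig,
    simulate_dge,
    simulate_genome,
    simulate_grain_weights,
    simulate_libraries,
)


def small_config(**overrides) -> SimulationConfig:
    base = dict(
        genome_length=25_000, n_known_mirnas=3, n_novel_hairpins=3,
        n_target_genes=3, n_decoy_genes=2,
        library_depths={s: 1200 for s in STAGES}, seed=5,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestSimulateGenome:
    def test_same_seed_identical(self):
        g1, _, t1 = simulate_genome(small_config())
        g2, _, t2 = simulate_genome(small_config())
        assert g1 == g2
        assert [m.locus for m in t1.planted_mirnas] == [m.locus for m in t2.planted_mirnas]

    def test_different_seed_differs(self):
        g1, _, _ = simulate_genome(small_config(seed=1))
        g2, _, _ = simulate_genome(small_config(seed=2))
        assert g1 != g2

    def test_zero_novel_hairpins(self):
        _, _, truth = simulate_genome(small_config(n_novel_hairpins=0))
        assert truth.by_kind("novel") == []
        assert len(truth.by_kind("known")) == 3

    def test_placement_error_when_overfull(self):
        with pytest.raises(PlacementError):
            simulate_genome(small_config(genome_length=2_000, n_known_mirnas=40))

    def test_planted_matures_are_substrings_of_precursors(self):
        _, _, truth = simulate_genome(small_config())
        for m in truth.planted_mirnas:
            assert m.mature in m.precursor
            assert m.star in m.precursor

    def test_planted_loci_match_genome(self):
        genome, _, truth = simulate_genome(small_config())
        for m in truth.planted_mirnas:
            lo, hi, strand = m.locus
            assert genome[lo:hi] == m.precursor
            ms, me = m.mature_span
            assert genome[ms:me] == m.mature

    def test_all_planted_hairpins_fold_below_threshold(self):
        _, _, truth = simulate_genome(small_config(n_novel_hairpins=10))
        novel = truth.by_kind("novel")
        assert len(novel) == 10
        for m in novel:
            assert fold_window(m.precursor).mfe <= -18.0

    def test_planted_duplexes_pass_package_criteria(self):
        _, _, truth = simulate_genome(small_config())
        for m in truth.planted_mirnas:
            read = CollapsedRead(m.mature, {s: 3 for s in STAGES})
            cand = build_candidate((0, len(m.precursor), "+"), m.precursor, read)
            assert cand is not None
            crit = check_duplex_criteria(cand)
            assert crit.passed, (m.planted_id, crit.failures())

    def test_known_track_excludes_novel(self):
        _, tracks, truth = simulate_genome(small_config())
        known_ids = {p.precursor_id for p in tracks.mirna_precursors}
        assert known_ids == {m.planted_id for m in truth.by_kind("known")}


class TestSimulateLibraries:
    def test_determinism(self):
        cfg = small_config()
        genome, tracks, truth = simulate_genome(cfg)
        l1 = simulate_libraries(genome, tracks, truth, cfg)
        l2 = simulate_libraries(genome, tracks, truth, cfg)
        for s in STAGES:
            assert [(r.sequence, r.counts) for r in l1[s]] == [
                (r.sequence, r.counts) for r in l2[s]
            ]

    def test_depth_conservation(self, libraries, sim_config):
        for s in STAGES:
            assert sum(r.counts[s] for r in libraries[s]) == sim_config.library_depths[s]

    def test_read_lengths_in_18_30(self, libraries):
        for s in STAGES:
            for r in libraries[s]:
                assert 18 <= len(r.sequence) <= 30

    def test_noise_free_flat_template_proportional_to_depth(self):
        depths = {"10DAF": 1000, "15DAF": 2000, "21DAF": 3000, "27DAF": 1500, "35DAF": 2500}
        cfg = small_config(
            library_depths=depths,
            profile_templates={"flat": (1.0, 1.0, 1.0, 1.0, 1.0)},
            noise_dispersion=0.0,
        )
        genome, tracks, truth = simulate_genome(cfg)
        libs = simulate_libraries(genome, tracks, truth, cfg)
        m = truth.planted_mirnas[0]
        for s in STAGES:
            count = next(r.counts[s] for r in libs[s] if r.sequence == m.mature)
            assert count == round(cfg.mirna_fraction * depths[s])

    def test_star_ratio_override_exact(self):
        cfg = small_config(n_novel_hairpins=0)
        genome, tracks, truth = simulate_genome(cfg)
        target = truth.planted_mirnas[0].planted_id
        cfg.star_ratio_overrides = {target: 50.0}
        cfg.profile_templates = {k: (1.0, 1.0, 1.0, 1.0, 1.0) for k in cfg.profile_templates}
        cfg.mirna_fraction = 0.001
        libs = simulate_libraries(genome, tracks, truth, cfg)
        planted = truth.planted_mirnas[0]
        for s in STAGES:
            mature = next(r.counts[s] for r in libs[s] if r.sequence == planted.mature)
            star = next(r.counts[s] for r in libs[s] if r.sequence == planted.star)
            assert star == 50 * mature

    def test_star_dominant_species_possible(self):
        # the override above IS the >1 star:mature scenario; check flag logic
        cfg = small_config()
        genome, tracks, truth = simulate_genome(cfg)
        cfg.star_ratio_overrides = {truth.planted_mirnas[0].planted_id: 2.0}
        libs = simulate_libraries(genome, tracks, truth, cfg)
        m = truth.planted_mirnas[0]
        stage = max(
            STAGES,
            key=lambda s: next(
                (r.counts[s] for r in libs[s] if r.sequence == m.mature), 0
            ),
        )
        mature = next(r.counts[stage] for r in libs[stage] if r.sequence == m.mature)
        star = next(r.counts[stage] for r in libs[stage] if r.sequence == m.star)
        assert star > mature

    def test_overdispersed_counts_still_conserve_depth(self):
        cfg = small_config(noise_dispersion=0.3)
        genome, tracks, truth = simulate_genome(cfg)
        libs = simulate_libraries(genome, tracks, truth, cfg)
        for s in STAGES:
            assert sum(r.counts[s] for r in libs[s]) == cfg.library_depths[s]

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            small_config(library_depths={s: 0 for s in STAGES}).validate()
        with pytest.raises(ConfigError):
            small_config(noise_dispersion=-1.0).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(profile_templates={"bad": (1.0, 2.0)}).validate()


class TestSimulateDGE:
    def test_coupling_minus_one_exact_anticorrelation(self):
        cfg = small_config()
        _, _, truth = simulate_genome(cfg)
        profiles = {
            m.planted_id: cfg.profile_templates[m.profile_label]
            for m in truth.planted_mirnas
        }
        transcripts, tag_libs = simulate_dge(truth, profiles, cfg, coupling=-1.0)
        for mid, targets in truth.planted_targets.items():
            p = np.array(profiles[mid], dtype=float)
            if len(set(p)) == 1:
                continue
            for t in targets:
                from grainfill.dge import canonical_tags

                primary = [
                    tg for tg in canonical_tags(transcripts[t.transcript_id])
                    if tg.primary
                ][0]
                counts = np.array(
                    [dict(tag_libs[s]).get(primary.sequence, 0) for s in STAGES],
                    dtype=float,
                )
                r = np.corrcoef(p, counts)[0, 1]
                assert r == pytest.approx(-1.0)

    def test_planted_sites_are_perfect_complements(self):
        cfg = small_config()
        _, _, truth = simulate_genome(cfg)
        profiles = {
            m.planted_id: cfg.profile_templates[m.profile_label]
            for m in truth.planted_mirnas
        }
        transcripts, _ = simulate_dge(truth, profiles, cfg)
        from grainfill.fold import revcomp

        by_id = {m.planted_id: m for m in truth.planted_mirnas}
        for mid, targets in truth.planted_targets.items():
            for t in targets:
                site = transcripts[t.transcript_id][t.site_start:t.site_end]
                assert site == revcomp(by_id[mid].mature)

    def test_every_transcript_has_usable_catg(self):
        cfg = small_config()
        _, _, truth = simulate_genome(cfg)
        profiles = {
            m.planted_id: cfg.profile_templates[m.profile_label]
            for m in truth.planted_mirnas
        }
        transcripts, _ = simulate_dge(truth, profiles, cfg)
        from grainfill.dge import canonical_tags

        for seq in transcripts.values():
            assert canonical_tags(seq)

    def test_decoys_uncorrelated_in_expectation(self):
        # Monte-Carlo over >= 100 seeds: decoy |PCC| stays below threshold
        decoy_abs, planted_abs = [], []
        for seed in range(100):
            cfg = small_config(seed=seed, n_target_genes=1, n_decoy_genes=1)
            _, _, truth = simulate_genome(cfg)
            profiles = {
                m.planted_id: cfg.profile_templates[m.profile_label]
                for m in truth.planted_mirnas
            }
            transcripts, tag_libs = simulate_dge(truth, profiles, cfg, coupling=-1.0)
            from grainfill.dge import canonical_tags

            ref = np.array(
                next(iter(profiles.values())), dtype=float
            )
            mid = next(iter(truth.planted_targets))
            ref = np.array(profiles[mid], dtype=float)
            for tx_id, seq in transcripts.items():
                primary = [t for t in canonical_tags(seq) if t.primary][0]
                counts = np.array(
                    [dict(tag_libs[s]).get(primary.sequence, 0) for s in STAGES],
                    dtype=float,
                )
                if counts.std() == 0 or ref.std() == 0:
                    continue
                r = abs(np.corrcoef(ref, counts)[0, 1])
                (decoy_abs if tx_id.startswith("decoy") else planted_abs).append(r)
        assert np.mean(decoy_abs) < 0.6
        assert np.mean(planted_abs) > 0.95

    def test_invalid_coupling_rejected(self):
        cfg = small_config()
        _, _, truth = simulate_genome(cfg)
        profiles = {
            m.planted_id: cfg.profile_templates[m.profile_label]
            for m in truth.planted_mirnas
        }
        with pytest.raises(ConfigError):
            simulate_dge(truth, profiles, cfg, coupling=0.5)


class TestSimulateWeightsDeterminism:
    def test_seeded_noise_reproducible(self):
        w1 = simulate_grain_weights((20, 100, 0.2), range(5, 50, 5), 0.3, seed=4)
        w2 = simulate_grain_weights((20, 100, 0.2), range(5, 50, 5), 0.3, seed=4)
        assert w1 == w2
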