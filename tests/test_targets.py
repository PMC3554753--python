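"""Target-prediction tests: scoring, the six rules, scan oracle, monotonicity."""

from __future__ import annotations

import numpy as np
import pytest

from grainfill.fold import PAIR_BOND, revcomp
from grainfill.targets import (
    apply_rules,
    duplex_mfe,
    render_duplex,
    scan_transcriptome,
    score_duplex,
)


def perfect_site(mirna: str) -> str:
    """The transcript window that pairs the miRNA perfectly."""
    return revcomp(mirna)


def site_with_states(mirna: str, changes: dict[int, str]) -> str:
    """Build a site realising given per-position states (1-based miRNA pos).

    ``changes[pos]`` is ``"GU"`` or ``"MM"``; untouched positions stay WC.
    """
    faced = list(revcomp(mirna)[::-1])  # faced[i] pairs mirna[i]
    gu_partner = {"G": "T", "T": "G"}
    mm_partner = {"A": "C", "C": "A", "G": "A", "T": "C"}
    for pos, state in changes.items():
        base = mirna[pos - 1]
        if state == "GU":
            faced[pos - 1] = gu_partner[base]  # only G or T can wobble
        else:
            faced[pos - 1] = mm_partner[base]
    return "".join(reversed(faced))


MIRNA = "TGACGTACGTTACGATCGAGT"  # 21 nt


class TestScoreDuplex:
    def test_perfect_match_scores_zero(self):
        aln = score_duplex(MIRNA, perfect_site(MIRNA))
        assert aln.total_score == 0.0
        assert set(aln.states) == {"WC"}

    def test_single_gu_half_mismatch(self):
        site = site_with_states(MIRNA, {1: "GU"})  # position 1 is T -> G:U
        aln = score_duplex(MIRNA, site)
        assert aln.total_score == 0.5
        assert aln.states[0] == "GU"

    def test_eight_gu_scores_four(self):
        gu_positions = [i + 1 for i, b in enumerate(MIRNA) if b in "GT"][:8]
        assert len(gu_positions) == 8
        aln = score_duplex(MIRNA, site_with_states(MIRNA, {p: "GU" for p in gu_positions}))
        assert aln.total_score == 4.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            score_duplex("ACGT", "ACGTA")

    def test_strand_exchange_symmetry(self):
        # scoring is symmetric in the two strands of the duplex
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = "".join(rng.choice(list("ACGT"), 21))
            s = "".join(rng.choice(list("ACGT"), 21))
            assert score_duplex(m, s).total_score == score_duplex(s, m).total_score

    def test_revcomp_invariance_without_wobbles(self):
        site = site_with_states(MIRNA, {5: "MM"})
        a = score_duplex(MIRNA, site)
        b = score_duplex(revcomp(MIRNA), revcomp(site))
        assert "GU" not in a.states
        assert a.total_score == b.total_score


class TestApplyRules:
    def test_perfect_site_passes_all(self):
        flags = apply_rules(score_duplex(MIRNA, perfect_site(MIRNA)))
        assert flags.passed

    def test_mismatch_at_position_10_rejected(self):
        aln = score_duplex(MIRNA, site_with_states(MIRNA, {10: "MM"}))
        flags = apply_rules(aln)
        assert not flags.cleavage_site_ok
        assert not flags.passed

    def test_adjacent_mismatches_at_13_14(self):
        aln = score_duplex(MIRNA, site_with_states(MIRNA, {13: "MM", 14: "MM"}))
        flags = apply_rules(aln)
        assert flags.total_score_ok        # 2 <= 4
        assert flags.adjacency_ok          # run of 2 <= 2
        assert flags.seed_adjacency_ok     # both outside 2-12
        assert flags.cleavage_site_ok
        assert flags.seed_score_ok

    def test_adjacent_mismatches_inside_seed_rejected(self):
        aln = score_duplex(MIRNA, site_with_states(MIRNA, {5: "MM", 6: "MM"}))
        assert not apply_rules(aln).seed_adjacency_ok

    def test_seed_boundary_pair_12_13_allowed(self):
        # only one member of the adjacent pair lies in 2-12
        aln = score_duplex(MIRNA, site_with_states(MIRNA, {12: "MM", 13: "MM"}))
        assert apply_rules(aln).seed_adjacency_ok

    def test_three_adjacent_mismatches_rejected_anywhere(self):
        aln = score_duplex(MIRNA, site_with_states(MIRNA, {13: "MM", 14: "MM", 15: "MM"}))
        assert not apply_rules(aln).adjacency_ok

    def test_seed_score_above_2_5_rejected(self):
        aln = score_duplex(MIRNA, site_with_states(MIRNA, {2: "MM", 4: "MM", 6: "MM"}))
        assert sum({"WC": 0, "GU": 0.5, "MM": 1}[s] for s in aln.states[:12]) == 3.0
        assert not apply_rules(aln).seed_score_ok

    def test_gu_does_not_count_for_adjacency(self):
        site = site_with_states(MIRNA, {5: "GU", 6: "GU"})  # G, T: wobble-capable
        flags = apply_rules(score_duplex(MIRNA, site))
        assert flags.seed_adjacency_ok and flags.adjacency_ok

    def test_total_above_four_rejected(self):
        changes = {p: "MM" for p in (1, 3, 13, 15, 17)}
        aln = score_duplex(MIRNA, site_with_states(MIRNA, changes))
        assert aln.total_score == 5.0
        assert not apply_rules(aln).total_score_ok


class TestDuplexMFE:
    def test_perfect_site_ratio_one(self):
        aln = score_duplex(MIRNA, perfect_site(MIRNA))
        assert aln.mfe == aln.mfe_perfect
        assert apply_rules(aln).energy_ok

    def test_all_mismatch_fails_energy(self):
        site = "".join({"A": "C", "C": "A", "G": "A", "T": "C"}[b] for b in revcomp(MIRNA))
        aln = score_duplex(MIRNA, site)
        assert aln.mfe == 0.0
        assert not apply_rules(aln).energy_ok

    def test_hand_computed_toy_duplex(self):
        mirna = "GGGGGAAAAA"
        mfe, mfe_perfect = duplex_mfe(mirna, revcomp(mirna))
        # bonds 3,3,3,3,3,2,2,2,2,2 -> stacks: 4*3 + (3+2)/2 + 4*2
        assert mfe_perfect == pytest.approx(-(4 * 3 + 2.5 + 4 * 2))
        assert mfe == mfe_perfect


class TestScan:
    def naive_hits(self, mirnas, transcripts):
        """Independent re-implementation of the whole rule stack."""
        weight = {"WC": 0.0, "GU": 0.5, "MM": 1.0}
        wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
        gu = {("G", "T"), ("T", "G")}
        hits = set()
        for mid, m in mirnas.items():
            L = len(m)
            for tid, tx in transcripts.items():
                for i in range(len(tx) - L + 1):
                    win = tx[i:i + L]
                    states = []
                    for k in range(L):
                        pair = (m[k], win[L - 1 - k])
                        states.append("WC" if pair in wc else "GU" if pair in gu else "MM")
                    total = sum(weight[s] for s in states)
                    if total > 4:
                        continue
                    mm = [s == "MM" for s in states]
                    if any(mm[k] and mm[k + 1] and mm[k + 2] for k in range(L - 2)):
                        continue
                    if any(mm[k] and mm[k + 1] for k in range(1, 11)):  # pos 2..12
                        continue
                    if (len(mm) > 9 and mm[9]) or (len(mm) > 10 and mm[10]):
                        continue
                    if sum(weight[s] for s in states[:12]) > 2.5:
                        continue
                    from grainfill.fold import duplex_energy

                    e = duplex_energy(m, win)
                    ep = duplex_energy(m, revcomp(m))
                    if abs(e) < 0.75 * abs(ep):
                        continue
                    hits.add((mid, tid, i))
        return hits

    def test_scan_equals_naive_oracle(self):
        rng = np.random.default_rng(12)
        mirnas = {
            f"m{i}": "".join(rng.choice(list("ACGT"), 21)) for i in range(2)
        }
        transcripts = {
            f"t{i}": "".join(rng.choice(list("ACGT"), 400)) for i in range(3)
        }
        # plant a perfect site and a near-miss
        transcripts["t0"] = (
            transcripts["t0"][:100] + revcomp(mirnas["m0"]) + transcripts["t0"][100:]
        )
        got = {(h.mirna_id, h.transcript_id, h.start) for h in
               scan_transcriptome(mirnas, transcripts)}
        assert got == self.naive_hits(mirnas, transcripts)
        assert ("m0", "t0", 100) in got

    def test_planted_sites_recovered(self, simulation, dge_data):
        _, _, truth = simulation
        transcripts, _, _ = dge_data
        mirnas = {m.planted_id: m.mature for m in truth.planted_mirnas}
        hits = scan_transcriptome(mirnas, transcripts)
        hit_keys = {(h.mirna_id, h.transcript_id, h.start) for h in hits}
        for mid, targets in truth.planted_targets.items():
            for t in targets:
                assert (mid, t.transcript_id, t.site_start) in hit_keys

    def test_no_duplicate_hits(self, simulation, dge_data):
        _, _, truth = simulation
        transcripts, _, _ = dge_data
        mirnas = {m.planted_id: m.mature for m in truth.planted_mirnas}
        hits = scan_transcriptome(mirnas, transcripts)
        keys = [(h.mirna_id, h.transcript_id, h.start) for h in hits]
        assert len(keys) == len(set(keys))


class TestMonotonicity:
    def test_wc_to_mismatch_never_rescues(self):
        rng = np.random.default_rng(21)
        mm_partner = {"A": "C", "C": "A", "G": "A", "T": "C"}
        for _ in range(40):
            m = "".join(rng.choice(list("ACGT"), 21))
            # start near the acceptance boundary with a couple of defects
            site = site_with_states(m, {int(rng.integers(1, 22)): "MM"})
            base_flags = apply_rules(score_duplex(m, site))
            wc_positions = [
                i for i, s in enumerate(score_duplex(m, site).states) if s == "WC"
            ]
            if not wc_positions:
                continue
            i = int(rng.choice(wc_positions))
            faced = list(site[::-1])
            faced[i] = mm_partner[m[i]]
            worse = "".join(reversed(faced))
            worse_flags = apply_rules(score_duplex(m, worse))
            if not base_flags.passed:
                assert not worse_flags.passed


class TestRender:
    def test_render_marks(self):
        aln = score_duplex(MIRNA, site_with_states(MIRNA, {1: "GU", 5: "MM"}))
        text = render_duplex(aln)
        lines = text.splitlines()
        assert lines[1].strip(" ").count(":") == 1
        assert "|" in lines[1]
        assert lines[2].endswith("3'")
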