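"""Rule-based miRNA target prediction.

A miRNA is aligned, ungapped, against every same-length window of each
transcript; position ``i`` of the miRNA (1-based from its 5' end) faces the
window read 3'->5'.  Each position is Watson-Crick, G:U wobble, or a
mismatch; G:U counts 0.5 towards the weighted mismatch sums but does not
count as a mismatch for the adjacency rules.  A window is a target site when
all six rules hold:

1. weighted mismatches <= 4 over the whole duplex;
2. no run of more than two adjacent mismatches anywhere;
3. no adjacent mismatches within positions 2-12;
4. no mismatch at position 10 or 11;
5. weighted mismatches over positions 1-12 <= 2.5;
6. duplex free energy >= 75 % of the energy against the perfect-complement
   site (both negative: ``|mfe| >= 0.75 * |mfe_perfect|``).

Bulged (gapped) sites are out of scope: the positional rules are only
well-defined for an ungapped core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .fold import duplex_energy, normalize, pair_state, revcomp

WEIGHT = {"WC": 0.0, "GU": 0.5, "MM": 1.0}

MAX_TOTAL_SCORE = 4.0
MAX_SEED_SCORE = 2.5
MFE_RATIO = 0.75
SEED_RANGE = (1, 12)  # 1-based, inclusive
CLEAVAGE_POSITIONS = (10, 11)


@dataclass
class DuplexAlignment:
    """An ungapped miRNA:site pairing with per-position states."""

    mirna: str  # 5'->3'
    site: str  # target window, 5'->3'
    states: tuple[str, ...]  # per miRNA position from its 5' end
    total_score: float
    mfe: float
    mfe_perfect: float

    @property
    def mfe_ratio(self) -> float:
        return self.mfe / self.mfe_perfect if self.mfe_perfect != 0 else 0.0


@dataclass(frozen=True)
class RuleFlags:
    total_score_ok: bool
    adjacency_ok: bool
    seed_adjacency_ok: bool
    cleavage_site_ok: bool
    seed_score_ok: bool
    energy_ok: bool

    @property
    def passed(self) -> bool:
        return all(
            (self.total_score_ok, self.adjacency_ok, self.seed_adjacency_ok,
             self.cleavage_site_ok, self.seed_score_ok, self.energy_ok)
        )

    def as_tuple(self) -> tuple[bool, ...]:
        return (self.total_score_ok, self.adjacency_ok, self.seed_adjacency_ok,
                self.cleavage_site_ok, self.seed_score_ok, self.energy_ok)


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int  # 0-based half-open on the transcript
    end: int
    alignment: DuplexAlignment
    flags: RuleFlags


def duplex_mfe(mirna: str, site: str) -> tuple[float, float]:
    """Hybridisation energy of miRNA vs site, and vs its perfect match.

    Both under the shared stacking model; the perfect-match reference is the
    miRNA bound to its exact reverse complement.
    """
    mirna = normalize(mirna)
    site = normalize(site)
    return duplex_energy(mirna, site), duplex_energy(mirna, revcomp(mirna))


def score_duplex(mirna: str, site: str) -> DuplexAlignment:
    """Score an ungapped duplex; G:U wobbles weigh 0.5, mismatches 1."""
    mirna = normalize(mirna)
    site = normalize(site)
    if len(mirna) != len(site):
        raise ValueError("miRNA and site must have equal length (ungapped core)")
    faced = site[::-1]  # site read 3'->5' against the miRNA 5'->3'
    states = tuple(pair_state(m, t) for m, t in zip(mirna, faced))
    total = sum(WEIGHT[s] for s in states)
    mfe, mfe_perfect = duplex_mfe(mirna, site)
    return DuplexAlignment(mirna, site, states, total, mfe, mfe_perfect)


def apply_rules(alignment: DuplexAlignment) -> RuleFlags:
    """Evaluate the six acceptance rules on a scored duplex."""
    states = alignment.states
    L = len(states)
    mm = [s == "MM" for s in states]

    longest = run = 0
    for f in mm:
        run = run + 1 if f else 0
        longest = max(longest, run)

    lo, hi = SEED_RANGE
    seed_adjacent = any(
        mm[i - 1] and mm[i]
        for i in range(1, L)
        # a pair (i, i+1) violates only when both positions lie in 2..12
        if max(2, lo) <= i <= hi - 1 and i + 1 <= hi
    )
    cleavage_mm = any(mm[p - 1] for p in CLEAVAGE_POSITIONS if p <= L)
    seed_score = sum(WEIGHT[states[i]] for i in range(min(hi, L)))

    energy_ok = abs(alignment.mfe) >= MFE_RATIO * abs(alignment.mfe_perfect)
    return RuleFlags(
        total_score_ok=alignment.total_score <= MAX_TOTAL_SCORE,
        adjacency_ok=longest <= 2,
        seed_adjacency_ok=not seed_adjacent,
        cleavage_site_ok=not cleavage_mm,
        seed_score_ok=seed_score <= MAX_SEED_SCORE,
        energy_ok=energy_ok,
    )


def scan_transcriptome(
    mirnas: Mapping[str, str], transcripts: Mapping[str, str]
) -> list[TargetHit]:
    """Evaluate every window of each transcript against each miRNA.

    Scanning is on the mRNA sense strand only; hits are windows passing all
    six rules, in deterministic (mirna, transcript, position) order.
    """
    hits: list[TargetHit] = []
    for mirna_id in sorted(mirnas):
        mirna = normalize(mirnas[mirna_id])
        L = len(mirna)
        for tx_id in sorted(transcripts):
            seq = normalize(transcripts[tx_id])
            for start in range(0, len(seq) - L + 1):
                aln = score_duplex(mirna, seq[start:start + L])
                flags = apply_rules(aln)
                if flags.passed:
                    hits.append(TargetHit(mirna_id, tx_id, start, start + L, aln, flags))
    return hits


def render_duplex(alignment: DuplexAlignment) -> str:
    """Text rendering with Watson-Crick bars and G:U colons.

    The target site is drawn 3'->5' on the top line so that paired positions
    line up with the miRNA below.
    """
    marks = {"WC": "|", "GU": ":", "MM": " "}
    top = alignment.site[::-1]
    bars = "".join(marks[s] for s in alignment.states)
    return (
        f"target 3' {top} 5'\n"
        f"          {bars}\n"
        f"miRNA  5' {alignment.mirna} 3'"
    )


def hits_to_rows(hits: Iterable[TargetHit]) -> list[dict]:
    """Flatten hits for tabular export."""
    rows = []
    for h in hits:
        rows.append(
            {
                "mirna": h.mirna_id,
                "transcript": h.transcript_id,
                "start": h.start,
                "end": h.end,
                "score": h.alignment.total_score,
                "mfe": h.alignment.mfe,
                "mfe_ratio": round(h.alignment.mfe_ratio, 4),
                **{
                    f"rule{i + 1}": ok
                    for i, ok in enumerate(h.flags.as_tuple())
                },
            }
        )
    return rows
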