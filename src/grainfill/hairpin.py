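"""Hairpin-based discovery of novel miRNAs from unannotated reads.

Candidate windows around unannotated read loci are folded under the package
energy model (:mod:`grainfill.fold`) and kept when the mature:star duplex
satisfies the MIREAP-style criteria:

* mature length 18-25 nt,
* precursor MFE <= -18 kcal/mol,
* >= 16 base pairs between the mature and star arms,
* largest bulge <= 4 nt, duplex asymmetry <= 4 nt,
* mature-star spacing <= 300 nt.

Survivors are promoted to novel miRNAs when a star read is observed in at
least one library (evidence ``star``) and/or the mature read is observed in
more than half of the libraries (evidence ``expression``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotation import MATURE_WINDOW, ClassifiedRead, CollapsedRead
from .fold import FoldResult, fold_window, normalize, revcomp

# duplex acceptance thresholds (documented criteria, inclusive bounds)
MIN_MATURE_LEN = 18
MAX_MATURE_LEN = 25
MAX_PRECURSOR_MFE = -18.0  # kcal/mol
MIN_PAIRED_BASES = 16
MAX_BULGE = 4
MAX_ASYMMETRY = 4
MAX_STAR_SPACING = 300
#: extra genomic sequence kept on each side of the trimmed precursor
FLANK = 20
#: half-width of the initial window around a read locus
WINDOW_RADIUS = 150
#: minimum window length accepted by the folder
MIN_WINDOW_LEN = 40


@dataclass
class DuplexMetrics:
    paired_bases: int
    max_bulge: int
    asymmetry: int
    loop_space: int


@dataclass
class HairpinCandidate:
    """A folded candidate locus with its mature/star geometry."""

    locus: tuple[int, int, str]  # genomic window (start, end, strand)
    precursor: str
    mature: str
    mature_span: tuple[int, int]  # within precursor
    arm: str  # "5p" | "3p"
    star: str | None
    star_span: tuple[int, int] | None
    mfe: float
    structure: str
    metrics: DuplexMetrics | None
    mature_read: CollapsedRead | None = None

    @property
    def mature_locus(self) -> tuple[int, int, str]:
        """Genomic span of the mature product."""
        lo, hi, strand = self.locus
        ms, me = self.mature_span
        if strand == "+":
            return (lo + ms, lo + me, strand)
        return (hi - me, hi - ms, strand)


@dataclass(frozen=True)
class CriteriaResult:
    length_ok: bool
    mfe_ok: bool
    paired_ok: bool
    bulge_ok: bool
    asymmetry_ok: bool
    spacing_ok: bool

    @property
    def passed(self) -> bool:
        return all(
            (self.length_ok, self.mfe_ok, self.paired_ok,
             self.bulge_ok, self.asymmetry_ok, self.spacing_ok)
        )

    def failures(self) -> list[str]:
        names = ("length", "mfe", "paired_bases", "bulge", "asymmetry", "spacing")
        flags = (self.length_ok, self.mfe_ok, self.paired_ok,
                 self.bulge_ok, self.asymmetry_ok, self.spacing_ok)
        return [n for n, ok in zip(names, flags) if not ok]


@dataclass
class NovelMiRNA:
    novel_id: str
    mature: str
    tpm: dict[str, float]
    evidence: str  # "star" | "expression" | "both"
    candidate: HairpinCandidate | None = field(default=None, repr=False)

    @property
    def length(self) -> int:
        return len(self.mature)


def extract_candidates(
    unannotated: Sequence[ClassifiedRead],
    genome: str,
    flank: int = FLANK,
    radius: int = WINDOW_RADIUS,
) -> list[tuple[tuple[int, int, str], str]]:
    """Candidate windows around unannotated read loci.

    Each mapped locus is expanded by ``radius`` nt per side plus the
    precursor ``flank``, clipped at the genome ends; overlapping windows on
    the same strand are merged.  Returns ``(locus, window sequence)`` pairs
    with the window sequence given 5'->3' on the read strand.
    """
    intervals: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
    for cr in unannotated:
        for start, end, strand in cr.loci:
            lo = max(0, start - radius - flank)
            hi = min(len(genome), end + radius + flank)
            intervals[strand].append((lo, hi))
    out: list[tuple[tuple[int, int, str], str]] = []
    for strand, ivs in intervals.items():
        for lo, hi in merge_intervals(ivs):
            seq = genome[lo:hi]
            if strand == "-":
                seq = revcomp(seq)
            out.append(((lo, hi, strand), seq))
    out.sort(key=lambda t: (t[0][0], t[0][2]))
    return out


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching half-open intervals."""
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def fold_and_score(window: str) -> FoldResult | None:
    """Fold a candidate window; ``None`` signals a window too short to fold."""
    if len(window) < MIN_WINDOW_LEN:
        return None
    return fold_window(window)


def build_candidate(
    locus: tuple[int, int, str],
    window: str,
    mature_read: CollapsedRead,
    radius: int = WINDOW_RADIUS,
    flank: int = FLANK,
) -> HairpinCandidate | None:
    """Fold the precursor around a putative mature read.

    The window is trimmed to the mature locus plus ``radius + flank`` nt per
    side before folding (merged windows can be long; the precursor itself is
    bounded by the mature-star spacing limit).  The star is the opposite-arm
    region the mature's pairing partners imply under the fold.  Returns
    ``None`` when the read does not occur in the window or the trimmed
    window is too short to fold.
    """
    window = normalize(window)
    pos = window.find(mature_read.sequence)
    if pos == -1:
        return None
    ts = max(0, pos - radius - flank)
    te = min(len(window), pos + len(mature_read.sequence) + radius + flank)
    precursor = window[ts:te]
    lo, hi, strand = locus
    if strand == "+":
        trimmed_locus = (lo + ts, lo + te, strand)
    else:
        trimmed_locus = (hi - te, hi - ts, strand)
    fold = fold_and_score(precursor)
    if fold is None:
        return None
    window, locus = precursor, trimmed_locus
    ms = pos - ts
    me = ms + len(mature_read.sequence)
    pairs = fold.pair_table
    # The star arm is where the bulk of the mature's partners lie.  Stray
    # pairings of a base or two elsewhere (energy ties, flank structure) are
    # ignored: partners are clustered by position, splitting at gaps larger
    # than the bulge limit, and the largest cluster defines the star span.
    partners = sorted(
        pairs[i] for i in range(ms, me)
        if pairs[i] != -1 and not (ms <= pairs[i] < me)
    )
    clusters: list[list[int]] = []
    for p in partners:
        if clusters and p - clusters[-1][-1] <= MAX_BULGE + 1:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    star_span: tuple[int, int] | None = None
    star: str | None = None
    metrics: DuplexMetrics | None = None
    if clusters:
        best = max(clusters, key=len)
        star_span = (best[0], best[-1] + 1)
        star = window[star_span[0]:star_span[1]]
        metrics = _duplex_metrics(pairs, (ms, me), star_span)
    arm = "5p" if star_span is None or ms < star_span[0] else "3p"
    return HairpinCandidate(
        locus=locus, precursor=window, mature=mature_read.sequence,
        mature_span=(ms, me), arm=arm, star=star, star_span=star_span,
        mfe=fold.mfe, structure=fold.structure, metrics=metrics,
        mature_read=mature_read,
    )


def _duplex_metrics(
    pairs: Sequence[int], mature_span: tuple[int, int], star_span: tuple[int, int]
) -> DuplexMetrics:
    ms, me = mature_span
    ss, se = star_span
    paired = sum(1 for i in range(ms, me) if ss <= pairs[i] < se)
    unpaired_mature = [pairs[i] == -1 or not (ss <= pairs[i] < se)
                       for i in range(ms, me)]
    unpaired_star = [pairs[i] == -1 or not (ms <= pairs[i] < me)
                     for i in range(ss, se)]
    bulge = max(_longest_run(unpaired_mature), _longest_run(unpaired_star))
    asymmetry = abs(sum(unpaired_mature) - sum(unpaired_star))
    loop_space = ss - me if ss >= me else ms - se
    return DuplexMetrics(paired, bulge, asymmetry, loop_space)


def _longest_run(flags: Sequence[bool]) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def check_duplex_criteria(candidate: HairpinCandidate) -> CriteriaResult:
    """Evaluate the six duplex acceptance criteria (inclusive thresholds)."""
    m = candidate.metrics
    return CriteriaResult(
        length_ok=MIN_MATURE_LEN <= len(candidate.mature) <= MAX_MATURE_LEN,
        mfe_ok=candidate.mfe <= MAX_PRECURSOR_MFE,
        paired_ok=m is not None and m.paired_bases >= MIN_PAIRED_BASES,
        bulge_ok=m is not None and m.max_bulge <= MAX_BULGE,
        asymmetry_ok=m is not None and m.asymmetry <= MAX_ASYMMETRY,
        spacing_ok=m is not None and 0 <= m.loop_space <= MAX_STAR_SPACING,
    )


def star_sequence_set(candidate: HairpinCandidate, window: int = MATURE_WINDOW) -> set[str]:
    """All sequences matching the star arm within a +-``window`` nt shift."""
    if candidate.star_span is None:
        return set()
    ss, se = candidate.star_span
    seqs = set()
    for ds in range(-window, window + 1):
        for de in range(-window, window + 1):
            lo, hi = ss + ds, se + de
            if 0 <= lo < hi <= len(candidate.precursor):
                seqs.add(candidate.precursor[lo:hi])
    return seqs


def classify_evidence(
    candidate: HairpinCandidate,
    libraries: Mapping[str, Mapping[str, int]],
) -> str | None:
    """Evidence class of a candidate against per-stage sequence->count maps.

    ``star``: a read matching the star arm (+-2 nt) in >= 1 library;
    ``expression``: the mature read observed in more than half of the
    libraries (>= 3 of 5); ``both`` when both hold; ``None`` = rejected.
    """
    stars = star_sequence_set(candidate)
    star_seen = any(
        lib.get(s, 0) > 0 for lib in libraries.values() for s in stars
    )
    n_with_mature = sum(
        1 for lib in libraries.values() if lib.get(candidate.mature, 0) > 0
    )
    majority = len(libraries) // 2 + 1
    expressed = n_with_mature >= majority
    if star_seen and expressed:
        return "both"
    if star_seen:
        return "star"
    if expressed:
        return "expression"
    return None


@dataclass
class DiscoveryReport:
    novel: list[NovelMiRNA]
    rejected: list[tuple[HairpinCandidate, list[str]]]


def discover(
    unannotated: Sequence[ClassifiedRead],
    genome: str,
    libraries: Mapping[str, Mapping[str, int]],
    totals: Mapping[str, int],
    known_precursors: Sequence[tuple[int, int]] = (),
    min_candidate_count: int = 2,
) -> DiscoveryReport:
    """Full discovery pass: windows -> fold -> criteria -> evidence.

    ``libraries`` maps stage -> {sequence: raw count}; ``totals`` gives the
    per-stage clean-read totals used for TPM.  Within a (possibly merged)
    window, reads are considered in descending abundance; once a read has
    seeded a candidate, reads within its precursor neighbourhood (the star,
    isomiRs) do not seed further candidates.  Reads with a library-wide
    count below ``min_candidate_count`` never seed a candidate.  Candidates
    overlapping a known precursor interval are never emitted.
    """
    windows = extract_candidates(unannotated, genome)
    novel: list[NovelMiRNA] = []
    rejected: list[tuple[HairpinCandidate, list[str]]] = []
    n = 0
    exclusion = WINDOW_RADIUS + FLANK
    for locus, window in windows:
        lo, hi, strand = locus
        in_window = [
            cr.read for cr in unannotated
            if any(s == strand and lo <= a and b <= hi for a, b, s in cr.loci)
        ]
        in_window.sort(key=lambda r: (-r.total, r.sequence))
        used: list[tuple[int, int]] = []
        for read in in_window:
            if read.total < min_candidate_count:
                continue
            pos = window.find(read.sequence)
            if pos == -1:
                continue
            if any(a - exclusion < pos < b + exclusion for a, b in used):
                continue
            cand = build_candidate(locus, window, read)
            if cand is None:
                continue
            g_ms, g_me, _ = cand.mature_locus
            if any(g_ms < ke and ks < g_me for ks, ke in known_precursors):
                continue
            used.append((pos, pos + len(read.sequence)))
            crit = check_duplex_criteria(cand)
            if not crit.passed:
                rejected.append((cand, crit.failures()))
                continue
            evidence = classify_evidence(cand, libraries)
            if evidence is None:
                rejected.append((cand, ["evidence"]))
                continue
            n += 1
            tpm = {
                stage: libraries[stage].get(cand.mature, 0) / totals[stage] * 1e6
                for stage in libraries
            }
            novel.append(
                NovelMiRNA(f"novel-{n}-{cand.arm}", cand.mature, tpm, evidence, cand)
            )
    return DiscoveryReport(novel, rejected)
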