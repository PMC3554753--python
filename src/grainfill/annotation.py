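"""Small-RNA read collapsing, mapping, classification and quantification.

Classification follows a strict priority rule so that every unique read gets
exactly one annotation category::

    rRNA > tRNA > snRNA > snoRNA > known miRNA > repeat > exon > intron

(within the structural-RNA block a GenBank-like feature set is consulted
before an Rfam-like one).  Exon and intron hits are split into sense and
antisense by comparing the read strand with the gene strand; reads that map
nowhere, or only outside every track, fall through to ``no_annotation``.

All genomic coordinates are 0-based half-open.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fold import normalize, revcomp

#: reporting categories, in the order used by the classification table
CATEGORIES = (
    "exon_antisense",
    "exon_sense",
    "intron_antisense",
    "intron_sense",
    "known_miRNA",
    "rRNA",
    "repeat",
    "snRNA",
    "snoRNA",
    "tRNA",
    "no_annotation",
)

MIN_READ_LEN = 18
MAX_READ_LEN = 30

#: half-width of the positional window used to match mature/star reads
MATURE_WINDOW = 2


@dataclass
class CollapsedRead:
    """A unique small-RNA sequence with per-stage raw counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __post_init__(self) -> None:
        self.sequence = normalize(self.sequence)


@dataclass(frozen=True)
class Feature:
    """A typed genomic interval (0-based half-open)."""

    start: int
    end: int
    strand: str = "+"
    feature_id: str = ""
    source: str = "genbank"  # consulted before "rfam" within a category

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class MatureAnnotation:
    """An annotated mature (or star) product within a precursor."""

    mature_id: str
    start: int  # genomic
    end: int
    arm: str  # "5p" | "3p" | "star"


@dataclass(frozen=True)
class PrecursorAnnotation:
    precursor_id: str
    start: int
    end: int
    strand: str
    matures: tuple[MatureAnnotation, ...] = ()

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class AnnotationTrackSet:
    """Prioritised feature sets used for read classification."""

    rrna: list[Feature] = field(default_factory=list)
    trna: list[Feature] = field(default_factory=list)
    snrna: list[Feature] = field(default_factory=list)
    snorna: list[Feature] = field(default_factory=list)
    mirna_precursors: list[PrecursorAnnotation] = field(default_factory=list)
    repeats: list[Feature] = field(default_factory=list)
    exons: list[Feature] = field(default_factory=list)  # strand = gene strand
    introns: list[Feature] = field(default_factory=list)

    def priority_order(self):
        """(category, features) in classification priority order.

        Within each structural-RNA category, GenBank-like features sort
        before Rfam-like ones; the resulting category label is unaffected.
        """
        by_source = lambda fs: sorted(fs, key=lambda f: f.source != "genbank")
        return (
            ("rRNA", by_source(self.rrna)),
            ("tRNA", by_source(self.trna)),
            ("snRNA", by_source(self.snrna)),
            ("snoRNA", by_source(self.snorna)),
            ("known_miRNA", self.mirna_precursors),
            ("repeat", self.repeats),
            ("exon", self.exons),
            ("intron", self.introns),
        )


@dataclass
class ClassifiedRead:
    read: CollapsedRead
    category: str
    loci: list[tuple[int, int, str]] = field(default_factory=list)
    mature_id: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def collapse(reads: Iterable[tuple[str, str]]) -> list[CollapsedRead]:
    """Collapse (sequence, stage) observations into unique-read records.

    Order of first appearance is preserved; per-stage counts are conserved.
    """
    order: dict[str, CollapsedRead] = {}
    for seq, stage in reads:
        seq = normalize(seq)
        rec = order.get(seq)
        if rec is None:
            rec = order[seq] = CollapsedRead(seq, {})
        rec.counts[stage] = rec.counts.get(stage, 0) + 1
    return list(order.values())


def map_to_genome(read: str, genome: str) -> list[tuple[int, int, str]]:
    """All perfect-match loci of ``read`` on both strands of ``genome``.

    Returns ``(start, end, strand)`` triples, 0-based half-open on the plus
    strand reference, sorted by position.  A minus-strand locus means the
    read equals the reverse complement of ``genome[start:end]``.
    """
    read = normalize(read)
    loci: list[tuple[int, int, str]] = []
    for query, strand in ((read, "+"), (revcomp(read), "-")):
        pos = genome.find(query)
        while pos != -1:
            loci.append((pos, pos + len(read), strand))
            pos = genome.find(query, pos + 1)
    loci.sort(key=lambda t: (t[0], t[2]))
    return loci


def match_known_mature(
    locus: tuple[int, int, str],
    precursor: PrecursorAnnotation,
    window: int = MATURE_WINDOW,
) -> str | None:
    """Match a read locus against annotated mature/star products.

    A read is accepted as a given product when its start lies within
    ``window`` nt of the annotated start *and* its end within ``window`` nt
    of the annotated end.
    """
    start, end, strand = locus
    if strand != precursor.strand:
        return None
    for mat in precursor.matures:
        if abs(start - mat.start) <= window and abs(end - mat.end) <= window:
            return mat.mature_id
    return None


def classify(
    read: CollapsedRead,
    loci: Sequence[tuple[int, int, str]],
    tracks: AnnotationTrackSet,
) -> ClassifiedRead:
    """Assign the single highest-priority category over all loci of a read.

    Multi-locus reads are classified once by their best annotation; counts
    are never split.  Sense beats antisense within the exon and intron
    categories when both occur.
    """
    best_rank = len(CATEGORIES)
    best_cat = "no_annotation"
    best_mature: str | None = None
    # rank table: lower = higher priority; sense before antisense
    ranks = {
        "rRNA": 0, "tRNA": 1, "snRNA": 2, "snoRNA": 3, "known_miRNA": 4,
        "repeat": 5, "exon_sense": 6, "exon_antisense": 7,
        "intron_sense": 8, "intron_antisense": 9, "no_annotation": 10,
    }
    for category, features in tracks.priority_order():
        for start, end, strand in loci:
            for feat in features:
                if not feat.overlaps(start, end):
                    continue
                if category == "known_miRNA":
                    cat = "known_miRNA"
                    mature = match_known_mature((start, end, strand), feat)
                elif category in ("exon", "intron"):
                    sense = strand == feat.strand
                    cat = f"{category}_{'sense' if sense else 'antisense'}"
                    mature = None
                else:
                    cat, mature = category, None
                if ranks[cat] < best_rank:
                    best_rank, best_cat, best_mature = ranks[cat], cat, mature
    return ClassifiedRead(read, best_cat, list(loci), best_mature)


def classify_all(
    reads: Iterable[CollapsedRead],
    genome: str,
    tracks: AnnotationTrackSet,
) -> list[ClassifiedRead]:
    """Map and classify every collapsed read."""
    return [classify(r, map_to_genome(r.sequence, genome), tracks) for r in reads]


def partition_table(
    classified: Iterable[ClassifiedRead], stages: Sequence[str]
) -> pd.DataFrame:
    """Category x (stage, unique|total) partition of a classified read set.

    Mirrors the layout of the published small-RNA class summary; the per
    stage column sums equal the library totals (every unique read is in
    exactly one category).
    """
    cols = pd.MultiIndex.from_product([stages, ["unique", "total"]])
    table = pd.DataFrame(0, index=list(CATEGORIES), columns=cols)
    for cr in classified:
        for stage in stages:
            n = cr.read.counts.get(stage, 0)
            if n > 0:
                table.loc[cr.category, (stage, "unique")] += 1
                table.loc[cr.category, (stage, "total")] += n
    return table


def size_distribution(
    classified: Iterable[ClassifiedRead | CollapsedRead],
    level: str = "unique",
) -> dict[str, dict[int, float]]:
    """Per-stage read-length distribution, as fractions summing to 1.

    ``level="unique"`` counts each distinct sequence once per stage in which
    it occurs; ``level="total"`` weights by raw counts.
    """
    if level not in ("unique", "total"):
        raise ValueError("level must be 'unique' or 'total'")
    acc: dict[str, Counter] = defaultdict(Counter)
    for item in classified:
        read = item.read if isinstance(item, ClassifiedRead) else item
        for stage, n in read.counts.items():
            if n > 0:
                acc[stage][len(read.sequence)] += 1 if level == "unique" else n
    out: dict[str, dict[int, float]] = {}
    for stage, counter in acc.items():
        total = sum(counter.values())
        out[stage] = {length: c / total for length, c in sorted(counter.items())}
    return out


def tpm_normalize(
    raw: pd.DataFrame, totals: Mapping[str, int]
) -> pd.DataFrame:
    """Scale raw counts to transcripts per million.

    ``TPM(i, s) = raw(i, s) / totals[s] * 1e6``.  ``totals`` are the total
    clean reads (or clean tags) per stage library, not only the mappable
    ones.
    """
    scale = {}
    for stage in raw.columns:
        t = totals[stage]
        if t <= 0:
            raise ValueError(f"non-positive library total for stage {stage!r}")
        scale[stage] = 1e6 / t
    return raw.astype(float).mul(pd.Series(scale), axis=1)


def counts_matrix(
    reads: Iterable[CollapsedRead], stages: Sequence[str],
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Raw count matrix (rows = sequences or supplied ids, columns = stages)."""
    reads = list(reads)
    index = list(ids) if ids is not None else [r.sequence for r in reads]
    data = [[r.counts.get(s, 0) for s in stages] for r in reads]
    return pd.DataFrame(data, index=index, columns=list(stages))


@dataclass(frozen=True)
class StarRatio:
    mature_id: str
    star_id: str
    stage: str
    ratio: float  # inf when mature TPM is 0 and star TPM > 0
    star_dominant: bool


def star_ratio(
    matrix: pd.DataFrame, pairs: Iterable[tuple[str, str]]
) -> list[StarRatio]:
    """Per-stage star:mature TPM ratios, flagged when the star dominates.

    A zero mature TPM with positive star TPM yields ``ratio = inf`` (flagged
    star-dominant); 0/0 yields ``nan`` and no flag.
    """
    out: list[StarRatio] = []
    for mature_id, star_id in pairs:
        for stage in matrix.columns:
            m = float(matrix.loc[mature_id, stage])
            s = float(matrix.loc[star_id, stage])
            if m > 0:
                ratio = s / m
            elif s > 0:
                ratio = float("inf")
            else:
                ratio = float("nan")
            out.append(StarRatio(mature_id, star_id, stage, ratio, ratio > 1))
    return out
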