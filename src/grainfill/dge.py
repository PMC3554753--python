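"""NlaIII/MmeI digital gene expression tag profiling.

A canonical tag is the CATG recognition site plus the 17 nt immediately
downstream (21 nt total).  Observed tags are filtered (length exactly 21,
CATG prefix, more than one occurrence per library), mapped to transcripts
through their canonical tag sets, summed per gene, and TPM-normalised
against the per-stage total clean tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import tpm_normalize
from .fold import normalize

ANCHOR = "CATG"
TAG_TAIL = 17
TAG_LEN = len(ANCHOR) + TAG_TAIL  # 21
MIN_LIBRARY_COUNT = 2  # tags sequenced only once in a library are dropped


@dataclass
class CanonicalTag:
    sequence: str
    position: int  # 0-based CATG start on the transcript
    primary: bool  # 3'-most extractable site


@dataclass
class DGETag:
    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = normalize(self.sequence)
        if len(self.sequence) != TAG_LEN or not self.sequence.startswith(ANCHOR):
            raise ValueError(f"not a valid {TAG_LEN}-nt {ANCHOR} tag: {self.sequence!r}")


@dataclass
class GeneExpression:
    gene_id: str
    counts: dict[str, int]
    tpm: dict[str, float]
    ambiguous_tags: int = 0


def canonical_tags(transcript: str) -> list[CanonicalTag]:
    """Canonical tags of a transcript, one per usable CATG site.

    Sites with fewer than 17 nt downstream are skipped; the 3'-most usable
    site is flagged primary (the bead-bound fragment the protocol retains).
    An empty list means the transcript cannot be tag-profiled.
    """
    transcript = normalize(transcript)
    tags: list[CanonicalTag] = []
    pos = transcript.find(ANCHOR)
    while pos != -1:
        if pos + TAG_LEN <= len(transcript):
            tags.append(CanonicalTag(transcript[pos:pos + TAG_LEN], pos, False))
        pos = transcript.find(ANCHOR, pos + 1)
    if tags:
        tags[-1] = CanonicalTag(tags[-1].sequence, tags[-1].position, True)
    return tags


def filter_tags(
    raw: Mapping[str, Mapping[str, int]], stages: Sequence[str]
) -> list[DGETag]:
    """Filter observed tags: 21 nt, CATG prefix, count >= 2 per library.

    ``raw`` maps tag sequence -> stage -> count.  Counts below the
    per-library threshold are zeroed (the filter runs per library); tags
    left with no counts, wrong length or missing anchor are dropped.
    """
    kept: list[DGETag] = []
    for seq in raw:
        norm = normalize(seq)
        if len(norm) != TAG_LEN or not norm.startswith(ANCHOR):
            continue
        counts = {
            s: c for s in stages
            if (c := raw[seq].get(s, 0)) >= MIN_LIBRARY_COUNT
        }
        if counts:
            kept.append(DGETag(norm, counts))
    return kept


def quantify_genes(
    tags: Iterable[DGETag],
    transcripts: Mapping[str, str],
    stages: Sequence[str],
    totals: Mapping[str, int] | None = None,
    exclude_ambiguous: bool = False,
) -> list[GeneExpression]:
    """Assign filtered tags to genes and sum counts per gene per stage.

    A tag is assigned to every gene whose canonical tag set contains it;
    multi-gene tags are flagged ambiguous (and skipped entirely under
    ``exclude_ambiguous``).  TPM uses the supplied per-stage totals, or the
    per-stage sum of all filtered tag counts when not given.
    """
    index: dict[str, list[str]] = {}
    for gene_id, seq in transcripts.items():
        for tag in canonical_tags(seq):
            index.setdefault(tag.sequence, []).append(gene_id)

    tags = list(tags)
    if totals is None:
        totals = {
            s: sum(t.counts.get(s, 0) for t in tags) for s in stages
        }

    counts: dict[str, dict[str, int]] = {
        g: {s: 0 for s in stages} for g in transcripts
    }
    ambiguous: dict[str, int] = {g: 0 for g in transcripts}
    for tag in tags:
        genes = index.get(tag.sequence, [])
        if not genes:
            continue
        if len(genes) > 1:
            if exclude_ambiguous:
                continue
            for g in genes:
                ambiguous[g] += 1
        for g in genes:
            for s in stages:
                counts[g][s] += tag.counts.get(s, 0)

    raw = pd.DataFrame(
        [[counts[g][s] for s in stages] for g in transcripts],
        index=list(transcripts), columns=list(stages),
    )
    safe_totals = {s: max(1, totals.get(s, 0)) for s in stages}
    tpm = tpm_normalize(raw, safe_totals)
    return [
        GeneExpression(
            g, counts[g], {s: float(tpm.loc[g, s]) for s in stages}, ambiguous[g]
        )
        for g in transcripts
    ]


def expression_matrix(
    genes: Iterable[GeneExpression], stages: Sequence[str]
) -> pd.DataFrame:
    """Gene x stage TPM matrix."""
    genes = list(genes)
    return pd.DataFrame(
        [[g.tpm[s] for s in stages] for g in genes],
        index=[g.gene_id for g in genes], columns=list(stages),
    )
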