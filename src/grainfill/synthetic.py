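"""Deterministic simulation of the grain-filling small-RNA experiment.

One seeded generator drives everything: a toy genome with planted structural
RNAs, repeats, genes, known miRNA hairpins and novel hairpins; five
stage-labelled small-RNA libraries whose planted miRNA abundances follow
per-species profile templates; NlaIII/MmeI tag libraries whose planted
target transcripts are (anti-)coupled to their miRNA; and a logistic
grain-weight series.

Planted hairpins are built as perfect inverted repeats (mature + loop +
reverse complement), which satisfies every duplex criterion of
:mod:`grainfill.hairpin` by construction and folds below -18 kcal/mol under
the package energy model for any 18-25 nt mature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import STAGES
from .annotation import (
    AnnotationTrackSet,
    CollapsedRead,
    Feature,
    MatureAnnotation,
    PrecursorAnnotation,
)
from .dge import ANCHOR, TAG_LEN
from .fold import revcomp

ALPHABET = np.array(list("ACGT"))

# planted-feature geometry (nt)
MATURE_LEN = 21
LOOP_LEN = 8
HAIRPIN_FLANK = 10
FEATURE_GAP = 20


class PlacementError(ValueError):
    """Feature demand exceeds genome capacity."""


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    genome_length: int = 60_000
    n_known_mirnas: int = 5
    n_novel_hairpins: int = 5
    n_target_genes: int = 5
    n_decoy_genes: int = 4
    n_rrna: int = 2
    n_trna: int = 2
    n_snrna: int = 1
    n_snorna: int = 1
    n_repeats: int = 2
    n_genes: int = 3  # genomic genes providing exon/intron background
    library_depths: dict[str, int] = field(
        default_factory=lambda: {s: 4000 for s in STAGES}
    )
    profile_templates: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "rising": (0.2, 0.5, 1.0, 1.6, 2.0),
            "falling": (2.0, 1.6, 1.0, 0.5, 0.2),
            "peaked": (0.3, 1.2, 2.0, 1.2, 0.3),
            "flat": (1.0, 1.0, 1.0, 1.0, 1.0),
        }
    )
    #: fraction of a library allotted to one planted miRNA at template value 1
    mirna_fraction: float = 0.004
    #: star:mature emission ratio; per-species overrides by planted id
    star_ratio: float = 0.1
    star_ratio_overrides: dict[str, float] = field(default_factory=dict)
    noise_dispersion: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if any(d <= 0 for d in self.library_depths.values()):
            raise ConfigError("library depths must be positive")
        for label, tpl in self.profile_templates.items():
            if len(tpl) != len(STAGES) or any(v < 0 for v in tpl):
                raise ConfigError(
                    f"profile template {label!r} must have 5 non-negative entries"
                )
        if self.noise_dispersion < 0:
            raise ConfigError("noise_dispersion must be non-negative")
        if not 0 < self.mirna_fraction < 1:
            raise ConfigError("mirna_fraction must be in (0, 1)")


@dataclass
class PlantedMiRNA:
    planted_id: str
    kind: str  # "known" | "novel"
    locus: tuple[int, int, str]  # precursor span on the genome
    precursor: str
    mature: str
    mature_span: tuple[int, int]  # genomic
    star: str
    star_span: tuple[int, int]
    profile_label: str

    @property
    def star_ratio_key(self) -> str:
        return self.planted_id


@dataclass
class PlantedTarget:
    transcript_id: str
    mirna_id: str
    site_start: int  # 0-based on the transcript
    site_end: int


@dataclass
class GroundTruth:
    planted_mirnas: list[PlantedMiRNA]
    planted_targets: dict[str, list[PlantedTarget]] = field(default_factory=dict)
    logistic_params: tuple[float, float, float] = (20.0, 100.0, 0.2)

    def by_kind(self, kind: str) -> list[PlantedMiRNA]:
        return [m for m in self.planted_mirnas if m.kind == kind]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(ALPHABET, size=n))


def _hairpin(rng: np.random.Generator) -> tuple[str, str, str, tuple[int, int], tuple[int, int]]:
    """A perfect-stem hairpin: (precursor, mature, star, mature span, star span).

    Spans are relative to the precursor; the mature sits on the 5' arm.
    """
    mature = _random_seq(rng, MATURE_LEN)
    loop = _random_seq(rng, LOOP_LEN)
    pre = (
        _random_seq(rng, HAIRPIN_FLANK)
        + mature
        + loop
        + revcomp(mature)
        + _random_seq(rng, HAIRPIN_FLANK)
    )
    ms = HAIRPIN_FLANK
    me = ms + MATURE_LEN
    ss = me + LOOP_LEN
    se = ss + MATURE_LEN
    return pre, mature, pre[ss:se], (ms, me), (ss, se)


def simulate_genome(
    config: SimulationConfig,
) -> tuple[str, AnnotationTrackSet, GroundTruth]:
    """Generate the toy genome, its annotation tracks and the ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # build feature payloads first, then place them without overlap
    specs: list[tuple[str, str, dict]] = []  # (kind, sequence, meta)
    for i in range(config.n_rrna):
        specs.append(("rRNA", _random_seq(rng, 400), {"id": f"rRNA-{i + 1}"}))
    for i in range(config.n_trna):
        specs.append(("tRNA", _random_seq(rng, 80), {"id": f"tRNA-{i + 1}"}))
    for i in range(config.n_snrna):
        specs.append(("snRNA", _random_seq(rng, 120), {"id": f"snRNA-{i + 1}"}))
    for i in range(config.n_snorna):
        specs.append(("snoRNA", _random_seq(rng, 130), {"id": f"snoRNA-{i + 1}"}))
    for i in range(config.n_repeats):
        specs.append(("repeat", _random_seq(rng, 300), {"id": f"repeat-{i + 1}"}))
    for i in range(config.n_genes):
        exon1, intron, exon2 = 180, 120, 180
        strand = "+" if rng.random() < 0.5 else "-"
        specs.append(
            ("gene", _random_seq(rng, exon1 + intron + exon2),
             {"id": f"gene-{i + 1}", "strand": strand,
              "exons": [(0, exon1), (exon1 + intron, exon1 + intron + exon2)],
              "introns": [(exon1, exon1 + intron)]})
        )
    labels = sorted(config.profile_templates)
    hairpin_meta: list[dict] = []
    for i in range(config.n_known_mirnas):
        pre, mature, star, mspan, sspan = _hairpin(rng)
        meta = {"id": f"known-{i + 1}", "kind": "known", "mature": mature,
                "star": star, "mspan": mspan, "sspan": sspan,
                "profile": labels[i % len(labels)]}
        specs.append(("hairpin", pre, meta))
        hairpin_meta.append(meta)
    for i in range(config.n_novel_hairpins):
        pre, mature, star, mspan, sspan = _hairpin(rng)
        meta = {"id": f"novel-{i + 1}", "kind": "novel", "mature": mature,
                "star": star, "mspan": mspan, "sspan": sspan,
                "profile": labels[i % len(labels)]}
        specs.append(("hairpin", pre, meta))
        hairpin_meta.append(meta)

    total_len = sum(len(seq) for _, seq, _ in specs)
    n_gaps = len(specs) + 1
    slack = config.genome_length - total_len - n_gaps * FEATURE_GAP
    if slack < 0:
        raise PlacementError(
            f"features need {total_len + n_gaps * FEATURE_GAP} nt, "
            f"genome is {config.genome_length} nt"
        )
    order = rng.permutation(len(specs))
    extra = rng.multinomial(slack, np.ones(n_gaps) / n_gaps)
    gaps = extra + FEATURE_GAP

    tracks = AnnotationTrackSet()
    truth = GroundTruth(planted_mirnas=[], logistic_params=(20.0, 100.0, 0.2))
    parts: list[str] = []
    cursor = 0
    for slot, idx in enumerate(order):
        gap_seq = _random_seq(rng, int(gaps[slot]))
        parts.append(gap_seq)
        cursor += len(gap_seq)
        kind, seq, meta = specs[idx]
        start, end = cursor, cursor + len(seq)
        parts.append(seq)
        cursor = end
        if kind == "rRNA":
            tracks.rrna.append(Feature(start, end, "+", meta["id"]))
        elif kind == "tRNA":
            tracks.trna.append(Feature(start, end, "+", meta["id"]))
        elif kind == "snRNA":
            tracks.snrna.append(Feature(start, end, "+", meta["id"]))
        elif kind == "snoRNA":
            tracks.snorna.append(Feature(start, end, "+", meta["id"]))
        elif kind == "repeat":
            tracks.repeats.append(Feature(start, end, "+", meta["id"]))
        elif kind == "gene":
            for es, ee in meta["exons"]:
                tracks.exons.append(
                    Feature(start + es, start + ee, meta["strand"], meta["id"])
                )
            for is_, ie in meta["introns"]:
                tracks.introns.append(
                    Feature(start + is_, start + ie, meta["strand"], meta["id"])
                )
        elif kind == "hairpin":
            ms, me = meta["mspan"]
            ss, se = meta["sspan"]
            planted = PlantedMiRNA(
                planted_id=meta["id"], kind=meta["kind"],
                locus=(start, end, "+"), precursor=seq,
                mature=meta["mature"], mature_span=(start + ms, start + me),
                star=meta["star"], star_span=(start + ss, start + se),
                profile_label=meta["profile"],
            )
            truth.planted_mirnas.append(planted)
            if meta["kind"] == "known":
                tracks.mirna_precursors.append(
                    PrecursorAnnotation(
                        meta["id"], start, end, "+",
                        matures=(
                            MatureAnnotation(f"{meta['id']}-5p", start + ms,
                                             start + me, "5p"),
                            MatureAnnotation(f"{meta['id']}-star", start + ss,
                                             start + se, "star"),
                        ),
                    )
                )
    parts.append(_random_seq(rng, int(gaps[-1])))
    genome = "".join(parts)
    if len(genome) < config.genome_length:
        genome += _random_seq(rng, config.genome_length - len(genome))
    truth.planted_mirnas.sort(key=lambda m: m.locus[0])
    return genome, tracks, truth


def _noisy_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Count with multiplicative (negative-binomial) noise.

    ``dispersion == 0`` is the noise-free case: the rounded mean, so planted
    counts are exactly proportional to the template and depth.  For
    ``dispersion > 0`` the variance is ``mean + dispersion * mean**2``.
    """
    if mean <= 0:
        return 0
    if dispersion == 0:
        return int(round(mean))
    r = 1.0 / dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


#: background annotation classes sampled into each library, with weights
BACKGROUND_WEIGHTS = {
    "repeat": 0.30, "exon_sense": 0.14, "exon_antisense": 0.08,
    "intron_sense": 0.08, "intron_antisense": 0.05, "rRNA": 0.12,
    "tRNA": 0.05, "snRNA": 0.01, "snoRNA": 0.02, "intergenic": 0.15,
}
#: read-length weights over 18-30 nt, peaked at 24 then 21
_LEN_RANGE = np.arange(18, 31)
_LEN_WEIGHTS = np.array([1, 2, 3, 8, 3, 3, 14, 3, 2, 2, 1, 1, 1], dtype=float)
_LEN_WEIGHTS /= _LEN_WEIGHTS.sum()


def simulate_libraries(
    genome: str,
    tracks: AnnotationTrackSet,
    truth: GroundTruth,
    config: SimulationConfig,
) -> dict[str, list[CollapsedRead]]:
    """Five collapsed small-RNA libraries with planted dynamics.

    Planted mature counts at stage ``s`` are
    ``round(mirna_fraction * template[s] * depth[s])`` with optional
    negative-binomial noise; star reads are emitted at the per-species
    star:mature ratio; the remaining depth is filled with background reads
    drawn from the non-miRNA tracks and intergenic space.  The per-stage sum
    of counts equals the configured depth exactly.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    gaps = _intergenic_intervals(genome, tracks, truth)
    pools = _background_pools(tracks, gaps)
    libraries: dict[str, list[CollapsedRead]] = {}
    for si, stage in enumerate(STAGES):
        depth = config.library_depths[stage]
        counter: dict[str, int] = {}
        planted_total = 0
        for planted in truth.planted_mirnas:
            template = config.profile_templates[planted.profile_label]
            mean = config.mirna_fraction * template[si] * depth
            n_mature = _noisy_count(rng, mean, config.noise_dispersion)
            ratio = config.star_ratio_overrides.get(
                planted.planted_id, config.star_ratio
            )
            n_star = int(round(ratio * n_mature))
            if n_mature:
                counter[planted.mature] = counter.get(planted.mature, 0) + n_mature
            if n_star:
                counter[planted.star] = counter.get(planted.star, 0) + n_star
            planted_total += n_mature + n_star
        n_background = depth - planted_total
        if n_background < 0:
            raise ConfigError(
                f"planted reads ({planted_total}) exceed depth {depth} at {stage}; "
                "lower mirna_fraction or raise depths"
            )
        for seq in _background_reads(rng, genome, pools, n_background):
            counter[seq] = counter.get(seq, 0) + 1
        libraries[stage] = [
            CollapsedRead(seq, {stage: n}) for seq, n in counter.items()
        ]
    return libraries


def _intergenic_intervals(
    genome: str, tracks: AnnotationTrackSet, truth: GroundTruth
) -> list[tuple[int, int]]:
    """Genome intervals covered by no planted feature."""
    occupied = sorted(
        [(f.start, f.end) for fs in
         (tracks.rrna, tracks.trna, tracks.snrna, tracks.snorna,
          tracks.repeats, tracks.exons, tracks.introns) for f in fs]
        + [(p.start, p.end) for p in tracks.mirna_precursors]
        + [(m.locus[0], m.locus[1]) for m in truth.planted_mirnas]
    )
    gaps: list[tuple[int, int]] = []
    cursor = 0
    for start, end in occupied:
        if start > cursor:
            gaps.append((cursor, start))
        cursor = max(cursor, end)
    if cursor < len(genome):
        gaps.append((cursor, len(genome)))
    return gaps


def _background_pools(
    tracks: AnnotationTrackSet, gaps: list[tuple[int, int]]
) -> dict[str, list[tuple[int, int, str]]]:
    """(interval, read strand) pools per background class."""
    pools: dict[str, list[tuple[int, int, str]]] = {}
    pools["repeat"] = [(f.start, f.end, "+") for f in tracks.repeats]
    pools["rRNA"] = [(f.start, f.end, "+") for f in tracks.rrna]
    pools["tRNA"] = [(f.start, f.end, "+") for f in tracks.trna]
    pools["snRNA"] = [(f.start, f.end, "+") for f in tracks.snrna]
    pools["snoRNA"] = [(f.start, f.end, "+") for f in tracks.snorna]
    flip = {"+": "-", "-": "+"}
    pools["exon_sense"] = [(f.start, f.end, f.strand) for f in tracks.exons]
    pools["exon_antisense"] = [(f.start, f.end, flip[f.strand]) for f in tracks.exons]
    pools["intron_sense"] = [(f.start, f.end, f.strand) for f in tracks.introns]
    pools["intron_antisense"] = [
        (f.start, f.end, flip[f.strand]) for f in tracks.introns
    ]
    pools["intergenic"] = [(s, e, "+") for s, e in gaps if e - s >= 40]
    return pools


def _background_reads(
    rng: np.random.Generator,
    genome: str,
    pools: Mapping[str, list[tuple[int, int, str]]],
    n: int,
) -> list[str]:
    classes = [c for c in BACKGROUND_WEIGHTS if pools.get(c)]
    weights = np.array([BACKGROUND_WEIGHTS[c] for c in classes])
    weights /= weights.sum()
    reads: list[str] = []
    class_draw = rng.choice(len(classes), size=n, p=weights)
    len_draw = rng.choice(_LEN_RANGE, size=n, p=_LEN_WEIGHTS)
    for ci, length in zip(class_draw, len_draw):
        intervals = pools[classes[ci]]
        start_iv, end_iv, strand = intervals[rng.integers(len(intervals))]
        length = int(min(length, end_iv - start_iv))
        pos = int(rng.integers(start_iv, end_iv - length + 1))
        seq = genome[pos:pos + length]
        reads.append(seq if strand == "+" else revcomp(seq))
    return reads


def simulate_grain_weights(
    params: tuple[float, float, float],
    days: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[tuple[float, float]]:
    """Logistic grain weights ``K / (1 + a e^{-bt})`` with Gaussian noise."""
    K, a, b = params
    if K <= 0 or a <= 0 or b <= 0:
        raise ValueError("logistic parameters must be positive")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = []
    for t in days:
        w = K / (1.0 + a * np.exp(-b * t))
        if noise_sd > 0:
            w += rng.normal(0.0, noise_sd)
        out.append((float(t), float(w)))
    return out


class DGEConstructionError(ValueError):
    """A transcript that cannot carry a CATG tag was requested."""


#: per-transcript baseline tag count at template value 1
DGE_UNIT = 200.0


def simulate_dge(
    truth: GroundTruth,
    mirna_profiles: Mapping[str, Sequence[float]],
    config: SimulationConfig,
    coupling: float = -1.0,
) -> tuple[dict[str, str], dict[str, list[tuple[str, int]]]]:
    """Target/decoy transcripts and per-stage DGE tag libraries.

    Each planted-target transcript carries one perfect-complement site for
    its miRNA and at least one usable CATG tag; its stage profile is the
    miRNA profile for ``coupling=+1`` or its exact reflection
    ``max+min - profile`` for ``coupling=-1`` (PCC is then exactly +-1 in the
    noise-free case).  Decoy transcripts get independent random profiles.

    Returns ``(transcripts, tag_libraries)`` with tag libraries mapping
    stage -> list of (tag sequence, count).
    """
    if coupling not in (-1.0, 1.0):
        raise ConfigError("coupling must be -1 or +1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    # couple targets to miRNAs with non-constant profiles where possible;
    # a constant profile has no sign to anti-correlate against
    mirnas = [
        m for m in truth.planted_mirnas
        if len(set(mirna_profiles[m.planted_id])) > 1
    ] or truth.planted_mirnas
    if not mirnas:
        raise DGEConstructionError("no planted miRNAs to target")
    transcripts: dict[str, str] = {}
    profiles: dict[str, np.ndarray] = {}
    truth.planted_targets = {}
    seen_tags: set[str] = set()
    for i in range(config.n_target_genes):
        planted = mirnas[i % len(mirnas)]
        tx_id = f"target-{i + 1}"
        seq, site_start = _make_transcript(rng, revcomp(planted.mature), seen_tags)
        transcripts[tx_id] = seq
        truth.planted_targets.setdefault(planted.planted_id, []).append(
            PlantedTarget(tx_id, planted.planted_id,
                          site_start, site_start + len(planted.mature))
        )
        p = np.asarray(mirna_profiles[planted.planted_id], dtype=float)
        if coupling < 0:
            p = (p.max() + p.min()) - p
        profiles[tx_id] = p
    for i in range(config.n_decoy_genes):
        tx_id = f"decoy-{i + 1}"
        seq, _ = _make_transcript(rng, None, seen_tags)
        transcripts[tx_id] = seq
        profiles[tx_id] = rng.uniform(0.5, 2.0, size=len(STAGES))

    tag_libraries: dict[str, list[tuple[str, int]]] = {}
    for si, stage in enumerate(STAGES):
        rows: list[tuple[str, int]] = []
        for tx_id, seq in transcripts.items():
            from .dge import canonical_tags  # local import avoids cycle at module load

            primary = [t for t in canonical_tags(seq) if t.primary][0]
            mean = DGE_UNIT * profiles[tx_id][si]
            n = _noisy_count(rng, mean, config.noise_dispersion)
            if n > 0:
                rows.append((primary.sequence, n))
        tag_libraries[stage] = rows
    return transcripts, tag_libraries


def _make_transcript(
    rng: np.random.Generator,
    site: str | None,
    seen_tags: set[str],
) -> tuple[str, int]:
    """Random transcript with a unique primary tag and optional target site."""
    for _ in range(50):
        head = _strip_anchor(_random_seq(rng, 60))
        tag_tail = _strip_anchor(_random_seq(rng, TAG_LEN - len(ANCHOR)))
        mid = _strip_anchor(_random_seq(rng, 80))
        tail = _strip_anchor(_random_seq(rng, 40))
        site_seq = site or ""
        seq = head + ANCHOR + tag_tail + mid + site_seq + tail
        tag = ANCHOR + tag_tail
        # exactly one CATG by construction unless the site introduced more;
        # extra sites are fine, but the primary tag must stay unique
        from .dge import canonical_tags

        tags = canonical_tags(seq)
        if not tags:
            continue
        primary = [t for t in tags if t.primary][0]
        if primary.sequence in seen_tags:
            continue
        seen_tags.add(primary.sequence)
        site_start = len(head) + len(ANCHOR) + len(tag_tail) + len(mid)
        return seq, site_start
    raise DGEConstructionError("could not construct a unique-tag transcript")


def _strip_anchor(seq: str) -> str:
    while ANCHOR in seq:
        seq = seq.replace(ANCHOR, "CATC")
    return seq
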