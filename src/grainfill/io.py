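"""Readers and writers for the formats the pipeline touches.

* FASTA via Biopython (genome, transcripts, miRNA sets);
* collapsed small-RNA FASTA with ``>id_xCOUNT`` headers;
* GFF3 annotation tracks (1-based inclusive on disk, 0-based half-open in
  memory);
* miRBase-like mature FASTA headers: ``>mature_id precursor_id start end arm``
  with 0-based half-open precursor-relative coordinates;
* TSV tables (pandas) and JSON (model parameters, ground truth).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import (
    AnnotationTrackSet,
    CollapsedRead,
    Feature,
    MatureAnnotation,
    PrecursorAnnotation,
)

GFF_TYPE_MAP = {
    "rRNA": "rrna",
    "tRNA": "trna",
    "snRNA": "snrna",
    "snoRNA": "snorna",
    "repeat_region": "repeats",
    "exon": "exons",
    "intron": "introns",
}


def write_fasta(path: str | Path, records: Mapping[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path), "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_collapsed_fasta(path: str | Path, reads: Iterable[CollapsedRead], stage: str) -> None:
    """One library: ``>r{i}_x{count}`` headers carrying the stage count."""
    with open(path, "w") as fh:
        i = 0
        for read in reads:
            count = read.counts.get(stage, 0)
            if count <= 0:
                continue
            i += 1
            fh.write(f">r{i}_x{count}\n{read.sequence}\n")


def read_collapsed_fasta(path: str | Path, stage: str) -> list[CollapsedRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = int(rec.id.rsplit("_x", 1)[1])
        reads.append(CollapsedRead(str(rec.seq), {stage: count}))
    return reads


def write_tracks_gff3(path: str | Path, tracks: AnnotationTrackSet, seqid: str = "chr1") -> None:
    """GFF3 dump of all tracks (genes appear as gene + exon records)."""
    inv = {v: k for k, v in GFF_TYPE_MAP.items()}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")

        def row(ftype: str, start: int, end: int, strand: str, attrs: str, source: str = "grainfill"):
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )

        for attr in ("rrna", "trna", "snrna", "snorna", "repeats", "exons", "introns"):
            for f in getattr(tracks, attr):
                row(inv[attr], f.start, f.end, f.strand,
                    f"ID={f.feature_id}", source=f.source)
        for p in tracks.mirna_precursors:
            row("miRNA_primary_transcript", p.start, p.end, p.strand, f"ID={p.precursor_id}")
            for m in p.matures:
                row("miRNA", m.start, m.end, p.strand,
                    f"ID={m.mature_id};Derives_from={p.precursor_id};arm={m.arm}")


def read_tracks_gff3(path: str | Path) -> AnnotationTrackSet:
    tracks = AnnotationTrackSet()
    precursors: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            _, source, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            fields = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            start0, end0 = int(start) - 1, int(end)
            if ftype in GFF_TYPE_MAP:
                getattr(tracks, GFF_TYPE_MAP[ftype]).append(
                    Feature(start0, end0, strand, fields.get("ID", ""), source)
                )
            elif ftype == "miRNA_primary_transcript":
                precursors[fields["ID"]] = {
                    "start": start0, "end": end0, "strand": strand, "matures": []
                }
            elif ftype == "miRNA":
                precursors[fields["Derives_from"]]["matures"].append(
                    MatureAnnotation(fields["ID"], start0, end0, fields.get("arm", "5p"))
                )
    for pid, d in precursors.items():
        tracks.mirna_precursors.append(
            PrecursorAnnotation(pid, d["start"], d["end"], d["strand"],
                                tuple(d["matures"]))
        )
    return tracks


def write_mirna_fastas(
    prefix: str | Path, precursors: Mapping[str, str],
    matures: Sequence[tuple[str, str, str, int, int, str]],
) -> tuple[Path, Path]:
    """miRBase-like precursor and mature FASTAs.

    ``matures`` rows are ``(mature_id, sequence, precursor_id, start, end,
    arm)`` with precursor-relative 0-based half-open coordinates.
    """
    prefix = Path(prefix)
    pre_path = prefix.with_name(prefix.name + "_precursors.fasta")
    mat_path = prefix.with_name(prefix.name + "_matures.fasta")
    write_fasta(pre_path, precursors)
    with open(mat_path, "w") as fh:
        for mature_id, seq, pre_id, start, end, arm in matures:
            fh.write(f">{mature_id} {pre_id} {start} {end} {arm}\n{seq}\n")
    return pre_path, mat_path


def read_mature_fasta(path: str | Path) -> list[tuple[str, str, str, int, int, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        out.append(
            (parts[0], str(rec.seq).upper(), parts[1], int(parts[2]),
             int(parts[3]), parts[4])
        )
    return out


def write_weights_tsv(path: str | Path, weights: Sequence[tuple[float, float]]) -> None:
    with open(path, "w") as fh:
        fh.write("daf\tweight_mg\n")
        for t, w in weights:
            fh.write(f"{t:g}\t{w:.6f}\n")


def read_weights_tsv(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path, sep="\t")
    return list(zip(df.iloc[:, 0].astype(float), df.iloc[:, 1].astype(float)))


class _TruthEncoder(json.JSONEncoder):
    def default(self, o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def write_truth_json(path: str | Path, truth) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, cls=_TruthEncoder, indent=1, sort_keys=True)


def write_table_tsv(path: str | Path, df: pd.DataFrame, decimals: int | None = None) -> None:
    """TSV export; TPM-bearing tables use 2-decimal fixed formatting."""
    out = df.copy()
    if decimals is not None:
        out = out.round(decimals)
        float_format = f"%.{decimals}f"
    else:
        float_format = None
    out.to_csv(path, sep="\t", float_format=float_format)


def read_table_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, **kwargs)
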