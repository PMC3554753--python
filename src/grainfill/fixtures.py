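"""Packaged reference tables from the rice grain-filling survey.

Two small TSVs ship with the package:

* ``novel_mirnas.tsv`` -- the 45-record novel-miRNA catalogue (id, mature
  sequence, length, five per-stage TPM values, evidence tag).  Evidence
  ``*`` marks detection of the corresponding star read in at least one
  library; ``T`` marks detection of the mature in at least three of the
  five libraries; ``*, T`` marks both.
* ``small_rna_classes.tsv`` -- the per-stage partition of unique and total
  small-RNA reads over the 11 annotation categories, plus the library
  totals.

Both loaders validate structural invariants and raise :class:`FixtureError`
on any mismatch.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import STAGES

EXPECTED_NOVEL_RECORDS = 45
EVIDENCE_VALUES = {"*", "*, T", "T"}
PARTITION_CATEGORIES = (
    "exon_antisense", "exon_sense", "intron_antisense", "intron_sense",
    "miRNA", "rRNA", "repeat", "snRNA", "snoRNA", "tRNA", "No_annotation",
)


class FixtureError(ValueError):
    """A packaged table failed validation on load."""


def _data_path(name: str):
    return resources.files("grainfill.data").joinpath(name)


def load_novel_mirna_table() -> pd.DataFrame:
    """The 45-record novel-miRNA catalogue, validated.

    Checks: exactly 45 rows; unique ids; each record's ``length`` equals the
    character length of its sequence; evidence is one of ``*``, ``*, T``,
    ``T``; TPM values non-negative.
    """
    with resources.as_file(_data_path("novel_mirnas.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype={"evidence": str})
    if len(df) != EXPECTED_NOVEL_RECORDS:
        raise FixtureError(
            f"expected {EXPECTED_NOVEL_RECORDS} novel-miRNA records, got {len(df)}"
        )
    if df["mirna_id"].duplicated().any():
        raise FixtureError("duplicate novel-miRNA ids")
    bad_len = df[df["sequence"].str.len() != df["length"]]
    if not bad_len.empty:
        raise FixtureError(
            f"length/sequence mismatch for {list(bad_len['mirna_id'])}"
        )
    bad_ev = set(df["evidence"]) - EVIDENCE_VALUES
    if bad_ev:
        raise FixtureError(f"unknown evidence values {bad_ev}")
    tpm_cols = [f"tpm_{s}" for s in STAGES]
    if (df[tpm_cols] < 0).any().any():
        raise FixtureError("negative TPM value")
    return df.set_index("mirna_id")


def load_read_class_table() -> pd.DataFrame:
    """Per-stage unique/total read counts by annotation category.

    Rows: ``Total`` plus the 11 categories; columns: a (stage, unique|total)
    MultiIndex.  Validated for row completeness and non-negative counts.
    """
    with resources.as_file(_data_path("small_rna_classes.tsv")) as path:
        df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(PARTITION_CATEGORIES) - set(df.index)
    if missing:
        raise FixtureError(f"missing partition categories {missing}")
    if "Total" not in df.index:
        raise FixtureError("missing Total row")
    if (df < 0).any().any():
        raise FixtureError("negative count")
    df.columns = pd.MultiIndex.from_tuples(
        [tuple(c.rsplit("_", 1)) for c in df.columns]
    )
    return df


def partition_sum(df: pd.DataFrame, stage: str, level: str) -> int:
    """Sum of the 11 category counts for one stage column."""
    return int(df.loc[list(PARTITION_CATEGORIES), (stage, level)].sum())
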