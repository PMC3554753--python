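"""End-to-end pipeline: simulate -> annotate -> discover -> targets -> dge -> dynamics.

Everything is driven by one :class:`PipelineConfig`; a fixed seed makes the
whole report bundle byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import STAGE_DAYS, STAGES
from .annotation import (
    classify_all,
    counts_matrix,
    partition_table,
    size_distribution,
    tpm_normalize,
)
from .dge import expression_matrix, filter_tags, quantify_genes
from .dynamics import (
    cluster_profiles,
    filter_expressed,
    fit_logistic,
    mirna_target_correlation,
)
from .hairpin import discover
from .io import (
    write_collapsed_fasta,
    write_fasta,
    write_table_tsv,
    write_tracks_gff3,
    write_truth_json,
    write_weights_tsv,
)
from .synthetic import (
    SimulationConfig,
    simulate_dge,
    simulate_genome,
    simulate_grain_weights,
    simulate_libraries,
)
from .targets import hits_to_rows, scan_transcriptome

log = logging.getLogger("grainfill")


class StageFailure(RuntimeError):
    """A pipeline stage aborted; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: Path = Path("grainfill-out")
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    tpm_filter: float = 10.0
    n_clusters: int = 4
    weight_noise_sd: float = 0.3
    weight_days: tuple[float, ...] = tuple(float(d) for d in range(5, 50, 5))
    coupling: float = -1.0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        self.simulation.seed = self.seed


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle under ``outdir``.

    Returns a summary dict (also written as ``summary.json``).
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}

    def timed(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s started", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                if exc is not None:
                    raise StageFailure(name, exc) from exc
                summary["stages"][name] = round(dt, 3)
                log.info("stage %s done in %.2fs", name, dt)

        return _Timer()

    with timed("simulate"):
        sim = config.simulation
        genome, tracks, truth = simulate_genome(sim)
        libraries = simulate_libraries(genome, tracks, truth, sim)
        weights = simulate_grain_weights(
            truth.logistic_params, config.weight_days,
            noise_sd=config.weight_noise_sd, seed=config.seed,
        )
        profiles = {
            m.planted_id: sim.profile_templates[m.profile_label]
            for m in truth.planted_mirnas
        }
        transcripts, tag_libraries = simulate_dge(
            truth, profiles, sim, coupling=config.coupling
        )
        write_fasta(out / "genome.fasta", {"chr1": genome})
        write_tracks_gff3(out / "tracks.gff3", tracks)
        write_fasta(out / "transcripts.fasta", transcripts)
        write_weights_tsv(out / "weights.tsv", weights)
        write_truth_json(out / "truth.json", {
            "planted_mirnas": truth.planted_mirnas,
            "planted_targets": truth.planted_targets,
            "logistic_params": truth.logistic_params,
        })
        for stage in STAGES:
            write_collapsed_fasta(out / f"library_{stage}.fasta", libraries[stage], stage)

    with timed("annotate"):
        merged: dict[str, dict[str, int]] = {}
        for stage in STAGES:
            for read in libraries[stage]:
                merged.setdefault(read.sequence, {})[stage] = read.counts[stage]
        from .annotation import CollapsedRead

        collapsed = [CollapsedRead(s, c) for s, c in merged.items()]
        classified = classify_all(collapsed, genome, tracks)
        part = partition_table(classified, STAGES)
        write_table_tsv(out / "partition.tsv", part)
        sizes = size_distribution(classified, "unique")
        size_df = pd.DataFrame(sizes).fillna(0.0).sort_index()
        write_table_tsv(out / "size_distribution_unique.tsv", size_df, decimals=4)
        totals = {s: config.simulation.library_depths[s] for s in STAGES}
        raw = counts_matrix(collapsed, STAGES)
        tpm = tpm_normalize(raw, totals)
        write_table_tsv(out / "tpm_all_reads.tsv", tpm, decimals=2)
        summary["partition_totals"] = {
            s: int(part.xs((s, "total"), axis=1).sum()) for s in STAGES
        }

    with timed("discover"):
        unannotated = [c for c in classified if c.category == "no_annotation"]
        libs = {
            s: {r.sequence: r.counts[s] for r in libraries[s]} for s in STAGES
        }
        known_iv = [(p.start, p.end) for p in tracks.mirna_precursors]
        report = discover(unannotated, genome, libs, totals, known_iv)
        rows = [
            {"id": n.novel_id, "sequence": n.mature, "length": n.length,
             **{f"tpm_{s}": round(n.tpm[s], 2) for s in STAGES},
             "evidence": n.evidence}
            for n in report.novel
        ]
        pd.DataFrame(rows).to_csv(out / "novel_mirnas.tsv", sep="\t", index=False)
        with open(out / "novel_structures.txt", "w") as fh:
            for n in report.novel:
                fh.write(f">{n.novel_id}\n{n.candidate.precursor}\n{n.candidate.structure}\n")
        summary["novel_mirnas"] = len(report.novel)
        summary["novel_recovery"] = {
            "planted": len(truth.by_kind("novel")),
            "recovered": sum(
                1 for m in truth.by_kind("novel")
                if any(n.mature == m.mature for n in report.novel)
            ),
        }

    with timed("targets"):
        mature_seqs = {m.planted_id: m.mature for m in truth.planted_mirnas}
        hits = scan_transcriptome(mature_seqs, transcripts)
        pd.DataFrame(hits_to_rows(hits)).to_csv(out / "target_hits.tsv", sep="\t", index=False)
        planted_pairs = {
            (mid, t.transcript_id)
            for mid, targets in truth.planted_targets.items() for t in targets
        }
        summary["target_hits"] = len(hits)
        summary["planted_target_recovery"] = {
            "planted": len(planted_pairs),
            "recovered": len(
                planted_pairs & {(h.mirna_id, h.transcript_id) for h in hits}
            ),
        }

    with timed("dge"):
        raw_tags: dict[str, dict[str, int]] = {}
        for stage, rows_ in tag_libraries.items():
            for seq, n in rows_:
                raw_tags.setdefault(seq, {})[stage] = (
                    raw_tags.setdefault(seq, {}).get(stage, 0) + n
                )
        tags = filter_tags(raw_tags, STAGES)
        genes = quantify_genes(tags, transcripts, STAGES)
        gene_tpm = expression_matrix(genes, STAGES)
        write_table_tsv(out / "gene_tpm.tsv", gene_tpm, decimals=2)

    with timed("dynamics"):
        model = fit_logistic(weights)
        with open(out / "logistic_model.json", "w") as fh:
            json.dump({"K": model.K, "a": model.a, "b": model.b}, fh, indent=1)
        rate_df = pd.DataFrame({
            "daf": list(config.weight_days),
            "rate_mg_per_day": list(model.rate(list(config.weight_days))),
        }).set_index("daf")
        write_table_tsv(out / "filling_rate.tsv", rate_df, decimals=4)

        mature_ids = {m.mature: m.planted_id for m in truth.planted_mirnas}
        mirna_raw = raw.loc[[s for s in raw.index if s in mature_ids]]
        mirna_raw.index = [mature_ids[s] for s in mirna_raw.index]
        mirna_tpm = tpm_normalize(mirna_raw, totals)
        expressed = filter_expressed(mirna_tpm, config.tpm_filter)
        k = min(config.n_clusters, max(1, len(expressed)))
        clusters = cluster_profiles(expressed, k, model, STAGE_DAYS)
        clusters.labels.to_csv(out / "clusters.tsv", sep="\t")
        pairs = [
            (mid, t.transcript_id)
            for mid, targets in truth.planted_targets.items() for t in targets
            if mid in mirna_tpm.index
        ]
        reports = mirna_target_correlation(mirna_tpm, gene_tpm, pairs)
        pd.DataFrame(
            [{"mirna": r.mirna_id, "target": r.target_id,
              "pcc": round(r.pcc, 4) if r.pcc == r.pcc else "",
              "class": r.sign_class} for r in reports]
        ).to_csv(out / "mirna_target_correlation.tsv", sep="\t", index=False)
        summary["correlation"] = {
            "negative": sum(r.sign_class == "negative" for r in reports),
            "positive": sum(r.sign_class == "positive" for r in reports),
            "not_classifiable": sum(r.sign_class == "not_classifiable" for r in reports),
        }
        summary["logistic"] = {"K": model.K, "a": model.a, "b": model.b}

    # timings are logged but kept out of the bundle so that a fixed seed
    # yields byte-identical outputs
    persisted = {k: v for k, v in summary.items() if k != "stages"}
    with open(out / "summary.json", "w") as fh:
        json.dump(persisted, fh, indent=1, sort_keys=True)
    return summary
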