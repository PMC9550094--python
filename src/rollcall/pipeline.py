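"""End-to-end orchestration: filter -> repeat detection -> consensus ->
phasing/trimming -> accuracy scoring -> pool quantification.

Each stage's outputs are checkpointed under the output directory so stages
can be inspected or rerun independently; a run summary with per-stage record
counts is written as JSON and TSV. Stage counts are monotone non-increasing
by construction (a read can only leave the pipeline, never re-enter),
except that a chimeric read with several periodic regions contributes one
consensus per region.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from ._seq import validate_seq
from .accuracy import (
    AccuracyRecord,
    accuracy_histogram,
    bias_within_twofold,
    map_to_pool,
    normalize_counts,
    score_accuracy,
)
from .consensus import ConsensusRecord, TooFewUnitsError, consensus_from_units
from .phasing import PhasedInsert, phase_consensus, trim_adapter
from .reads import FilterConfig, Read, filter_reads, read_fasta, read_fastq, write_fasta
from .repeats import AnchorError, RepeatParams, find_periodic_region, segment_units, write_bed

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    adapter: str
    filter: FilterConfig = field(default_factory=FilterConfig)
    repeat: RepeatParams = field(default_factory=RepeatParams)
    references: str | None = None  # FASTA of known reference sequences
    pool: str | None = None  # FASTA of an equimolar pool
    output_dir: str = "rollcall_out"
    min_phase_run_fraction: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        self.adapter = validate_seq(self.adapter, "adapter")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "filter" in raw:
            raw["filter"] = FilterConfig(**raw["filter"])
        if "repeat" in raw:
            raw["repeat"] = RepeatParams(**raw["repeat"])
        return cls(**raw)


def process_reads(
    reads: Sequence[Read],
    adapter: str,
    repeat_params: RepeatParams = RepeatParams(),
    letter_consistency: float | None = None,
    min_phase_run_fraction: float = 0.5,
) -> tuple[list[ConsensusRecord], list[PhasedInsert], dict[str, int]]:
    """Repeat detection, consensus and phasing for already-filtered reads.

    Returns the consensus records, the successfully phased inserts, and the
    per-stage counts.
    """
    if letter_consistency is None:
        letter_consistency = repeat_params.letter_consistency
    consensuses: list[ConsensusRecord] = []
    phased_ok: list[PhasedInsert] = []
    n_with_repeats = 0
    for read in reads:
        annotations = find_periodic_region(read, repeat_params)
        if not annotations:
            continue
        n_with_repeats += 1
        for region_idx, ann in enumerate(annotations):
            read_id = read.id if len(annotations) == 1 else f"{read.id}/{region_idx + 1}"
            try:
                units = segment_units(read, ann)
                record = consensus_from_units(units, letter_consistency, read_id)
            except (AnchorError, TooFewUnitsError, ValueError) as exc:
                logger.info("read %s: consensus skipped (%s)", read_id, exc)
                continue
            consensuses.append(record)
            phased = phase_consensus(record, adapter, min_phase_run_fraction)
            if not phased.unphaseable:
                phased_ok.append(phased)
    counts = {
        "with_repeats": n_with_repeats,
        "consensus_called": len(consensuses),
        "phased": len(phased_ok),
    }
    return consensuses, phased_ok, counts


def run_pipeline(fastq: str | Path, config: RunConfig) -> dict:
    """Execute the full workflow on a FASTQ file; returns the run summary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    reads = list(read_fastq(fastq))
    filtered = filter_reads(reads, config.filter)
    logger.info("filter: %d in, %d kept", filtered.n_total, filtered.n_kept)

    annotations = []
    for read in filtered.kept:
        annotations.extend(find_periodic_region(read, config.repeat))
    write_bed(annotations, out / "repeats.bed")

    consensuses, phased, stage_counts = process_reads(
        filtered.kept,
        config.adapter,
        config.repeat,
        min_phase_run_fraction=config.min_phase_run_fraction,
    )
    logger.info(
        "repeats: %d reads, consensus: %d, phased: %d",
        stage_counts["with_repeats"], stage_counts["consensus_called"], stage_counts["phased"],
    )
    write_fasta(
        (
            (f"{c.read_id} n_units={c.n_units} identity={c.mean_unit_identity:.4f}", c.sequence)
            for c in consensuses
        ),
        out / "consensus.fasta",
    )
    inserts = [(p.read_id, trim_adapter(p)) for p in phased if p.insert]
    write_fasta(inserts, out / "inserts.fasta")
    pd.DataFrame(
        [
            {
                "read_id": p.read_id,
                "rotation_offset": p.rotation_offset,
                "strand": p.strand,
                "anchored_end": p.anchored_end,
                "ungapped_run": p.ungapped_alignment_length,
                "unphaseable": p.unphaseable,
            }
            for p in phased
        ]
    ).to_csv(out / "phasing.tsv", sep="\t", index=False)

    summary: dict = {
        "reads_in": filtered.n_total,
        "passed_filter": filtered.n_kept,
        **stage_counts,
        "inserts": len(inserts),
    }

    if config.references:
        refs = read_fasta(config.references)
        records: list[AccuracyRecord] = []
        for read_id, insert in inserts:
            best = max(
                (score_accuracy(insert, seq, read_id) for _, seq in refs),
                key=lambda r: r.percent_identity,
            )
            records.append(best)
        pd.DataFrame([vars(r) for r in records]).to_csv(
            out / "accuracy.tsv", sep="\t", index=False
        )
        if records:
            hist = accuracy_histogram(records)
            summary["accuracy"] = {
                f"ge_{int(row.threshold)}": row.fraction for row in hist.itertuples()
            }

    if config.pool:
        pool = read_fasta(config.pool)
        table = map_to_pool([s for _, s in inserts], pool)
        summary["total_mapped"] = table.total_mapped
        summary["unmapped"] = table.unmapped
        if table.total_mapped > 0:
            table = normalize_counts(table)
            summary["within_twofold_pct"] = bias_within_twofold(table)
        table.counts.to_csv(out / "counts.tsv", sep="\t")

    with open(out / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
    flat = {
        k: v for k, v in summary.items() if not isinstance(v, dict)
    }
    pd.DataFrame([flat]).to_csv(out / "summary.tsv", sep="\t", index=False)
    return summary
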