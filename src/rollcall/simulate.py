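"""Seeded simulator of rolling-circle concatemeric nanopore reads.

A library molecule is a small-RNA insert ligated to a known adapter and
circularized; rolling-circle reverse transcription then rolls the circle out
into a long cDNA of tandem repeats. The simulator emulates that product:
each read is the circular template (insert + adapter) unrolled R times
starting at a random phase on the circle, optionally reverse-complemented,
truncated by up to one template length at the tail, and passed through an
independent per-base substitution/insertion/deletion error channel. Phred
qualities are emitted so that the implied mean error probability matches the
configured total error rate.

Every read carries a ground-truth record (template, repeat count, strand,
phase) so downstream stages can be tested for exact parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from ._seq import revcomp, validate_seq
from .reads import Read

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}


@dataclass(frozen=True)
class SimulationConfig:
    insert_sequences: tuple[str, ...]
    adapter: str
    n_reads: int = 100
    repeat_distribution: str = "uniform"  # "uniform" or "fixed"
    repeat_min: int = 5
    repeat_max: int = 50
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    strand_fraction: float = 0.5
    seed: int = 0
    fixed_phase: int | None = None  # None: uniform over the circle
    fixed_tail: int | None = None  # None: uniform in [0, template length)
    quality_jitter: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "insert_sequences", tuple(validate_seq(s, "insert") for s in self.insert_sequences)
        )
        object.__setattr__(self, "adapter", validate_seq(self.adapter, "adapter"))
        if not self.insert_sequences:
            raise ValueError("at least one insert sequence is required")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        rates = (self.sub_rate, self.ins_rate, self.del_rate)
        if any(r < 0 for r in rates):
            raise ValueError("error rates must be >= 0")
        if sum(rates) >= 0.5:
            raise ValueError("total error rate must be < 0.5")
        if self.repeat_distribution not in ("uniform", "fixed"):
            raise ValueError("repeat_distribution must be 'uniform' or 'fixed'")
        if self.repeat_min < 1 or self.repeat_max < self.repeat_min:
            raise ValueError("repeat counts must satisfy 1 <= repeat_min <= repeat_max")
        if not 0.0 <= self.strand_fraction <= 1.0:
            raise ValueError("strand_fraction must lie in [0, 1]")

    @property
    def total_error_rate(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


@dataclass(frozen=True)
class GroundTruthRecord:
    read_id: str
    template_index: int
    true_repeat_count: int
    true_strand: str  # "+" or "-"
    true_phase_offset: int  # 0-based circle position where the read begins


def build_circular_template(insert: str, adapter: str) -> str:
    """Linear representation (insert followed by adapter) of the circular template."""
    insert = validate_seq(insert, "insert")
    adapter = validate_seq(adapter, "adapter")
    return insert + adapter


def _phred_for_rate(rate: float) -> int:
    if rate <= 0:
        return 40
    return int(np.clip(round(-10.0 * math.log10(rate)), 2, 40))


def _apply_errors(seq: str, cfg: SimulationConfig, rng: np.random.Generator) -> str:
    """Per original base: delete, else substitute, else emit; then insert
    a random base after each emitted position with probability ins_rate."""
    if cfg.total_error_rate == 0:
        return seq
    out: list[str] = []
    draws = rng.random(len(seq))
    for base, u in zip(seq, draws):
        if u < cfg.del_rate:
            pass
        elif u < cfg.del_rate + cfg.sub_rate:
            out.append(_OTHER[base][rng.integers(3)])
        else:
            out.append(base)
        if out and cfg.ins_rate > 0 and rng.random() < cfg.ins_rate:
            out.append(_BASES[rng.integers(4)])
    return "".join(out)


def simulate_reads(
    config: SimulationConfig,
) -> tuple[list[Read], list[GroundTruthRecord]]:
    """Generate concatemeric reads plus per-read ground truth.

    Identical config (including seed) yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    templates = [build_circular_template(s, config.adapter) for s in config.insert_sequences]
    base_q = _phred_for_rate(config.total_error_rate)

    reads: list[Read] = []
    truth: list[GroundTruthRecord] = []
    for i in range(config.n_reads):
        t_idx = int(rng.integers(len(templates)))
        template = templates[t_idx]
        length = len(template)
        if config.repeat_distribution == "fixed":
            repeat = config.repeat_min
        else:
            repeat = int(rng.integers(config.repeat_min, config.repeat_max + 1))
        phase = (
            int(rng.integers(length)) if config.fixed_phase is None else config.fixed_phase % length
        )
        tail = int(rng.integers(length)) if config.fixed_tail is None else config.fixed_tail % length
        strand = "-" if rng.random() < config.strand_fraction else "+"

        rolled = template[phase:] + template[:phase]
        clean = rolled * repeat
        if tail:
            clean = clean[:-tail]
        noisy = _apply_errors(clean, config, rng)
        if strand == "-":
            noisy = revcomp(noisy)

        if config.quality_jitter > 0:
            j = config.quality_jitter
            quals = tuple(
                int(q)
                for q in np.clip(
                    base_q + rng.integers(-j, j + 1, size=len(noisy)), 2, 40
                )
            )
        else:
            quals = (base_q,) * len(noisy)

        read_id = f"sim-{i:05d}"
        reads.append(Read(id=read_id, bases=noisy, quals=quals))
        truth.append(
            GroundTruthRecord(
                read_id=read_id,
                template_index=t_idx,
                true_repeat_count=repeat,
                true_strand=strand,
                true_phase_offset=phase,
            )
        )
    return reads, truth


def write_truth_tsv(records: Iterable[GroundTruthRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("read_id\ttemplate_index\trepeat_count\tstrand\tphase_offset\n")
        for r in records:
            handle.write(
                f"{r.read_id}\t{r.template_index}\t{r.true_repeat_count}"
                f"\t{r.true_strand}\t{r.true_phase_offset}\n"
            )


def random_references(
    n: int, min_len: int = 18, max_len: int = 26, seed: int = 0
) -> list[tuple[str, str]]:
    """Distinct random reference sequences, e.g. a synthetic equimolar pool."""
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(_BASES[b] for b in rng.integers(4, size=length))
        if seq not in seen:
            seen.add(seq)
            seqs.append(seq)
    return [(f"ref-{i:04d}", s) for i, s in enumerate(seqs)]
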