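"""FASTQ/FASTA I/O and read-level length / mean-quality filtering.

Reads are filtered by length (strictly greater than ``min_length``) and by
average per-base Phred quality (at least ``min_mean_quality``) before any
repeat detection. "Average quality" defaults to the arithmetic mean of the
Phred scores; the error-probability-weighted alternative used by some
basecallers is available via ``FilterConfig.quality_metric``.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np
from Bio import SeqIO

from ._seq import to_dna

MAX_PHRED = 93


class FastqParseError(ValueError):
    """Raised when a FASTQ record cannot be parsed; names the record index."""


@dataclass(frozen=True)
class Read:
    """One nanopore read: identifier, basecalled sequence and Phred scores."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but {len(self.quals)} qualities"
            )
        if self.quals and not (0 <= min(self.quals) and max(self.quals) <= MAX_PHRED):
            raise ValueError(f"read {self.id!r}: Phred scores must lie in [0, {MAX_PHRED}]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class FilterConfig:
    """Length is compared strictly (>), quality inclusively (>=)."""

    min_length: int = 1000
    min_mean_quality: float = 7.0
    quality_metric: str = "phred_mean"  # or "error_mean"

    def __post_init__(self) -> None:
        if self.min_length < 0:
            raise ValueError("min_length must be >= 0")
        if self.min_mean_quality < 0:
            raise ValueError("min_mean_quality must be >= 0")
        if self.quality_metric not in ("phred_mean", "error_mean"):
            raise ValueError("quality_metric must be 'phred_mean' or 'error_mean'")


@dataclass
class FilterResult:
    kept: list[Read] = field(default_factory=list)
    n_kept: int = 0
    n_dropped: int = 0

    @property
    def n_total(self) -> int:
        return self.n_kept + self.n_dropped


def mean_quality(read: Read, metric: str = "phred_mean") -> float:
    """Average per-base quality of a read.

    ``phred_mean`` is the arithmetic mean of the Phred scores; ``error_mean``
    converts to error probabilities, averages, and converts back.
    """
    if len(read) == 0:
        raise ValueError(f"read {read.id!r} is empty")
    q = np.asarray(read.quals, dtype=float)
    if metric == "phred_mean":
        return float(q.mean())
    if metric == "error_mean":
        return float(-10.0 * math.log10(np.power(10.0, -q / 10.0).mean()))
    raise ValueError(f"unknown quality metric {metric!r}")


def filter_reads(reads: Iterable[Read], cfg: FilterConfig = FilterConfig()) -> FilterResult:
    """Keep reads with length > min_length and mean quality >= min_mean_quality.

    Input order is preserved; kept/dropped counts are reported alongside.
    """
    result = FilterResult()
    for read in reads:
        if len(read) > cfg.min_length and (
            len(read) > 0 and mean_quality(read, cfg.quality_metric) >= cfg.min_mean_quality
        ):
            result.kept.append(read)
            result.n_kept += 1
        else:
            result.n_dropped += 1
    return result


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Parse Phred+33 FASTQ (optionally gzipped) into Read records.

    RNA bases (U) are transliterated to T at ingest; a malformed record
    raises :class:`FastqParseError` naming the record index.
    """
    index = 0
    with _open_text(path) as handle:
        parser = SeqIO.parse(handle, "fastq")
        while True:
            try:
                record = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(f"malformed FASTQ record at index {index}: {exc}") from exc
            yield Read(
                id=record.id,
                bases=to_dna(str(record.seq)),
                quals=tuple(record.letter_annotations["phred_quality"]),
            )
            index += 1


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write standard 4-line Phred+33 FASTQ; returns the record count."""
    n = 0
    with _open_text(path, "wt") as handle:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            handle.write(f"@{read.id}\n{read.bases}\n+\n{qual}\n")
            n += 1
    return n


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write (header, sequence) pairs as FASTA; returns the record count."""
    n = 0
    with _open_text(path, "wt") as handle:
        for header, seq in records:
            handle.write(f">{header}\n{seq}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (id, DNA sequence) pairs; U is transliterated to T."""
    with _open_text(path) as handle:
        return [(rec.id, to_dna(str(rec.seq))) for rec in SeqIO.parse(handle, "fasta")]
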