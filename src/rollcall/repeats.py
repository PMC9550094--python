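"""Tandem-repeat detection by k-mer positional periodicity.

A concatemeric read contains one copy of every template k-mer per traversal
of the circle, so the occurrence positions of such k-mers form near-arithmetic
progressions whose common difference is the template length. Detection
proceeds in three steps:

1. Candidate k-mers: count k-mer occurrences in sliding windows (50%
   overlap); a k-mer reaching ``peak_height`` occurrences within any single
   window is a periodicity candidate.
2. Runs and regions: for each candidate the sorted hit positions are split
   wherever consecutive hits are more than ``gap`` bases apart; every run of
   at least ``peak_height`` hits spans a region, extended by ``margin`` on
   both sides and clipped to the read. Overlapping regions from different
   k-mers are merged. The period of a merged region is the mode, across
   contributing runs, of the (rounded) median inter-hit spacing — the median
   is robust to hits lost to sequencing errors, and the cross-k-mer vote
   suppresses k-mers that happen to occur more than once per repeat unit.
3. Unit segmentation: one anchor k-mer per region — the most frequent k-mer
   whose own median spacing is consistent with the region period — cuts the
   region at each of its occurrences. Spans covering several periods (anchor
   hits lost to errors) are split evenly; flanking partial copies shorter
   than half a period are discarded.

Anchor ties are broken on the strand-canonical form min(kmer, revcomp) so
that detection is symmetric under reverse complementation of the read.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._seq import revcomp
from .reads import Read

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RepeatParams:
    k: int = 5
    window: int = 1000
    peak_height: int = 10
    gap: int = 200
    margin: int = 200
    letter_consistency: float = 0.5

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if self.window <= 2 * self.k:
            raise ValueError("window must exceed 2k")
        if self.peak_height < 2:
            raise ValueError("peak_height must be >= 2")
        if not 0.0 < self.letter_consistency <= 1.0:
            raise ValueError("letter_consistency must lie in (0, 1]")
        if self.gap < 1 or self.margin < 0:
            raise ValueError("gap must be >= 1 and margin >= 0")


@dataclass
class RepeatAnnotation:
    """A detected periodic region of a read and its repeat-unit intervals."""

    read_id: str
    region: tuple[int, int]  # half-open, 0-based on the read
    period: int
    unit_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return len(self.unit_intervals)


class AnchorError(ValueError):
    """Raised when a region has no usable anchor k-mer (fewer than 2 hits)."""


def _kmer_positions(seq: str, k: int) -> dict[str, np.ndarray]:
    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        positions[seq[i : i + k]].append(i)
    return {kmer: np.asarray(pos) for kmer, pos in positions.items()}


def _window_starts(n: int, window: int) -> list[int]:
    if n <= window:
        return [0]
    starts = list(range(0, n - window + 1, max(1, window // 2)))
    if starts[-1] != n - window:
        starts.append(n - window)
    return starts


def _max_window_count(pos: np.ndarray, starts: Sequence[int], window: int) -> int:
    best = 0
    for ws in starts:
        lo = np.searchsorted(pos, ws, side="left")
        hi = np.searchsorted(pos, ws + window, side="left")
        best = max(best, int(hi - lo))
    return best


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def find_periodic_region(read: Read, params: RepeatParams = RepeatParams()) -> list[RepeatAnnotation]:
    """Detect periodic repeat regions in a read; empty list when none."""
    seq = read.bases
    n = len(seq)
    if n < params.k:
        return []
    positions = _kmer_positions(seq, params.k)
    starts = _window_starts(n, params.window)

    # runs: (start, end, median spacing, kmer, hit positions)
    runs: list[tuple[int, int, float, str, np.ndarray]] = []
    for kmer, pos in positions.items():
        if len(pos) < params.peak_height:
            continue
        if _max_window_count(pos, starts, params.window) < params.peak_height:
            continue
        diffs = np.diff(pos)
        breaks = np.nonzero(diffs > params.gap)[0]
        for chunk in np.split(pos, breaks + 1):
            if len(chunk) < params.peak_height:
                continue
            start = max(0, int(chunk[0]) - params.margin)
            end = min(n, int(chunk[-1]) + params.k + params.margin)
            spacing = float(np.median(np.diff(chunk)))
            runs.append((start, end, spacing, kmer, chunk))

    if not runs:
        return []

    # merge overlapping regions across k-mers
    runs.sort(key=lambda r: (r[0], r[1]))
    merged: list[list] = []  # [start, end, list of runs]
    for run in runs:
        if merged and run[0] < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], run[1])
            merged[-1][2].append(run)
        else:
            merged.append([run[0], run[1], [run]])

    annotations: list[RepeatAnnotation] = []
    for start, end, region_runs in merged:
        votes = Counter(_round_half_up(r[2]) for r in region_runs)
        top = max(votes.values())
        period = min(p for p, c in votes.items() if c == top)
        if period <= 0:
            continue
        try:
            units = _cut_units(region_runs, (start, end), period, params)
        except AnchorError as exc:
            logger.warning("read %s region (%d,%d): %s", read.id, start, end, exc)
            continue
        annotations.append(
            RepeatAnnotation(
                read_id=read.id, region=(start, end), period=period, unit_intervals=units
            )
        )
    return annotations


def _cut_units(
    region_runs: list[tuple[int, int, float, str, np.ndarray]],
    region: tuple[int, int],
    period: int,
    params: RepeatParams,
) -> list[tuple[int, int]]:
    """Cut a region into repeat-unit intervals at anchor k-mer occurrences."""
    # anchor: most hits among k-mers whose spacing agrees with the period;
    # tie-break on the strand-canonical k-mer form, then the k-mer itself.
    # A k-mer occurring more than once per repeat unit shows alternating
    # spacings whose median can still fall near the period; such k-mers are
    # betrayed by their many sub-period gaps and must not anchor the cuts.
    def _period_consistent(run) -> bool:
        if not (0.75 * period <= run[2] <= 1.25 * period and len(run[4]) >= 2):
            return False
        diffs = np.diff(run[4])
        return float((diffs < 0.75 * period).mean()) <= 0.2

    eligible = [r for r in region_runs if _period_consistent(r)]
    if not eligible:
        raise AnchorError("no anchor k-mer with period-consistent spacing and >= 2 hits")
    anchor = min(eligible, key=lambda r: (-len(r[4]), min(r[3], revcomp(r[3])), r[3]))
    hits = [int(h) for h in anchor[4]]

    start, end = region
    spans = (
        [(start, hits[0], "lead")]
        + [(a, b, "mid") for a, b in zip(hits, hits[1:])]
        + [(hits[-1], end, "trail")]
    )
    pieces: list[tuple[int, int, int]] = []  # (start, end, effective length)
    for s, e, kind in spans:
        d = e - s
        if d <= 0:
            continue
        copies = max(1, _round_half_up(d / period))
        cuts = [s + _round_half_up(j * d / copies) for j in range(copies + 1)]
        for a, b in zip(cuts, cuts[1:]):
            eff = b - a
            if kind == "lead" and a == s:
                # a leading partial copy ends at the anchor; judge its length
                # inclusive of the anchor k-mer so the kept-unit count is
                # invariant under reverse complementation of the read
                eff += params.k
            pieces.append((a, b, eff))
    # keep near-period pieces; drop short flank partials and mis-split spans
    return [
        (a, b) for a, b, eff in pieces if eff >= 0.5 * period and (b - a) <= 1.5 * period
    ]


def segment_units(read: Read, annotation: RepeatAnnotation) -> list[str]:
    """Repeat-unit subsequences of a read, in order along the read."""
    if annotation.read_id != read.id:
        raise ValueError("annotation does not belong to this read")
    if annotation.n_units < 2:
        raise AnchorError(
            f"read {read.id}: region {annotation.region} has fewer than 2 repeat units"
        )
    return [read.bases[s:e] for s, e in annotation.unit_intervals]


def write_bed(annotations: Iterable[RepeatAnnotation], path: str | Path) -> None:
    """Annotations as BED (0-based, half-open): period in column 5, n_units in 7."""
    with open(path, "w") as handle:
        for ann in annotations:
            s, e = ann.region
            handle.write(
                f"{ann.read_id}\t{s}\t{e}\trepeat\t{ann.period}\t+\t{ann.n_units}\n"
            )
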