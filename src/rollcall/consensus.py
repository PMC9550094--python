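"""Per-read consensus calling from aligned repeat units.

The units of one read are near-identical short strings, so a center-star
multiple alignment is used: every unit is globally aligned (Needleman-
Wunsch, match +2 / mismatch -3 / gap open -5 / extend -2) to the unit whose
length is closest to the median, and the pairwise alignments are merged
column-wise ("once a gap, always a gap" in center coordinates, shared gap
columns left-aligned). The consensus emits, per column, the plurality base
when it reaches the letter-consistency threshold; columns where the gap
symbol is the strict plurality at or above the threshold emit nothing —
this removes bases created by random insertion errors, which appear in only
one unit each.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._align import make_aligner

_BASE_ORDER = "ACGT"  # fixed tie-break order


@dataclass(frozen=True)
class ConsensusRecord:
    read_id: str
    sequence: str
    n_units: int
    mean_unit_identity: float

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("consensus sequence must be non-empty")
        if self.n_units < 2:
            raise ValueError("a consensus requires at least 2 units")
        if not 0.0 <= self.mean_unit_identity <= 1.0:
            raise ValueError("mean_unit_identity must lie in [0, 1]")


class TooFewUnitsError(ValueError):
    """Fewer than two repeat units: consensus is skipped for the read."""


def _pairwise(aligner, center: str, unit: str) -> tuple[str, str]:
    alignment = aligner.align(center, unit)[0]
    return str(alignment[0]), str(alignment[1])


def _merge(master: str, rows: list[str], c_aln: str, u_aln: str) -> tuple[str, list[str], str]:
    """Merge one pairwise (center, unit) alignment into the growing MSA."""
    i = j = 0
    new_master: list[str] = []
    new_rows: list[list[str]] = [[] for _ in rows]
    new_unit: list[str] = []
    while i < len(master) or j < len(c_aln):
        mc = master[i] if i < len(master) else None
        cc = c_aln[j] if j < len(c_aln) else None
        if mc is not None and cc is not None and (mc == cc or (mc != "-" and cc != "-")):
            # same center character, or shared gap column (left-aligned)
            new_master.append(mc)
            for row, new_row in zip(rows, new_rows):
                new_row.append(row[i])
            new_unit.append(u_aln[j])
            i += 1
            j += 1
        elif mc == "-":
            new_master.append("-")
            for row, new_row in zip(rows, new_rows):
                new_row.append(row[i])
            new_unit.append("-")
            i += 1
        else:  # cc == "-" or master exhausted
            new_master.append("-" if cc is None else cc)
            for new_row in new_rows:
                new_row.append("-")
            new_unit.append(u_aln[j] if cc is not None else "-")
            j += 1
    return "".join(new_master), ["".join(r) for r in new_rows], "".join(new_unit)


def align_units(units: Sequence[str]) -> list[str]:
    """Center-star multiple alignment; returns gap-padded rows, one per unit,
    in the input order."""
    units = [u.upper() for u in units]
    if len(units) < 2:
        raise TooFewUnitsError("need at least 2 repeat units to align")
    if any(not u for u in units):
        raise ValueError("units must be non-empty")
    lengths = sorted(len(u) for u in units)
    median = lengths[len(lengths) // 2]
    center_idx = min(range(len(units)), key=lambda i: (abs(len(units[i]) - median), i))
    center = units[center_idx]

    aligner = make_aligner("global")
    master = center
    rows: list[str] = []  # aligned units in processing order (center excluded)
    for idx, unit in enumerate(units):
        if idx == center_idx:
            continue
        c_aln, u_aln = _pairwise(aligner, center, unit)
        master, rows, merged_unit = _merge(master, rows, c_aln, u_aln)
        rows.append(merged_unit)

    # restore input order, with the center as its own (gap-pattern) row
    out: list[str] = []
    r = 0
    for idx in range(len(units)):
        if idx == center_idx:
            out.append(master)
        else:
            out.append(rows[r])
            r += 1
    return out


def call_consensus(
    columns: Sequence[str], letter_consistency: float = 0.5, read_id: str = ""
) -> ConsensusRecord:
    """Plurality-vote consensus over MSA columns.

    A column emits its plurality base unless the gap symbol is the strict
    plurality and reaches the letter-consistency threshold; base-vs-gap ties
    favour the base, base-vs-base ties are broken in A<C<G<T order.
    """
    if not columns:
        raise ValueError("empty alignment")
    n_rows = len(columns)
    width = len(columns[0])
    if any(len(row) != width for row in columns):
        raise ValueError("alignment rows must have equal length")

    consensus: list[str] = []
    calls: list[str] = []  # per-column call incl. gap, for identity scoring
    for c in range(width):
        col = [row[c] for row in columns]
        base_counts = {b: 0 for b in _BASE_ORDER}
        gaps = 0
        for ch in col:
            if ch == "-":
                gaps += 1
            else:
                base_counts[ch] = base_counts.get(ch, 0) + 1
        best = max(_BASE_ORDER, key=lambda b: base_counts[b])
        # max() scans A<C<G<T and keeps the first maximum: ties break low
        best_n = base_counts[best]
        if gaps > best_n and gaps / n_rows >= letter_consistency:
            calls.append("-")
        else:
            consensus.append(best)
            calls.append(best)

    sequence = "".join(consensus)
    emitted = [i for i, ch in enumerate(calls) if ch != "-"]
    if emitted:
        identities = [
            sum(1 for i in emitted if row[i] == calls[i]) / len(emitted) for row in columns
        ]
        mean_identity = float(np.mean(identities))
    else:
        mean_identity = 0.0
    return ConsensusRecord(
        read_id=read_id, sequence=sequence, n_units=n_rows, mean_unit_identity=mean_identity
    )


def consensus_from_units(
    units: Sequence[str], letter_consistency: float = 0.5, read_id: str = ""
) -> ConsensusRecord:
    """Align units and call the consensus in one step."""
    return call_consensus(align_units(units), letter_consistency, read_id)
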