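"""Insert accuracy against a reference, and abundance bias against an
equimolar pool.

Accuracy uses a soft-clipped local (Smith-Waterman) alignment: the edit
distance inside the aligned region (mismatch + gap columns) is subtracted
from the number of aligned columns, giving

    percent_identity = 100 * (aligned_bases - edit_distance) / aligned_bases.

An alternative denominator (reference length) is available via
``denominator="reference"`` for comparability with mappers that count
soft-clipped bases as errors.

Pool quantification assigns each insert to its nearest pool member by
bounded edit distance (<= 2, unique best hit), normalises raw counts by the
expected per-member count (total mapped / pool size, so a perfectly
represented member scores 1.0), and summarises bias as the percentage of
members whose normalised count lies within two-fold of expectation
([0.5, 2.0], closed interval).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from ._align import alignment_column_counts, make_aligner
from ._seq import validate_seq


@dataclass(frozen=True)
class AccuracyRecord:
    read_id: str
    aligned_bases: int
    edit_distance: int
    percent_identity: float
    flagged: bool = False  # no positive-scoring local alignment


@dataclass
class CountTable:
    """Per-reference raw and normalised counts for a pool of references."""

    counts: pd.DataFrame  # index: reference_id; columns: raw_count, normalized_count
    pool_size: int
    total_mapped: int
    unmapped: int = 0

    def __post_init__(self) -> None:
        if self.pool_size <= 0:
            raise ValueError("pool_size must be positive")
        if int(self.counts["raw_count"].sum()) != self.total_mapped:
            raise ValueError("raw counts must sum to total_mapped")


def score_accuracy(
    insert: str, reference: str, read_id: str = "", denominator: str = "aligned"
) -> AccuracyRecord:
    """Percent identity of an insert to a reference by local alignment.

    Scoring is match +2 / mismatch -3 / gap open -5 / extend -2 with
    soft-clipping; an insert with no positive-scoring local alignment is
    flagged at 0% identity.
    """
    insert = validate_seq(insert, "insert")
    reference = validate_seq(reference, "reference")
    if denominator not in ("aligned", "reference"):
        raise ValueError("denominator must be 'aligned' or 'reference'")
    aligner = make_aligner("local")
    alignments = aligner.align(insert, reference)
    if len(alignments) == 0 or alignments[0].score <= 0:
        return AccuracyRecord(read_id, 0, 0, 0.0, flagged=True)
    alignment = alignments[0]
    identities, mismatches, gaps = alignment_column_counts(alignment)
    aligned_bases = identities + mismatches + gaps
    edit_distance = mismatches + gaps
    # aligned_bases - edit_distance == identities; the alternative denominator
    # charges soft-clipped reference bases against identity
    denom = aligned_bases if denominator == "aligned" else len(reference)
    percent = 100.0 * identities / denom if denom else 0.0
    return AccuracyRecord(
        read_id=read_id,
        aligned_bases=aligned_bases,
        edit_distance=edit_distance,
        percent_identity=max(0.0, percent),
    )


def accuracy_histogram(
    records: Sequence[AccuracyRecord], thresholds: Sequence[float] = (95.0, 100.0)
) -> pd.DataFrame:
    """Counts and fractions of reads at or above each identity threshold."""
    if not records:
        raise ValueError("no accuracy records to summarise")
    identities = np.array([r.percent_identity for r in records])
    rows = []
    for t in thresholds:
        n = int((identities >= t).sum())
        rows.append({"threshold": t, "count": n, "fraction": n / len(records)})
    return pd.DataFrame(rows)


def map_to_pool(
    inserts: Iterable[str],
    pool: Sequence[tuple[str, str]],
    max_distance: int = 2,
) -> CountTable:
    """Assign inserts to pool members by bounded edit distance.

    An insert counts toward the member with minimum global edit distance,
    provided that distance is <= ``max_distance`` and the best hit is
    unique; ambiguous or distant inserts are counted unmapped.
    """
    pool = list(pool)
    if not pool:
        raise ValueError("reference pool is empty")
    ids = [pid for pid, _ in pool]
    if len(set(ids)) != len(ids):
        raise ValueError("pool reference ids must be distinct")
    seqs = [validate_seq(s, f"pool member {pid}") for pid, s in pool]

    raw = {pid: 0 for pid in ids}
    unmapped = 0
    total = 0
    for insert in inserts:
        insert = validate_seq(insert, "insert", allow_empty=True)
        best_d, best_i, ambiguous = None, None, False
        if insert:
            for i, seq in enumerate(seqs):
                d = edlib.align(insert, seq, mode="NW", task="distance", k=max_distance)[
                    "editDistance"
                ]
                if d < 0:
                    continue
                if best_d is None or d < best_d:
                    best_d, best_i, ambiguous = d, i, False
                elif d == best_d:
                    ambiguous = True
        if best_d is None or ambiguous:
            unmapped += 1
        else:
            raw[ids[best_i]] += 1
            total += 1

    frame = pd.DataFrame(
        {"raw_count": [raw[pid] for pid in ids], "normalized_count": np.nan},
        index=pd.Index(ids, name="reference_id"),
    )
    return CountTable(counts=frame, pool_size=len(pool), total_mapped=total, unmapped=unmapped)


def normalize_counts(table: CountTable) -> CountTable:
    """Divide raw counts by the expected per-member count (total/pool size)."""
    if table.total_mapped <= 0:
        raise ValueError("cannot normalise a table with no mapped reads")
    expected = table.total_mapped / table.pool_size
    frame = table.counts.copy()
    frame["normalized_count"] = frame["raw_count"] / expected
    return CountTable(
        counts=frame,
        pool_size=table.pool_size,
        total_mapped=table.total_mapped,
        unmapped=table.unmapped,
    )


def bias_within_twofold(table: CountTable) -> float:
    """Percentage of pool members with normalised count in [0.5, 2.0]."""
    norm = table.counts["normalized_count"]
    if norm.isna().any():
        raise ValueError("normalised counts have not been computed")
    inside = ((norm >= 0.5) & (norm <= 2.0)).sum()
    return 100.0 * float(inside) / table.pool_size
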