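"""Circular-phase resolution and adapter trimming of per-read consensuses.

A consensus inherits an arbitrary rotation of the circular template
(insert + adapter) and may be on either cDNA strand. All rotations of the
consensus are enumerated and the adapter — in both orientations — is
globally aligned to each. The chosen rotation is the first (lowest offset)
that maximises the matching columns of a gap-free aligned run touching the
start or the end of the rotated sequence; that makes the adapter flush with
one end, so trimming it leaves a contiguous insert. Minus-strand inserts
are reverse-complemented back to the reference sense before output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from ._align import make_aligner
from ._seq import revcomp, validate_seq
from .consensus import ConsensusRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhasedInsert:
    read_id: str
    insert: str
    rotation_offset: int
    adapter_interval: tuple[int, int]  # half-open, on the rotated consensus
    strand: str  # "+" or "-"
    anchored_end: str  # "start" or "end"
    ungapped_alignment_length: int
    unphaseable: bool = False


class UnphaseableError(ValueError):
    """No rotation places an adequate un-gapped adapter run at either end."""


def enumerate_rotations(sequence: str) -> list[str]:
    """All |s| cyclic rotations, in offset order 0..|s|-1."""
    sequence = validate_seq(sequence, "sequence")
    return [sequence[i:] + sequence[:i] for i in range(len(sequence))]


def _anchored_runs(alignment, target: str, query: str) -> list[tuple[int, int, int]]:
    """Gap-free aligned blocks touching the target start or end.

    Returns (matching columns in the block, target start, target end)
    triples. A gap-free run is scored by its matching columns — a run of
    mismatches says nothing about where the adapter sits.
    """
    t_blocks, q_blocks = alignment.aligned
    runs = []
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if ts == 0 or te == len(target):
            matches = sum(a == b for a, b in zip(target[ts:te], query[qs:qe]))
            runs.append((int(matches), int(ts), int(te)))
    return runs


def phase_consensus(
    consensus: ConsensusRecord | str,
    adapter: str,
    min_run_fraction: float = 0.5,
) -> PhasedInsert:
    """Resolve the rotation and strand of a consensus against a known adapter.

    A consensus whose best anchored un-gapped run is shorter than
    ``min_run_fraction`` of the adapter is flagged unphaseable (and an empty
    recovered insert is likewise flagged).
    """
    if isinstance(consensus, ConsensusRecord):
        read_id, seq = consensus.read_id, consensus.sequence
    else:
        read_id, seq = "", consensus
    seq = validate_seq(seq, "consensus")
    adapter = validate_seq(adapter, "adapter")
    if len(seq) <= 0.5 * len(adapter):
        raise ValueError("consensus shorter than half the adapter cannot be phased")

    aligner = make_aligner("global")
    orientations = (("+", adapter), ("-", revcomp(adapter)))
    best = None  # (run length, rotation offset, strand, footprint, anchored end)
    L = len(seq)
    for offset, rotation in enumerate(enumerate_rotations(seq)):
        for strand, query in orientations:
            alignment = aligner.align(rotation, query)[0]
            runs = _anchored_runs(alignment, rotation, query)
            if not runs:
                continue
            run_len = max(r[0] for r in runs)
            blocks = alignment.aligned[0]
            footprint = (int(blocks[0][0]), int(blocks[-1][1]))
            anchored = "start" if any(r[1] == 0 and r[0] == run_len for r in runs) else "end"
            key = (-run_len, offset, 0 if strand == "+" else 1)
            if best is None or key < best[0]:
                best = (key, offset, strand, footprint, anchored, run_len)

    if best is None:
        return PhasedInsert(read_id, "", 0, (0, 0), "+", "start", 0, unphaseable=True)
    _, offset, strand, footprint, anchored, run_len = best
    rotation = seq[offset:] + seq[:offset]
    if anchored == "start":
        interval = (0, footprint[1])
        insert = rotation[footprint[1] :]
    else:
        interval = (footprint[0], L)
        insert = rotation[: footprint[0]]
    if strand == "-":
        insert = revcomp(insert)
    flagged = run_len < min_run_fraction * len(adapter) or not insert
    if flagged:
        logger.info(
            "consensus %s unphaseable (best anchored run %d of adapter %d)",
            read_id or "<anonymous>", run_len, len(adapter),
        )
    return PhasedInsert(
        read_id=read_id,
        insert=insert,
        rotation_offset=offset,
        adapter_interval=interval,
        strand=strand,
        anchored_end=anchored,
        ungapped_alignment_length=run_len,
        unphaseable=flagged,
    )


def trim_adapter(phased: PhasedInsert) -> str:
    """The adapter-free insert of a successfully phased consensus."""
    if phased.unphaseable:
        raise UnphaseableError(f"consensus {phased.read_id!r} was flagged unphaseable")
    if not phased.insert:
        logger.warning("consensus %s: adapter covers the whole sequence", phased.read_id)
    return phased.insert
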