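"""Pairwise aligner construction shared by the consensus, phasing and scoring stages.

One scoring scheme is used throughout: match +2, mismatch -3, gap open -5,
gap extend -2 (a gap of length g costs 5 + 2*(g-1)).
"""

from __future__ import annotations

from Bio import Align

MATCH = 2
MISMATCH = -3
GAP_OPEN = -5
GAP_EXTEND = -2


def make_aligner(mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def alignment_column_counts(alignment) -> tuple[int, int, int]:
    """(identities, mismatches, gap columns) within the alignment path.

    For a local alignment only the aligned region is counted; soft-clipped
    flanks contribute nothing.
    """
    counts = alignment.counts()
    return counts.identities, counts.mismatches, counts.gaps
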