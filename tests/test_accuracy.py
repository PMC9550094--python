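"""Accuracy scoring against references and equimolar-pool bias metrics."""

import numpy as np
import pandas as pd
import pytest

from rollcall import (
    CountTable,
    accuracy_histogram,
    bias_within_twofold,
    map_to_pool,
    normalize_counts,
    random_references,
    score_accuracy,
)
from rollcall._align import make_aligner
from rollcall.accuracy import AccuracyRecord

from conftest import random_seq

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -3, -5, -2
NEG = float("-inf")


def gotoh_local_score(a: str, b: str) -> float:
    """Naive affine-gap local alignment (Smith-Waterman/Gotoh) optimum,
    recomputed with explicit dynamic-programming matrices."""
    n, m = len(a), len(b)
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i, j] = max(0.0, s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]))
            X[i, j] = max(M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND)
            Y[i, j] = max(M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXTEND)
            best = max(best, M[i, j])
    return best


def recount_alignment_columns(alignment) -> tuple[int, int, int]:
    """Walk the alignment coordinates and recount identity / mismatch / gap
    columns independently of the library's own counting."""
    target, query = alignment.target, alignment.query
    coords = alignment.coordinates
    identities = mismatches = gaps = 0
    for c in range(coords.shape[1] - 1):
        t0, q0 = coords[0, c], coords[1, c]
        t1, q1 = coords[0, c + 1], coords[1, c + 1]
        dt, dq = t1 - t0, q1 - q0
        if dt and dq:
            for x, y in zip(target[t0:t1], query[q0:q1]):
                if x == y:
                    identities += 1
                else:
                    mismatches += 1
        else:
            gaps += dt + dq
    return identities, mismatches, gaps


class TestScoreAccuracy:
    def test_identical_insert(self, let7a):
        rec = score_accuracy(let7a, let7a)
        assert (rec.aligned_bases, rec.edit_distance) == (21, 0)
        assert rec.percent_identity == 100.0

    def test_single_mismatch(self, let7a):
        # an internal mismatch cannot be soft-clipped away
        base = "A" if let7a[10] != "A" else "C"
        mutated = let7a[:10] + base + let7a[11:]
        rec = score_accuracy(mutated, let7a)
        assert rec.edit_distance == 1
        assert rec.percent_identity == pytest.approx(100 * 20 / 21)

    def test_dissimilar_pair_flagged_zero(self):
        # no shared base at all: no positive-scoring local alignment exists
        rec = score_accuracy("AAAA", "TTTTTTTTTT")
        assert rec.flagged and rec.percent_identity == 0.0

    def test_soft_clipping_ignores_flanking_junk(self, let7a):
        rec = score_accuracy("GGGG" + let7a + "CCCC", let7a)
        assert rec.percent_identity == 100.0

    def test_matches_naive_dynamic_programming_oracle(self):
        """Percent identity on 200 random insert/reference pairs agrees
        exactly with an independent naive Gotoh DP recomputation."""
        rng = np.random.default_rng(404)
        aligner = make_aligner("local")
        for _ in range(200):
            reference = random_seq(rng, int(rng.integers(18, 31)))
            insert = list(reference)
            for _ in range(int(rng.integers(0, 4))):
                pos = int(rng.integers(len(insert)))
                op = rng.random()
                if op < 0.5:
                    insert[pos] = "ACGT"[rng.integers(4)]
                elif op < 0.75 and len(insert) > 1:
                    del insert[pos]
                else:
                    insert.insert(pos, "ACGT"[rng.integers(4)])
            insert = "".join(insert)
            rec = score_accuracy(insert, reference)
            alignment = aligner.align(insert, reference)[0]
            assert alignment.score == gotoh_local_score(insert, reference)
            identities, mismatches, gaps = recount_alignment_columns(alignment)
            if rec.flagged:
                assert alignment.score <= 0
                continue
            assert rec.aligned_bases == identities + mismatches + gaps
            assert rec.edit_distance == mismatches + gaps
            assert rec.percent_identity == pytest.approx(
                100.0 * identities / (identities + mismatches + gaps)
            )

    def test_reference_denominator_counts_clipping(self, let7a):
        rec = score_accuracy(let7a[:15], let7a, denominator="reference")
        assert rec.percent_identity == pytest.approx(100 * 15 / 21)


class TestAccuracyHistogram:
    def test_all_perfect(self):
        records = [AccuracyRecord("r", 21, 0, 100.0)] * 3
        hist = accuracy_histogram(records)
        assert (hist["fraction"] == 1.0).all()

    def test_mixed_identities(self):
        records = [
            AccuracyRecord("a", 21, 0, 100.0),
            AccuracyRecord("b", 21, 1, 95.2),
            AccuracyRecord("c", 20, 4, 80.0),
        ]
        hist = accuracy_histogram(records).set_index("threshold")
        assert hist.loc[95.0, "fraction"] == pytest.approx(2 / 3)
        assert hist.loc[100.0, "fraction"] == pytest.approx(1 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy_histogram([])


class TestMapToPool:
    POOL = [("m1", "ACGTACGTACGTACGTAC"), ("m2", "TTGGCCAATTGGCCAATT"), ("m3", "GATCGATCGATCGATCGA")]

    def test_exact_match_counts(self):
        table = map_to_pool([self.POOL[0][1]], self.POOL)
        assert table.counts.loc["m1", "raw_count"] == 1
        assert table.total_mapped == 1 and table.unmapped == 0

    def test_one_edit_still_maps(self):
        query = "A" + self.POOL[1][1][1:]
        table = map_to_pool([query], self.POOL)
        assert table.counts.loc["m2", "raw_count"] == 1

    def test_equidistant_insert_unmapped(self):
        pool = [("a", "AAAAAAAAAA"), ("b", "AAAAAAAAAC")]
        table = map_to_pool(["AAAAAAAAAG"], pool)  # distance 1 to both
        assert table.total_mapped == 0 and table.unmapped == 1

    def test_distant_insert_unmapped(self):
        table = map_to_pool(["A" * 18], self.POOL)
        assert table.unmapped == 1

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            map_to_pool(["ACGT"], [])

    def test_full_synthetic_pool_round_trip(self):
        """962 distinct members, one error-free read each: every count is 1."""
        pool = random_references(962, seed=5)
        table = map_to_pool([seq for _, seq in pool], pool)
        assert table.unmapped == 0
        assert (table.counts["raw_count"] == 1).all()
        table = normalize_counts(table)
        assert (table.counts["normalized_count"] == 1.0).all()
        assert bias_within_twofold(table) == 100.0


def make_table(raw: list[int], pool_size: int | None = None) -> CountTable:
    ids = [f"m{i}" for i in range(len(raw))]
    frame = pd.DataFrame(
        {"raw_count": raw, "normalized_count": np.nan},
        index=pd.Index(ids, name="reference_id"),
    )
    return CountTable(frame, pool_size or len(raw), int(sum(raw)))


class TestNormalization:
    def test_expected_count_normalises_to_one(self):
        # 962 members, 10 reads each: every member sits exactly at expectation
        table = normalize_counts(make_table([10] * 962))
        assert (table.counts["normalized_count"] == 1.0).all()

    def test_worked_ratio(self):
        # 9620 mapped reads over a 962-member pool: expected = 10 per member
        raw = [20] * 481 + [0] * 481
        table = normalize_counts(make_table(raw))
        assert table.total_mapped == 9620
        assert table.counts.iloc[0]["normalized_count"] == pytest.approx(2.0)

    def test_zero_raw_count_normalises_to_zero(self):
        table = normalize_counts(make_table([5, 0, 5]))
        assert table.counts.loc["m1", "normalized_count"] == 0.0

    def test_no_mapped_reads_rejected(self):
        with pytest.raises(ValueError):
            normalize_counts(make_table([0, 0]))

    def test_mean_normalized_count_is_one_with_full_pool(self):
        rng = np.random.default_rng(10)
        raw = list(rng.integers(1, 50, size=100))
        table = normalize_counts(make_table([int(x) for x in raw]))
        assert table.counts["normalized_count"].mean() == pytest.approx(1.0)


class TestBiasWithinTwofold:
    def test_uniform_pool_is_unbiased(self):
        table = normalize_counts(make_table([7] * 50))
        assert bias_within_twofold(table) == 100.0

    def test_extreme_skew(self):
        # 10 members hoard the reads (normalized ~4.8), 40 are nearly absent
        table = normalize_counts(make_table([195] * 10 + [2] * 40))
        assert bias_within_twofold(table) == 0.0

    def test_boundaries_inclusive(self):
        # normalized values exactly 0.5 and 2.0 both count as inside
        table = normalize_counts(make_table([2, 8, 3, 3]))  # expected 4 -> 0.5 and 2.0
        norm = table.counts["normalized_count"]
        assert norm.iloc[0] == 0.5 and norm.iloc[1] == 2.0
        assert bias_within_twofold(table) == 100.0

    def test_invariant_under_rescaling_raw_counts(self):
        raw = [3, 9, 1, 7, 0, 4]
        base = bias_within_twofold(normalize_counts(make_table(raw)))
        for factor in (2, 5, 17):
            scaled = bias_within_twofold(normalize_counts(make_table([factor * r for r in raw])))
            assert scaled == base
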