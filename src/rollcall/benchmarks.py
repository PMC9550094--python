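"""Reproducible benchmark scenarios run entirely from simulated data.

These functions regenerate the package's headline numbers from scratch:
the accuracy of consensus inserts from noisy rolling-circle reads of the
42 nt control template, exact recovery on error-free libraries, and the
repeat-count/read-length relationship. They are used by the test suite and
by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from ._seq import DEFAULT_ADAPTER, LET7A
from .accuracy import score_accuracy
from .phasing import trim_adapter
from .pipeline import process_reads
from .reads import FilterConfig, filter_reads
from .repeats import find_periodic_region
from .simulate import SimulationConfig, simulate_reads

#: Error model of the noisy benchmark: 8% total per-base error split
#: 50/25/25 between substitutions, insertions and deletions.
NOISY_ERRORS = {"sub_rate": 0.04, "ins_rate": 0.02, "del_rate": 0.02}


@dataclass(frozen=True)
class AccuracyBenchmark:
    n_reads: int
    n_inserts: int
    pct_ge_95: float
    pct_eq_100: float


def consensus_accuracy_benchmark(seed: int, n_reads: int = 1000) -> AccuracyBenchmark:
    """Full pipeline on noisy reads of the 42 nt control circle.

    Simulates ``n_reads`` concatemeric reads of the control template (21 nt
    miRNA insert + 21 nt adapter; repeat counts uniform 10-40; 8% total
    error), applies the standard length/quality filter, detects repeats,
    calls and phases consensuses, and scores every trimmed insert against
    the known insert. Returns the percentage of inserts at >= 95% and at
    100% identity.
    """
    config = SimulationConfig(
        insert_sequences=(LET7A,),
        adapter=DEFAULT_ADAPTER,
        n_reads=n_reads,
        repeat_min=10,
        repeat_max=40,
        seed=seed,
        **NOISY_ERRORS,
    )
    reads, _ = simulate_reads(config)
    filtered = filter_reads(reads, FilterConfig())
    _, phased, _ = process_reads(filtered.kept, DEFAULT_ADAPTER)
    identities = np.array(
        [
            score_accuracy(trim_adapter(p), LET7A, p.read_id).percent_identity
            for p in phased
            if p.insert
        ]
    )
    if identities.size == 0:
        return AccuracyBenchmark(n_reads, 0, 0.0, 0.0)
    return AccuracyBenchmark(
        n_reads=n_reads,
        n_inserts=int(identities.size),
        pct_ge_95=float((identities >= 95.0).mean() * 100.0),
        pct_eq_100=float((identities >= 100.0).mean() * 100.0),
    )


@dataclass(frozen=True)
class RecoveryBenchmark:
    n_reads: int
    n_detected: int
    fraction_exact_insert: float
    fraction_exact_period: float
    fraction_repeat_within_one: float


def error_free_recovery_benchmark(seed: int, n_reads: int = 200) -> RecoveryBenchmark:
    """Exact-recovery oracle on error-free reads of random templates.

    Each read uses a random insert (18-30 nt) plus the default adapter,
    a random rotation and strand, and repeat counts uniform 15-50 so every
    template k-mer clears the detector's peak-height threshold. The length
    filter is disabled: the check targets recovery, not read QC.
    """
    rng = np.random.default_rng(seed)
    inserts = tuple(
        "".join("ACGT"[b] for b in rng.integers(4, size=int(rng.integers(18, 31))))
        for _ in range(n_reads)
    )
    config = SimulationConfig(
        insert_sequences=inserts,
        adapter=DEFAULT_ADAPTER,
        n_reads=n_reads,
        repeat_min=15,
        repeat_max=50,
        seed=int(rng.integers(2**31)),
    )
    reads, truth = simulate_reads(config)
    exact_insert = exact_period = repeat_ok = detected = 0
    for read, gt in zip(reads, truth):
        annotations = find_periodic_region(read)
        if not annotations:
            continue
        detected += 1
        template_insert = inserts[gt.template_index]
        period_truth = len(template_insert) + len(DEFAULT_ADAPTER)
        _, phased, _ = process_reads([read], DEFAULT_ADAPTER)
        if len(annotations) == 1 and annotations[0].period == period_truth:
            exact_period += 1
        if any(abs(a.n_units - gt.true_repeat_count) <= 1 for a in annotations):
            repeat_ok += 1
        if any(p.insert == template_insert for p in phased):
            exact_insert += 1
    return RecoveryBenchmark(
        n_reads=n_reads,
        n_detected=detected,
        fraction_exact_insert=exact_insert / n_reads,
        fraction_exact_period=exact_period / n_reads,
        fraction_repeat_within_one=repeat_ok / n_reads,
    )


def repeat_length_correlation(seed: int, n_reads: int = 200) -> float:
    """Spearman rank correlation of read length vs detected unit count.

    Uses the noisy control-template model (repeat counts uniform 10-40, 8%
    total error) without the length filter, mirroring the expected
    proportionality between read length and repeat copies.
    """
    config = SimulationConfig(
        insert_sequences=(LET7A,),
        adapter=DEFAULT_ADAPTER,
        n_reads=n_reads,
        repeat_min=10,
        repeat_max=40,
        seed=seed,
        **NOISY_ERRORS,
    )
    reads, _ = simulate_reads(config)
    lengths, units = [], []
    for read in reads:
        annotations = find_periodic_region(read)
        if not annotations:
            continue
        lengths.append(len(read))
        units.append(sum(a.n_units for a in annotations))
    return float(spearmanr(lengths, units).statistic)
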