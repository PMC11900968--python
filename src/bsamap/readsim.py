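"""Pooled-sequencing read-count model.

Whole-genome sequencing of a DNA pool is reduced to its sufficient statistic per
variant site: the number of reads supporting the mutant allele and the total
read count. Site depth is Poisson around the pool's mean coverage; conditional
on depth, each read reports the mutant allele with probability
f' = f(1-e) + (1-f)e, where f is the true pooled allele frequency and e a
symmetric per-read miscall rate. SNPs and indels share this model, as one index
statistic is applied to both downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import PoolSpec, PopulationSim, pool_freqs

__all__ = [
    "SeqParams",
    "CountPair",
    "sample_read_counts",
    "sample_read_counts_array",
    "mean_depth",
    "simulate_pool_counts",
]


@dataclass(frozen=True)
class CountPair:
    """Mutant-allele and total read counts at one site in one pool."""

    alt_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if not 0 <= self.alt_reads <= self.total_reads:
            raise ValueError(
                f"invalid counts: alt={self.alt_reads}, total={self.total_reads}"
            )

    @property
    def ref_reads(self) -> int:
        return self.total_reads - self.alt_reads


@dataclass(frozen=True)
class SeqParams:
    """Sequencing design: mean depths per pool and the per-read error rate.

    Default depths are 43x for the mutant (white) pool and 33x for the
    wild-type (green) pool, the coverages of the mapping experiment this
    simulator emulates.
    """

    coverage_pool1: float = 43.0
    coverage_pool2: float = 33.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage_pool1 <= 0 or self.coverage_pool2 <= 0:
            raise ValueError("coverages must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")


def _effective_freq(freq: np.ndarray | float, error_rate: float):
    return freq * (1.0 - error_rate) + (1.0 - freq) * error_rate


def sample_read_counts(
    freq: float, cov: float, error_rate: float = 0.001, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CountPair:
    """Draw one (alt_reads, total_reads) pair for a site with pooled frequency ``freq``.

    total_reads ~ Poisson(cov); alt_reads ~ Binomial(total_reads, f') with the
    error-folded frequency f'. A zero-depth draw is returned as (0, 0), not
    suppressed; the index engine flags such sites as unevaluable.
    """
    if not 0.0 <= freq <= 1.0:
        raise ValueError("allele frequency must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    total = int(rng.poisson(cov))
    alt = int(rng.binomial(total, _effective_freq(freq, error_rate))) if total else 0
    return CountPair(alt, total)


def sample_read_counts_array(
    freqs: np.ndarray, cov: float, error_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised draw over many sites; returns (alt_reads, total_reads) arrays."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    totals = rng.poisson(cov, size=freqs.shape)
    alts = rng.binomial(totals, _effective_freq(freqs, error_rate))
    return alts, totals


def mean_depth(clean_bases: float, genome_size: float) -> tuple[int, float]:
    """Mean sequencing depth from total clean bases over a genome size.

    Returns (depth rounded to the nearest integer x, unrounded ratio):
    e.g. 12.14 Gb over a 370 Mb genome gives 33x.
    """
    if clean_bases <= 0:
        raise ValueError("clean_bases must be positive")
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    ratio = clean_bases / genome_size
    return int(round(ratio)), ratio


def simulate_pool_counts(
    pop: PopulationSim, pools: PoolSpec, seq: SeqParams
) -> tuple[list[CountPair], list[CountPair]]:
    """Sequence both phenotype pools at every simulated variant.

    Pool 1 is the mutant (white) pool, pool 2 the wild-type (green) pool, in
    the order the index filter expects. Deterministic for a fixed SeqParams seed.
    """
    rng = np.random.default_rng(seq.seed)
    f_white, f_green = pool_freqs(pop, pools)
    alt1, tot1 = sample_read_counts_array(f_white, seq.coverage_pool1, seq.error_rate, rng)
    alt2, tot2 = sample_read_counts_array(f_green, seq.coverage_pool2, seq.error_rate, rng)
    pool1 = [CountPair(int(a), int(t)) for a, t in zip(alt1, tot1)]
    pool2 = [CountPair(int(a), int(t)) for a, t in zip(alt2, tot2)]
    return pool1, pool2
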