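"""SNP/Indel-index computation and the two-pool candidate filter.

The SNP/Indel-index of a variant in a DNA pool is the ratio of reads carrying
the mutant allele to the total reads at that site. For a fully penetrant
recessive mutation mapped with two phenotype-selected pools from a selfed
heterozygote, the causal variant must show:

  1. index = 1 in the mutant pool (every mutant is homozygous for the
     causal allele, so every read is mutant), and
  2. index < 0.5 in the wild-type pool (a mix of homozygous wild-type,
     index 0, and heterozygous plants, index 0.5; expectation 1/3).

Unlinked heterozygous background variants sit near 0.5 in both pools and fail
criterion 1 at any reasonable depth, so the intersection of the two criteria
isolates variants tightly linked to the phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .population import (
    PoolSpec,
    PopulationSim,
    SimParams,
    build_pools,
    simulate_population,
)
from .readsim import CountPair, SeqParams, simulate_pool_counts

__all__ = [
    "VariantKey",
    "VariantRecord",
    "FilterConfig",
    "FilterResult",
    "MappingResult",
    "snp_index",
    "compute_indices",
    "apply_mutmap_filter",
    "rank_candidates",
    "run_mapping",
    "simulate_mapping_records",
]

#: expected wild-type-pool index at the causal locus (1 hom-ref : 2 het among
#: phenotypically normal sibs -> pooled allele frequency 1/3)
GREEN_POOL_EXPECTATION = 1.0 / 3.0

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant with per-pool counts and computed indices.

    ``index1``/``index2`` are None until computed, and None after computation
    exactly when the pool had zero depth (the index is undefined, never
    silently zero).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    pool1: CountPair
    pool2: CountPair
    index1: float | None = None
    index2: float | None = None

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    """The two-criterion candidate filter.

    The mutant-pool requirement is exact — alt_reads == total_reads — unless a
    nonzero ``mut_index_tolerance`` is set (accepting index >= 1 - tolerance),
    an off-by-default concession to error reads at high depth. ``wt_index_max``
    is a strict upper bound. Sites with either pool below ``min_depth`` total
    reads are reported as unevaluable rather than rejected: depth 1-2 sites
    reach index 1 too easily to be informative either way.
    """

    wt_index_max: float = 0.5
    min_depth: int = 5
    mut_index_tolerance: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.wt_index_max <= 1.0:
            raise ValueError("wt_index_max must lie in (0, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.0 <= self.mut_index_tolerance < 1.0:
            raise ValueError("mut_index_tolerance must lie in [0, 1)")


def snp_index(counts: CountPair) -> float:
    """SNP/Indel-index: alt_reads / total_reads.

    Raises on zero depth — an undefined index must be flagged, not coerced to 0.
    Full precision is retained here; output tables round to 2 decimals.
    """
    if counts.total_reads == 0:
        raise ValueError("SNP/Indel-index undefined at zero total depth")
    return counts.alt_reads / counts.total_reads


def compute_indices(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Fill index1/index2 on each record, leaving None where depth is zero."""
    out = []
    for rec in records:
        i1 = snp_index(rec.pool1) if rec.pool1.total_reads else None
        i2 = snp_index(rec.pool2) if rec.pool2.total_reads else None
        out.append(replace(rec, index1=i1, index2=i2))
    return out


@dataclass
class FilterResult:
    candidates: list[VariantRecord]
    rejected: list[VariantRecord]
    unevaluable: list[VariantRecord] = field(default_factory=list)


def _passes(rec: VariantRecord, cfg: FilterConfig) -> bool:
    if cfg.mut_index_tolerance == 0.0:
        crit1 = rec.pool1.alt_reads == rec.pool1.total_reads
    else:
        crit1 = rec.index1 is not None and rec.index1 >= 1.0 - cfg.mut_index_tolerance
    crit2 = rec.index2 is not None and rec.index2 < cfg.wt_index_max
    return crit1 and crit2


def apply_mutmap_filter(
    records: Iterable[VariantRecord], cfg: FilterConfig | None = None
) -> FilterResult:
    """Partition variants into candidates, rejections, and unevaluable sites.

    A candidate satisfies both pool criteria and has at least ``min_depth``
    total reads in each pool. The result is order-independent set semantics;
    ranking is a separate step.
    """
    cfg = cfg or FilterConfig()
    result = FilterResult([], [])
    for rec in compute_indices(records):
        if rec.pool1.total_reads < cfg.min_depth or rec.pool2.total_reads < cfg.min_depth:
            result.unevaluable.append(rec)
        elif _passes(rec, cfg):
            result.candidates.append(rec)
        else:
            result.rejected.append(rec)
    return result


def rank_candidates(candidates: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Order surviving candidates for reporting.

    Deeper mutant-pool support first; ties broken by closeness of the
    wild-type-pool index to its genetic expectation of 1/3, then by genomic
    coordinate. Stable and fully deterministic.
    """
    return sorted(
        candidates,
        key=lambda r: (
            -r.pool1.total_reads,
            abs((r.index2 if r.index2 is not None else 1.0) - GREEN_POOL_EXPECTATION),
            r.chrom,
            r.pos,
            r.ref,
            r.alt,
        ),
    )


@dataclass
class MappingResult:
    """Ranked candidates plus the full per-variant index report."""

    candidates: list[VariantRecord]
    table: pd.DataFrame
    unevaluable: list[VariantRecord]
    config: FilterConfig


def run_mapping(
    pool1_counts: Mapping[VariantKey, CountPair],
    pool2_counts: Mapping[VariantKey, CountPair],
    cfg: FilterConfig | None = None,
) -> MappingResult:
    """Join the two pools' counts, compute indices, filter, and rank.

    Variants present in only one pool are reported as unevaluable with a
    zero-depth CountPair standing in for the missing pool.
    """
    cfg = cfg or FilterConfig()
    keys = sorted(set(pool1_counts) | set(pool2_counts))
    records = [
        VariantRecord(
            *key,
            pool1=pool1_counts.get(key, CountPair(0, 0)),
            pool2=pool2_counts.get(key, CountPair(0, 0)),
        )
        for key in keys
    ]
    fres = apply_mutmap_filter(records, cfg)
    ranked = rank_candidates(fres.candidates)

    cand_keys = {r.key for r in fres.candidates}
    uneval_keys = {r.key for r in fres.unevaluable}
    rows = []
    for rec in compute_indices(records):
        status = (
            "candidate"
            if rec.key in cand_keys
            else "unevaluable" if rec.key in uneval_keys else "rejected"
        )
        reason = ""
        if status == "unevaluable":
            missing = [
                name
                for name, cp in (("pool1", rec.pool1), ("pool2", rec.pool2))
                if cp.total_reads < cfg.min_depth
            ]
            reason = "low depth: " + ",".join(missing)
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "alt1": rec.pool1.alt_reads,
                "tot1": rec.pool1.total_reads,
                "alt2": rec.pool2.alt_reads,
                "tot2": rec.pool2.total_reads,
                "index1": round(rec.index1, 2) if rec.index1 is not None else None,
                "index2": round(rec.index2, 2) if rec.index2 is not None else None,
                "index1_full": rec.index1,
                "index2_full": rec.index2,
                "status": status,
                "reason": reason,
            }
        )
    table = pd.DataFrame(rows)
    return MappingResult(ranked, table, fres.unevaluable, cfg)


def simulate_mapping_records(
    sim_params: SimParams,
    seq_params: SeqParams,
    n_white: int = 30,
    n_green: int = 30,
    pool_seed: int | None = None,
) -> tuple[PopulationSim, PoolSpec, list[VariantRecord]]:
    """One synthetic mapping experiment end to end.

    Simulates the selfed family, selects the phenotype pools, sequences both
    pools, and returns (population, pools, per-variant records) ready for
    ``apply_mutmap_filter`` or ``run_mapping``. Pool selection takes its own
    seed (default derived from the simulation seed).
    """
    pop = simulate_population(sim_params)
    if pool_seed is None:
        pool_seed = sim_params.seed + 1
    pools = build_pools(pop, n_white, n_green, seed=pool_seed)
    pool1, pool2 = simulate_pool_counts(pop, pools, seq_params)
    records = [
        VariantRecord(row.chrom, int(row.pos), row.ref, row.alt, p1, p2)
        for row, p1, p2 in zip(pop.variants.itertuples(index=False), pool1, pool2)
    ]
    return pop, pools, records
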