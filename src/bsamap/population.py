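"""Forward simulation of a selfed segregating family for bulked-segregant mapping.

A single heterozygous plant carries one causal recessive mutation plus a set of
background variants (the mutagenized-lineage load). Selfing yields progeny whose
genotype at the causal locus segregates 1 homozygous-reference : 2 heterozygous :
1 homozygous-mutant; only homozygous mutants show the (white, recessive) phenotype.
Phenotype-selected pools drawn from these progeny carry the allele-frequency
structure that the SNP/Indel-index statistic exploits: the mutant pool is fixed for
the causal allele, while unlinked heterozygous background variants sit near
frequency 0.5 in both pools.

Linkage follows the Haldane map function (no crossover interference); gametes are
generated per chromosome by sequential locus transmission. All genomic coordinates
are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Chromosome",
    "SimParams",
    "PopulationSim",
    "PoolSpec",
    "recomb_fraction",
    "simulate_population",
    "build_pools",
    "pooled_allele_freq",
]

GREEN = "green"
WHITE = "white"

#: genotype labels for the selfed parent
PARENT_HET = "het"
PARENT_HOM = "hom"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: physical length in bp and genetic length in Morgans.

    Physical positions are mapped to genetic positions by linear interpolation
    at a constant Morgans/bp rate (no genetic map is assumed).
    """

    name: str
    length_bp: int
    length_morgans: float

    def genetic_pos(self, pos_bp: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(pos_bp) / self.length_bp * self.length_morgans


def _rice_like_chromosomes() -> tuple[Chromosome, ...]:
    # 12 chromosomes, ~370 Mb genome, ~15.6 Morgans total map — rice-scale.
    return tuple(
        Chromosome(f"chr{i}", 31_000_000, 1.3) for i in range(1, 13)
    )


@dataclass(frozen=True)
class SimParams:
    """Design of the simulated family.

    Defaults reproduce the study conditions the pipeline targets: a rice-scale
    genome (~370 Mb), a causal variant on chromosome 8, ~2,000 mutagen-induced
    background variants, and a progeny population large enough to select
    30-plant phenotype pools from.
    """

    n_progeny: int = 240
    n_background: int = 2000
    chromosomes: tuple[Chromosome, ...] = field(default_factory=_rice_like_chromosomes)
    causal_chrom: str = "chr8"
    causal_pos: int = 14_169_090
    parent_het_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progeny <= 0:
            raise ValueError("n_progeny must be positive")
        if self.n_background < 0:
            raise ValueError("n_background must be non-negative")
        if not 0.0 <= self.parent_het_fraction <= 1.0:
            raise ValueError("parent_het_fraction must lie in [0, 1]")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if self.causal_chrom not in names:
            raise ValueError(
                f"causal variant placed on undeclared chromosome {self.causal_chrom!r}"
            )
        chrom = self.chrom(self.causal_chrom)
        if not 1 <= self.causal_pos <= chrom.length_bp:
            raise ValueError("causal_pos outside its chromosome")

    def chrom(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass
class PopulationSim:
    """A simulated selfed family.

    ``variants`` holds one row per variant (chrom, pos, ref, alt,
    parent_genotype, is_causal); ``dosages`` is the (n_progeny, n_variants)
    alt-allele dosage matrix with values in {0, 1, 2}; ``phenotypes`` labels
    each individual ``green`` or ``white``.
    """

    params: SimParams
    variants: pd.DataFrame
    dosages: np.ndarray
    phenotypes: np.ndarray

    @property
    def n_progeny(self) -> int:
        return self.dosages.shape[0]

    @property
    def causal_index(self) -> int:
        return int(np.flatnonzero(self.variants["is_causal"].to_numpy())[0])

    def white_ids(self) -> np.ndarray:
        return np.flatnonzero(self.phenotypes == WHITE)

    def green_ids(self) -> np.ndarray:
        return np.flatnonzero(self.phenotypes == GREEN)

    def write_truth(self, variants_path, dosages_path) -> None:
        """Write variant rows and the dosage matrix as TSV."""
        self.variants.to_csv(variants_path, sep="\t", index=False)
        pd.DataFrame(self.dosages).to_csv(
            dosages_path, sep="\t", index=False, header=False
        )


@dataclass(frozen=True)
class PoolSpec:
    """Phenotype-selected pools: member indices into the population."""

    white_members: np.ndarray
    green_members: np.ndarray

    def __post_init__(self) -> None:
        if set(self.white_members) & set(self.green_members):
            raise ValueError("pool members must be disjoint")

    @property
    def n_white(self) -> int:
        return len(self.white_members)

    @property
    def n_green(self) -> int:
        return len(self.green_members)

    def write(self, path) -> None:
        rows = [("white", int(i)) for i in self.white_members]
        rows += [("green", int(i)) for i in self.green_members]
        pd.DataFrame(rows, columns=["pool", "individual"]).to_csv(
            path, sep="\t", index=False
        )


def recomb_fraction(d: float) -> float:
    """Haldane map function: recombination fraction for d Morgans.

    r(d) = (1 - exp(-2 d)) / 2, assuming a Poisson crossover process with no
    interference. r(0) = 0 (complete linkage) and r -> 0.5 as d -> infinity
    (independent assortment).
    """
    d = float(d)
    if d < 0:
        raise ValueError("genetic distance must be non-negative")
    return (1.0 - np.exp(-2.0 * d)) / 2.0


def _draw_variant_sites(params: SimParams, rng: np.random.Generator) -> pd.DataFrame:
    """Place the causal indel plus background variants on the genome."""
    lengths = np.array([c.length_bp for c in params.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(params.chromosomes), size=params.n_background, p=probs)
    rows = []
    for i in range(params.n_background):
        chrom = params.chromosomes[chrom_idx[i]]
        pos = int(rng.integers(1, chrom.length_bp + 1))
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice(_BASES[_BASES != ref]))
        het = rng.random() < params.parent_het_fraction
        rows.append(
            (chrom.name, pos, ref, alt, PARENT_HET if het else PARENT_HOM, False)
        )
    # causal variant: a single-base deletion, anchor-base (VCF) convention
    rows.append((params.causal_chrom, params.causal_pos, "AG", "A", PARENT_HET, True))
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "parent_genotype", "is_causal"]
    )
    order = [c.name for c in params.chromosomes]
    df["chrom"] = pd.Categorical(df["chrom"], categories=order, ordered=True)
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    df["chrom"] = df["chrom"].astype(str)
    return df


def _simulate_gametes(
    genetic_pos: np.ndarray, n_gametes: int, rng: np.random.Generator
) -> np.ndarray:
    """Transmit one parental haplotype index (0 or 1) at each locus per gamete.

    Loci must be sorted by genetic position. The first locus is drawn uniformly;
    each subsequent locus switches haplotype with the Haldane recombination
    fraction of the interval, which realises the no-interference (Markov)
    crossover model exactly.
    """
    n_loci = len(genetic_pos)
    draws = np.empty((n_gametes, n_loci), dtype=np.int8)
    draws[:, 0] = rng.random(n_gametes) < 0.5
    if n_loci > 1:
        r = np.array([recomb_fraction(d) for d in np.diff(genetic_pos)])
        draws[:, 1:] = rng.random((n_gametes, n_loci - 1)) < r
    return np.cumsum(draws, axis=1) % 2


def simulate_population(params: SimParams) -> PopulationSim:
    """Simulate selfed progeny of the heterozygous parent.

    Parent-heterozygous variants are held in coupling phase: all their alternate
    alleles reside on parental haplotype 0 together with the causal allele, as
    expected when the variant load arose on one mutagenized chromosome set.
    Parent-homozygous variants give every progeny dosage 2. Phenotype is
    ``white`` exactly when causal dosage is 2 (fully penetrant recessive).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    variants = _draw_variant_sites(params, rng)
    n_var = len(variants)
    dosages = np.full((params.n_progeny, n_var), 2, dtype=np.int8)

    het_mask = (variants["parent_genotype"] == PARENT_HET).to_numpy()
    chrom_arr = variants["chrom"].to_numpy()
    pos_arr = variants["pos"].to_numpy()

    for chrom in params.chromosomes:
        idx = np.flatnonzero((chrom_arr == chrom.name) & het_mask)
        if idx.size == 0:
            continue
        gpos = chrom.genetic_pos(pos_arr[idx].astype(float))
        # two gametes per progeny, haplotype 0 carries the alt alleles
        hap = _simulate_gametes(np.asarray(gpos), 2 * params.n_progeny, rng)
        alt_copies = (hap == 0).astype(np.int8)
        dosages[:, idx] = alt_copies[::2] + alt_copies[1::2]

    causal_col = int(np.flatnonzero(variants["is_causal"].to_numpy())[0])
    phenotypes = np.where(dosages[:, causal_col] == 2, WHITE, GREEN)
    return PopulationSim(params, variants, dosages, phenotypes)


def build_pools(
    pop: PopulationSim, n_white: int = 30, n_green: int = 30, seed: int = 0
) -> PoolSpec:
    """Select phenotype pools uniformly at random without replacement."""
    rng = np.random.default_rng(seed)
    white, green = pop.white_ids(), pop.green_ids()
    if n_white > len(white):
        raise ValueError(
            f"requested {n_white} white individuals but only {len(white)} available"
        )
    if n_green > len(green):
        raise ValueError(
            f"requested {n_green} green individuals but only {len(green)} available"
        )
    white_sel = np.sort(rng.choice(white, size=n_white, replace=False))
    green_sel = np.sort(rng.choice(green, size=n_green, replace=False))
    return PoolSpec(white_sel, green_sel)


def pooled_allele_freq(pool_dosages) -> float:
    """Alt-allele frequency of a DNA pool: sum(dosage) / (2 * pool size)."""
    d = np.asarray(pool_dosages)
    if d.size == 0:
        raise ValueError("pooled allele frequency undefined for an empty pool")
    return float(d.sum() / (2 * d.size))


def pool_freqs(pop: PopulationSim, pools: PoolSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant pooled allele frequencies, (white pool, green pool)."""
    w = pop.dosages[pools.white_members]
    g = pop.dosages[pools.green_members]
    if w.size == 0 or g.size == 0:
        raise ValueError("pooled allele frequency undefined for an empty pool")
    return (
        w.sum(axis=0) / (2 * pools.n_white),
        g.sum(axis=0) / (2 * pools.n_green),
    )
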