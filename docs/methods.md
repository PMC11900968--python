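# Methods

## Genetic model

The simulator models the selfed progeny of a single plant heterozygous for a
fully penetrant recessive causal mutation. At the causal locus, progeny
genotypes segregate 1 homozygous-reference : 2 heterozygous : 1
homozygous-mutant; an individual is phenotypically mutant ("white") exactly
when its causal dosage is 2, and normal ("green") otherwise. Phenotyping is
error-free by design — the albino phenotype this emulates is unambiguous — and
a misclassification rate is deliberately not modelled (it would only dilute the
mutant pool's fixation and could be added as an extension).

Background variants represent the mutagenized lineage's load. Each is either
heterozygous in the parent (probability `parent_het_fraction`, default 0.5) or
homozygous; homozygous variants pass dosage 2 to every progeny and carry no
mapping information. Heterozygous variants are held in **coupling phase**: all
alternate alleles sit on the same parental haplotype as the causal allele, as
expected when the mutation load arose on one chromosome set. This is what
produces the linkage signal the index filter exploits; repulsion-phase
variants would only weaken nearby false positives, so coupling is the
conservative choice for measuring specificity.

### Linkage

Gametes are generated per chromosome by sequential locus transmission: the
first locus picks a parental haplotype uniformly, and each subsequent locus
switches haplotype with the Haldane recombination fraction of the interval,

    r(d) = (1 − e^(−2d)) / 2,   d in Morgans.

Under Haldane's no-interference assumption the crossover process is Markov, so
interval-wise switching reproduces the model exactly. Physical coordinates map
to genetic ones at a constant Morgans/bp rate per chromosome (no empirical
genetic map is assumed). The default genome is rice-scale: 12 chromosomes of
31 Mb (372 Mb total) and 1.3 M each (15.6 M map length), with the causal
single-base deletion placed at chr8:14,169,090.

## Sequencing model

Pooled sequencing is reduced to its per-site sufficient statistic. At a site
with true pooled allele frequency f, the total depth is Poisson with the
pool's mean coverage, and the mutant-read count is Binomial(total, f′) with

    f′ = f(1 − e) + (1 − f)e,

where e is a symmetric per-read miscall rate (default 0.001; no error model is
prescribed by the study design, and a symmetric rate folds miscalls in both
directions with one parameter). Poisson depth, rather than fixed depth,
captures the mean coverages while letting low-depth sites occur naturally;
zero-depth sites are emitted and flagged unevaluable, never dropped. SNPs and
indels share the count model because one index statistic is applied to both.
Default coverages are 43× for the mutant (white) pool and 33× for the
wild-type (green) pool — the depths implied by 16.03 G and 12.14 G clean bases
over a ~370 Mb genome.

What the simulator does **not** emulate: read-level artifacts (mapping bias
around indels, base-quality structure, strand bias), variant-calling errors,
repeat-region pileups, and contamination between pools. Passing tests
therefore demonstrate the statistical behaviour of the index filter under the
idealised count model, not robustness to alignment pathology in real data.

## The index filter

The SNP/Indel-index is alt_reads / total_reads, kept at full precision
internally and rounded to two decimals in reports; a zero-depth index is
undefined and flagged, never coerced to 0. The candidate filter requires:

1. mutant-pool index = 1, interpreted **exactly** as alt_reads == total_reads
   (the worked causal value is exactly 23/23). An optional
   `mut_index_tolerance` relaxes this (index ≥ 1 − tol) for high coverages
   where a single error read would otherwise veto fixation; it defaults off.
2. wild-type-pool index **strictly** below 0.5; 0.5 exactly — a plausible
   heterozygote value — is rejected.
3. total depth ≥ `min_depth` (default 5) in both pools. No depth floor is part
   of the published criteria; 5 guards against index = 1 artifacts at depth
   1–2, and sites failing it are reported as *unevaluable*, not rejected, so
   the choice is visible in output rather than silent.

Candidates are ranked by mutant-pool depth (descending), then by closeness of
the wild-type index to its genetic expectation 1/3, then by coordinate —
a stable, fully deterministic order. Multi-allelic sites must be decomposed
upstream; the engine assumes biallelic records.

Expected performance at the default design follows in closed form: the
probability that error reads spoil mutant-pool fixation at the causal locus is
1 − E[(1−e)^T] = 1 − exp(−cov·e) ≈ 4.2% at 43×, and the wild-type-pool index
(mean 1/3, binomial + pool-composition noise) exceeds 0.5 in ≈4% of
replicates, so the causal variant passes in roughly 92% of experiments — the
rate the replicate tests measure. False-positive survivors are almost
exclusively variants linked in coupling within a few cM of the causal locus.

## Segregation test

Pearson goodness-of-fit without continuity correction: E_i = N·ratio_i/Σratio,
χ² = Σ(O_i − E_i)²/E_i, compared to the α = 0.05 critical value at k−1 df
(3.84 for two classes). The uncorrected statistic is the field's convention
for segregation ratios — for 73:19 vs 3:1 it gives 16/69 + 16/23 = 0.928,
reported as 0.93 — and Yates' correction (0.71 for the same counts) is exposed
as an off-by-default flag. At n ≈ 92 the χ²₁ approximation's type-I error is
close to, and slightly below, nominal because of binomial discreteness; the
calibration test tolerates this within 3 SE.

## Consequence prediction

Variants are located against a gene model (GFF3: gene/mRNA/exon/CDS, 1-based
inclusive) as intergenic, intronic, UTR, or coding, with strand-aware exon
ordinals and the 1-based offset in the spliced CDS. Consequences of coding
indels are computed on the spliced CDS, assuming intra-exon indels leave
splicing intact; splice-site disruption and NMD are out of scope. Minus-strand
models are reverse-complemented into CDS orientation before any offset
arithmetic.

Translation uses the standard code from position 1, stops at (and excludes)
the first in-frame stop, ignores a trailing partial codon, and rejects
ambiguous bases. A complete CDS of length L encodes L/3 − 1 residues (3258 nt
→ 1085 aa). An indel shifts the frame iff its length mod 3 ≠ 0 — a property of
length only, never sequence content. Effects are classified as
frame-preserved, frameshift, stop-gain, stop-loss, or no-stop-found;
stop-search past the native stop uses only user-supplied 3′ sequence (no
genomic read-through), keeping results data-bounded and deterministic.

Recomputing real mutant protein truncations — e.g. 967 aa from the chr8
single-base deletion in *LOC_Os08g23430* (whose 3258-bp CDS encodes the
1085-aa OsRNE ribonuclease), or 68 aa from first-exon single-base insertions —
requires that gene's actual annotation build and genome sequence;
`consequence_for_genomic_variant` supports this with a user-supplied
GFF3 + FASTA, and no download is performed. These values are optional external
checks, not bundled tests. (Published descriptions of the causal change
disagree on whether the deleted base is a G or a C; the engine is agnostic to
the allele's identity, so nothing here depends on resolving that.)

## Differential-expression thresholds

`deg_classify` consumes a precomputed table (gene, log₂FC, q) and applies
q < 0.05 (strict) with |log₂FC| ≥ 1 (inclusive, per the printed wording of the
rule it mirrors). Differential testing, normalisation and enrichment are out
of scope; genome-wide DEG totals from real data (thousands of genes) depend on
the external expression dataset and are likewise external validations only.

## Problem sizes and determinism

Replicate-based statistics use 200 replicates of the default design
(240 progeny, 2,000 background variants, 30+30 pools) — enough for 3-SE bands
of a few percent while keeping a full run in tens of seconds. The progeny
default of 240 makes a 30-plant white pool available in essentially every
replicate (P(white < 30) < 10⁻⁵ under Binomial(240, ¼)). Every stochastic
stage takes an explicit integer seed (numpy `default_rng`); identical seeds
give bit-identical populations, pools, counts, and byte-identical report
files (reports embed version/config/seed metadata and no timestamps).

## Known limitations

- Single biallelic causal locus, full penetrance, one generation of selfing;
  no pedigrees, de novo mutation, or selfing series.
- Coupling phase for all parent-heterozygous variants is an assumption, not an
  inference; a mixed-phase parent would lower linked false-positive rates.
- The count model ignores alignment-level error structure (see above), so the
  measured ~92% recovery and near-zero unlinked false-positive rates are
  upper bounds on real-data performance.
- No sliding-window index smoothing or confidence bands; the filter is
  pointwise by design.
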