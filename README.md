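# bsamap

Bulked-segregant mapping of recessive mutations from pooled sequencing, built
around the per-variant **SNP/Indel-index** statistic, with a forward Mendelian
simulator standing in for raw sequencing data.

## The problem

A recessive, seedling-lethal mutation (e.g. an albino rice mutant from a
mutagenized lineage) cannot be mapped by outcrossing. Instead, the selfed
progeny of a *heterozygous* carrier segregate 3 normal : 1 mutant, and DNA
pools of ~30 phenotype-selected siblings per class are whole-genome sequenced.
For each variant site, the SNP/Indel-index in a pool is

```
index = (reads carrying the mutant allele) / (total reads at the site)
```

Because every mutant-phenotype plant is homozygous for the causal allele, the
causal variant (and anything tightly linked to it) must satisfy

1. **index = 1 in the mutant pool** — every read carries the mutant allele
   (e.g. 23 mutant reads / 23 total), and
2. **index < 0.5 in the wild-type pool** — normal siblings are a 1:2 mix of
   homozygous wild-type (index 0) and heterozygous (index 0.5) plants, so the
   pooled expectation is 1/3.

Unlinked heterozygous background variants sit near 0.5 in *both* pools and
fail criterion 1 at any reasonable depth, so intersecting the two criteria
collapses thousands of background variants to a handful of linked candidates.

The package covers the surrounding analysis steps of such a study:
segregation χ² testing (does 73 green : 19 white fit 3:1?), sequencing-depth
arithmetic (clean bases / genome size), coding-indel consequence prediction
(frameshift → premature stop → truncated protein), and threshold
classification of differential-expression tables (q < 0.05, |log₂FC| ≥ 1).

Variant calling itself is out of scope: the pipeline starts from per-variant
pooled read counts (a minimal 2-sample VCF with AD/DP, or a TSV), and a
forward simulator generates realistic inputs — Mendelian segregation with
Haldane-model linkage, phenotype-selected pools, Poisson depth and binomial
read sampling with a per-read error rate.

## Worked example

Segregation test — uncorrected χ² goodness-of-fit against 3:1:

```bash
$ bsamap segtest --observed 73,19 --ratio 3,1
observed 73:19 vs ratio 3:1: chi2 = 0.93 (df=1, critical 3.84 at alpha=0.05, p=0.336) -> retain the ratio
```

χ² = (73−69)²/69 + (19−23)²/23 = 0.93 < 3.84, so a monogenic recessive model
is retained. Simulate a mapping experiment and run the filter:

```bash
$ bsamap simulate --seed 7 --out-prefix demo
$ bsamap run --counts demo.counts.vcf --out-prefix demo
4 candidate(s), 0 unevaluable site(s)
$ column -t demo.candidates.tsv | head -6
chrom  pos       ref  alt  alt1  tot1  alt2  tot2  index1  index2  ...  status
chr8   14169090  AG   A    43    43    11    25    1.0     0.44         candidate
chr8   13494242  G    C    39    39    12    29    1.0     0.41         candidate
chr8   13593641  G    A    39    39    12    29    1.0     0.41         candidate
chr8   11847518  G    T    32    32    8     29    1.0     0.28         candidate
```

Of 2,001 simulated variants, four survive — the true causal indel at
chr8:14,169,090 (ranked first: every one of its 43 mutant-pool reads carries
the deletion, and its wild-type-pool index 0.44 < 0.5) plus three variants
linked to it in coupling phase. Everything off the causal chromosome is
filtered out. Columns `index1`/`index2` are the mutant- and wild-type-pool
indices (rounded; full precision alongside).

Consequence prediction for a coding indel (here on a toy gene model):

```bash
bsamap consequence --gff gene.gff3 --fasta genome.fa --variant chrT:150:GA:G
```

reports the exon, the offset in the spliced CDS, frameshift status, and the
wild-type and truncated mutant protein lengths. As a library:

```python
from bsamap import CountPair, snp_index, chi_square_segregation
snp_index(CountPair(23, 23))            # 1.0
snp_index(CountPair(3, 10))             # 0.3
chi_square_segregation((73, 19), (3, 1)).chi2  # 0.928...
```

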