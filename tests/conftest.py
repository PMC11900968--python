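"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from bsamap import GeneModel

# Hand-written standard genetic code — an oracle independent of the package's
# (Biopython-backed) translation path.
_CODON_TABLE = {}
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_B = "TCAG"
for i, aa in enumerate(_AA):
    codon = _B[i // 16] + _B[(i // 4) % 4] + _B[i % 4]
    _CODON_TABLE[codon] = aa

SENSE_CODONS = [c for c, aa in sorted(_CODON_TABLE.items()) if aa != "*"]
STOP_CODONS = [c for c, aa in sorted(_CODON_TABLE.items()) if aa == "*"]


def oracle_translate(seq: str) -> tuple[str, bool]:
    """Naive codon-walk translation: (protein up to first stop, no_stop_found)."""
    protein = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = _CODON_TABLE[seq[i : i + 3]]
        if aa == "*":
            return "".join(protein), False
        protein.append(aa)
    return "".join(protein), True


def random_complete_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 2) sense codons + one stop codon: a complete CDS."""
    body = rng.choice(SENSE_CODONS, size=n_codons - 2)
    stop = rng.choice(STOP_CODONS)
    return "ATG" + "".join(body) + str(stop)


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


# --- toy two-exon gene models on a small synthetic genome -------------------

#: the coordinate-arithmetic toy: exons 101-200 and 301-400, all coding, +
TOY_MODEL = GeneModel(
    gene_id="toy1",
    chrom="chrT",
    strand="+",
    exons=((101, 200), (301, 400)),
    cds=((101, 200), (301, 400)),
)


@dataclass(frozen=True)
class ToyGenome:
    fasta: str
    gff: str
    plus_cds: str  # spliced CDS of gene_plus (complete ORF)
    minus_cds: str  # spliced CDS of gene_minus (complete ORF)


@pytest.fixture
def toy_genome(tmp_path, rng) -> ToyGenome:
    """Synthetic two-chromosome genome (fabricated sequence, no real genome)
    with one fully-coding two-exon gene per chromosome.

    gene_plus on chrT (+): CDS exons 101-200 and 301-401 spliced into a
    complete 201-nt ORF. gene_minus on chrM (-): same exon layout, CDS read
    on the minus strand.
    """
    plus_cds = random_complete_cds(rng, 67)  # 201 nt
    minus_cds = random_complete_cds(rng, 67)

    def build(seq_parts: tuple[str, str]) -> str:
        chrom = list("".join(rng.choice(list("ACGT"), size=600)))
        chrom[100:200] = seq_parts[0]
        chrom[300:401] = seq_parts[1]
        return "".join(chrom)

    chrT = build((plus_cds[:100], plus_cds[100:]))
    g = revcomp(minus_cds)  # genomic-orientation concatenation for chrM
    chrM = build((g[:100], g[100:]))

    fasta = tmp_path / "toy.fa"
    fasta.write_text(f">chrT\n{chrT}\n>chrM\n{chrM}\n")

    rows = []
    for gid, chrom, strand in (("gene_plus", "chrT", "+"), ("gene_minus", "chrM", "-")):
        rows.append(f"{chrom}\ttoy\tgene\t101\t401\t.\t{strand}\t.\tID={gid}")
        rows.append(f"{chrom}\ttoy\tmRNA\t101\t401\t.\t{strand}\t.\tID={gid}.1;Parent={gid}")
        for s, e in ((101, 200), (301, 401)):
            rows.append(f"{chrom}\ttoy\texon\t{s}\t{e}\t.\t{strand}\t.\tParent={gid}.1")
            rows.append(f"{chrom}\ttoy\tCDS\t{s}\t{e}\t.\t{strand}\t0\tParent={gid}.1")
    gff = tmp_path / "toy.gff3"
    gff.write_text("##gff-version 3\n" + "\n".join(rows) + "\n")

    return ToyGenome(str(fasta), str(gff), plus_cds, minus_cds)
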