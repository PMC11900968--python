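"""Variant-to-gene annotation and protein-level consequence prediction.

Given a gene model (exon/CDS structure on a chromosome) and a variant, this
module locates the variant (intergenic, intron, UTR, or coding exon k with its
offset in the spliced CDS) and, for coding indels, predicts the protein
outcome: an indel whose length is not a multiple of 3 shifts the reading frame,
usually creating a premature termination codon and a truncated protein; an
in-frame indel adds or removes whole residues.

Consequences are computed on the spliced CDS, assuming intra-exon indels leave
splicing intact. Translation runs only through the supplied transcript sequence
(CDS plus any provided 3' UTR) — there is no genomic read-through — so a shifted
frame with no stop in that sequence is reported as such rather than guessed at.
Minus-strand models are reverse-complemented into CDS orientation before any
offset arithmetic; all reported offsets are CDS-relative and 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import gffutils
from Bio.Seq import Seq
from pyfaidx import Fasta

__all__ = [
    "GeneModel",
    "RegionAnnotation",
    "TranslationResult",
    "CdsIndel",
    "ConsequenceReport",
    "gene_model_from_gff",
    "annotate_variant",
    "translate",
    "predict_consequence",
    "spliced_cds",
    "genomic_to_cds_offset",
    "consequence_for_genomic_variant",
]

_VALID = set("ACGT")


@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS structure of one gene. Intervals are 1-based inclusive,
    stored in genomic order and non-overlapping; strand is '+' or '-'."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        for ivs in (self.exons, self.cds):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s1 > e1 or s2 > e2 or e1 >= s2:
                    raise ValueError("intervals must be sorted and non-overlapping")
        if sum(e - s + 1 for s, e in self.cds) < 3:
            raise ValueError("CDS shorter than one codon")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class RegionAnnotation:
    """Where a variant falls relative to a gene model.

    ``region`` is one of intergenic / intron / UTR / CDS. For coding positions
    ``exon`` is the strand-aware exon ordinal (1 = first exon of the mRNA) and
    ``cds_offset`` the 1-based position within the spliced CDS counted from the
    start codon.
    """

    region: str
    exon: int | None = None
    cds_offset: int | None = None


@dataclass(frozen=True)
class TranslationResult:
    protein: str
    no_stop_found: bool

    @property
    def length(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class CdsIndel:
    """A single insertion or deletion expressed in spliced-CDS coordinates.

    For a deletion, ``cds_offset`` is the first deleted base (1-based) and
    ``bases`` the deleted stretch; for an insertion, ``bases`` are inserted
    immediately after position ``cds_offset`` (0 inserts before the CDS start).
    """

    cds_offset: int
    op: str  # "ins" | "del"
    bases: str

    def __post_init__(self) -> None:
        if self.op not in ("ins", "del"):
            raise ValueError("op must be 'ins' or 'del'")
        if not self.bases or not set(self.bases) <= _VALID:
            raise ValueError("indel bases must be a non-empty A/C/G/T string")


@dataclass(frozen=True)
class ConsequenceReport:
    effect: str  # frame-preserved | frameshift | stop-gain | stop-loss | no-stop-found
    frameshift: bool
    premature_termination: bool
    wt_protein_length: int
    mut_protein_length: int | None  # None when no stop reached
    mutant_protein: str


def gene_model_from_gff(gff_path: str, gene_id: str | None = None) -> GeneModel:
    """Build a GeneModel from a GFF3 file (gene/mRNA/exon/CDS features).

    With multiple genes present, ``gene_id`` selects one; multi-isoform genes
    use the first mRNA in file order (isoform resolution is out of scope).
    """
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = list(db.features_of_type("gene"))
    if gene_id is not None:
        genes = [g for g in genes if g.id == gene_id]
    if not genes:
        raise ValueError(f"no gene feature found (gene_id={gene_id!r})")
    gene = genes[0]
    mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
    parent = mrnas[0] if mrnas else gene
    exons = tuple(
        (f.start, f.end) for f in db.children(parent, featuretype="exon", order_by="start")
    )
    cds = tuple(
        (f.start, f.end) for f in db.children(parent, featuretype="CDS", order_by="start")
    )
    if not exons:
        exons = cds
    return GeneModel(gene.id, gene.seqid, gene.strand, exons, cds)


def _exon_ordinal(model: GeneModel, genomic_exon_index: int) -> int:
    """Strand-aware exon number: exon 1 is 5'-most on the mRNA."""
    if model.strand == "+":
        return genomic_exon_index + 1
    return model.n_exons - genomic_exon_index


def genomic_to_cds_offset(model: GeneModel, pos: int) -> int | None:
    """1-based offset of a genomic position within the spliced CDS, or None."""
    cum = 0
    if model.strand == "+":
        for s, e in model.cds:
            if s <= pos <= e:
                return cum + (pos - s) + 1
            cum += e - s + 1
    else:
        for s, e in reversed(model.cds):
            if s <= pos <= e:
                return cum + (e - pos) + 1
            cum += e - s + 1
    return None


def annotate_variant(
    variant: tuple[str, int, str, str], model: GeneModel
) -> RegionAnnotation:
    """Classify a variant's position against a gene model.

    A variant on a different chromosome is intergenic by construction. Exonic
    positions outside the CDS are UTR.
    """
    chrom, pos = variant[0], variant[1]
    if chrom != model.chrom:
        return RegionAnnotation("intergenic")
    lo, hi = model.span
    if pos < lo or pos > hi:
        return RegionAnnotation("intergenic")
    for i, (s, e) in enumerate(model.exons):
        if s <= pos <= e:
            offset = genomic_to_cds_offset(model, pos)
            if offset is None:
                return RegionAnnotation("UTR", exon=_exon_ordinal(model, i))
            return RegionAnnotation("CDS", exon=_exon_ordinal(model, i), cds_offset=offset)
    return RegionAnnotation("intron")


def spliced_cds(model: GeneModel, fasta: str | Fasta) -> str:
    """Extract the spliced CDS in translation orientation from a genome FASTA."""
    fa = fasta if isinstance(fasta, Fasta) else Fasta(str(fasta))
    parts = [str(fa[model.chrom][s - 1 : e]).upper() for s, e in model.cds]
    seq = "".join(parts)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def translate(cds: str) -> TranslationResult:
    """Translate from position 1 with the standard code, stopping at (and
    excluding) the first in-frame stop codon.

    A trailing partial codon is ignored. If no in-frame stop exists within the
    sequence the full-length translation is returned with ``no_stop_found``.
    Ambiguous (non-ACGT) bases are rejected.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError("coding sequence shorter than one codon")
    if not set(cds) <= _VALID:
        bad = sorted(set(cds) - _VALID)
        raise ValueError(f"ambiguous/invalid bases not supported: {bad}")
    trimmed = cds[: len(cds) - len(cds) % 3]
    aa = str(Seq(trimmed).translate())
    stop = aa.find("*")
    if stop == -1:
        return TranslationResult(aa, no_stop_found=True)
    return TranslationResult(aa[:stop], no_stop_found=False)


def apply_cds_indel(cds: str, indel: CdsIndel) -> str:
    """Apply a single indel to a spliced CDS string."""
    n = len(cds)
    if indel.op == "del":
        if not 1 <= indel.cds_offset <= n:
            raise ValueError("deletion offset outside CDS")
        end = indel.cds_offset - 1 + len(indel.bases)
        if end > n:
            raise ValueError("deletion extends beyond CDS end")
        found = cds[indel.cds_offset - 1 : end]
        if found != indel.bases:
            raise ValueError(
                f"deleted bases mismatch: expected {indel.bases!r}, CDS has {found!r}"
            )
        return cds[: indel.cds_offset - 1] + cds[end:]
    if not 0 <= indel.cds_offset <= n:
        raise ValueError("insertion offset outside CDS")
    return cds[: indel.cds_offset] + indel.bases + cds[indel.cds_offset :]


def predict_consequence(
    wt_cds: str, indel: CdsIndel, three_prime_seq: str = ""
) -> ConsequenceReport:
    """Predict the protein consequence of a coding indel.

    The edit is applied to the spliced CDS, the mutant sequence (plus any
    supplied 3' sequence, for stop search past the native stop) is re-translated,
    and the outcome classified. Frameshift status depends only on the indel
    length modulo 3. ``premature_termination`` marks a mutant protein shorter
    than the wild-type one.
    """
    wt = translate(wt_cds)
    mut_seq = apply_cds_indel(wt_cds, indel) + three_prime_seq.upper()
    mut = translate(mut_seq) if len(mut_seq) >= 3 else TranslationResult("", True)

    shift = len(indel.bases) % 3 != 0
    if mut.no_stop_found:
        effect = "no-stop-found"
    elif shift:
        effect = "frameshift"
    else:
        delta = len(indel.bases) // 3
        expected = wt.length + (delta if indel.op == "ins" else -delta)
        if mut.length < expected:
            effect = "stop-gain"
        elif mut.length > expected:
            effect = "stop-loss"
        else:
            effect = "frame-preserved"
    return ConsequenceReport(
        effect=effect,
        frameshift=shift,
        premature_termination=(not mut.no_stop_found) and mut.length < wt.length,
        wt_protein_length=wt.length,
        mut_protein_length=None if mut.no_stop_found else mut.length,
        mutant_protein=mut.protein,
    )


def _genomic_indel_to_cds(
    model: GeneModel, pos: int, ref: str, alt: str
) -> CdsIndel:
    """Convert an anchor-base VCF indel into spliced-CDS coordinates."""
    if len(ref) > 1 and len(alt) == 1 and ref[0] == alt[0]:
        op, bases = "del", ref[1:]
        gstart, gend = pos + 1, pos + len(bases)
        off_start = genomic_to_cds_offset(model, gstart)
        off_end = genomic_to_cds_offset(model, gend)
        if off_start is None or off_end is None:
            raise ValueError("indel not fully contained in the CDS")
        if model.strand == "-":
            bases = str(Seq(bases).reverse_complement())
            off_start = off_end  # 5'-most deleted base in CDS orientation
        return CdsIndel(off_start, op, bases)
    if len(alt) > 1 and len(ref) == 1 and alt[0] == ref[0]:
        bases = alt[1:]
        off = genomic_to_cds_offset(model, pos)
        if off is None:
            raise ValueError("insertion anchor not in the CDS")
        if model.strand == "-":
            bases = str(Seq(bases).reverse_complement())
            off = off - 1  # insert 5' of the anchor in CDS orientation
        return CdsIndel(off, "ins", bases)
    raise ValueError("not a simple anchor-base indel (SNVs carry no frame effect)")


def consequence_for_genomic_variant(
    variant: tuple[str, int, str, str], model: GeneModel, fasta: str | Fasta
) -> tuple[RegionAnnotation, ConsequenceReport | None]:
    """Annotate a genomic indel against a gene model and, if coding, predict
    its protein consequence from the genome sequence.

    Requires a user-supplied GFF3-derived model and FASTA; nothing is fetched.
    Returns (annotation, report) with report None for non-coding positions.
    """
    ann = annotate_variant(variant, model)
    if ann.region != "CDS":
        return ann, None
    cds = spliced_cds(model, fasta)
    indel = _genomic_indel_to_cds(model, variant[1], variant[2], variant[3])
    return ann, predict_consequence(cds, indel)
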