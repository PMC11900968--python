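"""Readers and writers for the pipeline's file formats.

Variant counts travel either as a minimal two-sample VCFv4.2 (per-sample AD and
DP FORMAT fields; sample 1 the mutant pool, sample 2 the wild-type pool) or as
an equivalent 8-column TSV (chrom, pos, ref, alt, alt1, tot1, alt2, tot2). All
coordinates are 1-based; indel records use the VCF anchor-base convention.
Report files carry ``#bsamap`` metadata comment lines (version, config, seed)
and are byte-identical across reruns with the same inputs and seed — no
timestamps. Logging goes to stderr; results never do.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam
import yaml

from . import __version__
from .index import VariantRecord
from .readsim import CountPair

__all__ = [
    "read_variant_counts",
    "write_variant_counts_vcf",
    "write_variant_counts_tsv",
    "write_report",
    "load_config",
    "FormatError",
]

logger = logging.getLogger("bsamap")

TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "alt1", "tot1", "alt2", "tot2"]
SAMPLE_POOL1 = "pool1_mutant"
SAMPLE_POOL2 = "pool2_wildtype"


class FormatError(ValueError):
    """A malformed input file (missing fields, bad columns)."""


def write_variant_counts_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write records as a two-sample VCF with AD (ref,alt) and DP per sample."""
    records = list(records)
    header = pysam.VariantHeader()
    header.add_line("##source=bsamap v" + __version__)
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Read depth per allele (ref,alt)">'
    )
    header.add_line(
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">'
    )
    if contig_lengths is None:
        contig_lengths = {}
        for rec in records:
            end = rec.pos + len(rec.ref)
            contig_lengths[rec.chrom] = max(contig_lengths.get(rec.chrom, 0), end)
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=int(length))
    header.add_sample(SAMPLE_POOL1)
    header.add_sample(SAMPLE_POOL2)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rec in records:
            # '-' placeholder alleles from bare TSVs cannot be expressed in VCF
            vrec = vcf.new_record(
                contig=rec.chrom, start=rec.pos - 1, alleles=(rec.ref, rec.alt)
            )
            for sample, cp in ((SAMPLE_POOL1, rec.pool1), (SAMPLE_POOL2, rec.pool2)):
                vrec.samples[sample]["AD"] = (cp.ref_reads, cp.alt_reads)
                vrec.samples[sample]["DP"] = cp.total_reads
            vcf.write(vrec)


def _counts_from_sample(sample, where: str) -> CountPair:
    ad = sample.get("AD")
    dp = sample.get("DP")
    if ad is None or all(v is None for v in ad):
        raise FormatError(f"missing AD field at {where}")
    if dp is None:
        raise FormatError(f"missing DP field at {where}")
    ref_reads, alt_reads = int(ad[0]), int(ad[1])
    total = int(dp)
    if ref_reads + alt_reads != total:
        warnings.warn(
            f"AD sum != DP at {where}; recomputing DP from AD", stacklevel=2
        )
        total = ref_reads + alt_reads
    return CountPair(alt_reads, total)


def _read_vcf(path: str | Path) -> list[VariantRecord]:
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 2:
            raise FormatError(
                f"expected a 2-sample VCF (mutant, wild-type pools); got {samples}"
            )
        for vrec in vcf:
            if vrec.alts is None or len(vrec.alts) != 1:
                raise FormatError(
                    f"non-biallelic record at {vrec.chrom}:{vrec.pos}; decompose first"
                )
            where = f"{vrec.chrom}:{vrec.pos}"
            out.append(
                VariantRecord(
                    chrom=vrec.chrom,
                    pos=vrec.pos,
                    ref=vrec.ref,
                    alt=vrec.alts[0],
                    pool1=_counts_from_sample(vrec.samples[samples[0]], where),
                    pool2=_counts_from_sample(vrec.samples[samples[1]], where),
                )
            )
    return out


def _read_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    if missing := set(TSV_COLUMNS) - set(df.columns):
        raise FormatError(f"TSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            VariantRecord(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                pool1=CountPair(int(row.alt1), int(row.tot1)),
                pool2=CountPair(int(row.alt2), int(row.tot2)),
            )
        )
    return out


def read_variant_counts(path: str | Path, format: str = "auto") -> list[VariantRecord]:
    """Read per-variant pooled counts from a VCF or TSV file.

    ``format`` is ``vcf``, ``tsv``, or ``auto`` (by file extension).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def write_variant_counts_tsv(records: Iterable[VariantRecord], path: str | Path) -> None:
    rows = [
        (r.chrom, r.pos, r.ref, r.alt, r.pool1.alt_reads, r.pool1.total_reads,
         r.pool2.alt_reads, r.pool2.total_reads)
        for r in records
    ]
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def write_report(
    df: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None
) -> None:
    """Write a result table as TSV with ``#bsamap`` metadata header lines.

    Column order and rounding are those of the DataFrame; metadata (config,
    seed, ...) is embedded as comments so the file is self-describing, and the
    output is deterministic for identical inputs.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#bsamap version={__version__}\n")
        for key, value in (metadata or {}).items():
            fh.write(f"#bsamap {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    """Load a run configuration from a flat ``key=value`` file or YAML.

    A ``seed`` entry is mandatory: every stochastic stage must be reproducible
    from the recorded configuration.
    """
    text = Path(path).read_text()
    stripped = [
        ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if stripped and all("=" in ln for ln in stripped):
        cfg = {}
        for ln in stripped:
            key, _, value = ln.partition("=")
            cfg[key.strip()] = yaml.safe_load(value.strip())
    else:
        cfg = yaml.safe_load(text)
        if not isinstance(cfg, dict):
            raise FormatError(f"config file {path} did not parse to a mapping")
    if "seed" not in cfg:
        raise FormatError("config must set an explicit seed")
    return cfg
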