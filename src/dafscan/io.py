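"""Readers and writers for the standard formats the pipeline touches.

GFF3/GTF gene models are read through :mod:`gffutils`; BED and the
tabular SNP/outgroup/polarized tables are plain TSV handled with pandas.
All readers are gzip-transparent. File coordinates follow each format's
native convention (GFF 1-based inclusive, BED 0-based half-open) and are
converted to the package-wide 0-based half-open convention on read.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd

from .model import (
    GeneModel,
    GenomicInterval,
    OutgroupCall,
    PolarizedSNP,
    RegionSet,
    SNPFlags,
    SNPRecord,
    Transcript,
)

logger = logging.getLogger("dafscan")

FLAG_COLUMNS = {
    # column -> (attribute, permissive default)
    "multi_mapped": ("multi_mapped", False),
    "on_y": ("on_y", False),
    "in_dbsnp": ("in_dbsnp", True),
    "resequenced": ("resequenced", True),
    "biallelic_substitution": ("biallelic_substitution", True),
}


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# gene models


def read_genes(path) -> list[GeneModel]:
    """Load GFF3/GTF gene models (gene → transcript/mRNA → exon/CDS).

    1-based inclusive file coordinates become 0-based half-open. Records
    with an unknown strand are rejected; a CDS outside its transcript's
    exons or a broken feature hierarchy raises ``ValueError``.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        if g.strand not in {"+", "-"}:
            raise ValueError(
                f"gene {g.id}: strand {g.strand!r} is not '+'/'-' "
                f"(line: {str(g)})"
            )
        span = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand)
        transcripts = []
        for t in db.children(g, level=1):
            if t.featuretype not in {"mRNA", "transcript"}:
                continue
            exons = [
                GenomicInterval(c.seqid, c.start - 1, c.end, c.strand)
                for c in db.children(t, featuretype="exon")
            ]
            cds = [
                GenomicInterval(c.seqid, c.start - 1, c.end, c.strand)
                for c in db.children(t, featuretype="CDS")
            ]
            if not exons:
                raise ValueError(
                    f"transcript {t.id} of gene {g.id} has no exon features"
                )
            transcripts.append(Transcript(t.id, exons, cds))
        if not transcripts:
            raise ValueError(f"gene {g.id} has no transcript/mRNA children")
        gene = GeneModel(g.id, g.seqid, g.strand, span, transcripts)
        gene.validate()
        genes.append(gene)
    return genes


def write_genes_gff3(genes: Iterable[GeneModel], path, chrom_lengths: Optional[dict] = None) -> None:
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in (chrom_lengths or {}).items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "dafscan",
                        "gene",
                        str(g.span.start + 1),
                        str(g.span.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )
            for tx in g.transcripts:
                t_start = min(e.start for e in tx.exons)
                t_end = max(e.end for e in tx.exons)
                fh.write(
                    "\t".join(
                        [
                            g.chrom,
                            "dafscan",
                            "mRNA",
                            str(t_start + 1),
                            str(t_end),
                            ".",
                            g.strand,
                            ".",
                            f"ID={tx.transcript_id};Parent={g.gene_id}",
                        ]
                    )
                    + "\n"
                )
                for kind, itvs in (("exon", tx.exons), ("CDS", tx.cds)):
                    for i, itv in enumerate(itvs, 1):
                        fh.write(
                            "\t".join(
                                [
                                    g.chrom,
                                    "dafscan",
                                    kind,
                                    str(itv.start + 1),
                                    str(itv.end),
                                    ".",
                                    g.strand,
                                    "0" if kind == "CDS" else ".",
                                    f"ID={tx.transcript_id}.{kind}.{i};"
                                    f"Parent={tx.transcript_id}",
                                ]
                            )
                            + "\n"
                        )


# ---------------------------------------------------------------------------
# region sets (BED)


def read_region_set(path, label: str) -> RegionSet:
    """Load a BED3+ file verbatim (no merging) as a named region set."""
    intervals = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: end {end} <= start {start}"
                )
            intervals.append(GenomicInterval(chrom, start, end))
    return RegionSet(label, intervals)


def write_region_set(region_set: RegionSet, path) -> None:
    with open(path, "wt") as fh:
        for itv in region_set.intervals:
            fh.write(f"{itv.chrom}\t{itv.start}\t{itv.end}\n")


# ---------------------------------------------------------------------------
# SNP tables


def _snp_frame_to_records(df: pd.DataFrame, path) -> list[SNPRecord]:
    pops = [c[len("freq_"):] for c in df.columns if c.startswith("freq_")]
    if not pops:
        raise ValueError(f"{path}: no freq_<POP> columns found")
    if df["snp_id"].duplicated().any():
        dup = df["snp_id"][df["snp_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate snp_id {dup!r}")
    missing = [c for c in FLAG_COLUMNS if c not in df.columns]
    if missing:
        logger.info(
            "%s: flag columns %s missing; defaulting to permissive values",
            path,
            missing,
        )
    records = []
    for row in df.itertuples(index=False):
        freqs = {}
        for pop in pops:
            f = float(getattr(row, f"freq_{pop}"))
            if not (0.0 <= f <= 1.0):
                raise ValueError(
                    f"{path}: SNP {row.snp_id}: frequency {f} outside [0,1]"
                )
            freqs[pop] = f
        flag_kwargs = {}
        for col, (attr, default) in FLAG_COLUMNS.items():
            flag_kwargs[attr] = (
                bool(int(getattr(row, col))) if col in df.columns else default
            )
        records.append(
            SNPRecord(
                snp_id=str(row.snp_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                allele_a=str(row.allele_a),
                allele_b=str(row.allele_b),
                pop_freq=freqs,
                flags=SNPFlags(**flag_kwargs),
            )
        )
    return records


def read_snps(path) -> list[SNPRecord]:
    """Read a SNP table (TSV with header, ``pos`` 0-based).

    Expected columns: ``snp_id chrom pos allele_a allele_b freq_<POP>...``
    plus optional 0/1 flag columns (missing ones default to permissive
    values and are logged).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    return _snp_frame_to_records(df, path)


def write_snps(snps: Iterable[SNPRecord], path, populations: Optional[list] = None) -> None:
    snps = list(snps)
    if populations is None:
        populations = sorted({p for s in snps for p in s.pop_freq})
    rows = []
    for s in snps:
        row = {
            "snp_id": s.snp_id,
            "chrom": s.chrom,
            "pos": s.pos,
            "allele_a": s.allele_a,
            "allele_b": s.allele_b,
        }
        for pop in populations:
            row[f"freq_{pop}"] = repr(s.pop_freq[pop])
        for col, (attr, _) in FLAG_COLUMNS.items():
            row[col] = int(getattr(s.flags, attr))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_vcf(path) -> tuple[list[SNPRecord], list[OutgroupCall]]:
    """Read SNPs and outgroup calls from a VCF.

    Per-population frequencies of the ALT allele come from ``AF_<POP>``
    INFO keys; outgroup bases from ``AA_CHIMP``/``AA_MACAQUE``. Flag INFO
    keys (``MULTI_MAPPED``, ``NOT_DBSNP``, ``NOT_RESEQUENCED``) are
    optional and default permissive. Records that are not biallelic
    single-base substitutions (symbolic or multi-allelic ALTs, indels)
    are kept but flagged ``biallelic_substitution=False`` so the standard
    filter drops them with an accounted reason.
    """
    from cyvcf2 import VCF  # deferred: only VCF users need htslib bindings

    snps: list[SNPRecord] = []
    calls: list[OutgroupCall] = []
    seen: set[str] = set()
    for v in VCF(str(path)):
        snp_id = v.ID or f"{v.CHROM}:{v.POS}"
        if snp_id in seen:
            raise ValueError(f"{path}: duplicate snp_id {snp_id!r}")
        seen.add(snp_id)
        alt = v.ALT[0] if v.ALT else "N"
        biallelic = (
            len(v.ALT) == 1
            and len(v.REF) == 1
            and v.REF in "ACGT"
            and alt in "ACGT"
        )
        freqs = {}
        for key, value in v.INFO:
            if key.startswith("AF_"):
                f = float(value)
                if not (0.0 <= f <= 1.0):
                    raise ValueError(
                        f"{path}: SNP {snp_id}: frequency {f} outside [0,1]"
                    )
                freqs[key[3:]] = f
        flags = SNPFlags(
            multi_mapped=v.INFO.get("MULTI_MAPPED") is not None,
            on_y=v.CHROM in {"Y", "chrY"},
            in_dbsnp=v.INFO.get("NOT_DBSNP") is None,
            resequenced=v.INFO.get("NOT_RESEQUENCED") is None,
            biallelic_substitution=biallelic,
        )
        allele_b = alt if alt != v.REF else "N"
        snps.append(
            SNPRecord(snp_id, v.CHROM, v.POS - 1, v.REF, allele_b, freqs, flags)
        )
        chimp = v.INFO.get("AA_CHIMP")
        mac = v.INFO.get("AA_MACAQUE")
        calls.append(
            OutgroupCall(
                snp_id,
                chimp if chimp in {"A", "C", "G", "T"} else None,
                mac if mac in {"A", "C", "G", "T"} else None,
            )
        )
    return snps, calls


def read_outgroup(path) -> list[OutgroupCall]:
    """Read the outgroup-allele table: ``snp_id chimp macaque`` ('.' = missing)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            OutgroupCall(
                snp_id=row.snp_id,
                chimp_allele=None if row.chimp in {".", ""} else row.chimp,
                macaque_allele=None if row.macaque in {".", ""} else row.macaque,
            )
        )
    return calls


def write_outgroup(calls: Iterable[OutgroupCall], path) -> None:
    rows = [
        {
            "snp_id": c.snp_id,
            "chimp": c.chimp_allele or ".",
            "macaque": c.macaque_allele or ".",
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# polarized tables


def write_polarized(polarized: Iterable[PolarizedSNP], path, populations: Optional[list] = None) -> None:
    polarized = list(polarized)
    if populations is None:
        populations = sorted({p for s in polarized for p in s.daf})
    rows = []
    for s in polarized:
        row = {
            "snp_id": s.snp_id,
            "chrom": s.chrom,
            "pos": s.pos,
            "ancestral": s.ancestral_allele,
            "derived": s.derived_allele,
            "source": s.polarization_source,
        }
        for pop in populations:
            row[f"daf_{pop}"] = repr(s.daf[pop])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_polarized(path) -> list[PolarizedSNP]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    pops = [c[len("daf_"):] for c in df.columns if c.startswith("daf_")]
    return [
        PolarizedSNP(
            snp_id=str(r.snp_id),
            chrom=str(r.chrom),
            pos=int(r.pos),
            ancestral_allele=str(r.ancestral),
            derived_allele=str(r.derived),
            daf={pop: float(getattr(r, f"daf_{pop}")) for pop in pops},
            polarization_source=str(r.source),
        )
        for r in df.itertuples(index=False)
    ]
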