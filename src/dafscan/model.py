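"""Core genomic data types shared across the pipeline.

Coordinates are 0-based half-open everywhere in memory; file readers
convert on the way in (GFF3/GTF are 1-based inclusive on disk, BED is
native). A SNP occupies the 1-bp interval [pos, pos+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import intervals as iv

VALID_BASES = frozenset("ACGT")
STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """A named class of genomic intervals (e.g. "constrained elements").

    Intervals are stored verbatim as loaded; overlap is permitted.
    Merging is applied on demand (lengths, membership queries) so that
    downstream operations are explicit about union semantics.
    """

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def by_chrom(self, merged: bool = True) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, merged by default."""
        groups: dict[str, tuple[list[int], list[int]]] = {}
        for itv in self.intervals:
            s, e = groups.setdefault(itv.chrom, ([], []))
            s.append(itv.start)
            e.append(itv.end)
        out = {}
        for chrom, (s, e) in groups.items():
            if merged:
                out[chrom] = iv.merge_arrays(s, e)
            else:
                ss = np.asarray(s, dtype=np.int64)
                ee = np.asarray(e, dtype=np.int64)
                order = np.lexsort((ee, ss))
                out[chrom] = (ss[order], ee[order])
        return out

    @property
    def total_length_bp(self) -> int:
        """Length of the merged union of all intervals."""
        return sum(int(np.sum(e - s)) for s, e in self.by_chrom(merged=True).values())

    @property
    def unmerged_length_bp(self) -> int:
        return sum(itv.length for itv in self.intervals)

    def merged(self) -> "RegionSet":
        out = []
        for chrom in sorted(self.by_chrom()):
            s, e = self.by_chrom()[chrom]
            out.extend(
                GenomicInterval(chrom, int(a), int(b)) for a, b in zip(s, e)
            )
        return RegionSet(self.label, out)

    def contains_points(self, chroms, positions) -> np.ndarray:
        """Vectorized membership of SNP positions (1-bp interval semantics)."""
        chroms = np.asarray(chroms, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        res = np.zeros(positions.shape, dtype=bool)
        per_chrom = self.by_chrom(merged=True)
        for chrom, (s, e) in per_chrom.items():
            mask = chroms == chrom
            if mask.any():
                res[mask] = iv.points_in(s, e, positions[mask])
        return res


@dataclass
class Transcript:
    transcript_id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)

    def validate(self) -> None:
        ex = sorted(self.exons, key=lambda i: i.start)
        for a, b in zip(ex, ex[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        self.exons = ex
        if self.cds:
            ex_s = [i.start for i in ex]
            ex_e = [i.end for i in ex]
            for c in self.cds:
                sub_s, sub_e = iv.subtract_arrays([c.start], [c.end], ex_s, ex_e)
                if len(sub_s):
                    raise ValueError(
                        f"transcript {self.transcript_id}: CDS "
                        f"[{c.start},{c.end}) not contained in exons"
                    )
            self.cds = sorted(self.cds, key=lambda i: i.start)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    span: GenomicInterval
    transcripts: list[Transcript] = field(default_factory=list)

    def validate(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for tx in self.transcripts:
            tx.validate()
            for ex in tx.exons:
                if ex.chrom != self.chrom:
                    raise ValueError(
                        f"gene {self.gene_id}: exon on {ex.chrom} != {self.chrom}"
                    )
                if ex.start < self.span.start or ex.end > self.span.end:
                    raise ValueError(
                        f"gene {self.gene_id}: span does not cover transcript "
                        f"{tx.transcript_id}"
                    )


@dataclass
class SNPFlags:
    multi_mapped: bool = False
    on_y: bool = False
    in_dbsnp: bool = True
    resequenced: bool = True
    biallelic_substitution: bool = True


@dataclass
class SNPRecord:
    snp_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    pop_freq: dict[str, float]
    flags: SNPFlags = field(default_factory=SNPFlags)

    def __post_init__(self):
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        for pop, f in self.pop_freq.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(
                    f"{self.snp_id}: frequency {f} for {pop} outside [0,1]"
                )


@dataclass
class OutgroupCall:
    snp_id: str
    chimp_allele: Optional[str] = None
    macaque_allele: Optional[str] = None

    def __post_init__(self):
        for name, allele in (("chimp", self.chimp_allele), ("macaque", self.macaque_allele)):
            if allele is not None and allele not in VALID_BASES:
                raise ValueError(f"{self.snp_id}: bad {name} allele {allele!r}")


@dataclass
class PolarizedSNP:
    """A SNP with ancestral/derived assignment and per-population DAF."""

    snp_id: str
    chrom: str
    pos: int
    ancestral_allele: str
    derived_allele: str
    daf: dict[str, float]
    polarization_source: str  # "chimp" | "macaque"
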