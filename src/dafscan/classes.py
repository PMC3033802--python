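"""Annotation-derived genomic classes and SNP-to-class assignment.

Builds the gene-structure classes (promoter, splice control, coding)
from gene models, derives constrained-element subsets (minus coding,
minus genes, minimum gene distance), assigns SNPs to classes by interval
intersection, and reports per-class SNP densities and Venn-partition
intersection counts.

Window conventions (stated because boundary conventions are otherwise
ambiguous): bp offsets are inclusive of both stated endpoints and of the
anchor base where one exists. The promoter window therefore spans 1000
bases upstream of the transcription start site (TSS), the TSS base
itself, and 200 bases downstream — 1201 bp. The splice acceptor
(intron→exon) window spans 50 intronic + 2 exonic bases (52 bp) and the
donor (exon→intron) window 3 exonic + 6 intronic bases (9 bp); a
junction between bases has no anchor base. All windows are strand-aware
and clipped to the chromosome start and to their exon/intron extents.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv
from .model import GeneModel, GenomicInterval, RegionSet

logger = logging.getLogger("dafscan")

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 200
ACCEPTOR_INTRONIC = 50  # intron→exon: intronic bases upstream of the junction
ACCEPTOR_EXONIC = 2     # ... exonic bases downstream (incl. first exon base)
DONOR_EXONIC = 3        # exon→intron: exonic bases upstream of the junction
DONOR_INTRONIC = 6      # ... intronic bases downstream


def _clip0(x: int) -> int:
    return max(0, x)


def promoter_regions(genes: Iterable[GeneModel]) -> RegionSet:
    """Strand-aware promoter windows, one per transcript, union semantics.

    For a + strand transcript with TSS base t the window is
    [t-1000, t+201); mirrored for - strand; clipped at position 0.
    """
    out: list[GenomicInterval] = []
    for gene in genes:
        if gene.strand not in {"+", "-"}:
            raise ValueError(f"gene {gene.gene_id}: promoter undefined without strand")
        for tx in gene.transcripts:
            if gene.strand == "+":
                tss = min(e.start for e in tx.exons)
                start, end = _clip0(tss - PROMOTER_UPSTREAM), tss + PROMOTER_DOWNSTREAM + 1
            else:
                tss = max(e.end for e in tx.exons) - 1
                start, end = _clip0(tss - PROMOTER_DOWNSTREAM), tss + PROMOTER_UPSTREAM + 1
            out.append(GenomicInterval(gene.chrom, start, end))
    return RegionSet("promoter", out)


def splice_control_regions(genes: Iterable[GeneModel]) -> RegionSet:
    """Splice acceptor/donor windows at every intron, union semantics.

    Single-exon transcripts contribute nothing. Each window's intronic
    and exonic parts are clipped to the intron/exon they belong to.
    """
    out: list[GenomicInterval] = []
    for gene in genes:
        for tx in gene.transcripts:
            exons = sorted(tx.exons, key=lambda e: e.start)
            for left, right in zip(exons, exons[1:]):
                intron_len = right.start - left.end
                if intron_len <= 0:
                    continue
                if gene.strand == "+":
                    # donor at left junction (left.end), acceptor at right.start
                    pieces = [
                        (left.end - min(DONOR_EXONIC, left.length), left.end),
                        (left.end, left.end + min(DONOR_INTRONIC, intron_len)),
                        (right.start - min(ACCEPTOR_INTRONIC, intron_len), right.start),
                        (right.start, right.start + min(ACCEPTOR_EXONIC, right.length)),
                    ]
                else:
                    # transcript reads right-to-left: donor at right.start,
                    # acceptor at left.end
                    pieces = [
                        (right.start, right.start + min(DONOR_EXONIC, right.length)),
                        (right.start - min(DONOR_INTRONIC, intron_len), right.start),
                        (left.end, left.end + min(ACCEPTOR_INTRONIC, intron_len)),
                        (left.end - min(ACCEPTOR_EXONIC, left.length), left.end),
                    ]
                for s, e in pieces:
                    if e > s:
                        out.append(GenomicInterval(gene.chrom, _clip0(s), e))
    return RegionSet("splice_site", out)


def coding_regions(genes: Iterable[GeneModel]) -> RegionSet:
    out: list[GenomicInterval] = []
    for gene in genes:
        for tx in gene.transcripts:
            out.extend(GenomicInterval(gene.chrom, c.start, c.end) for c in tx.cds)
    if not out:
        logger.info("coding_regions: no CDS in any gene; empty class")
    return RegionSet("coding", out).merged()


def gene_span_regions(genes: Iterable[GeneModel]) -> RegionSet:
    return RegionSet(
        "genes", [GenomicInterval(g.chrom, g.span.start, g.span.end) for g in genes]
    ).merged()


def distance_to_nearest_gene(query, genes: Sequence[GeneModel]) -> float:
    """Minimum edge-to-edge gap (bp) between a query and any gene span.

    ``query`` is a GenomicInterval or anything with chrom/pos (a SNP,
    treated as its 1-bp interval). Returns 0 on intersection and +inf
    when the query's chromosome carries no gene.
    """
    if isinstance(query, GenomicInterval):
        chrom, qs, qe = query.chrom, query.start, query.end
    else:
        chrom, qs, qe = query.chrom, query.pos, query.pos + 1
    starts = [g.span.start for g in genes if g.chrom == chrom]
    ends = [g.span.end for g in genes if g.chrom == chrom]
    if not starts:
        return math.inf
    return float(iv.gap_distance(qs, qe, starts, ends))


def subset_constrained(constrained: RegionSet, genes: Sequence[GeneModel], rule: str, distance_bp: Optional[int] = None) -> RegionSet:
    """Derive a constrained-element subset.

    rule "minus_coding"/"minus_genes": base-wise subtraction of coding /
    gene-span coverage (elements may be truncated or split).
    rule "min_distance": keep whole elements whose gap to the nearest
    gene is >= ``distance_bp`` (atomic keep-or-drop, never truncated).
    """
    if rule in {"minus_coding", "minus_genes"}:
        other = coding_regions(genes) if rule == "minus_coding" else gene_span_regions(genes)
        other_by_chrom = other.by_chrom()
        out: list[GenomicInterval] = []
        for chrom, (s, e) in constrained.by_chrom(merged=True).items():
            if chrom in other_by_chrom:
                os_, oe_ = other_by_chrom[chrom]
                s, e = iv.subtract_arrays(s, e, os_, oe_)
            out.extend(GenomicInterval(chrom, int(a), int(b)) for a, b in zip(s, e))
        label = f"{constrained.label}_{rule}"
        return RegionSet(label, out)
    if rule == "min_distance":
        if distance_bp is None:
            raise ValueError("min_distance rule requires distance_bp")
        out = [
            itv
            for itv in constrained.intervals
            if distance_to_nearest_gene(itv, genes) >= distance_bp
        ]
        return RegionSet(f"{constrained.label}_min_distance_{distance_bp}", out)
    raise ValueError(f"unknown subset rule {rule!r}")


# ---------------------------------------------------------------------------
# catalog / membership


@dataclass
class ClassCatalog:
    region_sets: dict[str, RegionSet] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, region_set: RegionSet, provenance: str = "supplied") -> None:
        if region_set.label in self.region_sets:
            raise ValueError(f"duplicate class label {region_set.label!r}")
        self.region_sets[region_set.label] = region_set
        self.provenance[region_set.label] = provenance

    def labels(self) -> list[str]:
        return list(self.region_sets)


def build_catalog(
    genes: Sequence[GeneModel],
    supplied: dict[str, RegionSet],
    constrained_label: str = "constrained",
    derive_constrained_subsets: bool = True,
) -> ClassCatalog:
    """Assemble the full class catalog: gene-structure classes derived
    from the gene models, supplied region sets verbatim, and (when a
    constrained-element set is supplied) its four standard subsets."""
    catalog = ClassCatalog()
    if genes:
        catalog.add(promoter_regions(genes), "derived_from_genes")
        catalog.add(splice_control_regions(genes), "derived_from_genes")
        catalog.add(coding_regions(genes), "derived_from_genes")
    for label, rs in supplied.items():
        if rs.label != label:
            rs = RegionSet(label, rs.intervals)
        catalog.add(rs, "supplied")
    if derive_constrained_subsets and constrained_label in supplied and genes:
        ce = supplied[constrained_label]
        for rule, dist, name in (
            ("minus_coding", None, f"{constrained_label}_minus_coding"),
            ("minus_genes", None, f"{constrained_label}_minus_genes"),
            ("min_distance", 1_000, f"{constrained_label}_1kb_from_genes"),
            ("min_distance", 100_000, f"{constrained_label}_100kb_from_genes"),
        ):
            sub = subset_constrained(ce, genes, rule, dist)
            catalog.add(
                RegionSet(name, sub.intervals),
                f"derived_by_subset({constrained_label}, {rule}"
                + (f"={dist}" if dist else "")
                + ")",
            )
    return catalog


@dataclass
class ClassMembership:
    """Per-class sorted SNP-id arrays; classes are not mutually exclusive."""

    members: dict[str, np.ndarray] = field(default_factory=dict)

    def ids(self, label: str) -> set:
        return set(self.members[label])

    def __contains__(self, label: str) -> bool:
        return label in self.members

    def counts(self) -> dict[str, int]:
        return {label: len(v) for label, v in self.members.items()}


def assign_snps_to_classes(snps, catalog: ClassCatalog) -> ClassMembership:
    """Membership by intersection of each SNP's 1-bp interval [pos, pos+1)
    with the class's merged intervals (half-open: pos == end is outside)."""
    snps = list(snps)
    snp_ids = np.array([s.snp_id for s in snps], dtype=object)
    chroms = np.array([s.chrom for s in snps], dtype=object)
    positions = np.array([s.pos for s in snps], dtype=np.int64)
    members = {}
    for label, rs in catalog.region_sets.items():
        mask = rs.contains_points(chroms, positions)
        members[label] = np.sort(snp_ids[mask])
    return ClassMembership(members)


def snps_per_kb(n_snps: int, size_kb: float) -> float:
    """Class SNP density, rounded to 2 decimals as reported."""
    return round(n_snps / size_kb, 2)


def class_density_report(membership: ClassMembership, catalog: ClassCatalog) -> pd.DataFrame:
    """Per-class table {class, n_snps, size_kb, snps_per_kb} over merged
    region lengths; a zero-length class reports NaN density."""
    rows = []
    for label, rs in catalog.region_sets.items():
        n = len(membership.members.get(label, ()))
        size_bp = rs.total_length_bp
        size_kb = size_bp / 1000.0
        rows.append(
            {
                "class": label,
                "n_snps": n,
                "size_kb": round(size_kb, 3),
                "snps_per_kb": snps_per_kb(n, size_kb) if size_bp > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def intersection_counts(membership: ClassMembership, labels: Sequence[str]) -> dict[str, int]:
    """Counts of every cell of the Venn partition of 2-4 classes.

    Keys are '&'-joined subsets of ``labels`` (e.g. "A", "A&B"); values
    count SNPs belonging to exactly that subset. Values sum to |union|.
    """
    if not (2 <= len(labels) <= 4):
        raise ValueError("intersection_counts supports 2-4 labels")
    sets = {lab: membership.ids(lab) for lab in labels}
    union = set().union(*sets.values())
    counts: dict[str, int] = {}
    for pattern in range(1, 2 ** len(labels)):
        inside = [lab for i, lab in enumerate(labels) if pattern >> i & 1]
        outside = [lab for lab in labels if lab not in inside]
        cell = set.intersection(*(sets[lab] for lab in inside)) if inside else union
        for lab in outside:
            cell = cell - sets[lab]
        counts["&".join(inside)] = len(cell)
    return counts
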