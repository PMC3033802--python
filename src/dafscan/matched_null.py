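"""Hitchhiking / background-selection control via matched random regions.

For every region of a regulatory attribute, a random region of identical
size and identical edge distance to a randomly chosen gene is sampled.
SNPs inside the sampled regions are pooled and tested against the
background exactly as the real attribute is, yielding one "generated"
p-value per iteration (default 100). If the real p-value is smaller
than all generated ones, linked selection at nearby genes cannot
explain the attribute's DAF shift, since the generated regions share
the attribute's size and gene-proximity profile but not its annotation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import intervals as iv
from .classes import distance_to_nearest_gene
from .model import GeneModel, GenomicInterval, PolarizedSNP, RegionSet
from .scan import (
    GENOME_BACKGROUND,
    REPEAT_BACKGROUND,
    ScanConfig,
    bh_adjusted,
    mann_whitney,
    remove_overlap,
)

logger = logging.getLogger("dafscan")


def sample_matched_region(
    source_region: GenomicInterval,
    genes: Sequence[GeneModel],
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
    max_redraws: int = 100,
) -> GenomicInterval:
    """Sample a region of identical length and gene distance.

    A gene is drawn uniformly, then a side (upstream/downstream of its
    span) uniformly; the region is placed with edge gap exactly
    d = distance_to_nearest_gene(source). For d = 0 (source overlaps a
    gene) the source's offset relative to its nearest gene's start is
    transplanted onto the random gene. Draws violating chromosome bounds
    are retried up to ``max_redraws`` times.
    """
    if not genes:
        raise ValueError("sample_matched_region requires at least one gene")
    d = distance_to_nearest_gene(source_region, genes)
    if not np.isfinite(d):
        raise ValueError(
            f"source region {source_region} has no gene on its chromosome"
        )
    d = int(d)
    length = source_region.length
    if d == 0:
        host = min(
            (g for g in genes if g.chrom == source_region.chrom),
            key=lambda g: iv.gap_distance(
                source_region.start, source_region.end, [g.span.start], [g.span.end]
            ),
        )
        offset = source_region.start - host.span.start
    for _ in range(max_redraws):
        g = genes[int(rng.integers(len(genes)))]
        chrom_len = chrom_lengths[g.chrom]
        if d == 0:
            start = g.span.start + offset
            # the transplanted region must still overlap the drawn gene
            # (a gene shorter than the offset would break the d=0 match)
            if not (start < g.span.end and g.span.start < start + length):
                continue
        else:
            downstream = rng.random() < 0.5
            if downstream:
                start = g.span.end + d
            else:
                start = g.span.start - d - length
        if start >= 0 and start + length <= chrom_len:
            return GenomicInterval(g.chrom, start, start + length)
    raise RuntimeError(
        f"no feasible matched placement for region {source_region.chrom}:"
        f"[{source_region.start},{source_region.end}) after {max_redraws} redraws"
    )


@dataclass
class MatchedNullResult:
    attribute_label: str
    background_label: str
    population: str
    real_p: float
    real_adjusted_p: float
    generated_p: list[float] = field(default_factory=list)
    n_generated_le_real: int = 0
    seed: Optional[int] = None

    @property
    def n_iter(self) -> int:
        return len(self.generated_p)


def _pool_ids(regions: list[GenomicInterval], snp_chroms, snp_pos, snp_ids) -> set:
    """snp_ids inside the union of the regions (each SNP counted once)."""
    rs = RegionSet("_pool", regions)
    mask = rs.contains_points(snp_chroms, snp_pos)
    return set(snp_ids[mask])


def matched_null_test(
    attribute_regions: RegionSet,
    polarized: list[PolarizedSNP],
    genes: Sequence[GeneModel],
    chrom_lengths: dict[str, int],
    background_ids: set,
    population: str = "AFR",
    policy: str = GENOME_BACKGROUND,
    n_iter: int = 100,
    seed: int = 0,
    scan_config: Optional[ScanConfig] = None,
    m: int = 44,
    context_pvalues: Optional[Sequence[float]] = None,
) -> MatchedNullResult:
    """Permutation control for one attribute against one background.

    Per iteration every attribute region is matched-sampled, sampled
    regions are merged (overlaps pooled once), SNPs inside are pooled and
    tested against the background with the same overlap policy and
    Mann-Whitney settings as the real comparison. The real p-value is
    computed identically on the true regions; its BH-adjusted value uses
    the declared m and, when given, the context p-values of the other
    classes in the scan (the attribute's own rank within that ranking).

    An iteration pooling zero SNPs is redrawn once, then recorded as
    p = 1 with a warning. (seed, inputs) fully determine the output.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    cfg = scan_config or ScanConfig()
    rng = np.random.default_rng(seed)
    snp_chroms = np.array([s.chrom for s in polarized], dtype=object)
    snp_pos = np.array([s.pos for s in polarized], dtype=np.int64)
    snp_ids = np.array([s.snp_id for s in polarized], dtype=object)
    daf_by_id = {s.snp_id: s.daf[population] for s in polarized}

    def test_pool(pool: set) -> float:
        cls_ids, bg_ids = remove_overlap(pool, background_ids, policy)
        x = np.array([daf_by_id[i] for i in cls_ids], dtype=float)
        y = np.array([daf_by_id[i] for i in bg_ids], dtype=float)
        res = mann_whitney(
            x, y,
            alternative=cfg.alternative,
            method=cfg.method,
            exact_threshold=cfg.exact_threshold,
            genome_scale_limit=cfg.genome_scale_limit,
            population=population,
        )
        return res.p_raw

    real_pool = _pool_ids(attribute_regions.intervals, snp_chroms, snp_pos, snp_ids)
    real_p = test_pool(real_pool)

    generated: list[float] = []
    for it in range(n_iter):
        p = None
        for attempt in range(2):  # one redraw on an empty pool
            sampled = [
                sample_matched_region(r, genes, chrom_lengths, rng)
                for r in attribute_regions.intervals
            ]
            pool = _pool_ids(sampled, snp_chroms, snp_pos, snp_ids)
            if pool:
                p = test_pool(pool)
                break
        if p is None:
            warnings.warn(f"iteration {it}: empty SNP pool twice; recording p = 1")
            p = 1.0
        generated.append(p)

    context = list(context_pvalues) if context_pvalues is not None else [real_p]
    if not any(np.isclose(real_p, c) for c in context):
        context.append(real_p)
    adj = bh_adjusted(context, m=m)
    real_idx = int(np.argmin(np.abs(np.asarray(context) - real_p)))
    return MatchedNullResult(
        attribute_label=attribute_regions.label,
        background_label=GENOME_BACKGROUND if policy == GENOME_BACKGROUND else REPEAT_BACKGROUND,
        population=population,
        real_p=real_p,
        real_adjusted_p=float(adj[real_idx]),
        generated_p=generated,
        n_generated_le_real=int(sum(p <= real_p for p in generated)),
        seed=seed,
    )
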