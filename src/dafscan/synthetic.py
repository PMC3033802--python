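"""Synthetic input bundles with a controllable purifying-selection signal.

The generator emulates the inputs of a genome-wide derived-allele-
frequency (DAF) scan: non-overlapping gene models, named region sets
(constrained-element-like, regulatory-attribute-like, ancestral-repeat-
like), multi-population SNP frequencies, and outgroup (chimp/macaque)
calls with configurable failure rates.

Population frequencies are drawn from the classical diffusion form of
the site frequency spectrum under genic selection,

    f(q | gamma) = (1 - exp(-gamma (1 - q))) / (q (1 - q) (1 - exp(-gamma)))

with gamma = 4 N s the scaled selection coefficient (gamma < 0 is
deleterious; gamma = 0 gives the neutral 1/q limit). Each SNP draws a
single population frequency q from the normalized density and the
per-population sample DAFs are independent Binomial(2n, q)/2n draws —
a shared-q, independent-binomial model with no demographic covariance
and no linkage between sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .model import (
    GeneModel,
    GenomicInterval,
    OutgroupCall,
    RegionSet,
    SNPFlags,
    SNPRecord,
    Transcript,
)
from . import intervals as iv
from . import io as dio

BASES = np.array(list("ACGT"))

GRID_POINTS = 4096  # inverse-CDF grid resolution, below one 1/2n step


def sfs_density(q, gamma: float):
    """Un-normalized SFS density f(q | gamma) on 0 < q < 1.

    gamma = 0 returns the neutral limit 1/q. Scalar or array ``q``.
    """
    q_arr = np.asarray(q, dtype=float)
    if np.any((q_arr <= 0.0) | (q_arr >= 1.0)):
        raise ValueError("q must lie strictly inside (0, 1)")
    if gamma == 0.0:
        out = 1.0 / q_arr
    else:
        # expm1 keeps precision for small |gamma|
        out = np.expm1(-gamma * (1.0 - q_arr)) / (
            q_arr * (1.0 - q_arr) * np.expm1(-gamma)
        )
    if np.isscalar(q) or np.ndim(q) == 0:
        return float(out)
    return out


def _grid_and_cdf(gamma: float, two_n: int) -> tuple[np.ndarray, np.ndarray]:
    lo = 1.0 / (2.0 * two_n)
    grid = np.linspace(lo, 1.0 - lo, GRID_POINTS)
    pmf = sfs_density(grid, gamma)
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    return grid, cdf


def draw_sample_daf(gamma: float, two_n: int, rng: np.random.Generator, size: Optional[int] = None):
    """Sample DAF(s) on the 1/2n grid: q ~ normalized f(.|gamma), then
    Binomial(2n, q)/2n. Monomorphic outcomes (0 or 1) are permitted."""
    if two_n < 2:
        raise ValueError("two_n must be >= 2")
    n = 1 if size is None else int(size)
    grid, cdf = _grid_and_cdf(gamma, two_n)
    u = rng.random(n)
    q = grid[np.searchsorted(cdf, u)]
    daf = rng.binomial(two_n, q) / two_n
    if size is None:
        return float(daf[0])
    return daf


def expected_sample_daf(gamma: float, two_n: int) -> float:
    """E[sample DAF] under the generator, by the law of total expectation
    over the discretized q grid (E[Binom(2n,q)/2n | q] = q)."""
    grid, cdf = _grid_and_cdf(gamma, two_n)
    pmf = np.diff(np.concatenate([[0.0], cdf]))
    return float(np.sum(grid * pmf))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RegionSpec:
    label: str
    n_regions: int
    length_range: tuple[int, int]
    placement: str = "uniform"  # uniform | near_gene | far_from_gene
    min_distance_bp: int = 0    # for far_from_gene
    near_max_bp: int = 2000     # for near_gene: max edge gap to the chosen gene
    gamma: float = 0.0
    snps_per_kb: float = 3.7

    def validate(self) -> None:
        if self.placement not in {"uniform", "near_gene", "far_from_gene"}:
            raise ValueError(f"{self.label}: unknown placement {self.placement!r}")
        if not np.isfinite(self.gamma):
            raise ValueError(f"{self.label}: gamma must be finite")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError(f"{self.label}: bad length_range {self.length_range}")


@dataclass
class OutgroupModel:
    """Error model for outgroup calls.

    With probability ``1 - p_chimp_fail`` the chimp base reports the true
    ancestral allele (macaque agrees); otherwise the chimp base is missing
    or mismatching, and the macaque base rescues the ancestral allele with
    probability ``p_macaque_rescue``, else both fail and the SNP cannot be
    polarized downstream.
    """

    p_chimp_fail: float = 0.05
    p_macaque_rescue: float = 0.8

    @property
    def p_both_fail(self) -> float:
        return self.p_chimp_fail * (1.0 - self.p_macaque_rescue)

    def validate(self) -> None:
        for p in (self.p_chimp_fail, self.p_macaque_rescue):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"outgroup probability {p} outside [0,1]")


@dataclass
class SimulationConfig:
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}
    )
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (5_000, 20_000)
    n_transcripts_per_gene: tuple[int, int] = (1, 2)
    region_specs: list[RegionSpec] = field(default_factory=list)
    n_background_snps: int = 4000
    background_gamma: float = 0.0
    sample_size_chromosomes: int = 48  # 2n per population
    populations: tuple[str, ...] = ("AFR", "EUR", "CHN")
    outgroup: OutgroupModel = field(default_factory=OutgroupModel)
    seed: int = 0

    def validate(self) -> None:
        if self.sample_size_chromosomes < 2:
            raise ValueError("sample_size_chromosomes (2n) must be >= 2")
        if not self.populations:
            raise ValueError("at least one population required")
        for length in self.chrom_lengths.values():
            if length <= 0:
                raise ValueError("chromosome lengths must be positive")
        labels = [rs.label for rs in self.region_specs]
        if len(labels) != len(set(labels)):
            raise ValueError("region spec labels must be unique")
        self.outgroup.validate()
        for rs in self.region_specs:
            rs.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "region_specs" in d:
            d["region_specs"] = [
                rs if isinstance(rs, RegionSpec) else RegionSpec(**{
                    **rs,
                    "length_range": tuple(rs["length_range"]),
                })
                for rs in d["region_specs"]
            ]
        if "outgroup" in d and not isinstance(d["outgroup"], OutgroupModel):
            d["outgroup"] = OutgroupModel(**d["outgroup"])
        for key in ("gene_length_range", "n_transcripts_per_gene", "populations"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gene_length_range"] = list(self.gene_length_range)
        d["n_transcripts_per_gene"] = list(self.n_transcripts_per_gene)
        d["populations"] = list(self.populations)
        for rs in d["region_specs"]:
            rs["length_range"] = list(rs["length_range"])
        return d


def default_demo_config(seed: int = 0) -> SimulationConfig:
    """The package's demonstration conditions: a 30 Mb toy genome with one
    strongly selected constrained-element-like class (gamma = -15), one
    gene-associated regulatory-attribute-like class, and a neutral
    ancestral-repeat-like class."""
    return SimulationConfig(
        region_specs=[
            RegionSpec(
                "constrained", n_regions=120, length_range=(800, 2000),
                placement="uniform", gamma=-15.0,
            ),
            RegionSpec(
                "H3K79me3", n_regions=50, length_range=(500, 1500),
                placement="near_gene", gamma=-15.0,
            ),
            RegionSpec(
                "ancestral_repeats", n_regions=200, length_range=(300, 1000),
                placement="uniform", gamma=0.0,
            ),
        ],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# bundle generation


@dataclass
class FixtureBundle:
    config: SimulationConfig
    genes: list[GeneModel]
    region_sets: dict[str, RegionSet]
    snps: list[SNPRecord]
    outgroup_calls: list[OutgroupCall]
    truth: dict[str, float]


class PlacementError(RuntimeError):
    pass


def _pick_chrom(rng, chrom_lengths: dict[str, int], min_len: int) -> tuple[str, int]:
    names = [c for c, L in chrom_lengths.items() if L > min_len]
    if not names:
        raise PlacementError(f"no chromosome longer than {min_len} bp")
    lengths = np.array([chrom_lengths[c] for c in names], dtype=float)
    idx = rng.choice(len(names), p=lengths / lengths.sum())
    return names[idx], chrom_lengths[names[idx]]


def _place_genes(cfg: SimulationConfig, rng) -> list[GeneModel]:
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.chrom_lengths}
    genes: list[GeneModel] = []
    lo, hi = cfg.gene_length_range
    max_tries = 200 * max(cfg.n_genes, 1)
    tries = 0
    while len(genes) < cfg.n_genes:
        tries += 1
        if tries > max_tries:
            raise PlacementError("could not place genes without overlap")
        length = int(rng.integers(lo, hi + 1))
        chrom, chrom_len = _pick_chrom(rng, cfg.chrom_lengths, length)
        start = int(rng.integers(0, chrom_len - length))
        end = start + length
        if any(s < end and start < e for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{len(genes):04d}"
        transcripts = []
        n_tx = int(rng.integers(cfg.n_transcripts_per_gene[0], cfg.n_transcripts_per_gene[1] + 1))
        for ti in range(n_tx):
            transcripts.append(
                _make_transcript(f"{gid}.t{ti}", chrom, strand, start, end, rng)
            )
        gene = GeneModel(gid, chrom, strand, GenomicInterval(chrom, start, end, strand), transcripts)
        gene.validate()
        genes.append(gene)
    return genes


def _make_transcript(tid: str, chrom: str, strand: str, start: int, end: int, rng) -> Transcript:
    n_ex = 1 + int(rng.binomial(5, 0.6))  # 1..6 exons, mean ~4
    length = end - start
    if n_ex > 1 and length >= 4 * n_ex:
        cuts = np.sort(rng.choice(np.arange(start + 1, end - 1), size=2 * (n_ex - 1), replace=False))
        bounds = np.concatenate([[start], cuts, [end]])
        exons = [
            GenomicInterval(chrom, int(bounds[2 * i]), int(bounds[2 * i + 1]), strand)
            for i in range(n_ex)
            if bounds[2 * i + 1] > bounds[2 * i]
        ]
    else:
        exons = [GenomicInterval(chrom, start, end, strand)]
    # CDS: exon union minus terminal UTR-like trims
    utr5 = min(200, exons[0].length - 1) if strand == "+" else min(200, exons[-1].length - 1)
    utr3 = min(200, exons[-1].length - 1) if strand == "+" else min(200, exons[0].length - 1)
    ex_s = [e.start for e in exons]
    ex_e = [e.end for e in exons]
    trims = [
        (exons[0].start, exons[0].start + (utr5 if strand == "+" else utr3)),
        (exons[-1].end - (utr3 if strand == "+" else utr5), exons[-1].end),
    ]
    trims = [(s, e) for s, e in trims if e > s]  # 1-bp exons yield empty trims
    cds_s, cds_e = iv.subtract_arrays(
        ex_s, ex_e, [s for s, _ in trims], [e for _, e in trims]
    )
    cds = [GenomicInterval(chrom, int(s), int(e), strand) for s, e in zip(cds_s, cds_e)]
    return Transcript(tid, exons, cds)


def _gene_spans_by_chrom(genes: list[GeneModel]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    spans: dict[str, tuple[list, list]] = {}
    for g in genes:
        s, e = spans.setdefault(g.chrom, ([], []))
        s.append(g.span.start)
        e.append(g.span.end)
    return {
        c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
        for c, (s, e) in spans.items()
    }


def _place_regions(spec: RegionSpec, cfg: SimulationConfig, genes, rng) -> RegionSet:
    spans = _gene_spans_by_chrom(genes)
    intervals: list[GenomicInterval] = []
    max_tries = 500
    for _ in range(spec.n_regions):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        placed = False
        for _try in range(max_tries):
            if spec.placement == "near_gene":
                if not genes:
                    raise PlacementError(
                        f"region spec {spec.label!r}: near_gene placement needs genes"
                    )
                g = genes[int(rng.integers(len(genes)))]
                gap = int(rng.integers(0, spec.near_max_bp + 1))
                if rng.random() < 0.5:
                    start = g.span.end + gap
                else:
                    start = g.span.start - gap - length
                chrom = g.chrom
                if start < 0 or start + length > cfg.chrom_lengths[chrom]:
                    continue
            else:
                chrom, chrom_len = _pick_chrom(rng, cfg.chrom_lengths, length)
                start = int(rng.integers(0, chrom_len - length))
            end = start + length
            if spec.placement == "far_from_gene" and chrom in spans:
                s, e = spans[chrom]
                if iv.gap_distance(start, end, s, e) < spec.min_distance_bp:
                    continue
            intervals.append(GenomicInterval(chrom, start, end))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"region spec {spec.label!r}: no feasible placement after "
                f"{max_tries} retries"
            )
    return RegionSet(spec.label, intervals)


def _sample_positions_in_set(region_set: RegionSet, n: int, rng, taken: set) -> list[tuple[str, int]]:
    """Uniform positions within the (unmerged) intervals of a set, unique
    genome-wide across the bundle."""
    itvs = region_set.intervals
    lengths = np.array([i.length for i in itvs], dtype=float)
    out: list[tuple[str, int]] = []
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 100 * n + 1000:
            raise PlacementError(f"could not sample unique positions in {region_set.label}")
        k = int(rng.choice(len(itvs), p=lengths / lengths.sum()))
        pos = int(rng.integers(itvs[k].start, itvs[k].end))
        key = (itvs[k].chrom, pos)
        if key in taken:
            continue
        taken.add(key)
        out.append(key)
    return out


def _sample_background_positions(cfg: SimulationConfig, n: int, rng, taken: set) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 100 * n + 1000:
            raise PlacementError("could not sample unique background positions")
        chrom, chrom_len = _pick_chrom(rng, cfg.chrom_lengths, 1)
        pos = int(rng.integers(0, chrom_len))
        key = (chrom, pos)
        if key in taken:
            continue
        taken.add(key)
        out.append(key)
    return out


def _emit_snps(positions, gamma, cfg, rng, start_index, snps, calls) -> int:
    """Create SNP records + outgroup calls for positions at one gamma."""
    n = len(positions)
    if n == 0:
        return start_index
    two_n = cfg.sample_size_chromosomes
    grid, cdf = _grid_and_cdf(gamma, two_n)
    q = grid[np.searchsorted(cdf, rng.random(n))]
    dafs = {
        pop: rng.binomial(two_n, q) / two_n for pop in cfg.populations
    }
    anc_idx = rng.integers(0, 4, size=n)
    der_off = rng.integers(1, 4, size=n)
    swap = rng.random(n) < 0.5
    og = cfg.outgroup
    u_chimp = rng.random(n)
    u_mac = rng.random(n)
    chimp_missing = rng.random(n) < 0.5  # failed chimp call: missing vs mismatch
    for i, (chrom, pos) in enumerate(positions):
        anc = BASES[anc_idx[i]]
        der = BASES[(anc_idx[i] + der_off[i]) % 4]
        snp_id = f"snp{start_index + i:07d}"
        if swap[i]:
            allele_a, allele_b = der, anc
        else:
            allele_a, allele_b = anc, der
        freqs = {}
        for pop in cfg.populations:
            d = float(dafs[pop][i])
            freqs[pop] = d if allele_b == der else 1.0 - d
        snps.append(
            SNPRecord(snp_id, chrom, pos, str(allele_a), str(allele_b), freqs, SNPFlags())
        )
        others = [b for b in "ACGT" if b not in {allele_a, allele_b}]
        if u_chimp[i] >= og.p_chimp_fail:
            chimp, mac = str(anc), str(anc)
        else:
            chimp = None if chimp_missing[i] else others[int(rng.integers(2))]
            if u_mac[i] < og.p_macaque_rescue:
                mac = str(anc)
            else:
                mac = others[int(rng.integers(2))]
        calls.append(OutgroupCall(snp_id, chimp, mac))
    return start_index + n


def generate_bundle(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> FixtureBundle:
    """Generate a complete synthetic input bundle.

    All randomness flows from ``config.seed`` through per-stage child
    streams (genes, regions, SNPs), so bundles are reproducible and
    stages are insensitive to each other's draw counts.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rng_genes, rng_regions, rng_snps = rng.spawn(3)

    genes = _place_genes(config, rng_genes)
    region_sets = {
        spec.label: _place_regions(spec, config, genes, rng_regions)
        for spec in config.region_specs
    }

    snps: list[SNPRecord] = []
    calls: list[OutgroupCall] = []
    taken: set[tuple[str, int]] = set()
    idx = 0
    for spec in config.region_specs:
        rs = region_sets[spec.label]
        n = int(round(spec.snps_per_kb * rs.total_length_bp / 1000.0))
        positions = _sample_positions_in_set(rs, n, rng_snps, taken)
        idx = _emit_snps(positions, spec.gamma, config, rng_snps, idx, snps, calls)
    positions = _sample_background_positions(config, config.n_background_snps, rng_snps, taken)
    idx = _emit_snps(positions, config.background_gamma, config, rng_snps, idx, snps, calls)

    truth = {spec.label: spec.gamma for spec in config.region_specs}
    truth["background"] = config.background_gamma
    return FixtureBundle(config, genes, region_sets, snps, calls, truth)


def write_bundle(bundle: FixtureBundle, outdir) -> None:
    """Write genes.gff3, <label>.bed, snps.tsv, outgroup.tsv, truth.json,
    config.yaml into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dio.write_genes_gff3(bundle.genes, outdir / "genes.gff3", bundle.config.chrom_lengths)
    for label, rs in bundle.region_sets.items():
        dio.write_region_set(rs, outdir / f"{label}.bed")
    dio.write_snps(bundle.snps, outdir / "snps.tsv", list(bundle.config.populations))
    dio.write_outgroup(bundle.outgroup_calls, outdir / "outgroup.tsv")
    with open(outdir / "truth.json", "wt") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
    with open(outdir / "config.yaml", "wt") as fh:
        yaml.safe_dump(bundle.config.to_dict(), fh, sort_keys=False)
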