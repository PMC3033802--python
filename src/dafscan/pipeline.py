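"""End-to-end orchestration: filter → polarize → classes → scan → matched null.

The pipeline is deliberately a thin composition of the library modules;
every artifact it writes (density table, ranked scan tables, DAF
histograms, intersection counts, matched-null summaries, provenance) is
reproducible bit-for-bit from the config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as dio
from .classes import (
    assign_snps_to_classes,
    build_catalog,
    class_density_report,
    intersection_counts,
)
from .matched_null import matched_null_test
from .polarize import polarize_all
from .scan import GENOME_BACKGROUND, REPEAT_BACKGROUND, ScanConfig, run_scan

logger = logging.getLogger("dafscan")


@dataclass
class RunConfig:
    genes: str = ""
    snps: str = ""
    outgroup: str = ""
    beds: dict[str, str] = field(default_factory=dict)
    populations: list[str] = field(default_factory=lambda: ["AFR", "EUR", "CHN"])
    backgrounds: list[str] = field(default_factory=lambda: ["genome", "ancestral_repeats"])
    alpha: float = 0.05
    m_genome: Optional[int] = None
    m_repeats: Optional[int] = None
    exact_threshold: int = 50
    alternative: str = "less"
    require_resequenced: bool = True
    constrained_label: str = "constrained"
    venn_labels: Optional[list[str]] = None
    matched_null: Optional[dict] = None  # {attribute, backgrounds, n_iter, m}
    seed: int = 0
    out_dir: str = "dafscan_out"

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0,1)")
        if not self.populations:
            raise ValueError("at least one population required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        cfg = cls(**d)
        cfg.validate()
        return cfg


def chrom_lengths_from_gff3(path) -> dict[str, int]:
    """Chromosome lengths from ##sequence-region directives."""
    lengths: dict[str, int] = {}
    with dio._open_text(path) as fh:
        for line in fh:
            m = re.match(r"##sequence-region\s+(\S+)\s+(\d+)\s+(\d+)", line)
            if m:
                lengths[m.group(1)] = int(m.group(3))
            elif not line.startswith("#"):
                break
    return lengths


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full scan; returns a dict of in-memory results and
    writes all report artifacts under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage: read inputs")
    genes = dio.read_genes(config.genes) if config.genes else []
    snps = dio.read_snps(config.snps)
    outgroup = dio.read_outgroup(config.outgroup)
    snp_pops = set(snps[0].pop_freq) if snps else set()
    unknown = [p for p in config.populations if p not in snp_pops]
    if unknown:
        raise ValueError(f"unknown population(s) {unknown}; SNP table has {sorted(snp_pops)}")
    supplied = {label: dio.read_region_set(path, label) for label, path in config.beds.items()}

    logger.info("stage: filter + polarize")
    polarized, summary = polarize_all(snps, outgroup, config.require_resequenced)
    dio.write_polarized(polarized, out / "polarized.tsv", config.populations)
    with open(out / "polarization_summary.json", "wt") as fh:
        json.dump(asdict(summary), fh, indent=2, sort_keys=True)

    logger.info("stage: build classes")
    catalog = build_catalog(genes, supplied, constrained_label=config.constrained_label)
    membership = assign_snps_to_classes(polarized, catalog)
    density = class_density_report(membership, catalog)
    _write_tsv(density, out / "density.tsv")

    venn_labels = config.venn_labels or catalog.labels()[: min(3, len(catalog.labels()))]
    inter = {}
    if len(venn_labels) >= 2:
        inter = intersection_counts(membership, venn_labels)
        with open(out / "intersections.json", "wt") as fh:
            json.dump(inter, fh, indent=2, sort_keys=True)

    logger.info("stage: scan")
    scans = {}
    for background in config.backgrounds:
        if background != "genome" and background not in membership:
            logger.warning("background %r not available; skipped", background)
            continue
        m = config.m_genome if background == "genome" else config.m_repeats
        scfg = ScanConfig(
            alpha=config.alpha,
            m=m,
            alternative=config.alternative,
            exact_threshold=config.exact_threshold,
        )
        for pop in config.populations:
            res = run_scan(polarized, membership, catalog, pop, background, scfg)
            scans[(pop, background)] = res
            tag = f"{pop}_{background}"
            _write_tsv(res.ranked_frame(), out / f"scan_{tag}.tsv")
            hist_rows = []
            for label, s in res.summaries.items():
                for b, c in enumerate(s.histogram):
                    hist_rows.append(
                        {
                            "class": label,
                            "bin_start": round(b * 0.05, 2),
                            "bin_end": round((b + 1) * 0.05, 2),
                            "count": int(c),
                        }
                    )
            _write_tsv(pd.DataFrame(hist_rows), out / f"hist_{tag}.tsv")
            with open(out / f"scan_{tag}.json", "wt") as fh:
                json.dump(
                    {
                        "population": pop,
                        "background": background,
                        "alpha": res.fdr.alpha,
                        "m": res.fdr.m,
                        "significant": res.fdr.significant_labels(),
                        "medians": {
                            lab: s.median_daf for lab, s in res.summaries.items()
                        },
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )

    null_results = {}
    if config.matched_null:
        logger.info("stage: matched null")
        mn = config.matched_null
        attr_label = mn["attribute"]
        if attr_label not in catalog.region_sets:
            raise ValueError(f"matched-null attribute {attr_label!r} not in catalog")
        chrom_lengths = chrom_lengths_from_gff3(config.genes)
        if not chrom_lengths:
            raise ValueError("matched null needs ##sequence-region directives in the GFF3")
        pop = mn.get("population", config.populations[0])
        for background in mn.get("backgrounds", ["genome"]):
            if background == "genome":
                background_ids = {s.snp_id for s in polarized}
                policy = GENOME_BACKGROUND
            else:
                background_ids = membership.ids(background)
                policy = REPEAT_BACKGROUND
            scan_res = scans.get((pop, background))
            context = (
                [r.p_raw for r in scan_res.results] if scan_res is not None else None
            )
            res = matched_null_test(
                catalog.region_sets[attr_label],
                polarized,
                genes,
                chrom_lengths,
                background_ids,
                population=pop,
                policy=policy,
                n_iter=mn.get("n_iter", 100),
                seed=config.seed,
                m=mn.get("m", 44),
                context_pvalues=context,
            )
            null_results[background] = res
            tag = f"{attr_label}_{pop}_{background}"
            _write_tsv(
                pd.DataFrame({"iteration": range(res.n_iter), "generated_p": res.generated_p}),
                out / f"matched_null_{tag}.tsv",
            )
            with open(out / f"matched_null_{tag}.json", "wt") as fh:
                json.dump(
                    {
                        "attribute": attr_label,
                        "background": background,
                        "population": pop,
                        "real_p": res.real_p,
                        "real_adjusted_p": res.real_adjusted_p,
                        "n_iter": res.n_iter,
                        "n_generated_le_real": res.n_generated_le_real,
                        "seed": res.seed,
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )

    config_dict = asdict(config)
    provenance = {
        "dafscan_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
    }
    with open(out / "provenance.json", "wt") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)

    return {
        "polarized": polarized,
        "summary": summary,
        "catalog": catalog,
        "membership": membership,
        "density": density,
        "intersections": inter,
        "scans": scans,
        "matched_null": null_results,
    }
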