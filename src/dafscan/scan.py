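"""Class-vs-background DAF comparisons: Mann-Whitney rank tests with
Benjamini-Hochberg FDR control.

Each annotation class's derived-allele-frequency spectrum is compared
with a background spectrum — either the genome as a whole or the
ancestral-repeat set — by a Mann-Whitney U test, one-sided by default
(class stochastically smaller, i.e. an excess of low-frequency derived
alleles indicating purifying selection). Overlapping SNPs are removed
before testing: against the genome background they are removed from the
background only; against ancestral repeats, from both sides. Ranked
p-values are then subjected to Benjamini-Hochberg step-up control with
a declared number of tests m (which may exceed the number of computed
p-values when some declared comparisons were not run).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classes import ClassCatalog, ClassMembership
from .model import PolarizedSNP

logger = logging.getLogger("dafscan")

P_FLOOR = 1e-8  # reporting floor; internal computation keeps full precision

GENOME_BACKGROUND = "genome_background"
REPEAT_BACKGROUND = "ancestral_repeat_background"


def remove_overlap(class_snps: set, background_snps: set, policy: str) -> tuple[set, set]:
    """Remove SNPs shared by class and background before testing.

    genome policy: the class is a subset of the genome, so shared SNPs
    leave the background only. Repeat policy: shared SNPs leave both
    sides. Raises on a degenerate (empty) result.
    """
    class_snps = set(class_snps)
    background_snps = set(background_snps)
    if policy == GENOME_BACKGROUND:
        out = class_snps, background_snps - class_snps
    elif policy == REPEAT_BACKGROUND:
        out = class_snps - background_snps, background_snps - class_snps
    else:
        raise ValueError(f"unknown overlap policy {policy!r}")
    if not out[0] or not out[1]:
        raise ValueError(
            f"degenerate comparison: empty {'class' if not out[0] else 'background'} "
            f"after overlap removal ({policy})"
        )
    return out


@dataclass
class MWResult:
    class_label: str
    background_label: str
    population: str
    n_class: int
    n_background: int
    U: float
    p_value: float          # floored at P_FLOOR for reporting
    p_raw: float            # full precision, used for FDR
    method: str             # "exact" | "normal_approx"
    median_class: float
    median_background: float


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def mann_whitney(
    class_dafs,
    background_dafs,
    alternative: str = "less",
    method: str = "auto",
    exact_threshold: int = 50,
    genome_scale_limit: int = 5000,
    class_label: str = "class",
    background_label: str = "background",
    population: str = "",
) -> MWResult:
    """Mann-Whitney U test of the class DAFs against the background DAFs.

    ``alternative="less"`` tests the purifying-selection direction (class
    distribution stochastically smaller). ``method="auto"`` uses the exact
    null enumeration when the smaller sample is at most ``exact_threshold``,
    the larger is below ``genome_scale_limit`` (exact enumeration against a
    genome-sized background is computationally infeasible and is refused,
    with a logged fallback), and the pooled data are tie-free; otherwise
    the normal approximation with tie-corrected variance and continuity
    correction. Sample-frequency DAFs live on a 1/2n grid and tie heavily,
    so realistic comparisons use the approximation.
    """
    x = np.asarray(class_dafs, dtype=float)
    y = np.asarray(background_dafs, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = _has_ties(x, y)
    if method == "auto":
        use_exact = (
            min(x.size, y.size) <= exact_threshold
            and max(x.size, y.size) <= genome_scale_limit
            and not ties
        )
    elif method == "exact":
        use_exact = True
        if max(x.size, y.size) > genome_scale_limit:
            logger.info(
                "exact Mann-Whitney refused for n=%d background; "
                "falling back to normal approximation",
                max(x.size, y.size),
            )
            use_exact = False
    elif method == "normal_approx":
        use_exact = False
    else:
        raise ValueError(f"unknown method {method!r}")

    if np.unique(np.concatenate([x, y])).size == 1:
        warnings.warn("all values identical in both samples; p = 1")
        return MWResult(
            class_label, background_label, population, x.size, y.size,
            U=x.size * y.size / 2.0, p_value=1.0, p_raw=1.0,
            method="normal_approx",
            median_class=float(np.median(x)),
            median_background=float(np.median(y)),
        )

    scipy_method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=scipy_method)
    p_raw = float(res.pvalue)
    return MWResult(
        class_label=class_label,
        background_label=background_label,
        population=population,
        n_class=int(x.size),
        n_background=int(y.size),
        U=float(res.statistic),
        p_value=max(p_raw, P_FLOOR),
        p_raw=p_raw,
        method="exact" if use_exact else "normal_approx",
        median_class=float(np.median(x)),
        median_background=float(np.median(y)),
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


@dataclass
class FDREntry:
    rank: int
    class_label: str
    p_value: float
    critical_value: float   # i * alpha / m (step-up threshold)
    adjusted_p: float       # min_{j>=i} m p_j / j, capped at 1
    significant: bool


@dataclass
class FDRReport:
    alpha: float
    m: int
    entries: list[FDREntry] = field(default_factory=list)

    def significant_labels(self) -> list[str]:
        return [e.class_label for e in self.entries if e.significant]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries])


def bh_report(pvalues_by_class: dict[str, float], alpha: float = 0.05, m: Optional[int] = None) -> FDRReport:
    """Benjamini-Hochberg step-up over a declared number of tests m.

    m defaults to the number of supplied p-values and may exceed it (for
    declared-but-not-computed tests); it may not be smaller. Critical
    values are c_i = i*alpha/m; the step-up rule marks ranks 1..k
    significant for the largest k with p_(k) <= c_k, so the significant
    set is always a prefix of the ranking. Adjusted p-values are
    min_{j>=i} m*p_(j)/j capped at 1.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0,1)")
    k = len(pvalues_by_class)
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"declared m={m} smaller than number of p-values ({k})")
    for label, p in pvalues_by_class.items():
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value for {label!r} outside (0,1]: {p}")
    items = sorted(pvalues_by_class.items(), key=lambda kv: kv[1])
    ps = np.array([p for _, p in items], dtype=float)
    ranks = np.arange(1, k + 1)
    crit = ranks * alpha / m
    adj = np.minimum.accumulate((m * ps / ranks)[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    passing = np.flatnonzero(ps <= crit)
    k_sig = int(passing[-1]) + 1 if passing.size else 0
    entries = [
        FDREntry(
            rank=int(i + 1),
            class_label=items[i][0],
            p_value=float(ps[i]),
            critical_value=float(crit[i]),
            adjusted_p=float(adj[i]),
            significant=i < k_sig,
        )
        for i in range(k)
    ]
    return FDRReport(alpha=alpha, m=int(m), entries=entries)


def bh_adjusted(pvalues: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """BH-adjusted p-values for an unlabeled vector, in input order."""
    report = bh_report({f"_{i}": p for i, p in enumerate(pvalues)}, alpha=0.5, m=m)
    by_label = {e.class_label: e.adjusted_p for e in report.entries}
    return np.array([by_label[f"_{i}"] for i in range(len(pvalues))])


# ---------------------------------------------------------------------------
# scan driver


HIST_BINS = np.round(np.arange(0.0, 1.05, 0.05), 10)  # fixed 0.05-wide bins


@dataclass
class ScanConfig:
    alpha: float = 0.05
    m: Optional[int] = None           # declared number of tests
    alternative: str = "less"
    method: str = "auto"
    exact_threshold: int = 50
    genome_scale_limit: int = 5000


@dataclass
class ClassSummary:
    class_label: str
    n_snps: int
    median_daf: float
    histogram: np.ndarray  # counts in 20 bins of width 0.05 on [0,1]


@dataclass
class ScanResult:
    population: str
    background_label: str
    results: list[MWResult]
    fdr: FDRReport
    summaries: dict[str, ClassSummary]

    def ranked_frame(self) -> pd.DataFrame:
        by_label = {r.class_label: r for r in self.results}
        rows = []
        for e in self.fdr.entries:
            r = by_label[e.class_label]
            rows.append(
                {
                    "rank": e.rank,
                    "class": e.class_label,
                    "n_class": r.n_class,
                    "n_background": r.n_background,
                    "U": r.U,
                    "p_value": r.p_value,
                    "critical_value": e.critical_value,
                    "adjusted_p": e.adjusted_p,
                    "significant": e.significant,
                    "method": r.method,
                    "median_class": r.median_class,
                    "median_background": r.median_background,
                }
            )
        return pd.DataFrame(rows)


def daf_vector(polarized: Iterable[PolarizedSNP], population: str, ids: Optional[set] = None) -> np.ndarray:
    vals = [
        s.daf[population]
        for s in polarized
        if ids is None or s.snp_id in ids
    ]
    return np.asarray(vals, dtype=float)


def run_scan(
    polarized: list[PolarizedSNP],
    membership: ClassMembership,
    catalog: ClassCatalog,
    population: str,
    background_label: str = "genome",
    config: Optional[ScanConfig] = None,
    class_labels: Optional[Sequence[str]] = None,
) -> ScanResult:
    """Run the full class-vs-background scan for one population.

    background "genome" = all polarized SNPs (genome overlap policy);
    any other label must be a catalog class (repeat overlap policy).
    Classes absent from the membership are skipped with a warning and
    excluded from the ranking; they still count toward a declared m.
    """
    config = config or ScanConfig()
    daf_by_id = {s.snp_id: s.daf[population] for s in polarized}
    if background_label == "genome":
        background_ids = set(daf_by_id)
        policy = GENOME_BACKGROUND
    else:
        if background_label not in membership:
            raise ValueError(f"background class {background_label!r} not in membership")
        background_ids = membership.ids(background_label)
        policy = REPEAT_BACKGROUND
    if class_labels is None:
        class_labels = [
            lab for lab in catalog.labels() if lab not in {background_label, "genome"}
        ]

    results: list[MWResult] = []
    summaries: dict[str, ClassSummary] = {}
    for label in class_labels:
        if label not in membership:
            logger.warning("class %r absent from membership; skipped", label)
            continue
        class_ids = membership.ids(label)
        try:
            cls_ids, bg_ids = remove_overlap(class_ids, background_ids, policy)
        except ValueError as err:
            logger.warning("class %r: %s; skipped", label, err)
            continue
        x = np.array([daf_by_id[i] for i in cls_ids], dtype=float)
        y = np.array([daf_by_id[i] for i in bg_ids], dtype=float)
        res = mann_whitney(
            x,
            y,
            alternative=config.alternative,
            method=config.method,
            exact_threshold=config.exact_threshold,
            genome_scale_limit=config.genome_scale_limit,
            class_label=label,
            background_label=background_label,
            population=population,
        )
        results.append(res)
        hist, _ = np.histogram(x, bins=HIST_BINS)
        summaries[label] = ClassSummary(label, x.size, float(np.median(x)), hist)

    bg_daf = np.array([daf_by_id[i] for i in background_ids], dtype=float)
    hist, _ = np.histogram(bg_daf, bins=HIST_BINS)
    summaries[background_label] = ClassSummary(
        background_label, bg_daf.size, float(np.median(bg_daf)), hist
    )
    fdr = bh_report(
        {r.class_label: r.p_raw for r in results}, alpha=config.alpha, m=config.m
    )
    return ScanResult(population, background_label, results, fdr, summaries)
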