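"""SNP filtering and ancestral/derived allele assignment.

The ancestral allele at a biallelic human SNP is taken to be the allele
matching the orthologous chimpanzee base; when the chimp base matches
neither human allele (or is missing), the rhesus macaque base is used
as a fallback, and when neither outgroup matches, the SNP is discarded.
The derived allele frequency (DAF) in each population is then one minus
the ancestral-allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import OutgroupCall, PolarizedSNP, SNPRecord

logger = logging.getLogger("dafscan")

# drop reasons, in the fixed order the filter applies them (a SNP failing
# several rules is counted once, under the first failing rule)
FILTER_ORDER = (
    "multi_mapped",
    "on_Y",
    "not_in_dbsnp",
    "not_biallelic_substitution",
    "not_resequenced",
)


def filter_snps(
    snps: Iterable[SNPRecord], require_resequenced: bool = True
) -> tuple[list[SNPRecord], dict[str, int]]:
    """Apply the study's inclusion filters.

    Kept SNPs map uniquely (not multi-mapped), are autosomal/X (not on Y),
    appear in dbSNP, are biallelic single-base substitutions, and — when
    ``require_resequenced`` — come from the resequenced (ascertainment-
    bias-minimizing) subset. Returns (kept, drop counts partitioned by
    first failing rule).
    """
    kept: list[SNPRecord] = []
    drops = {reason: 0 for reason in FILTER_ORDER}
    for snp in snps:
        f = snp.flags
        if f.multi_mapped:
            drops["multi_mapped"] += 1
        elif f.on_y:
            drops["on_Y"] += 1
        elif not f.in_dbsnp:
            drops["not_in_dbsnp"] += 1
        elif not f.biallelic_substitution:
            drops["not_biallelic_substitution"] += 1
        elif require_resequenced and not f.resequenced:
            drops["not_resequenced"] += 1
        else:
            kept.append(snp)
    return kept, drops


def polarize(snp: SNPRecord, outgroup_call: OutgroupCall) -> Optional[PolarizedSNP]:
    """Assign ancestral/derived alleles from the outgroup call.

    Returns ``None`` (DISCARD) when neither the chimp nor the macaque base
    matches a human allele; a missing outgroup base counts as non-matching.
    """
    if outgroup_call.snp_id != snp.snp_id:
        raise ValueError(
            f"outgroup call {outgroup_call.snp_id} does not match SNP {snp.snp_id}"
        )
    alleles = {snp.allele_a, snp.allele_b}
    if outgroup_call.chimp_allele in alleles:
        ancestral = outgroup_call.chimp_allele
        source = "chimp"
    elif outgroup_call.macaque_allele in alleles:
        ancestral = outgroup_call.macaque_allele
        source = "macaque"
    else:
        return None
    derived = snp.allele_b if ancestral == snp.allele_a else snp.allele_a
    # stored frequencies are for allele_b
    daf = {
        pop: (f if derived == snp.allele_b else 1.0 - f)
        for pop, f in snp.pop_freq.items()
    }
    return PolarizedSNP(
        snp_id=snp.snp_id,
        chrom=snp.chrom,
        pos=snp.pos,
        ancestral_allele=ancestral,
        derived_allele=derived,
        daf=daf,
        polarization_source=source,
    )


@dataclass
class PolarizationSummary:
    n_input: int = 0
    n_kept: int = 0
    n_filter_dropped: int = 0
    n_polarization_discarded: int = 0
    drop_counts: dict[str, int] = field(default_factory=dict)
    source_counts: dict[str, int] = field(default_factory=dict)


def polarize_all(
    snps: Iterable[SNPRecord],
    outgroup_calls: Iterable[OutgroupCall],
    require_resequenced: bool = True,
) -> tuple[list[PolarizedSNP], PolarizationSummary]:
    """Filter then polarize a SNP table against its outgroup table.

    Every input SNP ends in exactly one bucket: kept-polarized,
    filter-dropped, or polarization-discarded; the summary counts sum to
    the input size. SNPs with no outgroup row are treated as having a
    fully missing call (hence discarded).
    """
    snps = list(snps)
    call_map = {c.snp_id: c for c in outgroup_calls}
    kept, drops = filter_snps(snps, require_resequenced=require_resequenced)
    summary = PolarizationSummary(
        n_input=len(snps),
        n_filter_dropped=sum(drops.values()),
        drop_counts=drops,
        source_counts={"chimp": 0, "macaque": 0},
    )
    out: list[PolarizedSNP] = []
    for snp in kept:
        call = call_map.get(snp.snp_id, OutgroupCall(snp.snp_id))
        pol = polarize(snp, call)
        if pol is None:
            summary.n_polarization_discarded += 1
        else:
            summary.source_counts[pol.polarization_source] += 1
            out.append(pol)
    summary.n_kept = len(out)
    logger.info(
        "polarization: %d input, %d kept (%d via chimp, %d via macaque), "
        "%d filter-dropped %s, %d discarded (no outgroup match)",
        summary.n_input,
        summary.n_kept,
        summary.source_counts["chimp"],
        summary.source_counts["macaque"],
        summary.n_filter_dropped,
        summary.drop_counts,
        summary.n_polarization_discarded,
    )
    return out, summary
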