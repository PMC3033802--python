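import numpy as np
import pytest

from dafscan.model import GeneModel, GenomicInterval, Transcript
from dafscan.polarize import polarize_all
from dafscan.synthetic import default_demo_config, generate_bundle


@pytest.fixture(scope="session")
def demo_bundle():
    """One demo-scale synthetic bundle shared across read-only tests."""
    return generate_bundle(default_demo_config(seed=1))


@pytest.fixture(scope="session")
def demo_polarized(demo_bundle):
    polarized, summary = polarize_all(demo_bundle.snps, demo_bundle.outgroup_calls)
    return polarized, summary


def make_gene(gene_id, chrom, strand, exon_coords, cds_coords=(), span=None):
    """Toy gene with one transcript from explicit exon/CDS coordinates."""
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
    cds = [GenomicInterval(chrom, s, e, strand) for s, e in cds_coords]
    if span is None:
        span = (min(s for s, _ in exon_coords), max(e for _, e in exon_coords))
    return GeneModel(
        gene_id,
        chrom,
        strand,
        GenomicInterval(chrom, span[0], span[1], strand),
        [Transcript(f"{gene_id}.t0", exons, cds)],
    )


def random_intervals(rng, n, max_coord=1000, max_len=80):
    starts = rng.integers(0, max_coord, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return starts.astype(np.int64), (starts + lengths).astype(np.int64)


def covered_bases(starts, ends):
    """Brute-force per-base set oracle for interval algebra."""
    out = set()
    for s, e in zip(starts, ends):
        out.update(range(int(s), int(e)))
    return out
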