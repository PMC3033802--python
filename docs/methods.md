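# Methods

`dafscan` detects purifying (negative) selection in classes of genomic
annotation by comparing the derived allele frequency (DAF) spectrum of
the SNPs inside each class against a background spectrum. This note
documents the statistical model, the conventions the implementation
commits to where the underlying procedure is ambiguous, the synthetic
data generator and what it does and does not emulate, and known
limitations.

## The scan

A SNP's **derived allele** is the human allele that does not match the
inferred ancestral state. The ancestral state is read from the
orthologous chimpanzee base; when the chimp base matches neither human
allele (or is missing), the rhesus macaque base is used as a fallback,
and when neither outgroup matches, the SNP is discarded. The per-
population DAF is then one minus the ancestral-allele frequency.
Purifying selection holds deleterious derived alleles at low frequency,
so a class under negative selection shows an excess of low-frequency
derived alleles relative to neutrally evolving sequence.

Before polarization, SNPs are filtered: multi-mapped SNPs, Y-chromosome
SNPs, SNPs absent from dbSNP, non-biallelic or non-substitution
variants, and (by default) SNPs outside the resequenced subset are
removed. The filter applies its rules in a fixed order and counts each
dropped SNP once, under the first failing rule, so drop accounting is
deterministic. Monomorphic sites within a single population (DAF 0
or 1) are retained in that population's spectrum; a switch excludes
them.

Each class's DAF vector is compared with a background by a
**Mann–Whitney U test**, one-sided by default (class stochastically
smaller; two-sided available). Two backgrounds are supported:

- *genome*: all kept, polarized SNPs. Shared SNPs are removed from the
  background only, since the class is a subset of the genome.
- *ancestral repeats*: SNPs in relics of transposable elements shared
  across mammals, a standard neutral reference. Shared SNPs are removed
  from **both** sides, leaving disjoint sets.

The exact null distribution of U is enumerated when the smaller sample
has at most `exact_threshold` (default 50) observations, the larger
sample is below `genome_scale_limit` (default 5000; exact enumeration
against a genome-sized background is computationally infeasible and is
refused with a logged fallback), and the pooled data are tie-free.
Otherwise the normal approximation with tie-corrected variance and
continuity correction is used. Sample DAFs live on a 1/2n grid and tie
heavily, so realistic comparisons use the approximation; the exact path
is exercised by small tie-free problems and verified against a
full-enumeration oracle in the tests. Reported p-values are floored at
1e-8; ranking and multiple-testing use full precision.

Ranked p-values receive **Benjamini–Hochberg step-up** control at
α = 0.05 over a *declared* number of tests m, which may exceed the
number of computed p-values (comparisons can be declared but not run;
the genome and ancestral-repeat scans may legitimately declare
different m, e.g. 32 vs 44). Step-up critical values are c_i = i·α/m;
the significant set is always a prefix of the ranking. Two distinct
quantities appear under "FDR" language in this literature and are kept
apart in the output: the critical value c_i (labelled
`critical_value`) and the BH-adjusted p-value min_{j≥i} m·p_j/j
(labelled `adjusted_p`).

## Annotation classes

Internal coordinates are 0-based half-open everywhere; GFF3/GTF input
is converted on read, BED is native. A SNP occupies [pos, pos+1) and
belongs to a class iff that interval intersects the class's merged
intervals. Classes are not mutually exclusive.

Stated bp windows are read as inclusive of both endpoints and of the
anchor base where one exists (a TSS is a base; a splice junction is a
boundary between bases):

- **promoter**: per transcript, 1000 bases upstream of the TSS, the TSS
  base, and 200 bases downstream — 1201 bp, strand-aware, clipped at
  the chromosome start; the class is the union over all transcripts
  (no canonical-transcript choice).
- **splice control**: per intron, an acceptor (intron→exon) window of
  50 intronic + 2 exonic bases (52 bp; covers the polypyrimidine
  tract) and a donor (exon→intron) window of 3 exonic + 6 intronic
  bases (9 bp), strand-aware, clipped to the intron/exon extents.
  Single-exon transcripts contribute nothing.
- **coding**: union of all CDS intervals.

Constrained-element subsets come in two kinds with deliberately
different semantics: `minus_coding` / `minus_genes` subtract coverage
base-wise (elements may be truncated or split), while
`min_distance(d)` keeps or drops whole elements by their gap to the
nearest gene span (distance is a property of an element; coverage is a
property of bases). Gene distance is measured to the transcript-union
gene span, not to exons.

**Distance convention.** The gap between two half-open intervals is
`max(0, b.start − a.end, a.start − b.end)` — the number of bases
strictly between them, 0 on intersection or book-ending, +∞ when the
query's chromosome carries no gene. The same formula is used for SNPs
(as 1-bp intervals), region subsets, and matched-region placement, so
the matched sampler's "identical distance" guarantee is exact under
the same measure that produced the source distance.

Class reports give SNP density as n/(merged kb), rounded to two
decimals; merged length is used because overlapping windows from
neighbouring transcripts would otherwise double-count bases (the
unmerged total remains available on `RegionSet.unmerged_length_bp`).

## The matched-region permutation null

A class can show a depressed DAF spectrum without being functional if
it preferentially sits near genes, where hitchhiking and background
selection depress linked neutral variation. The control: for each
region of the attribute, draw a random gene uniformly, a side
(upstream/downstream) uniformly, and place a region of *identical
length* at *identical edge distance* from that gene; pool the SNPs in
the sampled regions (overlaps merged so no SNP is counted twice) and
run the identical Mann–Whitney comparison. Repeating this (default
100 iterations) yields "generated" p-values; if the real p-value
undercuts all of them, gene proximity alone cannot explain the signal.

Choices the procedure does not pin down, resolved as follows: the
distance is matched to the *drawn* gene, not re-measured against all
genes (a sample may incidentally sit nearer another gene; re-measuring
would make exact matching infeasible); the side is randomized rather
than preserved; for a source region overlapping a gene (d = 0) the
source's offset relative to its nearest gene's start is transplanted
onto the drawn gene, redrawing when the transplant would miss the gene
or overrun the chromosome. Placements violating chromosome bounds are
redrawn (default 100 attempts) before erroring. An iteration that
pools zero SNPs is redrawn once, then recorded as p = 1 with a
warning. (seed, inputs) fully determine the output.

## Synthetic data generator

The generator emulates the scan's inputs at desk scale: a toy genome
(default three 10-Mb chromosomes), non-overlapping gene models with
1–2 transcripts of 1–6 exons and CDS trimmed by UTR-like ends, named
region sets with controllable placement (uniform, near a gene, at
least d from every gene), SNPs, and outgroup calls.

Population frequencies follow the classical diffusion form of the site
frequency spectrum under genic selection,

    f(q | γ) = (1 − e^(−γ(1−q))) / (q(1−q)(1 − e^(−γ))),

with γ the scaled selection coefficient (γ = 0 gives the neutral 1/q
limit; γ < 0 is deleterious, piling density onto low q). Each SNP
draws one q by inverse-CDF on a 4096-point grid spanning
(1/(4n), 1 − 1/(4n)) — resolution below one sample-frequency step —
and each population's sample DAF is an independent Binomial(2n, q)/2n
draw. This shared-q, independent-binomial model reproduces the
qualitative agreement of scans across populations while staying
analytic and fast; it deliberately models **no** demographic
covariance, linkage disequilibrium, bottlenecks/growth, or coalescent
noise, so passing tests demonstrate correctness of the scan machinery
under an idealized frequency model, not robustness to demography or
linked selection. Ancestral misidentification is likewise absent: when
an outgroup call succeeds it reports the true ancestral base
(chimp succeeds with probability 1 − p_chimp_fail, else macaque
rescues with probability p_macaque_rescue, else the SNP is lost to
polarization), so polarization error appears only as data loss, not as
spectrum folding.

Default conditions: 2n = 48 chromosomes per population (AFR/EUR/CHN
panel scale), per-class SNP density 3.7/kb (the genome-wide density
scale), a strongly selected constrained-element-like class at γ = −15,
a gene-associated attribute class at γ = −15, and a neutral
ancestral-repeat-like class. The genome-wide background is thinned to
4000 SNPs: once the background is an order of magnitude larger than a
class, additional background SNPs change the rank test negligibly,
while bundle generation stays fast enough for the replicated
calibration and power studies. All randomness flows from a single seed
through per-stage child streams, so bundles are bit-reproducible and
stages do not perturb each other's draws.

## Numerical and degenerate-input choices

- DAF histograms use fixed 0.05-wide bins on [0,1], right-open except
  the last.
- A comparison whose class or background empties after overlap removal
  is an error at the operation level and a logged skip in the scan
  driver (it still counts toward a declared m).
- Two samples with all values identical yield p = 1 with a warning.
- A zero-length class reports undefined (NaN) density, not an error.
- Chromosome names are taken verbatim from inputs; no chr-prefix
  normalization.
- TSV float round-tripping uses repr on write and round-trip parsing
  on read, so write→read reproduces records exactly and pipeline
  reruns are byte-identical.

## Problem sizes in the replicated checks

Calibration and power are estimated by rerunning the full pipeline on
fresh bundles: type-I error over 200 seeds (one neutral class of
~110 SNPs against a 2000-SNP background), power and matched-null
clearance over 20 seeds of the demo conditions (selected class
≥500 SNPs), and matched-null rank calibration over 50 seeds with a
zero-density neutral attribute. These sizes give binomial/KS checks
useful resolution while keeping the whole suite at around a minute.

## Known limitations

- The exact Mann–Whitney path does not correct for ties; it is only
  selected for tie-free data. The R implementation the field commonly
  uses behaves the same way.
- Multi-assembly SNP bookkeeping (alternative haplotypes, supercontigs)
  is reduced to the `multi_mapped` input flag; the package does not
  re-derive it.
- Regulatory-feature construction, constrained-element scoring (GERP),
  and ancestral-repeat identification are consumed as BED inputs, never
  computed.
- No liftover, no reference-FASTA allele validation, no LD-based or
  SFS-model-fitting selection statistics (Tajima's D, DFE inference).
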