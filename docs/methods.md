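# Methods

This note documents the generative model behind the synthetic hybrid-ESC
experiment, the statistical procedures in each analysis stage, the defaults
and why they were chosen, and what the tests do and do not demonstrate.

## The synthetic experiment (`simhybrid`)

**Genomes.** Two chromosomes of i.i.d. random sequence: a 200-kb main
chromosome carrying the focal gene (4 kb, high expression), two neutral
bystanders and a 1.3-kb enhancer 20 kb downstream of the focal gene's 3'
end; and a 100-kb auxiliary chromosome carrying the copy-number control gene
(with the control interval used by the qPCR analysis) plus four
trans-down, four trans-up and four neutral genes.  This is a deliberate
desk-scaling of the real topology (a 13-kb SE 100 kb from its gene inside a
~1.5-Mb gene desert): it preserves every structural relationship the
analysis relies on — enhancer outside all gene bodies, same chromosome as
the focal gene, control region in trans — while keeping whole-pipeline runs
in seconds.  All distances are configurable.

**Variants.** Phased SNPs/indels are planted as a Poisson process
(default 2/kb, ~10% indels of 1–3 bp) with a 10-bp minimum spacing;
requesting a density too high to honour the spacing is an explicit error.
CAST is the reference frame (VCF REF, `GT 0|1`); the 129 haplotype is built
by applying the alternate alleles, and both coordinate frames are tracked
through cumulative indel offsets.  Two diagnostic SNPs are always planted in
the downstream junction-primer flank so deletion amplicons are
allele-informative (omitted when `snp_density=0`, in which case junction
genotyping refuses to run rather than silently return nothing).  The real
CAST × 129 cross is denser (~7 variants/kb); the default is desk-scaled to
keep the exhaustive dummy-read QC fast, and the parameter-recovery tests
that need more informative reads raise it locally.

**Clone editing.** Each deleted allele has the enhancer interval excised in
its own coordinate frame and an NHEJ scar applied at the fusion point:
geometric(p = 0.3) length, deletion-biased 2:1 over insertion, capped at
±50 bp.  The distribution is a modelling choice (the source data show only
that junction indels are small and variable).  An allele can instead carry
the excised segment re-inserted reverse-complemented (`inverted`), which
preserves copy number and lengthens the junction amplicon.  The canonical
16-clone roster used throughout (2 biallelic, 5 monoallelic-129,
1 monoallelic-CAST, 8 WT) models all monoallelic clones as plain deletions:
a fully retained inverted segment would still amplify in the
enhancer-internal qPCR assay and so would not read as a one-copy clone.

**RNA-seq.** Expected read count per (gene g, allele h):

    mu(g,h) = n_reads · base_g / (2 Σ base) · cis(g,h) · trans(g)^dosage

where `cis = cis_residual` (default 0.07) for the focal gene on a deleted
allele and 1 otherwise; `trans` is 5.0 for planted up genes and 0.2 for down
genes; and `dosage` is 0 / 0.5 / 1 for WT / monoallelic / biallelic clones,
so the monoallelic trans effect is the geometric mean of the WT and
biallelic effects.  Counts are negative-binomial with dispersion
α = 0.005 (var = μ + αμ²), drawn independently per gene and allele: this
models the residual clone-to-clone overdispersion of isogenic lines after
library-scale effects, which FPKM normalisation removes, and degrades to
Poisson at α = 0.  Reads are uniform `read_length`-substrings of the
haplotype transcript, sense-strand only (dUTP-style protocol), with no
sequencing-error model by default; every read carries a ground-truth allele
tag.  Gene bodies are never touched by the excision, so transcripts come
from the reference haplotypes.

**qPCR.** `Ct = Ct0 − log2(copies) + N(0, ct_sd)` per well, three wells per
assay; the control assay always sees two copies.  Zero template (biallelic
deletion) yields the no-amplification sentinel (missing Ct) rather than an
arbitrary high cycle.

**Hi-C.** The main chromosome is digested at AAGCTT; anchor–fragment counts
are Poisson with mean ∝ distance^−γ (γ = 1 by default, no fragment-length
factor), normalised to `hic_n_contacts` (2500) anchor-incident pairs, with
fragments overlapping the enhancer multiplied by `loop_enrichment` (5).
These depths give per-fragment counts in the tens-to-hundreds, matching the
bar-graph scale of fragment-resolution anchor profiles.

**Determinism.** Every `simulate_*` operation seeds an independent stream
from (config seed, stage tag, clone id), so outputs are byte-identical for a
given configuration regardless of call order.

## Variant QC (`variantqc`)

Dummy reads are the exhaustive enumeration of read-length windows
overlapping the variant's allele span on each haplotype.  The default mapper
is an exact-match lookup over both haplotype genomes (k-mer-seeded); any
aligner honouring the same contract can be plugged in.  Bias is
`|m_A − m_B| / max(m_A, m_B)` over reads that map uniquely and to their true
locus (1 if nothing maps); SNPs above 5% and indels above 10% are flagged,
both strict inequalities.  The CNV filter is a two-sided exact binomial test
of the genomic-DNA allele split against 1:1; the het-quality filter is a
one-sided binomial test that the minor-allele fraction reaches 0.15
(configurable — the criterion behind the published "poor heterozygous calls"
is not specified, so a minimum-minor-fraction test was chosen); both use
Benjamini–Hochberg at 5% FDR.  Zero-coverage variants are untestable and
flagged as poor het calls.

## Allele counting (`allelecount`)

Reads are placed exactly (simulation truth or exact-match placements) and
compared to both haplotype windows; a read matching exactly one haplotype is
assigned to it, matching both (no informative variant) or none of the usable
variants is unassigned, and when neither window matches exactly (sequencing
errors) a per-SNP majority vote with tie→unassigned decides.  Indels
contribute evidence only through the exact window match, avoiding gapped
realignment.  An optional mapper-based uniqueness screen discards reads
whose sequence occurs at more than one reference locus, emulating an
aligner's unique-mapping requirement; this is what makes variant
blacklisting consequential in the bias-interaction tests, since exact
placement alone is structurally immune to mapping bias.  The specificity
statistic is computed as `log2(c_CAST + 10) − log2(c_129 + 10)` so that
label-swap antisymmetry holds exactly in floating point; the pseudo-count
is applied only to the statistic, never to stored counts.

## Expression signatures (`exprsig`)

FPKM = count·10⁹/(length·library).  Signature calls use
`(FPKM_mut + 4)/(FPKM_wt + 4)` with the 3-fold boundary counted as a
signature (the inclusive reading of a "3-fold cutoff"); calls compare one
mutant clone to one WT clone, as in the original design.  The
promoter-binding enrichment is a two-sided exact binomial test of the bound
count among down-regulated genes against the pooled bound fraction of both
lists (the published test's null is not stated; the pooled proportion is the
natural two-list null).  Signature overlap uses the upper binomial tail of
the observed intersection against |A||B|/U per directional quadrant.

## Loop calling (`loopcall`)

Fragments are binned into 20 equal-occupancy bins of log distance to the
anchor.  Each fragment's expected count comes from bin count rates computed
with that fragment left out (so a genuine loop cannot inflate its own
expectation), constrained to be non-increasing with distance by weighted
pool-adjacent-violators, and interpolated linearly in log rate vs log
distance between bin centres, extending the terminal slopes beyond the first
and last bins.  The interpolation and extrapolation matter: a step-function
expectation on a steep decay is systematically misfit at count depths of
hundreds and miscalibrates the Poisson test, and clamping at the first bin
centre under-estimates the nearest fragments.  Significance is the upper
Poisson tail with BH across tested fragments at 5% FDR.  A Poisson (rather
than negative-binomial) test matches the generative model exactly, so the
calibration tests are a clean check of the machinery; on real Hi-C data the
Poisson tail would be anti-conservative.

## Pipeline (`pipeline`) and interfaces

One configuration drives simulate → genotyping → variant QC → allele
counting → expression → loop calling; logging reports counts in and out of
every filter, and the manifest fingerprint (config hash, seed, metrics, file
checksums; timings excluded) is reproducible bit-for-bit.  All external
formats are plain text: FASTA/FASTQ, VCF 4.2 (flags in FILTER), BED6, TSV,
YAML.  The `crisprdel` console script exposes each stage as a subcommand.

## Problem sizes used by the tests and the acceptance script

Unit and property tests run at the desk-scale defaults (16 clones ×
2×10⁴ reads; toy references of a few hundred bp for enumeration oracles).
Parameter-recovery checks use 3×10⁵ reads per clone on a SNP-dense
reference (6/kb) in the Poisson limit; the acceptance script uses 12
monoallelic, 6 WT and 2 biallelic clones at 2×10⁵ reads each with default
dispersion, and 20-seed replication for FDR calibration and signature
performance.  These sizes put the Monte-Carlo standard error of each
stochastic quantity well inside the tolerance being checked.

## What passing tests do and do not show

The generator reproduces the statistical structure the analysis assumes —
phased variants, cis-confined dosage loss, dosage-scaled trans effects,
distance-decaying contacts with one planted loop — under exactly the
distributional assumptions the tests exploit (NB/Poisson counts, Gaussian
Ct noise, error-free reads, exact placements).  Passing therefore
demonstrates correctness of the statistical machinery and internal
consistency of the pipeline, not robustness to real-data pathologies:
alignment artefacts beyond exact-match ambiguity, PCR duplicates,
sequencing error, allelic mapping bias subtler than repeats, restriction
efficiency, or matrix-level Hi-C biases (no ICE/balancing is performed).
Known limitations, by design: no probabilistic read assignment, no
replicate-aware differential expression (single-clone fold changes only),
no genome-wide loop calling, and the expected-contact model uses distance
only (no fragment length/GC covariates).
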