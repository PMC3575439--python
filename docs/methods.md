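# Methods

This note documents the models, conventions and numerical choices behind
`medipmap`, in the order the pipeline runs them.

## Coordinates and the feature partition

All internal coordinates are 0-based half-open; GTF (1-based inclusive)
and BED (0-based half-open) are converted at the file boundary, and
bisulfite amplicon tables keep their printed 1-based inclusive
convention with the half-open interval derived alongside. A single
internal convention removes the main source of off-by-one drift in
interval pipelines.

The genome is labelled from transcript models: gene body = transcript
span (TSS to TES), promoter = TSS ± 2 kb (strand-aware, clipped to the
chromosome), upstream2k/downstream2k = the 2 kb strictly outside the
span, introns = body minus exons, UTRs derived from the CDS (transcripts
without CDS contribute none), intergenic = complement of merged gene
bodies. Labels are deliberately **not** forced disjoint — a promoter
extends 2 kb into the body, and peak/CGI counts are reported per
component independently — except gene_body vs intergenic, which
partition the genome exactly. Overlapping transcripts are merged within
each label before counting, so a base carries a label at most once.

## CpG-island scanning

Islands are detected with 100 bp windows stepped by 1 bp. Each window
yields a GC fraction and an observed/expected CpG ratio in the
Gardiner-Garden form O/E = #CpG · L / (#C · #G) (0 when #C or #G is 0;
windows containing N score 0, so no island spans an N run of a window
length or more). Each *position* is then scored with the mean of these
two statistics over every window covering it — the moving-average
convention of the classical island plotters. This choice matters at
boundaries: scoring positions by whole covering windows smears islands
up to a window beyond the dense region, while scoring by the centred
window alone undershoots by half a window; the covering-window average
tracks the dense region from both sides to within a few tens of bases.
Maximal runs of passing positions are trimmed to the first/last CpG they
contain and re-validated over the final span against all three criteria
(length ≥ 200 bp, GC > 0.5, O/E > 0.6, all thresholds strict except the
length, which is taken inclusive). Soundness is therefore guaranteed by
construction: every emitted island passes all criteria when re-scored
from scratch, which the tests assert directly. Reverse-complement
symmetry of island ends is not asserted — CpG counting is
strand-symmetric but trimming to CpG boundaries can shift an end by a
base.

## Peak calling

The caller is an intentionally simple, fully specified Poisson model
with a MACS-flavoured dynamic background, not a MACS clone; externally
called peaks can be supplied as BED and flow through every downstream
module unchanged. Reads are extended from their 5′ end to
`fragment_extension` (default 200 bp, matching a 220–320 bp
size-selected library minus adapters), counted as fragments overlapping
non-overlapping tiling windows (width = fragment_extension by default).
A window is a candidate when P(X ≥ k | λ_local) < 10⁻⁵ (the classical
default), with λ_local the maximum of the genome-wide rate and rates
estimated in 5 kb and 10 kb windows centred on the candidate, all scaled
by (span + fragment) to be comparable overlap-count expectations. The
1 kb window some callers use with a control sample is **excluded from
the default**: without a control it is dominated by the candidate's own
reads, so λ_local ≈ k inside genuine enrichments and real peaks are
suppressed; it can still be passed via `local_lambda_windows`.
Candidates within one window merge; merged peaks are re-scored over the
final span (count, λ, p, fold = k/λ, summit at maximum fragment
coverage). With the default merge gap equal to the fragment length, no
fragment can bridge two separate peaks, so per-peak read counts sum to
at most the library size. The caller is fully deterministic.

Under the test conditions (10,000 reads uniform on 1 Mb), the
discreteness of the Poisson tail puts the realised per-window false-call
rate well below the nominal 10⁻⁵; the measured spurious-peak rate is
about 0.005 per run, so 20-seed suites expect essentially zero.

## Profiling conventions

Reads are classified into exactly one of {CGI, gene body, repeat, other}
by precedence, CGI first: it is by far the rarest class (~1 % of reads)
and would otherwise be absorbed into gene bodies. Peaks are counted once
per component they overlap and once in the deduplicated genome total.
Methylation density is peaks per Mb of a component's merged length. A
CGI is methylated iff it shares ≥ 1 bp with a peak; the summary percent
is printed to one decimal. Island size bins are 100 bp wide from 200 bp
with an open top bin at 1 kb, each bin normalised across components
(component assignment precedence promoter > 5′UTR > 3′UTR > exon >
intron > intergenic). A peak overlapping several repeat families is
split 1/n to each so family percentages form a partition summing to 100.

## Differential methylation

Coverage is unique-read counts per gene × region (a read overlapping two
regions of a gene counts once in each); "coverage" as read counts rather
than peak counts is used because the reported regions are finer than
peaks. The test behind "p < 0.01" is a two-sided Fisher exact test on
the 2×2 table (count, library − count) for the two samples — the
standard choice for pooled single-library count comparisons without
replicates. Fold change uses counts-per-million with a 0.5 pseudocount
so zero-count regions remain comparable; a call requires fold ≥ 2 in
either direction *and* p < 0.01 on the raw p (BH q-values are reported
in the output for transparency but do not gate calls, mirroring how such
thresholds are conventionally applied). Direction `up` means greater
normalised coverage in the second sample of the contrast. Swapping the
samples provably flips every direction and nothing else. Note that very
low-coverage regions (e.g. short UTRs) can clear both gates on a handful
of reads; planted-truth evaluations therefore score on the gene-body
region, where counts are large.

## Enrichment

Hypergeometric upper tail per term, optionally in the conservative EASE
variant (one study hit removed before the tail, so EASE p ≥ plain p
always), BH-adjusted within a namespace, filtered at p < 0.005 and
adjusted p < 0.05. The adjustment is Benjamini–Hochberg (labelled as
such in outputs). No ontology content is bundled; maps are two-column
TSV inputs, and the default background is the set of genes carrying at
least one peak in any sample.

## Bisulfite validation

Conversion is modelled exactly: every cytosine outside a protected CpG
becomes thymine; the operation is idempotent on its own output. Clones
are globally aligned (match +1, mismatch −1, gap −2) to the reference
with all non-CpG cytosines pre-converted; the clone base at each
reference CpG gives the call (C methylated, T unmethylated, gap/other
NA). C/T status at CpG sites is excluded from the 90 % identity gate so
methylation state cannot reject a clone. Simulated clones draw each
site independently, with conversion-failure and
inappropriate-conversion rates both defaulting to 0.01. Concordance is
the qualitative agreement the validation experiments report: peak
presence should coincide with mean clone methylation above the low
threshold (0.2). One published amplicon (PM3) has a start coordinate
inconsistent with its printed product length; it is kept verbatim,
flagged, and excluded from coordinate-to-length checks.

## Synthetic data

The generator emulates the study design end to end with four sample
groups (WRR_h, WRR_l, XH_h, XH_l) and writes every truth table needed to
score downstream modules. Defaults: a 0.8 Mb two-chromosome genome at
40 % GC with ~80 % of background CpG dinucleotides broken (vertebrate
genomes are CpG-depleted; without depletion island boundaries have no
contrast), 30 planted islands of 250–800 bp built from a CpG-rich
process that passes all three island criteria in every window (so the
planted truth is unambiguous), 40 non-overlapping genes with 2–8 exons,
repeat families at coverage fractions led by LINE/CR1 (the dominant
chicken repeat), and 100,000 single-end 50 bp reads per sample — a
desk-scale stand-in for the tens of millions in a real library, chosen
so peak and differential statistics have comfortable counts while the
whole pipeline runs in seconds.

MeDIP enrichment is the simplest monotone surrogate: a fragment
(uniform 100–500 bp, the sonication range) is sampled with probability
proportional to α + β · (summed methylation level over the CpG sites it
covers), α = 1, β = 5, via vectorised rejection sampling; the read is
the fragment's 5′ 50 bp. Methylated domains are shared across samples
and placed clear of gene bodies and islands, so the only between-sample
differences are the planted gene-body levels: null genes sit at level
0.5 everywhere, planted genes at 0.2 vs 0.8 (a 4-fold change; the
additive α compresses the realised coverage ratio slightly below 4,
which the fold ≥ 2 gate absorbs). Because enrichment weights are
additive in α, expected fold changes are exact only in the β-dominated
regime — one reason the generator plants levels well inside [0,1].

What the generator does **not** model: sequencing error, adapter
contamination, mappability variation, paired-end fragment inference,
duplicate artefacts, copy-number variation, or antibody efficiency
differences between samples. Passing tests therefore demonstrate the
pipeline's logic and statistics under a faithful enrichment model, not
robustness to every artefact of real libraries.

## Determinism and problem sizes

Every stochastic step takes a `numpy` Generator seeded from the config;
identical configs give byte-identical outputs (the run manifest records
SHA-256 checksums). The verification suites use 5 kb mosaics × 50 seeds
for the scanner, 1 Mb × 10,000 reads × 20 seeds for the caller, and
300 kb × 20 genes × 2×40,000 reads × 10 seeds for differential calling —
sizes at which every targeted effect is detectable with wide margins
while a full run of the suite stays within a few minutes.
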