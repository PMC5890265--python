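# Methods

This note documents the models, estimators and design choices behind
`temeth`, what the synthetic data do and do not emulate, and the numerical
conventions a user should know before pointing the tools at real data.

## The truth methylome model

Each reference cytosine *i* (both strands, independently by default)
receives a true methylation probability

p_i ~ Beta(κ·m, κ·(1−m)),

where m is the context target — `cg_level` (default 0.70) at CG sites,
`ch_level` (default 0.01) at CH sites — and κ (`heterogeneity`, default 2)
is the Beta concentration. Small κ disperses sites toward 0 and 1; large κ
concentrates them at m. Sequencing a site then draws one Bernoulli(p_i) per
read (per molecule), so p_i plays the role of the fraction of cells
methylated at that site: the model is a per-site, per-cell Beta-Bernoulli
mixture. κ = 2 is a free choice — no quantitative cell-heterogeneity
parameterisation is established for these methylomes — and it reproduces
the qualitative picture: a unimodal site-level distribution, most sites
above 0.2, a small fully-unmethylated tail, and many but not all reads
fully methylated. The expected fully-unmethylated fraction at coverage n is
E[((1−p)(1−ε))ⁿ] (ε the non-conversion rate), which the test suite checks
against the observed fraction; at 30× genome coverage a strand-specific
record carries ~15 informative reads, giving ≈1.4% at κ = 2.

CH methylation on transposons is multiplied by `ch_te_3prime_bias`
(default 5) over the 3'-most `ch_te_tail_fraction` (default 0.25) of each
element, with the Beta mean capped at 1 — the planted analogue of
3'-biased CH methylation on elements. The spike-in contig
(`lambda_control`, 48,502 bp of random sequence standing in for the lambda
phage genome) is fully unmethylated.

The two strands of a CG dinucleotide draw p independently by default,
reflecting stochastic per-cell methylation gain rather than maintenance of
palindromic pairs; `symmetric_cg=True` copies the plus-strand draw onto the
paired minus-strand cytosine for contrast experiments. These two modes
bracket the observable: measured strand concordance is r ≈ 0 under
independence and r > 0.95 under symmetry at 30×.

## Bisulfite reads and the pileup convention

Reads are single-end, uniformly placed, emitted pre-aligned (mapping is out
of scope) and written as standard SAM so real mapped data can substitute.
On a top-strand read each plus-strand cytosine reads C with probability p_i
and T otherwise; every unmethylated outcome reverts to the methylated call
with probability `non_conversion` (default 0.005). Bottom-strand reads are
stored in forward orientation, so their cytosines sit at reference G
positions and read G (methylated) or A (converted). No indels, PCR
duplicates, paired ends or mappability bias are simulated; a uniform
substitution error is available (`seq_error`, default 0). Consequently,
passing tests demonstrate correctness of the accounting and estimators
under clean alignments — not robustness to mapping artefacts, which real
data retain.

The pileup counts, per reference cytosine and strand, methylated calls
(C on top-strand reads; G on bottom-strand reads) over informative calls
(C+T, G+A respectively); other bases are ignored. Reads flagged duplicate,
secondary, supplementary, unmapped, or with MAPQ < 10 are skipped.
`opposite_g_fraction` is the fraction of opposite-strand reads supporting
the paired guanine (in stored orientation: C for a plus-strand site, G for
a minus-strand site). The genotype filter removes records whose opposite
strand reaches `min_opposite_cov` (3) reads but supports the G at below
`min_opposite_g` (0.8) — such a site is treated as a C→T variant
masquerading as an unmethylated cytosine. The exact rule used by upstream
callers is not published; this one is a documented, configurable stand-in,
and on planted variants it removes 100% at 30× with no true sites lost.

Methylation levels are read-weighted everywhere (Σ mC / Σ calls).
`adjust_level` applies the closed-form non-conversion correction
max(0, (ℓ − ε)/(1 − ε)).

## DMRs

Differential methylation is assessed per CG dinucleotide (strands pooled)
by Fisher's exact test on the 2×2 methylated/unmethylated table; candidate
sites (p < 0.01, consistent direction) are merged when separated by at most
`max_gap` = 300 bp, and a region is reported when it spans ≥ 5 CGs, the
pooled level difference reaches 0.2, and mean site coverage in both samples
reaches `min_cov` (default 4). The region p combines per-site p-values by
directional Stouffer. The delta/min-CG/p defaults follow the established
analysis practice for such comparisons; the merge gap and coverage filter
are this package's choices, exposed as parameters. Two properties matter in
interpretation: (i) on same-truth null comparisons the procedure reports
zero regions at these defaults, and its region-level false-positive rate in
repeated scaled-down null simulations stays below the site threshold;
(ii) a single chance-significant site within `max_gap` of a true region
joins it, so recovered boundaries are accurate to a couple of CG sites,
occasionally one site more — boundary recovery is asserted with a ±2-site
tolerance at genomic CG spacing.

## Element structure

ORFs are maximal six-frame open reading frames (default ≥ 100 aa), starting
at the first ATG after the previous stop (or at the frame boundary with
`require_start=False`); the reported interval includes the stop codon.
Domain hits (HMMER domtblout or a 5-column TSV) attach to ORFs by target
id; overlapping envelopes resolve to the lower e-value, and the ordered
labels form the architecture string. The simulator's planted-domain bridge
plays the role of the profile-HMM search for synthetic elements.

TSDs are the longest exact flanking duplication with length in [4, 20]
(a mismatch-tolerant mode exists). Terminal repeats are found by exact
15-mer self-seeding on shared diagonals with ungapped extension tolerating
short mismatch runs; boundaries are pinned on a clean block of 8 matching
columns, so at zero divergence the planted coordinates are recovered
exactly (a chance 8-mer match beyond a true edge, probability 4⁻⁸ per
position, is the residual failure mode). One repeat family spanning both
termini is the LTR arrangement `A...A`; two interleaved families ordered
A, coding, B, A, B is the DIRS arrangement. Classification: DIRS
arrangement → DIRS; single terminal pair → LTR; reverse transcriptase
(RVT_1) plus a TSD and no terminal repeats → LINE; otherwise unclassified.
The `-DNMT` suffix requires the DNA_methylase domain in an ORF upstream of
the RVT ORF (LINE) or sharing the RVT ORF (DIRS/LTR). A polyA tail
(≥ 8 A's within 30 bp of the 3' end) is recorded but never required — the
LINE families modelled here lack one.

CpG depletion uses O/E = f(CG)/(((f(C)+f(G))/2)²) with frequencies over
non-N bases (f(CG) over valid adjacent pairs). The printed raw-count form
of this ratio is not dimensionless, so the frequency normalisation is the
default; a `literal` mode applies the raw-count formula for exact
reproduction. N-containing pairs are excluded; the ratio is invariant under
reverse complement. Family comparisons use the one-sided Wilcoxon rank-sum
test (depleted < control) at α = 0.01.

## Element evolution

Pairwise identity in internal mode is 1 − d/max(|a|,|b|), with d the
unit-cost global (Levenshtein) alignment distance. This convention is
independent of which co-optimal alignment is traced — "matches over aligned
columns" is not, since co-optimal alignments can differ in match count —
and reproduces the intuitive hand values (MKV vs MKL = 2/3). Hit-table mode
uses the table's own identity field, symmetrised by maximum, self-hits
excluded. Components of the thresholded network (0.8 within genomes, 0.6
across species) are subfamilies; raising the threshold can only split
components, never merge them.

Dollo parsimony places each subfamily's single gain at the MRCA of its
present tips and counts one loss per maximal absent subtree below the gain;
this is provably the minimum-event single-gain reconstruction, and the test
suite verifies it against exhaustive enumeration on 4- and 6-tip trees.
Reconstructed losses can undercount the true history (a loss erasing an
entire clade is indistinguishable from a later gain), which is why the
simulator's truth satisfies inferred ≤ true losses — asserted, never
violated.

Ka/Ks is Nei–Gojobori (1986): per-codon synonymous site fractions
(mutations to stop codons count as nonsynonymous, so N + S = 3 × codons
exactly), observed differences averaged with equal weight over all minimal
mutational pathways excluding stop intermediates (falling back to all
pathways when none avoids a stop), Jukes–Cantor correction
K = −¾ ln(1 − 4p/3). pS ≥ 0.74 — the correction's domain boundary minus a
0.01 tolerance — sets the `saturated` flag and leaves Ks undefined, making
"saturated synonymous rates" an explicit, testable state. The ratio is
undefined when Ks is 0 or undefined. The estimator choice is this
package's; the uncorrected p-distances are exposed on the result object,
and a cross-method check against an independent R implementation (a
Li-family estimator) agrees to within the expected between-method spread.
The codon-pair simulator accepts synonymous proposals always and
nonsynonymous ones with probability ω, so estimated Ka/Ks tracks ω: with
the default transition bias the estimator reads ≈ 0.07/0.37/0.73 at
ω = 0.1/0.5/1.0 — monotone, and conservative near neutrality, which is the
safe direction for a purifying-selection screen at the 0.2 cutoff.

## Study conditions and problem sizes

The demo conditions (`temeth.experiments.demo_config`) are a 200 kb main
contig, 20 genes, four element families (a DNMT-bearing LINE with an 8-bp
TSD, a DNMT-bearing DIRS with 250-bp repeats, a plain Gypsy-like LTR
element, and an old LINE family with CpG deamination rate 0.5), mCG 0.70,
mCH 0.01 with 5× 3' bias, κ = 2, non-conversion 0.005, 30× coverage of
100-bp reads, and a 48.5-kb spike-in. Focused experiments (DMR recovery,
symmetry contrast, genotype filtering) use 60-kb genomes at the same
coverage; the Ka/Ks calibration uses 30 pairs of 150 codons per ω and the
test suite additionally runs 100 pairs of 300 codons at ω = 1. These sizes
give sampling errors an order of magnitude below the assertion tolerances
while keeping every analysis script and the full test suite in the
seconds-to-minutes range.

## Limitations

- The simulator omits paired-end structure, duplicates, indels, mapping
  bias and context-specific conversion failure; estimator robustness to
  those must be judged on real alignments.
- Repeat detection is exact-seed/ungapped: highly diverged (> ~15%) or
  indel-riddled terminal repeats will be missed; the upstream annotation of
  old element families should rely on dedicated repeat finders.
- The DMR procedure is a defined Fisher+merge+Stouffer construction, not a
  reimplementation of any smoothing-based package; parameters are exposed
  and results should be compared at the region level.
- Dollo parsimony assumes presence/absence is called correctly per genome;
  assembly gaps violate the single-gain logic in ways the model cannot see.
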