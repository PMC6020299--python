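# Methods

This note documents the models behind each analysis, the tunable parameters
and their defaults, what the synthetic generator does and does not emulate,
and the numerical choices a maintainer would want to know.

## Pseudogene classification

Every CDS is translated (minus-strand features reverse-complemented first;
translation stops at the first internal stop codon, keeping the prefix) and
searched against a reference proteome. The comparison primitive is an
affine-gap Gotoh dynamic program (numba-compiled) in local
(Smith–Waterman) or global mode; a gap of length L costs
`gap_open + gap_extend·L` (defaults 11/1, BLOSUM62, the BLASTP
convention). Any residue pair involving X scores 0. Ties are broken
deterministically: diagonal > up > left within the DP, smallest end cell in
local mode, lexicographically smaller subject id between equal-scoring
subjects.

The classification rule: a locus is a possible **pseudogene** when
`query_length / subject_length < θ_len = 0.60` or
`positives / aligned_columns < θ_sim = 0.30`, both strict inequalities, for
the best-scoring hit. Both lengths are full protein lengths, not aligned
spans — truncation is exactly what the length clause is meant to measure,
and reference hit lengths are conventionally reported full-length.
"Similarity" is the BLAST positives convention: aligned columns whose
substitution score is positive. A best hit below a raw-score floor of 50
yields **orphan**, not pseudogene: the rule needs a hit to compare against.

For references larger than 50 proteins, full dynamic programming runs only
on the 25 candidates sharing the most 4-mers with the query (an inverted
k-mer index, BLAST-like seeding). Exactness tests use small references
searched exhaustively; the seeded search is a documented heuristic, like
every seeded homology search.

Note one behavioral consequence of the rule: because local alignments are
positive-scoring by construction, the similarity clause rarely fires; the
length clause does nearly all the work. A spurious low-scoring local hit
above the score floor can therefore classify an unrelated protein as
"functional". This mirrors the rule as stated; the score floor is the only
guard, and both thresholds are configurable.

## Intra-sample diversity

Input is a bespoke 8-column pileup TSV (`contig, pos, ref, depth, A, C, G,
T`) rather than SAM/BAM: the analysis needs only per-site base counts, and
the invariant `depth = A+C+G+T` is enforced on read. Per site, only the
single majority alternate base is scored (ties broken A<C<G<T);
`alt_freq = alt_count / depth` with the site's own depth as denominator.
Classes: error-like (`alt_freq < f_err = 5·10⁻⁴`), polymorphic
(`> f_poly = 10⁻²`), intermediate between; the polymorphism rate divides by
total genome length, with the callable-length variant available by passing
a different denominator.

**Known limitation, implemented literally:** at any depth below 2,000× a
single alternate read already exceeds the 0.05 % threshold, so
`frac_error_like` is near zero on realistic data even when essentially all
alternates are sequencing errors — at depth 10⁴ with a 10⁻³ error rate the
majority-alternate count is the max of three ~Poisson(3.3) draws and
exceeds the threshold on most sites (expected error-like fraction ≈ 0.4,
computed by direct simulation in the tests). The thresholds are kept at
their stated defaults rather than recalibrated; the spectrum itself (which
shows the error mass concentrated at low frequency regardless) is the
robust summary.

## Molecular clock fitting

Likelihoods use Felsenstein pruning with site-pattern compression and
per-pattern log scaling. Reversible models are built as
`Q = S·diag(π)` rescaled to one expected substitution per site, with
transition probabilities from the symmetric eigendecomposition
`diag(π)^{1/2} Q diag(π)^{−1/2}` (always real). Discrete-gamma rate
heterogeneity uses K equal-probability categories with category means
computed from the incomplete-gamma identity; category likelihoods are
combined by logsumexp. Amino-acid models load from PAML-dialect
rate-matrix files; a Poisson (equal-rates) model ships built in.
Substitution parameters (exchangeabilities, frequencies — the latter
available empirically via `empirical_frequencies`) are fixed across both
clock fits, so the models differ by the rate multiplier alone and df = 1;
free joint estimation of exchangeabilities is out of scope.

Clock models operate on a fixed rooted binary topology. Node heights are
measured in expected substitutions per site: without fossil or time
calibrations only the product of rate and time is identifiable, so the
background rate is fixed at 1 and reported as such. The null model is a
strict global clock (heights only: n−1 free parameters for n taxa); the
alternative adds exactly one rate multiplier r ≥ 10⁻³ applied to every
branch of a designated monophyletic foreground clade *including its stem*
(the stem carries most of the separation signal; a flag excludes it).
df = 1 by construction.

Optimization is a single quasi-Newton (L-BFGS-B) run over a transformed
parameterization — log root height, logit of each internal node's
height-fraction of its parent, log r — with bounds keeping heights in
[10⁻⁶, 50] substitutions. The alternative fit starts from the null optimum
(so nesting `lnL_A ≥ lnL_0` holds structurally; a violation beyond 10⁻⁴
raises) plus one accelerated start at r = 2.5. This replaces per-parameter
coordinate sweeps: with ~n parameters the joint fit converges in a few
hundred likelihood evaluations and needs no random restarts.

Two identifiability caveats are detected and logged: (i) a foreground set
covering all taxa makes r a pure rescaling of the heights; (ii) a
foreground clade that is a child of the root is absorbed by the root height
(no background path crosses the root — the pulley principle), so the test
has no power there. Simulation utilities avoid root-child clades.

`lrt` floors LR at 0 and uses the χ² upper tail. For published model
tables, `lrt_from_neg_lnl` reproduces the arithmetic from printed −lnL
values taken as inputs.

## TE census and burst detection

Family assignment aligns each proteome entry against one representative per
IS family and assigns the best-scoring family when identity ≥ 0.3 over
aligned columns and aligned subject coverage ≥ 0.3 of the family's full
length (common IS-annotation practice; both configurable). When censusing a
genome directly, CDS translation uses stop-readthrough (internal stops
become X) because decayed transposase fragments are full of nonsense
substitutions but family assignment wants the full conceptual translation.

Terminal inverted repeats are sought in ±`window` (default 100 bp) regions
around each element boundary: the longest pair (u, reverse-complement
match) with ≤ 2 mismatches and length ≥ 10, by exhaustive numba-compiled
scan. With these defaults, windows of random sequence produce occasional
spurious ≥10 bp pairs (expected a handful per element at window 100); the
completeness call — complete iff aligned fraction ≥ 0.9 **and** IRs present
— is therefore conservative on truncation but permissive on IR presence.
Completeness accuracy is asserted on clean constructions; the burst and
family statistics do not depend on it.

Within-family trees are built by neighbor joining on Poisson-corrected
distances `d = −ln(1−p)` (p = mismatch fraction over aligned columns of a
global alignment; saturated pairs capped at 10). NJ rather than ML: the
burst statistic needs branch-length geometry, not support values, and NJ is
exact on additive matrices (property-tested). Negative NJ branch lengths
are clamped to zero with the deficit moved to the sister branch.

The burst test roots the copies+outgroup tree at an outgroup leaf and finds
maximal copy-only clades. Verdicts: `single_expansion` when the copies are
monophyletic and stem/mean-crown-depth ≥ 3.0; `multiple_expansions` when
≥ 2 maximal copy clades each clear that ratio; otherwise `no_expansion`.
The 3.0 default keeps uniform-rate (no-burst) arrangements below the
threshold with comfortable margin in simulation while the star-on-a-stem
geometry of a genuine expansion sits well above it.

## Reduction metrics

Orthologs are reciprocal best hits by protein alignment score between
functional CDS sets. Nucleotide identity is computed by back-mapping the
protein alignment to codons (3 nt per aligned residue pair), and ANI is the
length-weighted mean (unweighted available). For exact A/B symmetry each
RBH pair is re-aligned in lexicographic gene-id order, removing path-tie
ambiguity. Percent reduction is `100(1 − target/reference)`, reported
negative if the target exceeds the reference. Category counts allow
multi-category genes (each tag counts once); pathway completeness requires
every enzyme label of a pathway to match a *functional* gene product —
pseudogenized enzymes do not count. Pathway and category fixtures are
editable TSVs; the bundled ones are synthetic emulations.

## Synthetic data generator

`simulate_ancestor` builds a single-contig genome of intact ORFs
(ATG…stop, no internal stops) with configurable GC, gene length
(default mean 900 nt), and intergenic spacing (default 150 nt); category
tags are assigned in contiguous operon-like runs so that protected category
blocks form contiguous genomic intervals.

`degrade_genome` applies, per gene and independently: deletion (sequence
removed — deletional bias shrinks the genome), pseudogenization (the gene
keeps a recorded 5′ fraction drawn from `truncation_range`, default
0.1–0.5), or retention. Genes in protected categories are exempt from all
three fates and from insertions — modeling purifying selection on essential
clusters, which is what makes them recoverable as insertion-free regions.
A configurable fraction (default 0.5) of pseudogenizations are attributed
to TE insertion: the copy lands immediately downstream of the truncation
point. TE bursts insert copies of an IR + transposase-ORF + IR element
(4 nt target-site duplication) into length-weighted random unprotected
intergenic positions; each copy independently decays by point substitutions
(default rate 0.05/site) and possible end-truncation (probability 0.4,
keeping 30–80 %). The annotated CDS covers only the frame-aligned surviving
ORF, as real annotation would. Ground truth (fates, truncation points,
per-copy decay, completeness, coordinates) is recorded in a JSON-ready
TruthRecord keyed by the run's single RNG seed.

Sequence evolution on trees samples i.i.d. sites from the reversible model
down a rooted tree, with foreground branches (clade + stem) multiplied by
r. Pileups draw per-site depth ~ Poisson, per-alternate error counts
~ Binomial(depth, error/3), and planted polymorphic sites add
Binomial(depth, freq) of a stated alternate.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: paralogy and horizontal transfer (pseudogene
precision on real genomes depends on the reference's paralog structure),
frameshift-only pseudogenes (degradation here is truncation-based, matching
the length-ratio rule), composite or nested transposons, recombination,
codon-usage selection, alignment/assembly error, and real indel processes
in reads. The IS reference shipped is synthetic; real censuses should use
ISfinder representatives.

## Problem sizes and defaults in the demonstration

The end-to-end demonstration (`demo_synthetic`, also driven by
`scripts/acceptance.py`) uses 1,000 ancestral genes (~1 Mb), 30 %
pseudogenization with truncations below half length, 15 % deletion, one
IS5-like burst of 200 decayed copies, two protected ~25 kb clusters, a
10-taxon tree of height 0.15 substitutions with a 2–4 taxon foreground
clade at r = 3.5 (6 kb HKY alignments; 20 replicates for recovery, 200 for
the null calibration), and a 100 kb pileup at depth 1,000 with a 10⁻³
error floor and 160 polymorphic sites at frequency 0.05 (1.6/kb). Outgroup
transposases for the burst test are placed at 55 % divergence via a shared
outgroup ancestor — cross-genus transposase orthologs typically show
40–60 % identity, and this reproduces the long-stem/short-crown geometry a
recent within-genome expansion displays.

## Numerical choices

* Branch/height lower bounds 10⁻⁶–10⁻⁹ keep matrix exponentials
  well-conditioned; transition matrices are clipped to [0,1] and
  row-renormalized after eigen-reconstruction.
* Site-pattern compression is exact (unique columns with weights); pattern
  likelihoods are scaled per internal node by their maximum with the log
  accumulated separately.
* Degenerate inputs: empty pileups return empty tables (not errors);
  `classify_sites` on no nonzero-alternate sites reports a null fraction;
  identical sequences drive clock heights to the lower bound with the
  closed-form likelihood Σ log π; zero-length local alignments report empty
  spans.
* All generators take explicit integer seeds and are bit-reproducible;
  pipeline reports embed a config hash.
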