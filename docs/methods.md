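# Methods

This note documents the models, numerical choices, and limitations behind
`utrkit`, in the order data flows through the toolkit.

## Coordinate conventions

All internal intervals are 0-based half-open; GTF I/O converts at the
boundary (1-based closed on disk), BED and coverage tables are native
0-based. A cleavage site (CS) is the genomic coordinate of the last
transcribed nucleotide, strand-aware. Window intersections ("40 nt windows
centered on 3′ ends") compare center-to-center distances, so a window of 40
means |Δ| ≤ 20; opposite-strand features never match. Keeping one convention
everywhere, with conversion confined to `io`, is what makes the off-by-one
surface testable.

## Cleavage-site atlas

**Peak calling.** Per cell type, single-nucleotide coverage of read 5′ ends
is merged greedily to local modes: the highest-count position absorbs all
positions within a 30 nt radius, and the process repeats on the remainder.
Ties in count break toward the 5′-most (smallest) coordinate — an arbitrary
but deterministic rule. Modes are kept only when support is strictly greater
than 5 reads per million; the RPM denominator defaults to the per-cell-type
coverage total (supplying a library size is supported). A brute-force
restatement of the same rule serves as the test oracle; the two
implementations agree on tens of thousands of random inputs, and the
greedy structure guarantees retained peaks are pairwise more than one
radius apart.

**Harmonization.** Per-cell-type peaks are pooled, counts summed at
identical positions, and re-merged with the same rule. A harmonized site
records how many cell types contributed reads, which later feeds the usage
score.

**Classification.** A candidate within ±20 nt of an annotated transcript
end (transcripts with unvalidated 3′ ends excluded) is *validated*; failing
that, within ±20 nt of an external poly(A)-site cluster of ≥ 3 TPM it is
*supported*; failing that it is *likely* if it passes the internal-priming
filter, else *discarded*. The retained novel atlas is the supported ∪ likely
union; validated sites already exist in the annotation and are tracked
separately.

**Internal-priming filter.** Oligo(dT) mispriming at genomic A stretches
produces spurious 3′ ends. We use a transparent sequence heuristic instead
of a trained classifier: a site fails when the 20 nt downstream window
(transcript orientation; truncated at contig ends) has A-fraction ≥ 0.65 or
any run of ≥ 8 consecutive A. Both thresholds are configurable. This is a
deliberate design choice — deterministic, dependency-free, and directly
testable — and it will not reproduce the exact site set of probabilistic
classifiers on real genomes; borderline A-rich but genuine sites are the
known casualty.

**Region labels.** Each site takes the highest-precedence label over all
same-strand overlapping transcripts: three_prime_UTR > five_prime_UTR >
exon > intron > extended_five_prime_UTR > extended_three_prime_UTR >
intergenic, with 5′ ends extended 1 kb upstream and 3′ ends 5 kb downstream.
The 3′UTR test uses the annotated stop-codon position where available.

**Usage score.** score = |cell types using the site| / |cell types
expressing the gene|. "Using" means the site survived per-cell-type peak
calling; "expressing" means ≥ 1 UMI in that cell type's pseudobulk — neither
is defined more precisely upstream, so these operational definitions are
ours. A site used in fewer than 10 expressing cell types is *minor* (count
rule, the default); a documented switch (`minor_rule="fraction"`) instead
calls a site minor below a 10% usage score, since both formulations are in
circulation. A gene expressed in zero cell types has no defined score and
raises.

**Motif densities.** IUPAC motifs are scanned (overlapping matches counted)
in strand-oriented windows around each CS; occurrence centers (k-mer start +
(k−1)//2) are pooled into a histogram scaled so the global mode is 1.

## Truncated UTRome

Novel three_prime_UTR sites interior to a transcript's 3′UTR generate
*upstream* isoforms truncated at the site; extended_three_prime_UTR sites
within 5 kb generate *downstream* isoforms whose last exon is extended.
Sites labeled three_prime_UTR but landing 5′ of a transcript's stop codon
are rejected and reported. All isoforms are then clipped to their 3′-most
500 spliced nucleotides (exon structure intersected by a spliced-coordinate
walk; the 3′ end itself is preserved exactly, so the truncated sequence is
always a suffix of the original).

**Deduplication.** Within a gene, isoforms whose 3′ ends are < 50 nt apart
(chained transitively — for 1-D points, adjacent chaining equals the full
transitive closure) collapse to one representative: the most 3′ end, with
downstream-sourced isoforms outranking annotation-derived ones at the same
position, carrying the lexicographically smallest transcript id of the
chain. We interpret "< 50 nt difference" as 3′-end genomic distance: the
truncated bodies are suffixes, so end distance determines sequence
difference, and the stricter reading (identical after truncation) is the
distance-0 special case of the same code path.

**Merge table.** Each isoform maps to the most 3′ same-gene isoform < 200 nt
away; raw pointers are resolved to a fixed point so chains (0/150/300 nt)
collapse onto the distal member. Fixed-point resolution is a deviation from
recording only the immediate downstream neighbor: counting requires a single
representative per group, and pointers strictly increase 3′-ward so
resolution terminates. Applying the table to a count matrix conserves total
counts exactly (columns are added, never dropped).

**IPA flags.** An isoform is flagged intronic-polyadenylation (IPA) when its
3′ end falls inside an annotated intron of its gene; IPA isoforms are
excluded from 3′UTR-fraction computations and drive the IPA gene class.

## Read assignment, EM, and the resolution simulation

A read is compatible with a truncated isoform when its 3′-end position lies
inside the isoform's truncated body. Reads are deduplicated on (barcode,
UMI, gene). Unique reads count directly; multi-compatible reads whose
isoforms share a merge-table representative count to that representative;
the rest form equivalence classes resolved by EM on a categorical mixture
with uniform within-class likelihood. No effective-length weighting is
applied: 3′-tag coverage concentrates at the 3′ end and violates the
uniform-coverage assumption that weighting encodes. EM iterates to a max
abundance change < 1e−8 (cap 1000 iterations), asserts a non-decreasing
log-likelihood at every step, and flags non-identifiable class structures
(membership matrix rank < number of covered isoforms), returning the uniform
fixed point in that case. An independent coarse-to-fine grid search over the
simplex (2–3 isoforms) is the cross-check oracle.

The two-isoform resolution simulation draws read distances from a
discretized gamma with mean 300 nt and sd 100 nt — shape (300/100)² = 9,
scale 100/3, rounded to the nearest integer and floored at the 100 nt read
length so a read never ends downstream of the CS (the discretization detail
is our choice; only mean and sd are externally fixed). Proximal and distal
isoforms truncated to the test length are quantified by assignment + EM
with no merge table (the merge rule is the *output* of this calibration,
not an input), and relative errors are computed on abundance fractions, so
reads falling outside both truncated bodies (the gamma tail beyond the
truncation) drop out of numerator and denominator symmetrically. The
standard sweep covers CS distances 50–700 nt (step 50), truncations 350–600
(step 50), proximal/distal counts {50, 100}, 10 replicates per cell; at
50 nt separation mean |relative error| exceeds 0.4, and from 500 nt on it
sits below 0.02, which is why counts within 200 nt are merged to the distal
site. The "resolved" flag helper takes an explicit tolerance (default 0.05)
rather than hard-coding a distance.

## Bootstrap statistics

Isoform columns must be ordered 5′→3′ within each gene; positional weights
are wᵢ = (i−1)/(n−1). All statistics are computed on pseudobulk — counts
summed over the cells of a (re)sampled group — not on per-cell averages,
matching how the confidence intervals are defined. The two-sample test
resamples cells with replacement from the union of both groups into
pseudo-groups of the original sizes; one seeded generator drives a single
set of bootstrap cell indices shared by all genes (vectorized as a
resampling-matrix product, which is also the statistically correct
cell-level resampling). Two-sided means "as extreme" on absolute values of
the difference statistic. The p-value carries a pseudocount of 1 in
numerator and denominator, so p ≥ 1/(B_valid+1) and never 0; bootstrap
samples with fewer than `min_cells_per_gene` (default 50) expressing cells
in either pseudo-group are discarded per gene, the retained count is
reported, and a gene with zero valid bootstraps gets NA rather than being
dropped silently. Genes whose *observed* groups fail the minimum are not
tested at all. TPM throughout means UMIs per million total UMIs — no length
normalization, as UMI counts are already end-tagged molecule counts.

Calibration under the generator's own conditions (1000 two-isoform null
genes, 200 cells per group, multinomial counts around a 0.5 WUI, 1000
bootstraps): type-I error at α = 0.05 lands in [0.03, 0.07], and a planted
dWUI of 0.3 is detected at q < 0.05 with power > 0.9. Percentile confidence
intervals use 2000 resamples; per-cell TPM is averaged for the TPM CI and
pseudobulk WUI recomputed for the WUI CI.

## Cell-type analyses

A *qualifying* isoform is a last-exon (non-IPA) isoform reaching ≥ 10%
(inclusive) of a gene's 3′UTR counts in at least one cell-type pseudobulk;
genes with ≥ 2 qualifying isoforms are multi-UTR. Count fractions are used
(identical to TPM fractions under per-million scaling). IPA genes are those
whose IPA isoforms reach 10% of all gene 3′-end reads in some cell type.
Dominant-isoform switching is evaluated in cell types with ≥ 200 cells and
gene expression > 5 TPM; argmax ties resolve to the more 3′ isoform,
deterministically.

DGE uses a Welch t-test on per-cell log2(normalized + 1) gene counts, with
per-cell library-size factors scaled to mean 1 as the default normalization
(a hook accepts externally computed factors, e.g. pooling-based ones; the
substitution is intentional — library-size factors are transparent and
adequate for synthetic data without composition effects). Fold changes are
de-logged group-mean differences; significance requires |FC| > 1.5 in
either direction and BH q < 0.05. The DGE × DUL independence test tabulates
coexpressed multi-UTR genes into a 2×2 significance table; the
Yates-corrected chi-square is reported as the 2×2 default alongside the
uncorrected statistic. Null calibration uses the uncorrected p-value, since
continuity correction is conservative by construction. The lower-abundance
isoform analysis is restricted to two-UTR genes, excludes exact abundance
ties, and reports the fraction of significant genes whose larger |log2FC|
falls on the less abundant isoform.

## Perturbation screens

dWUI(pert, gene) = WUI_pert − baseline, with the baseline a cell-count-
weighted mean over non-targeting perturbations; perturbations need ≥ 30
cells. Per-perturbation average dWUI (and dIPA, computed identically on IPA
fractions) averages over genes with control TPM > 5 and baseline value in
[0.1, 0.9] — a global statistic that cancels out bidirectional changes by
design. For clustering, genes are additionally filtered (≤ 20% non-detecting
cells where that information exists, control TPM ≥ 20), missing effects are
imputed as exactly 0 (identical to baseline), and each perturbation row is
divided by its uncentered standard deviation (root mean square): the center
is already pinned by the non-targeting baseline, so variance about zero is
scaled to 1. Zero-variance rows stay zero and are flagged.

Clustering rounds run PCA (at most min(n−1, dims) components, full SVD for
determinism) → unweighted kNN graph → walktrap communities (4-step walks,
modularity-optimal cut). The kNN graph uses union symmetrization by default;
mutual-neighbor symmetrization is available but can isolate vertices on
small inputs, so the union is the safer default and the choice is exposed.
Rounds alternate axes (perturbations with k = 5, genes with k = 4, both with
k = 3). "Patternless" cluster removal in the early rounds — a visual
judgment upstream — is operationalized as dropping clusters whose mean
|zdWUI| falls below a configurable quantile (default: bottom quartile) of
cluster dispersions; we make no claim that this proxy reproduces any
particular retained-set size. On planted three-module matrices (60
perturbations × 300 genes, unit signal, noise sd 0.3) recovery is exact
(ARI 1.0).

Cluster tests are two-sided Mann-Whitney per gene (perturbations as
replicates, non-targeting as reference; exact enumeration at small n, e.g.
U = 0 with n = m = 3 gives p = 0.1), BH per cluster; DGE analogously on TPM
with |FC| > 1.5. Compensation classification (two-isoform genes only)
splits gene TPM by WUI into short/long-UTR isoform TPMs, takes cluster-vs-
control differences, and calls the change *coordinated* when
−2 ≤ dTPM_LU/dTPM_SU ≤ −0.5 with inclusive bounds; otherwise the isoform
with the larger |dTPM| names the category (ties at exactly equal |dTPM| go
to SU, a measure-zero case). Both-zero changes are uncategorized. The
construction is symmetric: swapping isoform roles maps SU-specific ↔
LU-specific exactly.

Overlap between cluster target sets is a one-sided hypergeometric
(enrichment) tail; the universe defaults to the genes tested in both
clusters. Replicate validation correlates replicate effect vectors with the
cluster-average profile on that cluster's significant response genes and
compares against correlations of non-targeting profiles by one-sided
Mann-Whitney (alternative: replicates correlate higher), BH across
clusters. Feature correlations are Pearson per (cluster, feature) over
genes with control TPM > 5, BH within feature.

**Half-life fitting.** Mean conversion rates per timepoint (0/120/240/360
min; read-count-weighted over replicates) are fit to c(t) = c_max(1 −
e^(−kt)) by nonlinear least squares with c_max free, initialized just above
the maximum observed rate; half-life = ln 2/k. The upstream model family is
unspecified beyond "first-order kinetics", so the saturating form with a
fitted plateau is our interpretation. Non-increasing conversion profiles
and curves saturating before the second timepoint are flagged unreliable;
all-zero conversion returns an infinite half-life flag. Noiseless curves
invert exactly (k = 0.005/min → 138.63 min).

## Synthetic data generation

The fixture generator is the study-condition definition for every
stochastic test. Per cell and gene, total UMIs are Poisson around a mean
expression level (default 20 UMIs/cell for statistics fixtures — a
realistically deep 3′-tag gene); the isoform split is multinomial around
target fractions derived from a planted WUI (mass interpolated between the
two bracketing positional ranks so the pseudobulk WUI hits the target
exactly in expectation), optionally Dirichlet-overdispersed to mimic
cell-to-cell usage variability. Calibration tests use pure multinomial
counts (overdispersion 0): the bootstrap's null is exchangeability of
cells, which overdispersion does not break, but the clean case is the
sharper check of the resampling arithmetic. The toy annotation generator
produces single-exon multi-isoform genes with ends spaced a fixed distance
apart on alternating strands over a random genome.

What the generator does *not* emulate: ambient RNA, doublets, UMI
collisions and sequencing errors, gene-length or GC biases, correlated
isoform usage across genes, and batch structure. Passing tests therefore
demonstrate the correctness and calibration of the algorithms under their
stated models, not robustness to every artifact of real libraries.

## Problem sizes

Test-suite and acceptance-script simulations use desk-scale sizes chosen to
give tight Monte-Carlo bands while keeping runs fast: 1000 genes × 400
cells × 1000 bootstraps for calibration, 10 replicates per resolution-sweep
cell, 200 random layouts and 10,000 peak-calling cases for oracle checks,
60 × 300 effect matrices for cluster recovery. These are the package's own
standard conditions; headline numbers from production-scale atlases
(hundreds of cell types, thousands of perturbations) are outside what toy
data can reproduce.

## Known limitations

- The internal-priming heuristic is not a trained classifier; threshold
  choices are conventional, not fitted.
- Read assignment is exact-coordinate; no alignment uncertainty, soft
  clipping, or UMI error correction is modeled.
- The dispersion-quantile proxy for "patternless" clusters is a stand-in
  for a visual judgment and is configurable for exactly that reason.
- `cluster_diff_tests` loops genes × clusters in Python; it is meant for
  toy-scale matrices, not genome-wide screens.
- Barcodes are namespaced by sample when merging datasets; cross-sample
  barcode collisions are otherwise undefined upstream.
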