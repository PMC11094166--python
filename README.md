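# utrkit

Most genes produce mRNA isoforms that differ only in 3′UTR length, set by
which cleavage-and-polyadenylation site (CS) terminates the transcript.
Standard scRNA-seq pipelines quantify how *much* of each gene is expressed
but not how *long* its transcripts are, even though 3′-tag protocols carry
that information. `utrkit` is a toolkit for recovering it: it builds
single-nucleotide CS atlases from 3′-end read coverage, derives a truncated
"UTRome" annotation suitable for 3′-end isoform quantification, and tests
for differential 3′UTR isoform usage across cell types and perturbations —
entirely on synthetic or toy-scale data, with every algorithmic step exposed
as a tested library function.

It is aimed at computational biologists who want the statistical machinery
of 3′UTR analysis (peak calling, annotation truncation, EM read assignment,
bootstrap usage tests, perturbation-effect clustering) as composable,
inspectable Python rather than a monolithic pipeline.

## What it computes

**CS atlas.** Per cell type, read 5′-end coverage is merged to local modes
within a 30 nt radius (highest count wins, ties break 5′-most) and retained
when support exceeds 5 reads per million. Cell-type peaks are pooled and
re-merged, then classified: *validated* (within ±20 nt of an annotated
transcript end), *supported* (within ±20 nt of an external poly(A)-site
cluster with ≥ 3 TPM), *likely* (passes an internal-priming filter on
downstream A-content: fails at A-fraction ≥ 0.65 or an ≥ 8-A run in the 20 nt
downstream window), or *discarded*. Each site gets an ordered region label
(3′UTR > 5′UTR > exon > intron > extended regions > intergenic, with 1 kb /
5 kb end extensions) and a usage score — the fraction of gene-expressing
cell types that use it; sites used in fewer than 10 cell types are *minor*.

**Truncated UTRome.** Annotated transcripts are augmented with novel-CS
isoforms (truncated at interior 3′UTR sites, or extended up to 5 kb to
downstream sites), clipped to their 3′-most 500 spliced nucleotides,
deduplicated when 3′ ends lie < 50 nt apart (keeping the distal end), and
summarized in a merge table that maps each isoform to the most 3′ isoform
< 200 nt away — the resolution limit established by the built-in two-isoform
simulation, in which reads end a gamma-distributed distance (mean 300 nt,
sd 100 nt) upstream of the CS and ambiguous reads are resolved by EM over
equivalence classes.

**Isoform usage statistics.** For a gene with isoforms ordered 5′→3′ and
expression fractions *f*, the weighted UTR index is

    WUI = Σᵢ wᵢ fᵢ,   wᵢ = (i − 1)/(n − 1)   (weights {0,1}, {0,½,1}, {0,⅓,⅔,1}, …)

so WUI = 0 when all counts sit on the shortest isoform and 1 on the longest;
for two-isoform genes it is the long-isoform fraction. The companion
statistics are UI (one flagged isoform's fraction difference) and WD (half
the L1 distance between fraction vectors, the earth-mover distance on the
isoform ladder); for two-isoform genes |UI| = WD = |ΔWUI| exactly.
Significance comes from a cell-resampling bootstrap under the null that two
cell groups are exchangeable: p = (1 + #{|T_b| ≥ |T_obs|}) / (1 + B_valid),
with bootstrap samples discarded for a gene unless both resampled groups
contain ≥ 50 expressing cells, and BH correction across genes. Differential
gene expression uses a Welch t-test on log2 size-factor-normalized counts
(significant at |FC| > 1.5, q < 0.05), and a chi-square test asks whether
DGE and differential 3′UTR length hit independent gene sets.

**Perturbation screens.** Per-perturbation dWUI effects relative to a
cell-count-weighted non-targeting baseline are z-scaled (rows divided by
their uncentered standard deviation, missing values imputed as 0), clustered
over multiple rounds of PCA → kNN graph → walktrap communities, and tested
per cluster with Mann-Whitney. Two-isoform genes with significant changes
are classified as short-UTR-specific, long-UTR-specific, or *coordinated*
when −2 ≤ dTPM_LU/dTPM_SU ≤ −0.5 (at least half the expression gained by one
isoform is lost by the other, where TPM_SU = TPM·(1−WUI), TPM_LU = TPM·WUI).
Cluster target overlap uses one-sided Fisher tests, replicate validation
uses Pearson correlations against non-targeting controls, and isoform
half-lives come from first-order kinetics c(t) = c_max(1 − e^(−kt)) fit to
metabolic-labeling conversion rates (half-life = ln 2 / k).

## Worked example

Plant a WUI shift of 0.35 in one of three two-isoform genes across two
groups of 300 cells, then test:

```python
from utrkit.synth import generate_fixture
from utrkit.bootstrap import two_sample_bootstrap_test

ccm, truth = generate_fixture(
    n_genes=3, isoforms_per_gene=2,
    groups={"HSC": {"n_cells": 300, "wui": [0.70, 0.50, 0.50], "mean_counts": 25.0},
            "Ery": {"n_cells": 300, "wui": [0.35, 0.50, 0.50], "mean_counts": 25.0}},
    seed=42)
res = two_sample_bootstrap_test(ccm, "HSC", "Ery", mode="wui",
                                n_boot=2000, min_cells_per_gene=50, seed=1)
print(res[["gene_id", "observed", "p", "q", "n_bootstraps_retained"]].to_string(index=False))
```

```
gene_id  observed        p        q  n_bootstraps_retained
  g0000  0.360299 0.000500 0.001499                   2000
  g0001 -0.003293 0.685157 0.685157                   2000
  g0002 -0.006385 0.448776 0.673163                   2000
```

The planted gene is recovered at the pseudocount floor p = 1/2001 ≈ 5·10⁻⁴
(bootstrap p-values are never zero); the two null genes are correctly
retained. The same machinery is available from the shell; for example, the
resolution simulation at 100 nt CS separation:

```
$ utrkit simulate --distance 100 --truncation 500 --reps 10 --seed 42 --out err.tsv
mean |relative error| proximal=0.5495 distal=0.2748
```

showing that two cleavage sites 100 nt apart cannot be reliably resolved —
the motivation for the 200 nt merge rule. Subcommands: `atlas`, `utrome`,
`quant`, `simulate`, `test`, `classify`, `diff`, `perturb`, `fixture`
(see `utrkit --help`).

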