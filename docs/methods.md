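# Methods

`enhdyn` analyses antibody-targeted chromatin profiling data (CUT&RUN/CUT&TAG
coverage tracks and per-peak fragment counts) across a two-state cell
transition — here called *naive* and *formative*, after the successive
pluripotent states of mouse embryonic stem cells — in wild-type (WT) cells and
cells lacking the MLL3/4 (KMT2C/KMT2D) methyltransferases (DKO).  Its purpose
is to classify enhancers by how their marks change during the transition and
by whether those marks depend on MLL3/4, and then to ask whether the chromatin
changes are coupled to transcription of nearby genes.

## Coordinates and formats

All interval arithmetic uses the BED convention: 0-based, half-open
`[start, end)`.  `to_one_based`/`from_one_based` convert at the boundary for
1-based tools, and the conversion is an identity round trip.  The package
reads and writes only plain text: BED3/BED6, 4-column bedGraph, and TSV tables
with a header row.  Signal values are written with six decimals, which round
trips CPM-scaled coverage losslessly at the package's precision.  Unknown
chromosome names are accepted; no genome dictionary is required.

## Peak calling

The caller is a sparse-enrichment design in the SEACR family.  The primitive
is the *signal block*: a maximal run of strictly positive, contiguous
coverage; its total signal (AUC = sum of value x width) is the test statistic.
In control mode, target blocks are retained when their AUC strictly exceeds
the (1 − alpha) empirical quantile (type-7 interpolation) of the IgG control's
block AUCs; alpha defaults to 0.05.  Ties at the threshold are excluded, which
makes the rule deterministic and exactly testable.  In `top_fraction` mode the
top `t` fraction of blocks by AUC is kept (`floor(t*n)` blocks, coordinate
tie-break).  Blocks separated by even a single zero base are never merged
("stringent"-like behaviour).  Spike-in calibration is not implemented: all
tracks are CPM-scaled, and the control-quantile rule plays the role the
spike-in threshold would.  Two properties are guaranteed and tested:
lowering alpha never adds peaks, and jointly rescaling target and control
leaves the called set unchanged.

## Quantification and normalization

Per-peak counts are raw integers; **library sizes are the genome-wide totals**
(total mapped fragments), fixed when a matrix is constructed and never
recomputed after row filtering — CPM is a whole-library scale, and filtering
must not move it.  The CPM expression filter keeps features with CPM > 1 in at
least two samples.

Between-sample normalization is the trimmed mean of M-values (TMM): 30%
two-sided trim on log-ratios, 5% two-sided trim on average log-intensity,
delta-method precision weights, reference sample = the one whose
75th-percentile count fraction is closest to the mean; factors are normalized
to geometric mean 1.  Two caveats are deliberate and documented: (i) the
precision weights depend weakly on library size, so TMM factors are only
approximately invariant to rescaling one sample; (ii) `differential_test`
computes TMM *within the contrast* being tested when no factors are supplied,
so that the reference sample always belongs to one of the compared groups —
with a global reference, composition shifts of 25–30% of features can sit at
the trim boundary and leak a systematic fold-change bias.

The per-bp abundance used for reporting and expression summaries is the
literal Log2CPM density: `log2(count/library * 1e6 + 1) / width_bp` — scale to
CPM, add one, take log2, then divide by the peak width, in that order.

## Differential testing

Fold changes are log2 ratios of TMM-normalized group means with pseudocount
0.5 (bounded at zero counts).  Two exchangeable tests are provided:

- **nb_wald** — a per-feature negative-binomial GLM (log link, library-size
  offset) fit with statsmodels.  Dispersions are method-of-moments estimates
  pooled within groups, shrunk 70% toward a running-median trend over
  abundance.  The Wald statistic is referred to a t distribution with
  `(n_samples − 2) + 4` degrees of freedom: the residual df plus a prior df
  for the information the trend lends each feature, in the spirit of
  quasi-likelihood moderation.  Within the moderated range (prior df 2–6) the
  null calibration and the power of the test are both stable; 4 is the middle
  of that range.  Requires ≥2 replicates per group.
- **permutation** — the label-permutation null of |log2FC|: all distinct group
  assignments when there are ≤1000, otherwise 1000 sampled under the given
  seed.  Needs no dispersion estimate and is the fallback for unreplicated
  designs.

Both are symmetric (swapping groups negates log2FC and preserves p).  Multiple
testing uses an in-repo Benjamini–Hochberg step-up
(`q_(i) = min_{j≥i} p_(j)·m/j`), cross-checked in the tests against
statsmodels' implementation.

## Classification rules

With the default `Thresholds`:

- **dynamics** (WT formative vs naive): *formative* if FDR < 0.05 and
  log2FC > 1; *naive* if FDR < 0.05 and log2FC < −1; *shared* if FDR > 0.1 and
  |log2FC| < 0.7; otherwise *unclassified*.  The FDR cutoff for dynamic peaks
  is exposed because 0.01 is an equally defensible choice.
- **dependency** (DKO/WT within each state): *dependent* if either state's
  log2FC < −1; *independent* if both are > −0.7; otherwise *intermediate*.
  The two cutoffs deliberately leave a buffer zone rather than forcing a
  binary call.
- **feature class**: *Promoter* when the peak midpoint lies within ±1 kb of a
  TSS (the window is a package choice, exposed in `Thresholds`); otherwise
  *Distal* for intergenic or intronic midpoints.  With full gene structure
  (exon intervals) exonic midpoints are *Other*; with BED6-only genes the
  fallback is gene-body → *Other*, outside genes → *Distal*.
- **accessibility intersection**: a peak is kept when it covers at least 75%
  *of the ATAC peak's width* (the fraction is measured on the ATAC peak; a
  flag switches to fraction-of-self for sensitivity analysis).
- **joint mark categories**: each H3K4me1 peak is labelled by the behaviour of
  any-overlap (≥1 bp) H3K27ac peaks — formative → *gain*, naive → *lose*,
  shared/unclassified → *maintain*, none → *never*; when several overlap, the
  largest overlap wins.
- **gene classes**: transition genes use the same dynamic-gene thresholds on
  the WT comparison.  A formative gene is MLL3/4-*dependent* when DKO vs WT in
  the formative state is significantly down **and** the gene has no
  pre-existing naive defect (naive Log2CPM DKO/WT > −1).  The mirrored rule
  (DKO naive significantly down) is applied to naive genes as a package
  choice — the source analysis states the rule only for formative genes.

## Gene linkage and coupling statistics

Peaks link to the gene with the nearest TSS *on the same chromosome*
(|midpoint − TSS|; ties break to the lower TSS coordinate, then the
lexicographically smaller gene id; peaks on gene-less chromosomes are dropped
with a warning).  Per-category expression tests use the Wilcoxon signed-rank
on per-gene Log2CPM across sample classes — the paired test is the right
reading of a "paired rank-sum" design; an unpaired flag exists.  Exact null
for n ≤ 25 without ties, normal approximation with continuity correction
above.  Genes linked by several peaks of a category count once.  BH correction
spans the whole family of (category × comparison) tests.

The chromatin-state / gene-set control is a Monte-Carlo permutation test:
the Mann–Whitney U of the state's gene set against all genes is compared with
the U of random same-size draws from all genes (without replacement, two-sided
on the deviation of U from its null mean); all `C(n, k)` draws are enumerated
when there are ≤ `n_perm` of them, making small cases exact.  `n_perm`
defaults to 1000 and the seed is required, since the source does not state a
draw count.  A state set of 2 genes is allowed with a coarseness warning
(the exactness toy uses size 2); below 2 is an error.

Per-gene coupling summaries: an ordinary least-squares fit of gene log2FC
(DKO/WT) on the number of MLL3/4-dependent enhancers linked to the gene
(slope with 95% CI); and binning of genes by the percentage of their enhancers
that are dependent ({0, (0,25], (25,50], (50,75], (75,100]}%), with rank-sum
tests of each bin against the 0% bin, BH-corrected.  Genes with no linked
enhancer are excluded from both.

## Chromatin states

Genome bins (200 bp by default, the conventional choice) are binarized per
track by a Poisson upper-tail rule: a bin is "present" when
`P(X ≥ count | λ) < 1e-4`, with λ the genome-wide mean per bin or estimated
from the IgG control.  With the four tracks H3K4me1-WT, H3K4me1-DKO,
H3K27ac-WT, H3K27ac-DKO (most-significant bit first), the 16 combinations are
the chromatin states, and the default segmenter simply encodes each bin
(`state = 1 + binary encoding`): over binary tracks a 16-state model is
saturated, so training adds nothing in the noiseless limit.  A
Bernoulli-emission HMM is also provided for smoothed segmentations: Baum-Welch
with emissions initialised from perturbed empirical track frequencies (seeded),
scaled forward–backward (algebraically equivalent to log-domain arithmetic and
underflow-free for arbitrarily long sequences; Viterbi runs in log space),
monotone non-decreasing log-likelihood, stopping at `tol=1e-4` or 200
iterations.  Chromosomes are independent training sequences.  Parameter
recovery is tested by minimal-cost assignment between fitted and planted
emission rows.  Each condition is segmented separately.

The per-state expression test restricts state intervals to distal accessible
chromatin (≥75% ATAC-peak coverage, non-promoter), maps them to nearest TSSs,
and runs the permutation control per state, BH-corrected, excluding states
with no mark emission (combinatorial state 1, or HMM states with all emission
probabilities < 0.1).

## The synthetic genome

The generator plants every structure the pipeline must recover, so all stages
are testable with known answers.  Defaults define the study conditions:

| parameter | default | rationale |
|---|---|---|
| genome | 2 chromosomes × 5 Mb | desk scale, <1 min generation |
| enhancers | 2000 × 1 kb, intergenic, ≥1.5 kb from any TSS | all planted enhancers are distal by construction |
| genes | 1000, bodies 1–4 kb, random strand | enough TSSs for dense nearest-TSS structure |
| dynamics proportions | naive 0.25 / formative 0.25 / shared 0.5 | each directional tail stays inside the TMM trim |
| dependency proportion | 0.30 per mark | the reported dependency fraction of H3K4me1 peaks (~29%); also within TMM's breakdown point |
| base enrichment | 2³ = 8× background | strong but realistic peak over a sparse background |
| dynamics / dependency log2FC | +2 / −2 | planted effect sizes |
| marks | H3K4me1 always; H3K27ac 70%; ATAC 80% | produces all joint-mark categories |
| NB dispersion | 0.02 (BCV ≈ 0.14) | cell-line biological replicates |
| depth | 1e6 fragments/sample, ±10% lognormal jitter | desk-scale libraries with realistic size spread |
| track bins / background | 100 bp, 0.003 fragments/bp | sparse background whose block-AUC distribution gives the control-quantile caller realistic operating characteristics |
| replicates | 2 per genotype × condition | minimal replicated design |
| coupling κ | 1.0 (flag per enhancer, prob 1.0) | fully coupled null model; κ=0 plants decoupling |

Marked enhancers carry the base enrichment in their enriched state and
`base − 2` in the other state (shared: both); in the DKO, dependent marks drop
by the dependency log2FC, floored at background.  Tracks are per-bin Poisson
counts, CPM-scaled, pooled across replicates, with a background-only IgG track
per genotype × condition.  Counts are negative binomial around
`depth × width × 2^enrichment / genome_length` per replicate.  Expression
counts give each gene a lognormal baseline; the WT transition effect comes
from the dynamics of its coupled enhancers, and the DKO/WT effect in a
condition is `κ ×` the mean planted H3K27ac change of its coupled enhancers
*that are active in that condition* — an enhancer drives its gene only where
it is on, which keeps a formative-dependent enhancer from planting a spurious
naive expression defect.  Truth linkage is nearest-TSS by construction
(computed by an inline brute force, so the linkage module can be compared to
it honestly).  Everything derives from one seeded generator: outputs are
byte-identical under a fixed seed.

What the generator does **not** emulate: read-level artifacts (no FASTQ, no
mappability or duplication structure), fragment-length distributions,
spike-ins, promoter-proximal enhancers, overlapping genes, exon/intron
structure (so the *Other* class is exercised only via the BED6 fallback and
explicit exon fixtures), copy-number or batch effects, and indirect
(trans) regulatory effects.  Passing recovery tests therefore demonstrates the
pipeline's logic and statistics, not robustness to alignment-level noise in
real libraries.

In the end-to-end workflow the chromatin-state stage bins at 1000 bp rather
than 200 bp: at the generator's desk-scale depth a 200 bp bin holds too few
fragments for the Poisson binarization to separate 8× signal from background;
1 kb bins (the enhancer width) give clean separation.  The CLI default remains
200 bp for deeper real tracks.

## Numerical choices

Quantiles are type-7 (numpy default, stated for the peak threshold).  The
fold-change pseudocount is 0.5.  The permutation p-value counts ties as
exceedances (`≥ observed − 1e-12`).  Emission probabilities are clipped to
[1e-6, 1−1e-6] to keep logs finite.  Degenerate inputs error early:
zero-width intervals, overlapping bedGraph records, negative signal, all-zero
samples (TMM), all-zero binarized matrices (HMM), zero-variance burden
covariates.

## Known limitations

The NB Wald test's moderated-df calibration is a pragmatic small-sample
device, not an exact theory; with many replicates it converges to the usual
Wald test.  TMM assumes most features unchanged between the compared groups —
datasets violating this (e.g., global loss) need spike-in normalization, which
is out of scope.  The combinatorial segmenter treats bins independently; runs
shorter than a bin are invisible at the chosen resolution.  `union_peaks`
merges book-ended intervals, so peaks separated by exactly zero bases are one
feature downstream.
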