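# Methods

## Model and assumptions

The pipeline treats a centered log-expression matrix X (genes × samples) as
a noisy linear mixture X = M A + E of a small number of independently
modulated gene programs. Identifiability rests on the ICA assumptions: the
columns of M (gene weights) are mutually independent and non-Gaussian —
in practice sparse and heavy-tailed, because each program touches a small
subset of genes — while E is unstructured noise. Activities A are recovered
up to permutation and sign; the sign convention fixes the largest-magnitude
gene weight of every component to be positive, and all weight columns are
unit Euclidean norm so activities carry the scale.

Centering is on a designated reference condition: after log2(TPM + 1), each
gene's mean over the reference samples is subtracted, so both X and the
activities read as log2 fold differences from that condition. The +1
pseudocount keeps zeros finite; it is the only offset choice exposed
(`pseudocount` argument of `log_center`).

## Robust ICA

FastICA is the symmetric fixed-point iteration with the log-cosh contrast,
convergence tolerance 1e-6 and at most 1000 iterations, on data whitened to
the requested dimension by SVD. Runs that hit the iteration cap are flagged
and still contribute components; at dimensions above the true source count
this is expected behaviour on the noise directions, not an error.

Reproducibility is established across `n_runs` (default 10) runs. Each run
draws a fresh random initialization **and a bootstrap resample of the
sample columns**. The resampling matters: with initialization-only restarts
on a fixed matrix, the fixed points of the FastICA iteration — including
those created by finite-sample fluctuations of pure noise — are properties
of the data and recur in every run, so restart-reproducibility cannot
separate signal from noise (on pure Gaussian matrices it certifies 5–10
spurious components as "robust"). Under bootstrap resampling the spurious
optima move from run to run while genuine sources persist; on Gaussian
matrices the robust count drops to zero, and on planted-module benchmarks
exactly the true K components survive across requested dimensions from K to
2K. `resample=False` restores the pure-restart protocol; in that mode the
retained components lie exactly in the whitened subspace, and when all of
them survive clustering the reconstruction S·A equals the rank-d SVD
approximation of X, a property the tests check.

Pooled components are clustered by DBSCAN under the 1 − |Pearson r|
distance with radius 0.3 and min_samples = ceil(min_fraction · n_runs);
clusters containing components from fewer than `min_fraction` (default 0.5)
of the runs are dropped. The cluster representative is the sign-aligned
cluster mean anchored at the centrotype (the member with minimal summed
distance to the rest). The mean rather than the raw centrotype is used
because bootstrap runs carry run-specific estimation noise in the weaker
gene weights; averaging cancels it, which measurably improves membership
recovery near the thresholding boundary. Activities of the representatives
are recomputed by least squares against the full (un-resampled) matrix, so
S·A is always the exact projection of X onto the representative span.

Dimension selection scans a grid: at each dimension the robust components
are classified as single-gene (one gene holding more than half the squared
weight norm) or not, and the chosen dimension is the smallest one whose
non-single-gene count is within `plateau_tolerance` (default 0) of the grid
maximum. Past the true dimensionality extra components are either
irreproducible (removed by the clustering) or single-gene, so the count
plateaus; choosing the smallest plateau dimension avoids carrying redundant
components.

## iModulon structure

Member genes are the |weight| outliers of a component. The scan sorts genes
by |weight| descending and removes the top i = 0, 1, 2, … genes until the
D'Agostino K² normality statistic of the remaining weights falls below a
cutoff; the removed genes are the members. The K² statistic grows roughly
linearly with the number of genes for a fixed departure from normality, so
a flat cutoff is only meaningful at one universe size: the conventional
value 550 corresponds to a ~4.3k-gene bacterial genome, and the default
cutoff is rescaled as 550 · n_genes / 4322 (an explicit cutoff always
overrides). Universes below 20 genes, where the statistic is undefined, use
a quantile fallback (members = |weight| > mean + 3 sd).

Explained variance of an iModulon is the fraction of ‖X‖²_F removed by its
rank-1 reconstruction, clipped below at zero (under non-orthogonality a
rank-1 term can slightly increase the residual; negative fractions are not
meaningful for filtering). The reporting filter keeps iModulons explaining
strictly more than 0.5% by default. Matching against a prior structure
computes |Pearson r| between all weight-column pairs over the shared gene
universe and pairs greedily in descending |r| down to 0.7; greedy rather
than globally optimal assignment is deterministic, cheap, and identical to
the optimal assignment at the correlation separations seen in practice (the
Hungarian solution is kept as a test oracle).

## Enrichment

Each iModulon × regulon pair gets a one-sided hypergeometric tail
P(overlap ≥ observed); q-values are Benjamini–Hochberg over the full family
of tests (one global FDR bar, default 10⁻⁴, matching a single declared
rate). An iModulon is named by its lowest-q significant regulator, ties
broken by higher F1 then lexicographic name; all significant regulators
remain in the records, so co-regulated iModulons keep their full
annotation. Depletion and combination (AND/OR) regulons are out of scope.

## Activities

Activities of a fixed structure in new samples solve the per-sample least
squares min‖x − M a‖₂ (minimum-norm solution with a warning when M is
rank-deficient). Normalization to a reference sample is a subtraction —
activities are log-scale-like and cross zero, so division is not
meaningful. Differential calls compare replicate-averaged activities
between two samples: U when the difference exceeds the threshold (default
5), D below its negation, "−" otherwise; comparisons are strict, so a
difference exactly at the threshold is "no change". Activity correlations
report Pearson r with a two-sided p from the t distribution on n − 2
degrees of freedom (a permutation oracle verifies this in the tests).
Hierarchical clustering of activity rows uses 1 − r distance with average
linkage, falling back to scaled Euclidean for pairs involving a constant
row.

## Synthetic compendium

The generator runs the model forward. Gene weights: k disjoint (optionally
overlapping) modules of member genes with Laplace-magnitude weights, a 0.1
minimum-magnitude floor (keeping the support exact and the columns
non-Gaussian), random signs, unit-norm columns. Activities: per (module,
condition) a trajectory shape — flat, sigmoid-up, sigmoid-down, or
transient-pulse — with random midpoint and steepness, evaluated at the
design time points and repeated across replicates; declared module pairs
can be exactly anti-correlated (full-row negation, as in mutually exclusive
stress programs). A block of background samples with i.i.d. Gaussian
activities (sd = amplitude/2) stands in for the large reference compendium
that time-course samples are concatenated with: it provides the centering
reference and the activity diversity ICA needs (a time course alone leaves
module activities too correlated to separate). Expression: X = M A + E
with E i.i.d. Gaussian (replicate noise is the only replicate-to-replicate
difference; no batch effects); the TPM image adds per-gene baselines drawn
uniformly in log2 [3, 10], exponentiates, and rescales every sample column
to 10⁶.

Default design: 3 element-limiting conditions × 6 time points (3–24 h) × 2
replicates plus 30 background samples, amplitude 5, noise sd = 0.25 × the
median per-gene signal sd over module members. The benchmark used by the
tests and the acceptance script trims to 5 time points (60 samples total,
300 genes, 10 modules of 15 genes) so the full pipeline — including the
4-point dimension scan with 10 bootstrap runs each — completes in a few
seconds on one core.

What the generator does not emulate: count overdispersion, dropout, batch
effects, library-size artefacts, correlated noise across genes, or TRNs
with overlapping/nested regulons beyond the controllable-fidelity and decoy
mechanisms. Passing the recovery benchmark therefore demonstrates the
correctness of the decomposition/annotation machinery under the stated
model, not robustness to every artefact of real compendia.

## Numerical choices and degenerate inputs

FastICA tolerance 1e-6, max 1000 iterations; whitening rank guarded at
sv > sv_max · 1e-10; DBSCAN radius 0.3 in 1 − |r|; component ordering by
reproducibility then pool order for determinism; all randomness flows from
integer seeds through `numpy.random.default_rng`, and matrices are written
at full round-trip precision, so identical configurations yield
byte-identical artifacts. Degenerate inputs raise typed errors: constant
matrices (PCA), all-equal weights or <20 genes (thresholding), zero-norm X
(explained variance), zero-variance rows (correlation), empty gene
intersections (assembly, matching).

## Known limitations

- The bootstrap robustness protocol trades a small amount of reconstruction
  optimality for noise rejection; with `resample=False` the reconstruction
  bound is exact but Gaussian-noise components can be certified robust.
- Greedy matching and naming are deterministic but not globally optimal
  under adversarial correlation/tie structure.
- The K² cutoff rescaling is a first-order correction; universes far from
  both calibration scales (hundreds vs thousands of genes) may warrant an
  explicit cutoff.
- Manual curation of iModulon names (operon-style labels for unenriched
  components) is inherently out of scope; such components keep their
  ``IC_k`` identifiers.
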