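# Methods

This note documents the statistical model behind `rerscan`, the choices made
where the design was genuinely open, and what the synthetic studies used in
the tests do and do not demonstrate.

## Relative evolutionary rates

A gene tree's branch length measures amino-acid substitutions accumulated by
that gene on that branch. Branch lengths confound two things: the gene's own
level of constraint and the genome-wide substitution rate of the lineage.
The master tree — each branch the arithmetic mean of that branch's length
over all gene trees containing it — estimates the genome-wide component.
Gene trees with missing species are aligned to the master by pruning the
master to the gene's tips; branch identity is the descendant tip-set, which
is stable under pruning (a surviving branch's tip-set is the original
tip-set intersected with the kept species). A gene branch that spans a path
of collapsed master branches is attributed to the child-most branch on the
path; with full species coverage the mapping is the identity.

Per gene, branches whose length falls below the `cutoff` (default 0.001
substitutions, applied to both the gene and the master length of the branch)
are treated as missing. Remaining gene lengths are divided by their sum
(`scale`, removing gene-level average rate), square-root transformed (a
variance-stabilizing transform for count-like substitution data; the
identity transform is available), and regressed with intercept on the
equally transformed master lengths. The residuals are the RERs.

### Heteroskedasticity weighting

Residual spread grows with branch length even after the square-root
transform, and — critically — the Brownian phenotype paths the residuals
are later correlated with also have variance proportional to branch length.
Any residual branch-length-dependent scale in the RERs therefore inflates
the null variance of the gene-phenotype correlation and produces an excess
of small p-values. The weighting is designed to remove that scale
completely:

* A single mean-variance curve is estimated by pooling (fitted value,
  residual) pairs across **all** genes. Pooling matters: the long-branch
  tail, exactly where phenotype paths are largest, contains only a dozen
  branches per gene, and per-gene variance estimates there are far too
  noisy.
* First-pass OLS residuals are divided by √(1−h) (hat-matrix leverage)
  before entering the curve, since the regression shrinks observed
  residuals most at the high-leverage long branches.
* Per-bin variance is the median squared residual divided by 0.45494 (the
  median of χ²₁). The median resists contamination from the minority of
  genes with genuine rate shifts on a branch; the constant rescaling is
  irrelevant because only relative weights enter the fit.
* Bins are equal-count (10 up to 50 as pooled data allows); log-variance is
  interpolated piecewise-linearly between bin centers and extrapolated
  linearly beyond them (flat extrapolation demonstrably underestimates
  variance on the longest branches).
* Weights are floored at the 5th percentile of bin variances for the refit
  (one reweighting pass), but the final residuals are standardized by the
  **unfloored** interpolated variance times (1−h), so even the shortest,
  floored branches land on a common unit scale.

With `weight=off` the RERs are exact OLS residuals, verified against the
closed-form normal equations. If residuals are pure float noise (a gene
exactly proportional to the master), weighting is skipped rather than
amplifying that noise.

Winsorization caps the k−1 most extreme RER values per tail at the k-th
most extreme (default k=3: the two most extreme values per tail are set to
the third). It is applied symmetrically in both tails; vectors with fewer
than 2k−1 finite values are left unchanged, since the two tails would
overlap.

## Phenotypes and paths

Maximum lifespan (years) and adult body size (mass) are log10-transformed —
they span orders of magnitude across mammals — z-scored, and decomposed by
PCA. PC1 ("3L") is the shared size/longevity axis; PC2 ("ELL"), orthogonal
by construction, contrasts lifespan against its size prediction. PCA signs
are arbitrary, so they are fixed by convention: 3L correlates positively
with log lifespan, ELL positively with the residual of log lifespan on log
size. Raw-scale PCA is available via a flag; the log-scale default is a
package choice, as is the orientation rule.

Ancestral states under Brownian motion are the minimizer of
Σ_branches (Δstate)²/length, a sparse quadratic problem solved through the
tree's weighted Laplacian; the solution equals the conditional expectation
of each internal node given the tips (and is verified against brute-force
numeric likelihood maximization in the tests). The solve is precomputed as
a linear operator per tree, so reconstructing thousands of permulated
phenotypes is a single matrix multiplication. Zero-length branches receive
an epsilon of 1e-9 × tree height to keep the system proper, and operator
row sums are corrected to exact values so constant traits reconstruct
exactly despite the resulting ill-conditioning. Phenotype paths are
child-minus-parent state differences on every branch, terminal branches
included, computed on the master tree's branch lengths.

## Association and enrichment

Each gene's winsorized RERs are Pearson-correlated with the paths over
pairwise-complete branches; two-sided p comes from the t distribution with
n−2 degrees of freedom, floored at 1e-300 so the signed statistic
sign(ρ)·(−log p) stays finite (natural log; the ranking is invariant to the
base). Genes with fewer than `min_branches` usable branches (default 10, a
package convention), or zero variance, are excluded.

Pathway enrichment restricts the background to genes appearing in at least
one annotation, then compares member statistics to the rest with the
tie-corrected, continuity-corrected normal approximation of the Wilcoxon
rank-sum statistic. Sets with fewer than 10 or more than 500 members after
intersection with the measured genes are excluded (conventional bounds,
configurable). The normal approximation tracks exact
enumeration within ~10% in the bulk of the distribution for group sizes ≥ 8;
its relative error grows in the far tail, which is one reason the headline
pathway p-values come from permulations instead.

## Permulations and π1

A permulated phenotype is built by simulating Brownian motion on the master
tree (root state 0, increments N(0, σ²·length); σ² is irrelevant because
only ranks are used) and giving the species with the k-th smallest simulated
value the k-th smallest observed value. Every replicate is therefore an
exact permutation of the observed values — asserted in the loop — that
respects the phylogeny. Simulated-value ties break by species-label order
and observed ties are assigned in stable sorted order, so file-rounded
inputs remain deterministic. Replicate r draws from a generator seeded by
(seed, r): results are independent of execution order, and the loop is
embarrassingly parallel by contract.

Empirical p-values count nulls more extreme than the observed statistic,
with three conventions: `signed` (default; one-sided in the direction of
the observed statistic's sign — the directional reading appropriate for
enrichment statistics), `two-sided` (by absolute value), and `greater`.
Note that under the null the `signed` p is supported on [0, ½] (it is half
a two-sided p), so calibration checks use the two-sided variant, which is
exactly uniform. The default estimate is the plain proportion; a
pseudocount variant (1+count)/(1+n) is available. π1 = 1 − π0 with
π0 = #(p>λ)/((1−λ)n) against the uniform null, or the ratio of tail
proportions of real to permulation-null parametric p-values; λ defaults to
0.5 with a sensitivity sweep over 0.05–0.95. The permulation-null form is
the headline estimator because the parametric p-values are mildly
anticonservative under tree-structured phenotypes (see below) and the
ratio cancels that shape.

## The synthetic generator

The generator emulates the structure of a real rate-trait study with known
ground truth. Defaults define the reference condition used throughout the
tests:

* **Tree** — the bundled 61-species mammal tree (the printed 62-tip tree
  minus the cape golden mole, which lacks longevity data).
* **Traits** — bivariate Brownian motion of log10 body size and log10
  lifespan with increment correlation 0.75 (body mass and lifespan are
  strongly but not perfectly coupled across mammals); rates 6.0 and 1.0
  log10-units² per substitution, chosen so tips span several orders of
  magnitude of mass and about two of lifespan on a tree of ~0.4
  substitutions root-to-tip depth; roots at 1 kg and 16 years.
* **Gene trees** — 500 genes; branch length = master length × gene-level
  lognormal rate (sd 0.5 on the log scale) × multiplicative lognormal noise
  with cv 0.3 (keeps lengths positive and mimics substitution-count
  dispersion). 10% of genes are planted: their branch multiplier is further
  scaled by exp(−0.5·z_b) where z_b is the standardized phenotype path on
  branch b — the coupling targets the same quantity the method tests, so
  recovery is a genuine end-to-end validity check. The planted direction is
  negative (constraint increases with the phenotype), mirroring the
  dominant signal in real longevity scans.
* **Gene sets** — 50 sets of 25 genes; 10% are enriched, drawn entirely
  from planted genes, the rest uniformly.

What the generator does **not** emulate: non-Brownian trait evolution,
species missingness patterns of real alignments (missingness is exercised
separately through pruning), gene-gene correlation beyond the planted sets,
alignment or tree-estimation error, and codon-level selection. Passing
tests therefore show the estimator chain is correct and calibrated under
its own assumptions, not that those assumptions hold for any particular
real dataset.

## Calibration behaviour and measurement protocol

Under phenotype-independent RERs, the parametric correlation p-values are
calibrated on average (type-I rate ≈ 0.05 at the 0.05 level) but retain a
small phenotype-draw-specific coherence: all genes share the one observed
path vector, whose heavy-tailed alignment with any leftover per-branch
scale shifts every gene's p slightly and coherently. The weighting scheme
above removes the systematic part; the draw-specific part is irreducible
without conditioning on the draw and is exactly what permulation nulls
absorb at the pathway level. Consequently a single 500-gene study estimates
π1 with a sampling sd of roughly 0.05–0.07. The acceptance measurements
therefore average five independent replicate studies (SE ≈ 0.025), sized
from that power analysis; each study uses 500 genes, 61 species and 200
permulations, which keeps the full acceptance run under a minute on one
CPU. The permulation-null π1 for planted studies centers slightly below
the planted fraction because planted genes' null parametric p-values are
themselves mildly low-skewed, inflating the null tail denominator — a
conservative bias of a few points.

## Known limitations

* Master construction requires at least one gene tree spanning the full
  species universe; supertree assembly from partial trees is out of scope.
* The heteroskedasticity weighting is this package's own scheme; other
  implementations of branch-rate regression weight differently, so numeric
  parity with them is not guaranteed.
* The alternate-topology harness re-maps gene branches by tip-set, leaving
  topologically conflicted branches missing; re-estimating gene trees under
  the alternate topology would require sequence data and is out of scope.
* Pearson is the only correlation method; binary-trait support
  (`min_pos`) is accepted for config compatibility but inert.
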