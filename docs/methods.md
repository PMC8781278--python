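# Methods

## The model

The workflow assumes the responses of a designed multi-response experiment
decompose into modules: disjoint groups of responses that co-vary because
they reflect one underlying phenomenon (fermentation kinetics, primary
fermentation products, ester block, higher-alcohol block). Within a module
the autoscaled data are approximately rank one,

    Z_c ≈ t_c p_c',

with p_c the unit PC1 loading vector and t_c the per-run PC1 score. The
score, not the individual responses, is what the experimental factors are
modelled against: t_c is regressed on the coded factors and their
second-order terms by forward stepwise selection with partial F-tests.
Predicting t̂_c predicts every member response at once through the outer
product t̂_c p_c' followed by inverse autoscaling — "reconstruction".

This is a principal-component-regression variant in which the components
are cluster-local rather than global, preserving interpretability: each
fitted model speaks about one functional block.

## Design generation

Only the face-centered CCD (star distance α = 1) is implemented; it is the
only variant whose factors take exactly three levels, which is what the
three-level factor specification (low/mid/high) can encode. Other α values
raise an error rather than silently decoding to undefined physical levels.
Coded levels are stored as exact integers {−1, 0, +1}; physical units are
derived on demand via the linear map mid + coded·(high − mid), which
requires mid = (low + high)/2 and is checked at construction. The run
order is a seeded uniform permutation — the convention chosen for
"randomized execution order" since no specific mechanism is standard.

Default factors are the wine-fermentation set: sugar 150/225/300 g/L,
nitrogen 100/300/500 mg/L, temperature 10/20/30 °C, co-inoculum
0/5×10⁵/1×10⁶ CFU/mL. Coded −1 on the inoculum axis means "no
co-inoculation" but is treated numerically like any other level.

## Synthetic data

The generator emulates the study conditions: a 31-run design (2⁴ factorial
+ 8 axial + 7 center replicates) and 18 responses in five modules of sizes
1/2/7/3/5. For run i and module c,

    s_c(x_i) = Σ_t β_ct g_t(x_i),      g_t ∈ {x_j, x_j x_l, x_j²}
    y_ij     = μ_j + λ_j (p_cj s_c(x_i) + ε_ij),   ε_ij ~ N(0, σ_c²) i.i.d.

Defaults: the published cluster-level PC1 loadings and stepwise beta
coefficients of the fermentation study act as generating truth (printed
loading vectors are renormalized to unit norm); μ_j = 0, λ_j = 1, i.e. the
standardized scale, since the pipeline autoscales anyway; σ = 0.05, a
residual spread consistent with center-replicate variability in this kind
of assay. Noise enters before λ scaling so that autoscaling approximately
recovers the standardized generating model.

What the generator does *not* emulate: non-Gaussian or heteroscedastic
measurement error, missing values, detection limits, module overlap, and
any mechanistic fermentation kinetics. Passing tests therefore demonstrate
that the workflow recovers modular polynomial latent structure under
homoscedastic Gaussian noise — not that real fermentation data satisfy
those assumptions.

## Stage 1 numerics

Autoscaling uses the sample (n−1) standard deviation, matching mainstream
statistical environments and keeping PCA eigenvalue accounting
conventional. Constant columns are an error, not silently dropped; missing
values are a load-time error, not imputed. The level-summary table (n,
mean, quartiles, min, max per response × factor × coded level) is the
numeric content of the usual level-wise boxplots; plotting is left to the
caller.

## Stage 2: PCA and variable clustering

PCA components are eigenvectors of the sample correlation matrix of the
autoscaled responses (equivalently the covariance of the scaled data),
ordered by decreasing eigenvalue; explained percentages are
100·λ_i/Σλ. Unscaled input is rejected. Component signs are pinned so the
largest-|loading| variable loads positively, making scores and everything
regressed on them deterministic across linear-algebra backends.

The variable dissimilarity is d = 1 − |r|. The unsigned form is forced by
the application: fermentation length and maximum fermentation rate are
strongly *negatively* correlated members of one functional module, and the
signed form 1 − r would push them apart. The signed variant remains
available (`distance="signed"`) for comparison. Linkage is average
(UPGMA) by default — the conventional choice for correlation-distance
variable clustering — with complete and single selectable. The cluster
count k is a required input (default 5, the study's module count); no
automatic cut-height heuristic is applied, because none is robust at 18
variables. The dendrogram is cut with `scipy`'s `cut_tree`, which undoes
exactly m − k merges and hence always yields k clusters even under tied
merge heights; merge ties themselves are resolved by scipy's deterministic
agglomeration order. Cluster ids are renumbered 1..k by first appearance
in response-column order, so labels are a pure function of (X, k).

## Stage 3: surrogates, stepwise selection, reconstruction

Cluster-level PCA reuses the global machinery restricted to member
columns; a singleton cluster degenerates to loading (1) with PC1
explaining 100% — its surrogate is the autoscaled column itself. For any
two-member cluster of standardized variables the PC1 loadings are
±1/√2 ≈ 0.7071 analytically, and PC1 explains 100·(1 + |r|)/2 percent.

The candidate set for k factors is the k main effects, k(k−1)/2 pairwise
interactions and k quadratics, in that canonical order. Candidates are
standardized (centered, unit sample sd) before fitting and betas are
reported on that scale; the PC1 response is used as-is — it is centered by
construction, and its variance is left untouched so that the reported
betas refer to the surrogate's natural scale. On a face-centered design
the quadratic columns take raw values in {0, 1} and are mutually
correlated; no orthogonalization is applied — the partial-F machinery
handles correlated candidates, and the selection outcome, not
orthogonality, is the target.

The greedy loop: at each iteration the excluded term with the smallest
partial-F p-value enters if p < α_enter (ties break toward the earlier
canonical label); then included terms are re-tested and the largest-p term
with p > α_remove leaves. α_enter = α_remove = 0.05 by default — a single
reference level, with no distinction between the two thresholds. No
effect-heredity constraint is imposed: a quadratic or interaction may
enter without its parent main effects, since sparse models like {N, S²} or
{I, N×I} are legitimate outcomes in this setting. A term whose addition
would leave fewer than 2 residual degrees of freedom is ineligible that
iteration (recorded as a refusal in the trace), and the loop carries an
iteration cap against add/drop cycling, which is possible in principle
when the entry and removal thresholds coincide. The final model's betas,
standard errors and per-term p-values come from an ordinary OLS fit with
intercept (fitted, reported only in the machine-readable results).

Partial F for a single term equals the squared t-statistic of that term's
coefficient in the augmented model; the test suite checks this identity on
random instances and checks the whole greedy path against an independent
brute-force implementation.

## Numerical choices and degenerate inputs

- Eigendecompositions use `numpy.linalg.eigh` on correlation matrices;
  eigenvalues are clipped at 0 to absorb −1e−16-scale round-off.
- OLS inside the stepwise scans uses `numpy.linalg.lstsq`; the reported
  final fit uses `statsmodels` OLS for standard errors and p-values.
- A perfect fit (zero residual) makes a term's addition infinitely
  significant (F = ∞, p = 0) rather than dividing by zero.
- Distance matrices are clipped to [0, 1]; the diagonal is forced to 0.
- Empty stepwise selections report R² = 0 with an empty term list.

## Problem sizes used in the checks

Simulation-based checks run at the study's own scale (31 runs, 18
responses): module recovery over 100 seeds, effect recovery over 200
replicates per module, reconstruction error averaged over 50 seeds per
noise level. The pure-noise false-entry comparison runs the implementation
for 400 replicates against an independent Monte-Carlo of the same greedy
rule at 1500 replicates on a 20-run, 5-term instance — sizes chosen to
make the ±3-point comparison statistically meaningful while keeping the
suite quick to run.

## Known limitations

- Response-surface *optimization* (desirability, stationary points) is out
  of scope; the models identify drivers, they do not locate optima.
- No lack-of-fit test against center-replicate pure error is performed.
- Stepwise selection inherits its classical caveats: p-values of the
  final model are conditional on selection and optimistic; the workflow
  treats them as ranking evidence for factor relevance, not as calibrated
  inference.
- Cluster count k is user-chosen; the package deliberately refuses to
  guess it from the dendrogram.
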