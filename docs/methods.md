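# Methods

## Scope

`efagrid` implements one extraction method (iterative principal axis
factoring) and one rotation family (varimax followed by promax), in every
variant that differs across the major statistical programs, together with
the evaluation statistics and simulation machinery needed to compare those
variants. Maximum-likelihood extraction, oblimin/geomin rotation,
Schmid-Leiman transformation, and polychoric input are deliberately out of
scope.

## Principal axis factoring

The reduced correlation matrix is R with its diagonal replaced by the
current communality estimates h. Each iteration eigendecomposes the
reduced matrix, keeps the m eigenpairs with the largest *raw* eigenvalues,
forms loadings Λ = V_m · diag(√|λ|_m), and sets h to the row sums of Λ².
Convergence is declared when either |Σh_new − Σh_old| (referent `sum`) or
max_i |h_new,i − h_old,i| (referent `max_individual`) falls below the
tolerance (default 1e-3; 1e-6 as the strict alternative). The iteration
cap is 5000 with an explicit `converged` flag — no silent truncation.

*Eigenvalue treatment.* With `abs_eigen=True` the square root is taken of
the eigenvalue magnitude, so negative eigenvalues never halt the
procedure. With `abs_eigen=False` a negative eigenvalue among the m
largest raises a dedicated error; selection always ranks by raw eigenvalue
before magnitudes are applied, since re-ranking by magnitude is not part
of any documented pipeline.

*Seeds and fallbacks.* Initial communalities are unity, the maximum
absolute correlation (MAC), or squared multiple correlations
(SMC = 1 − 1/(R⁻¹)ᵢᵢ). When SMC seeds fail under raw eigenvalues, the
fallback policy reruns with unity (psych-style) or MAC (SPSS-style) seeds,
or propagates the error (`error`, used in grid runs so failures are
counted rather than patched).

*Sign convention.* Each loading column is flipped so its
largest-magnitude entry is positive. No convention is standard; this one
is deterministic, which the test suite requires. Exact eigenvalue ties at
the retention boundary (e.g. an identity input) keep the decomposition's
ordering and emit a warning.

## Rotation

*Varimax, `kaiser` variant.* The classic algorithm: closed-form pairwise
planar rotation angles maximizing the normal varimax criterion
Σ_j [pΣa⁴ − (Σa²)²]/p², swept until the criterion's relative change is
below tolerance (1e-10). The criterion is non-decreasing across sweeps and
is asserted as such.

*Varimax, `svd` variant.* The gradient-projection algorithm used by R's
`stats::varimax`: rotate by UV' from the SVD of the criterion gradient
until the sum of singular values stabilizes. One consequence is inherited
from the reference implementation: at an exact stationary point of the
criterion (e.g. loadings mixed at exactly 45°) the gradient vanishes and
the algorithm does not move. R's implementation behaves identically
(verified directly); the test suite pins this as faithful-to-reference
behavior and uses the kaiser variant for the analytic 45° fixture.

*Kaiser normalization* (default on) divides loading rows by √communality
before rotation and re-multiplies after. Zero-communality rows make the
normalization undefined and raise an error.

*Promax.* The target Q is the varimax loading matrix raised element-wise
to power k with signs preserved; with `p_type="norm"` each row of the
target basis is first scaled to unit length (the row-normalized variant).
The oblique transformation U = (A'A)⁻¹A'Q is always fitted against the
unnormalized varimax loadings A, then column-rescaled by
√diag((U'U)⁻¹) so the implied factors have unit variance. Pattern = AU,
Φ = (U'U)⁻¹ (unit diagonal by construction; symmetrized against rounding),
structure = pattern · Φ. k defaults to 4; the grid's alternative rule uses
3 for unnormalized and 2 for normalized targets. With m = 1 both rotations
are identity pass-throughs so single-factor pipelines run unchanged.

The SPSS-style preset claims "SPSS-like", not bit-identical output: the
exact varimax-criterion modification in that program is not publicly
documented, so the kaiser variant here is the classic algorithm and all
assertions about it are property-based.

## Evaluation statistics

Factor solutions are identified only up to column permutation and sign.
Alignment maximizes the summed |Tucker congruence| over matched pairs,
exhaustively over all m! permutations for m ≤ 6 (exact at the scale used
everywhere here) and greedily beyond; signs make each matched congruence
non-negative. RMSE against a population pattern is
√(trace((Λ−Λ̂)'(Λ−Λ̂))/pm) after alignment. A Heywood case is any
communality or unrotated |loading| ≥ .998; salience is |pattern| ≥ .20
(absolute value — negatives count); a solution is admissible when it has
no Heywood case and every factor carries at least two salient pattern
coefficients. Correspondence differences count indicators whose
salient-factor *sets* differ after alignment, which covers both
"different factor" and "salient in only one solution".

## Population models and simulation

`p|m|λ[|c]` codes expand to block pattern matrices: p/m indicators per
factor, loading values cycled per factor (default) or per indicator with a
factor-indexed offset (`wb`, mixing values within and between factors
while keeping every value in use for any p/m). Cross-loadings give the
first c indicators a secondary loading — the smallest value in the set —
on the next factor. The default manifest holds 27 codes spanning m ∈
{3, 6}, indicator-to-factor ratios 2–6, loadings .3–.9, heterogeneous and
wb-mixed sets, and cross-loading variants; crossed with four
intercorrelation levels (0, .3, .7, mixed .3/.5/.7 cycled over factor
pairs — verified positive definite for m = 3 and 6) it yields 108
population models. With two sample sizes (180, 450) and 1000 replicates
the full design specifies 216,000 data sets; both the manifest and all
sizes are arguments, and a YAML manifest can replace the built-in codes.

Sampling is multivariate normal with zero means and unit SDs, via the
Cholesky factor of R (eigendecomposition square root for PSD-but-singular
input). Seeding is counter-based: each (model, n, replicate) cell derives
its seed from the master seed via `SeedSequence`, so any subset of the
design reproduces the identical draws, and all implementations score the
same data set. Per-run failures (degenerate samples, negative-eigenvalue
aborts) are recorded in the output, never raised.

What the generator does *not* emulate: ordinal or non-normal indicators,
model error (population correlations are exact ΛΦΛ' + unit diagonal, with
no minor factors), missing data, and sampling designs beyond i.i.d. rows.
Passing recovery tests therefore bound implementation error under ideal
distributional conditions; they do not certify behavior on real scale
data, where no true model exists.

## Factor retention

Parallel analysis operates on SMC-reduced matrices (diagonal ← SMC) for
both the empirical data and each of the random standard-normal comparison
data sets of the same n × p (1000 by default). The first empirical
eigenvalue is tested against the 95th percentile of the first random
eigenvalues, subsequent ones against the corresponding random means,
stopping at the first failure. Random data are drawn from normal
distributions rather than resampled — the convention of the R
implementations this package mirrors. The admissibility-driven search
fits two implementations at a starting factor count and decrements until
both solutions are admissible, recording the per-step trace and each
implementation's own first-admissible count; exhausting all counts
returns an explicit all-inadmissible flag.

## Numerical choices

- Positive definiteness: smallest eigenvalue > 1e-8. Smoothing floors
  eigenvalues at max(1e-10·λmax, 1e-7), reconstructs, rescales to unit
  diagonal, and rechecks, so smoothed output always clears the PD
  tolerance and the operation is idempotent; already-PD input is returned
  unchanged. An abort mode mirrors programs that refuse non-PD input.
- Symmetry tolerance at correlation construction: 1e-12; the stored matrix
  is exactly symmetrized with an exact unit diagonal.
- Aggregation orders implementations by mean RMSE with ties broken
  alphabetically by label, so reports are deterministic.

## Problem sizes in the shipped studies

The acceptance studies use the design's own conditions at desk scale: the
closed-form one-factor fixture (p = 4, exact population input), parameter
recovery for the orthogonal `18|3|6` model at n = 10,000 with 20
replicates, the data-structure contrast (`18|3|3` at Φ = .7 vs `18|3|6`
orthogonal) at n = 450 with 100 replicates, and the program-divergence
study (`18|3|36`, Φ = .7) at n = 180 with 20 replicates. The full
216,000-data-set grid is enumerated and sized but not executed by the test
suite; `efagrid sim` runs any slice of it.

## Known limitations

- The kaiser varimax variant is the textbook algorithm; closed-source
  programs may deviate in undocumented ways, so equality with their output
  is not claimed or tested.
- Cross-loading placement and heterogeneous-loading layout within the code
  grammar are conventions of this package (documented above); studies
  needing a specific published layout should supply explicit pattern
  matrices through the manifest.
- Greedy alignment beyond m = 6 is not guaranteed optimal; all shipped
  designs stay at m ≤ 6.
- `correlation_from_raw` requires complete data; missing-data strategies
  are out of scope.
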