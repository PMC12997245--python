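# Methods

## Model

The response is Log 1/EC50 (log µM) of acetylcholinesterase inhibition, one
value per ionic liquid (cation–anion pair). The model class is ordinary
multiple linear regression over sigma-profile descriptors:

Log 1/EC50 = Σᵢ aᵢ·CatDesᵢ + Σⱼ bⱼ·AniDesⱼ + c

Descriptors are values of the ion's COSMO-RS sigma profile at fixed surface
charge densities σ ∈ {−0.030, −0.029, …, +0.030} e/Å² (61 points per
species, 122 candidate descriptors per IL). Profile values are treated as
surface amounts (Å²-scale, typically 0–30 per bin); no renormalization to
unit area is performed, matching the magnitudes of the published descriptor
rows. Descriptor names follow the published spelling: species prefix `C`/`A`
plus the σ value at three decimals with no plus sign (`C-0.008`, `A0.004`).

The packaged published model has 8 cationic and 3 anionic descriptors with
coefficients stored exactly as printed (4 decimals) and intercept −2.6595.
Because those coefficients are rounded, predictions computed from them can
differ from the originally computed values by ~0.01; the packaged worked
examples are asserted at that tolerance.

## Fitting and internal validation

`fit_ols` always includes an intercept and solves the least-squares problem
by QR/SVD (`numpy.linalg.lstsq`); an explicit normal-equations solve exists
only as an independent oracle in the tests. Rank-deficient designs are
rejected with the list of collinear columns.

Statistics (n observations, p descriptors):

- R² = 1 − SSres/SStot; R²adj = 1 − (1 − R²)(n−1)/(n−p−1);
- F = (SSreg/p)/(SSres/(n−p−1));
- S = √(SSres/(n−p−1)); RMSE = √(SSres/n) (so S² (n−p−1) = RMSE² n);
- AAD = mean |error|; %AARD = 100 · mean(|error|/|y|). The absolute value
  in the denominator is deliberate: the responses are negative, and a
  signed denominator would flip the metric's sign.

Q²(LOO) uses the PRESS shortcut: for OLS the held-out residual is
e_i/(1−h_ii) with h the hat-matrix diagonal, algebraically identical to n
refits (asserted to 1e-10 against brute-force refits in the tests). The
denominator SStot is taken about the full training mean, the convention of
the QSAR validation literature. Q²(LMO) averages over random subsamplings
(default: 20% left out, 1000 iterations, seeded). Y-scrambling refits after
uniform random permutation of the response; for an OLS fit with p
descriptors the expected scrambled R² is p/(n−1) — with p = 11, n = 183
this is 11/182 ≈ 0.060, which is what a sound model's scrambled R² should
collapse to.

## External validation

On a held-out test block with predictions ŷ:

- CCC (Lin) = 2·Sxy / (Sxx + Syy + n(x̄−ȳ)²);
- Q²F1 = 1 − SSres/Σ(y−ȳ_train)²; Q²F2 = 1 − SSres/Σ(y−ȳ_test)²;
  Q²F3 = 1 − (SSres/n_test)/(SStot_train/n_train). Q²F1 ≥ Q²F2 is an
  algebraic identity (centering about the test mean minimizes the sum of
  squares) and is asserted as a property;
- r²m = r²·(1 − √|r² − r₀²|) where r² is the squared correlation of
  observed vs predicted and r₀² the through-origin R²; computed for both
  axis orders, reported as the pair's mean and absolute difference. The
  unscaled variant is used: it reproduces the published values (0.649 and
  0.201 computed vs 0.648 and 0.205 printed).

The external "R²" reported for a test set is the squared Pearson
correlation of experimental vs predicted — that, not 1 − SSres/SStot, is
what the published test-block value corresponds to (0.7514 vs 0.731); both
are available from the package.

## Applicability domain

Leverage h_i = z_i (ZᵀZ)⁻¹ z_iᵀ with Z the training design including the
intercept column (hence Σh_i = p+1 over training rows, asserted at 1e-8).
Critical leverage h\* = 3(p+1)/n. Standardized residuals divide by the
training-set RMSE for both blocks, so train and test are comparable on one
Williams plot. Flags: structural outlier h > h\*, response outlier
|SDR| > 3. The flag set is deterministic.

## Descriptor selection

The GA works on fixed-size chromosomes (index sets of exactly k bins):
binary-tournament selection, uniform crossover (rate 0.8), per-gene
mutation (rate 0.05), elitism 2, population 100, generations 200 by
default; fitness is Q²(LOO) (training rows only) or training R². After
crossover/mutation a repair step drops duplicate genes and refills randomly
so every individual keeps exactly k genes. Rank-deficient subsets score −∞
rather than erroring. Ties are broken toward the lexicographically smaller
descriptor-name tuple, making results platform-reproducible. The final best
subset is polished by a steepest-ascent single-swap hill climb (on by
default, `GAConfig.local_search`): plain generational search at this scale
is good at finding near-optimal regions but unreliable at pinning the exact
optimum in pools of ~100+ bins, and the swap refinement closes that gap at
negligible cost. With elitism the best-fitness trace is non-decreasing.

`exhaustive_select` enumerates all C(|pool|, k) subsets (budget-guarded)
and serves as the exact oracle in the tests; the GA is asserted to match it
on 91-pair instances in ≥99/100 seeded runs.

Breaking-point analysis scans k over a range, records best fitness and
training R² per k (enumerating exactly when the pool is small, GA
otherwise), and reports the smallest k whose R² is within delta (default
0.01) of the range's maximum. Candidate pools for size-recovery studies
are kept moderate (~25 bins): with very large pools the best spurious bin
adds ~(1−R²)·max-χ²/n ≈ 0.01 to R², the same order as the detection delta,
and the plateau location becomes ill-posed regardless of search quality.

## Synthetic data

The generator emulates the structure of real descriptor tables so that
every stage can be validated against ground truth. Each ion's profile is a
mixture of 1–3 Gaussian bumps over the σ grid (width ~0.004 e/Å² by
default, so adjacent bins are correlated, reproducing the collinearity
regime of real profiles), with cation bumps biased toward positive σ and
anion bumps toward negative σ, and total surface in [100, 500] Å². Defaults
mirror the modelled study's scale: 113 cations × 29 anions combined into
243 ILs, split 75:25 into 183 training and 60 test rows. The planted
response follows the model equation over 11 bins shaped like the published
model (anion coefficients several-fold smaller than cationic ones, scaled
so responses stay on the ~1 log µM scale), plus Gaussian noise; when no
noise level is given it is calibrated so the planted signal explains 82% of
the response variance — the fit regime of the modelled study. A single
planted response outlier (default 6σ) is available for applicability-domain
tests. All randomness flows from one integer seed through a dedicated
generator.

What the generator does **not** emulate: real chemistry (profiles are not
solutions of any screening model), activity cliffs beyond the single
planted outlier, repeated-ion pairing structure of real IL datasets, or
measurement-error heteroscedasticity. Passing tests therefore demonstrate
the correctness of the statistical machinery under known ground truth, not
predictive validity on new chemical space.

## Numerical and design choices

- Fixtures: the packaged 243-IL table stores the published experimental and
  predicted values (2 decimals) with train/test membership; metrics
  recomputed from it match the published statistics within ±0.005 (fit
  block) and ±0.01 (external block), consistent with prediction rounding.
- The σ grid is closed at both ends ([−0.030, +0.030]); off-grid values are
  rejected rather than snapped beyond a 1e-6-step tolerance.
- Bins that are zero across all training ILs are dropped before selection
  (they are unidentifiable).
- Monte-Carlo bias checks compare 11 coefficients simultaneously, so the
  per-coefficient 2-SE band is Bonferroni-widened to 3 SE; a joint plain
  2-SE test would reject an exactly unbiased estimator in a large fraction
  of runs.
- Problem sizes in the test suite are scaled for tightness of the checks:
  coefficient-bias runs use 100-IL studies over 200 seeds; breaking-point
  recovery uses the full 183-row training scale over 100 seeds with a
  25-bin pool (see above for why).
- LMO folds leaving fewer than p+2 rows, zero-variance responses and
  zero reference RMSEs are rejected with descriptive errors rather than
  producing NaNs.

## Known limitations

- The full descriptor table of the original 243-IL study is not
  redistributable here, so its Q²LOO (0.789), Q²LMO (0.785) and the
  identity of its single Williams-plot outlier cannot be recomputed;
  the corresponding machinery is validated on synthetic ground truth
  instead.
- Random-split validation estimates interpolation error; for ILs with
  genuinely unseen ions, component-based (leave-cation-out /
  leave-anion-out) splits — provided by the study driver — give the more
  honest error estimate.
- r²m is reported in its unscaled variant only.
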