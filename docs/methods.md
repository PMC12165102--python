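# Methods

## Scope

Two statistical pipelines over macronutrient space: (i) Scheffé
mixture-model selection for isocaloric feeding experiments with
right-angled mixture-triangle (RMT) visualization, and (ii) a
penalized-spline generalized additive mixed model (GAMM) engine for
country-year panels of macronutrient supplies, GDP and a disease-burden
rate. Both are exercised on seeded synthetic data whose generating truth
is returned with the data; nothing here estimates uncertainty intervals
or p-values for smooth terms, and no real GBD/FAOSTAT/Maddison extracts
are bundled or downloaded.

## The diet design

A diet is a point (P, C, F) on the 2-simplex of energy fractions, plus
an energy density (MJ/kg dry food). The reference array holds energy
density fixed at 14.5 MJ/kg so diets differ only in mixture. Its three
apex diets are HP = 60:20:20, HC = 5:75:20 and HF = 5:20:75 (P:C:F
percent); AIN-93G (20:64:16), the rodent growth-control formulation, is
carried as a reference composition but is not part of the generated
10-diet array. The sampled window is 5–60% protein, 20–75% carbohydrate,
20–75% fat; on the simplex this window is exactly the triangle with the
three apex diets as vertices.

The published array's seven non-apex compositions are not available, so
`make_full_design` generates them by seeded greedy maximin selection
from a uniform sample of the window: each new diet maximizes its minimum
distance to the diets already chosen (apices included). This reproduces
a space-filling design of the stated extent without inventing specific
unpublished numbers; any fixed seed gives a reproducible array, and the
apex diets are always present exactly.

A diet is classified ketogenic when its carbohydrate energy fraction is
strictly below 10% — the HF diet, at 20%, is deliberately not ketogenic.

## Mixture models

Scheffé polynomials are the canonical regression family when predictors
are proportions summing to one: the intercept is absorbed by the linear
terms, so models 1–4 carry no constant column. Candidate terms:

| model | terms | k |
|---|---|---|
| null | 1 | 1 |
| 1 | P, C, F | 3 |
| 2 | + PC, PF, CF | 6 |
| 3 | model 2 + PCF | 7 |
| 4 | model 2 + PC(P−C), PF(P−F), CF(C−F), PCF | 10 |

Fitting is ordinary least squares through a rank-revealing orthogonal
solve (LAPACK `gelsd`) rather than explicit normal equations — near
collinear designs (e.g. replicated identical diets) are detected and
reported with the offending terms instead of silently amplifying
round-off. Responses are modelled on their raw scale (Treg % in the
motivating application); percentages are kept as-is rather than
logit-transformed because the observed outcomes sit well inside (0, 100)
and the display convention labels isolines in raw percent.

Model scores are `AIC = n·ln(RSS/n) + 2(k+1)`, counting the error
variance as a parameter. The additive constant is irrelevant for
ranking; fixing it makes reported AICs bit-reproducible. The lowest AIC
wins; exact fits (RSS = 0, log-likelihood degenerate) are selected
outright over any positive-RSS candidate, with ties — exact or within
1e-9 — resolved toward the smaller model.

A selection caveat documented here because the test suite measures it:
with nested candidates, lowest-AIC selection retains a known asymptotic
probability of preferring a strictly larger model when the smaller one
is true (≈ P(χ²_q > 2q) for q extra parameters; ~14–15% summed over
models 2–4). Under the default simulation conditions the linear model is
therefore selected in ~85% of replicates, with the remainder going to
its supersets; the fat-dominant *direction* of the effect is recovered
essentially always.

## RMT surfaces

The projection is (x, y) = (100·P, 100·F) with carbohydrate implicit on
the hypotenuse (C% = 100 − x − y) — an invertible affine map, so
round-trips are exact to machine precision. Surfaces are evaluated on a
regular grid at 1% resolution by default (≤101×101 points, desk-scale
and visually smooth), masked to the axis-aligned design window rather
than the convex hull of the diets: the display convention shows the full
stated window, and hull masking is available as an option. Isolines come
from marching squares (contourpy) on the masked grid; requested levels
outside the observed value range are skipped with a warning rather than
an error. Rendering uses a fixed style with no timestamps, so a given
surface always produces identical bytes; the default palette maps high
responses to red and low to blue, with a red-to-green option for the
supply-surface convention.

## The GAMM engine

### Model

For a single sex stratum of a country-year panel:

```
log(rate + 0.5) = β₀ + Σₜ fₜ(xₜ) + u_country + ε
```

Rates per 100,000 are positive and right-skewed, hence the log
transform; the +0.5 offset keeps zero-rate records finite. An identity
transform is available. GDP enters all smooths as log dollars: supply
and burden relationships with income are conventionally multiplicative.

### Smooths

Every smooth is a P-spline: a B-spline basis with equally spaced knots
over the observed range (boundary-extended, partition of unity) and an
order-2 difference penalty whose null space is the linear functions —
at infinite smoothing a 1D smooth degenerates to a straight line.
Multi-variable terms are tensor products (row-wise Kronecker of marginal
bases) with one penalty block per margin (marginal penalty ⊗ identity).
Default marginal sizes: K = 5 for 1D smooths, K = 4 (cubic) per margin
for the 3-variable nutrient smooth (64 columns), K = 3 per margin for
the 4-variable nutrient×GDP tensor — three basis functions force the
marginal degree down to quadratic, keeping that block at 81 columns,
tractable and identifiable on ~4,350-row panels.

Smooth columns are mean-centered against the intercept. Because B-spline
rows sum to one, the centered block annihilates the constant coefficient
direction exactly, and the difference penalties annihilate it too; that
direction never touches the fitted values, so it is pinned inside the
first penalty block of each term (adding `11ᵀ/p`). This keeps the
penalized system positive definite without altering any prediction —
omitting the pin makes the effective-degrees-of-freedom trace numerically
meaningless, which materially distorts AIC comparisons.

### Random effects and fitting

Country random intercepts are a full dummy block under an identity
(ridge) penalty with its own smoothing parameter — the standard
penalized-regression representation of a Gaussian random intercept; the
estimated intercepts are shrunk toward zero relative to raw country mean
residuals. The whole model is one penalized least-squares problem; for
each candidate λ-vector the solver forms `A = XᵀX + Σ λ_b S_b`, solves
by Cholesky (falling back to a pseudo-inverse when a zero λ is forced
and A is genuinely singular), and computes `edf = tr(A⁻¹XᵀX)`.

Smoothing parameters minimize `GCV = n·RSS/(n − edf)²` by coordinate
descent over the log₁₀ grid {−4, …, +4}, three sweeps, with caching.
GCV rather than REML keeps selection deterministic and dependency-free;
it is adequate for the structure-selection conclusions this package
draws, though REML (as in mgcv) would typically smooth slightly more.

### Candidate set and selection

"All combinations of individual, additive and interactive effects" is
unbounded as stated, so the candidate set is a fixed, documented list of
ten structures built from blocks N = te(protein, carb, fat),
G = s(gdp), Y = s(year), N×G = te(protein, carb, fat, gdp):
null, N, G, Y, N+G, N+Y, G+Y, N+G+Y, N×G, N×G+Y — every structure the
motivating analysis reports, including the favored interaction-plus-time
model, all with the country random intercept. Candidates are ranked by
`AIC = n·ln(RSS/n) + 2(edf+1)` (a conditional-AIC analogue with the
effective dimension in place of the parameter count, applied uniformly);
ties break toward fewer columns, and the full AIC table is retained.

### Surfaces and geometry

Prediction surfaces hold protein supply at a quantile of the observed
distribution (25%/50%/75% conventionally), GDP at the panel median and
year at the latest observed year, set the country intercept to zero, and
evaluate over a (fat, carb) grid masked to the convex hull of observed
supply pairs — no extrapolation outside supported supply space. The
isocaloric line f + c = E − protein (slope −1) and origin radials
c = r·f (constant carbohydrate:fat ratio r) overlay the surface to
separate changes in nutrient balance from changes in total energy.

## Synthetic data

### Country panel

Defaults emulate the real analysis conditions: 150 countries × years
1990–2018 (4,350 rows per stratum), one "both-sexes" stratum. Per
country, log-GDP starts from a N(9, 1) baseline (~8,100 constant
dollars) and follows a random walk with drift 0.02/yr and innovation sd
0.03. Each supply is country baseline (N(300/1500/600, 40/150/100) kcal
for P/C/F) + calendar trend (1.5/6/5 kcal/yr) + positive coupling to
log-GDP (30/120/80 kcal per log-dollar) + noise, floored at 30 kcal —
so supplies, GDP and time are strongly intercorrelated (pooled
supply–log-GDP correlations ≈ 0.5–0.7), which is precisely the
disentangling challenge the GAMM faces.

The truth surface on the log-rate scale is

```
f(C, F, gdp) = (1 + a_int·tanh(z_g)) · [a_c·g(z_c) − a_f·g(z_f)],
g(z) = tanh(nl·z)/nl
```

with supplies standardized around (1500, 600) kcal and z_g = log-GDP − 9.
Defaults a_c = a_f = 0.4, nl = 0.6, a_int = 0.6, year trend −0.004/yr,
country intercept sd 0.3, residual sd 0.10, baseline log-rate 3.3
(rates ~ tens per 100,000, mildly declining with time). The shape
encodes the qualitative pattern the method should recover — burden
rising in carbohydrate supply and falling in fat supply with mild
saturation — without committing to any published effect size; the GDP
modulation (±0.54 relative between poorest and richest countries) makes
the interaction structurally identifiable by AIC at this panel size, as
it evidently was in the motivating analysis, while a_int = 0 gives the
additive counterfactual used in selection tests. tanh keeps both
monotonicities global, so sign-recovery checks are well defined
everywhere.

What the generator does *not* emulate: GBD-style uncertainty intervals,
missing-data structure beyond an optional uniform dropout, reporting
artefacts, age-standardization error, or non-Gaussian residuals.
Passing recovery tests therefore demonstrates the estimator works under
smooth truths with realistic collinearity and panel dimensions — not
that real-world confounding is resolved.

### Feeding experiment

Per-animal responses are `X(diet, truth_model)·β + N(0, σ)` over the
10-diet design, default 8 animals/diet (the experimental N was 6–8),
truth model 1 with fat-dominant β = (2, 4, 12) — predicted responses
~4–10%, matching the scale of observed Treg fractions — and σ = 1.
Generators take a mandatory seed, use a single RNG stream per call, and
are byte-reproducible.

## Numerical conventions and edge cases

- Simplex closure is validated at 1e-8; percent inputs are normalized on
  read.
- Exact mixture fits (RSS = 0) have undefined AIC; `aic()` raises and
  the selector prefers them outright at smallest k.
- B-spline evaluation outside the boundary knots raises (points within
  1e-8 of the boundary are clamped); degenerate constant predictors
  widen to a safe interval.
- GCV denominators are guarded against edf → n; RSS is floored at zero
  against round-off.
- Contour levels outside the surface range log a warning and are
  skipped; an empty mask region raises.
- Problem sizes used in tests and the acceptance script: 10-seed suites
  of full-scale (150×29) panels for recovery/selection, 200-replicate
  suites for mixture selection, 50 random tables for oracle
  equivalence, 25×25 prediction grids — all chosen as the smallest
  sizes at which the measured rates are stable.

## Known limitations

- GCV with a coarse λ-grid can undersmooth relative to REML; AIC
  comparisons remain valid because the same convention is applied to
  every candidate.
- The conditional-AIC analogue ignores smoothing-parameter uncertainty.
- The candidate set excludes 3-way tensors (e.g. nutrient×GDP×year).
- Mixture models here are fixed-effects only; per-animal random effects
  (litter, cage) are out of scope.
- Lowest-AIC selection over nested candidates has the irreducible
  overfitting probability discussed above; consumers wanting stricter
  parsimony should apply their own ΔAIC threshold to the reported AIC
  table.
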