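# Methods

## Model family

All mean functions are constant-allometric-ratio (CAR) power laws,
`Y = a0·DBH^a1` or `Y = a0·DBH^a1·H^a2`, with DBH in cm, total height H
in m, and Y in kg of oven-dry mass (or kg C for carbon responses).  The
error is additive on the arithmetic scale and heteroscedastic: its
variance grows with the mean.  We do not use log-regression (which would
require back-transformation bias correction); instead squared residuals
are weighted by `1/f(x)^power` with `power = 1` by default — the
standardization `residual/√f(x)` — and `power = 2` available for a
variance-∝-mean² assumption.  Weights come from the current fitted means
(iteratively reweighted NLS: log–log OLS start, weights refreshed from
each iterate, relative parameter tolerance 1e-8, at most 50 iterations,
means floored at 1e-12 before inversion).  Weighting by the observed
response instead of the fitted mean is available for comparison
(`WeightSpec(source="observed_response")`); the default is fitted means,
which keeps the estimator a proper IRLS scheme.

## Simultaneous systems (NSUR)

Component equations are estimated jointly by nonlinear seemingly-
unrelated regression, implemented as iterated feasible GLS: (i) each
equation is fitted by weighted NLS to initialize; (ii) the
cross-equation error covariance Σ is estimated from heteroscedasticity-
standardized residuals; (iii) the joint Σ⁻¹-weighted least-squares
objective is minimized (Levenberg–Marquardt, or trust-region-reflective
when parameters are bounded); steps (ii)–(iii) repeat until the relative
parameter change falls below 1e-8 (at most 100 outer iterations).  A
singular Σ — which arises by construction on noise-free data — is
ridge-regularized with a warning; the regularization does not move the
zero-residual optimum.

**Aggregation structure.**  Stem (bivariate), branch and leaf
(univariate) equations are estimated jointly with a 3×3 Σ; the total is
their algebraic sum.  Because observed aboveground biomass is *defined*
as the component sum, a fourth total equation would be an exact linear
combination of the first three and would make Σ singular; additivity of
the totals therefore holds identically without estimating it.

**Decomposition structure.**  Components are shares
`{1, g_branch, g_leaf}/(1 + g_branch + g_leaf)` of an aboveground total
f1.  The g's are CAR-form proportion functions in DBH (configurable to
bivariate), kept positive by bounding their coefficients below at 1e-9,
so shares lie in (0,1) and sum to one identically.  f1 is the
independent weighted aboveground fit and is frozen by default —
hierarchical assignment of an established total model — with joint
re-estimation available (`refit_total=True`).

**Climate-parameterized aggregation.**  Each component's coefficient and
exponents are linear in one assigned climate indicator:
`(c0+c01·c)·DBH^(e1+e11·c)[·H^(e2+e21·c)]`, with the default assignment
stem → DD<0 (degree-days below 0 °C), branch → PAS (precipitation as
snow), leaf → TD (continentality).  Starting values come from a
log-linearized regression of `ln y` on `[1, c, ln D, c·ln D(, ln H,
c·ln H)]` with the coefficient linearized around the mean climate value;
the zero-slope start from the plain aggregation fit sits on the wrong
side of a long coefficient/exponent-slope valley and stalls.  A fit
whose effective coefficient is non-positive for any training record is
rejected with a diagnostic.  Indicator screening picks, per component,
the indicator with the largest |Pearson r| against component biomass,
demoting a candidate whose |r| with an already-chosen indicator exceeds
0.7 (ties break lexicographically); zero-variance columns are excluded
with a warning.

**Root:shoot ratio.**  `M_root = (b0·DBH^b1[·H^b2])·M_agb`, the two
equations (aboveground CAR, root ratio × aboveground) estimated jointly
by SUR on the root-excavated subsample with shared aboveground
parameters; the belowground equation's weights use the root mean
function.  The ratio form makes the root prediction compatible with any
aboveground source.  Error propagation:
`MPE_adj = √(1 − (1 − 1/K)·r²)·MPE_sub`, with K the aboveground-to-root
sample ratio from the data and r the Pearson correlation of observed
root and aboveground biomass on the subsample (the estimator of r is a
package choice; the source formulation leaves it open).

## Carbon

Carbon stock = dry biomass × component carbon fraction (stem 0.4820 —
the wood/bark arithmetic mean, branch 0.4805, leaf 0.4923).  Two routes
are supported and agree by the multiplicativity of the CAR form: scale a
biomass model's coefficient, or refit on converted responses.  No root
carbon fraction is published; the package exposes a default of 0.4685,
implied by the ratio of the published belowground carbon and biomass
coefficients (0.0245/0.0523), and always warns that it is a
reconstruction.

## Evaluation

R²_adj with (N−1)/(N−P−1), SEE with divisor (N−P), TRE =
100·Σ(y−ŷ)/Σŷ, and MPE = 100·t·(SEE/Ȳ)/√N with t the two-sided 95%
Student quantile at N−P degrees of freedom.  That t convention is fixed
by back-calculation: it reproduces the published MPE values (5.17, 4.39,
5.82, 9.29, 16.02) to the printed 2 decimals from the printed SEE,
component means, N and P; two published values (9.49, 3.31) are off by
0.01 under every t convention and are treated as source rounding noise.
The jackknife is delete-one refitting with out-of-sample prediction of
the held-out tree (not pseudo-value aggregation), statistics computed on
the out-of-sample prediction vector.

## Synthetic populations

The generator reproduces the calibration design rather than any one
dataset: 160 trees in ten diameter classes centered at
{2,4,6,8,12,16,20,24,28,32} cm (uniform within half the gap to the
neighbouring class) plus 15 uniform extras on (1.4, 31.5) cm, scaled
proportionally for other sample sizes; heights from
`H = 1.3 + 27·(1 − e^(−0.027·DBH))` m with lognormal scatter (CV 0.20,
truncated to [1.4, 20.5] m), calibrated so the design mean is ≈9.75 m
and the marginal height CV ≈0.5; ages ≈ 3.5·DBH yr with CV 0.25 on
[5, 130]; 17 climate indicators uniform on ranges plausible for
temperate monsoon Northeast China (TD bounded below at 32 °C so the
published leaf climate equation's effective coefficient stays positive
over the training range), drawn independently per tree.

Component biomasses are the published univariate power laws times
multiplicative lognormal noise with mean 1 and `Var ∝ mean^power`
(default power 2, i.e. constant CV — the assumption under which the
1/f(x) weighting is exact).  Root biomass is the published ratio form
times the aboveground mean.  Residual CVs are back-calculated from the
published SEEs under this noise model: SEE² = cv²·E[f(x)²] over the
design, giving stem 0.27, branch 0.40, leaf 0.46, root 0.40.  (SEE
divided by the component mean would overstate the noise by ~60%, because
E[f²] ≫ (E[f])² across a 1.4–31.5 cm diameter range.)  The published
summary table of the calibration data is not machine-readable in our
source; component means (stem 95.2, branch 47.23, leaf 5.65, root 40.30,
aboveground 148.17 kg) are back-calculated from the published SEE/MPE
pairs and are reconstructions, not verbatim values.  The root-excavated
subsample (53 of 175 by default) is allocated across diameter classes by
largest-remainder proportional rounding, mirroring the class-wise
excavation design; purely random subsampling is available.

What the generator does **not** emulate: spatial/site structure (climate
is independent of tree size, so climate–biomass correlations are zero by
construction in the default population), between-site height–diameter
variation beyond a single scatter parameter, crown variables, and any
growth dynamics.  Passing tests on these populations therefore
demonstrate correctness of the estimators under the study's design and
noise level — not that the published coefficients are right for any
particular forest.

## Identifiability at study scale

With heights tightly coupled to diameters, `ln H` is nearly collinear
with `ln D`, so bivariate exponent pairs (a1, a2) are identified only
jointly: at the calibrated noise level the median error of the
aggregation stem a2 over 200 synthetic replicates is ≈10% even though
the fit is exact on noise-free data to 1e-4.  The same holds for the
root-ratio exponent b1 (|b1| ≈ 0.28 estimated from 53 trees inside a
product with the aboveground power; median error ≈45%), while the fitted
ratio *value* at mid-diameter is stable.  This mirrors the published
tables themselves, where the stem (a1, a2) pair moves from (1.73, 1.04)
to an effective (1.90, 0.68) between structurally different refits of
the same data.  Univariate DBH exponents are well identified: median
recovery errors are 1.7–3.5% across components and systems.  Recovery
claims in the tests are therefore asserted on univariate-equation DBH
exponents (and on effective coefficients/exponents at fixed climate
values for the climate system); full-parameter recovery is asserted on
noise-free data.

## Numerical choices

Optimizer tolerances 1e-14 (xtol/ftol/gtol) inside each weighted
least-squares solve; IRLS and NSUR outer tolerance 1e-8 on relative
parameter change; weight floor 1e-12; Σ ridge 1e-8·tr(Σ)/m.  Degenerate
inputs: an all-equal response raises a singular-fit error; zero-variance
climate columns are excluded from screening with a warning; empty
allocation classes are reported with NaN means and a warning; trees
outside the age groups are assigned to the nearest group with a warning.
Diameter/height class membership is by nearest class center with
half-open boundaries at midpoints; age groups are [lo, hi) with the last
group closed.  Proportion–climate significance uses raw α = 0.05 per
pair by default, matching the source's practice; a Holm step-down
adjustment is available but off by default.

## Known limitations

The NSUR estimator concentrates Σ rather than maximizing a full
likelihood, so its standard errors are not reported (the evaluation
statistics are prediction-based instead).  The climate-parameterized
system inherits the screening's single-indicator-per-component
restriction.  All models are applicable only inside the calibration
envelope (DBH < 33 cm, H < 20.5 m), and the univariate forms only for
DBH < 33 cm.
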