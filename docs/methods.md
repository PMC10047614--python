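# Methods

This note records the models the package implements, the choices made where
the design was genuinely open, and what the synthetic-data tests do and do
not establish about real field data.

## Connectivity metrics

**Perch density (PD).** At the bird's initial position the distance to the
nearest perch is taken in each of the four quadrants demarcated by the
cardinal half-lines, and PD is the literal inverse of the mean of the four
distances (units m⁻¹). Two conventions had to be fixed:

- *Axis ties.* A perch exactly on a cardinal axis belongs to the
  clockwise-next quadrant (N axis → NE, E → SE, S → SW, W → NW). Any
  consistent rule works; this one is branchless to state and test.
- *Empty quadrants* substitute a configurable ceiling `max_radius_m`
  (default 100 m) and flag the record. Dropping the quadrant instead would
  bias density upward, since quadrants are empty precisely where perches
  are far.
- A perch coincident with the bird floors that distance at 0.1 m and flags
  the record rather than producing an infinite density.

The classical point-centred quarter estimator of *areal* density is
`1 / mean(d)²` per m²; the inverse-mean form is what the escape analysis
uses, but `classical=True` switches to the areal form for sensitivity
analysis.

**Route connectivity (RC).** A 10 m wide rectangle is spanned from the
initial position to the refuge; a grid (default 1 m spacing) is laid out in
the **rectangle's local frame** — rows along the route axis, columns across
it, the first row half a spacing in from the initial end. RC is the
fraction of grid points whose raster cell holds cover. Local-frame
anchoring makes RC invariant to where the encounter sits on the map (a
world-aligned grid would make RC depend on the route's phase relative to
the raster); the grid-in-GIS workflow the metric descends from is ambiguous
on this, so the choice is the package's own. Points falling outside the
raster count as non-vegetated and are flagged, never dropped — the
denominator stays "all points within the escape route". Flights of ≤ 5 m
take RC = 1.0 exactly, with `n_grid_points = 0` recorded as a sentinel: at
that range the bird never leaves its immediate surroundings.

At 1 m spacing on a half-plane landscape RC is within one grid column of
the analytic vegetated area fraction, and it converges to the exact
fraction as the spacing shrinks (tested at 1, 0.5 and 0.25 m).

*A consequence of the ≤ 5 m rule worth knowing:* short flights carry
RC = 1.0 regardless of the landscape, so any regression of distance fled on
RC that includes short flights inherits a negative association purely from
the convention. The hazard-equality null test in the suite therefore
conditions on flights > 5 m; the emergent-effect study does not need to,
because its effect has the same sign as the artefact and is far larger.

## Starting-distance adjustment

FID rises with starting distance (StD) and cannot exceed it, so StD and FID
are strongly collinear. Each observation is mapped to its expected FID at
the species' mean StD: `FID_adj = FID + β̂ (x̄_StD − StD)` with `β̂` the
per-species OLS slope of FID on StD. On the fitting sample `FID_adj`
preserves the mean FID and has exactly zero Pearson correlation with StD
(both identities are asserted to 1e-8 in the tests). The slope is fitted on
the post-exclusion analysis set — excluded rows should not inform the
adjustment — and negative adjusted values are left as they are, since
Model 2 uses FID_adj only as a z-scaled covariate.

## Exclusion cascade

Row filters run in a fixed order: non-responses, then escapes by walking or
running, then rows whose refuge could not be determined; species counts are
taken **after** these row filters and a species needs strictly more than 20
FIDs to enter analysis. The report partitions the input exactly (an
invariant under test) and exposes counts at every stage, so alternative
orderings of the narrative percentages can be audited. Field-protocol
checks — perches above the 10 m sampling ceiling, FID exceeding StD,
same-species samples within 50 m of an earlier one — emit warnings only and
never drop rows.

## Mixed models

Both models include the park (location) of the approach as a Gaussian
random intercept; predictors are centred and scaled to sample SD 1 before
fitting, and interaction columns are products of the scaled main effects.

- **Gaussian** (identity link, optionally on log distance): REML linear
  mixed model via `statsmodels` MixedLM. Wald t statistics with residual
  degrees of freedom n − p; MixedLM's lbfgs can fail on a singular profile
  Hessian when the random variance sits at zero, so the fit falls through
  powell and Nelder–Mead before giving up.
- **Poisson / negative binomial** (log link): the random-intercept
  likelihood is maximised under a **Laplace approximation** written in the
  package — per park a one-dimensional Newton search finds the conditional
  mode of the intercept (vectorised across parks), and L-BFGS-B maximises
  the resulting approximate likelihood over (β, log σ_b, log α). The NB is
  the quadratic NB2 form, Var = μ + αμ², with α estimated by maximum
  likelihood. Wald covariance comes from a finite-difference Hessian of the
  Laplace objective; z statistics and 95 % CIs follow. On a test dataset
  the fit agrees with glmmTMB's NB mixed model to four decimals in every
  coefficient, SE, the random SD and α; the suite keeps an lme4 `glmer`
  Poisson cross-check as an independent oracle.
- **Boundary variance.** A random SD estimated below 1e-3 is flagged; the
  σ direction is dropped from the Wald Hessian (it is flat there) and a
  fixed-effects-only fit is attached to the result for comparison, never
  silently substituted.
- **Diagnostics.** Collinearity: all pairwise Pearson correlations among
  predictors, flagged above |r| = 0.5. Overdispersion: Pearson χ²/df of the
  conditional Poisson fit; a ratio above 1.5 (configurable) recommends the
  NB refit, and the pipeline applies it automatically. Influence: one-step
  Cook's distances from the conditional IRLS weights; rows above 4/n
  (configurable) are removed and the model refitted, reporting whether any
  term's classification changes; a refit on fewer than 10 rows is refused.
- **Effect classification:** significant at p < 0.05, trend at
  0.05 ≤ p < 0.10, none otherwise (boundaries exactly as stated).

## Synthetic data

**Tabular mode** draws covariates directly — StD uniform on 15–60 m, RC
from Beta(2, 2) (smooth coverage of [0, 1] without boundary spikes), PD
log-normal (log-mean −2, log-SD 0.7, median ≈ 0.14 m⁻¹) — and the two
responses from the generative counterparts of the models: FID is
`5 + 0.3·StD` plus a park effect and truncated-normal noise (SD 3 m),
resampled into the open interval (1 m, StD) rather than clipped, so no
boundary mass accumulates; distance fled has log mean
`2.5 + β·z-covariates + park effect` under a gaussian (log-normal,
residual SD 0.5), poisson or NB2 (α = 0.5) family. Default effects are a
route-connectivity coefficient of −0.5 — the magnitude shared by the five
study species — and zero for everything else. Park effects are mean-zero
Gaussian (SD 0.3) and shared between the two responses of a park, mirroring
the single location random factor. Exclusion flags are drawn at the
observed field rates (6.2 % non-response, 0.6 % walk/run, 2.3 %
refuge-unknown). Empirical means and variances of the distance response
match the families' closed-form moments (tested at n = 5000).

**Spatial mode** places birds uniformly on a raster, simulates the observer
approach for FID as above, then walks the escape in 1 m steps (matching the
1 m metric grid) in a direction away from the observer with ±30° jitter
(or uniform, for robustness checks). At each step the bird stops with
probability 0.4 inside cover and 0.02 in the open (per metre); on an
all-cover raster with hazard p the distance fled is geometric with mean
1/p, which the tests verify against the closed form. Initial and refuge
coordinates are stored so the metrics stage can recompute RC and PD from
geometry alone; the recomputed RC equals the generation-time value (CSV
round-trips use exact float parsing, since a 1-ulp error can flip the
route grid's row count at integer route lengths).

**Landscapes** are circular vegetation patches (gamma-distributed radii,
mean 12 m) stamped until the realised cover fraction is within ±0.05 of
target, with an overshoot guard that shrinks a patch that would exceed the
band; perches fall as a uniform Poisson process (default 40/ha).

*What the generator does not emulate:* flock dynamics, predator pursuit,
directed flight toward specific refuges, perch-height effects on PD,
spatially autocorrelated perch clustering, observer measurement error. A
passing suite shows the estimators and pipeline are correct and calibrated
under the stated statistical structure, not that field data satisfy that
structure.

## Validation studies (sizes and expectations)

- *Parameter recovery:* 100 simulations, NB family, β_RC = −0.5, 20 parks
  × 15 encounters. Expected: 95 % Wald CI covers the truth ≥ 88/100;
  negative sign ≥ 97/100.
- *Null calibration:* 400 simulations with all effects zero, gaussian
  (log-normal distance) family — chosen because its Wald tests are exactly
  calibrated at this n, so the study isolates pipeline type-I control from
  likelihood-approximation error. Expected: each term significant at
  5 % ± 2 %.
- *Spatial emergence:* 100 replicates, fresh landscape each, hazards
  0.4/0.02 per metre, 10 parks × 15 encounters; OLS slope of log distance
  fled on z-scaled RC. Expected: negative in ≥ 95/100. Mean slope ≈ −1.25
  per SD of RC — stronger than the tabular default because the hazard
  contrast is extreme.

These sizes run in roughly a minute total on one CPU and are the same in
the test suite and the acceptance script.

## Known limitations

- The Laplace approximation is least accurate for few parks with small
  counts; adaptive quadrature is not implemented (lme4's `nAGQ > 1` would
  be the reference there).
- Gaussian mixed-model p-values use a residual-df t approximation, not
  Satterthwaite/Kenward–Roger.
- RC treats the raster as ground truth; digitisation error in real cover
  maps propagates directly into RC.
- The exclusion narrative's refuge-unknown percentage is reported against
  flight responses (as field studies quote it) while non-response and
  non-flight are against all approaches; both bases are in the report.
- Geographic coordinates must be projected to planar metres upstream;
  the package never touches latitude/longitude.
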