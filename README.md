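# fidescape

Escape behaviour of urban woodland birds is shaped by the habitat in which
an escape happens: where protective cover and perches are sparse, a fleeing
bird must travel further before it can stop, and the *cost* of escape rises.
`fidescape` is an analysis pipeline for testing this **habitat connectivity
hypothesis of escape** with flight-initiation-distance (FID) field data. It
is written for behavioural ecologists who collect FID approaches (one row
per human approach to a focal bird) together with simple spatial layers
(a 1 m boolean vegetation raster and a perch point layer).

The pipeline has five parts:

1. **Connectivity metrics** (`fidescape.metrics`)
   - *Perch density* (PD, m⁻¹) at the bird's initial position: an adapted
     point-centred quarter estimate, `PD = 1 / mean(d₁…d₄)` with `dᵢ` the
     distance to the nearest perch in each cardinal quadrant (empty
     quadrants substitute a configurable 100 m ceiling).
   - *Route connectivity* (RC ∈ [0, 1]): the proportion of points of a
     1 × 1 m grid, laid over a 10 m wide rectangle spanning the escape route
     (initial position → refuge), that fall in vegetation or perchable
     infrastructure. Flights ≤ 5 m take RC = 1.0 by convention.
2. **Starting-distance adjustment** (`fidescape.fid_adjust`): per species,
   `FID_adj = FID + β̂ · (mean(StD) − StD)` with `β̂` the OLS slope of FID
   on starting distance — the expected FID at the species' mean StD, exactly
   uncorrelated with StD on the fitting sample.
3. **Exclusion cascade** (`fidescape.filtering`): non-responses → non-flight
   escapes → refuge-unknown rows → species with ≤ 20 FIDs, with a report
   that partitions the input exactly.
4. **Mixed models** (`fidescape.glmm`): per species,
   - Model 1: `FID ~ RC + PD + StD + (1 | park)`
   - Model 2: `distance fled ~ FID_adj * (RC + PD) + (1 | park)`
   with z-scaled predictors, gaussian / poisson / negative-binomial (NB2)
   families, Wald inference, collinearity and overdispersion checks, and a
   Cook's-distance influence refit. The poisson/NB random-intercept
   likelihood is maximised under a Laplace approximation implemented in the
   package; gaussian models use REML via `statsmodels`.
5. **Synthetic data** (`fidescape.simulate`): landscapes, perch layers and
   encounter tables with known ground truth — either drawn directly from
   the generative models (*tabular* mode, for parameter-recovery studies)
   or produced mechanistically by escape walks with cover-dependent
   stopping hazards on a raster (*spatial* mode, for end-to-end tests).

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (all outputs under `results/`):

```sh
python analysis/01_simulate.py --seed 0       # landscape + 5-species community
python analysis/02_connectivity_metrics.py    # PD and RC per encounter
python analysis/03_filter_and_adjust.py       # exclusions + FID adjustment
python analysis/04_fit_models.py              # per-species mixed models
python analysis/05_validation_studies.py      # seeded validation studies
```

`03` prints the exclusion narrative:

```
301 approaches; 24 non-responses (8.0%), 2 non-flight escapes, 6 refuge-unknown;
0 rows in species with <= 20 FIDs; 269 retained
```

`04` fits both models per species; an excerpt of the rendered table:

```
Model 2: distance fled ~ FID_Adj * (RC + PD) + (1 | park)
Model                            Parameter     Estimate       SE      z/t         P  Lower CI  Upper CI
common_myna (Poisson)            FID_Adj          0.304    0.053    5.774     0.000*     0.201     0.407
                                 RC              -0.575    0.060   -9.626     0.000*    -0.693    -0.458
noisy_miner (negative binomial)  RC              -0.775    0.075  -10.268     0.000*    -0.923    -0.627
```

Every species shows the negative route-connectivity effect on distance fled
that its generator imposed (here −0.74 to −0.40 on the log scale), and the
one species simulated with a positive FID_adj effect (common myna, +0.25)
recovers it. `05` summarises the three validation studies:

```
recovery: CI coverage 98/100, negative sign 100/100, mean estimate -0.505 (truth -0.5)
null calibration: per-term significant rates {'FID_Adj': 0.062, 'RC': 0.043,
  'PD': 0.04, 'FID_Adj:RC': 0.043, 'FID_Adj:PD': 0.04} (nominal 0.05)
spatial emergence: negative RC slope in 100/100 replicates, mean slope -1.252
```

The third study is the strongest check: escape walks stop with hazard
0.4/m inside cover versus 0.02/m in the open, and the negative relationship
between route connectivity and log distance fled *emerges* from that
mechanism — no distance-fled effect is imposed anywhere.

## Layout

```
src/fidescape/     library: geometry, raster, metrics, fid_adjust,
                   filtering, glmm, simulate, studies, pipeline, report
analysis/          numbered drivers (the shell interface) and run_all.py,
                   a config-driven end-to-end runner (exit codes: 0 ok,
                   2 config error, 3 data validation, 4 non-convergence)
scripts/           acceptance.py
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    models, assumptions, parameter choices, limitations
```
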