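# critspeed

Estimation of **critical speed (CS)** and **d′** from exhaustive
constant-speed running trials, with statistically appropriate fitting
procedures, an agreement battery for comparing procedures, and a
synthetic-cohort simulator.

CS is the asymptote of the speed–duration relationship — the boundary
between the heavy and severe exercise-intensity domains, widely used by
researchers and coaches to prescribe training intensity.  d′ is the
finite distance a runner can cover above CS before exhaustion.  Both
come from fitting a two-parameter model to a handful of time-to-
exhaustion trials:

    t(s) = d′/(s − CS)     d(s) = s·d′/(s − CS)
    s(t) = d′/t + CS       d(t) = d′ + CS·t

The four forms are mathematically equivalent, but least squares
minimises error along the vertical axis only.  In a fixed-speed
protocol the measured, error-carrying variable is the time to
exhaustion (with variance proportional to its magnitude), so the
statistically appropriate procedures are **t(s) and d(s) under weighted
least squares** (weights ∝ 1/t and 1/(s²t)); **s(t) under LS** puts the
error on the wrong axis, and **d(t) under LS** is endogenous (distance
error = speed × time error).  This package fits all four — the
inappropriate ones deliberately, to quantify what using them costs —
and classifies any directed form for any design (fixed speed, distance
or time).  See `docs/methods.md` for the full model description.

## Worked example

Fit all four procedures to one simulated runner (CS 4.39 m/s,
d′ 226 m, four trials at 90–120% of peak speed with Var(t) ∝ t noise):

```sh
python examples/02_fit_four_procedures.py
```

```
truth: CS = 4.39 m/s, d' = 226.0 m
procedure         CS (m/s) d_prime (m)   %SEE      RSE
t(s) using WLS       4.399       202.4   3.26    9.783
d(s) using WLS       4.399       202.4   3.26   52.350
s(t) using LS        4.394       202.7   6.22    0.056
d(t) using LS        4.399       201.7   3.38    9.642
```

CS is recovered to ~0.01 m/s by the appropriate procedures; d′, the
curvature of only four points, scatters more.  The RSE column is in the
units of each procedure's vertical axis (s, m, m/s, m) and must not be
compared across rows — the tiny RSE of s(t)-LS is an artefact of
putting speed on the vertical axis, not a better fit.

The other examples cover the speed–duration curve and peak-speed
computation (`01`), cohort simulation and parameter recovery (`03`),
the Bland–Altman/RM-ANOVA agreement battery (`04`), and the
procedure-selection decision table (`05`).

A thin CLI wraps the same functions:

```sh
critspeed simulate --out cohort.csv --seed 1
critspeed fit --input cohort.csv --out fits/
critspeed compare --input fits/estimates.csv --out report/
critspeed recommend --fixed speed
```

## Library layout

| module | contents |
|---|---|
| `critspeed.models` | the four model forms, trial/subject containers, peak speed |
| `critspeed.fitting` | LS/WLS Levenberg–Marquardt fits, SEE, %SEE, RSE |
| `critspeed.agreement` | Bland–Altman battery, Durbin–Watson, Shapiro–Wilk, RM-ANOVA + Holm |
| `critspeed.selector` | appropriateness classification of all six directed forms |
| `critspeed.cohort` | synthetic cohorts with Var(t) ∝ t noise; CSV round trip |
| `critspeed.pipeline` | cohort-level fit tables, summaries, comparison reports |

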