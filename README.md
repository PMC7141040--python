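# semrec

Seminal-recovery analysis for cross-sectional depletion experiments in
decapod crustaceans — built around the male kelp crab design: deplete the
vasa deferentia by electroejaculation at day 0, hold males under crossed
temperature (12/16 °C), food (ad libitum / deprived) and time (15/30 d)
treatments, sacrifice each group once, and ask how much of the seminal
stock was rebuilt and what it cost in energy reserves.

## What it computes

**Recovery index (RI).** With VDW the paired vasa deferentia dry weight
(mg), E the electroejaculated animals, C the intact controls, and t₀/t₁ the
start and end of a holding period:

    A  = mean VDW(E, t1) − mean VDW(E, t0)     increment regained
    B  = mean VDW(C, t0) − mean VDW(E, t0)     amount to be recovered
    RI(%) = A / B × 100

RI is a function of group means (the design is cross-sectional: each group
is a different set of sacrificed animals). RI > 100 % is overcompensation;
negative RI is reported, not clamped.

**Uncertainty.** Stratified case resampling (with replacement, within each
of the three groups, original sizes preserved; B = 1,000) with
bias-corrected accelerated (BCa) 95 % intervals: bias term z₀ from the
replicate distribution, acceleration a from a delete-one jackknife. Two
indices are declared significantly different only when their intervals do
not overlap.

**Hepatosomatic index (HSI)** = hepatopancreas / whole-body dry weight ×
100, the energy-reserve indicator. Inference on HSI is by permutation: a
full-factorial ANOVA (sequential sums of squares, unrestricted response
permutation, per-term p = (b+1)/(m+1) with a sequential stopping rule and
exact enumeration for small designs) and two-group permutation contrasts
against the day-0 baseline.

A synthetic-data generator reproduces the study design (group sizes,
means ± SE, within-group normal variation) so the whole pipeline runs and
is tested without any external data. Classical companions (one-way ANOVA,
OLS regression reporting adjusted R², one-way ANCOVA, Bartlett and
Shapiro–Wilk diagnostics) are included.

## Worked example

```python
from semrec import RecoveryIndexInput, compute_ri

inp = RecoveryIndexInput.from_groups(
    control_t0=[80.0, 88.0, 82.0, 86.0],   # mean 84 mg
    ee_t0=[50.0, 54.0, 48.0, 56.0],        # mean 52 mg
    ee_t1=[100.8, 108.8, 102.8, 106.8],    # mean 104.8 mg
)
res = compute_ri(inp)
print(f"A = {res.A:.1f} mg, B = {res.B:.1f} mg, RI = {res.ri:.1f} %")
```

prints `A = 52.8 mg, B = 32.0 mg, RI = 165.0 %`: the group rebuilt 165 % of
the depleted stock — 65 % more seminal material than the intact controls
held at day 0. Bootstrapping the same cell on a simulated study
(`examples/02_bootstrap_ci.py`) prints

```
30d_16C_deprived       RI =  168.0 %   95% BCa CI [ 136.9,  227.4]   (z0=+0.021, a=+0.019, 0 invalid replicates)
15d_12C_deprived       RI =    3.1 %   95% BCa CI [ -37.5,   34.2]   (z0=+0.038, a=+0.009, 0 invalid replicates)
intervals disjoint -> significantly different: True
```

— the interval for a cold, food-deprived group after 15 days covers 0 %
(no detectable recovery), the warm deprived group at 30 days sits far above
100 %, and the non-overlap rule calls them significantly different.

The `examples/` directory has one short script per capability (indices,
bootstrap intervals, permutation tests, full pipeline). A thin CLI mirrors
the stages:

```bash
semrec simulate --seed 42 --out study.csv
semrec ri --in study.csv --cell 16,deprived,30 --bootstrap 1000 --seed 1
semrec anova --in study.csv --seed 1
semrec report --seed 42 --out out/      # full bundle + JSON manifest
```

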