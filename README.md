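# scopetrack

Tools for linking laboratory metabolic phenotypes of individual fish to
their volitional activity in the wild, built around three components:

1. **Respirometry** — extract standard metabolic rate (SMR), maximal
   metabolic rate (MMR), aerobic metabolic scope (AMS = MMR − SMR) and
   seven secondary traits from intermittent-flow respirometry traces,
   using the uptake equation `MO2 = K·V·β/M` with per-cycle OLS slopes,
   an r² ≥ 0.90 quality filter and constant background correction.
2. **Telemetry** — turn 30 s-burst acoustic position fixes into daily
   moved distance (A_day), instantaneous and daily-maximal swimming speed
   (U_inst, U_max, filtered to fixes classified active at p_active ≥ 0.75
   by a two-state step-length hidden Markov model) and daily covered area
   (AR_day, a merged 0.5 m track buffer).
3. **Mixed models** — random-intercept LMMs with a separate residual
   variance per fish, `y_ij = α + β_FL·FL_j + β_X·X_j + a_j + ε_ij` with
   `a_j ~ N(0, σ_a²)`, `ε_ij ~ N(0, σ_j²)`, giving fish-specific
   repeatability `ICC_j = σ_a²/(σ_a² + σ_j²)`; AIC/LRT model selection
   under ML with REML refits for reported estimates.

Because raw data of this study design are typically not public, the
package includes a synthetic-data generator that emulates the full design
(cohort distributions, chase-recovery traces, two-state switching tracks
with positional noise) with recorded ground truth, so every estimator is
validated by parameter recovery. See `docs/methods.md` for the models,
assumptions and known limitations.

## Worked example

```python
from scopetrack import SimConfig, generate_cohort, traits_from_trace, ActivityHMM
from scopetrack.synthetic import simulate_respirometry_trace, simulate_track

cfg = SimConfig(n_fish=4, seed=42, n_days_track=2)
cohort = generate_cohort(cfg)
p = cohort[0]

traits = traits_from_trace(simulate_respirometry_trace(p, cfg))
print(f"SMR {traits.smr:.1f}  MMR {traits.mmr:.1f}  AMS {traits.ams:.1f}")

track = simulate_track(p, cfg)
fit = ActivityHMM.from_fixes(track.fixes.drop(columns=["true_state"])).fit(seed=11)
print(fit.summary())
```

prints

```
SMR 88.9  MMR 267.2  AMS 178.4
Two-state activity HMM (Baum-Welch)
============================================
log-likelihood      -3881.560
iterations          10 (converged: True)
sigma_noise         0.2000 m
inactive mean step  0.3545 m
gamma shape/scale   1.900 / 1.9887
active mean step    3.7793 m
P(in->act)          0.0481
P(act->in)          0.1050
stationary P(act)   0.3144
```

Fish F01's extracted SMR (88.9 mg O2 kg⁻¹ h⁻¹) sits within 1% of its
generating value (88.3); MMR is recovered to ~7% (the chase-recovery decay
means the first measurement cycle averages slightly below the instantaneous
maximum). The HMM recovers the simulated positional noise exactly
(σ_noise = 0.2 m) and the switching rates (true 0.05/0.10), and its
stationary active probability (0.31) matches s/(s+r) of the generating
chain.

The same stages run from the shell:

```sh
scopetrack simulate --out-dir cohort --n-fish 23 --seed 1
scopetrack respiro --trace-dir cohort/traces --mass-table cohort/phenotypes.csv --out traits.csv
scopetrack phenotype --traits traits.csv --phenotypes cohort/phenotypes.csv
scopetrack run-all --out-dir run1 --seed 1        # full pipeline + reports
```

`run-all` writes the trait table, PCA loadings, per-fish-day activity,
model-selection grids and optimal-model summaries (with per-fish ICCs),
plus a manifest (config hash + seed) that makes the run bit-reproducible.

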