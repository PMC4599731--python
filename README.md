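# smoltroutes

Tools for studying fine-scale marine migration routes of juvenile salmonid
smolts (sockeye, steelhead) from acoustic telemetry detections at
cross-strait receiver "curtains", and for linking route variability to
apparent survival further along the migration corridor.

The package targets the data situation at the northern Strait of Georgia
(NSOG) line: 27 receivers spaced ~0.8 km apart spanning Malaspina Strait
(receivers 1–7, east of Texada Island) and the Strait of Georgia proper
(receivers 8–27), with an ~8 km gap at the island. Smolts detected there may
later be detected at the Queen Charlotte Strait (QCS) line ~250 km downstream;
any QCS detection defines apparent survival S_QCS.

## What it computes

1. **Detection sequences.** Raw pings are collapsed into maximal runs where
   consecutive detections are < 1 h apart and ≤ 1.6 km apart along the
   curtain.
2. **Route classification.** Comparing where a smolt's first sequence ended
   with where its second began: second sequence west → *counterclockwise*,
   east → *clockwise*, same receiver (or a single sequence followed by a QCS
   detection) → *linear*. Lateral displacements Δx₁₂ and Δx₂₃ are signed km
   (east positive, 0.8 km per receiver, +8.0 km for island-spanning moves).
3. **Hypothesis statistics.** Width-weighted binomial tests of strait use,
   signed-rank tests of Δx against zero, rank-sum species comparisons,
   Kendall τ-b of displacement vs milling duration, release-group-weighted
   ANOVA of route proportions with Tukey HSD, Fisher's exact survival×strait
   test, and Pearson confounding checks against migration rate.
4. **Survival GLMs.** Binomial models of S_QCS with predictors standardized
   by two sample SDs, all-subsets enumeration under marginality, AICc
   ranking, and coefficient averaging (zero-substitution, Burnham–Anderson
   unconditional SEs) over the ΔAICc ≤ 2 set:

   AICc = −2·logLik + 2k + 2k(k+1)/(n−k−1),  wᵢ ∝ exp(−ΔAICcᵢ/2),
   β̄ⱼ = Σᵢ wᵢ βᵢⱼ (βᵢⱼ = 0 when model i omits term j).

5. **Synthetic cohorts.** A seeded agent-based generator emulating the study
   system (release groups, ~1 BL/s ground speeds clamped to 13–17 km/day,
   Malaspina-skewed arrivals, westward loop behaviour, V7/V9 detection
   efficiencies, hazard-based mortality with logistic covariate modifiers)
   together with a per-fish ground-truth table.

## Worked example

```python
from smoltroutes import SimulationConfig, simulate, sequence_frame, \
    build_route_records, route_tallies, SurvivalModel
from smoltroutes.io import Detection

cfg = SimulationConfig()           # release groups mirror the study cohorts
dep, det, truth = simulate(cfg, seed=1)
dets = [Detection(r.tag_id, r.array, int(r.receiver), r.timestamp)
        for r in det.itertuples(index=False)]
seqs = sequence_frame(dets, {"NSOG": cfg.geometry})
records = build_route_records(seqs, dep, cfg.geometry)
print(route_tallies(records)[["species", "population", "release_year",
                              "n_linear", "n_counterclockwise", "n_clockwise"]].head(3))
results = SurvivalModel(records, "sockeye", "entry").fit()
print(results.summary())
```

prints (seed 1) the per-group route tallies

```
  species population  release_year  n_linear  n_counterclockwise  n_clockwise
  sockeye     Cultus          2004        23                  19           14
  sockeye    Sakinaw          2004        25                  14            6
  sockeye     Cultus          2005        86                  68           36
```

and a model summary whose header reads

```
Apparent-survival GLMs (sockeye, entry set)
n = 2263 smolts, 13 converged candidate models, 3 within ΔAICc <= 2
```

followed by the AICc ranking table and the averaged coefficients; with the
default generator settings the standardized entry-position coefficient
(`P_initial`, west positive) is positive with a 95% CI excluding zero —
smolts entering along western receivers survive better, as configured in the
generator's mortality model.

The same stages are available from a shell:

```bash
smoltroutes simulate --seed 1 --out run/
smoltroutes sequence --detections run/detections.csv --out run/sequences.csv
smoltroutes classify --sequences run/sequences.csv --deployments run/deployments.csv --out run/route_records.csv
smoltroutes stats    --records run/route_records.csv --out run/
smoltroutes survive  --records run/route_records.csv --out run/
smoltroutes report   --seed 1 --out run/
```

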