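# Methods

## The observation model

A receiver curtain turns a continuous migration into a sparse sequence of
(tag, receiver, time) triples. Two conventions anchor everything else:

* **Receiver axis.** Indices are 1-based from the easternmost receiver and
  increase westward; one fixed east-positive axis is used package-wide, so a
  westward movement always carries a negative sign.
* **Distance.** Adjacent receivers are 0.8 km apart; the island gap between
  receivers 7 and 8 contributes 8.0 km. For the analytical displacement
  Δx the gap is *added* to the 0.8·|Δindex| magnitude (a 7→8 move is
  −8.8 km), which follows the stated adjustment rule; chainage (used by the
  simulator and by the sequencing step rule) treats the gap as 8.0 km total.
  `gap_mode="replace"` makes Δx match chainage for sensitivity checks.

## Detection sequences

A sequence is a maximal run of one tag's detections at one array with
consecutive gaps strictly less than 1 h and steps of at most 1.6 km of
chainage. Boundary conventions: a gap of exactly 60 min breaks, a step of
exactly 1.6 km retains. Because the step rule is metric, the pair flanking
the island gap always breaks a sequence even though the indices are
adjacent; `step_mode="index"` restores the two-receiver index rule.
Detections sharing a timestamp are ordered by receiver index before
segmentation so output is deterministic. The greedy left-to-right
segmentation provably yields the unique minimum-cut valid partition (the
rules are pairwise-local); the test suite checks this against exhaustive
boundary enumeration and an independent dynamic program.

## Route classes and covariates

With ≥ 2 sequences at the upstream curtain the route is read from the first
sequence's last receiver vs the second sequence's first receiver: west →
counterclockwise, east → clockwise, equal → linear. A single sequence
followed by a downstream detection is linear; a single sequence with no
downstream detection is *unclassified* — the three behavioural classes
cannot cover such fish, and they are excluded from route-proportion
denominators. Fish detected on the westward-exit (Juan de Fuca) curtain are
tallied separately and excluded from upstream analyses. Apparent survival
is the bare downstream-detection indicator and confounds death with
non-detection; no detection-efficiency correction (e.g.
Cormack–Jolly–Seber) is attempted, deliberately.

## Hypothesis statistics

Exact null distributions are used for the binomial, signed-rank and
rank-sum tests whenever n ≤ 25 and the data are tie-free; otherwise the
normal approximation with continuity correction. Signed-rank tests drop
exact zeros (classical convention) while zeros remain in reported means.
Kendall's correlation is the tie-corrected τ-b. The route-proportion ANOVA
treats release groups as replicates and weights each group by its number of
route-classified fish, applied as case weights; Tukey HSD comparisons use
the weighted model's error variance with group total weight as effective
group size (Tukey–Kramer, studentized-range reference distribution).
Fisher's exact test reports the conditional maximum-likelihood odds ratio.
No multiplicity correction is applied across the battery.

## Survival GLMs and multi-model inference

Continuous predictors are standardized to (x − mean)/(2·SD) so their
coefficients are comparable to binary predictors'. Two candidate families
are fitted per species: an *entry* set (initial receiver position, Julian
arrival day, population, plus fork length and release year for steelhead,
with population × Julian and population × position interactions) over all
detected smolts, and a *lateral* set (Δx₁₂, inter-sequence duration, and the
same auxiliary terms) over smolts with ≥ 2 sequences. Sockeye omit fork
length and year (collinear with population); steelhead lateral models drop
the Seymour population (too few multi-sequence fish). Every
marginality-valid subset of the full term list is fitted by IRLS (deviance
tolerance 1e-8); quasi-separated or non-converged fits are flagged and
excluded from averaging. Candidates are ranked by AICc with k counting all
estimated coefficients including the intercept and n the number of smolts
in the set.

Coefficients are averaged over the ΔAICc ≤ 2 set with renormalized Akaike
weights. The primary estimator is the full (zero-substitution) average —
absent terms contribute zero — because it yields the shrunken "relative
effect size" reading appropriate for effect screening; conditional
(subset) averages are emitted alongside, since both are standard and give
identical answers when a term appears in every top model. Unconditional
standard errors follow Burnham–Anderson,
SE = Σ wᵢ·sqrt(seᵢ² + (βᵢ − β̄)²), and 95% CIs are Wald intervals.
Model fit is summarized by McFadden's pseudo-R² and the penalized variant
1 − (logLik − k)/logLik_null. Prediction curves invert the averaged linear
predictor along one variable's observed range (per population when
population terms are present), holding other covariates at their means.

Categorical coding is treatment coding with the alphabetically first level
as reference, for determinism. Averaging operates on design columns, so
each population contrast is averaged separately.

## The synthetic-data generator

The generator produces the statistical structure the analysis assumes — it
is an observation-process emulator, not an ocean model. Movement is
one-dimensional along-migration plus discrete east-west crossing positions;
counterclockwise behaviour is an imposed class, not an emergent property of
a current field (a `current_drift_km_per_day` hook superimposes ambient
drift on loop amplitudes for sensitivity tests).

Defaults and their grounds:

| parameter | default | rationale |
|---|---|---|
| release groups | 21 groups, 2737 sockeye + 728 steelhead | the study's printed cohort table |
| ground speed | 1 BL/s, clamped 13–17 km/day | reported achieved speeds over ground |
| behaviour probabilities | linear 0.65, ccw 0.25, cw 0.10 | reported sockeye route mix |
| arrival distribution | 66% Malaspina (receivers 1–7), uniform within strait | reported eastern-channel share; the within-strait shape is unreported and is a modelling choice exposed in config |
| loop amplitude | lognormal, median 7 km (SD of log 0.7), floor 1.8 km | reported Δx₁₂ spread (~9 km SD) |
| dwell between crossings | lognormal, median 45 h (SD of log 1.0), floor 1.1 h | reported ~70 h mean inter-sequence durations; the floor keeps crossings in distinct sequences |
| third-crossing probability | 0.5 | roughly half of multi-sequence fish showed a third sequence |
| detection efficiency | V7 0.675, V9 0.90 | reported 60–75% / ~90% array efficiencies, applied per crossing |
| baseline daily hazard | 0.058 d⁻¹ | gives ~39% survival over the ~16-day transit, matching the detected-to-downstream ratio |
| westward-exit probability | 0.014 | <2% reported use of the Juan de Fuca route |

Mortality before the downstream curtain is a single Bernoulli draw per fish
with log-odds logit(exp(−h·T)) + β_strait·[SOG] + β_p·z(P) + β_j·z(Julian) +
β_d·z(dwell), where T is the 250 km transit at the fish's speed and z is the
two-SD standardization computed from the simulated cohort (per species;
non-milling fish contribute zero to the dwell term). With all β = 0 the
realized survival equals the closed form exp(−h·T), which the tests verify.
Default modifiers (β_p = +0.5, β_j = −0.3, β_d = −0.8) reproduce the
qualitative findings — western entrants and brief millers survive better —
at plausible standardized magnitudes.

Two deliberate geometric conveniences: a looper drawn at an array-end
receiver whose loop direction would leave the array has its entry receiver
nudged one slot inward, and within-crossing receiver drift never crosses the
island gap. Both keep the generator's declared behaviour class always
expressible in the detections, which is what makes exact route-recovery
checks possible.

What the generator does **not** emulate: mortality (or non-entry) between
release and the upstream curtain, so simulated per-group detection counts
are far higher than the study's; tidal/rotary current fields; depth;
receiver-level detection-radius physics (detection is per-crossing
Bernoulli); clock drift and false detections. Passing recovery tests
therefore demonstrates correctness of the *analysis* under the assumed
observation process, not realism of the movement model.

## Numerical and design notes

* Transit times: with 250 km between curtains and 13–17 km/day over ground,
  simulated downstream transits are ~15–19 days plus milling. The reported
  ~12.5-day mean transit would require ~20 km/day over that distance; the
  generator preserves the stated speeds and distance rather than the
  transit summary, since the former are mechanistic inputs.
* Within-sequence drift tests are one-sample; they are implemented as
  Wilcoxon signed-rank against zero.
* The sequencing 1-hour rule is applied strictly (exactly one hour breaks);
  the source wording does not fix the boundary case.
* Problem sizes: oracle-agreement suites run 500 random detection strings
  (n ≤ 30) and exhaustive small-n enumerations; simulation recovery uses
  2000-smolt cohorts and 50 replicates for the GLM coefficient, sizes at
  which binomial error is well inside the stated tolerances.
* Degenerate inputs: constant responses, constant predictors, zero-margin
  contingency tables, all-zero displacement vectors and empty candidate sets
  raise or warn explicitly rather than returning silent NaNs.

## Known limitations

Apparent survival confounds mortality with non-detection, and aliasing from
imperfect detection (missed first crossings) deflates the counterclockwise
share and manufactures spurious clockwise classifications — the package
quantifies this on synthetic cohorts (acceptance script: ccw share at V7
efficiency vs perfect detection) but cannot correct it. The weighted Tukey
HSD uses group total weight as effective sample size, an approximation
adequate for screening. Adjusted pseudo-R² can exceed neither R² nor its
unpenalized reading; no attempt is made to reproduce alternative fit
metrics. Real deployments with unmodelled heterogeneity (tag failure,
shed tags, predation of tagged fish) will violate the generator's
assumptions in ways the tests do not probe.
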