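# Methods

## Dosing model

All internal quantities are canonical: µg, ml, kg, s, dose rates in
µg/kg/min. A continuous-infusion preparation is fully described by the
final syringe concentration *C* (µg/ml) and volume *V* (ml); the pump rate
for a prescription *d* (µg/kg/min) at weight *w* (kg) is

    r = 60 · d · w / C   [ml/h],

and the inverse map gives the delivered dose of any executed preparation,
`delivered = C_executed · r_executed / (60 · w)`. Mass conservation
(`C · V = stock_concentration · stock_volume`) is an invariant of every
plan object, checked to 0.1% relative.

### Concentration selection

How a guided preparation system picks *C* is a genuine design choice; we
use target-rate-band selection. The preferred concentration is the
rate-table value `C = 60 · scale · w` (see below), which maps round
prescriptions to round pump rates; if that leaves the configured
comfortable band (default 1–20 ml/h), requires more stock volume than the
syringe holds, or needs more than `max_vials` vials, the planner scales the
concentration by 2/5/10-structured factors, trying candidates in order of
increasing departure from the preferred value. Admissible final volumes
default to {20, 50} ml. A genuinely unsatisfiable order raises an explicit
infeasibility error rather than silently producing an unpumpable rate.

### Rate-table comparator

The conventional method dilutes `3 · scale · w` mg to 50 ml so that 1 ml/h
delivers exactly `scale` µg/kg/min (generalised to other volumes as
`0.06 · scale · w · V` mg). `scale` is a per-drug formulary field
(1 for dopamine/dobutamine, 0.1 for the catecholamine pressors). Because
the planner prefers the same concentration, a preparation executed exactly
per the table scores zero deviation against the planner's reference — the
two methods prescribe identical delivered doses and differ only in the
human arithmetic they demand.

### Deviation and error metrics

Deviation is `100 · (delivered − prescribed) / prescribed` percent. An
observation is an error when |deviation| exceeds the tolerance (default
preset 5%, with a 20% "clinically critical" preset also exported), classed
over-/underdose by sign; or, at a correct final dose, when an intermediate
step (stock or diluent volume) departs from the reference plan by more than
the tolerance — the *lucky path* class, a miscalculation that reached the
right dosage by chance. Volumes are rounded (0.01 ml, pump rate 0.1 ml/h —
typical device graduations) only at presentation, never inside checks.

## Formulary defaults

The default formulary carries six continuous-infusion and nineteen bolus
drugs. Dopamine (40,000 µg/ml, 5 ml ≡ 200 mg vials), norepinephrine
(1,000 µg/ml, 1 ml ≡ 1 mg vials) and epinephrine (1:10,000 ≡ 100 µg/ml;
1:1,000 ≡ 1,000 µg/ml) use literature-standard presentations; with these,
the 7-kg scenario needs three norepinephrine vials versus one dopamine
vial. The remaining entries are plausible placeholders, and every strength
is overridable through a user formulary file.

## Trial statistics

The trial is a two-period, two-arm crossover (10 nurses per arm; arm A uses
the guided method first). Because the conventional method speeds up in
period 2 — nurses who have just used the guided app carry experience over —
time outcomes are compared **between arms within each period**, never
paired across periods. The comparison is Welch's t on group summaries:

    SE² = s₁²/n₁ + s₂²/n₂,
    df  = SE⁴ / [ (s₁²/n₁)²/(n₁−1) + (s₂²/n₂)²/(n₂−1) ],

with the CI `diff ± t(1−α/2, df)·SE`. The unequal-variance form is the
default because the app arm is markedly less variable than the control arm;
the pooled-variance form is available behind a flag. Per-cell means get
one-sample t intervals; error proportions get exact Clopper–Pearson
intervals (beta quantiles); the paired app-vs-table error comparison uses
the exact McNemar test, `p = min(1, 2·P[Bin(b+c, ½) ≤ min(b, c)])`. No
multiple-testing adjustment is applied. Degenerate inputs are handled by
convention: both-variances-zero Welch comparisons report p = 1 at equal
means, zero-variance paired differences are flagged with an undefined p.

Formatted reports use journal style (times to 1 d.p., percents as
integers, p-values with a `<.001` floor); data structures keep full
precision. Summary-driven recomputation has one intrinsic limit: published
tables print means/SDs rounded to 1 d.p., so a CI bound recomputed from
them can differ from the bound computed from raw data by up to ~0.07 in
the last printed digit. Tests therefore compare such bounds to within one
unit of the final printed digit.

## Synthetic trial generator

The generator stands in for the trial's per-nurse raw times, which were
never deposited. Per (method, period) cell it draws two independent
positive components — TDP, and the pump set-up interval TDD − TDP — from
lognormal distributions whose (µ, σ) are solved exactly from target means
and SDs (`σ² = ln(1 + sd²/mean²)`). Lognormal was chosen for positivity
and the right skew typical of task times; a normal family is available
behind a flag. Set-up targets are derived from the TDP/TDD marginal
moments under independence (mean difference; SD = √(TDD sd² − TDP sd²)),
the unique choice matching both marginals at once.

Defaults are moment-matched to the study conditions: TDP (mean, SD) =
(128.1, 36.5) app / (308.1, 128.3) conventional in period 1, (143.7, 21.9)
app / (198.4, 60.2) conventional in period 2, with the corresponding TDD
rows; error probabilities 0.8 and 0.6 for the conventional method in
periods 1 and 2, 0 for the app; erroneous preparations deliver
prescribed × R with R log-uniform over [2.0, 53.33] (period 1, pure
overdoses) or [0.19, 1.38] (period 2, under- and overdoses straddling the
correct dose — the range that produces by-chance-correct preparations).
The log-uniform family is a documented non-identifiable choice: only the
range of the ratios is constrained by the published record.

Design choices where the record is silent: the period-2 conventional
targets already embed the observed carryover, so `carryover_multiplier`
defaults to 1.0 and acts as an *additional* factor on those target means
(set period-2 cells equal to period-1 cells to study carryover in
isolation); between-period within-nurse correlation defaults to 0, with an
optional shared lognormal per-nurse speed factor (`nurse_effect_sd`) since
no published statistic constrains it. A single integer seed drives all
randomness; replication spawns independent child streams from one
`numpy.random.SeedSequence`.

What passing tests show — and don't: the simulator reproduces the *summary
statistics* of the trial (cell moments, error counts, their sampling
behaviour), so the analysis pipeline is validated end to end; it does not
model stress, cognitive load, the washout task, or real between-nurse
heterogeneity, so it cannot validate human-performance claims themselves.

## Problem sizes and numerics

Property suites run a few hundred randomized orders over weights
0.5–100 kg and each drug's labelled rate range; round-trip identity is
checked to 1e-9 relative. Clopper–Pearson is cross-checked against a
direct binomial-tail-inversion oracle for all k ≤ n ≤ 30 (1e-6), and its
simulated coverage at n=10 over 10,000 draws stays ≥ 95%. Parameter
recovery averages cell estimates over 100 replicates at 200 nurses per arm
(2% relative tolerance on moments, ±0.05 on error probabilities —
single-replicate SD estimates of a skewed lognormal at n=200 carry ~8%
sampling noise, so recovery is asserted on the averaged estimator). The
replication harness uses 1,000 replicates of the n=10-per-arm trial; the
mean period-1 TDP difference estimate has Monte-Carlo SE ≈ 1.3 s around
the generative 180 s.

## Known limitations

* The drug list beyond the four anchored presentations is placeholder
  content, not a clinical reference; the package is not a medical device.
* Bolus dosing is weight-based only (no length-based estimation).
* No pharmacokinetics, drug compatibility, or smart-pump integration.
* The crossover analysis follows the period-wise comparison design; no
  mixed-effects carryover model is fitted.
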