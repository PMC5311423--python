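# pedinfuse

Weight-based preparation of pediatric continuous drug infusions, and the
statistics of a two-period crossover trial comparing a guided (app-style)
preparation method against the conventional infusion-rate table.

## The problem

During pediatric resuscitation, vasoactive drugs (dopamine, norepinephrine,
epinephrine) are prescribed as weight-based continuous infusions in
µg/kg/min, but syringe pumps are programmed in ml/h. The nurse must dilute a
stock vial to a suitable concentration *C* (µg/ml) and convert the order
with

```
pump_rate [ml/h] = dose_rate [µg/kg/min] × weight [kg] × 60 / C [µg/ml]
```

under time pressure, with small weights and µg/mg unit changes — a classic
source of tenfold dosing errors. `pedinfuse` implements:

* **`formulary`** — typed drugs/patients/prescriptions in canonical units
  (µg, ml, kg, s), YAML formulary IO with a published schema, dose-range
  checks that warn rather than block;
* **`preparation`** — the three-step plan (drug → dilution → pump rate),
  choosing *C* so the pump rate lands in a comfortable 1–20 ml/h band, plus
  the inverse map (delivered dose from an executed preparation) and
  deviation/error metrics including "lucky path" errors (right dose reached
  through wrong intermediate steps);
* **`shann`** — the conventional comparator: the infusion-rate table that
  dilutes 3 × scale × weight mg into 50 ml so 1 ml/h delivers `scale`
  µg/kg/min;
* **`eventlog`** — append-only timestamped action logs and extraction of the
  two trial outcomes, time to drug preparation (TDP) and time to drug
  delivery (TDD);
* **`trial_stats`** — one-sample t intervals, Welch's unequal-variance t
  with Satterthwaite degrees of freedom, exact Clopper–Pearson binomial
  intervals, the exact McNemar test on discordant pairs, paired t, and a
  full trial report builder that works directly from per-nurse records *or*
  printed group summaries (n, mean, SD);
* **`trial_sim`** — a seeded generator of the whole crossover trial
  (lognormal task times moment-matched to the study conditions, a period-2
  carryover speed-up in the conventional arm, Bernoulli error processes with
  log-uniform dose-deviation ratios), plus a replication harness.

## Worked example

The trial scenario: a 7-kg infant, dopamine at 5 µg/kg/min.

```
$ pedinfuse plan --drug dopamine --weight-kg 7 --rate 5 --volume-ml 50
dopamine 5.0 µg/kg/min for 7.0 kg:
  1. draw 0.53 ml of stock (1 vial(s))
  2. dilute with 49.48 ml to 50.0 ml (420.0 µg/ml)
  3. run pump at 5.0 ml/h
```

420 µg/ml is the rate-table concentration (3 × 1 × 7 mg in 50 ml), so the
5 µg/kg/min order maps to a round 5.0 ml/h; one 200-mg dopamine vial
suffices. The same order for norepinephrine 0.1 µg/kg/min needs 2.1 mg —
three 1-mg vials — and runs at 1.0 ml/h. The comparator table itself:

```
$ pedinfuse shann-table --weight-kg 7
Rate table for 7 kg (50 ml syringe)
  dobutamine                21.00 mg  (1 ml/h = 1 µg/kg/min, 1 vial(s))
  dopamine                  21.00 mg  (1 ml/h = 1 µg/kg/min, 1 vial(s))
  ...
```

Simulate a full trial and analyze it:

```
$ pedinfuse simulate --seed 42 --out records.csv
$ pedinfuse analyze --records records.csv
TDP period 1          app: 119.9 s (95% CI 108.6-131.3), SD 15.9, n=10
TDP period 1 conventional: 266.2 s (95% CI 227.2-305.1), SD 54.4, n=10
TDP period 1   difference: 146.2 s (95% CI 106.5-185.9, P<.001; 55% of conventional time)
...
errors conventional   pooled: 15/20 (75%, 95% CI 50.9-91.3)
paired error difference: 15/20 (75%, 95% CI 50.9-91.3)
exact McNemar: P<.001
```

Each line is one cell of the trial's reporting: group mean with its t
interval, the Welch between-arm difference per period with its p-value and
the saving as a percent of the conventional-method mean, and exact binomial
intervals for the error proportions. The same statistics are available from
printed summaries alone, e.g.

```python
>>> from pedinfuse import SummaryStats, welch_t
>>> ci, test = welch_t(SummaryStats(10, 308.1, 128.3), SummaryStats(10, 128.1, 36.5))
>>> round(ci.estimate, 1), round(ci.lower, 1), round(ci.upper, 1)
(180.0, 86.6, 273.4)
```

— the 180-second period-1 preparation-time saving with its 95% CI.

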