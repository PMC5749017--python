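# babyfeed

Ascertaining exclusive breastfeeding from primary-care electronic medical
records (EMRs), end to end: a synthetic well-baby EMR corpus generator, a
rule-based feeding-status extractor for free-text and structured Rourke Baby
Record notes, longitudinal inference of exclusive-breastfeeding status at
2, 4 and 6 months of age, and the associated epidemiological statistics
(rates, rate ratios with 95% confidence intervals, standardized differences,
Cohen's kappa).

## The problem

Population surveys of infant feeding rely on self-report. Family-practice
EMRs offer an alternative: well-baby visits are charted on (or around) the
2-, 4- and 6-month immunization schedule, and feeding mode is routinely
recorded — in structured Rourke Baby Record fields, in free-text phrases
("exclusively breastfeeding", "feeding both breast and formula"), and in
historical statements ("was exclusively breastfed until 4 months"). Turning
those notes into defensible population rates requires:

1. **Detection** — find charts with a well-baby form, whose name varies
   ("Rourke", "Well Baby Visit", "Newborn Visit", ...);
2. **Classification** — map each note to exclusively breastfed (EBF),
   exclusively formula-fed, or mixed, with tense and stated durations;
3. **Longitudinal inference** — for each target age *t* ∈ {60, 122, 182}
   days, use the visit closest to but not preceding *t*; when that visit is
   far past the target, infer earlier status from current or historical
   exclusive breastfeeding documented at later visits (exclusive
   breastfeeding, once ended, does not resume);
4. **Epidemiology** — stratum-level rates and rate ratios
   RR = p₁/p₀ with the Katz log-normal interval
   exp( ln RR ± z·√((1−p₁)/(n₁p₁) + (1−p₀)/(n₀p₀)) ),
   covariate balance via standardized differences, and chance-corrected
   agreement κ = (p_o − p_e)/(1 − p_e).

Real EMR corpora of this kind are not public, so the package ships a
calibrated generator: latent feeding trajectories follow a
piecewise-constant discontinuation hazard solved so that population EBF
survival is 39.5% / 32.4% / 25.1% at 60 / 122 / 182 days, with
covariate-dependent persistence (maternal age, urbanicity, income,
immigration), ~80% Rourke coverage and ~11.8% of infants with no
recoverable feeding documentation. Because the generator's ground truth is
known, every downstream stage is testable exactly.

## Worked example

```python
import babyfeed as bf

cfg = bf.SimConfig(n_infants=2000, seed=42)
registry, trajectories, notes = bf.simulate_corpus(cfg)
lexicon = bf.load_lexicon()
observations = bf.extract_all(notes, lexicon)
cohort = bf.build_cohort(registry, observations)
statuses = bf.timepoint_table(cohort)

for target, (num, den, pct) in bf.ebf_rates(statuses).items():
    print(f"EBF at {target:3d} d: {num:4d}/{den} = {pct:.1f}%")

st_df = bf.statuses_frame(statuses)
reg_df = bf.registry_frame(cohort.records)
for row in bf.stratified_rr_table(st_df, reg_df, "urban", 182):
    print(f"urban={row.stratum_label:3s} n={row.n:4d} rate={row.rate:.1f}% "
          f"RR={row.rr:.2f} (95% CI {row.ci_low:.2f}-{row.ci_high:.2f})")
```

prints

```
EBF at  60 d:  695/1720 = 40.4%
EBF at 122 d:  559/1726 = 32.4%
EBF at 182 d:  396/1581 = 25.0%
urban=No  n= 390 rate=16.9% RR=1.00 (95% CI 0.73-1.36)
urban=Yes n=1191 rate=27.7% RR=1.64 (95% CI 1.29-2.08)
```

The three overall rates recover the generator's survival targets up to
binomial noise at n = 2000 (denominators differ by target because an infant
only contributes at ages it has a qualifying visit for, and undetermined
infants are excluded). The urban row reads: urban residents exclusively
breastfeed at 6 months 1.64 times as often as rural residents in this
synthetic draw, with a 95% CI excluding 1.

The same pipeline is available from the shell:

```bash
babyfeed simulate --n 2000 --seed 42 --out corpus/
babyfeed extract  --corpus corpus/ --out extracted/
babyfeed analyze  --corpus corpus/ --observations extracted/observations.csv \
                  --out analysis/ --complete-case
babyfeed reproduce-study --out repro.csv
```

Every run writes a manifest (config digest, seed, stage counts), and a fixed
seed reproduces byte-identical outputs.

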