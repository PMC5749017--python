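# Methods

This note documents the models, rules and numerical choices behind
`babyfeed`, and what the synthetic experiments do and do not demonstrate.

## 1. The synthetic EMR generator

### Birth registry

One row per infant–mother pair, drawn independently from configurable
marginals (defaults in parentheses, chosen to match the EMR cohort the
package emulates): urban residence (0.756), maternal age ~ round(N(30.2,
5.3²)) clipped to [12, 55], primiparity P(parity = 0) = 0.47 with a
geometric tail for higher parity, residential income quintile
(0.175, 0.188, 0.218, 0.216, 0.199) plus a 0.4% "unknown" sentinel
(serialized as 0 in `registry.csv`), maternal world region of birth
(Canada 87.6%, the immigrant flag is region ≠ Canada), birthweight ~
N(3490, 464²) g, gestational age round(N(39.3, 1.1²)) clipped to [37, 42]
(the generator emits only cohort-eligible singleton term infants; ineligible
records for exercising the eligibility filter are constructed in tests),
infant sex (male 0.514), and birth date drawn band-first — 23% in
2002–2007, the rest in 2008–2013 — reflecting growing EMR uptake across the
study window (April 2002 – March 2013).

### Feeding trajectories

Each infant carries a latent pair (`ebf_end_age`, `mixed_end_age`): status
at age *a* is EBF iff *a* < `ebf_end_age`, MIXED between the two ends,
FORMULA after. The model for `ebf_end_age`:

* a point mass at 0 with probability 1 − `ebf_init_prob` (default
  initiation 0.90, the order of magnitude reported for Ontario);
* conditional on initiation, a piecewise-constant discontinuation hazard on
  (0, 60], (60, 122], (122, 182], (182, 750], solved in closed form so the
  **unconditional** survival at 60/122/182 days equals the configured
  targets (defaults 0.395/0.324/0.251). The last piece is not identified by
  three targets and reuses the (122, 182] hazard.

Covariates multiply the hazard by exp(Σⱼ βⱼ(xⱼ − x̄ⱼ)) with mean-centred
covariates, so strata show gradients while population survival stays on
target (the Jensen-gap inflation of the mean multiplier is < 2% at the
default effect sizes, well inside the 3-binomial-SE calibration band at
n = 8000). Default log hazard ratios: −0.35 per decade of maternal age,
−0.25 urban, −0.08 immigrant, −0.06 per income quintile — signs and rough
sizes that qualitatively reproduce the observed persistence gradients;
exact published rate ratios are deliberately **not** a generator target.
Sampling is by inversion of the integrated hazard; discontinuations beyond
the 750-day chart horizon get a sentinel age (10 000) meaning "still
exclusively breastfed at every observable visit". After exclusive
breastfeeding ends (or never starts), 60% of infants pass through a mixed
phase with exponential duration (mean 60 d post-weaning, 120 d when mixed
from birth) before formula only.

### Visit process and note text

Visits follow a schedule of (age, attendance probability, jitter SD)
slots — default {7, 60, 122, 182} days at 0.9 attendance, delay SD 7 d. The
delay is **half-normal** (visit at or after the nominal age): families run
late, not early, and this keeps the generator coherent with the study
design's "closest to but not preceding the target" index-visit rule. Note
text is assembled from controlled templates consistent with the latent
truth at the visit age: an optional Rourke form-name header (per-infant
probability 0.80, randomized case, several real-world name variants), a
feeding sentence (or a structured `feeding` field on 30% of Rourke notes),
and for infants who have stopped exclusive breastfeeding, a historical
clause ("previously exclusively breastfed for 9 weeks") with probability
0.75. Stated durations are phrased in days below two weeks, integer weeks
below twelve weeks, and months to one decimal beyond — parseable back to
within ±3.5 days. With probability 0.118 an infant's notes carry no feeding
terms at all, emulating charts from which feeding is unrecoverable.

All randomness descends from a single seed through three spawned
`numpy.random` streams (registry, trajectories, corpus); identical configs
yield byte-identical corpora.

### What the generator does *not* emulate

Templates are lexicon-complete by construction, so extraction accuracy on
this corpus is an upper bound: passing tests show the **pipeline logic** is
correct (closure, calibration, invariants), not that the shipped lexicon
would achieve any particular sensitivity on real clinical prose with typos,
French text, copy-forward noise, or idiosyncratic phrasing. Visit
attendance is independent across slots and of feeding status; real
missingness is unlikely to be completely at random.

## 2. Extraction rules

Matching is case-insensitive, whitespace-normalized, word-boundary-anchored
phrase search; no stemming. Rourke detection takes the earliest-starting
variant (longest on ties). Classification order per note: structured field
→ breast+formula/mixed ⇒ MIXED → breast+exclusivity ⇒ EBF → breast alone ⇒
EBF → formula alone ⇒ FORMULA → else NONE_DOCUMENTED. An unqualified breast
term counts as exclusive because the three-way scheme has no
"breast, non-exclusive" bucket; this is a convention, not an inference.
Historical duration statements are captured first and masked out before the
current-status rules run, and each spawns a separate historical EBF
observation (months × 30.44 days, rounded half away from zero; unparsable
durations yield tense = historical with no duration). A negation marker
within 3 tokens before a feeding term cancels it, but only the *nearest*
following term — "no formula, breast milk only" keeps its breast term. The
default lexicon is a plain-language reconstruction and fully
user-overridable; none of the statistics depend on its exact wording.

## 3. Eligibility and timepoint inference

Eligible: singleton (plurality 1), term (≥ 37 completed weeks — "term" is
used without a threshold in the source cohort, so 37 weeks is this
package's definition), at least one visit before 190 days; observations
past 750 days are dropped, the infant retained. Status at target *t*:

1. no visit at ≥ *t* → out of denominator, UNDETERMINED;
2. index visit (earliest at ≥ *t*) currently EBF → EBF;
3. index visit within the carry-forward window (62/60/568 days for
   *t* = 60/122/182 — the gap to the next target, unbounded for the last)
   and currently formula/mixed → NOT_EBF;
4. otherwise: any later current-EBF observation → EBF; else a historical
   statement "exclusively breastfed for *d* days" decides EBF (*d* ≥ *t*)
   vs NOT_EBF (*d* < *t*), since exclusive breastfeeding does not resume
   once ended; else UNDETERMINED;
5. EBF at a later target back-propagates to all earlier targets.

Rates are computed among infants with a qualifying visit **and** a
determined status; UNDETERMINED infants leave numerator and denominator.
The complete-case subset keeps infants decided by an index visit at all
three targets (no future-visit inference), mirroring the sensitivity
analysis such studies run against inference-induced misclassification.
`ebf_duration` is the age at the latest visit with confirmed current EBF.

Known bias under the default (jittered) visit process: an infant who stops
exclusive breastfeeding between the target and a slightly-late index visit
is scored NOT_EBF at the target (≈ −0.7 points at the default hazards),
partly offset by selective loss of weaned infants without historical
clauses (+≈ 0.7). Both are properties of the ascertainment design itself,
are reproduced faithfully, and stay inside 3 binomial SEs at n = 8000,
where the parameter-recovery test pins them.

## 4. Statistics

Rate ratio CIs use the Katz log-normal method (the standard choice for a
ratio of independent binomial proportions; z = Φ⁻¹(0.975)). Zero numerators
flag the CI non-computable (NaN); a zero-event referent degrades the whole
table's RR columns to NaN rather than raising, since small synthetic
cohorts legitimately produce empty strata. Standardized differences:
(p_a − p_b)/√((p_a(1−p_a) + p_b(1−p_b))/2) for proportions,
(m_a − m_b)/√((s_a² + s_b²)/2) for means. Cohen's kappa from the raters'
marginals, with degenerate perfect-chance agreement raised as an error.
Referent convention: fixed conventional referents (lowest age band, rural,
Q1, earlier birth-year band, ...) by default, with `referent="lowest"`
switching to the lowest-rate stratum; "Unknown" strata are never referents.
Display rounding is half-away-from-zero: rates 1 dp, RR/CI 2 dp,
standardized differences 1 dp. When recomputing published table rows, the
printed stratum rates are used directly as proportions; re-deriving integer
numerators first would stack a second rounding on the printed one and can
flip the final digit of a ratio.

## 5. Problem sizes

Tests run the full pipeline once at the emulated cohort size (n = 8815,
session fixture), one 8000-draw trajectory calibration, and small corpora
elsewhere; the complete suite finishes in well under a minute. The
acceptance script runs the n = 8815 pipeline plus the 8000-draw calibration
(~10 s). Property tests (hypothesis) are derandomized for reproducibility.

## 6. Limitations

* The extractor is deliberately pre-statistical: no ML, no spelling
  correction, no French. It quantifies what a transparent rule set can do,
  and the closed loop with the generator tests logic, not real-world recall.
* Historical-duration phrasing coarser than the generator's (e.g. integer
  months) would introduce ±15-day boundary error at the targets; the parser
  handles such inputs, but calibration claims hold only for the shipped
  rendering precision.
* The covariate model is log-linear with independent draws; real cohorts
  have correlated covariates (income × urbanicity × immigration), so
  synthetic stratified tables should not be read as effect-size forecasts.
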