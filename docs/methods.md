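# Methods

## Setting

An eye with axial length above 26.0 mm (high myopia) and cataract needs
one of four surgical recommendations: none (0), cataract surgery (1),
retinal surgery (2), or combined cataract–retinal surgery (3). The
toolkit evaluates automated pipelines for this call: grading the cataract
on LOCS III, predicting postoperative best-corrected visual acuity
(BCVA), applying a rule table, and comparing the resulting decisions with
a gold standard and with human raters.

## Visual acuity

All arithmetic is in logMAR. Snellen fractions convert as
`log10(den/num)`; the conventional clinical value is the 2-decimal
rounding (6/12 → 0.30, not 0.30103), which is the default; the raw value
is available with `rounding=None`. The off-chart categories counting
fingers, hand motion, light perception and no light perception take the
fixed values 1.9, 2.3, 2.7 and 3.0 logMAR. The good/poor VA split is at
0.30 logMAR with the boundary assigned to **poor** (the poor group is
defined as ≥ 0.30); prediction errors within ±0.30 logMAR count as hits
on a closed interval, implemented with a 1e-12 epsilon so a boundary
error represented inexactly in binary floating point (e.g. |0.4 − 0.1|)
still lands inside the band.

Group sensitivity for group *g* divides correctly-grouped eyes by eyes
whose **actual** group is *g*; precision divides by eyes whose
**predicted** group is *g*. A group absent from the relevant margin makes
the metric undefined; undefined metrics are reported as explicit `None`
markers, never as zero.

## Grading evaluation

Grades follow LOCS III: nuclear 1.0–6.0, cortical and posterior
subcapsular 1.0–5.0, at 0.1 resolution. The per-eye grading error is the
absolute difference from the gold standard; Re1.0 is the percentage of
errors ≤ 1.0 (boundary inclusive). Agreement on the continuous scale is
ICC(2,1) — two-way random effects, absolute agreement, single measure —
because the clinically relevant question for an automated grader versus a
gold standard is absolute agreement, offsets included. The mean squares
are returned alongside so other ICC forms can be derived. The ICC is
undefined (None) when total variance is zero.

Binary diagnostics use the surgical-indication threshold: a grade
strictly above 3.5 indicates surgery (3.5 exactly does not). In the
consolidated report each subtype is scored against its own flag (nuclear
grade > 3.5 for the nuclear column, cortical for cortical), with the
subtype's continuous automated grade as the ROC score; this keeps the two
columns' diagnostics independent, which is how per-subtype accuracy
tables are constructed in practice. The engine's combined rule (nuclear
**or** cortical > 3.5) is a separate operation, `surgical_indication`.

AUC uses the Mann–Whitney identity with midranks (ties count 1/2), which
equals the trapezoidal area under the empirical ROC curve (curve points
from scikit-learn). DeLong's structural-components estimator provides the
AUC variance, the normal-approximation CI, and the two-sided test for two
correlated AUCs on the same eyes. The estimator is algebraically
identical to the grouped two-sample delete-one jackknife, which the test
suite uses as an exact oracle. When the variance of the AUC difference is
degenerate (identical scores), the comparison reports p = 1 for equal
AUCs and an explicit undefined marker otherwise.

## Decision engine

The engine runs at most five steps in fixed order; the skeleton (step
order, four categories, the 3.5 grade rule, the 0.30 logMAR convention)
is standard, while the branch predicates of steps 1, 2, 4 and 5 are this
package's reconstruction and every constant is configurable:

1. **Preoperative VA** — BCVA better than `preop_va_threshold`
   (default 0.30 logMAR) with no OCT finding mapped to retinal surgery →
   category 0; otherwise continue.
2. **Predicted improvement** — gain = preoperative BCVA − predicted
   postoperative BCVA; a gain ≥ `improvement_threshold` (default 0.20
   logMAR, about two Snellen lines, a conventional "clinically
   meaningful" change — not an empirically fitted value) is flagged.
3. **Grading** — cataract significant iff nuclear or cortical grade
   (from the chosen source, automated or gold) strictly exceeds
   `grade_threshold` (default 3.5).
4. **OCT** — any finding mapped to `retinal_surgery` forces a retinal
   component: category 3 with a significant cataract, else 2. By default
   all structural macular pathologies map to retinal surgery and CNV maps
   to none (typically managed medically with anti-VEGF); the map is total
   over the vocabulary and fully overridable.
5. **Axial length** — a significant cataract with meaningful gain → 1;
   without meaningful gain → 1 only if axial length is below
   `al_caution_threshold` (default 30.0 mm — a caution bound for extreme
   elongation, chosen by this package), else 0. No significant cataract
   → 0.

The engine is deterministic, total over valid records, and returns the
ordered trace of evaluated steps so the applied rule is auditable.
Conflicts are resolved purely by the fixed step order.

## Agreement

Decisions are cross-tabulated with rows = gold standard, columns =
comparator, categories ordered 0,1,2,3. Consistency is 100·trace/n,
always reported with its fraction. Kappa is **unweighted** Cohen's kappa;
the reconstruction check in the test suite (published four-category
tables reproduce to three decimals under the unweighted formula) supports
that choice over weighted variants, which are deliberately not offered as
defaults. Since kappa is a function of (row sums, column sums, trace)
only, `kappa_from_marginals` reconstructs it exactly from published
per-category counts plus the agreement count. Reported kappas round
half-up to 3 decimals; raw values are retained. When both raters are
constant on one category, chance agreement is 1 and kappa is undefined
(None with po preserved).

Special cases are eyes whose gold decision is 0, 2 or 3. Subset
agreement keeps the full four-category table restricted to those eyes
(the comparator may still answer 1); how published special-case kappas
were tabulated is not stated anywhere authoritative, so ours are defined
by this construction and not asserted against published values.

## Synthetic cohorts

The generator emulates the statistical structure the evaluation assumes,
not real ocular biology. Per eye: a latent gold category from the
prevalence vector (default 1:95:5:6 across categories 0:1:2:3, a
plausible tertiary-care case mix); gold grades drawn from truncated
normals consistent with the category (surgical categories get at least
one grade above 3.5, with the nuclear subtype the driver 80% of the
time); automated grades equal to gold plus a N(0, σ) error rounded to the
0.1 LOCS step and clipped to the scale; true postoperative BCVA from a
category-dependent normal (retinal-pathology classes shifted worse);
predicted BCVA = truth + N(0, σ_pred) unclipped, so the MAE calibration
stays exact; an OCT finding consistent with the category; axial length
from a normal truncated at the 26 mm floor; and per-rater decisions drawn
independently from each rater's confusion-matrix row given the gold
category (no eye-difficulty random effect).

Calibration: σ per grading subtype is solved by bisection (tolerance
1e-6 on the probability) from a target Re1.0 via
P(|rounded error| ≤ 1.0) = 2Φ(1.05/σ) − 1; defaults target 99.07%
(nuclear) and 88.79% (cortical). σ_pred defaults to
MAE·√(π/2) ≈ 0.1955 for a target MAE of 0.156 logMAR via the half-normal
mean. Clipping at the scale ends biases realised grading errors downward
(cortical Re1.0 simulates ~2 points above its target because surgical
cortical grades sit near the 5.0 ceiling); calibration checks in the
tests therefore restrict to interior grades. The default rater confusion
matrices are synthetic integer realizations consistent with published
per-category counts and agreement totals (which fix only marginals and
trace, not the full table), row-normalised.

One global seed drives named per-eye, per-field substreams
(`SeedSequence([seed, eye_index, crc32(field)])`), so the same seed gives
a byte-identical cohort CSV and adding a field never perturbs existing
draws.

What passing tests on simulated cohorts do **not** show: the generator's
conditionals (grade distributions, VA distributions, OCT joint structure)
are stand-ins, raters are conditionally independent given the gold class,
and there is no image content at all — so results demonstrate the
correctness of the evaluation arithmetic and engine logic, not clinical
performance of any grading or prediction model.

## Numerical choices and problem sizes

Snellen conversion rounds to 2 decimals by default; percentages report to
2 decimals, kappa/ICC/AUC to 3 (half-up), logMAR metrics to 4. The
large-sample checks (prevalence recovery, Re1.0 and MAE calibration,
perfect-rater kappa) run on one shared 10,000-eye cohort; smaller
pipeline tests use 80–500 eyes. Distributional assertions use 3-standard-
error bands at fixed seeds (4 SE for the grading calibration, which is
conditioned on an interior-grade subset).

## Known limitations

* The rule table's branch predicates beyond the fixed skeleton are a
  reconstruction; they are configuration, not ground truth.
* No ETDRS letter scores or decimal acuity; no longitudinal modelling.
* No weighted kappa, Fleiss' kappa, or kappa CIs; no IOL-power or
  risk-score modelling; PSC grades are carried but not evaluated.
* DeLong's test uses the normal approximation; very small samples or
  AUCs at 1.0 yield degenerate variances, surfaced as explicit markers.
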