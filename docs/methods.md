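# Methods

This note records the modelling choices, defaults and known limitations of
`langtraj` at the level of detail a user of the statistical output needs.

## Feature extraction

Transcripts are sequences of speaker turns.  Only responder turns are
featurized by default (interviewer speech can be included via a flag for
sensitivity analysis).  The tokenizer is deliberately fully specified
rather than delegated to an external toolkit: lowercase, split on
whitespace and on em/en dashes, strip leading/trailing punctuation, keep
word-internal apostrophes, hyphens and slashes.  This keeps tokens like
`can't` and `9/11` intact and makes every downstream count reproducible by
hand.

Three feature families are produced per document:

* **n-gram relative frequencies** for orders 1–3.  Windows never cross a
  turn boundary (a turn is the natural utterance unit).  Each order is
  normalized by its own window total, so each order is a proper
  distribution (sums to 1 ± 1e-9); an order with no windows is an empty
  map, never NaN.
* **binary indicators**: 1 for every observed n-gram, absent otherwise.
* **topic prevalence**: with a word→topic loading table interpreted as
  p(topic | word), score(t) = Σ_w p(t|w)·relfreq(w).  Scores lie in [0, 1]
  and sum to 1 when the table is column-normalized and the document is
  fully in-vocabulary.

## The nine assessments

Four trait scores apply user-supplied pre-trained linear models
(intercept + Σ weight·feature over `ngram:`/`bin:`/`topic:` namespaced
features) exactly as shipped — no refitting.  Three lexicon scores are
weighted relative frequencies of category terms; a trailing `*` in a term
is a prefix wildcard, and a token matched by several patterns in one
category counts once with the longest matching pattern's weight (exact
beats wildcard on ties) — the simplest deterministic resolution.  Lexicon
scores are normalized by total word count, the same denominator as 1-gram
relative frequencies.  The two meta variables are the token count and the
mean characters per token.

The bundled lexicon/topic/model files are small open stand-ins so the
pipeline runs end to end; licensed resources (e.g. a commercial dictionary
or published trait-model weights) are supplied as file paths and never
bundled.

## Cohort rules and trajectories

Elapsed times are days/365.25 in years throughout; dates are ISO-8601.
"Within 2 years" is closed on both sides (|Δt| ≤ 2.0).  The baseline PCL is
the observation minimizing |Δt| within that window; an exact pre/post tie
takes the pre-interview value, which cannot be contaminated by
post-interview events.  Longitudinal eligibility additionally requires ≥3
strictly post-interview PCLs with the last ≥2.0 years out, so every
retained subject contributes at least four observations overall.

The trajectory slope is the per-subject OLS line through the
post-interview (t > 0) observations.  A post-interview baseline
observation contributes a point by default; `exclude_baseline_from_slope`
drops it for sensitivity.  Constant-time series and <2 points are hard
errors (selection guarantees ≥3).

## Association models

All variables are z-scored with the n−1 standard deviation; a constant
variable is a hard error naming it.  Fits are ordinary least squares with
intercept; p values are two-sided t tests on n−k residual d.f., CIs are
95% t-based Wald intervals.  Without controls the standardized coefficient
is identically the Pearson correlation, which the tests verify to 1e-10.
Benjamini–Hochberg is applied within each model family across exactly the
nine assessments (m = 9) — the family matching one column of a results
table; whether the original family spanned both outcome tables jointly is
unknowable from the source description, and per-table adjustment is the
more conservative reading of a table-wise significance column.  Gender is
coded male = 1, occupation police = 1, marital married = 1; standardization
makes the assessment coefficients invariant to these codings.

Two-stage estimation (per-subject slopes, then person-level OLS on the
slopes) is the primary implementation of the prospective model; the
time-unit for the "years since event" control is irrelevant after
standardization.

Tercile curves: subjects are ranked by an assessment (stable ties), split
into thirds (sizes within 1), and each subject's expected trajectory is
predicted from controls-only models of the per-subject intercepts and
slopes; residual curves (observed minus expected, linearly interpolated
within each subject's observed span only) are averaged within the top and
bottom groups on a common time grid.  The mediation check refits the
adjusted model with standardized marital status added and reports whether
previously significant assessments stay significant.

## Synthetic cohorts

The generator emulates: interviews of ~10,000 words (mean-corrected
lognormal, dispersion 0.25); baseline PCL mean 33.7, s.d. 16.2, clipped and
rounded to the 17–85 instrument range; one pre-interview visit (~−1.2 y), a
baseline visit (~+0.2 y) and four follow-ups ending at ~5.5 y (s.d. 1.3,
floored at 2.6 y so the default cohort is fully longitudinal-eligible);
interviews ~10.31 y (s.d. 1.43) after the index event; 90% male, 48%
police, 60% married, age ~N(55, 8).  Visit-level PCL noise s.d. is 4.0
(test–retest-sized measurement error) and the between-subject slope s.d. is
3.0 PCL/yr around mean 0 — values chosen once as clinically plausible.

Latent structure: baseline factor b and slope factor s are standard normal
with configurable correlation (default 0).  Each planted assessment gets a
latent mixing b, s and fresh noise; token pools tied to each assessment
(trait-model words, pronouns, articles, long words) are linearly modulated
by their latent (gain 0.4 per s.d.).  Modulated mass is compensated inside
two filler-word reservoirs solved to conserve both total probability and
total character count, so one assessment's modulation perturbs neither the
other assessments' relative frequencies nor the average word length; the
long-word pool is compensated at the corpus-mean length so its length
signal survives.

A planted effect is defined as the standardized coefficient the pipeline
recovers in expectation.  The latent mixing coefficients are therefore
inflated by computed attenuation factors: multinomial sampling noise of
each score (closed form), and the correlation of b with the observed
baseline and of s with the fitted slope (Monte-Carlo, since rounding and
the 17–85 clipping make these awkward analytically).  The default planted
effects are the five headline magnitudes this design targets
(+0.32 depression and +0.31 first-person singular on baseline severity;
+0.30 anxiety, −0.36 first-person plural and −0.35 word length on the
slope).

The document-free path (`simulate_assessments`) scores multinomial token
counts through the identical featurize/assess code without constructing
text, and is used for simulation studies; the text path is exercised end to
end at smaller sizes and agrees token-for-token with the counts path.

What the generator does **not** emulate: discourse structure or semantic
coherence; vocabulary beyond ~120 types; topic usage correlated with
outcomes; informative missingness of visits; floor/ceiling-driven
measurement properties of real PCL items.  Passing recovery tests
demonstrates that the statistical machinery is unbiased and calibrated
under the stated generative model, not that the assessments are valid on
real clinical language.

## Numerical and reporting choices

* Result TSVs serialize floats with `repr`, so reruns are byte-identical.
* Per-subject RNG streams derive from (seed, subject index): cohorts are
  reproducible under parallel generation.
* Simulation sizes in the test suite: 50 seeds × n = 500 for effect
  recovery; 200 replicates × n = 75 (the longitudinal sample size) for the
  null false-positive rate, with 2,000-word documents for the null runs.
* Known limitation: clipping at the PCL floor couples baseline severity to
  fitted slopes (floor effect), so baseline-planted features leak small
  (|β| ≲ 0.05 at the defaults) spurious slope associations.  The
  Monte-Carlo oracle quantifies this; the analytic oracle ignores it.
* Known limitation: the two eligibility counts reported in the source
  cohort description (cross-sectional vs trajectory samples) cannot both be
  reproduced from stated rules alone; the eligibility report therefore
  exposes both sample definitions per subject rather than resolving the
  discrepancy.
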