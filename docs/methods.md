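# Methods

This note documents the statistical models behind `emonet`, the choices
that were genuinely open, and what the synthetic-data tests do and do not
establish about real experience-sampling data.

## Data model

A *report* is one answered prompt: participant id, local-clock timestamp,
and one binary indicator per emotion of an 18-item taxonomy (9 positive:
alertness, amusement, awe, gratitude, hope, joy, love, pride, satisfaction;
9 negative: anger, anxiety, contempt, disgust, embarrassment, fear, guilt,
offense, sadness). The canonical ordering — positives alphabetically, then
negatives alphabetically — fixes the meaning of every vector and matrix in
the package. The all-zero vector is legal ("no emotion right now").
Timestamps are kept in the participant's local time and never
timezone-converted, because hour-of-day analyses are about the local clock.
Duplicate (participant, timestamp) rows are kept with a warning: prompt
snoozing can legitimately produce them.

## Frequency estimation

For a binary per-report outcome (an emotion indicator, a report category,
or "any emotion"), the target quantity is the percentage of reports on
which the outcome occurs. Reports are nested within participants, so the
model-based estimate is the intercept of a linear-probability model with a
compound-symmetry within-participant covariance — equal variances and a
common within-person correlation. We fit it as a GEE with exchangeable
working correlation (statsmodels), which is the marginal formulation of the
same model: the point estimate is the exchangeable-GLS weighted mean of
participant means, and the sandwich standard error is cluster-robust, so
the estimator degrades gracefully to the pooled proportion with a
cluster-robust CI when the within-person correlation is estimated at zero.
An intercept-only random-effects ML fit of the identical model proved
numerically fragile for linear-probability outcomes at scale (boundary
variance estimates, singular Hessians), which is why the GEE formulation is
the engine.

Choices: the identity link is the default (the estimand is a percentage and
its CI is symmetric on that scale); a logit link is available. CIs are
Wald-type, truncated to [0, 100]. A constant outcome yields a degenerate
zero-width CI; a single participant yields the pooled proportion with a
Wilson binomial CI, flagged as such. Both the model-based estimate and the
raw pooled proportion appear in the frequency table, because the two can
differ under unbalanced cluster sizes and readers should see both.

Report categories: `positive_only` (≥1 positive, 0 negative), `negative_only`
(mirror), `mixed` (≥1 of each valence in the same report), `none`
(all-zero). These partition the reports, so pooled category percentages sum
to 100 exactly and "any emotion" = 100 − "none" — both are exact identities
and are tested as such. The positive/negative ratio is defined as
positive-only frequency ÷ negative-only frequency and is undefined (NaN,
with a warning) when no report is negative-only.

Temporal profiles are pooled per-bin frequencies: hour bins are the floor
of the local hour, restricted by default to 6:00–22:00 and to bins with at
least 1000 reports (both configurable; night hours are sparsely sampled and
would otherwise yield unstable frequencies). Weekdays are ISO
(Monday = 1). The fluctuation-magnitude statistic is the mean, over an
emotion set, of the sample standard deviation (n−1 denominator) of each
emotion's hourly frequencies; it requires all profiles to cover the same
bins, which the binning construction guarantees.

## The emotion network

Edge weights are phi coefficients — Pearson correlations of the pooled
binary indicator vectors, identical to the 2×2-table formula
(n11·n00 − n10·n01)/√(n1.·n0.·n.1·n.0). Pooling across all reports mixes
between- and within-person covariation deliberately: the network describes
which emotions coexist in moments, over everyone's moments. A
person-centered variant (participant means removed) is available behind a
flag for sensitivity analysis. A constant indicator (possible for a 1%
emotion in small samples) makes phi undefined; such edges are stored as 0
and flagged in a mask so degree centrality stays defined.

Degree centrality is DC(e) = Σ_{a≠e} |w(e,a)|, at most 17 for 18 emotions,
attained only when every edge is ±1. The connector/provincial/distal
typology is an explicit operationalization of a qualitative idea: with a
strength threshold τ (default 0.1 — roughly the magnitude below which a phi
between rare binary indicators is practically negligible), an emotion with
strong edges to both valences is a connector, with strong same-valence
edges only is provincial, and with no strong same-valence edge is distal.
An emotion whose *only* strong edges are opposite-valence is filed as
distal and logged; the typology's defining feature is the same-valence
core, and this corner case is genuinely ambiguous. The rule is a threshold
formalization, so its labels need not coincide with any particular visual
reading of a network diagram.

Group comparison: paired t-test across the 18 emotions' DC values
(df = 17), with Cohen's d for paired data (mean difference / SD of
differences); differences are first-argument minus second. The
frequency–centrality association is a Pearson r over the 18 (frequency,
DC) pairs with a Fisher-z 95% CI — with n = 18 this interval is wide by
construction.

## Synthetic-data generator

The generator emulates a large smartphone ESM study: ~11.6k participants;
an overdispersed answered-prompt count per participant (negative binomial
with mean 5.7 and SD 9.6, floored at 1); 75% female; prompt hours drawn
from a waking-day weight profile with a morning mode at 9:00 and very few
overnight prompts; and prompt dates spread over a ~14-month window with
each participant active for about 35 days.

Emission is a multivariate probit: indicator_e = 1 iff
u_i + z_e + s_e(h) > c_e, with a single participant random intercept
u_i ~ N(0, σ_u²) shared across emotions, z ~ MVN(0, R) per report, and
thresholds c_e = √(1+σ_u²)·Φ⁻¹(1−p_e) so marginal prevalences hit their
targets exactly. Defaults:

- **Prevalences** p_e: joy .35, love .30, anxiety .29, satisfaction .27,
  alertness .24, hope .22, sadness .20, amusement .16, pride .13,
  disgust .11, anger .10, gratitude .09, guilt/fear/awe/offense/
  embarrassment .05, contempt .01 — the frequency ordering characteristic
  of everyday-emotion ESM data.
- **Latent correlation** R: +0.4 within valence, −0.3 between valences
  (positive semi-definite by construction; eigenvalues 6.9, 1.5, 0.6).
- **σ_u = 0.5**, i.e. a latent intraclass correlation of
  σ²/(1+σ²) = 0.2, a typical between-person share for momentary emotion
  endorsement.
- **Hour effects** s_e(h): a cosine on the latent scale peaking at 20:00,
  amplitude 0.10 for positive and 0.02 for negative emotions, centred
  under the hour weights so the weighted-mean shift is zero and marginals
  stay on target. The amplitudes were set by a probit delta-method
  calculation (prevalence amplitude ≈ φ(Φ⁻¹(1−p))·A/√(1+σ_u²)) to make
  positive emotions fluctuate roughly three times more across the day than
  negative ones — mean hourly SDs near .017 and .006 respectively, the
  asymmetry the analysis should be able to detect.

All randomness derives from one master seed through independently spawned
child streams, so identical configs give bitwise-identical datasets.

### The closed-form phi oracle

Because the model is a Gaussian copula, the population phi between two
indicators has a closed form. The shared intercept adds σ_u² to every
latent covariance, so the total correlation is
ρ* = (ρ_ab + σ_u²)/(1 + σ_u²); with standardized thresholds
t_e = Φ⁻¹(1−p_e), P11 is the bivariate-normal orthant probability
P(Z_a > t_a, Z_b > t_b; ρ*) and
phi = (P11 − p_a·p_b)/√(p_a(1−p_a)p_b(1−p_b)). This is the independent
oracle the network estimator is validated against (and it is itself
cross-checked against a 10⁶-draw Monte-Carlo simulation to within 0.005).
Hour effects are ignored by the oracle, so recovery experiments switch
them off.

Two structural consequences of the defaults are worth knowing. First, at
the phi level the shared intercept almost cancels the −0.3 between-valence
latent correlation (ρ* ≈ −0.04 at σ_u = 0.5), so default between-valence
phi values are only about −0.01 to −0.02: under the default generator every
emotion classifies as provincial at τ = 0.1. Connector and distal behaviour
is exercised with purpose-built correlation matrices. Second, the category
frequencies (any / positive-only / negative-only / mixed) are properties of
the joint distribution that the generator does not target — only marginals
are calibrated — and under the defaults they come out near 80 / 36 / 17 /
27 percent. Real large-scale data shows more "any" (≈90%) and more mixed
reports (≈33%), i.e. real co-endorsement structure is not a homogeneous
valence-block copula. This is a known, deliberate simplification.

### What the generator does not emulate

No serial dependence within a day beyond the shared intercept, no
nonresponse or self-selection mechanisms, no gender differences in
dependence structure (group-comparison tests construct their own groups),
and no emotion-specific random-effect variances. Passing parameter-recovery
tests therefore shows the estimators are correct under a realistic but
idealized data-generating process; it does not certify behaviour under
informative missingness or heterogeneous dependence.

## Numerical and interface choices

- Phi matrices come from the sample correlation of the 0/1 columns;
  symmetric by construction, clipped to [−1, 1], diagonal set to 0 by the
  no-self-edge convention.
- Orthant probabilities use the scipy bivariate-normal CDF; perfect
  correlations are short-circuited to min(p_a, p_b) / max(0, p_a+p_b−1).
- Edge-list CSVs are written with full round-trippable float precision and
  re-read with `float_precision="round_trip"`, so write→read is the
  identity; GraphML likewise.
- The loader defaults to failing fast on a malformed row (naming row and
  column); `errors="drop"` switches to reject-and-log for bulk ingestion.
- Problem sizes in the validation suite: oracle equivalence uses 1000 small
  random datasets; parameter recovery uses ~2×10⁵ reports from 10⁵
  participants (phi tolerance 0.02 ≈ 5 sampling SEs; prevalence tolerance
  3 binomial SEs, with few prompts per participant so the binomial bound is
  appropriate); CI coverage uses 100 replicates of 500 participants × ~20
  prompts. These sizes make the checks sharp while keeping the whole suite
  fast on a laptop.

## Known limitations

- The typology depends on τ; near-threshold edges can flip labels between
  samples. The τ-rule is a formalization, not a canonical definition.
- Pooled phi conflates between- and within-person covariation; the
  person-centered variant is provided but the default follows the pooled
  definition of the network.
- The linear-probability model can in principle produce CIs outside
  [0, 100] for extreme prevalences; they are truncated, and the logit link
  is available where that matters.
- The frequency–centrality CI assumes bivariate normality of the 18 pairs
  through the Fisher transform; with n = 18 it is indicative only.
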