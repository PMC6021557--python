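# Methods

`delphiset` analyses two-round Delphi consensus surveys in which an
expert panel rates candidate items — here, resource-use items for a
standardized patient-completed costing questionnaire — on a 1 (not
important) to 9 (very important) scale, with the goal of reducing a
long list to an agreed core set.

## Retention rules

All verdicts are computed on exact fractions (count / n), never on the
two-decimal percentages used for display. Thresholds default to the
prespecified protocol and follow its wording literally:

* **Round 1, overall consensus** — retained if strictly more than 50%
  of the panel scored the item 7–9 *and* strictly fewer than 15% scored
  it 1–3.
* **Round 1, subgroup consensus** — failing the overall test, retained
  if the same band test passes within two or more of the six care-type
  experience subgroups (physical, mental, public health, older adults,
  primary care, secondary care). Subgroups are evaluated independently,
  so a rater with several memberships counts once in each; a subgroup
  contributing fewer than 5 ratings for an item is treated as not
  evaluable (a guard against one-rater subgroups in synthetic panels —
  configurable via `Thresholds.subgroup_min_raters`).
* **Round 1, top-10 prioritization** — failing both, retained if at
  least 15% of the panel ("15% or more", inclusive, unlike the other
  thresholds) listed the item in their personal top-10. The
  denominator defaults to every round-1 rater, including the few who
  skipped the top-10 task; a `completers` policy restricts it to raters
  with a nonempty list, since the protocol does not pin this down.
* **Near-miss review** — a dropped item whose % rating 7–9 falls within
  10 percentage points of the overall threshold (low band still
  passing), or whose top-10 share is within 2 points of the top-10
  threshold, is flagged for human review. A flag never retains by
  itself; a manual override field records the review outcome. Both
  margins are arguments to `flag_near_miss`.
* **New items** — suggested additions enter round 2 only when backed by
  strictly more than 10% of the panel.
* **Round 2, pre-agreed rule** — retained if strictly more than 70%
  scored 7–9 and fewer than 15% scored 1–3. The **stringent** variant
  replaces the high band with 8–9; because that band is a subset of
  7–9, stringent retention implies pre-agreed retention on any input.

When several rules pass, the recorded reason follows the priority
overall > subgroup > top-10; the published retained-items table is
consistent with this ordering.

## Summaries and quantile conventions

Per-item summaries report the band percentages, the sorted-midpoint
median, quartiles by linear interpolation between closest ranks (the
numpy default), the mean, and the sample SD (ddof = 1). The published
tables print percentages to two decimals; at the study's panel sizes
(45 and 42) every achievable percentage is a multiple of 100/45 or
100/42, none of which lies within rounding distance of any threshold,
so replaying printed values through the same comparators is safe (this
is asserted in the test suite rather than assumed).

## Agreement statistics

The headline agreement statistic is the intraclass correlation from a
two-way random-effects ANOVA with items as targets and panelists as
raters. The default form is the single-measure absolute-agreement
coefficient ICC(2,1):

    ICC(2,1) = (MS_I − MS_E) / (MS_I + (k−1) MS_E + k (MS_R − MS_E)/n)

with n items, k raters. The protocol says only "two-way random
effects"; single-measure absolute agreement is the conservative
reading, and the average-measure form ICC(2,k) is exposed via
`form="average"`. The 95% CI uses the standard F-based construction
with a Satterthwaite-approximated denominator degree of freedom; the
implementation is cross-checked against `pingouin.intraclass_corr` in
the tests. A matrix with zero total variance raises an error (the
coefficient is undefined, not 1), while zero residual variance with
real item spread yields exactly 1 with a degenerate CI. Raters with any
missing rating are dropped listwise for the ICC (the study's raters
scored every item); the other metrics use pairwise-complete data.

Supporting statistics: the bimodality flag (>40% in the 7–9 band *and*
>40% in the 1–3 band, a marker of irreconcilable disagreement —
impossible once either band exceeds 60%); per-item and per-rater mean
absolute score change between rounds with the shares changing by 1–2
and by ≥3 points; per-item SD change; a Welch two-sample comparison of
round-1 rater means between round-2 responders and nonresponders
(pooled-variance optional; the protocol does not name its test, and
with a 42-vs-3 split unequal variances are the safer default); and an
OLS regression of per-rater mean absolute change on experience band,
coded ordinally 0–3 by default with categorical contrasts available.

## Synthetic panel generator

The raw panel ratings were never released, so the generator exists to
give every downstream stage inputs with known truth. The generative
model is additive on the latent scale:

    x_ri = mu_i + beta_r + delta_{g(r),i} + eps_ri

with item importances mu_i (given explicitly, or uniform on [2, 9]),
rater offsets beta_r ~ N(0, sigma_rater²), optional subgroup-by-item
bumps delta (summed over the rater's memberships), and residual noise
eps ~ N(0, sigma_noise²). Reported scores round half-away-from-zero
and clamp to [1, 9]; continuous mode skips both so that metrics can be
validated against closed forms (under it the ICC estimand is exactly
sigma_mu² / (sigma_mu² + sigma_rater² + sigma_noise²)). Round 2 draws
a returning rater's latent value as
(1 − w)·x1_latent + w·median₁(i) + eps′, so the convergence weight w
interpolates between independent reratings (w = 0) and total collapse
onto the fed-back medians (w = 1); per-item SD is non-increasing and
the round-2 ICC non-decreasing in w, matching the direction of the
published round-1 → round-2 change. Dropout is informative: the
log-odds of skipping round 2 rise by `dropout_slope` per point of
centered round-1 rater mean, with the intercept solved per panel so the
average dropout probability equals `dropout_p` exactly.

Defaults were fixed once to emulate the study conditions: 45 raters ×
60 items; experience-band and subgroup prevalences drawn with the
published panel frequencies; `sigma_rater = 1.0` and
`sigma_noise = 1.5` (per-item SDs land in the 1.4–2.4 range of the
published stability table, and responder rater-mean spread is near the
published 1.09); `dropout_p = 3/45`; `dropout_slope = 3.0`, which
reproduces the published attrition pattern (simulated nonresponders
outscore responders by ≈1.2–1.4 points on average, against a printed
gap of 1.40, and in the right direction in ≈98% of runs);
`convergence_w = 0.3`, giving SD reductions of the size seen between
the published rounds. Top-10 lists rank a rater's 7+-scored items by
mu with an infinitesimal seeded tie-break, so output is bit-identical
for a given seed.

What the generator does *not* emulate: item-wording effects and the
mid-study rewording of some items, free-text commentary, correlated
rater errors within care settings, and any non-additive
rater-by-item interaction beyond the subgroup bumps. Passing tests
therefore show that the pipeline recovers the truth of this model
class, not that the model describes real panels.

## Numerical and design notes

* Scores live in a long-format table; a missing rating is an absent
  row, never a sentinel, so percentage denominators are always counts
  of observed ratings.
* Feedback packets contain exactly the retained item set; a skipped
  round-1 item appears with an explicit missing own-score marker.
* Pipeline outputs are a pure function of (inputs, config, seed): a
  rerun with the same seed produces byte-identical CSVs, and every run
  log records seed, thresholds, input hashes, and package version.
* Degenerate inputs fail loudly: empty score sets, constant matrices
  (undefined ICC), empty retained sets, zero top-10 denominators, and
  single-band regressions all raise with the offending record named.
* The attrition comparison reports p = 1 when both groups are constant
  and equal (a vacuous comparison, not an error).

## Validation problem sizes

The simulation-based checks run at the study's own 45 × 60 geometry:
ICC parameter recovery averages 100 seeded continuous-mode panels
(observed |bias| < 0.01 against the closed-form estimand 4/5.5); CI
coverage uses 500 panels (observed ≈95–97% against the nominal 95%);
the informative-dropout direction check uses 500 panels; and the
convergence-direction check compares w ∈ {0, 0.5, 0.9} over 30 seeds
per point. These sizes keep the full suite and the acceptance script
each under a minute of compute while leaving Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

* The published ICC values cannot be matched exactly because the
  protocol does not state which ICC variant produced them; only
  direction and construction are validated.
* Printed medians/IQRs are carried as fixtures but no verdict depends
  on them, so the quantile convention affects reporting only.
* The Phase-3 selection meeting is human judgment; the package records
  its outcomes via manual-override fields and final-outcome labels but
  does not model it.
* Qualitative comment analysis is out of scope; comment text is carried
  as opaque digests only.
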