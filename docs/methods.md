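# Methods

## Case model and design

A patient case is a point in the 3⁵ factorial over the five ICF domains
(personal factors, environmental factors, body functions, activities,
participation), each at complexity level 1 (low), 2 (medium) or 3 (high).
Modelled complexity is summarised two ways: the **sum score** Σ levels
(range 5–15, treats domains additively) and the **product score** Π levels
(range 1–243, lets high levels compound). Within any 13-case design the two
are strongly rank-correlated; the package computes both throughout.

Case ids use the canonical encoding `id = 1 + Σ_d (level_d − 1)·3^(5−d)`
with the domains in the ICF order above and domain 1 most significant. The
built-in 13-case study design {82, 64, 34, 21, 17, 175, 218, 60, 171, 201,
131, 241, 153} decodes under this convention to the published sum/product
pairs with median sum 10 and median product 18. One caveat is inherent to
decoding from ids alone: the digit-to-domain assignment of a balanced
design is only partially identifiable. The study text places the
exceptional 5/5/3 level-count profile on *Activities*, but in the decoded
design that profile falls on the third (body-functions) digit; since every
analysis quantity here is invariant to domain order, `load_study_design`
carries its observed constraint profile, `select_balanced_design` follows
the text (5/5/3 on Activities), and `check_balance` offers a
permutation-insensitive mode for comparing the two conventions.

**Design selection.** Balance constraints fix, per domain, how often each
level appears across the 13 cases. The sampler draws each domain column as
an independent uniform permutation of the multiset its constraint
prescribes — the marginal counts then hold by construction — and rejects
only draws containing duplicate cases, retrying up to `max_attempts`
(default 10 000; duplicate draws are rare, so the budget is effectively
never binding for feasible constraints). Given a seed the result is
deterministic.

## Synthetic cohort generator

The generator emulates the questionnaire study the analysis was built for:
~110 analysable respondents from nursing (47 %), medical (42 %) and
health/social (11 %) professions scoring 13 cases. All outcome models are
driven by z(S_c), the design-standardized modelled sum score (population
SD; the product score can be selected with `complexity_driver="product"`).

Per respondent j, drawn once per cohort:

| parameter | default | role |
|---|---|---|
| μ_j (perceived baseline) | Normal(50, 10) | response-scale location, 0–100 slider units |
| β_j (perceived slope) | Normal(15, 6) | slider units per SD of modelled complexity |
| baseline/slope, inclination | Normal(55, 10) / Normal(15, 6) | same, for the care-plan inclination slider |
| σ_j (slider noise SD) | Uniform(6, 14) | within-respondent noise |
| α_j, γ_j (meeting log-odds) | Normal(0.2, 0.8), Normal(1.3, 0.4) | meeting probability ≈ 0.1 at the design's minimum complexity, ≈ 0.9 at its maximum |
| π_j (completion) | 90 %: Uniform(0.9, 1); 10 %: Uniform(0.2, 0.6) | record-level Bernoulli missingness; the low group mostly fails the >50 % completion rule, mimicking the ~10 % attrition between consenting and analysable respondents |

Slider values are clipped to [0, 100] (slider censoring), not resampled.
Roster selection, asked only when a meeting is indicated, is independent
per member with probability logistic(a_m + b_m·z): core members (parent,
paediatric nurse, paediatrician) have a_m ≥ 3.5 and are near-always
selected; the two urology specialists are mid-frequency; the remaining
members have negative intercepts and positive slopes near 1, so teams widen
and densify as complexity rises. Profession-group effects on preferences
default to zero but the parameter set is fully overridable.

What the generator does **not** emulate: correlated slopes across outcomes
within a respondent, heteroscedastic noise over complexity, profession- or
experience-dependent preference structure, free-text "other" entries, and
any ordering or fatigue effects. Passing tests therefore demonstrate that
the analysis machinery recovers structure of this idealized kind, not that
the original study's specific coefficient values are reproduced — those
depend on the unavailable raw responses.

## Preprocessing

Respondents are retained only if they completed strictly more than half of
the design's cases. Mean-centring is per respondent over completed cases;
rank transformation uses mid-ranks for ties and is likewise computed
within respondent (the per-participant correlation design requires ranks
on each respondent's own completed subset, including the modelled-score
ranks). The binary meeting answer stays coded 1/no, 2/yes and is never
ranked.

## Correlation aggregation

Per variable pair, each respondent contributes a Pearson r_j over their
completed cases (minimum 3; respondents with a constant variable — e.g.
"yes" to every meeting question — are excluded and logged). Aggregation
uses completed-case weights w_j:

* R_weighted = Σw_j r_j / Σw_j (raw-r averaging; a Fisher-z variant is
  available via `ci_method="fisher"`),
* p_weighted = Σw_j p_j / Σw_j — a *descriptive* average of per-respondent
  p-values, deliberately reported as such: averaging p-values is not a
  calibrated combined test, and no inferential claim should rest on it,
* 95 % CI_weighted = R_weighted ± 1.96·s_w truncated to [−1, 1], with s_w
  the weighted standard deviation of the r_j in population form
  (denominator Σw_j, so equal weights reduce exactly to the unweighted
  population SD). The interval describes inter-individual spread; its
  upper bound truncates at 1 whenever strong responders pile up near
  r = 1, which is the expected appearance under a positive regime.

Kendall's tau-b is computed by explicit concordant/discordant pair
counting with tie correction — exact at the 13-case scale this analysis
ever needs — with two-sided p by full permutation enumeration for n ≤ 8
and the tie-corrected normal approximation otherwise.

## Networks

Per case, only respondents indicating a meeting contribute. Nodes are the
fixed 15-member roster; node weight is the selection proportion among
those responders; an edge joins two members co-selected by at least one
responder (threshold configurable), weighted by the count of such
responders. Centralities are computed on the binarized edge-presence
graph: integer degree; unnormalized Brandes betweenness (fractional credit
over multiple shortest paths, endpoints excluded); closeness as 1/Σd
restricted to the node's connected component and undefined (NaN) for
isolates. These conventions match the magnitudes a 15-node roster table
produces (closeness exactly 1/14 for a member adjacent to all others;
integer degrees 0–14). Density is 2E/(N(N−1)) with N = 15 by default; an
observed-members base is provided because either reading of "all potential
interactions" is defensible. Display cases for centrality tables are the
minimum, quartiles, median and maximum of modelled complexity, with
product score and then case id breaking sum-score ties.

## Numerical and scale choices

Analyses in the test-suite and acceptance script run at the study's own
scale — 13 cases, 110 respondents, 50–100 replicate cohorts where a claim
is about replication frequency — which keeps every run deterministic,
seconds-fast and statistically adequate for the qualitative claims being
checked. The pipeline fans a single global seed into per-stage child seeds
via `numpy.random.SeedSequence(seed).generate_state(...)`, so stages can
be rerun in isolation. Degenerate inputs are handled by explicit signals:
constant vectors reject correlation, all-tied vectors reject tau-b,
sub-2-node bases reject density, empty per-case networks are returned
flagged with zero responders.

## Known limitations

The weighted CI and averaged p-value follow the aggregation they are meant
to describe and are not inferential machinery; users needing tests should
fit a mixed model instead. The generator's independence assumptions (see
above) make recovery checks necessary but not sufficient evidence about
real questionnaire data. Closeness on disconnected graphs is
component-restricted by construction, so comparing closeness across cases
with different component structures compares within-component efficiency
only.
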