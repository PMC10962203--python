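"""Synthetic respondent cohorts for the vignette questionnaire.

The reference study's raw questionnaire responses are not public, so this
module simulates cohorts with the statistical structure the downstream
analysis assumes: each respondent carries their own response-scale baseline,
complexity sensitivity and noise level (the study reports large
inter-individual variation), scores every vignette they complete on 0-100
sliders for perceived complexity and inclination towards integrated care
planning, indicates whether an interprofessional team meeting is needed
(probability rising with complexity), and — only when a meeting is
indicated — multi-selects team members from the fixed 15-member roster,
with core members (parent, paediatric nurse, paediatrician) near-always
chosen and peripheral members increasingly chosen as complexity rises.

All outcome models are driven by the standardized modelled complexity of a
case within the design, z(S_c):

    perceived   = clip[0,100]( mu_j + beta_j * z + Normal(0, sigma_j) )
    inclination = analogous, own baseline/slope
    P(meeting)  = logistic( alpha_j + gamma_j * z )
    P(member m | meeting) = logistic( a_m + b_m * z )

Record-level missingness is independent Bernoulli with per-respondent
completion probability pi_j; a sub-population with low pi_j mimics the
respondents that the >50 % completion rule later removes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import BalancedDesign
from .roster import ROSTER_NAMES

PROFESSION_GROUPS = ("nursing", "medical", "health_social")

SELECTION_SEP = ";"


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class MemberPropensity:
    """Logistic selection model of one roster member: intercept ``a`` and
    slope ``b`` on standardized case complexity (log-odds units)."""

    a: float
    b: float


#: Default roster selection propensities.  Core members (parent, paediatric
#: nurse, paediatrician) are near-always selected; the two urology
#: specialists are context-typical mid-frequency picks; the remaining
#: members are peripheral at low complexity and increasingly selected as
#: complexity rises.
DEFAULT_MEMBER_PROPENSITIES: dict[str, MemberPropensity] = {
    "parent": MemberPropensity(4.0, 0.3),
    "paediatric nurse": MemberPropensity(3.5, 0.4),
    "nurse specialist urology": MemberPropensity(1.5, 0.8),
    "other paediatric nurse specialist": MemberPropensity(-1.5, 1.2),
    "paediatrician": MemberPropensity(3.5, 0.4),
    "paediatric urologist": MemberPropensity(1.5, 0.8),
    "other medical specialist": MemberPropensity(-1.5, 1.2),
    "dietician": MemberPropensity(-2.0, 1.0),
    "physiotherapist": MemberPropensity(-2.0, 1.0),
    "social worker": MemberPropensity(-1.0, 1.2),
    "medical pedagogical care provider": MemberPropensity(-1.5, 1.0),
    "psychologist": MemberPropensity(-1.0, 1.2),
    "other health professional": MemberPropensity(-2.5, 1.0),
    "general practitioner": MemberPropensity(-1.0, 0.8),
    "other external professional": MemberPropensity(-2.5, 1.0),
}


@dataclass(frozen=True)
class CohortParams:
    """Population-level parameters from which per-respondent profiles are
    drawn.

    Defaults emulate the reference study's qualitative regime: a cohort of
    ~110 analysable respondents split roughly 47/42/11 % across nursing,
    medical and health/social professions; positive mean complexity
    sensitivity with wide inter-individual spread; meeting probability
    rising from roughly 0.1 at minimum modelled complexity to 0.9 at the
    maximum; and about one respondent in ten completing too few cases to
    survive the >50 % completion rule.
    """

    # profession mix (probabilities over PROFESSION_GROUPS)
    group_probs: tuple[float, float, float] = (0.47, 0.42, 0.11)
    # perceived complexity (0-100 slider)
    perceived_baseline_mean: float = 50.0
    perceived_baseline_sd: float = 10.0
    perceived_slope_mean: float = 15.0
    perceived_slope_sd: float = 6.0
    # inclination towards integrated care planning (0-100 slider)
    inclination_baseline_mean: float = 55.0
    inclination_baseline_sd: float = 10.0
    inclination_slope_mean: float = 15.0
    inclination_slope_sd: float = 6.0
    # slider noise sd, uniform per respondent
    noise_sd_low: float = 6.0
    noise_sd_high: float = 14.0
    # meeting indication (log-odds scale)
    meeting_intercept_mean: float = 0.2
    meeting_intercept_sd: float = 0.8
    meeting_slope_mean: float = 1.3
    meeting_slope_sd: float = 0.4
    # record-level completion
    complete_responder_prob: float = 0.9
    completion_full_range: tuple[float, float] = (0.9, 1.0)
    completion_low_range: tuple[float, float] = (0.2, 0.6)
    # roster selection model
    member_propensities: dict[str, MemberPropensity] = field(
        default_factory=lambda: dict(DEFAULT_MEMBER_PROPENSITIES)
    )
    # which modelled complexity score drives outcomes
    complexity_driver: str = "sum"  # "sum" | "product"

    def __post_init__(self) -> None:
        if abs(sum(self.group_probs) - 1.0) > 1e-9:
            raise ValueError("group_probs must sum to 1")
        if not 0.0 <= self.complete_responder_prob <= 1.0:
            raise ValueError("complete_responder_prob must be a probability")
        for lo, hi in (self.completion_full_range, self.completion_low_range):
            if not (0.0 < lo <= hi <= 1.0):
                raise ValueError("completion probability ranges must lie in (0, 1]")
        if self.noise_sd_low < 0 or self.noise_sd_high < self.noise_sd_low:
            raise ValueError("noise sd range must be non-negative and ordered")
        if self.complexity_driver not in ("sum", "product"):
            raise ValueError("complexity_driver must be 'sum' or 'product'")
        if set(self.member_propensities) != set(ROSTER_NAMES):
            raise ValueError("member_propensities must cover the 15-member roster exactly")

    def replace(self, **changes) -> "CohortParams":
        return dataclasses.replace(self, **changes)


def default_cohort_params() -> CohortParams:
    """The documented default parameter set (see class docstring)."""
    return CohortParams()


@dataclass(frozen=True)
class ResponseTable:
    """Long-format respondent x case questionnaire records.

    ``records`` columns: respondent_id, case_id, perceived, inclination,
    meeting (1 = no meeting, 2 = meeting), selections (semicolon-joined
    roster names, empty when meeting = 1).  ``respondents`` carries the
    simulated per-respondent profiles (profession group, true baselines,
    slopes, noise, completion probability) for parameter-recovery checks;
    it is absent for tables read from external files.
    """

    records: pd.DataFrame
    design: BalancedDesign
    respondents: pd.DataFrame | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.records.duplicated(["respondent_id", "case_id"]).any():
            raise ValueError("duplicate (respondent_id, case_id) pairs")
        known = set(self.design.case_ids)
        bad = set(self.records["case_id"]) - known
        if bad:
            raise ValueError(f"records reference case ids outside the design: {sorted(bad)}")

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def standardized_complexity(design: BalancedDesign, driver: str = "sum") -> np.ndarray:
    """z-scores of the design's modelled complexity (population sd)."""
    scores = np.asarray(
        design.sum_scores if driver == "sum" else design.product_scores, dtype=float
    )
    sd = scores.std()
    if sd == 0:
        raise ValueError("design complexity scores are constant; cannot standardize")
    return (scores - scores.mean()) / sd


def simulate_cohort(
    design: BalancedDesign,
    n_respondents: int,
    params: CohortParams | None = None,
    seed: int = 0,
) -> ResponseTable:
    """Simulate a respondent cohort over a questionnaire design.

    Deterministic given ``seed``.  Respondent ids are ``r001`` ...; records
    for cases a respondent did not complete are simply absent.
    """
    if n_respondents < 1:
        raise ValueError("n_respondents must be >= 1")
    if not design.cases:
        raise ValueError("design is empty")
    params = params or default_cohort_params()
    rng = np.random.default_rng(seed)
    n_cases = len(design.cases)
    z = standardized_complexity(design, params.complexity_driver)
    case_ids = np.asarray(design.case_ids)
    member_names = list(ROSTER_NAMES)
    a = np.array([params.member_propensities[m].a for m in member_names])
    b = np.array([params.member_propensities[m].b for m in member_names])

    width = max(3, len(str(n_respondents)))
    resp_rows = []
    rec_rows: dict[str, list] = {
        "respondent_id": [], "case_id": [], "perceived": [],
        "inclination": [], "meeting": [], "selections": [],
    }
    for j in range(n_respondents):
        rid = f"r{j + 1:0{width}d}"
        group = PROFESSION_GROUPS[rng.choice(3, p=params.group_probs)]
        mu_p = rng.normal(params.perceived_baseline_mean, params.perceived_baseline_sd)
        beta_p = rng.normal(params.perceived_slope_mean, params.perceived_slope_sd)
        mu_i = rng.normal(params.inclination_baseline_mean, params.inclination_baseline_sd)
        beta_i = rng.normal(params.inclination_slope_mean, params.inclination_slope_sd)
        sigma = rng.uniform(params.noise_sd_low, params.noise_sd_high)
        alpha = rng.normal(params.meeting_intercept_mean, params.meeting_intercept_sd)
        gamma = rng.normal(params.meeting_slope_mean, params.meeting_slope_sd)
        if rng.random() < params.complete_responder_prob:
            pi = rng.uniform(*params.completion_full_range)
        else:
            pi = rng.uniform(*params.completion_low_range)
        resp_rows.append(
            {
                "respondent_id": rid, "profession_group": group,
                "perceived_baseline": mu_p, "perceived_slope": beta_p,
                "inclination_baseline": mu_i, "inclination_slope": beta_i,
                "noise_sd": sigma, "meeting_intercept": alpha,
                "meeting_slope": gamma, "completion_prob": pi,
            }
        )
        kept = rng.random(n_cases) < pi
        perceived = np.clip(mu_p + beta_p * z + rng.normal(0, sigma, n_cases), 0, 100)
        inclination = np.clip(mu_i + beta_i * z + rng.normal(0, sigma, n_cases), 0, 100)
        meeting = np.where(rng.random(n_cases) < _logistic(alpha + gamma * z), 2, 1)
        sel_prob = _logistic(a[None, :] + b[None, :] * z[:, None])
        selected = rng.random((n_cases, len(member_names))) < sel_prob
        for c in range(n_cases):
            if not kept[c]:
                continue
            if meeting[c] == 2:
                names = [m for m, s in zip(member_names, selected[c]) if s]
            else:
                names = []
            rec_rows["respondent_id"].append(rid)
            rec_rows["case_id"].append(int(case_ids[c]))
            rec_rows["perceived"].append(float(perceived[c]))
            rec_rows["inclination"].append(float(inclination[c]))
            rec_rows["meeting"].append(int(meeting[c]))
            rec_rows["selections"].append(SELECTION_SEP.join(names))
    records = pd.DataFrame(rec_rows)
    respondents = pd.DataFrame(resp_rows)
    return ResponseTable(records=records, design=design, respondents=respondents, seed=seed)


def read_responses_csv(path: str | Path, design: BalancedDesign) -> ResponseTable:
    """Ingest an externally supplied responses file (same schema the
    simulator writes), validating ranges and roster membership."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    problems = validate_records(df)
    if problems:
        raise ValueError(f"invalid responses file {path}: " + "; ".join(problems))
    df = df.copy()
    df["selections"] = df["selections"].fillna("")
    return ResponseTable(records=df, design=design)


def validate_records(df: pd.DataFrame) -> list[str]:
    """Schema/range violations of a long-format responses frame (empty list
    when clean)."""
    problems: list[str] = []
    required = ["respondent_id", "case_id", "perceived", "inclination", "meeting", "selections"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        return [f"missing columns: {missing}"]
    for col in ("perceived", "inclination"):
        vals = pd.to_numeric(df[col], errors="coerce")
        out = df.loc[vals.notna() & ((vals < 0) | (vals > 100))]
        if len(out):
            problems.append(f"{col} outside [0, 100] in {len(out)} records")
    meet = pd.to_numeric(df["meeting"], errors="coerce")
    bad_meet = df.loc[~meet.isin([1, 2]) & meet.notna()]
    if len(bad_meet):
        problems.append(f"meeting not in {{1, 2}} in {len(bad_meet)} records")
    roster = set(ROSTER_NAMES)
    unknown: set[str] = set()
    for s in df["selections"].fillna(""):
        if s:
            unknown |= {m for m in str(s).split(SELECTION_SEP) if m and m not in roster}
    if unknown:
        problems.append(f"unknown roster members in selections: {sorted(unknown)}")
    if df.duplicated(["respondent_id", "case_id"]).any():
        problems.append("duplicate (respondent_id, case_id) pairs")
    return problems
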