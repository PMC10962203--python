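"""Per-participant correlations, weighted aggregation and rank statistics.

The repeated-measures design (every respondent scores the same 13 cases)
is handled by computing a Pearson correlation per participant over that
participant's completed cases and aggregating across participants with
weights equal to each participant's completed-case count w_j:

    R_weighted = sum_j w_j r_j / sum_j w_j
    p_weighted = sum_j w_j p_j / sum_j w_j
    95 % CI_weighted = R_weighted +/- 1.96 * s_w,  truncated to [-1, 1]

where s_w is the weighted (population-form) standard deviation of the r_j.
The interval describes inter-individual variation in the association, not
a standard error of the mean; p_weighted is a descriptive average of
per-participant p-values, not a combined significance test.  A Fisher-z
variant of the aggregation is available behind ``ci_method="fisher"``.

Kendall's tau-b (tie-corrected) links per-case network density to modelled
and perceived complexity; it is computed by explicit concordant/discordant
pair counting, which is exact and fast at questionnaire scale (13 cases).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Variable pairs of the correlation analysis: label -> (x column, y column)
#: of a preprocessed frame.  The binary meeting indication enters as coded
#: 1/2 (point-biserial equivalence); all other variables enter rank-
#: transformed.
VARIABLE_PAIRS: dict[str, tuple[str, str]] = {
    "sum~perceived": ("rt_sum", "rt_perceived"),
    "product~perceived": ("rt_product", "rt_perceived"),
    "sum~inclination": ("rt_sum", "rt_inclination"),
    "product~inclination": ("rt_product", "rt_inclination"),
    "sum~meeting": ("rt_sum", "meeting"),
    "product~meeting": ("rt_product", "meeting"),
    "perceived~inclination": ("rt_perceived", "rt_inclination"),
    "inclination~meeting": ("rt_inclination", "meeting"),
    "perceived~meeting": ("rt_perceived", "meeting"),
}

MIN_CASES_PER_CORRELATION = 3


@dataclass(frozen=True)
class WeightedCorrSummary:
    pair: str
    r_weighted: float
    ci_low: float
    ci_high: float
    p_weighted: float
    n_participants: int
    n_excluded: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.r_weighted <= self.ci_high):
            raise ValueError("weighted CI must bracket the weighted mean")


@dataclass(frozen=True)
class KendallResult:
    tau: float
    p_value: float
    n: int


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p from the
    t-distribution (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < MIN_CASES_PER_CORRELATION:
        raise ValueError(f"need at least {MIN_CASES_PER_CORRELATION} paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def per_participant_correlations(processed: pd.DataFrame, pair: str) -> pd.DataFrame:
    """One Pearson correlation per respondent for a variable pair.

    Respondents with fewer than three completed cases or a constant
    variable (e.g. answering "yes" to the meeting question on every case)
    have no defined correlation; they are excluded and logged.

    Returns columns respondent_id, r, p, w (completed-case count).
    """
    if processed.empty:
        raise ValueError("processed table is empty")
    if pair not in VARIABLE_PAIRS:
        raise KeyError(f"unknown pair {pair!r}; known: {sorted(VARIABLE_PAIRS)}")
    xcol, ycol = VARIABLE_PAIRS[pair]
    rows, excluded = [], []
    for rid, g in processed.groupby("respondent_id", sort=False):
        x = g[xcol].to_numpy(dtype=float)
        y = g[ycol].to_numpy(dtype=float)
        if x.size < MIN_CASES_PER_CORRELATION or np.ptp(x) == 0 or np.ptp(y) == 0:
            excluded.append(rid)
            continue
        r, p = pearson_r(x, y)
        rows.append({"respondent_id": rid, "r": r, "p": p, "w": int(x.size)})
    if excluded:
        logger.info(
            "pair %s: excluded %d respondent(s) with undefined correlation: %s",
            pair, len(excluded), ", ".join(map(str, excluded[:10])),
        )
    out = pd.DataFrame(rows, columns=["respondent_id", "r", "p", "w"])
    out.attrs["pair"] = pair
    out.attrs["n_excluded"] = len(excluded)
    return out


def aggregate_weighted(
    correlations: pd.DataFrame, *, ci_method: str = "normal"
) -> WeightedCorrSummary:
    """Aggregate per-participant correlations with completed-case weights.

    ``ci_method="normal"`` (default) averages the raw r_j; ``"fisher"``
    averages Fisher-z transforms and back-transforms the mean and interval.
    Both intervals are mean +/- 1.96 weighted population SD, truncated to
    [-1, 1].
    """
    if len(correlations) < 2:
        raise ValueError("need at least 2 participants to aggregate")
    if ci_method not in ("normal", "fisher"):
        raise ValueError(f"ci_method must be 'normal' or 'fisher', got {ci_method!r}")
    r = correlations["r"].to_numpy(dtype=float)
    p = correlations["p"].to_numpy(dtype=float)
    w = correlations["w"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    wsum = w.sum()
    p_weighted = float((w * p).sum() / wsum)
    if ci_method == "normal":
        r_weighted = float((w * r).sum() / wsum)
        s_w = math.sqrt(float((w * (r - r_weighted) ** 2).sum() / wsum))
        lo, hi = r_weighted - 1.96 * s_w, r_weighted + 1.96 * s_w
    else:
        z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
        z_mean = float((w * z).sum() / wsum)
        z_sd = math.sqrt(float((w * (z - z_mean) ** 2).sum() / wsum))
        r_weighted = float(np.tanh(z_mean))
        lo, hi = np.tanh(z_mean - 1.96 * z_sd), np.tanh(z_mean + 1.96 * z_sd)
    return WeightedCorrSummary(
        pair=correlations.attrs.get("pair", ""),
        r_weighted=r_weighted,
        ci_low=float(max(lo, -1.0)),
        ci_high=float(min(hi, 1.0)),
        p_weighted=p_weighted,
        n_participants=len(correlations),
        n_excluded=int(correlations.attrs.get("n_excluded", 0)),
    )


def correlation_summaries(
    processed: pd.DataFrame,
    pairs: list[str] | None = None,
    *,
    ci_method: str = "normal",
) -> dict[str, WeightedCorrSummary]:
    """Weighted correlation summary for each requested variable pair."""
    out = {}
    for pair in pairs or list(VARIABLE_PAIRS):
        out[pair] = aggregate_weighted(
            per_participant_correlations(processed, pair), ci_method=ci_method
        )
    return out


def _pair_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    """Concordant and discordant pair counts over all i < j (ties in either
    variable count as neither)."""
    i, j = np.triu_indices(x.size, k=1)
    s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
    return int((s > 0).sum()), int((s < 0).sum())


def _tau_b_from_counts(x: np.ndarray, y: np.ndarray, conc: int, disc: int) -> float:
    n = x.size
    n0 = n * (n - 1) // 2
    n1 = sum(t * (t - 1) // 2 for t in np.unique(x, return_counts=True)[1])
    n2 = sum(t * (t - 1) // 2 for t in np.unique(y, return_counts=True)[1])
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0:
        raise ValueError("tau-b undefined: a variable is entirely tied")
    return (conc - disc) / denom


def kendall_tau_b(x, y, *, exact_max_n: int = 8) -> KendallResult:
    """Kendall's tau-b by explicit pair counting with tie correction.

    The two-sided p-value is by exact permutation enumeration for
    n <= ``exact_max_n`` and the tie-corrected normal approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    conc, disc = _pair_counts(x, y)
    tau = _tau_b_from_counts(x, y, conc, disc)
    if n <= exact_max_n:
        hits = total = 0
        target = abs(tau) - 1e-12
        for perm in itertools.permutations(y):
            yp = np.asarray(perm)
            c, d = _pair_counts(x, yp)
            if abs(_tau_b_from_counts(x, yp, c, d)) >= target:
                hits += 1
            total += 1
        p = hits / total
    else:
        # tie-corrected asymptotic variance of C - D
        _, tx = np.unique(x, return_counts=True)
        _, ty = np.unique(y, return_counts=True)
        v0 = n * (n - 1) * (2 * n + 5)
        vt = sum(t * (t - 1) * (2 * t + 5) for t in tx)
        vu = sum(u * (u - 1) * (2 * u + 5) for u in ty)
        v1 = (
            sum(t * (t - 1) for t in tx) * sum(u * (u - 1) for u in ty)
        ) / (2 * n * (n - 1))
        v2 = (
            sum(t * (t - 1) * (t - 2) for t in tx)
            * sum(u * (u - 1) * (u - 2) for u in ty)
        ) / (9 * n * (n - 1) * (n - 2))
        var = (v0 - vt - vu) / 18 + v1 + v2
        z = (conc - disc) / math.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
    return KendallResult(tau=float(tau), p_value=float(min(p, 1.0)), n=int(n))


def case_descriptives(processed: pd.DataFrame, design) -> pd.DataFrame:
    """Per-case descriptive statistics in ascending modelled complexity:
    modelled sum/product, mean (SD) of MC perceived and MC inclination and
    the percentage of respondents indicating a meeting, plus a design-level
    summary row of medians and IQRs."""
    scores = design.to_frame()[["case_id", "sum_score", "product_score"]]
    rows = []
    for _, case in scores.sort_values(["sum_score", "product_score"]).iterrows():
        g = processed[processed["case_id"] == case["case_id"]]
        rows.append(
            {
                "case_id": int(case["case_id"]),
                "sum_score": int(case["sum_score"]),
                "product_score": int(case["product_score"]),
                "mc_perceived_mean": g["mc_perceived"].mean(),
                "mc_perceived_sd": g["mc_perceived"].std(ddof=1),
                "mc_inclination_mean": g["mc_inclination"].mean(),
                "mc_inclination_sd": g["mc_inclination"].std(ddof=1),
                "pct_meeting_yes": 100.0 * (g["meeting"] == 2).mean() if len(g) else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    sums = scores["sum_score"]
    prods = scores["product_score"]

    def _iqr(s: pd.Series) -> float:
        return float(s.quantile(0.75) - s.quantile(0.25))

    out.attrs["summary"] = {
        "sum_median": float(sums.median()),
        "sum_iqr": _iqr(sums),
        "product_median": float(prods.median()),
        "product_iqr": _iqr(prods),
        "pct_meeting_yes_mean": float(out["pct_meeting_yes"].mean()),
    }
    return out


def iqr_by_rank(processed: pd.DataFrame, rank_col: str = "rt_sum") -> pd.DataFrame:
    """Interquartile range of the RT outcome scores across participants,
    grouped by modelled-complexity rank (inter-individual spread per rank)."""
    if rank_col not in processed.columns:
        raise KeyError(f"no rank column {rank_col!r} in processed table")
    rows = []
    for rank, g in processed.groupby(rank_col):
        rows.append(
            {
                "rank": float(rank),
                "n": len(g),
                "iqr_rt_perceived": float(
                    g["rt_perceived"].quantile(0.75) - g["rt_perceived"].quantile(0.25)
                ),
                "iqr_rt_inclination": float(
                    g["rt_inclination"].quantile(0.75) - g["rt_inclination"].quantile(0.25)
                ),
            }
        )
    return pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)


def posthoc_coeff_vs_spread(
    correlations: pd.DataFrame, processed: pd.DataFrame, score_col: str = "mc_perceived"
) -> KendallResult:
    """Association between participants' correlation coefficients and their
    own score variability (SD of an MC/RT score) — the check that strong
    individual associations are not an artefact of wide response spread."""
    if len(correlations) < 3:
        raise ValueError("need at least 3 participants")
    sds = processed.groupby("respondent_id")[score_col].std(ddof=1)
    merged = correlations.set_index("respondent_id").join(sds.rename("sd"), how="inner")
    return kendall_tau_b(merged["r"], merged["sd"], exact_max_n=0)
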