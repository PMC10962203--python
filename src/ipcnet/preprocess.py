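"""Preprocessing: completion filter, mean-centring and rank transformation.

Two steps precede the correlation analysis.  Mean-centring (MC) subtracts
each respondent's own mean from their perceived-complexity and inclination
scores, removing individual response-scale baselines in the repeated-
measures design.  Rank transformation (RT) replaces values by within-
respondent mid-ranks to robustify Pearson correlations against non-normal
slider distributions; it is applied to MC perceived, MC inclination and the
modelled sum/product complexity scores (the binary meeting indication stays
coded 1/2).  Ranks are computed within each respondent over that
respondent's completed cases only, because correlations are later computed
per participant.

Respondents are retained only if they completed strictly more than half of
the design's cases.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import ResponseTable

logger = logging.getLogger(__name__)


def mean_centre(values) -> np.ndarray:
    """Subtract the mean of ``values`` from each value."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot mean-centre an empty vector")
    return arr - arr.mean()


def rank_transform(values) -> np.ndarray:
    """Ascending ranks with ties assigned mid-ranks."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty vector")
    return rankdata(arr, method="average")


def encode_meeting(answer: str) -> int:
    """Code the meeting question: ``"no"`` -> 1, ``"yes"`` -> 2."""
    coded = {"no": 1, "yes": 2}
    key = str(answer).strip().lower()
    if key not in coded:
        raise ValueError(f"meeting answer must be 'yes' or 'no', got {answer!r}")
    return coded[key]


def filter_completion(table: ResponseTable, threshold: float = 0.5) -> ResponseTable:
    """Keep respondents who completed strictly more than ``threshold`` of
    the design's cases (default: more than 50 %)."""
    design_size = len(table.design.cases)
    counts = table.records.groupby("respondent_id").size()
    keep = counts[counts > threshold * design_size].index
    dropped = len(counts) - len(keep)
    if dropped:
        logger.info("completion filter dropped %d of %d respondents", dropped, len(counts))
    records = table.records[table.records["respondent_id"].isin(keep)].reset_index(drop=True)
    if records.empty:
        logger.warning("completion filter removed every respondent")
    respondents = table.respondents
    if respondents is not None:
        respondents = respondents[respondents["respondent_id"].isin(keep)].reset_index(drop=True)
    return ResponseTable(
        records=records, design=table.design, respondents=respondents, seed=table.seed
    )


def preprocess(table: ResponseTable, threshold: float = 0.5) -> pd.DataFrame:
    """Apply the completion filter, then MC and within-respondent RT.

    Returns a long-format frame with, per record: the raw scores, the
    design's modelled sum/product scores, ``mc_perceived``/``mc_inclination``,
    within-respondent mid-ranks ``rt_perceived``/``rt_inclination``/
    ``rt_sum``/``rt_product``, and the respondent's completed-case count
    ``weight`` (the later aggregation weight).
    """
    filtered = filter_completion(table, threshold)
    scores = filtered.design.to_frame()[["case_id", "sum_score", "product_score"]]
    df = filtered.records.merge(scores, on="case_id", how="left")

    if df.empty:
        for col in ("mc_perceived", "mc_inclination", "rt_perceived",
                    "rt_inclination", "rt_sum", "rt_product", "weight"):
            df[col] = pd.Series(dtype=float)
        return df

    parts = []
    for _, g in df.groupby("respondent_id", sort=False):
        g = g.copy()
        g["mc_perceived"] = mean_centre(g["perceived"])
        g["mc_inclination"] = mean_centre(g["inclination"])
        g["rt_perceived"] = rank_transform(g["mc_perceived"])
        g["rt_inclination"] = rank_transform(g["mc_inclination"])
        g["rt_sum"] = rank_transform(g["sum_score"])
        g["rt_product"] = rank_transform(g["product_score"])
        g["weight"] = len(g)
        parts.append(g)
    return pd.concat(parts, ignore_index=True)
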