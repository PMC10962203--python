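"""End-to-end orchestration: design -> simulate -> preprocess -> correlate
-> network, with persisted intermediates and a machine-readable report.

A single global seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence(seed).generate_state(...)`` (stage order:
design, cohort), so each stage can be rerun in isolation with its own seed
while the whole run stays deterministic under the global one.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import design as design_mod
from . import network as net_mod
from . import stats as stats_mod
from .preprocess import preprocess as preprocess_table
from .cohort import CohortParams, ResponseTable, default_cohort_params, simulate_cohort

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    design_source: str = "study"  # "study" | "generated" | path to a design CSV
    n_respondents: int = 110
    cohort_params: CohortParams = field(default_factory=default_cohort_params)
    completion_threshold: float = 0.5
    ci_method: str = "normal"  # "normal" | "fisher"
    node_base: str = "full_roster"  # "full_roster" | "observed"
    edge_threshold: int = 1
    significance_level: float = 0.05
    pairs: tuple[str, ...] = tuple(stats_mod.VARIABLE_PAIRS)
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.significance_level < 1.0:
            raise ValueError("significance_level must be in (0, 1)")
        unknown = set(self.pairs) - set(stats_mod.VARIABLE_PAIRS)
        if unknown:
            raise ValueError(f"unknown variable pairs: {sorted(unknown)}")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds from the global seed."""
    state = np.random.SeedSequence(seed).generate_state(2)
    return {"design": int(state[0] % 2**31), "cohort": int(state[1] % 2**31)}


def resolve_design(config: PipelineConfig) -> design_mod.BalancedDesign:
    if config.design_source == "study":
        return design_mod.load_study_design()
    if config.design_source == "generated":
        return design_mod.select_balanced_design(seed=stage_seeds(config.seed)["design"])
    return design_mod.read_design_csv(config.design_source)


def _summary_dict(s: stats_mod.WeightedCorrSummary) -> dict:
    return {
        "pair": s.pair,
        "r_weighted": s.r_weighted,
        "ci_low": s.ci_low,
        "ci_high": s.ci_high,
        "p_weighted": s.p_weighted,
        "n_participants": s.n_participants,
        "n_excluded": s.n_excluded,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return the report dict.

    When ``config.out_dir`` is set, all intermediates (design, responses,
    processed table, per-participant correlations, density and centrality
    tables) and ``report.json`` are written there.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    logger.info("stage design: source=%s", config.design_source)
    design = resolve_design(config)

    logger.info("stage simulate: n=%d", config.n_respondents)
    table = simulate_cohort(
        design, config.n_respondents, config.cohort_params,
        seed=stage_seeds(config.seed)["cohort"],
    )

    logger.info("stage preprocess")
    processed = preprocess_table(table, config.completion_threshold)
    n_retained = processed["respondent_id"].nunique() if len(processed) else 0
    if n_retained < config.n_respondents:
        warnings.append(
            f"completion filter removed {config.n_respondents - n_retained} respondent(s)"
        )

    logger.info("stage correlate: %d pairs", len(config.pairs))
    summaries: dict[str, stats_mod.WeightedCorrSummary] = {}
    participant_tables: dict[str, pd.DataFrame] = {}
    for pair in config.pairs:
        corr = stats_mod.per_participant_correlations(processed, pair)
        participant_tables[pair] = corr
        if corr.attrs.get("n_excluded"):
            warnings.append(f"pair {pair}: {corr.attrs['n_excluded']} respondent(s) excluded")
        summaries[pair] = stats_mod.aggregate_weighted(corr, ci_method=config.ci_method)
    descriptives = stats_mod.case_descriptives(processed, design)

    logger.info("stage network")
    networks = net_mod.build_all_networks(table_after_filter(table, processed),
                                          edge_threshold=config.edge_threshold)
    densities = [net_mod.network_density(n, config.node_base) for n in networks.values()]
    density_taus = net_mod.density_vs_complexity(
        networks, design, processed, node_base=config.node_base
    )
    centralities = net_mod.centrality_table(
        {cid: networks[cid] for cid in net_mod.quintile_cases(design)}
    )

    meeting_yes = int((processed["meeting"] == 2).sum())
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": {
            "seed": config.seed,
            "stage_seeds": stage_seeds(config.seed),
            "design_source": str(config.design_source),
            "n_respondents": config.n_respondents,
            "completion_threshold": config.completion_threshold,
            "ci_method": config.ci_method,
            "node_base": config.node_base,
            "edge_threshold": config.edge_threshold,
            "significance_level": config.significance_level,
            "cohort_params": _params_dict(config.cohort_params),
        },
        "counts": {
            "design_cases": len(design.cases),
            "simulated_respondents": config.n_respondents,
            "retained_respondents": int(n_retained),
            "records": int(len(processed)),
            "meeting_yes": meeting_yes,
            "meeting_yes_pct": 100.0 * meeting_yes / len(processed) if len(processed) else None,
        },
        "correlations": {p: _summary_dict(s) for p, s in summaries.items()},
        "design_summary": descriptives.attrs["summary"],
        "densities": [dataclasses.asdict(d) for d in densities],
        "density_vs_complexity": {
            k: dataclasses.asdict(v) for k, v in density_taus.items()
        },
        "quintile_cases": list(net_mod.quintile_cases(design)),
        "warnings": warnings,
    }

    if out_dir:
        design.to_csv(out_dir / "design.csv")
        table.to_csv(out_dir / "responses.csv")
        processed.to_csv(out_dir / "processed.csv", index=False)
        for pair, corr in participant_tables.items():
            corr.to_csv(out_dir / f"correlations_{pair.replace('~', '_vs_')}.csv", index=False)
        descriptives.to_csv(out_dir / "case_descriptives.csv", index=False)
        pd.DataFrame([dataclasses.asdict(d) for d in densities]).to_csv(
            out_dir / "densities.csv", index=False
        )
        centralities.to_csv(out_dir / "centralities.csv", index=False)
        for cid in net_mod.quintile_cases(design):
            net_mod.export_edge_list(networks[cid], out_dir / f"network_case_{cid}.csv")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        logger.info("wrote report and intermediates to %s", out_dir)
    return report


def table_after_filter(table: ResponseTable, processed: pd.DataFrame) -> ResponseTable:
    """Restrict a response table to the respondents surviving preprocessing,
    so networks use the same analysis population as the correlations."""
    keep = set(processed["respondent_id"]) if len(processed) else set()
    records = table.records[table.records["respondent_id"].isin(keep)].reset_index(drop=True)
    return ResponseTable(
        records=records, design=table.design, respondents=table.respondents, seed=table.seed
    )


def _params_dict(params: CohortParams) -> dict:
    d = dataclasses.asdict(params)
    d["member_propensities"] = {
        m: [mp["a"], mp["b"]] for m, mp in d["member_propensities"].items()
    }
    return d


def validate_inputs(path: str | Path) -> list[str]:
    """Schema report for an external responses CSV (empty list = clean)."""
    from .cohort import validate_records

    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    return validate_records(df)
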