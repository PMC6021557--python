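"""End-to-end orchestration of the two-round Delphi analysis.

``run_pipeline`` chains the stages — summarize round 1, apply the
retention rules, assemble the round-2 item set, generate feedback,
summarize and classify round 2, and compute the agreement/stability
metrics — over either a simulated study or CSV inputs, writing report
tables that mirror the published table layouts so real and synthetic
runs are directly diffable.

``reproduce_study`` replays every claim that the packaged printed-table
fixtures can verify (retention counts, round-2 outcomes, bimodality,
participant arithmetic) and reports pass/fail per claim.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    AttritionResult,
    ICCResult,
    RegressionResult,
    StabilityReport,
    attrition_compare,
    bimodality_flag,
    experience_regression,
    icc_two_way_random,
    score_change_stats,
)
from .consensus import (
    ItemSummary,
    RetentionDecision,
    Round2Outcome,
    Thresholds,
    build_round2_itemset,
    classify_round1,
    classify_round2,
    flag_near_miss,
    subgroup_summaries,
    summarize_panel,
    top10_pct,
)
from .feedback import FeedbackPacket, feedback_for_panel
from .fixtures import (
    PARTICIPANT_COUNTS,
    fixture_decisions,
    fixture_summaries,
    load_fixture,
    round1_summaries,
)
from .io import PanelBundle, read_panel
from .simulate import SimConfig, simulate_round1, simulate_round2
from .types import Participant, RatingsPanel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "reproduce_study"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one input source applies: a :class:`SimConfig` for a
    simulated study, or the CSV paths for a real one (the ratings file
    may hold both rounds).  ``manual_overrides`` lists item ids whose
    near-miss flags a human review converted to retention.
    """

    sim: SimConfig | None = None
    ratings_path: str | None = None
    participants_path: str | None = None
    catalog_path: str | None = None
    top10_path: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    denominator_policy: str = "all_raters"
    near_miss_margin: float = 10.0
    manual_overrides: tuple[str, ...] = ()
    icc_form: str = "single"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.sim is None and self.ratings_path is None:
            raise ValueError("either a simulation config or CSV input paths are required")


@dataclass
class PipelineResult:
    """Everything one run computed, plus paths of any files written."""

    round1: RatingsPanel
    round2: RatingsPanel | None
    participants: dict[str, Participant]
    summaries_round1: dict[str, ItemSummary]
    summaries_round2: dict[str, ItemSummary]
    decisions: dict[str, RetentionDecision]
    round2_itemset: dict[str, str]
    outcomes: dict[str, Round2Outcome]
    feedback: dict[str, FeedbackPacket]
    icc_round1: ICCResult | None
    icc_round2: ICCResult | None
    stability: StabilityReport | None
    attrition: AttritionResult | None
    regression: RegressionResult | None
    bimodal_round1: list[str] = field(default_factory=list)
    bimodal_round2: list[str] = field(default_factory=list)
    output_paths: dict[str, Path] = field(default_factory=dict)


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full two-round analysis; see module docstring."""
    thr = config.thresholds

    # -- stage: inputs ----------------------------------------------------
    input_hashes: dict[str, str] = {}
    if config.sim is not None:
        sim1 = simulate_round1(config.sim)
        round1, participants = sim1.panel, sim1.participants
        round2: RatingsPanel | None = None  # simulated after retention known
    else:
        bundle = read_panel(
            config.ratings_path,
            config.participants_path,
            config.catalog_path,
            config.top10_path,
        )
        if "round1" not in bundle.panels:
            raise ValueError("input stage: ratings file contains no round1 rows")
        round1 = bundle.panels["round1"]
        round2 = bundle.panels.get("round2")
        participants = bundle.participants
        for name in ("ratings_path", "participants_path", "catalog_path", "top10_path"):
            p = getattr(config, name)
            if p is not None:
                input_hashes[name] = _file_hash(p)

    # -- stage: round-1 summaries and retention ---------------------------
    summaries1 = summarize_panel(round1)
    per_subgroup = subgroup_summaries(round1, participants, thr.subgroup_min_raters)
    n_raters = round1.n_raters
    decisions: dict[str, RetentionDecision] = {}
    for item_id, overall in summaries1.items():
        t10 = (
            top10_pct(round1.top10, item_id, n_raters, config.denominator_policy)
            if round1.top10
            else None
        )
        decisions[item_id] = classify_round1(
            overall, per_subgroup.get(item_id, {}), t10, thr
        )
    decisions = flag_near_miss(decisions, summaries1, thr, margin=config.near_miss_margin)
    itemset = build_round2_itemset(decisions, config.manual_overrides)
    if not itemset:
        raise ValueError("retention stage: no item survived round 1")

    # -- stage: feedback and round 2 --------------------------------------
    feedback = feedback_for_panel(round1, itemset)
    if config.sim is not None:
        round2 = simulate_round2(config.sim, round1, itemset)
    summaries2 = summarize_panel(round2) if round2 is not None else {}
    outcomes = {
        item_id: classify_round2(s, thr)
        for item_id, s in summaries2.items()
        if item_id in itemset
    }

    # -- stage: agreement metrics ------------------------------------------
    def _icc(panel: RatingsPanel | None) -> ICCResult | None:
        if panel is None:
            return None
        try:
            return icc_two_way_random(panel.score_matrix(), form=config.icc_form)
        except ValueError as exc:
            logger.warning("metrics stage: ICC not computed (%s)", exc)
            return None

    icc1, icc2 = _icc(round1), _icc(round2)
    bimodal1 = [i for i, s in summaries1.items() if bimodality_flag(s)]
    bimodal2 = [i for i, s in summaries2.items() if bimodality_flag(s)]

    stability = attrition = regression = None
    if round2 is not None:
        stability = score_change_stats(round1, round2)
        responders = sorted(set(round1.rater_ids) & set(round2.rater_ids))
        nonresponders = sorted(set(round1.rater_ids) - set(round2.rater_ids))
        if responders and nonresponders:
            attrition = attrition_compare(
                round1.rater_means().to_dict(), responders, nonresponders
            )
        bands = {pid: p.experience_band for pid, p in participants.items()}
        changes = stability.per_rater["mean_abs_change"].to_dict()
        if len({bands[r] for r in changes if r in bands}) >= 2:
            regression = experience_regression(changes, bands)

    result = PipelineResult(
        round1=round1,
        round2=round2,
        participants=participants,
        summaries_round1=summaries1,
        summaries_round2=summaries2,
        decisions=decisions,
        round2_itemset=itemset,
        outcomes=outcomes,
        feedback=feedback,
        icc_round1=icc1,
        icc_round2=icc2,
        stability=stability,
        attrition=attrition,
        regression=regression,
        bimodal_round1=bimodal1,
        bimodal_round2=bimodal2,
    )
    if config.out_dir is not None:
        result.output_paths = _write_reports(result, config, input_hashes)
    return result


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def round1_report_frame(
    summaries: Mapping[str, ItemSummary], decisions: Mapping[str, RetentionDecision]
) -> pd.DataFrame:
    """Round-1 table: % bands, median (IQR), decision and reason per item."""
    rows = []
    for item_id in sorted(summaries):
        s, d = summaries[item_id], decisions[item_id]
        rows.append(
            {
                "item_id": item_id,
                "n": s.n,
                "pct_7to9": round(s.pct_7to9, 2),
                "pct_1to3": round(s.pct_1to3, 2),
                "median": s.median,
                "iqr_low": s.iqr[0] if s.iqr else None,
                "iqr_high": s.iqr[1] if s.iqr else None,
                "retained": d.effective_retained,
                "reason": d.reason,
                "qualifying_subgroups": ";".join(d.qualifying_subgroups),
                "top10_pct": None if d.top10_pct is None else round(d.top10_pct, 2),
            }
        )
    return pd.DataFrame(rows)


def round2_report_frame(
    summaries: Mapping[str, ItemSummary], outcomes: Mapping[str, Round2Outcome]
) -> pd.DataFrame:
    """Round-2 table: % bands and the two rule verdicts per item."""
    rows = []
    for item_id in sorted(outcomes):
        s, o = summaries[item_id], outcomes[item_id]
        rows.append(
            {
                "item_id": item_id,
                "n": s.n,
                "pct_7to9": round(s.pct_7to9, 2),
                "pct_8or9": round(s.pct_8or9, 2),
                "pct_1to3": round(s.pct_1to3, 2),
                "preagreed": "Include" if o.preagreed else "Exclude",
                "stringent": "Include" if o.stringent else "Exclude",
            }
        )
    return pd.DataFrame(rows)


def stability_report_frame(
    result: PipelineResult,
) -> pd.DataFrame:
    """Feedback-response table: mean +/- SD per round, changes, band %, change %."""
    rows = []
    for item_id, rec in result.stability.per_item.iterrows():
        s1 = result.summaries_round1.get(item_id)
        s2 = result.summaries_round2.get(item_id)
        rows.append(
            {
                "item_id": item_id,
                "mean_round1": round(s1.mean, 2) if s1 else None,
                "sd_round1": round(rec["sd_round1"], 2),
                "mean_round2": round(s2.mean, 2) if s2 else None,
                "sd_round2": round(rec["sd_round2"], 2),
                "change_in_mean": round((s2.mean - s1.mean), 2) if s1 and s2 else None,
                "change_in_sd": round(rec["delta_sd"], 2),
                "pct_7to9_round1": round(s1.pct_7to9, 2) if s1 else None,
                "pct_7to9_round2": round(s2.pct_7to9, 2) if s2 else None,
                "pct_changing_1or2": round(rec["pct_small"], 2),
                "pct_changing_3plus": round(rec["pct_large"], 2),
            }
        )
    return pd.DataFrame(rows)


def _write_reports(
    result: PipelineResult, config: RunConfig, input_hashes: dict[str, str]
) -> dict[str, Path]:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["round1_table"] = out_dir / "round1_items.csv"
    round1_report_frame(result.summaries_round1, result.decisions).to_csv(
        paths["round1_table"], index=False
    )
    if result.outcomes:
        paths["round2_table"] = out_dir / "round2_items.csv"
        round2_report_frame(result.summaries_round2, result.outcomes).to_csv(
            paths["round2_table"], index=False
        )
    if result.stability is not None:
        paths["stability_table"] = out_dir / "stability.csv"
        stability_report_frame(result).to_csv(paths["stability_table"], index=False)

    log: dict[str, object] = {
        "package_version": __version__,
        "thresholds": vars(config.thresholds) | {},
        "denominator_policy": config.denominator_policy,
        "near_miss_margin": config.near_miss_margin,
        "seed": config.sim.seed if config.sim is not None else None,
        "input_hashes": input_hashes,
        "n_raters_round1": result.round1.n_raters,
        "n_items_round1": result.round1.n_items,
        "round2_itemset_size": len(result.round2_itemset),
    }
    for name, icc in (("icc_round1", result.icc_round1), ("icc_round2", result.icc_round2)):
        if icc is not None:
            log[name] = {
                "estimate": icc.estimate,
                "ci": [icc.ci_low, icc.ci_high],
                "form": icc.form,
            }
    if result.attrition is not None:
        log["attrition"] = {
            "mean_nonresponders": result.attrition.mean_nonresponders,
            "mean_responders": result.attrition.mean_responders,
            "p_value": result.attrition.p_value,
            "method": result.attrition.method,
        }
    if result.regression is not None:
        log["experience_regression"] = {
            "slope": result.regression.slope,
            "p_value": result.regression.p_value,
            "coding": result.regression.coding,
        }
    paths["run_log"] = out_dir / "run_log.json"
    with open(paths["run_log"], "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# fixture replay
# ---------------------------------------------------------------------------

def reproduce_study(thr: Thresholds | None = None, verbose: bool = True) -> dict[str, dict]:
    """Replay every claim the printed-table fixtures can verify.

    Returns ``{claim: {"passed": bool, "expected": ..., "observed": ...}}``.
    Failures are reported, never raised, so the same function doubles as
    a sensitivity probe when called with perturbed thresholds.
    """
    thr = thr or Thresholds()
    claims: dict[str, dict] = {}

    def record(name: str, expected, observed) -> None:
        claims[name] = {
            "passed": bool(expected == observed),
            "expected": expected,
            "observed": observed,
        }

    all60 = round1_summaries()
    table2 = load_fixture("table2")
    consensus_labelled = set(table2.loc[table2["printed_label"] == "Consensus", "item_id"])
    overall_pass = {
        iid
        for iid, s in all60.items()
        if s.pct_7to9 > thr.r1_high and s.pct_1to3 < thr.r1_low
    }
    record("round1_overall_consensus_count", 27, len(overall_pass))
    record("round1_overall_consensus_set_matches_labels", consensus_labelled, overall_pass)

    decisions = fixture_decisions()
    itemset = build_round2_itemset(decisions)
    record("round2_itemset_count", 34, len(itemset))
    record("dropped_item_count", 26, int((~pd.Series(
        [d.effective_retained for d in decisions.values()]
    )).sum()))
    record("catalog_item_count", 60, len(all60))

    table5 = load_fixture("table5")
    r2_summaries = fixture_summaries("table5")
    printed = {
        row["item_id"]: (row["preagreed"] == "Include", row["stringent"] == "Include")
        for _, row in table5.iterrows()
    }
    computed = {
        iid: (o.preagreed, o.stringent)
        for iid, o in ((iid, classify_round2(s, thr)) for iid, s in r2_summaries.items())
    }
    n_match = sum(1 for iid in printed if printed[iid] == computed[iid])
    record("round2_outcomes_reproduced", 34, n_match)
    record(
        "stringent_subset_of_preagreed",
        True,
        all(pre or not strict for pre, strict in computed.values()),
    )

    record(
        "bimodal_items_round1", 0, sum(1 for s in all60.values() if bimodality_flag(s))
    )
    record(
        "bimodal_items_round2",
        0,
        sum(1 for s in r2_summaries.values() if bimodality_flag(s)),
    )

    rate = round(
        100.0 * PARTICIPANT_COUNTS["round2_responders"] / PARTICIPANT_COUNTS["round1_raters"],
        1,
    )
    record("round2_response_rate_pct", 93.3, rate)
    counts = load_fixture("table1_counts")
    lt5 = counts[(counts["characteristic"] == "experience") & (counts["level"] == "lt5")]
    record("experience_total", 45, int(counts[counts["characteristic"] == "experience"]["n"].sum()))
    record(
        "pct_experience_lt5",
        24.4,
        round(100.0 * int(lt5["n"].iloc[0]) / 45, 1),
    )

    if verbose:
        for name, rec in claims.items():
            status = "PASS" if rec["passed"] else "FAIL"
            print(f"[{status}] {name}: expected {rec['expected']!r}, observed {rec['observed']!r}")
    return claims
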