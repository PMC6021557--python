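"""Per-item rating summaries and the prespecified retention rules.

Round 1 of the Delphi keeps an item when, among all panelists, more
than 50% score it 7-9 (high priority) and fewer than 15% score it 1-3
(low priority); failing that, when the same band test passes in two or
more care-experience subgroups; failing that, when at least 15% of the
panel placed the item in their personal top-10 list.  Items missing
every criterion but coming close are flagged for human review rather
than silently dropped.  After round 2 an item is retained when more
than 70% score it 7-9 (and fewer than 15% score 1-3); a more stringent
variant demands more than 70% scoring 8 or 9, to help a final selection
meeting identify the most crucial items without a third round.

Verdicts are always evaluated on exact fractions (count / n), never on
the two-decimal percentages used for display; printed tables can still
be replayed through the same comparators because the published values
are nowhere near the 1e-2 rounding boundary of any threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ItemSummary",
    "Thresholds",
    "RetentionDecision",
    "Round2Outcome",
    "summarize_item",
    "summarize_panel",
    "subgroup_summaries",
    "classify_round1",
    "classify_round2",
    "top10_pct",
    "new_item_candidates",
    "flag_near_miss",
    "build_round2_itemset",
]


@dataclass(frozen=True)
class ItemSummary:
    """Distribution summary of one item's scores in one round.

    Percentages are exact fractions of ``n`` times 100 (not rounded);
    ``pct_8or9`` is populated for round-2 summaries where the stringent
    rule needs it.  ``mean``/``sd``/``median``/``iqr`` may be None when a
    summary is reconstructed from a printed table that omits them.
    """

    item_id: str
    n: int
    pct_7to9: float
    pct_1to3: float
    pct_8or9: float | None = None
    median: float | None = None
    iqr: tuple[float, float] | None = None
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        for name in ("pct_7to9", "pct_1to3", "pct_8or9"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100] for item {self.item_id!r}")


@dataclass(frozen=True)
class Thresholds:
    """Retention-rule cutoffs, defaulting to the prespecified protocol.

    Strictness follows the protocol wording: the high-band tests are
    strict (> 50 in round 1, > 70 in round 2, > 10 for new-item
    suggestions), the low-band tests are strict (< 15), and the top-10
    test is inclusive (>= 15, "15% or more").  ``subgroup_min`` is the
    number of subgroups that must independently pass the band test;
    ``subgroup_min_raters`` is the smallest subgroup treated as
    evaluable at all.
    """

    r1_high: float = 50.0
    r1_low: float = 15.0
    subgroup_min: int = 2
    subgroup_min_raters: int = 5
    top10_min: float = 15.0
    newitem_min: float = 10.0
    r2_high: float = 70.0
    r2_low: float = 15.0

    def __post_init__(self) -> None:
        for name in ("r1_high", "r1_low", "top10_min", "newitem_min", "r2_high", "r2_low"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"threshold {name}={v} outside [0, 100]")


#: Reason priority: an item keeps the first reason whose rule it passes.
REASON_ORDER = ("consensus_overall", "subgroup", "top10", "near_miss_review", "dropped")


@dataclass
class RetentionDecision:
    """Round-1 verdict for one item, with machine-readable evidence."""

    item_id: str
    retained: bool
    reason: str
    qualifying_subgroups: tuple[str, ...] = ()
    top10_pct: float | None = None
    manual_override: bool = False

    def __post_init__(self) -> None:
        if self.reason not in REASON_ORDER:
            raise ValueError(f"unknown reason {self.reason!r}")

    @property
    def effective_retained(self) -> bool:
        """Retained by rule or by an explicit human override of a flag."""
        return self.retained or self.manual_override


@dataclass(frozen=True)
class Round2Outcome:
    """Round-2 verdicts under the pre-agreed and the stringent rules."""

    item_id: str
    preagreed: bool
    stringent: bool

    def __post_init__(self) -> None:
        if self.stringent and not self.preagreed:
            raise ValueError(
                f"item {self.item_id!r}: stringent include without pre-agreed include "
                "(the 8-9 band is a subset of the 7-9 band)"
            )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_item(scores: Sequence[float] | np.ndarray, item_id: str = "item") -> ItemSummary:
    """Summarize one item's scores: band percentages, median/IQR, mean, SD.

    Percentages are exact fractions of the number of observed scores;
    the median is the sorted midpoint and quartiles use linear
    interpolation between closest ranks (the numpy default).  The SD is
    the sample standard deviation (ddof=1; NaN for a single score).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError(f"no scores for item {item_id!r}")
    n = arr.size
    q1, q3 = np.percentile(arr, [25, 75])
    return ItemSummary(
        item_id=item_id,
        n=int(n),
        pct_7to9=100.0 * np.count_nonzero((arr >= 7) & (arr <= 9)) / n,
        pct_1to3=100.0 * np.count_nonzero((arr >= 1) & (arr <= 3)) / n,
        pct_8or9=100.0 * np.count_nonzero(arr >= 8) / n,
        median=float(np.median(arr)),
        iqr=(float(q1), float(q3)),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if n > 1 else float("nan"),
    )


def summarize_panel(panel) -> dict[str, ItemSummary]:
    """Per-item summaries for every item in a :class:`RatingsPanel`."""
    return {
        item_id: summarize_item(grp["score"].to_numpy(), item_id=item_id)
        for item_id, grp in panel.scores.groupby("item_id", sort=True)
    }


def subgroup_summaries(
    panel,
    participants: Mapping[str, "Participant"],
    min_raters: int = 5,
) -> dict[str, dict[str, ItemSummary]]:
    """Per-item summaries within each care-experience subgroup.

    Returns ``{item_id: {subgroup: ItemSummary}}``; a subgroup whose
    members scored an item fewer than ``min_raters`` times is omitted
    (not evaluable) rather than summarized.
    """
    from .types import SUBGROUPS  # local import to avoid a cycle

    members = {
        g: {pid for pid, p in participants.items() if g in p.subgroups} for g in SUBGROUPS
    }
    out: dict[str, dict[str, ItemSummary]] = {}
    for item_id, grp in panel.scores.groupby("item_id", sort=True):
        by_group: dict[str, ItemSummary] = {}
        for g in SUBGROUPS:
            sub = grp[grp["participant_id"].isin(members[g])]
            if len(sub) >= min_raters:
                by_group[g] = summarize_item(sub["score"].to_numpy(), item_id=item_id)
        out[item_id] = by_group
    return out


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------

def _band_pass(summary: ItemSummary, high: float, low: float) -> bool:
    """The consensus band test: strictly above `high` in 7-9, strictly below `low` in 1-3."""
    return summary.pct_7to9 > high and summary.pct_1to3 < low


def classify_round1(
    overall: ItemSummary,
    per_subgroup: Mapping[str, ItemSummary] | Iterable[ItemSummary] = (),
    top10_pct: float | None = None,
    thr: Thresholds = Thresholds(),
) -> RetentionDecision:
    """Apply the round-1 retention rules to one item.

    Rules are tried in priority order — overall consensus, then
    subgroup consensus (the band test passing in at least
    ``thr.subgroup_min`` subgroups), then top-10 prioritization — and
    the first that passes fixes the recorded reason.  Items passing
    nothing are dropped here; :func:`flag_near_miss` may later mark a
    dropped item for human review.
    """
    if isinstance(per_subgroup, Mapping):
        subgroup_items = list(per_subgroup.items())
    else:
        subgroup_items = [(s.item_id, s) for s in per_subgroup]

    if _band_pass(overall, thr.r1_high, thr.r1_low):
        return RetentionDecision(overall.item_id, True, "consensus_overall", top10_pct=top10_pct)

    qualifying = tuple(
        name for name, s in subgroup_items if _band_pass(s, thr.r1_high, thr.r1_low)
    )
    if len(qualifying) >= thr.subgroup_min:
        return RetentionDecision(
            overall.item_id, True, "subgroup", qualifying_subgroups=qualifying, top10_pct=top10_pct
        )

    if top10_pct is not None and top10_pct >= thr.top10_min:
        return RetentionDecision(
            overall.item_id, True, "top10", qualifying_subgroups=qualifying, top10_pct=top10_pct
        )

    return RetentionDecision(
        overall.item_id, False, "dropped", qualifying_subgroups=qualifying, top10_pct=top10_pct
    )


def top10_pct(
    selections: Mapping[str, Sequence[str]],
    item_id: str,
    n_raters: int,
    denominator_policy: str = "all_raters",
) -> float:
    """Percentage of the panel naming ``item_id`` in their top-10 list.

    ``denominator_policy`` is ``"all_raters"`` (default: every round-1
    rater counts in the denominator, including those who skipped the
    top-10 task) or ``"completers"`` (only participants with a
    nonempty selection list).
    """
    if denominator_policy == "all_raters":
        denom = n_raters
    elif denominator_policy == "completers":
        denom = sum(1 for items in selections.values() if items)
    else:
        raise ValueError(f"unknown denominator policy {denominator_policy!r}")
    if denom == 0:
        raise ZeroDivisionError("top-10 denominator is zero")
    count = sum(1 for items in selections.values() if item_id in items)
    return 100.0 * count / denom


def new_item_candidates(
    suggestion_counts: Mapping[str, int],
    n_participants: int,
    thr: Thresholds = Thresholds(),
) -> list[str]:
    """Suggested new items backed by strictly more than ``thr.newitem_min``% of the panel."""
    if n_participants <= 0:
        raise ValueError("n_participants must be positive")
    return [
        text
        for text, count in suggestion_counts.items()
        if count >= 0 and 100.0 * count / n_participants > thr.newitem_min
    ]


def flag_near_miss(
    decisions: Mapping[str, RetentionDecision],
    summaries: Mapping[str, ItemSummary],
    thr: Thresholds = Thresholds(),
    margin: float = 10.0,
    top10_margin: float = 2.0,
) -> dict[str, RetentionDecision]:
    """Mark dropped items that narrowly missed a criterion for review.

    A dropped item is flagged when its overall % rating 7-9 is within
    ``margin`` percentage points of the round-1 high threshold (with the
    low-band test still satisfied), or when its top-10 percentage is
    within ``top10_margin`` points of the top-10 threshold.  Flagging
    never retains by itself: the decision's reason becomes
    ``near_miss_review`` and a human sets ``manual_override`` to convert
    the flag into retention.  Returns a new decision map.
    """
    out: dict[str, RetentionDecision] = {}
    for item_id, dec in decisions.items():
        if dec.retained or dec.reason != "dropped":
            out[item_id] = dec
            continue
        s = summaries[item_id]
        near_overall = _band_pass(s, thr.r1_high - margin, thr.r1_low)
        near_top10 = (
            dec.top10_pct is not None and dec.top10_pct >= thr.top10_min - top10_margin
        )
        if near_overall or near_top10:
            out[item_id] = replace(dec, reason="near_miss_review")
        else:
            out[item_id] = dec
    return out


def classify_round2(summary: ItemSummary, thr: Thresholds = Thresholds()) -> Round2Outcome:
    """Apply the round-2 pre-agreed and stringent rules to one item.

    Pre-agreed: > ``thr.r2_high``% scoring 7-9 and < ``thr.r2_low``%
    scoring 1-3.  Stringent: the same low-band test but > ``thr.r2_high``%
    scoring 8 or 9.  Both comparisons are strict, so an item sitting
    exactly on a threshold is excluded.
    """
    if summary.pct_8or9 is None:
        raise ValueError(f"item {summary.item_id!r}: pct_8or9 required for the stringent rule")
    low_ok = summary.pct_1to3 < thr.r2_low
    return Round2Outcome(
        item_id=summary.item_id,
        preagreed=summary.pct_7to9 > thr.r2_high and low_ok,
        stringent=summary.pct_8or9 > thr.r2_high and low_ok,
    )


def build_round2_itemset(
    decisions: Mapping[str, RetentionDecision],
    manual_overrides: Iterable[str] = (),
) -> dict[str, str]:
    """Assemble the round-2 item set with per-item provenance.

    The set is the union of all rule-retained items, items whose
    decision already carries a manual override, and item ids listed in
    ``manual_overrides``.  Returns ``{item_id: provenance}`` where
    provenance is the decision reason or ``"manual_override"``.
    """
    overrides = set(manual_overrides)
    unknown = overrides - set(decisions)
    if unknown:
        raise KeyError(f"manual override for unknown item(s): {sorted(unknown)}")
    out: dict[str, str] = {}
    for item_id in sorted(decisions):
        dec = decisions[item_id]
        if dec.retained:
            out[item_id] = dec.reason
        elif dec.manual_override or item_id in overrides:
            out[item_id] = "manual_override"
    return out
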