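"""Packaged study fixtures: the published per-item summary tables.

The raw participant-level ratings of the expert panel were never
released; what the study published are per-item distribution summaries.
These fixtures transcribe them exactly as printed (percentages to two
decimals) so that the retention rules, bimodality checks, and
bookkeeping can be replayed against the real study:

* ``table2``        — the 34 items retained after round 1, with
  % rating 7-9, % rating 1-3, median (IQR) and the printed inclusion
  reason (Consensus / Top 10 / Subgroup / Close).
* ``table3``        — the 26 items dropped after round 1.
* ``table5``        — round-2 summaries for the 34 rerated items with
  % rating 7-9, % rating 8-9, % rating 1-3 and the printed outcome
  under the pre-agreed and the more stringent rules.
* ``table1_counts`` — participant characteristics of the 45-member
  round-1 panel (experience bands, care-type subgroups, background).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .consensus import ItemSummary

FIXTURE_NAMES = ("table2", "table3", "table5", "table1_counts")

#: Participant flow through the study as published: 45 usable round-1
#: responses, of whom 41 completed the top-10 task; 42 returned round 2.
PARTICIPANT_COUNTS = {
    "round1_raters": 45,
    "round1_top10_completers": 41,
    "round2_responders": 42,
    "round2_nonresponders": 3,
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged summary table by name.

    Returns a DataFrame with one row per item (or, for
    ``table1_counts``, per participant characteristic).  Percentages
    are exactly as printed, to two decimals.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    ref = resources.files("delphiset.data").joinpath(f"{name}.csv")
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    if "pct_7to9" in df.columns:
        for col in ("pct_7to9", "pct_1to3", "pct_8or9"):
            if col in df.columns:
                df[col] = df[col].astype(float)
    return df


def fixture_summaries(name: str, n_raters: int | None = None) -> dict[str, ItemSummary]:
    """Convert a per-item fixture into :class:`ItemSummary` records.

    The printed tables give band percentages and median/IQR but not the
    full distributions, so ``mean`` and ``sd`` are left as None; the
    rating count defaults to the published panel size for the table's
    round (45 in round 1, 42 in round 2).
    """
    if name == "table1_counts":
        raise KeyError("table1_counts is not a per-item summary fixture")
    df = load_fixture(name)
    if n_raters is None:
        n_raters = (
            PARTICIPANT_COUNTS["round2_responders"]
            if name == "table5"
            else PARTICIPANT_COUNTS["round1_raters"]
        )
    out: dict[str, ItemSummary] = {}
    for _, row in df.iterrows():
        out[row["item_id"]] = ItemSummary(
            item_id=row["item_id"],
            n=n_raters,
            pct_7to9=float(row["pct_7to9"]),
            pct_1to3=float(row["pct_1to3"]),
            pct_8or9=float(row["pct_8or9"]) if "pct_8or9" in df.columns else None,
            median=float(row["median"]) if "median" in df.columns else None,
            iqr=(
                (float(row["iqr_low"]), float(row["iqr_high"]))
                if "iqr_low" in df.columns
                else None
            ),
        )
    return out


def round1_summaries() -> dict[str, ItemSummary]:
    """Printed round-1 summaries for the full 60-item catalog."""
    merged = fixture_summaries("table2")
    merged.update(fixture_summaries("table3"))
    return merged


#: Printed inclusion-reason labels mapped to decision reasons.
_LABEL_TO_REASON = {
    "Consensus": "consensus_overall",
    "Subgroup": "subgroup",
    "Top 10": "top10",
    "Close": "near_miss_review",
}


def fixture_decisions() -> dict[str, "RetentionDecision"]:
    """Round-1 decisions for all 60 items, as printed.

    Items in the retained table carry their printed inclusion reason;
    a "Close" item was retained by the study team's review, so it is
    represented as a near-miss flag with the manual override set.
    Items in the dropped table are plain drops.
    """
    from .consensus import RetentionDecision

    out: dict[str, RetentionDecision] = {}
    for _, row in load_fixture("table2").iterrows():
        reason = _LABEL_TO_REASON[row["printed_label"]]
        out[row["item_id"]] = RetentionDecision(
            item_id=row["item_id"],
            retained=reason in ("consensus_overall", "subgroup", "top10"),
            reason=reason,
            manual_override=reason == "near_miss_review",
        )
    for _, row in load_fixture("table3").iterrows():
        out[row["item_id"]] = RetentionDecision(
            item_id=row["item_id"], retained=False, reason="dropped"
        )
    return out


def participant_count(characteristic: str, level: str) -> int:
    df = load_fixture("table1_counts")
    sel = df[(df["characteristic"] == characteristic) & (df["level"] == level)]
    if sel.empty:
        raise KeyError(f"no Table 1 row for ({characteristic!r}, {level!r})")
    return int(sel["n"].iloc[0])
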