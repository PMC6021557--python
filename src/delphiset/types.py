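"""Core data model for two-round Delphi rating panels.

A panel is a set of expert participants who each rate a catalog of
candidate items on a 1 (not important) to 9 (very important) scale.
Round 1 additionally asks each participant to pick a "top 10" of the
items they themselves rated 7-9.  Scores live in a long-format table so
that a missing rating is simply an absent row, never a sentinel value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The eight care settings items are grouped under.
CATEGORIES = (
    "hospital",
    "emergency",
    "gp_clinic",
    "home",
    "remote",
    "community",
    "residential",
    "medication",
)

#: Care-experience subgroups a participant may belong to (any number).
SUBGROUPS = (
    "physical",
    "mental",
    "public_health",
    "older_adults",
    "primary_care",
    "secondary_care",
)

#: Length-of-experience bands, in increasing order (ordinal code 0-3).
EXPERIENCE_BANDS = ("lt5", "5to10", "10to20", "gt20")

ROUND_LABELS = ("round1", "round2")


class PanelValidationError(ValueError):
    """Raised when a ratings table violates the panel contract."""


@dataclass(frozen=True)
class Item:
    """A candidate resource-use item in the catalog."""

    item_id: str
    text: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for item {self.item_id!r}; "
                f"expected one of {CATEGORIES}"
            )


@dataclass(frozen=True)
class Participant:
    """A panel member with experience metadata.

    ``subgroups`` records which of the six care-type experience
    subgroups the participant reported; memberships overlap freely and
    may be empty.
    """

    participant_id: str
    experience_band: str
    subgroups: frozenset[str] = frozenset()
    background: str = "academia"

    def __post_init__(self) -> None:
        if self.experience_band not in EXPERIENCE_BANDS:
            raise ValueError(
                f"unknown experience band {self.experience_band!r}; "
                f"expected one of {EXPERIENCE_BANDS}"
            )
        bad = set(self.subgroups) - set(SUBGROUPS)
        if bad:
            raise ValueError(f"unknown subgroup(s) {sorted(bad)} for {self.participant_id!r}")
        object.__setattr__(self, "subgroups", frozenset(self.subgroups))

    @property
    def experience_code(self) -> int:
        """Ordinal 0-3 coding of the experience band."""
        return EXPERIENCE_BANDS.index(self.experience_band)


@dataclass
class RatingsPanel:
    """Scores from one Delphi round in long format.

    Parameters
    ----------
    round_label
        ``"round1"`` or ``"round2"``.
    scores
        Long table with columns ``participant_id``, ``item_id``,
        ``score``.  One row per observed rating; absence means the
        participant skipped the item.
    top10
        Map from participant id to that participant's ordered top-10
        item list (round 1 only; participants who skipped the task are
        simply absent from the map).
    continuous
        When true the panel carries unrounded, unclamped latent values
        (produced by the simulator's continuous mode for metric
        validation); the integer-in-[1, 9] contract is not enforced.
    latent
        Optional pre-rounding latent values aligned with ``scores``
        (same columns, ``score`` holding the latent float).  Attached by
        the simulator so that round 2 can be generated from the latent
        round-1 state rather than the discretized report.
    """

    round_label: str
    scores: pd.DataFrame
    top10: dict[str, list[str]] = field(default_factory=dict)
    continuous: bool = False
    latent: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.round_label not in ROUND_LABELS:
            raise ValueError(f"round_label must be one of {ROUND_LABELS}")
        required = {"participant_id", "item_id", "score"}
        missing = required - set(self.scores.columns)
        if missing:
            raise PanelValidationError(f"scores table missing columns {sorted(missing)}")
        self.scores = self.scores.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------

    @property
    def rater_ids(self) -> list[str]:
        return sorted(self.scores["participant_id"].unique())

    @property
    def item_ids(self) -> list[str]:
        return sorted(self.scores["item_id"].unique())

    @property
    def n_raters(self) -> int:
        return self.scores["participant_id"].nunique()

    @property
    def n_items(self) -> int:
        return self.scores["item_id"].nunique()

    def scores_for_item(self, item_id: str) -> np.ndarray:
        """All observed scores for one item."""
        return self.scores.loc[self.scores["item_id"] == item_id, "score"].to_numpy()

    def score_of(self, participant_id: str, item_id: str) -> float | None:
        """A single participant's score for an item, or None if skipped."""
        sel = self.scores[
            (self.scores["participant_id"] == participant_id)
            & (self.scores["item_id"] == item_id)
        ]
        if sel.empty:
            return None
        return sel["score"].iloc[0]

    def score_matrix(self) -> pd.DataFrame:
        """Items x raters wide matrix (NaN where a rating is missing)."""
        return self.scores.pivot(index="item_id", columns="participant_id", values="score")

    def rater_means(self) -> pd.Series:
        """Mean score per participant over the items they rated."""
        return self.scores.groupby("participant_id")["score"].mean()

    def subset_items(self, item_ids: Iterable[str]) -> "RatingsPanel":
        keep = set(item_ids)
        scores = self.scores[self.scores["item_id"].isin(keep)].reset_index(drop=True)
        latent = None
        if self.latent is not None:
            latent = self.latent[self.latent["item_id"].isin(keep)].reset_index(drop=True)
        top10 = {
            pid: [i for i in items if i in keep] for pid, items in self.top10.items()
        }
        return RatingsPanel(
            round_label=self.round_label,
            scores=scores,
            top10=top10,
            continuous=self.continuous,
            latent=latent,
        )

    # -- validation ------------------------------------------------------

    def validate(
        self,
        catalog: Mapping[str, Item] | None = None,
        participants: Mapping[str, Participant] | None = None,
    ) -> list[str]:
        """Check the panel contract; raise on violation.

        Returns a human-readable report (row counts, missingness) as a
        list of lines.  Checks: integer scores in [1, 9] (unless the
        panel is continuous), no duplicate (participant, item) cell,
        all ids known to the catalog/participant registry when given,
        and the top-10 constraints (length <= 10, no duplicates, every
        listed item scored 7-9 by that participant).
        """
        df = self.scores
        if not self.continuous:
            score_arr = df["score"].to_numpy()
            non_integer = score_arr != np.floor(score_arr)
            out_of_range = (score_arr < 1) | (score_arr > 9)
            bad = non_integer | out_of_range
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                rec = df.iloc[row]
                raise PanelValidationError(
                    f"score {rec['score']!r} outside 1-9 at row {row} "
                    f"(participant {rec['participant_id']!r}, item {rec['item_id']!r})"
                )
        dup = df.duplicated(subset=["participant_id", "item_id"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            rec = df.iloc[row]
            raise PanelValidationError(
                f"duplicate rating at row {row} "
                f"(participant {rec['participant_id']!r}, item {rec['item_id']!r})"
            )
        if catalog is not None:
            unknown = set(df["item_id"]) - set(catalog)
            if unknown:
                raise PanelValidationError(f"unknown item id(s): {sorted(unknown)}")
        if participants is not None:
            unknown = set(df["participant_id"]) - set(participants)
            if unknown:
                raise PanelValidationError(f"unknown participant id(s): {sorted(unknown)}")

        scored_high = {
            pid: set(grp.loc[grp["score"] >= 7, "item_id"])
            for pid, grp in df.groupby("participant_id")
        }
        for pid, items in self.top10.items():
            if pid not in scored_high:
                raise PanelValidationError(f"top-10 list for unknown participant {pid!r}")
            if len(items) > 10:
                raise PanelValidationError(f"top-10 list for {pid!r} has {len(items)} items")
            if len(set(items)) != len(items):
                raise PanelValidationError(f"duplicate item in top-10 list for {pid!r}")
            if catalog is not None and set(items) - set(catalog):
                raise PanelValidationError(
                    f"top-10 list for {pid!r} names items outside the catalog"
                )
            not_high = set(items) - scored_high[pid]
            if not_high:
                raise PanelValidationError(
                    f"top-10 list for {pid!r} contains item(s) {sorted(not_high)} "
                    "not scored 7-9 by that participant"
                )

        n_cells = len(df)
        n_possible = self.n_raters * self.n_items
        report = [
            f"panel {self.round_label}: {self.n_raters} raters x {self.n_items} items",
            f"observed cells: {n_cells} of {n_possible} "
            f"({n_possible - n_cells} missing)",
            f"top-10 lists: {len(self.top10)}",
        ]
        return report


def participants_frame(participants: Iterable[Participant]) -> pd.DataFrame:
    """Tabulate participants (one row each; subgroups ';'-joined)."""
    rows = [
        {
            "participant_id": p.participant_id,
            "experience_band": p.experience_band,
            "subgroups": ";".join(sorted(p.subgroups)),
            "background": p.background,
        }
        for p in participants
    ]
    return pd.DataFrame(rows, columns=["participant_id", "experience_band", "subgroups", "background"])


def catalog_frame(items: Iterable[Item]) -> pd.DataFrame:
    rows = [{"item_id": i.item_id, "text": i.text, "category": i.category} for i in items]
    return pd.DataFrame(rows, columns=["item_id", "text", "category"])
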