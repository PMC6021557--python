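"""Round-2 feedback packets.

Between rounds each panelist receives, for every retained item, the
panel's round-1 median score alongside a reminder of their own round-1
score, so that reratings are informed by the group position without any
individual dominating the discussion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .types import RatingsPanel

__all__ = ["FeedbackEntry", "FeedbackPacket", "generate_feedback", "feedback_for_panel"]


@dataclass(frozen=True)
class FeedbackEntry:
    """Feedback shown for one item: group median plus the rater's own score.

    ``own_score`` is None when the participant skipped the item in
    round 1 (an explicit missing marker, never a sentinel value).
    """

    item_id: str
    group_median: float
    own_score: float | None
    reworded: bool = False
    comment_digest: str = ""


@dataclass
class FeedbackPacket:
    """All round-2 feedback for one participant, one entry per retained item."""

    participant_id: str
    entries: dict[str, FeedbackEntry] = field(default_factory=dict)

    @property
    def item_ids(self) -> list[str]:
        return sorted(self.entries)


def generate_feedback(
    round1: RatingsPanel,
    retained: Iterable[str],
    participant_id: str,
    reworded: Iterable[str] = (),
    comment_digests: Mapping[str, str] | None = None,
) -> FeedbackPacket:
    """Build one participant's feedback packet for the retained items.

    Group medians are sorted-midpoint medians of the round-1 scores.
    Raises if the participant did not take part in round 1 or the
    retained set is empty.
    """
    retained = sorted(set(retained))
    if not retained:
        raise ValueError("retained item set is empty")
    if participant_id not in set(round1.scores["participant_id"]):
        raise KeyError(f"participant {participant_id!r} did not take part in round 1")
    missing = set(retained) - set(round1.item_ids)
    if missing:
        raise ValueError(f"retained item(s) not rated in round 1: {sorted(missing)}")

    reworded = set(reworded)
    digests = comment_digests or {}
    own = round1.scores[round1.scores["participant_id"] == participant_id]
    own_map = dict(zip(own["item_id"], own["score"]))

    packet = FeedbackPacket(participant_id=participant_id)
    for item_id in retained:
        packet.entries[item_id] = FeedbackEntry(
            item_id=item_id,
            group_median=float(np.median(round1.scores_for_item(item_id))),
            own_score=float(own_map[item_id]) if item_id in own_map else None,
            reworded=item_id in reworded,
            comment_digest=digests.get(item_id, ""),
        )
    return packet


def feedback_for_panel(
    round1: RatingsPanel, retained: Iterable[str], **kwargs
) -> dict[str, FeedbackPacket]:
    """Feedback packets for every round-1 participant."""
    return {
        pid: generate_feedback(round1, retained, pid, **kwargs)
        for pid in round1.rater_ids
    }
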