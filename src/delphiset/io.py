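"""CSV readers and writers for panels, catalogs, and participants.

File dialect (comma-separated, UTF-8, header row mandatory):

* ratings:      participant_id, round, item_id, score   (long format)
* top-10:       participant_id, rank, item_id
* participants: participant_id, experience_band, subgroups, background
                (subgroups ';'-joined, possibly empty)
* catalog:      item_id, text, category

Missing ratings are absent rows — there is no sentinel score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .types import (
    Item,
    PanelValidationError,
    Participant,
    RatingsPanel,
    catalog_frame,
    participants_frame,
)

logger = logging.getLogger(__name__)

RATINGS_COLUMNS = ["participant_id", "round", "item_id", "score"]
TOP10_COLUMNS = ["participant_id", "rank", "item_id"]


@dataclass
class PanelBundle:
    """A validated in-memory study: catalog, participants, per-round panels."""

    catalog: dict[str, Item]
    participants: dict[str, Participant]
    panels: dict[str, RatingsPanel]
    validation_report: list[str] = field(default_factory=list)


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise PanelValidationError(f"{path}: missing column(s) {missing}")


def read_catalog(path) -> dict[str, Item]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["item_id", "text", "category"], path)
    items: dict[str, Item] = {}
    for _, row in df.iterrows():
        if row["item_id"] in items:
            raise PanelValidationError(f"{path}: duplicate item_id {row['item_id']!r}")
        items[row["item_id"]] = Item(row["item_id"], row["text"], row["category"])
    return items


def read_participants(path) -> dict[str, Participant]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["participant_id", "experience_band"], path)
    out: dict[str, Participant] = {}
    for _, row in df.iterrows():
        pid = row["participant_id"]
        if pid in out:
            raise PanelValidationError(f"{path}: duplicate participant_id {pid!r}")
        raw = row.get("subgroups", "") or ""
        subgroups = frozenset(s for s in raw.split(";") if s)
        out[pid] = Participant(
            participant_id=pid,
            experience_band=row["experience_band"],
            subgroups=subgroups,
            background=row.get("background", "academia") or "academia",
        )
    return out


def read_top10(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, dtype={"participant_id": str, "item_id": str, "rank": int})
    _require_columns(df, TOP10_COLUMNS, path)
    out: dict[str, list[str]] = {}
    for pid, grp in df.sort_values("rank").groupby("participant_id"):
        out[str(pid)] = list(grp["item_id"])
    return out


def read_panel(
    ratings_path,
    participants_path,
    catalog_path,
    top10_path=None,
) -> PanelBundle:
    """Read and fully validate a study from its CSV files.

    The ratings file may contain one or both rounds; one
    :class:`~delphiset.types.RatingsPanel` is built per round label
    present.  Any contract violation (score outside 1-9, unknown id,
    duplicate cell) raises :class:`PanelValidationError` naming the
    offending row.
    """
    catalog = read_catalog(catalog_path)
    participants = read_participants(participants_path)
    ratings = pd.read_csv(
        ratings_path,
        dtype={"participant_id": str, "round": str, "item_id": str},
    )
    _require_columns(ratings, RATINGS_COLUMNS, ratings_path)
    top10 = read_top10(top10_path) if top10_path is not None else {}

    panels: dict[str, RatingsPanel] = {}
    report: list[str] = [f"read {len(ratings)} rating rows from {ratings_path}"]
    for label, grp in ratings.groupby("round", sort=True):
        panel = RatingsPanel(
            round_label=str(label),
            scores=grp[["participant_id", "item_id", "score"]].reset_index(drop=True),
            top10=top10 if label == "round1" else {},
        )
        report.extend(panel.validate(catalog=catalog, participants=participants))
        panels[str(label)] = panel
    for line in report:
        logger.info(line)
    return PanelBundle(catalog, participants, panels, report)


def write_panel(
    bundle_or_panel,
    out_dir,
    participants: Mapping[str, Participant] | None = None,
    catalog: Mapping[str, Item] | None = None,
) -> dict[str, Path]:
    """Write a bundle (or a single panel plus metadata) to CSV files.

    Produces ``ratings.csv``, ``catalog.csv``, ``participants.csv`` and,
    when any top-10 list exists, ``top10.csv``.  Output is sorted so a
    given panel always serializes to identical bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(bundle_or_panel, PanelBundle):
        panels = bundle_or_panel.panels
        participants = bundle_or_panel.participants
        catalog = bundle_or_panel.catalog
    else:
        panel = bundle_or_panel
        panels = {panel.round_label: panel}
    if participants is None or catalog is None:
        raise ValueError("participants and catalog are required to write a panel")

    frames = []
    top10_rows = []
    for label in sorted(panels):
        p = panels[label]
        df = p.scores.copy()
        df.insert(1, "round", label)
        frames.append(df)
        for pid in sorted(p.top10):
            for rank, item_id in enumerate(p.top10[pid], start=1):
                top10_rows.append({"participant_id": pid, "rank": rank, "item_id": item_id})
    ratings = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["round", "participant_id", "item_id"], kind="mergesort")
        .reset_index(drop=True)
    )

    paths = {"ratings": out_dir / "ratings.csv"}
    ratings.to_csv(paths["ratings"], index=False)
    paths["catalog"] = out_dir / "catalog.csv"
    catalog_frame(catalog.values()).sort_values("item_id").to_csv(paths["catalog"], index=False)
    paths["participants"] = out_dir / "participants.csv"
    participants_frame(participants.values()).sort_values("participant_id").to_csv(
        paths["participants"], index=False
    )
    if top10_rows:
        paths["top10"] = out_dir / "top10.csv"
        pd.DataFrame(top10_rows, columns=TOP10_COLUMNS).to_csv(paths["top10"], index=False)
    return paths
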