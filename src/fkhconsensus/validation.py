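"""Functional validation of consensus targets by deletion / overexpression.

A consensus target is judged against two genome-wide perturbation readouts:
the change in its transcript level when the transcription factor is deleted,
and its trajectory over a TF-overexpression time course.  Direction calls
use symmetric cutoffs: UP when the score is at or above +cutoff, DOWN at or
below -cutoff, NONE otherwise (and NONE when the gene is absent from a
table — absence is lack of evidence, not a measured zero).

By default overexpression responsiveness is judged at the final time point,
matching how end-of-time-course direction is the natural summary of a
sustained response; an any-time-point rule is available behind
``oe_rule="any"``.

Category semantics: BOTH ("fully validated") when both perturbations give a
direction; DELETION_ONLY / OVEREXPRESSION_ONLY when exactly one does;
NEITHER otherwise.  "(Partially) validated" is everything except NEITHER.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Literal, Mapping

import pandas as pd

from .data_io import ValidationTables

logger = logging.getLogger(__name__)


class Direction(str, Enum):
    UP = "UP"
    DOWN = "DOWN"
    NONE = "NONE"


class Trajectory(str, Enum):
    MONOTONE_OR_FLAT = "MONOTONE_OR_FLAT"
    UP_THEN_DOWN = "UP_THEN_DOWN"
    DOWN_THEN_UP = "DOWN_THEN_UP"


class Category(str, Enum):
    BOTH = "BOTH"
    DELETION_ONLY = "DELETION_ONLY"
    OVEREXPRESSION_ONLY = "OVEREXPRESSION_ONLY"
    NEITHER = "NEITHER"


@dataclass(frozen=True)
class ResponseClass:
    deletion_direction: Direction
    oe_final_direction: Direction
    oe_trajectory: Trajectory

    @property
    def category(self) -> Category:
        has_del = self.deletion_direction is not Direction.NONE
        has_oe = self.oe_final_direction is not Direction.NONE
        if has_del and has_oe:
            return Category.BOTH
        if has_del:
            return Category.DELETION_ONLY
        if has_oe:
            return Category.OVEREXPRESSION_ONLY
        return Category.NEITHER


def _direction(score: float | None, cutoff: float) -> Direction:
    if score is None:
        return Direction.NONE
    if score >= cutoff:
        return Direction.UP
    if score <= -cutoff:
        return Direction.DOWN
    return Direction.NONE


def classify_response(
    gene: str,
    tables: ValidationTables,
    oe_rule: Literal["final", "any"] = "final",
) -> ResponseClass:
    """Classify one gene's deletion and overexpression responses.

    The trajectory label requires threshold exceedance on *both* sides (an
    earlier point past +cutoff and a final point past -cutoff, or the
    mirror); a mere sign change within the noise band stays
    MONOTONE_OR_FLAT.
    """
    del_dir = _direction(tables.deletion.get(gene), tables.deletion_cutoff)

    course = tables.overexpression.get(gene)
    if course is None:
        return ResponseClass(del_dir, Direction.NONE, Trajectory.MONOTONE_OR_FLAT)

    cutoff = tables.oe_cutoff
    final_dir = _direction(course[-1], cutoff)
    if oe_rule == "final":
        oe_dir = final_dir
    elif oe_rule == "any":
        if final_dir is not Direction.NONE:
            oe_dir = final_dir
        else:
            crossing = [x for x in course if _direction(x, cutoff) is not Direction.NONE]
            if crossing:
                extreme = max(crossing, key=abs)
                oe_dir = _direction(extreme, cutoff)
            else:
                oe_dir = Direction.NONE
    else:
        raise ValueError(f"unknown oe_rule {oe_rule!r}")

    earlier = course[:-1]
    if final_dir is Direction.DOWN and any(x >= cutoff for x in earlier):
        traj = Trajectory.UP_THEN_DOWN
    elif final_dir is Direction.UP and any(x <= -cutoff for x in earlier):
        traj = Trajectory.DOWN_THEN_UP
    else:
        traj = Trajectory.MONOTONE_OR_FLAT
    return ResponseClass(del_dir, oe_dir, traj)


def validation_categories(
    consensus: Iterable[str],
    tables: ValidationTables,
    oe_rule: Literal["final", "any"] = "final",
) -> tuple[dict[str, ResponseClass], dict[str, Category], Counter]:
    """Classify every consensus gene and tally the four categories.

    Returns (per-gene response classes, per-gene categories, category
    counts).  The four categories partition the consensus set.
    """
    genes = sorted(set(consensus))
    if not genes:
        logger.warning("empty consensus set: no genes to validate")
    classes = {g: classify_response(g, tables, oe_rule) for g in genes}
    categories = {g: c.category for g, c in classes.items()}
    counts = Counter(categories.values())
    for cat in Category:
        counts.setdefault(cat, 0)
    return classes, categories, counts


def fully_validated(categories: Mapping[str, Category]) -> frozenset[str]:
    """Genes responding to both deletion and overexpression."""
    return frozenset(g for g, c in categories.items() if c is Category.BOTH)


def partially_validated(categories: Mapping[str, Category]) -> frozenset[str]:
    """Genes responding to at least one perturbation (includes fully validated)."""
    return frozenset(g for g, c in categories.items() if c is not Category.NEITHER)


def direction_summary(
    categories: Mapping[str, Category],
    classes: Mapping[str, ResponseClass],
) -> pd.DataFrame:
    """Direction tallies over the fully validated set.

    Counts of final overexpression direction (UP/DOWN), of UP_THEN_DOWN
    trajectories, and of deletion direction (UP/DOWN).
    """
    full = [g for g, c in categories.items() if c is Category.BOTH]
    oe_finals = Counter(classes[g].oe_final_direction for g in full)
    del_dirs = Counter(classes[g].deletion_direction for g in full)
    trajs = Counter(classes[g].oe_trajectory for g in full)
    return pd.DataFrame(
        [
            ("fully_validated", len(full)),
            ("oe_final_up", oe_finals[Direction.UP]),
            ("oe_final_down", oe_finals[Direction.DOWN]),
            ("oe_up_then_down", trajs[Trajectory.UP_THEN_DOWN]),
            ("deletion_up", del_dirs[Direction.UP]),
            ("deletion_down", del_dirs[Direction.DOWN]),
        ],
        columns=["metric", "count"],
    )


def classes_to_frame(
    categories: Mapping[str, Category],
    classes: Mapping[str, ResponseClass],
) -> pd.DataFrame:
    """Per-gene validation table for TSV export."""
    rows = [
        (
            g,
            categories[g].value,
            classes[g].deletion_direction.value,
            classes[g].oe_final_direction.value,
            classes[g].oe_trajectory.value,
        )
        for g in sorted(categories)
    ]
    return pd.DataFrame(
        rows,
        columns=["gene", "category", "deletion_direction", "oe_final_direction", "oe_trajectory"],
    )
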