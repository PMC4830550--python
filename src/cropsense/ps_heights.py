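"""Direct participant crop-height measurements (M1 categories, M2 ruler).

M1 heights are estimated by picking one of ten human-figure symbols marked
at equal height levels; the participant's own body height anchors the top
category, so category k maps to k/10 of the body height. M2 heights are
plain ruler measurements in centimeters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_io import MeasurementRecord, Participant, ValidationError

N_CATEGORIES = 10


def category_to_cm(category: int, participant: Participant) -> float:
    """Convert an M1 category (1-10) to centimeters.

    Equal intervals anchored at the participant's body height: category 10
    is the full body height, so category k maps to k * body_height / 10.
    """
    if not (1 <= category <= N_CATEGORIES) or int(category) != category:
        raise ValidationError(f"M1 category must be an integer in 1-10, got {category}")
    return category * participant.body_height_cm / N_CATEGORIES


def cm_to_category(height_cm: float, participant: Participant) -> int:
    """Nearest-category inverse of :func:`category_to_cm` (clipped to 1-10)."""
    k = round(height_cm * N_CATEGORIES / participant.body_height_cm)
    return int(min(max(k, 1), N_CATEGORIES))


@dataclass
class GroupSummary:
    """Per-group tally of a survey, mirroring a campaign-overview table row."""

    group: str
    n_total: int
    n_i1: int
    n_i2: int
    mean_m2_cm: Optional[float]
    mean_m1_cm: Optional[float]
    spearman_m1_m2: Optional[float]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def group_summary(records: Sequence[MeasurementRecord],
                  participants: Optional[dict[int, Participant]] = None) -> GroupSummary:
    """Counts per instruction, M2 mean, M1 mean (when body heights are
    known) and the Spearman rank correlation between M1 categories and M2
    heights (average ranks for the heavily tied categories)."""
    if not records:
        raise ValidationError("cannot summarize an empty record set")
    groups = {r.group for r in records}
    if len(groups) != 1:
        raise ValidationError(f"records span multiple groups: {sorted(groups)}")
    n_i1 = sum(1 for r in records if r.instruction == "I1")
    n_i2 = sum(1 for r in records if r.instruction == "I2")

    m2 = [r.m2_height_cm for r in records if r.m2_height_cm is not None]
    mean_m2 = float(np.mean(m2)) if m2 else None

    mean_m1 = None
    if participants is not None:
        m1_cm = [category_to_cm(r.m1_category, participants[r.participant_id])
                 for r in records
                 if r.m1_category is not None and r.participant_id in participants]
        if m1_cm:
            mean_m1 = float(np.mean(m1_cm))

    both = [(r.m1_category, r.m2_height_cm) for r in records
            if r.m1_category is not None and r.m2_height_cm is not None]
    spearman = None
    if len(both) >= 2:
        a, b = zip(*both)
        if len(set(a)) > 1 and len(set(b)) > 1:
            spearman = float(stats.spearmanr(a, b).statistic)

    return GroupSummary(
        group=records[0].group,
        n_total=len(records),
        n_i1=n_i1,
        n_i2=n_i2,
        mean_m2_cm=mean_m2,
        mean_m1_cm=mean_m1,
        spearman_m1_m2=spearman,
    )
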