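"""Per-segment mean count differences (± 2 SD) between two normal databases."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .database import NormalDatabase
from .errors import InvalidArgumentError
from .geometry import SEGMENT_NAMES, SegmentMasks

__all__ = ["SegmentRow", "SegmentTable", "segment_table"]


@dataclass(frozen=True)
class SegmentRow:
    mean_diff: float
    two_sd: float


@dataclass
class SegmentTable:
    """Segmental summary of the difference between two databases.

    ``rows`` maps segment name -> (mean difference, 2 x SD of the pixel-wise
    difference over the segment), on the -100..100 normalized scale.
    """

    rows: dict[str, SegmentRow]
    label_a: str
    label_b: str

    def difference_map(self):  # pragma: no cover - accessor
        return self._difference_map

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment": list(self.rows),
                "mean_diff": [r.mean_diff for r in self.rows.values()],
                "two_sd": [r.two_sd for r in self.rows.values()],
            }
        )


def segment_table(
    db_a: NormalDatabase, db_b: NormalDatabase, segments: SegmentMasks
) -> SegmentTable:
    """Per-segment mean (and 2 SD) of the db_A-minus-db_B mean-map difference.

    The SD is over pixels of the difference map within the segment
    (denominator ``n_pixels - 1``); the basal ring is excluded by
    construction of the segment masks.
    """
    if not db_a.geometry.same_as(db_b.geometry):
        raise InvalidArgumentError("databases have mismatched geometries")
    diff = db_a.mean_map - db_b.mean_map
    rows: dict[str, SegmentRow] = {}
    for name in SEGMENT_NAMES:
        mask = getattr(segments, name)
        if not mask.any():
            raise InvalidArgumentError(f"segment {name!r} is empty")
        values = diff[mask]
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        rows[name] = SegmentRow(mean_diff=float(values.mean()), two_sd=2.0 * sd)
    table = SegmentTable(rows=rows, label_a=db_a.group.label(), label_b=db_b.group.label())
    table._difference_map = diff
    return table
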