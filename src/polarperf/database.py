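"""Pixel-wise normal stress databases (mean and SD maps) from normalized cohorts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Cohort
from .errors import InsufficientDataError, InvalidStateError
from .geometry import Geometry

__all__ = ["GroupSelector", "NormalDatabase", "build_database"]


@dataclass(frozen=True)
class GroupSelector:
    """Stratum descriptor: each field is a value or 'all'."""

    correction: str
    gender: str = "all"
    bmi: str = "all"

    def label(self) -> str:
        return f"{self.correction}/{self.gender}/{self.bmi}"


@dataclass
class NormalDatabase:
    """Per-pixel mean and sample SD over a normalized cohort stratum.

    Values are defined only on the geometry's valid disc; outside it both
    maps are NaN.  ``n`` is the number of contributing maps (one per subject
    within one correction type).
    """

    mean_map: np.ndarray
    sd_map: np.ndarray
    n: int
    group: GroupSelector
    geometry: Geometry


def build_database(cohort: Cohort, group: GroupSelector) -> NormalDatabase:
    """Build the pixel-wise mean/SD database for one stratum.

    The sample SD uses denominator ``n - 1``.

    Raises
    ------
    InsufficientDataError
        If fewer than 2 maps match the selector.
    InvalidStateError
        If any selected map is not normalized.
    """
    selected = cohort.select(
        gender=group.gender, bmi=group.bmi, correction=group.correction
    )
    if len(selected) < 2:
        raise InsufficientDataError(
            f"selector {group.label()} matched {len(selected)} map(s); need >= 2"
        )
    unnormalized = [pm.meta.subject_id for pm in selected.maps if not pm.normalized]
    if unnormalized:
        raise InvalidStateError(
            f"selector {group.label()} matched unnormalized maps: {unnormalized[:5]}"
        )
    stack = np.stack([pm.counts for pm in selected.maps])
    mean_map = stack.mean(axis=0)
    sd_map = stack.std(axis=0, ddof=1)
    outside = ~cohort.geometry.valid_mask
    mean_map[outside] = np.nan
    sd_map[outside] = np.nan
    return NormalDatabase(
        mean_map=mean_map,
        sd_map=sd_map,
        n=len(selected),
        group=group,
        geometry=cohort.geometry,
    )
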