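"""Core data carriers: per-subject metadata, polar maps, and cohorts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, PairingError
from .geometry import Geometry

__all__ = ["GENDERS", "BMI_CLASSES", "CORRECTIONS", "SubjectMeta", "PolarMap", "Cohort"]

GENDERS = ("male", "female")
BMI_CLASSES = ("normal", "obese")
CORRECTIONS = ("NC", "AC")


@dataclass(frozen=True)
class SubjectMeta:
    """Identity and stratification of one subject's map.

    The NC and AC maps of one subject share ``subject_id``, ``gender`` and
    ``bmi_class`` and differ only in ``correction``.
    """

    subject_id: str
    gender: str
    bmi_class: str
    correction: str

    def __post_init__(self):
        if self.gender not in GENDERS:
            raise InvalidArgumentError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if self.bmi_class not in BMI_CLASSES:
            raise InvalidArgumentError(
                f"bmi_class must be one of {BMI_CLASSES}, got {self.bmi_class!r}"
            )
        if self.correction not in CORRECTIONS:
            raise InvalidArgumentError(
                f"correction must be one of {CORRECTIONS}, got {self.correction!r}"
            )


@dataclass
class PolarMap:
    """One subject's bull's eye count grid.

    ``counts`` is a full square grid of floats; pixels outside the geometry's
    validity disc are NaN (invalid, not zero).  ``normalized`` records whether
    the map has been placed on the common count scale.
    """

    counts: np.ndarray
    meta: SubjectMeta
    geometry: Geometry
    normalized: bool = False

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != self.geometry.valid_mask.shape:
            raise InvalidArgumentError(
                f"counts shape {counts.shape} does not match geometry grid "
                f"{self.geometry.valid_mask.shape}"
            )
        valid = self.geometry.valid_mask
        if np.any(counts[valid] < 0) or np.any(np.isnan(counts[valid])):
            raise InvalidArgumentError("counts must be finite and non-negative on the valid disc")
        counts = counts.copy()
        counts[~valid] = np.nan
        self.counts = counts

    def valid_values(self) -> np.ndarray:
        """Counts over valid pixels, flattened row-major."""
        return self.counts[self.geometry.valid_mask]

    def with_counts(self, counts: np.ndarray, normalized: bool | None = None) -> "PolarMap":
        return PolarMap(
            counts=counts,
            meta=self.meta,
            geometry=self.geometry,
            normalized=self.normalized if normalized is None else normalized,
        )


@dataclass
class Cohort:
    """A set of polar maps sharing one geometry, optionally NC/AC paired."""

    maps: list[PolarMap]
    geometry: Geometry

    def __post_init__(self):
        for pm in self.maps:
            if not pm.geometry.same_as(self.geometry):
                raise InvalidArgumentError(
                    f"map {pm.meta.subject_id} has a different geometry than the cohort"
                )
        seen = set()
        for pm in self.maps:
            key = (pm.meta.subject_id, pm.meta.correction)
            if key in seen:
                raise InvalidArgumentError(f"duplicate (subject_id, correction) entry: {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.maps)

    @property
    def subject_ids(self) -> list[str]:
        ids = []
        seen = set()
        for pm in self.maps:
            if pm.meta.subject_id not in seen:
                seen.add(pm.meta.subject_id)
                ids.append(pm.meta.subject_id)
        return ids

    def select(
        self,
        gender: str = "all",
        bmi: str = "all",
        correction: str = "all",
    ) -> "Cohort":
        """Sub-cohort matching the given strata; 'all' matches everything."""
        maps = [
            pm
            for pm in self.maps
            if (gender == "all" or pm.meta.gender == gender)
            and (bmi == "all" or pm.meta.bmi_class == bmi)
            and (correction == "all" or pm.meta.correction == correction)
        ]
        return Cohort(maps=maps, geometry=self.geometry)

    def stacked(self) -> np.ndarray:
        """(n_maps, n_valid) matrix of valid-pixel values, map order preserved."""
        if not self.maps:
            raise InvalidArgumentError("cohort is empty")
        return np.stack([pm.valid_values() for pm in self.maps])

    def paired_with(self, other: "Cohort") -> tuple[list[PolarMap], list[PolarMap]]:
        """Align this cohort with ``other`` by subject id (one map each).

        Raises :class:`PairingError` listing offending subject ids if the two
        cohorts do not contain exactly the same subjects, once each.
        """
        mine = {pm.meta.subject_id: pm for pm in self.maps}
        theirs = {pm.meta.subject_id: pm for pm in other.maps}
        if len(mine) != len(self.maps) or len(theirs) != len(other.maps):
            raise PairingError("cohorts contain repeated subject ids; cannot pair")
        offenders = sorted(set(mine) ^ set(theirs))
        if offenders:
            raise PairingError(
                f"unmatched subject ids between cohorts: {offenders}", offenders=offenders
            )
        ids = sorted(mine)
        return [mine[i] for i in ids], [theirs[i] for i in ids]
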