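"""End-to-end replication drivers: null FWER simulation and effect recovery.

These functions re-run the full pipeline (calibrate -> generate -> normalize
-> build databases -> segment table / pixel-wise comparison) from scratch,
and back both the acceptance test suite and the acceptance report script.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import Cohort
from .database import GroupSelector, build_database
from .errors import InvalidArgumentError
from .geometry import make_segments
from .normalization import normalize_cohort
from .segmental import segment_table
from .stats import ComparisonConfig, compare
from .synthetic import (
    GeneratorConfig,
    STUDY_STRATA,
    calibrate_to_segment_targets,
    generate_cohort,
)

__all__ = [
    "TABLE1_INFERIOR_TARGETS",
    "fwer_null_simulation",
    "recover_inferior_difference",
    "inferior_significance_fraction",
]

#: Published inferior-segment mean count differences used as calibration
#: targets (gender contrasts are men minus women; correction contrasts NC
#: minus AC).
TABLE1_INFERIOR_TARGETS = {
    "nc_men_vs_women": -6.6,
    "men_nc_vs_ac": -14.0,
    "ac_men_vs_women": -0.6,
}

#: Cohort sizes entering each recovery comparison.
_RECOVERY_STRATA = {
    "nc_men_vs_women": STUDY_STRATA,
    "ac_men_vs_women": STUDY_STRATA,
    "men_nc_vs_ac": {k: (v if k[0] == "male" else 0) for k, v in STUDY_STRATA.items()},
}


def fwer_null_simulation(
    n_runs: int = 1000,
    n_per_group: int = 20,
    n_permutations: int = 199,
    alpha: float = 0.001,
    seed: int = 0,
) -> dict:
    """Empirical family-wise error rate under a complete null.

    Each run draws two cohorts of ``n_per_group`` subjects from one identical
    generative model, normalizes the NC maps, and runs the two-sample
    pixel-wise comparison with the max-|t| permutation threshold; a run
    counts as a rejection if any pixel is declared significant.
    """
    sequences = np.random.SeedSequence(seed).spawn(n_runs)
    config = GeneratorConfig()
    rejections = 0
    for seq in sequences:
        run_seed = int(seq.generate_state(1)[0])
        cohort = generate_cohort(
            config,
            n_male_normal=2 * n_per_group,
            n_male_obese=0,
            n_female_normal=0,
            n_female_obese=0,
            seed=run_seed,
        )
        nc = normalize_cohort(cohort.select(correction="NC"))
        ids = nc.subject_ids
        first = set(ids[:n_per_group])
        group_a = Cohort([m for m in nc.maps if m.meta.subject_id in first], nc.geometry)
        group_b = Cohort([m for m in nc.maps if m.meta.subject_id not in first], nc.geometry)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # alpha below permutation resolution
            result = compare(
                group_a,
                group_b,
                ComparisonConfig(
                    alpha=alpha, n_permutations=n_permutations,
                    design="two_sample", seed=run_seed,
                ),
            )
        rejections += result.n_significant > 0
    return {
        "n_runs": n_runs,
        "rejections": rejections,
        "fwer": rejections / n_runs,
        "alpha": alpha,
    }


def _calibrated_normalized_cohort(comparison: str, seed: int):
    target = TABLE1_INFERIOR_TARGETS[comparison]
    config = calibrate_to_segment_targets(
        {(comparison, "inferior"): target}, GeneratorConfig()
    )
    strata = _RECOVERY_STRATA[comparison]
    cohort = generate_cohort(
        config,
        n_male_normal=strata[("male", "normal")],
        n_male_obese=strata[("male", "obese")],
        n_female_normal=strata[("female", "normal")],
        n_female_obese=strata[("female", "obese")],
        seed=seed,
    )
    return target, normalize_cohort(cohort)


def recover_inferior_difference(comparison: str, seed: int = 0) -> dict:
    """Calibrate to the published inferior cell, regenerate at study n, recover.

    Returns the calibration target, the recovered inferior-segment mean
    difference, its 2 SD, and the subject counts involved.
    """
    if comparison not in TABLE1_INFERIOR_TARGETS:
        raise InvalidArgumentError(
            f"unknown comparison {comparison!r}; expected one of "
            f"{sorted(TABLE1_INFERIOR_TARGETS)}"
        )
    target, cohort = _calibrated_normalized_cohort(comparison, seed)
    if comparison == "men_nc_vs_ac":
        db_a = build_database(cohort, GroupSelector(correction="NC", gender="male"))
        db_b = build_database(cohort, GroupSelector(correction="AC", gender="male"))
    else:
        corr = "NC" if comparison.startswith("nc") else "AC"
        db_a = build_database(cohort, GroupSelector(correction=corr, gender="male"))
        db_b = build_database(cohort, GroupSelector(correction=corr, gender="female"))
    segments = make_segments(cohort.geometry)
    row = segment_table(db_a, db_b, segments).rows["inferior"]
    return {
        "comparison": comparison,
        "target": target,
        "recovered": row.mean_diff,
        "two_sd": row.two_sd,
        "n_A": db_a.n,
        "n_B": db_b.n,
    }


def inferior_significance_fraction(
    comparison: str,
    seed: int = 0,
    alpha: float = 0.001,
    n_permutations: int = 1999,
) -> dict:
    """Fraction of inferior-segment pixels declared significantly lower.

    Runs the gender contrast at study n after calibrating to the published
    inferior cell; used to mirror the near-null AC vs pronounced NC contrast.
    """
    if comparison not in ("nc_men_vs_women", "ac_men_vs_women"):
        raise InvalidArgumentError("significance fraction applies to gender contrasts")
    _, cohort = _calibrated_normalized_cohort(comparison, seed)
    corr = "NC" if comparison.startswith("nc") else "AC"
    men = cohort.select(gender="male", correction=corr)
    women = cohort.select(gender="female", correction=corr)
    result = compare(
        men,
        women,
        ComparisonConfig(alpha=alpha, n_permutations=n_permutations,
                         design="two_sample", seed=seed),
    )
    inferior = make_segments(cohort.geometry).inferior
    return {
        "comparison": comparison,
        "fraction": float(result.sig_lower[inferior].sum() / inferior.sum()),
        "threshold": result.threshold,
        "n_significant": result.n_significant,
    }
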