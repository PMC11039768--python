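"""Design constants and descriptives of the smoking-cessation cohort.

These values are inputs to worked examples and synthetic defaults: the
scan design (6-minute resting-state scan at TR = 0.72 s), the cohort
composition (20 nicotine-patch-only plus 29 patch + e-cigarette
participants; 28 male, 21 female) and the pre/post-scan desire-to-smoke
ratings used to define cue-induced craving.
"""

from __future__ import annotations

import math

TR_SECONDS = 0.72
SCAN_MINUTES = 6.0

ARM_SIZES = {"patch_only": 20, "patch_plus_ecig": 29}
N_MALE = 28
N_FEMALE = 21

DESIRE_PRE_MEAN = 2.14
DESIRE_POST_MEAN = 2.71

N_PRIMARY_MODELS = 6

#: cohort-average fit indices of the person-specific models (worked-example
#: input for the 2-of-4 excellent-fit rule)
REPORTED_MEAN_FIT_INDICES = {"CFI": 0.9615, "NNFI": 0.9375, "RMSEA": 0.0678, "SRMR": 0.0395}


def n_volumes(scan_minutes: float = SCAN_MINUTES, tr_seconds: float = TR_SECONDS) -> int:
    """Number of fMRI volumes (time points) a scan yields."""
    if scan_minutes <= 0 or tr_seconds <= 0:
        raise ValueError("scan length and TR must be positive")
    return int(math.floor(scan_minutes * 60.0 / tr_seconds))


def cohort_size() -> int:
    return sum(ARM_SIZES.values())


def male_percentage() -> float:
    return 100.0 * N_MALE / (N_MALE + N_FEMALE)


def cue_craving_mean_difference() -> float:
    """Mean post-scan minus pre-scan desire-to-smoke rating."""
    return round(DESIRE_POST_MEAN - DESIRE_PRE_MEAN, 2)
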