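"""Study-condition presets: group means, group sizes and exclusion profiles.

Age groups are ordered (5-6, 7-9, 10-12, adult) throughout; a "slope" is
always in AUC units per age-group step with groups coded 0..3.
"""

from __future__ import annotations

from .data_model import AGE_GROUPS

# --- Experiment 1 (267 ms presentation) -----------------------------------

#: Retained participants per age group after exclusions.
EXP1_NS: tuple[int, ...] = (25, 35, 30, 32)
#: Age-effect model group mean AUCs (slope 0.033 per group step).
EXP1_AGE_MEANS: tuple[float, ...] = (0.800, 0.833, 0.867, 0.900)
#: No-age-effect model: all groups at the adult mean.
EXP1_NULL_MEANS: tuple[float, ...] = (0.900, 0.900, 0.900, 0.900)
#: Common within-group SD of the simulated AUCs.
MODEL_SD: float = 0.1

# --- Experiment 2 (133 ms presentation, registered report) ----------------

#: Registered minimum sample size per group.
EXP2_PLANNED_NS: tuple[int, ...] = (35, 35, 35, 35)
#: Realized retained sample sizes.
EXP2_REALIZED_NS: tuple[int, ...] = (45, 59, 52, 49)
#: Hypothesis 1 (Type 1 discrimination) age-effect means, slope 0.033.
EXP2_H1_MEANS: tuple[float, ...] = (0.791, 0.824, 0.857, 0.891)
EXP2_H1_NULL_MEANS: tuple[float, ...] = (0.891,) * 4
#: Hypothesis 2 (Type 2 metacognition) age-effect means, slope 0.025.
EXP2_H2_MEANS: tuple[float, ...] = (0.716, 0.741, 0.765, 0.790)
EXP2_H2_NULL_MEANS: tuple[float, ...] = (0.790,) * 4

# --- Recruitment / exclusion profiles -------------------------------------
# Per age group: (n_recruited, n_fail_practice, n_incomplete, n_fail_catch).
# Recruited minus the three exclusion counts gives the retained n above.

EXP1_EXCLUSION_PROFILE: dict[str, tuple[int, int, int, int]] = {
    "5-6": (39, 3, 9, 2),
    "7-9": (51, 9, 6, 1),
    "10-12": (56, 14, 9, 3),
    "adult": (42, 5, 4, 1),
}

EXP2_EXCLUSION_PROFILE: dict[str, tuple[int, int, int, int]] = {
    "5-6": (84, 29, 8, 2),
    "7-9": (79, 11, 4, 5),
    "10-12": (67, 8, 3, 4),
    "adult": (62, 5, 5, 3),
}


def retained_ns(profile: dict[str, tuple[int, int, int, int]]) -> tuple[int, ...]:
    """Retained group sizes implied by a recruitment/exclusion profile."""
    return tuple(
        profile[g][0] - profile[g][1] - profile[g][2] - profile[g][3]
        for g in AGE_GROUPS
    )
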