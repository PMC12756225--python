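"""Factorial trial tables for the judgment task and the training phase.

The perceptual judgment task crosses three central slants (15, 25, 35
deg) with three central tilts (0, 45, 90 deg) and two discrepancy levels
([30, 0] and [30, 45] deg on slant/tilt), giving 18 cue-conflict
configurations; at 5 repetitions each that is 90 trials.

The visuomotor training phase comes in three flavors: joint control of
both cues with a fixed tilt discrepancy (ATD: 4 discrepancy levels x 2
target positions x 3 repetitions = 24 trials) and single-cue control
(AT / AD: 3 slants x 8 tilts of the fixed cue x 2 target positions = 48
trials).  Trial order is a uniform permutation under the supplied seed;
counts and factor balance are seed-invariant.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

__all__ = [
    "JUDGMENT_SLANTS",
    "JUDGMENT_TILTS",
    "JUDGMENT_DISCREPANCIES",
    "TRAINING_GROUPS",
    "judgment_design",
    "training_design",
]

JUDGMENT_SLANTS = (15.0, 25.0, 35.0)
JUDGMENT_TILTS = (0.0, 45.0, 90.0)
#: (delta_sigma, delta_tau) pairs, degrees.
JUDGMENT_DISCREPANCIES = ((30.0, 0.0), (30.0, 45.0))
TRAINING_GROUPS = ("ATD", "AT", "AD")

#: Tilt-discrepancy levels for joint-control (ATD) training, degrees.
ATD_DELTA_TAUS = (-90.0, -45.0, 45.0, 90.0)
#: Fixed-cue pose grid for single-control (AT/AD) training, degrees.
TRAINING_SLANTS = (15.0, 25.0, 35.0)
TRAINING_TILTS = tuple(float(t) for t in range(0, 360, 45))
#: Two diametrically opposite target-direction axes, degrees.
TARGET_POSITIONS = (45.0, 135.0)


def _shuffled(df: pd.DataFrame, seed: int | None) -> pd.DataFrame:
    if seed is None:
        return df.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    return df.iloc[rng.permutation(len(df))].reset_index(drop=True)


def judgment_design(repetitions: int = 5, seed: int | None = None) -> pd.DataFrame:
    """Trial table for the cue-conflict judgment task.

    Columns: task, sigma_c, tau_c, delta_sigma, delta_tau, repetition.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    rows = [
        {
            "task": "judgment",
            "sigma_c": s,
            "tau_c": t,
            "delta_sigma": ds,
            "delta_tau": dt,
            "repetition": rep,
        }
        for s, t, (ds, dt), rep in itertools.product(
            JUDGMENT_SLANTS,
            JUDGMENT_TILTS,
            JUDGMENT_DISCREPANCIES,
            range(1, repetitions + 1),
        )
    ]
    return _shuffled(pd.DataFrame(rows), seed)


def training_design(group: str, seed: int | None = None) -> pd.DataFrame:
    """Trial table for one visuomotor training condition.

    ATD rows carry the joint tilt discrepancy; AT/AD rows carry the pose
    of the cue that stays fixed while the other is manipulated.
    """
    if group not in TRAINING_GROUPS:
        raise ValueError(f"unknown training group {group!r}; expected one of {TRAINING_GROUPS}")
    if group == "ATD":
        rows = [
            {
                "task": "training",
                "group": group,
                "delta_tau": dt,
                "target_position": tp,
                "repetition": rep,
            }
            for dt, tp, rep in itertools.product(
                ATD_DELTA_TAUS, TARGET_POSITIONS, (1, 2, 3)
            )
        ]
    else:
        rows = [
            {
                "task": "training",
                "group": group,
                "fixed_sigma": s,
                "fixed_tau": t,
                "target_position": tp,
                "repetition": 1,
            }
            for s, t, tp in itertools.product(
                TRAINING_SLANTS, TRAINING_TILTS, TARGET_POSITIONS
            )
        ]
    return _shuffled(pd.DataFrame(rows), seed)
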