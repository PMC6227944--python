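"""Kinematic transmission (KT) of the linkage outputs.

KT is the ratio of output link rotation to input rotation (dimensionless,
epaxial input) or to input translation (rad/mm, hypaxial input).  Because
KT varies as the mechanism moves, each simulation yields one instantaneous
KT per step — the incremental rotation of the output link over one step
divided by the per-step input increment — and their arithmetic mean KT̄ is
the summary metric used throughout the sensitivity analysis.

Output rotations are measured as the unsigned 3D angle between the output
link's direction vector in successive poses.  The right side is canonical;
for bilaterally symmetric geometries and inputs the left side is identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .solver import Pose, Trajectory

__all__ = ["OUTPUTS", "KTSeries", "link_rotation", "instantaneous_kt", "mean_kt"]

#: Output link name -> (from-joint, to-joint) base ids of its direction vector.
OUTPUT_VECTORS = {
    "suspensorium": ("NS", "HS"),
    "hyoid": ("HS", "CH"),
    "lower_jaw": ("JQ", "SYM"),
}

OUTPUTS: tuple[str, ...] = tuple(OUTPUT_VECTORS)

_SUFFIX = {"left": "_L", "right": "_R"}


def _direction(pose: Pose, output: str, side: str) -> np.ndarray:
    a, b = OUTPUT_VECTORS[output]
    suffix = _SUFFIX[side]
    a = a + suffix if a not in ("HYM", "SYM", "NV") else a
    b = b + suffix if b not in ("HYM", "SYM", "NV") else b
    return pose.position(b) - pose.position(a)


def link_rotation(pose: Pose, reference_pose: Pose, output: str, side: str = "right") -> float:
    """Unsigned 3D angle (rad, in [0, pi]) between the output link's direction
    in `pose` versus `reference_pose`."""
    if output not in OUTPUT_VECTORS:
        raise ValueError(f"unknown output {output!r}; expected one of {OUTPUTS}")
    u = _direction(reference_pose, output, side)
    v = _direction(pose, output, side)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError(f"{output}: zero-length direction vector")
    return math.atan2(float(np.linalg.norm(np.cross(u, v))), float(u @ v))


@dataclass(frozen=True)
class KTSeries:
    """Instantaneous KT at each mouth-opening step, plus the mean KT̄.

    Units depend on the input: dimensionless for epaxial rotation input,
    rad/mm for hypaxial translation input — series from different input
    types must never be averaged together.
    """

    output: str
    input_type: str
    values: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def units(self) -> str:
        return "dimensionless" if self.input_type == "epaxial" else "rad/mm"

    def __len__(self) -> int:
        return len(self.values)


def instantaneous_kt(trajectory: Trajectory, output: str, side: str = "right") -> KTSeries:
    """Per-step KT: rotation of the output link over each step divided by the
    per-step input increment (n_steps values for n_steps+1 poses)."""
    if len(trajectory) < 2:
        raise ValueError("trajectory must contain at least two poses")
    per_step = trajectory.input.per_step
    values = np.array(
        [
            link_rotation(trajectory[k + 1], trajectory[k], output, side) / per_step
            for k in range(len(trajectory) - 1)
        ]
    )
    return KTSeries(output, trajectory.input.input_type, values)


def mean_kt(trajectory: Trajectory, output: str, side: str = "right") -> float:
    """KT̄: the mean of the instantaneous KT across all steps of one simulation."""
    return instantaneous_kt(trajectory, output, side).mean


def kt_frame(trajectory: Trajectory):
    """DataFrame `step,input_value,kt_suspensorium,kt_hyoid,kt_lower_jaw`
    (step k covers the interval from pose k to pose k+1)."""
    import pandas as pd

    series = {out: instantaneous_kt(trajectory, out) for out in OUTPUTS}
    return pd.DataFrame(
        {
            "step": np.arange(len(trajectory) - 1),
            "input_value": [trajectory[k + 1].input_value for k in range(len(trajectory) - 1)],
            **{f"kt_{out}": series[out].values for out in OUTPUTS},
        }
    )
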