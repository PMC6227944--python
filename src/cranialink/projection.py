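"""Iterative constraint-projection solver used to cross-validate the
closed-form pose solver.

Instead of parametrising the suspensorium rotation, this solver treats the
positions of the five non-actuated joints (HS and JQ on each side, plus
SYM) as 15 unknowns and projects them onto the constraint manifold with a
damped least-squares iteration started from the previous pose:

* per side — axial coordinate and radius of HS and JQ about the
  suspensorium axis through NS (4), the triangle edge |HS−JQ| (1), and the
  hyoid coupler |HS−CH| (1);
* the three symphysis spheres |JQ_L−SYM|, |JQ_R−SYM|, |HYM−SYM|.

That is 15 equations in 15 unknowns.  The route shares no algebra with the
closed-form circle–sphere/trilateration solution, so agreement between the
two is a meaningful check of both.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .geometry import LinkageGeometry, MechanismConfig, sided_joint
from .solver import InputSpec, Pose, hypohyal_pose, neurocranium_pose

__all__ = ["project_pose"]

_FREE = ("HS_L", "HS_R", "JQ_L", "JQ_R", "SYM")


def project_pose(
    geometry: LinkageGeometry,
    config: MechanismConfig,
    input_spec: InputSpec,
    value: float,
    previous: Pose,
) -> Pose:
    """Solve the pose at cumulative input `value` by least-squares projection
    of all rigid constraints, warm-started from `previous`."""
    theta, t = (value, 0.0) if input_spec.input_type == "epaxial" else (0.0, value)
    fixed, axes, R = neurocranium_pose(geometry, config, theta)
    fixed = dict(fixed)
    fixed.update(hypohyal_pose(geometry, config, t))

    targets = []  # (kind-specific constants), assembled once
    for side in ("left", "right"):
        ns0 = geometry.position(sided_joint("NS", side))
        a0 = config.suspensorium_axis
        for base in ("HS", "JQ"):
            r0 = geometry.position(sided_joint(base, side)) - ns0
            targets.append((side, base, float(a0 @ r0), float(np.linalg.norm(r0))))

    tri_edge = {
        side: float(
            np.linalg.norm(
                geometry.position(sided_joint("HS", side)) - geometry.position(sided_joint("JQ", side))
            )
        )
        for side in ("left", "right")
    }
    hyoid_len = {side: geometry.reference_length("hyoid", side) for side in ("left", "right")}
    jaw_len = {side: geometry.reference_length("lower_jaw", side) for side in ("left", "right")}
    ph_len = geometry.reference_length("protractor_hyoideus")

    def unpack(x: np.ndarray) -> dict[str, np.ndarray]:
        return {name: x[3 * i : 3 * i + 3] for i, name in enumerate(_FREE)}

    def residuals(x: np.ndarray) -> np.ndarray:
        p = unpack(x)
        res = []
        for side, base, axial0, radius0 in targets:
            ns = fixed[sided_joint("NS", side)]
            a = axes[side]
            r = p[sided_joint(base, side)] - ns
            res.append(float(a @ r) - axial0)
            res.append(float(np.linalg.norm(r)) - radius0)
        for side in ("left", "right"):
            hs = p[sided_joint("HS", side)]
            jq = p[sided_joint("JQ", side)]
            res.append(float(np.linalg.norm(hs - jq)) - tri_edge[side])
            res.append(float(np.linalg.norm(hs - fixed[sided_joint("CH", side)])) - hyoid_len[side])
        sym = p["SYM"]
        res.append(float(np.linalg.norm(p["JQ_L"] - sym)) - jaw_len["left"])
        res.append(float(np.linalg.norm(p["JQ_R"] - sym)) - jaw_len["right"])
        res.append(float(np.linalg.norm(fixed["HYM"] - sym)) - ph_len)
        return np.asarray(res)

    x0 = np.concatenate([np.asarray(previous.joint_positions[name], float) for name in _FREE])
    sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not sol.success or float(np.max(np.abs(sol.fun))) > 1e-8:
        raise RuntimeError(f"constraint projection failed (max residual {np.max(np.abs(sol.fun)):.3g})")
    positions = dict(fixed)
    positions.update({k: v.copy() for k, v in unpack(sol.x).items()})
    return Pose(positions, dict(previous.suspensorium_angle), value)
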