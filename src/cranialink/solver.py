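"""Closed-form pose solver for the cranial linkage.

The mechanism has one degree of freedom per input.  A pose is solved in
three stages:

1. the actuated body is placed — the neurocranium (rigid body
   {NV, NS_L, NS_R}) rotated dorsally about the mediolateral axis through
   NV, or the hypohyal body {CH_L, HYM, CH_R} translated posteriorly;
2. each suspensorium (rigid triangle {NS, HS, JQ}) is rotated about its
   axis through NS until the hyoid link HS–CH regains its reference
   length — a circle–sphere intersection with a closed-form solution;
3. the symphysis SYM is trilaterated from the two quadrate joints and the
   hypohyal midpoint using the lower-jaw and protractor-hyoideus lengths.

Every stage is exact (to floating-point rounding), so solved trajectories
conserve all link lengths to well below 1e-9 mm.  Branch ambiguities are
resolved by continuity with the previous step; at the start of a
simulation the branch reproducing the stored geometry is taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .geometry import (
    JOINT_IDS,
    LinkageGeometry,
    MechanismConfig,
    link_sides,
    sided_endpoints,
    sided_joint,
)

__all__ = [
    "InputSpec",
    "Pose",
    "Trajectory",
    "ConstancyReport",
    "LinkageInfeasible",
    "neurocranium_pose",
    "hypohyal_pose",
    "solve_suspensorium_side",
    "solve_symphysis",
    "solve_pose",
    "simulate",
    "check_link_constancy",
]

DEFAULT_EPAXIAL_MAGNITUDE = 0.2  # rad, dorsal neurocranium rotation
DEFAULT_HYPAXIAL_MAGNITUDE = 3.0  # mm, posterior hypohyal translation
DEFAULT_N_STEPS = 50


class LinkageInfeasible(RuntimeError):
    """The linkage cannot close for the requested input value."""

    def __init__(self, message: str, residual: float = math.nan, step: int | None = None):
        super().__init__(message)
        self.residual = residual
        self.step = step


@dataclass(frozen=True)
class InputSpec:
    """One muscle input: epaxial neurocranium rotation or hypaxial hypohyal retraction."""

    input_type: str  # "epaxial" | "hypaxial"
    magnitude: float | None = None  # rad (epaxial) or mm (hypaxial)
    n_steps: int = DEFAULT_N_STEPS

    def __post_init__(self) -> None:
        if self.input_type not in ("epaxial", "hypaxial"):
            raise ValueError(f"input_type must be 'epaxial' or 'hypaxial', got {self.input_type!r}")
        if self.magnitude is None:
            default = DEFAULT_EPAXIAL_MAGNITUDE if self.input_type == "epaxial" else DEFAULT_HYPAXIAL_MAGNITUDE
            object.__setattr__(self, "magnitude", default)
        if not self.magnitude > 0:
            raise ValueError("input magnitude must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def per_step(self) -> float:
        return self.magnitude / self.n_steps

    @classmethod
    def epaxial(cls, magnitude: float = DEFAULT_EPAXIAL_MAGNITUDE, n_steps: int = DEFAULT_N_STEPS) -> "InputSpec":
        return cls("epaxial", magnitude, n_steps)

    @classmethod
    def hypaxial(cls, magnitude: float = DEFAULT_HYPAXIAL_MAGNITUDE, n_steps: int = DEFAULT_N_STEPS) -> "InputSpec":
        return cls("hypaxial", magnitude, n_steps)


@dataclass(frozen=True)
class Pose:
    """One solved configuration of all 11 joints."""

    joint_positions: Mapping[str, np.ndarray]
    suspensorium_angle: Mapping[str, float]  # side -> phi (rad)
    input_value: float

    def position(self, joint_id: str) -> np.ndarray:
        return np.asarray(self.joint_positions[joint_id])


@dataclass(frozen=True)
class Trajectory:
    """Solved poses at evenly spaced cumulative inputs 0 … magnitude."""

    poses: tuple[Pose, ...]
    input: InputSpec
    geometry: LinkageGeometry

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)

    def __getitem__(self, k: int) -> Pose:
        return self.poses[k]


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    ax = np.asarray(axis, dtype=float)
    c, s = math.cos(angle), math.sin(angle)
    K = np.array([[0.0, -ax[2], ax[1]], [ax[2], 0.0, -ax[0]], [-ax[1], ax[0], 0.0]])
    return c * np.eye(3) + s * K + (1.0 - c) * np.outer(ax, ax)


# ---------------------------------------------------------------------------
# stage 1: actuated bodies


def neurocranium_pose(
    geometry: LinkageGeometry, config: MechanismConfig, theta: float
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], np.ndarray]:
    """Rigidly rotate {NV, NS_L, NS_R} dorsally by `theta` about the axis through NV.

    Returns (new positions of NV/NS_L/NS_R, co-rotated suspensorium axis per
    side, rotation matrix).  Positive theta moves points anterior to NV
    dorsally (+y).
    """
    pivot = geometry.position(config.neurocranium_pivot)
    R = _rotation_matrix(config.neurocranium_axis, theta)
    positions = {j: pivot + R @ (geometry.position(j) - pivot) for j in ("NV", "NS_L", "NS_R")}
    axes = {side: R @ config.suspensorium_axis for side in ("left", "right")}
    return positions, axes, R


def hypohyal_pose(geometry: LinkageGeometry, config: MechanismConfig, t: float) -> dict[str, np.ndarray]:
    """Rigidly translate the hypohyal body {CH_L, HYM, CH_R} by `t` mm posteriorly."""
    shift = t * config.hypohyal_translation_axis
    return {j: geometry.position(j) + shift for j in ("CH_L", "CH_R", "HYM")}


# ---------------------------------------------------------------------------
# stage 2: suspensorium closure (circle–sphere intersection)


def _circle_sphere_roots(
    centre: np.ndarray,
    axis: np.ndarray,
    radial: np.ndarray,
    sphere_centre: np.ndarray,
    sphere_radius: float,
) -> list[float]:
    """Angles phi where the point `centre + cos(phi)*radial + sin(phi)*(axis x radial)`
    lies on the given sphere.  Reduces to A cos(phi) + B sin(phi) = C."""
    u = radial
    v = np.cross(axis, u)
    d = centre - sphere_centre
    A = 2.0 * float(d @ u)
    B = 2.0 * float(d @ v)
    C = sphere_radius**2 - float(d @ d) - float(u @ u)
    amp = math.hypot(A, B)
    if amp == 0.0:
        # circle concentric on the sphere; any phi works iff C == 0
        return [0.0] if abs(C) < 1e-12 else []
    ratio = C / amp
    if abs(ratio) > 1.0:
        # allow a whisker of rounding slack before declaring a miss
        if abs(ratio) - 1.0 > 1e-12:
            return []
        ratio = math.copysign(1.0, ratio)
    base = math.atan2(B, A)
    delta = math.acos(ratio)
    return [base + delta, base - delta]


def solve_suspensorium_side(
    geometry: LinkageGeometry,
    config: MechanismConfig,
    side: str,
    theta: float,
    ch_position: np.ndarray,
    phi_prev: float = 0.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Rotate one suspensorium triangle {NS, HS, JQ} about its axis through NS
    until |HS − CH| equals the hyoid reference length.

    `theta` is the current neurocranium rotation (the triangle and its axis
    are carried with the neurocranium before the suspensorium rotation phi
    is applied).  Among the up-to-two roots, the one closest to `phi_prev`
    is returned; exactly equidistant roots abort rather than guess.

    Returns (phi, HS position, JQ position).
    """
    ns_id = sided_joint("NS", side)
    hs_id = sided_joint("HS", side)
    jq_id = sided_joint("JQ", side)
    pivot = geometry.position(config.neurocranium_pivot)
    R = _rotation_matrix(config.neurocranium_axis, theta)
    ns = pivot + R @ (geometry.position(ns_id) - pivot)
    axis = R @ config.suspensorium_axis
    r_hs = R @ (geometry.position(hs_id) - geometry.position(ns_id))
    r_jq = R @ (geometry.position(jq_id) - geometry.position(ns_id))
    hyoid_len = geometry.reference_length("hyoid", side)

    # decompose r_hs into axial + radial parts: rotation sweeps the radial part
    axial = float(axis @ r_hs) * axis
    radial = r_hs - axial
    centre = ns + axial
    roots = _circle_sphere_roots(centre, axis, radial, np.asarray(ch_position, float), hyoid_len)
    if not roots:
        d = centre - np.asarray(ch_position, float)
        gap = abs(math.hypot(math.sqrt(float(d @ d)), 0.0) - hyoid_len)
        raise LinkageInfeasible(
            f"{side} suspensorium: hyoid cannot reach HS circle (gap ~{gap:.3g} mm)", residual=gap
        )
    # wrap roots to the turn nearest phi_prev before comparing
    wrapped = [phi_prev + math.remainder(r - phi_prev, math.tau) for r in roots]
    if len(wrapped) == 2:
        d0, d1 = abs(wrapped[0] - phi_prev), abs(wrapped[1] - phi_prev)
        if d0 == d1 and abs(wrapped[0] - wrapped[1]) > 1e-12:
            raise LinkageInfeasible(
                f"{side} suspensorium: ambiguous branch (roots equidistant from previous phi)"
            )
        phi = wrapped[0] if d0 <= d1 else wrapped[1]
    else:
        phi = wrapped[0]
    Rp = _rotation_matrix(axis, phi)
    hs = ns + Rp @ r_hs
    jq = ns + Rp @ r_jq
    return phi, hs, jq


# ---------------------------------------------------------------------------
# stage 3: symphysis trilateration


def solve_symphysis(
    jq_left: np.ndarray,
    jq_right: np.ndarray,
    hym: np.ndarray,
    jaw_length_left: float,
    jaw_length_right: float,
    ph_length: float,
    previous: np.ndarray | None = None,
) -> np.ndarray:
    """Trilaterate SYM from spheres around JQ_L, JQ_R and HYM.

    Of the up-to-two intersection points, the one closest to `previous` is
    returned; with no `previous`, the ventral (−y) branch is taken.
    """
    p1 = np.asarray(jq_left, float)
    p2 = np.asarray(jq_right, float)
    p3 = np.asarray(hym, float)
    r1, r2, r3 = jaw_length_left, jaw_length_right, ph_length
    if min(r1, r2, r3) <= 0:
        raise LinkageInfeasible("sphere radii must be positive")

    ex_raw = p2 - p1
    d = float(np.linalg.norm(ex_raw))
    if d == 0.0:
        raise LinkageInfeasible("quadrate joints coincide; trilateration degenerate")
    ex = ex_raw / d
    i = float(ex @ (p3 - p1))
    ey_raw = p3 - p1 - i * ex
    ey_norm = float(np.linalg.norm(ey_raw))
    if ey_norm < 1e-12:
        raise LinkageInfeasible("trilateration centres are collinear")
    ey = ey_raw / ey_norm
    ez = np.cross(ex, ey)
    j = ey_norm

    x = (r1**2 - r2**2 + d**2) / (2.0 * d)
    y = (r1**2 - r3**2 + i**2 + j**2 - 2.0 * i * x) / (2.0 * j)
    z2 = r1**2 - x**2 - y**2
    if z2 < 0.0:
        if z2 < -1e-9 * max(1.0, r1**2):
            raise LinkageInfeasible(
                f"jaw spheres do not intersect (residual {abs(z2):.3g} mm^2)", residual=abs(z2)
            )
        z2 = 0.0
    z = math.sqrt(z2)
    cand = [p1 + x * ex + y * ey + z * ez, p1 + x * ex + y * ey - z * ez]
    if previous is not None:
        prev = np.asarray(previous, float)
        d0 = float(np.linalg.norm(cand[0] - prev))
        d1 = float(np.linalg.norm(cand[1] - prev))
        if d0 == d1 and z > 1e-12:
            raise LinkageInfeasible("ambiguous symphysis branch (solutions equidistant from previous)")
        return cand[0] if d0 <= d1 else cand[1]
    # no history: take the ventral branch
    return cand[0] if cand[0][1] <= cand[1][1] else cand[1]


# ---------------------------------------------------------------------------
# full pose & trajectory


def _rest_pose(geometry: LinkageGeometry) -> Pose:
    return Pose(geometry.positions(), {"left": 0.0, "right": 0.0}, 0.0)


def solve_pose(
    geometry: LinkageGeometry,
    config: MechanismConfig,
    input_spec: InputSpec,
    value: float,
    previous: Pose | None = None,
) -> Pose:
    """Solve the full linkage pose at cumulative input `value`.

    The non-actuated input is held fixed at zero (inputs are analysed
    separately to isolate their effects).
    """
    if value < 0:
        raise ValueError("input value must be non-negative")
    if value == 0.0 and previous is None:
        return _rest_pose(geometry)
    if previous is None:
        previous = _rest_pose(geometry)

    if input_spec.input_type == "epaxial":
        theta, t = value, 0.0
    else:
        theta, t = 0.0, value

    positions: dict[str, np.ndarray] = {}
    nc_positions, _, _ = neurocranium_pose(geometry, config, theta)
    positions.update(nc_positions)
    positions.update(hypohyal_pose(geometry, config, t))

    angles: dict[str, float] = {}
    for side in ("left", "right"):
        ch = positions[sided_joint("CH", side)]
        phi, hs, jq = solve_suspensorium_side(
            geometry, config, side, theta, ch, previous.suspensorium_angle[side]
        )
        angles[side] = phi
        positions[sided_joint("HS", side)] = hs
        positions[sided_joint("JQ", side)] = jq

    positions["SYM"] = solve_symphysis(
        positions["JQ_L"],
        positions["JQ_R"],
        positions["HYM"],
        geometry.reference_length("lower_jaw", "left"),
        geometry.reference_length("lower_jaw", "right"),
        geometry.reference_length("protractor_hyoideus"),
        previous.joint_positions["SYM"],
    )
    return Pose(positions, angles, value)


def simulate(geometry: LinkageGeometry, config: MechanismConfig, input_spec: InputSpec) -> Trajectory:
    """Solve n_steps+1 poses at evenly spaced cumulative inputs 0 … magnitude.

    Each step is seeded from the previous for branch continuity; step 0 is
    the starting geometry itself.
    """
    poses = [_rest_pose(geometry)]
    for k in range(1, input_spec.n_steps + 1):
        v = input_spec.magnitude * k / input_spec.n_steps
        try:
            poses.append(solve_pose(geometry, config, input_spec, v, poses[-1]))
        except LinkageInfeasible as exc:
            raise LinkageInfeasible(f"step {k} (input {v:.6g}): {exc}", residual=exc.residual, step=k) from exc
    return Trajectory(tuple(poses), input_spec, geometry)


@dataclass(frozen=True)
class ConstancyReport:
    """Per-link maximum deviation of length from reference over a trajectory."""

    max_deviation: Mapping[tuple[str, str | None], float]
    tol: float

    @property
    def passed(self) -> bool:
        return all(d <= self.tol for d in self.max_deviation.values())

    @property
    def failures(self) -> list[tuple[str, str | None]]:
        return [k for k, d in self.max_deviation.items() if d > self.tol]

    @property
    def worst(self) -> float:
        return max(self.max_deviation.values())

    def to_dict(self) -> dict:
        return {
            "tol_mm": self.tol,
            "passed": self.passed,
            "max_deviation_mm": {f"{link}[{side or 'midline'}]": d for (link, side), d in self.max_deviation.items()},
        }


def check_link_constancy(trajectory: Trajectory, tol: float = 1e-9) -> ConstancyReport:
    """Verify no link was forced to change length during mouth opening."""
    refs = trajectory.geometry.all_link_lengths()
    worst = {key: 0.0 for key in refs}
    for pose in trajectory.poses:
        for (link, side), ref in refs.items():
            a, b = sided_endpoints(link, side)
            length = float(np.linalg.norm(pose.position(a) - pose.position(b)))
            dev = abs(length - ref)
            if dev > worst[(link, side)]:
                worst[(link, side)] = dev
    return ConstancyReport(worst, tol)


def trajectory_frame(trajectory: Trajectory):
    """Long-format DataFrame: one row per (step, joint)."""
    import pandas as pd

    rows = []
    for step, pose in enumerate(trajectory.poses):
        for j in JOINT_IDS:
            p = pose.position(j)
            rows.append(
                {"step": step, "input_value": pose.input_value, "joint": j, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]}
            )
    return pd.DataFrame(rows)
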