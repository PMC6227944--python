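"""Mechanical-sensitivity experiments.

A *modelling experiment* fixes a reference link, a joint (or symmetric
joint pair, or the coordinated neurocranium set) that serves as one of its
endpoints, a Cartesian axis, and an input type.  The joint is shifted
along that axis so the reference link's length sweeps 75–125% of its
original value in 1% increments (51 geometries when unrestricted); each
geometry is simulated over the full input and summarised by the mean
kinematic transmission KT̄ of the three outputs.

Sensitivity is the finite-difference rate of change of KT̄ with link
length L:

* instantaneous at the default geometry i —
  dKT = (KT̄_{i+1} − KT̄_{i−1}) / (L_{i+1} − L_{i−1});
* averaged over the sweep —
  dKT_avg = Σ_i |dKT_i| / a, where the sum runs over the interior
  geometries (endpoints carry no central difference) and a is the number
  of geometries retained.

Experiments for which two of the three outputs have (near-)zero
sensitivity isolate the third output's KT; ranking sensitivities per
(reference link, output) identifies the most and least influential ways
to change each link.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import LinkageGeometry, MechanismConfig, link_sides, sided_endpoints, sided_joint
from .kt import OUTPUTS, mean_kt
from .solver import InputSpec, LinkageInfeasible, check_link_constancy, simulate

__all__ = [
    "AXES",
    "ExperimentSpec",
    "ExperimentRecord",
    "ExperimentResult",
    "SensitivityRecord",
    "PerturbationInfeasible",
    "perturb_geometry",
    "run_experiment",
    "delta_kt_instantaneous",
    "delta_kt_average",
    "summarize_experiment",
    "classify_isolation",
    "rank_sensitivity",
    "kt_surface",
    "enumerate_experiments",
]

AXES = ("x", "y", "z")
_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

#: The coordinated neurocranium set: moving NV and both NS joints together
#: changes the NS-anchored suspensorium links while preserving NV–NS length.
COORDINATED_NEUROCRANIUM: tuple[str, ...] = ("NV", "NS_L", "NS_R")

DEFAULT_PCT_RANGE: tuple[int, ...] = tuple(range(75, 126))


class PerturbationInfeasible(ValueError):
    """The requested link length cannot be reached along the given axis."""


@dataclass(frozen=True)
class ExperimentSpec:
    """One modelling experiment: (reference link, moved joints, axis, input)."""

    reference_link: str
    moved_joints: tuple[str, ...]
    axis: str
    input_type: str = "epaxial"
    pct_range: tuple[int, ...] = DEFAULT_PCT_RANGE

    def __post_init__(self) -> None:
        object.__setattr__(self, "moved_joints", tuple(self.moved_joints))
        object.__setattr__(self, "pct_range", tuple(self.pct_range))
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if 100 not in self.pct_range:
            raise ValueError("pct_range must contain 100 (the default geometry)")
        if any(p <= 0 for p in self.pct_range):
            raise ValueError("percentages must be positive")
        if self.moved_joints != COORDINATED_NEUROCRANIUM:
            endpoint_bases = set()
            for side in link_sides(self.reference_link):
                endpoint_bases.update(sided_endpoints(self.reference_link, side))
            for j in self.moved_joints:
                if j not in endpoint_bases:
                    raise ValueError(
                        f"moved joint {j} is not an endpoint of link {self.reference_link}"
                    )

    @property
    def joints_label(self) -> str:
        if self.moved_joints == COORDINATED_NEUROCRANIUM:
            return "NV+NS"
        bases = sorted({j[:-2] if j.endswith(("_L", "_R")) else j for j in self.moved_joints})
        return "+".join(bases)

    @property
    def label(self) -> str:
        return f"{self.reference_link}:{self.joints_label}:{self.axis}:{self.input_type}"


@dataclass(frozen=True)
class ExperimentRecord:
    """One retained geometry of a sweep."""

    pct: int
    length_mm: float
    displacement_mm: float
    kt_mean: Mapping[str, float]  # output -> KT̄


@dataclass(frozen=True)
class ExperimentResult:
    """Retained KT̄ curve of one modelling experiment, sorted by link length."""

    spec: ExperimentSpec
    records: tuple[ExperimentRecord, ...]
    dropped: tuple[tuple[int, str], ...]  # (pct, reason)

    @property
    def a(self) -> int:
        """Number of geometries retained (denominator of the averaged sensitivity)."""
        return len(self.records)

    @property
    def retained_range(self) -> tuple[int, int]:
        pcts = [r.pct for r in self.records]
        return (min(pcts), max(pcts))

    def record_at(self, pct: int) -> ExperimentRecord:
        for r in self.records:
            if r.pct == pct:
                return r
        raise KeyError(f"no retained record at {pct}% in experiment {self.spec.label}")

    def curve(self, output: str) -> tuple[np.ndarray, np.ndarray]:
        L = np.array([r.length_mm for r in self.records])
        kt = np.array([r.kt_mean[output] for r in self.records])
        return L, kt


@dataclass(frozen=True)
class SensitivityRecord:
    """Sensitivity summary of one experiment for one output."""

    spec: ExperimentSpec
    output: str
    dkt_instantaneous: float  # signed central difference at the default geometry
    dkt_average: float  # >= 0 by construction
    kt_max: float
    kt_min: float


# ---------------------------------------------------------------------------
# geometry perturbation


def _perturbation_roots(p: np.ndarray, q: np.ndarray, axis_idx: int, target: float) -> list[float]:
    """Displacements s along the axis with |p + s e − q| = target."""
    diff = p - q
    b = float(diff[axis_idx])
    c = float(diff @ diff) - target**2
    disc = b * b - c
    if disc < 0.0:
        return []
    root = math.sqrt(disc)
    return [-b + root, -b - root]


def _canonical_pair(spec: ExperimentSpec) -> tuple[str, str]:
    """(moved endpoint, fixed endpoint) on the canonical (right) side."""
    if spec.moved_joints == COORDINATED_NEUROCRANIUM:
        # the moved NS endpoint drives the NS-anchored reference link
        moved_base = "NS"
    else:
        bases = {j[:-2] if j.endswith(("_L", "_R")) else j for j in spec.moved_joints}
        if len(bases) != 1:
            raise ValueError(f"moved joints {spec.moved_joints} must be one joint or one symmetric pair")
        (moved_base,) = bases
    side = "right" if spec.reference_link not in ("protractor_hyoideus",) else None
    a, b = sided_endpoints(spec.reference_link, side)
    moved = sided_joint(moved_base, "right")
    if moved == a:
        return a, b
    if moved == b:
        return b, a
    raise ValueError(f"moved joint {moved_base} is not an endpoint of {spec.reference_link}")


def _apply_displacement(
    geometry: LinkageGeometry, spec: ExperimentSpec, s: float
) -> LinkageGeometry:
    """Displace the moved joints by s along the axis (mirror-symmetric for
    pairs: equal x/y shifts, opposite-sign z shifts; coordinated set and
    midline joints shifted identically)."""
    idx = _AXIS_INDEX[spec.axis]
    updates = {}
    for j in spec.moved_joints:
        shift = np.zeros(3)
        if spec.axis == "z" and j.endswith("_L") and spec.moved_joints != COORDINATED_NEUROCRANIUM:
            shift[idx] = -s
        else:
            shift[idx] = s
        updates[j] = geometry.position(j) + shift
    return geometry.with_positions(updates)


def perturb_geometry(
    geometry: LinkageGeometry,
    spec: ExperimentSpec,
    pct: float,
    s_hint: float = 0.0,
) -> tuple[LinkageGeometry, float]:
    """Shift the moved joint(s) along the spec's axis so the reference link's
    (right-side) length equals pct/100 of its current value.

    Returns (perturbed geometry, displacement in mm).  The root of the
    induced quadratic closest to `s_hint` is taken (hint 0 gives the branch
    through zero displacement at pct = 100); an exact tie is broken toward
    the positive root.  Raises PerturbationInfeasible when the target length
    is unreachable along that axis.
    """
    if pct <= 0:
        raise ValueError("pct must be positive")
    moved, fixed_ep = _canonical_pair(spec)
    idx = _AXIS_INDEX[spec.axis]
    p = geometry.position(moved)
    q = geometry.position(fixed_ep)
    L0 = float(np.linalg.norm(p - q))
    target = pct / 100.0 * L0
    roots = _perturbation_roots(p, q, idx, target)
    if not roots:
        raise PerturbationInfeasible(
            f"{spec.label}: length {target:.6g} mm unreachable by moving {moved} along {spec.axis}"
        )
    roots.sort(key=lambda s: (abs(s - s_hint), -s))
    s = roots[0]
    return _apply_displacement(geometry, spec, s), s


# ---------------------------------------------------------------------------
# experiment execution


def run_experiment(
    geometry: LinkageGeometry,
    config: MechanismConfig,
    spec: ExperimentSpec,
    constancy_tol: float = 1e-9,
) -> ExperimentResult:
    """Sweep the percentage range, simulate every feasible geometry, and
    collect the KT̄ of all three outputs.

    Percentages whose perturbation is geometrically unreachable, whose
    simulation breaks, or whose trajectory fails the link-constancy check
    are dropped (with a recorded reason), reproducing the range reduction
    of the sweep protocol.  The displacement branch is tracked continuously
    outward from 100% in both directions.
    """
    input_spec = InputSpec(spec.input_type)
    pcts = sorted(set(spec.pct_range))
    upward = [p for p in pcts if p >= 100]
    downward = [p for p in pcts if p < 100][::-1]

    records: list[ExperimentRecord] = []
    dropped: list[tuple[int, str]] = []

    def evaluate(pct: int, s_hint: float) -> float | None:
        try:
            perturbed, s = perturb_geometry(geometry, spec, pct, s_hint)
        except PerturbationInfeasible:
            dropped.append((pct, "infeasible-perturbation"))
            return None
        try:
            traj = simulate(perturbed, config, input_spec)
        except LinkageInfeasible:
            dropped.append((pct, "solver-failure"))
            return s
        report = check_link_constancy(traj, constancy_tol)
        if not report.passed:
            dropped.append((pct, "non-constant-length"))
            return s
        length = perturbed.reference_length(
            spec.reference_link, "right" if spec.reference_link != "protractor_hyoideus" else None
        )
        records.append(
            ExperimentRecord(pct, length, s, {out: mean_kt(traj, out) for out in OUTPUTS})
        )
        return s

    for chain in (upward, downward):
        s_hint = 0.0
        for pct in chain:
            s = evaluate(pct, s_hint)
            if s is not None:
                s_hint = s

    if len(records) < 3:
        raise PerturbationInfeasible(
            f"{spec.label}: only {len(records)} geometries retained; derivatives undefined"
        )
    records.sort(key=lambda r: r.length_mm)
    lengths = [r.length_mm for r in records]
    if any(b <= a for a, b in zip(lengths, lengths[1:])):
        raise PerturbationInfeasible(f"{spec.label}: retained link lengths are not strictly monotone")
    return ExperimentResult(spec, tuple(records), tuple(sorted(dropped)))


# ---------------------------------------------------------------------------
# sensitivity statistics


def central_differences(lengths: Sequence[float], kt: Sequence[float]) -> np.ndarray:
    """Central-difference slopes at interior samples of a KT̄(L) curve."""
    L = np.asarray(lengths, float)
    y = np.asarray(kt, float)
    if len(L) < 3:
        raise ValueError("need at least three samples for central differences")
    return (y[2:] - y[:-2]) / (L[2:] - L[:-2])


def delta_kt_instantaneous(result: ExperimentResult, output: str) -> float:
    """Signed sensitivity at the default geometry:
    (KT̄ at 101% − KT̄ at 99%) / (L at 101% − L at 99%)."""
    try:
        lo, hi = result.record_at(99), result.record_at(101)
    except KeyError as exc:
        raise ValueError(
            f"{result.spec.label}: records at 99% and 101% are required for the "
            f"instantaneous sensitivity ({exc})"
        ) from exc
    return (hi.kt_mean[output] - lo.kt_mean[output]) / (hi.length_mm - lo.length_mm)


def delta_kt_average(result: ExperimentResult, output: str, denominator: str = "geometries") -> float:
    """Mean absolute sensitivity over the sweep: Σ|dKT_i| / a.

    `denominator="geometries"` divides by the number of retained geometries
    a (the literal definition; endpoints contribute no derivative term);
    `denominator="terms"` divides by the number of interior derivative
    terms (a − 2) instead.
    """
    L, kt = result.curve(output)
    slopes = np.abs(central_differences(L, kt))
    if denominator == "geometries":
        return float(slopes.sum() / result.a)
    if denominator == "terms":
        return float(slopes.mean())
    raise ValueError("denominator must be 'geometries' or 'terms'")


def summarize_experiment(result: ExperimentResult) -> dict[str, SensitivityRecord]:
    """SensitivityRecord per output for one experiment."""
    out: dict[str, SensitivityRecord] = {}
    for output in OUTPUTS:
        L, kt = result.curve(output)
        try:
            dkt_inst = delta_kt_instantaneous(result, output)
        except ValueError:
            # one-sided sweep (default at the edge of the retained range):
            # the central difference at the default geometry is undefined
            dkt_inst = math.nan
        out[output] = SensitivityRecord(
            spec=result.spec,
            output=output,
            dkt_instantaneous=dkt_inst,
            dkt_average=delta_kt_average(result, output),
            kt_max=float(kt.max()),
            kt_min=float(kt.min()),
        )
    return out


DEFAULT_ZERO_THRESHOLD = 1e-10


def classify_isolation(
    summaries: Mapping[str, Mapping[str, SensitivityRecord]],
    zero_threshold: float = DEFAULT_ZERO_THRESHOLD,
) -> dict:
    """Label each output of each experiment null/active and report which
    experiments isolate a single output's KT.

    `summaries` maps experiment label -> output -> SensitivityRecord.  An
    output is *null* when both |dKT_instantaneous| and dKT_average are at or
    below `zero_threshold`; an experiment with exactly one active output
    isolates that KT; all-null experiments have no effect.
    """
    def _is_null(rec: SensitivityRecord) -> bool:
        stats = [abs(rec.dkt_instantaneous), abs(rec.dkt_average)]
        finite = [s for s in stats if not math.isnan(s)]
        # NaN statistics (undefined on one-sided sweeps) are ignored
        return bool(finite) and all(s <= zero_threshold for s in finite)

    experiments = {}
    isolating: dict[str, list[str]] = {out: [] for out in OUTPUTS}
    for label in sorted(summaries):
        recs = summaries[label]
        status = {out: ("null" if _is_null(recs[out]) else "active") for out in OUTPUTS}
        active = [out for out, s in status.items() if s == "active"]
        if not active:
            verdict = "no-effect"
        elif len(active) == 1:
            verdict = f"isolates:{active[0]}"
            isolating[active[0]].append(label)
        else:
            verdict = "coupled"
        experiments[label] = {"outputs": status, "verdict": verdict}
    return {
        "zero_threshold": zero_threshold,
        "experiments": experiments,
        "isolating": isolating,
    }


def rank_sensitivity(
    summaries: Mapping[str, Mapping[str, SensitivityRecord]],
) -> pd.DataFrame:
    """Rank experiments by sensitivity within each (reference link, output).

    Returns a DataFrame with |dKT_instantaneous| and dKT_average, ranks
    (1 = most sensitive) per group for each statistic, and flags for the
    group extremes.  Ties are broken by experiment label, so the ranking is
    independent of insertion order.
    """
    rows = []
    for label in sorted(summaries):
        for output, rec in summaries[label].items():
            rows.append(
                {
                    "reference_link": rec.spec.reference_link,
                    "output": output,
                    "joints": rec.spec.joints_label,
                    "axis": rec.spec.axis,
                    "input_type": rec.spec.input_type,
                    "experiment": label,
                    "delta_kt_inst_abs": abs(rec.dkt_instantaneous),
                    "delta_kt_avg": rec.dkt_average,
                    "kt_max": rec.kt_max,
                    "kt_min": rec.kt_min,
                }
            )
    df = pd.DataFrame(rows).sort_values(
        ["reference_link", "output", "delta_kt_inst_abs", "experiment"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    group = df.groupby(["reference_link", "output"], sort=False)
    df["rank_inst"] = group["delta_kt_inst_abs"].rank(method="first", ascending=False).astype(int)
    df["rank_avg"] = group["delta_kt_avg"].rank(method="first", ascending=False).astype(int)
    df["is_max_inst"] = df["rank_inst"] == 1
    df["is_min_inst"] = group["delta_kt_inst_abs"].transform(
        lambda s: s.rank(method="first", ascending=True) == 1
    )
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# KT surfaces (two displacement directions on one link)


def kt_surface(
    geometry: LinkageGeometry,
    config: MechanismConfig,
    spec1: ExperimentSpec,
    spec2: ExperimentSpec,
    grid1: Iterable[float],
    grid2: Iterable[float],
) -> pd.DataFrame:
    """Evaluate KT̄ on the Cartesian product of two displacement grids (mm)
    applied to two joint/axis combinations on the same reference link.

    Returns long-format rows `d1_mm,d2_mm,output,kt_mean`; infeasible cells
    carry NaN.  The (0, 0) cell is the default geometry.
    """
    if spec1.reference_link != spec2.reference_link:
        raise ValueError("both surface specs must reference the same link")
    if spec1.input_type != spec2.input_type:
        raise ValueError("both surface specs must share the input type")
    input_spec = InputSpec(spec1.input_type)
    rows = []
    for d1 in grid1:
        for d2 in grid2:
            perturbed = _apply_displacement(
                _apply_displacement(geometry, spec1, float(d1)), spec2, float(d2)
            )
            try:
                traj = simulate(perturbed, config, input_spec)
                if not check_link_constancy(traj).passed:
                    raise LinkageInfeasible("non-constant link length")
                kts = {out: mean_kt(traj, out) for out in OUTPUTS}
            except (LinkageInfeasible, ValueError):
                kts = {out: math.nan for out in OUTPUTS}
            for out in OUTPUTS:
                rows.append({"d1_mm": float(d1), "d2_mm": float(d2), "output": out, "kt_mean": kts[out]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# roster


def enumerate_experiments(
    geometry: LinkageGeometry,
    input_type: str = "epaxial",
    pct_range: tuple[int, ...] = DEFAULT_PCT_RANGE,
) -> list[ExperimentSpec]:
    """The full deterministic roster of modelling experiments.

    Every (link, endpoint joint or pair, Cartesian axis) triple, plus the
    coordinated neurocranium set (x and y) for the NS-anchored suspensorium
    links.  Duplicate-free, ordered by link roster then joint then axis.
    """
    from .geometry import LINK_ENDPOINTS, MIDLINE_JOINTS

    specs: list[ExperimentSpec] = []
    seen = set()
    for link, (a, b) in LINK_ENDPOINTS.items():
        for base in (a, b):
            if base in MIDLINE_JOINTS:
                joints: tuple[str, ...] = (base,)
            else:
                joints = (base + "_L", base + "_R")
            for axis in AXES:
                key = (link, joints, axis)
                if key in seen:
                    continue
                seen.add(key)
                specs.append(ExperimentSpec(link, joints, axis, input_type, pct_range))
        if link in ("anterior_suspensorium", "posterior_suspensorium"):
            for axis in ("x", "y"):
                specs.append(
                    ExperimentSpec(link, COORDINATED_NEUROCRANIUM, axis, input_type, pct_range)
                )
    return specs


def run_roster(
    geometry: LinkageGeometry,
    config: MechanismConfig,
    specs: Iterable[ExperimentSpec],
) -> tuple[dict[str, dict[str, SensitivityRecord]], dict[str, str]]:
    """Run a set of experiments; returns (summaries by label, failures by label)."""
    summaries: dict[str, dict[str, SensitivityRecord]] = {}
    failures: dict[str, str] = {}
    for spec in specs:
        try:
            result = run_experiment(geometry, config, spec)
            summaries[spec.label] = summarize_experiment(result)
        except (PerturbationInfeasible, ValueError, LinkageInfeasible) as exc:
            failures[spec.label] = str(exc)
    return summaries, failures


def experiment_frame(result: ExperimentResult) -> pd.DataFrame:
    """Long-format sweep table including dropped percentages."""
    rows = []
    for r in result.records:
        rows.append(
            {
                "reference_link": result.spec.reference_link,
                "joints": result.spec.joints_label,
                "axis": result.spec.axis,
                "input_type": result.spec.input_type,
                "pct": r.pct,
                "length_mm": r.length_mm,
                "kt_suspensorium": r.kt_mean["suspensorium"],
                "kt_hyoid": r.kt_mean["hyoid"],
                "kt_lower_jaw": r.kt_mean["lower_jaw"],
                "retained": True,
                "drop_reason": "",
            }
        )
    for pct, reason in result.dropped:
        rows.append(
            {
                "reference_link": result.spec.reference_link,
                "joints": result.spec.joints_label,
                "axis": result.spec.axis,
                "input_type": result.spec.input_type,
                "pct": pct,
                "length_mm": math.nan,
                "kt_suspensorium": math.nan,
                "kt_hyoid": math.nan,
                "kt_lower_jaw": math.nan,
                "retained": False,
                "drop_reason": reason,
            }
        )
    return pd.DataFrame(rows).sort_values("pct").reset_index(drop=True)
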