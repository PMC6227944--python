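"""Linkage geometry: joints, links, symmetry, and file I/O.

The model is a simplified 3D mechanism of the teleost skull during mouth
opening.  Eleven named joints (four bilateral pairs plus three midline
joints) are connected by rigid links representing the neurocranium, the
suspensoria, the hyoid bars, the hypohyal, the lower jaws and the
protractor hyoideus muscle (held in tension during mouth opening and
therefore treated as a rigid link).

Coordinate convention: +x anterior, +y dorsal, +z toward the animal's
right; the midsagittal plane is z = 0.  Coordinates and lengths are in mm.
Link lengths are always *derived* from joint coordinates — they are never
stored independently, so moving a joint is the only way to change a length.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "JOINT_IDS",
    "MIDLINE_JOINTS",
    "SYMMETRY_PAIRS",
    "LINK_ENDPOINTS",
    "LINK_NAMES",
    "Joint",
    "LinkSpec",
    "LinkageGeometry",
    "MechanismConfig",
    "SymmetryReport",
    "GeometryError",
    "read_geometry",
    "write_geometry",
    "link_length",
    "validate_symmetry",
]


class GeometryError(ValueError):
    """Raised for malformed or inconsistent linkage geometry."""


#: Anatomical roster.  NV: neurocranium-vertebral column joint; NS: anterior
#: neurocranium-suspensorium joints; HS: posterior ceratohyal-suspensorium
#: joints; JQ: lower jaw-quadrate joints; CH: anterior ceratohyal-hypohyal
#: joints; HYM: midpoint of the hypohyal; SYM: inferior aspect of the lower
#: jaw symphysis.
JOINT_IDS: tuple[str, ...] = (
    "NV",
    "NS_L",
    "NS_R",
    "HS_L",
    "HS_R",
    "JQ_L",
    "JQ_R",
    "CH_L",
    "CH_R",
    "HYM",
    "SYM",
)

MIDLINE_JOINTS: tuple[str, ...] = ("NV", "HYM", "SYM")

SYMMETRY_PAIRS: tuple[tuple[str, str], ...] = (
    ("NS_L", "NS_R"),
    ("HS_L", "HS_R"),
    ("JQ_L", "JQ_R"),
    ("CH_L", "CH_R"),
)

ANATOMICAL_NAMES: Mapping[str, str] = {
    "NV": "neurocranium-vertebral column joint",
    "NS_L": "left anterior neurocranium-suspensorium joint",
    "NS_R": "right anterior neurocranium-suspensorium joint",
    "HS_L": "left posterior ceratohyal-suspensorium joint",
    "HS_R": "right posterior ceratohyal-suspensorium joint",
    "JQ_L": "left lower jaw-quadrate joint",
    "JQ_R": "right lower jaw-quadrate joint",
    "CH_L": "left anterior ceratohyal-hypohyal joint",
    "CH_R": "right anterior ceratohyal-hypohyal joint",
    "HYM": "midpoint of the hypohyal",
    "SYM": "inferior aspect of the lower jaw symphysis",
}

#: Link roster keyed by name; endpoints are *base* joint ids (without the
#: _L/_R suffix); per-side resolution happens in :func:`sided_endpoints`.
LINK_ENDPOINTS: Mapping[str, tuple[str, str]] = {
    "neurocranium": ("NV", "NS"),
    "anterior_suspensorium": ("NS", "JQ"),
    "posterior_suspensorium": ("NS", "HS"),
    "ventral_suspensorium": ("HS", "JQ"),
    "hyoid": ("HS", "CH"),
    "hypohyal": ("CH", "HYM"),
    "lower_jaw": ("JQ", "SYM"),
    "protractor_hyoideus": ("HYM", "SYM"),
}

LINK_NAMES: tuple[str, ...] = tuple(LINK_ENDPOINTS)

#: Links whose two endpoints are both midline joints carry no side.
MIDLINE_LINKS: tuple[str, ...] = ("protractor_hyoideus",)

_SUFFIX = {"left": "_L", "right": "_R"}


def joint_side(joint_id: str) -> str:
    if joint_id in MIDLINE_JOINTS:
        return "midline"
    return "left" if joint_id.endswith("_L") else "right"


def sided_joint(base: str, side: str) -> str:
    """Resolve a base joint id ('NS') to a sided id ('NS_R')."""
    if base in MIDLINE_JOINTS:
        return base
    return base + _SUFFIX[side]


def sided_endpoints(link: str, side: str | None) -> tuple[str, str]:
    """Endpoint joint ids of `link` on `side` (side ignored for midline links)."""
    if link not in LINK_ENDPOINTS:
        raise GeometryError(f"unknown link {link!r}")
    a, b = LINK_ENDPOINTS[link]
    if link in MIDLINE_LINKS:
        return a, b
    if side not in ("left", "right"):
        raise GeometryError(f"link {link!r} requires side 'left' or 'right', got {side!r}")
    return sided_joint(a, side), sided_joint(b, side)


def link_sides(link: str) -> tuple[str | None, ...]:
    return (None,) if link in MIDLINE_LINKS else ("left", "right")


@dataclass(frozen=True)
class Joint:
    """A named joint with a 3D position in mm."""

    id: str
    position: np.ndarray
    anatomical_name: str = ""

    @property
    def side(self) -> str:
        return joint_side(self.id)

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise GeometryError(f"joint {self.id}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.anatomical_name:
            object.__setattr__(self, "anatomical_name", ANATOMICAL_NAMES.get(self.id, ""))


@dataclass(frozen=True)
class LinkSpec:
    """A rigid link with per-side reference lengths derived from coordinates."""

    name: str
    reference_lengths: Mapping[str | None, float]  # side -> mm

    def endpoints(self, side: str | None) -> tuple[str, str]:
        return sided_endpoints(self.name, side)


class LinkageGeometry:
    """Immutable collection of the 11 joints plus derived link lengths."""

    def __init__(self, positions: Mapping[str, Iterable[float]]):
        missing = [j for j in JOINT_IDS if j not in positions]
        if missing:
            raise GeometryError(f"missing joint {missing[0]}" if len(missing) == 1 else f"missing joints {missing}")
        extra = [j for j in positions if j not in JOINT_IDS]
        if extra:
            raise GeometryError(f"unknown joint id(s) {extra}")
        self._joints = {j: Joint(j, np.asarray(positions[j], dtype=float)) for j in JOINT_IDS}
        self._links = {
            name: LinkSpec(name, {side: self._distance(name, side) for side in link_sides(name)})
            for name in LINK_NAMES
        }
        for name, spec in self._links.items():
            for side, length in spec.reference_lengths.items():
                if not (length > 0 and math.isfinite(length)):
                    raise GeometryError(f"link {name} ({side or 'midline'}) has non-positive length {length}")

    def _distance(self, link: str, side: str | None) -> float:
        a, b = sided_endpoints(link, side)
        return float(np.linalg.norm(self._joints[a].position - self._joints[b].position))

    # -- access -----------------------------------------------------------
    @property
    def joints(self) -> Mapping[str, Joint]:
        return dict(self._joints)

    @property
    def links(self) -> Mapping[str, LinkSpec]:
        return dict(self._links)

    @property
    def symmetry_pairs(self) -> tuple[tuple[str, str], ...]:
        return SYMMETRY_PAIRS

    def position(self, joint_id: str) -> np.ndarray:
        return self._joints[joint_id].position.copy()

    def positions(self) -> dict[str, np.ndarray]:
        return {j: self._joints[j].position.copy() for j in JOINT_IDS}

    def reference_length(self, link: str, side: str | None = "right") -> float:
        if link not in self._links:
            raise GeometryError(f"unknown link {link!r}")
        if link in MIDLINE_LINKS:
            side = None
        return self._links[link].reference_lengths[side]

    def all_link_lengths(self) -> dict[tuple[str, str | None], float]:
        """All 15 link lengths keyed by (link, side); 14 sided + 1 midline."""
        return {
            (name, side): spec.reference_lengths[side]
            for name, spec in self._links.items()
            for side in link_sides(name)
        }

    # -- derivation -------------------------------------------------------
    def with_positions(self, updates: Mapping[str, Iterable[float]]) -> "LinkageGeometry":
        """New geometry with some joints moved; lengths re-derived."""
        pos = {j: self._joints[j].position for j in JOINT_IDS}
        pos.update({j: np.asarray(p, dtype=float) for j, p in updates.items()})
        return LinkageGeometry(pos)

    def transformed(self, rotation: np.ndarray, translation: Iterable[float]) -> "LinkageGeometry":
        """Apply a rigid transform x -> R x + t to every joint."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return LinkageGeometry({j: R @ self._joints[j].position + t for j in JOINT_IDS})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LinkageGeometry):
            return NotImplemented
        return all(np.array_equal(self._joints[j].position, other._joints[j].position) for j in JOINT_IDS)

    def __repr__(self) -> str:
        return f"LinkageGeometry({len(self._joints)} joints, {len(self._links)} links)"


@dataclass(frozen=True)
class MechanismConfig:
    """Axes, pivots and tolerances defining the mechanism's kinematics.

    The neurocranium rotates about a mediolateral axis through NV (epaxial
    input); each suspensorium rotates about an axis through its NS joint
    that is fixed in the neurocranium frame (default: anteroposterior, +x,
    giving lateral abduction); the hypohyal body translates along the
    anteroposterior axis (hypaxial input, applied posteriorly).
    """

    neurocranium_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    neurocranium_pivot: str = "NV"
    suspensorium_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    hypohyal_translation_axis: np.ndarray = field(default_factory=lambda: np.array([-1.0, 0.0, 0.0]))
    constraint_tol: float = 1e-9  # mm
    continuity_tol: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("neurocranium_axis", "suspensorium_axis", "hypohyal_translation_axis"):
            v = np.asarray(getattr(self, name), dtype=float)
            n = np.linalg.norm(v)
            if not n > 0:
                raise GeometryError(f"{name} must be non-zero")
            object.__setattr__(self, name, v / n)
        if not (self.constraint_tol > 0 and self.continuity_tol > 0):
            raise GeometryError("tolerances must be positive")


# ---------------------------------------------------------------------------
# measurement & validation


def link_length(geometry: LinkageGeometry, link: str, side: str | None = "right") -> float:
    """Euclidean distance between the current endpoint joints of `link`."""
    if link in MIDLINE_LINKS:
        side = None
    a, b = sided_endpoints(link, side)
    return float(np.linalg.norm(geometry.position(a) - geometry.position(b)))


@dataclass(frozen=True)
class SymmetryReport:
    pair_deviations: Mapping[str, tuple[float, float, float]]  # pair -> |dx|,|dy|,| |zL|-|zR| or z-sum |
    midline_deviations: Mapping[str, float]  # joint -> |z|
    tol: float

    @property
    def passed(self) -> bool:
        return self.max_deviation <= self.tol

    @property
    def max_deviation(self) -> float:
        devs = [d for trip in self.pair_deviations.values() for d in trip]
        devs += list(self.midline_deviations.values())
        return max(devs) if devs else 0.0

    @property
    def failures(self) -> list[str]:
        out = [p for p, trip in self.pair_deviations.items() if max(trip) > self.tol]
        out += [j for j, d in self.midline_deviations.items() if d > self.tol]
        return out


def validate_symmetry(geometry: LinkageGeometry, tol: float = 1e-9) -> SymmetryReport:
    """Report bilateral-symmetry deviations.

    Left/right partners must share x and y and carry opposite-sign z;
    midline joints must lie on the midsagittal plane z = 0.
    """
    pairs: dict[str, tuple[float, float, float]] = {}
    for left, right in SYMMETRY_PAIRS:
        pl, pr = geometry.position(left), geometry.position(right)
        pairs[left[:-2]] = (abs(pl[0] - pr[0]), abs(pl[1] - pr[1]), abs(pl[2] + pr[2]))
    midline = {j: abs(geometry.position(j)[2]) for j in MIDLINE_JOINTS}
    return SymmetryReport(pairs, midline, tol)


# ---------------------------------------------------------------------------
# file I/O

_CSV_COLUMNS = ["joint", "side", "x_mm", "y_mm", "z_mm"]


def read_geometry(path: str | Path, format: str | None = None) -> LinkageGeometry:
    """Read a geometry from CSV (joint,side,x_mm,y_mm,z_mm) or JSON."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        try:
            df = pd.read_csv(path, dtype={"joint": str, "side": str}, float_precision="round_trip")
        except ValueError as exc:
            raise GeometryError(f"cannot parse geometry CSV {path}: {exc}") from exc
        if list(df.columns) != _CSV_COLUMNS:
            raise GeometryError(f"geometry CSV must have columns {_CSV_COLUMNS}, got {list(df.columns)}")
        positions = {}
        for row_no, row in enumerate(df.itertuples(index=False), start=2):
            coords = (row.x_mm, row.y_mm, row.z_mm)
            try:
                vec = [float(c) for c in coords]
            except (TypeError, ValueError) as exc:
                raise GeometryError(f"non-numeric coordinate in row {row_no} of {path}") from exc
            if any(not math.isfinite(c) for c in vec):
                raise GeometryError(f"non-finite coordinate in row {row_no} of {path}")
            positions[str(row.joint)] = vec
    elif fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        joints = payload["joints"] if isinstance(payload, dict) and "joints" in payload else payload
        positions = {}
        for rec in joints:
            try:
                positions[str(rec["joint"])] = [float(rec[k]) for k in ("x_mm", "y_mm", "z_mm")]
            except (KeyError, TypeError, ValueError) as exc:
                raise GeometryError(f"malformed joint record {rec!r} in {path}") from exc
    else:
        raise GeometryError(f"unknown geometry format {fmt!r}")
    return LinkageGeometry(positions)


def write_geometry(geometry: LinkageGeometry, path: str | Path, format: str | None = None) -> None:
    """Write a geometry to CSV or JSON at full double precision (round-trip safe)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    rows = [
        {
            "joint": j,
            "side": joint_side(j),
            "x_mm": float(geometry.position(j)[0]),
            "y_mm": float(geometry.position(j)[1]),
            "z_mm": float(geometry.position(j)[2]),
        }
        for j in JOINT_IDS
    ]
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(",".join(_CSV_COLUMNS) + "\n")
            for r in rows:
                fh.write(f"{r['joint']},{r['side']},{r['x_mm']!r},{r['y_mm']!r},{r['z_mm']!r}\n")
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump({"joints": rows}, fh, indent=2)
            fh.write("\n")
    else:
        raise GeometryError(f"unknown geometry format {fmt!r}")
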