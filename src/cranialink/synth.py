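"""Packaged default geometry and randomized synthetic geometries.

The packaged default is a synthetic reconstruction of a salmon-like skull
layout (it reproduces the qualitative arrangement of the simplified
cranial linkage, not measured specimen landmarks).  The generator jitters
that template to produce bilaterally symmetric geometries and rejection-
samples until the result simulates cleanly over both full input ranges
(0.2 rad dorsal neurocranium rotation; 3 mm posterior hypohyal
retraction), so every emitted geometry is usable by every later stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .geometry import (
    MIDLINE_JOINTS,
    SYMMETRY_PAIRS,
    LinkageGeometry,
    MechanismConfig,
    read_geometry,
    validate_symmetry,
)
from .solver import InputSpec, LinkageInfeasible, check_link_constancy, simulate

__all__ = ["SynthesisParams", "default_geometry", "generate_geometry"]

_DATA_PACKAGE = "cranialink._data"
_DEFAULT_FILE = "salmon_default_synthetic.csv"


@dataclass(frozen=True)
class SynthesisParams:
    """Controls for the random geometry generator.

    scale rescales the whole head (template head length is ~60 mm, a large
    adult-salmon head being of that order); jitter is the fractional
    coordinate noise applied to the template; n_attempts bounds the
    rejection-sampling loop.
    """

    seed: int
    scale: float = 60.0
    jitter: float = 0.1
    n_attempts: int = 200

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        if not 0 <= self.jitter < 0.5:
            raise ValueError("jitter must be in [0, 0.5)")
        if self.n_attempts < 1:
            raise ValueError("n_attempts must be >= 1")


def default_geometry() -> LinkageGeometry:
    """The packaged default geometry (synthetic salmon-like reconstruction).

    Validated on load: bilaterally symmetric and solvable over both full
    input ranges.
    """
    ref = resources.files(_DATA_PACKAGE).joinpath(_DEFAULT_FILE)
    if not ref.is_file():
        raise FileNotFoundError(
            f"packaged default geometry {_DEFAULT_FILE} is missing; supply a geometry "
            "transcribed from the cranial-linkage input data (landmark coordinates) instead"
        )
    with resources.as_file(ref) as path:
        return read_geometry(path, "csv")


# Template proportions (head length ~60 mm), chosen to match the
# qualitative layout of the linkage: NV posterior-dorsal at the origin,
# NS anterior-dorsal-lateral, HS ventral and posterior to NS, JQ anterior
# to HS, CH/HYM in the anteroventral midline region, SYM anterior-ventral.
# x anterior, y dorsal, z right; midline joints at z = 0.
_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "NV": (0.0, 0.0, 0.0),
    "NS_R": (36.0, -8.0, 6.0),
    "NS_L": (36.0, -8.0, -6.0),
    "HS_R": (20.0, -29.0, 12.0),
    "HS_L": (20.0, -29.0, -12.0),
    "JQ_R": (40.0, -18.0, 8.0),
    "JQ_L": (40.0, -18.0, -8.0),
    "CH_R": (42.0, -31.0, 4.0),
    "CH_L": (42.0, -31.0, -4.0),
    "HYM": (46.0, -34.0, 0.0),
    "SYM": (53.0, -36.0, 0.0),
}

_TEMPLATE_HEAD_LENGTH = 60.0


def _simulates_cleanly(geometry: LinkageGeometry, config: MechanismConfig) -> bool:
    for input_spec in (InputSpec.epaxial(), InputSpec.hypaxial()):
        try:
            traj = simulate(geometry, config, input_spec)
        except (LinkageInfeasible, ValueError):
            return False
        if not check_link_constancy(traj).passed:
            return False
    return True


def generate_geometry(params: SynthesisParams, config: MechanismConfig | None = None) -> LinkageGeometry:
    """Draw a random, bilaterally symmetric, fully solvable geometry.

    Right-side and midline template coordinates are jittered (midline z
    pinned to 0, left partners mirrored), scaled to `params.scale`, and the
    candidate is rejected unless both full-range inputs simulate with link
    constancy.  Deterministic in `params.seed`.
    """
    config = config or MechanismConfig()
    rng = np.random.default_rng(params.seed)
    factor = params.scale / _TEMPLATE_HEAD_LENGTH
    base = {j: np.asarray(p, float) * factor for j, p in _TEMPLATE.items()}
    amplitude = params.jitter * params.scale / 3.0  # per-axis noise scale

    last_reason = "no attempts made"
    for _ in range(params.n_attempts):
        positions: dict[str, np.ndarray] = {}
        for j in MIDLINE_JOINTS:
            noise = rng.normal(0.0, amplitude, size=3)
            noise[2] = 0.0
            positions[j] = base[j] + noise
        for left, right in SYMMETRY_PAIRS:
            noise = rng.normal(0.0, amplitude, size=3)
            pr = base[right] + noise
            positions[right] = pr
            positions[left] = pr * np.array([1.0, 1.0, -1.0])
        try:
            candidate = LinkageGeometry(positions)
        except ValueError as exc:
            last_reason = f"invalid geometry: {exc}"
            continue
        if not validate_symmetry(candidate, 1e-9).passed:
            last_reason = "symmetry violated"
            continue
        if _simulates_cleanly(candidate, config):
            return candidate
        last_reason = "full-range simulation failed"
    raise RuntimeError(
        f"could not generate a solvable geometry in {params.n_attempts} attempts "
        f"(last failure: {last_reason})"
    )
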