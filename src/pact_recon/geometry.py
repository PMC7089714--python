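"""Transducer array, scan trajectory, and reconstruction-grid geometry.

Coordinate frame (right-handed, all distances in mm):

* axis 0 — **depth** ``z``: the imaging direction. The array sits at
  ``z = 0`` looking into ``+z``.
* axis 1 — **lateral** ``x``: along the array's element row, centered on 0.
* axis 2 — **elevation** ``y``: the mechanical scanning direction,
  perpendicular to the element row.

Times are in µs and the speed of sound in mm/µs throughout the package, so
a volume of ``200 × 430 × 200`` voxels reads depth × probe-width ×
scan-distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ArrayGeometry",
    "ScanTrajectory",
    "ReconGrid",
    "FocalLine",
    "ReconConfig",
    "ConfigError",
    "build_grid",
    "element_position",
    "load_config",
]


class ConfigError(ValueError):
    """A geometry/reconstruction config file violates the documented schema."""


def _round_half_away(x: float) -> int:
    """Round half away from zero (86 mm × RF 5 → exactly 430 voxels)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class ArrayGeometry:
    """A 1D linear transducer array, optionally focused in elevation.

    Parameters
    ----------
    n_elements : int
        Number of elements in the row (default 128).
    pitch : float
        Center-to-center element spacing in mm. The default 86/128 mm makes
        the 128-element row span an 8.6 cm lateral aperture.
    center_frequency : float
        Element center frequency in MHz (default 2.25).
    focal_length : float
        Elevation focal distance of the acoustic lens in mm; 0 means an
        unfocused (point-detector) element.
    """

    n_elements: int = 128
    pitch: float = 86.0 / 128.0
    center_frequency: float = 2.25
    focal_length: float = 0.0

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise ValueError(f"n_elements must be >= 1, got {self.n_elements}")
        if self.pitch <= 0:
            raise ValueError(f"pitch must be > 0, got {self.pitch}")
        if self.focal_length < 0:
            raise ValueError(f"focal_length must be >= 0, got {self.focal_length}")

    @property
    def element_lateral_positions(self) -> np.ndarray:
        """Lateral (x) coordinates of the element centers, symmetric about 0."""
        i = np.arange(self.n_elements, dtype=float)
        return (i - (self.n_elements - 1) / 2.0) * self.pitch

    @property
    def aperture_width(self) -> float:
        """Distance between the first and last element centers, mm."""
        return (self.n_elements - 1) * self.pitch


@dataclass(frozen=True)
class ScanTrajectory:
    """Uniform mechanical scan along the elevation axis.

    Defaults emulate a 40 mm elevation scan at 0.1 mm steps: 400 scan
    lines spanning 39.9 mm between the first and last line centers.
    """

    step_size: float = 0.1
    n_positions: int = 400
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise ValueError(f"n_positions must be >= 1, got {self.n_positions}")
        if self.step_size <= 0:
            raise ValueError(f"step_size must be > 0, got {self.step_size}")

    @property
    def elevations(self) -> np.ndarray:
        """Elevation (y) coordinate of every scan line, mm."""
        return self.start_offset + self.step_size * np.arange(self.n_positions)

    @property
    def span(self) -> float:
        """Distance between first and last scan line, mm."""
        return self.step_size * (self.n_positions - 1)


@dataclass(frozen=True)
class ReconGrid:
    """Voxel lattice for the reconstructed volume.

    ``rf`` is the resolution factor: voxels per mm, i.e. the reciprocal of
    the voxel size. ``origin`` is the physical coordinate of the *center*
    of voxel ``(0, 0, 0)``; voxel ``(i, j, k)`` is centered at
    ``origin + (i, j, k) / rf``.
    """

    extents: tuple[float, float, float]  # (depth, lateral, elevation) mm
    rf: float
    origin: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.rf <= 0:
            raise ValueError(f"rf must be > 0, got {self.rf}")
        if any(e <= 0 for e in self.extents):
            raise ValueError(f"extents must be > 0, got {self.extents}")
        if any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be >= 1, got {self.dims}")

    @property
    def voxel_size(self) -> float:
        """Edge length of a voxel in mm (1/rf)."""
        return 1.0 / self.rf

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.dims[axis]) / self.rf

    def index_to_coord(self, index) -> np.ndarray:
        """Physical coordinate (mm) of voxel center(s); index shape (..., 3)."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) / self.rf

    def coord_to_index(self, coord) -> np.ndarray:
        """Nearest voxel index for physical coordinate(s) of shape (..., 3)."""
        idx = np.rint((np.asarray(coord, dtype=float) - np.asarray(self.origin)) * self.rf)
        return idx.astype(int)

    def voxel_coords(self) -> np.ndarray:
        """All voxel-center coordinates, shape (n_voxels, 3), C order."""
        z, x, y = (self.axis_coords(a) for a in range(3))
        zz, xx, yy = np.meshgrid(z, x, y, indexing="ij")
        return np.stack([zz.ravel(), xx.ravel(), yy.ravel()], axis=-1)


def build_grid(
    extent_depth: float,
    extent_lateral: float,
    extent_elevation: float,
    rf: float,
    origin: tuple[float, float, float] | None = None,
) -> ReconGrid:
    """Construct a :class:`ReconGrid` from physical extents and RF.

    ``dims[k] = round(extent[k] * rf)`` (half away from zero), so the
    8.6 cm × 4 cm imaging area at RF 5 with a 40 mm depth extent yields the
    200 × 430 × 200 voxel volume. Voxel centers are registered at
    ``corner + (index + 0.5) / rf``; the default corner puts depth and
    elevation at 0 and centers the lateral axis on the array (x = 0).

    Parameters
    ----------
    origin : optional
        Physical coordinate of the corner of the grid (not of the first
        voxel center). Defaults to ``(0, -extent_lateral/2, 0)``.
    """
    for name, v in [
        ("extent_depth", extent_depth),
        ("extent_lateral", extent_lateral),
        ("extent_elevation", extent_elevation),
        ("rf", rf),
    ]:
        if not (v > 0):
            raise ValueError(f"{name} must be > 0, got {v}")
    extents = (float(extent_depth), float(extent_lateral), float(extent_elevation))
    dims = tuple(_round_half_away(e * rf) for e in extents)
    if origin is None:
        corner = (0.0, -extent_lateral / 2.0, 0.0)
    else:
        corner = tuple(float(c) for c in origin)
    half = 0.5 / rf
    first_center = tuple(c + half for c in corner)
    return ReconGrid(extents=extents, rf=float(rf), origin=first_center, dims=dims)


def element_position(
    geometry: ArrayGeometry,
    trajectory: ScanTrajectory,
    element_index: int,
    scan_index: int,
) -> np.ndarray:
    """Physical position (mm) of one element at one scan position.

    Returns ``(depth=0, lateral, elevation)``; raises ``IndexError`` for
    out-of-range indices.
    """
    if not 0 <= element_index < geometry.n_elements:
        raise IndexError(
            f"element_index {element_index} out of range [0, {geometry.n_elements})"
        )
    if not 0 <= scan_index < trajectory.n_positions:
        raise IndexError(
            f"scan_index {scan_index} out of range [0, {trajectory.n_positions})"
        )
    lateral = geometry.element_lateral_positions[element_index]
    elevation = trajectory.start_offset + scan_index * trajectory.step_size
    return np.array([0.0, lateral, elevation])


@dataclass(frozen=True)
class FocalLine:
    """The line through the elevation foci of all elements of the array.

    For each scan position it runs parallel to the lateral axis at
    ``depth = focal_length`` and at that position's elevation coordinate.
    """

    depth: float
    elevations: np.ndarray = field(repr=False)

    @classmethod
    def from_geometry(cls, geometry: ArrayGeometry, trajectory: ScanTrajectory) -> "FocalLine":
        return cls(depth=geometry.focal_length, elevations=trajectory.elevations)


# ---------------------------------------------------------------------------
# Config file


_CONFIG_KEYS = {
    "n_elements",
    "pitch_mm",
    "center_frequency_mhz",
    "focal_length_mm",
    "scan_step_mm",
    "n_scan_positions",
    "speed_of_sound_mm_per_us",
    "rf",
    "extent_depth_mm",
    "extent_lateral_mm",
    "extent_elevation_mm",
    # reconstruction-mode selectors
    "delay_model",
    "weighting",
    "scan_start_mm",
}

_DELAY_MODELS = {"point", "focal_line"}
_WEIGHTINGS = {"uniform", "solid_angle"}


@dataclass(frozen=True)
class ReconConfig:
    """Everything a reconstruction needs, as declared in a config file."""

    geometry: ArrayGeometry
    trajectory: ScanTrajectory
    grid: ReconGrid
    speed_of_sound: float = 1.54
    delay_model: str = "focal_line"
    weighting: str = "uniform"


def load_config(path: str | Path) -> ReconConfig:
    """Read a YAML key–value config file into a :class:`ReconConfig`.

    Unknown keys produce a warning, not an error, so configs written for
    newer versions degrade gracefully.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping of keys to values")
    unknown = sorted(set(raw) - _CONFIG_KEYS)
    if unknown:
        warnings.warn(f"{path}: ignoring unknown config keys {unknown}", stacklevel=2)
    known = {k: v for k, v in raw.items() if k in _CONFIG_KEYS}

    try:
        geometry = ArrayGeometry(
            n_elements=int(known.get("n_elements", 128)),
            pitch=float(known.get("pitch_mm", 86.0 / 128.0)),
            center_frequency=float(known.get("center_frequency_mhz", 2.25)),
            focal_length=float(known.get("focal_length_mm", 0.0)),
        )
        trajectory = ScanTrajectory(
            step_size=float(known.get("scan_step_mm", 0.1)),
            n_positions=int(known.get("n_scan_positions", 400)),
            start_offset=float(known.get("scan_start_mm", 0.0)),
        )
        grid = build_grid(
            extent_depth=float(known.get("extent_depth_mm", 40.0)),
            extent_lateral=float(known.get("extent_lateral_mm", 86.0)),
            extent_elevation=float(known.get("extent_elevation_mm", 40.0)),
            rf=float(known.get("rf", 5.0)),
        )
        v_s = float(known.get("speed_of_sound_mm_per_us", 1.54))
        if v_s <= 0:
            raise ValueError(f"speed_of_sound_mm_per_us must be > 0, got {v_s}")
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc

    delay_model = str(known.get("delay_model", "focal_line"))
    if delay_model not in _DELAY_MODELS:
        raise ConfigError(
            f"{path}: delay_model must be one of {sorted(_DELAY_MODELS)}, got {delay_model!r}"
        )
    weighting = str(known.get("weighting", "uniform"))
    if weighting not in _WEIGHTINGS:
        raise ConfigError(
            f"{path}: weighting must be one of {sorted(_WEIGHTINGS)}, got {weighting!r}"
        )
    return ReconConfig(
        geometry=geometry,
        trajectory=trajectory,
        grid=grid,
        speed_of_sound=v_s,
        delay_model=delay_model,
        weighting=weighting,
    )
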