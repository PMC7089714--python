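"""Time-of-arrival models: point detector and focal-line virtual detector.

An elevation-focused linear array does not behave like a row of point
receivers: the acoustic lens focuses each element onto a point at
``depth = focal_length``, and the line through all those foci is the focal
line. A wave originating anywhere in the volume is detected predominantly
via the path that crosses the focal line, so the effective travel path is

    path = focal_length ± |voxel - focus|,

with ``+`` for voxels deeper than the focal plane and ``-`` for shallower
ones — the element's focus acts as a *virtual point detector*. At
``focal_length = 0`` this reduces to the ordinary point-detector delay
``|voxel - element| / v_s``.

All positions are (depth, lateral, elevation) triples in mm, delays in µs,
sound speed in mm/µs (soft tissue: 1.54).
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .geometry import ArrayGeometry, ReconGrid, ScanTrajectory

__all__ = [
    "DEFAULT_SOUND_SPEED",
    "MemoryBudgetError",
    "point_delay",
    "focal_line_delay",
    "element_scan_positions",
    "iter_delay_tiles",
    "delay_table",
]

DEFAULT_SOUND_SPEED = 1.54
"""Speed of sound in soft tissue, mm/µs."""

DELAY_MODELS = ("point", "focal_line")


class MemoryBudgetError(RuntimeError):
    """A delay-table request cannot fit inside the configured memory budget."""


def _check_sound_speed(v_s: float) -> None:
    if not (v_s > 0):
        raise ValueError(f"speed of sound must be > 0, got {v_s}")


def point_delay(voxel, element, v_s: float = DEFAULT_SOUND_SPEED):
    """Point-detector time of arrival: Euclidean distance over sound speed.

    Broadcasts over leading dimensions of ``voxel`` and ``element``
    (trailing axis is the coordinate triple). Symmetric in its two
    position arguments; coincident points give 0.
    """
    _check_sound_speed(v_s)
    voxel = np.asarray(voxel, dtype=float)
    element = np.asarray(element, dtype=float)
    return np.linalg.norm(voxel - element, axis=-1) / v_s


def focal_line_delay(voxel, element, focal_length: float, v_s: float = DEFAULT_SOUND_SPEED):
    """Virtual-point-detector time of arrival for an elevation-focused element.

    The element's focus — the point on the focal line at
    ``(depth = element_depth + focal_length, element_lateral,
    element_elevation)`` — is treated as the receiver. The returned delay is
    ``(focal_length + s * |voxel - focus|) / v_s`` with ``s = +1`` for voxels
    deeper than the focal plane and ``-1`` for shallower ones (``+`` on the
    plane itself). ``focal_length = 0`` reduces exactly to
    :func:`point_delay`.
    """
    if focal_length < 0:
        raise ValueError(f"focal_length must be >= 0, got {focal_length}")
    if focal_length == 0:
        return point_delay(voxel, element, v_s)
    _check_sound_speed(v_s)
    voxel = np.asarray(voxel, dtype=float)
    element = np.asarray(element, dtype=float)
    focus = element + np.array([focal_length, 0.0, 0.0])
    d_vf = np.linalg.norm(voxel - focus, axis=-1)
    s = np.where(voxel[..., 0] >= focus[..., 0], 1.0, -1.0)
    return (focal_length + s * d_vf) / v_s


def element_scan_positions(geometry: ArrayGeometry, trajectory: ScanTrajectory) -> np.ndarray:
    """Physical positions of every (element, scan position) pair.

    Returns an array of shape ``(n_elements, n_positions, 3)``; the array
    face sits at depth 0.
    """
    lat = geometry.element_lateral_positions
    elev = trajectory.elevations
    pos = np.zeros((geometry.n_elements, trajectory.n_positions, 3))
    pos[:, :, 1] = lat[:, None]
    pos[:, :, 2] = elev[None, :]
    return pos


def _tile_delays(vox, positions, model: str, focal_length: float, v_s: float) -> np.ndarray:
    """Delays for a block of voxels against all (element, position) pairs."""
    v = vox[:, None, None, :]  # (T, 1, 1, 3)
    p = positions[None, :, :, :]  # (1, E, S, 3)
    if model == "point":
        return point_delay(v, p, v_s)
    if model == "focal_line":
        return focal_line_delay(v, p, focal_length, v_s)
    raise ValueError(f"delay model must be one of {DELAY_MODELS}, got {model!r}")


def iter_delay_tiles(
    grid: ReconGrid,
    geometry: ArrayGeometry,
    trajectory: ScanTrajectory,
    model: str = "focal_line",
    v_s: float = DEFAULT_SOUND_SPEED,
    memory_budget_bytes: int = 2**30,
) -> Iterator[tuple[slice, np.ndarray]]:
    """Lazily yield ``(voxel_slice, delays)`` tiles of the full delay table.

    Each tile has shape ``(tile_voxels, n_elements, n_positions)`` in float64
    and is sized so that a tile plus its broadcast scratch stays within
    ``memory_budget_bytes``. Voxels are ordered as in
    :meth:`ReconGrid.voxel_coords` (C order over depth, lateral, elevation).

    Raises
    ------
    MemoryBudgetError
        If even a single voxel's row of delays exceeds the budget.
    """
    pairs = geometry.n_elements * trajectory.n_positions
    # one delay tile + ~4x scratch for the broadcast difference/norm
    bytes_per_voxel = pairs * 8 * 5
    tile_voxels = int(memory_budget_bytes // bytes_per_voxel)
    if tile_voxels < 1:
        raise MemoryBudgetError(
            f"one voxel row of the delay table needs ~{bytes_per_voxel} bytes "
            f"({geometry.n_elements} elements x {trajectory.n_positions} positions), "
            f"exceeding the {memory_budget_bytes}-byte budget; raise "
            "memory_budget_bytes or reduce elements/positions"
        )
    positions = element_scan_positions(geometry, trajectory)
    coords = grid.voxel_coords()
    n = coords.shape[0]
    for start in range(0, n, tile_voxels):
        stop = min(start + tile_voxels, n)
        yield slice(start, stop), _tile_delays(
            coords[start:stop], positions, model, geometry.focal_length, v_s
        )


def delay_table(
    grid: ReconGrid,
    geometry: ArrayGeometry,
    trajectory: ScanTrajectory,
    model: str = "focal_line",
    v_s: float = DEFAULT_SOUND_SPEED,
    memory_budget_bytes: int = 2**30,
) -> np.ndarray:
    """Materialize the full delay table, shape (n_voxels, n_elements, n_positions).

    Intended for small grids (tests, diagnostics); reconstruction streams
    tiles instead. Raises :class:`MemoryBudgetError` if the assembled table
    would exceed the budget.
    """
    total = grid.n_voxels * geometry.n_elements * trajectory.n_positions * 8
    if total > memory_budget_bytes:
        raise MemoryBudgetError(
            f"full delay table needs {total} bytes, exceeding the "
            f"{memory_budget_bytes}-byte budget; use iter_delay_tiles instead"
        )
    out = np.empty((grid.n_voxels, geometry.n_elements, trajectory.n_positions))
    for sl, tile in iter_delay_tiles(
        grid, geometry, trajectory, model, v_s, memory_budget_bytes
    ):
        out[sl] = tile
    return out
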