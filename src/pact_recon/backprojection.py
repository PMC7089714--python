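"""Back-projection reconstruction core.

For every voxel ``r`` the reconstructed initial pressure is the weighted sum
of the conditioned integrand of every trace evaluated at that voxel's time
of arrival:

    p0(r) = sum_{e,s} w(r, e, s) * b_{e,s}( tau(r, e, s) ),

over all 128-element x 400-scan-line (element, position) pairs at full
geometry. ``b`` is the ``2p - 2t dp/dt`` term, ``tau`` the selected delay
model (point or focal-line virtual detector), and ``w`` the discretized
solid-angle weighting.

Two implementations share one contract: :func:`reconstruct` is the
vectorized production core (tiled over depth slabs inside a memory budget),
and :func:`reconstruct_reference` is a deliberately plain triple loop over
voxels, elements, and positions that serves as the readable correctness
oracle. The two agree to ~1e-9 relative on any input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import nibabel as nib
import numpy as np
import tifffile

from . import delay as _delay
from .conditioning import SensorData, sample_at, ubp_term
from .geometry import ArrayGeometry, ReconGrid, ScanTrajectory

__all__ = [
    "Volume",
    "reconstruct",
    "reconstruct_reference",
    "save_volume_nifti",
    "load_volume_nifti",
    "save_volume_tiff",
]

WEIGHTING_MODES = ("uniform", "solid_angle")
INTEGRANDS = ("ubp", "das")


@dataclass(frozen=True)
class Volume:
    """Reconstructed initial pressure on a grid, indexed (depth, lateral, elevation)."""

    values: np.ndarray
    grid: ReconGrid

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if tuple(values.shape) != tuple(self.grid.dims):
            raise ValueError(
                f"values shape {values.shape} does not match grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        object.__setattr__(self, "values", values)


def _validate_inputs(
    data: SensorData,
    geometry: ArrayGeometry,
    trajectory: ScanTrajectory,
    model: str,
    weighting: str,
    integrand: str,
) -> None:
    if data.n_elements != geometry.n_elements:
        raise ValueError(
            f"sinogram has {data.n_elements} elements but geometry declares "
            f"{geometry.n_elements}"
        )
    if data.n_positions != trajectory.n_positions:
        raise ValueError(
            f"sinogram has {data.n_positions} scan positions but trajectory "
            f"declares {trajectory.n_positions}"
        )
    if model not in _delay.DELAY_MODELS:
        raise ValueError(f"model must be one of {_delay.DELAY_MODELS}, got {model!r}")
    if weighting not in WEIGHTING_MODES:
        raise ValueError(f"weighting must be one of {WEIGHTING_MODES}, got {weighting!r}")
    if integrand not in INTEGRANDS:
        raise ValueError(f"integrand must be one of {INTEGRANDS}, got {integrand!r}")
    finite = np.isfinite(data.samples)
    if not finite.all():
        k, e, s = np.argwhere(~finite)[0]
        raise ValueError(
            f"non-finite input sample at (time={k}, element={e}, position={s})"
        )


def _solid_angle_weight(vox: np.ndarray, elem: np.ndarray) -> np.ndarray:
    """Discretized solid-angle weight cos(theta) / d^2 for one element.

    theta is the angle between the voxel->element ray and the element normal
    (+depth); contributions from behind the array face get weight 0, as does
    a voxel coincident with the element.
    """
    diff = vox - elem
    d2 = np.sum(diff * diff, axis=-1)
    d = np.sqrt(d2)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = np.where(d > 0, diff[..., 0] / d, 0.0)
        w = np.where(d > 0, np.maximum(cos, 0.0) / d2, 0.0)
    return w


def reconstruct(
    data: SensorData,
    geometry: ArrayGeometry,
    trajectory: ScanTrajectory,
    grid: ReconGrid,
    model: str = "focal_line",
    weighting: str = "uniform",
    v_s: float = _delay.DEFAULT_SOUND_SPEED,
    integrand: str = "ubp",
    memory_budget_bytes: int = 2**30,
    progress: Callable[[int, int], None] | None = None,
) -> Volume:
    """Vectorized back-projection of a sinogram onto a voxel grid.

    Parameters
    ----------
    model : {"point", "focal_line"}
        Delay model; "focal_line" uses the element focus as a virtual point
        detector (requires ``geometry.focal_length`` > 0 to differ from
        "point").
    weighting : {"uniform", "solid_angle"}
        "uniform" averages all contributing traces (the solid-angle
        normalization absorbed into a count); "solid_angle" weights each
        term by cos(theta)/d^2 and renormalizes per voxel.
    integrand : {"ubp", "das"}
        "ubp" applies the 2p - 2t dp/dt term (default); "das" back-projects
        the raw pressure (plain delay-and-sum).
    memory_budget_bytes : int
        Upper bound for per-slab scratch arrays; the volume is processed in
        depth-slabs sized to fit. Tiling never changes the result.
    progress : callable, optional
        Called as ``progress(scan_index, n_positions)`` once per scan line;
        purely observational.

    The operation is linear in the sinogram and fully deterministic.
    """
    _validate_inputs(data, geometry, trajectory, model, weighting, integrand)
    b = ubp_term(data) if integrand == "ubp" else data
    traces = np.ascontiguousarray(b.samples, dtype=float)
    times = b.times
    coords = grid.voxel_coords()  # (N, 3)
    n_vox = coords.shape[0]

    # depth-slab tiling: per-pair scratch is ~5 float64 arrays per voxel
    bytes_per_voxel = 8 * 5
    tile = max(1, int(memory_budget_bytes // bytes_per_voxel))
    slabs = [slice(i, min(i + tile, n_vox)) for i in range(0, n_vox, tile)]

    lat = geometry.element_lateral_positions
    elevs = trajectory.elevations
    acc = np.zeros(n_vox)
    wsum = np.zeros(n_vox)
    uniform = weighting == "uniform"

    for s in range(trajectory.n_positions):
        if progress is not None:
            progress(s, trajectory.n_positions)
        for e in range(geometry.n_elements):
            elem = np.array([0.0, lat[e], elevs[s]])
            trace = traces[:, e, s]
            for sl in slabs:
                vox = coords[sl]
                if model == "focal_line" and geometry.focal_length > 0:
                    tau = _delay.focal_line_delay(vox, elem, geometry.focal_length, v_s)
                else:
                    tau = _delay.point_delay(vox, elem, v_s)
                val = np.interp(tau, times, trace, left=0.0, right=0.0)
                if uniform:
                    acc[sl] += val
                else:
                    w = _solid_angle_weight(vox, elem)
                    acc[sl] += w * val
                    wsum[sl] += w

    if uniform:
        values = acc / (geometry.n_elements * trajectory.n_positions)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(wsum > 0, acc / wsum, 0.0)
    return Volume(values=values.reshape(grid.dims), grid=grid)


def reconstruct_reference(
    data: SensorData,
    geometry: ArrayGeometry,
    trajectory: ScanTrajectory,
    grid: ReconGrid,
    model: str = "focal_line",
    weighting: str = "uniform",
    v_s: float = _delay.DEFAULT_SOUND_SPEED,
    integrand: str = "ubp",
) -> Volume:
    """Naive triple-loop back-projection: the readability-first oracle.

    Identical contract to :func:`reconstruct`, written as the plainest
    possible loops over scan positions, elements, and voxels with scalar
    delay and interpolation calls. Use only on small grids.
    """
    _validate_inputs(data, geometry, trajectory, model, weighting, integrand)
    b = ubp_term(data) if integrand == "ubp" else data
    lat = geometry.element_lateral_positions
    elevs = trajectory.elevations
    nz, nx, ny = grid.dims
    acc = np.zeros(grid.dims)
    wsum = np.zeros(grid.dims)
    uniform = weighting == "uniform"

    for s in range(trajectory.n_positions):
        for e in range(geometry.n_elements):
            elem = np.array([0.0, lat[e], elevs[s]])
            trace = b.samples[:, e, s]
            for iz in range(nz):
                for ix in range(nx):
                    for iy in range(ny):
                        vox = grid.index_to_coord((iz, ix, iy))
                        if model == "focal_line" and geometry.focal_length > 0:
                            tau = _delay.focal_line_delay(
                                vox, elem, geometry.focal_length, v_s
                            )
                        else:
                            tau = _delay.point_delay(vox, elem, v_s)
                        val = sample_at(trace, tau, b.sampling_rate, b.t0)
                        if uniform:
                            acc[iz, ix, iy] += val
                        else:
                            w = _solid_angle_weight(vox, elem)
                            acc[iz, ix, iy] += w * val
                            wsum[iz, ix, iy] += w

    if uniform:
        values = acc / (geometry.n_elements * trajectory.n_positions)
    else:
        values = np.where(wsum > 0, acc / np.where(wsum > 0, wsum, 1.0), 0.0)
    return Volume(values=values, grid=grid)


# ---------------------------------------------------------------------------
# Volume I/O


def _affine(grid: ReconGrid) -> np.ndarray:
    vox = grid.voxel_size
    aff = np.diag([vox, vox, vox, 1.0])
    aff[:3, 3] = grid.origin
    return aff


def save_volume_nifti(volume: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; voxel size 1/rf mm, origin in the affine."""
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.grid))
    img.header.set_xyzt_units(xyz="mm")
    nib.save(img, str(path))


def load_volume_nifti(path: str | Path) -> Volume:
    """Read a volume written by :func:`save_volume_nifti`, rebuilding its grid
    from the affine (voxel size -> rf, translation -> origin)."""
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    aff = img.affine
    vox = float(aff[0, 0])
    if vox <= 0:
        raise ValueError(f"{path}: non-positive voxel size in affine")
    rf = 1.0 / vox
    dims = tuple(int(d) for d in values.shape)
    grid = ReconGrid(
        extents=tuple(d / rf for d in dims),
        rf=rf,
        origin=tuple(float(c) for c in aff[:3, 3]),
        dims=dims,
    )
    return Volume(values=values, grid=grid)


def save_volume_tiff(volume: Volume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF, elevation slices as pages.

    Each page is a (depth x lateral) float32 image; grid metadata rides in
    the ImageDescription tag as JSON.
    """
    pages = np.moveaxis(volume.values.astype(np.float32), 2, 0)  # (elev, depth, lat)
    meta = {
        "rf": volume.grid.rf,
        "origin_mm": list(volume.grid.origin),
        "extents_mm": list(volume.grid.extents),
        "axes_page": "elevation",
        "axes_image": "depth,lateral",
    }
    tifffile.imwrite(
        str(path), pages, photometric="minisblack", description=json.dumps(meta)
    )
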