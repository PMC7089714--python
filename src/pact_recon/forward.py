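"""Analytic forward simulation of photoacoustic signals from sphere phantoms.

A uniformly heated sphere of radius ``a`` at distance ``d`` from an ideal
broadband point receiver emits the classic N-shaped bipolar pulse

    p(t) = p0 * (d - v_s t) / (2 d)   for |d - v_s t| <= a,   else 0,

rising to ``+p0 a / (2d)`` at the leading edge, crossing zero at
``t = d / v_s``, and integrating to zero over its support. Ideal point
absorbers (``a = 0``) emit a band-limited derivative-of-Gaussian pulse
centered at ``t = d / v_s``.

Sinograms are synthesized with the *same* delay model the reconstruction
will use (point or focal-line), so forward-inverse consistency tests close
the loop on the geometry exactly. Vasculature-like targets are approximated
as chains of overlapping spheres along a polyline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import yaml

from . import delay as _delay
from .conditioning import SensorData
from .geometry import ArrayGeometry, ReconGrid, ScanTrajectory, build_grid

__all__ = [
    "Absorber",
    "Phantom",
    "VesselPhantom",
    "Fixture",
    "sphere_signal",
    "simulate",
    "fixture_suite",
    "load_phantom",
]

DEFAULT_PULSE_SIGMA = 0.25
"""Gaussian width (µs) of the point-absorber pulse.

Chosen so the pulse's positive correlation lobe (± v_s·sigma ≈ ±0.39 mm in
path length) spans a voxel on the coarsest reconstruction grid the fixtures
use (RF 2, 0.5 mm voxels): argmax localization is then grid-limited rather
than phase-limited. Configurable per call for finer grids.
"""


@dataclass(frozen=True)
class Absorber:
    """One spherical absorber: center (depth, lateral, elevation) mm,
    radius mm (0 = ideal point), amplitude in initial-pressure units."""

    center: tuple[float, float, float]
    radius: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"radius must be >= 0, got {self.radius}")
        if not np.isfinite(self.amplitude):
            raise ValueError(f"amplitude must be finite, got {self.amplitude}")


@dataclass(frozen=True)
class Phantom:
    """A collection of spherical absorbers plus an additive-noise model.

    ``noise_sd`` is the standard deviation of zero-mean white Gaussian
    noise added to every sample; ``seed`` makes it bit-reproducible. An
    empty absorber list yields pure noise (or zeros).
    """

    absorbers: tuple[Absorber, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "absorbers", tuple(self.absorbers))
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass(frozen=True)
class VesselPhantom:
    """A tube approximated by overlapping spheres along a polyline.

    ``sphere_spacing <= tube_radius`` guarantees the spheres overlap into a
    continuous tube.
    """

    control_points: tuple[tuple[float, float, float], ...]
    tube_radius: float
    sphere_spacing: float

    def __post_init__(self) -> None:
        if len(self.control_points) < 2:
            raise ValueError("a vessel needs at least 2 control points")
        if self.tube_radius <= 0:
            raise ValueError(f"tube_radius must be > 0, got {self.tube_radius}")
        if not 0 < self.sphere_spacing <= self.tube_radius:
            raise ValueError(
                f"sphere_spacing must be in (0, tube_radius={self.tube_radius}], "
                f"got {self.sphere_spacing}"
            )

    def to_absorbers(self, amplitude: float = 1.0) -> tuple[Absorber, ...]:
        """Sample the polyline at ``sphere_spacing`` into sphere absorbers."""
        pts = np.asarray(self.control_points, dtype=float)
        seg = np.diff(pts, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = arclen[-1]
        n = max(2, int(np.floor(total / self.sphere_spacing)) + 1)
        stations = np.linspace(0.0, total, n)
        centers = np.empty((n, 3))
        for k in range(3):
            centers[:, k] = np.interp(stations, arclen, pts[:, k])
        return tuple(
            Absorber(center=tuple(c), radius=self.tube_radius, amplitude=amplitude)
            for c in centers
        )


def sphere_signal(
    d: float,
    a: float,
    p0: float,
    v_s: float,
    t,
    pulse_sigma: float = DEFAULT_PULSE_SIGMA,
):
    """Pressure received at distance ``d`` from a sphere of radius ``a``.

    For ``a > 0``: the far-field N-shape ``p0 (d - v_s t) / (2 d)`` on
    ``|d - v_s t| <= a``, zero outside. For ``a = 0``: a
    derivative-of-Gaussian pulse of width ``pulse_sigma`` (µs) centered at
    ``t = d / v_s``, peak-normalized to ``p0``. Vectorized over ``t``.

    Raises an error when the receiver lies inside the absorber (d <= a).
    """
    if a < 0:
        raise ValueError(f"radius must be >= 0, got {a}")
    if d <= a:
        raise ValueError(
            f"receiver at distance {d} mm lies inside absorber of radius {a} mm"
        )
    if v_s <= 0:
        raise ValueError(f"speed of sound must be > 0, got {v_s}")
    t = np.asarray(t, dtype=float)
    if a > 0:
        x = d - v_s * t
        return np.where(np.abs(x) <= a, p0 * x / (2.0 * d), 0.0)
    if pulse_sigma <= 0:
        raise ValueError(f"pulse_sigma must be > 0, got {pulse_sigma}")
    u = (d / v_s - t) / pulse_sigma
    return p0 * (u * np.exp(0.5 - 0.5 * u * u))


def _support_halfwidth(absorber: Absorber, v_s: float, pulse_sigma: float) -> float:
    """Half-width (µs) of the pulse support around the arrival time."""
    if absorber.radius > 0:
        return absorber.radius / v_s
    return 4.0 * pulse_sigma


def simulate(
    phantom: Phantom,
    geometry: ArrayGeometry,
    trajectory: ScanTrajectory,
    sampling_rate: float = 9.0,
    t0: float = 0.0,
    duration: float = 40.0,
    model: str = "point",
    v_s: float = _delay.DEFAULT_SOUND_SPEED,
    pulse_sigma: float = DEFAULT_PULSE_SIGMA,
) -> SensorData:
    """Synthesize the sinogram a phantom produces on a scanned linear array.

    Every trace is the superposition over absorbers of :func:`sphere_signal`
    with the effective distance ``tau * v_s`` given by the chosen delay
    model, plus optional white Gaussian noise drawn from ``phantom.seed``.
    With the seed fixed the output is bit-reproducible.

    Warns (naming the absorber) when an absorber's pulse falls partly
    outside the recorded time window.
    """
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration}")
    if sampling_rate <= 0:
        raise ValueError(f"sampling_rate must be > 0, got {sampling_rate}")
    if model not in _delay.DELAY_MODELS:
        raise ValueError(f"model must be one of {_delay.DELAY_MODELS}, got {model!r}")
    n_time = int(round(duration * sampling_rate)) + 1
    times = t0 + np.arange(n_time) / sampling_rate
    t_last = times[-1]
    samples = np.zeros((n_time, geometry.n_elements, trajectory.n_positions))
    positions = _delay.element_scan_positions(geometry, trajectory)  # (E, S, 3)

    for i, ab in enumerate(phantom.absorbers):
        center = np.asarray(ab.center, dtype=float)
        if model == "focal_line" and geometry.focal_length > 0:
            tau = _delay.focal_line_delay(center, positions, geometry.focal_length, v_s)
        else:
            tau = _delay.point_delay(center, positions, v_s)
        geom_dist = _delay.point_delay(center, positions, v_s) * v_s
        if np.any(geom_dist <= ab.radius):
            raise ValueError(
                f"absorber {i} at {ab.center}: an element lies inside its "
                f"radius {ab.radius} mm"
            )
        d_eff = tau * v_s
        # The focal-line virtual-detector path F - |voxel - focus| goes
        # negative for shallow absorbers seen by far-off elements — outside
        # the model's validity region. Those pairs contribute nothing, just
        # as their negative delays sample nothing during reconstruction.
        valid = d_eff > ab.radius
        half = _support_halfwidth(ab, v_s, pulse_sigma)
        if valid.any():
            tmin, tmax = tau[valid].min(), tau[valid].max()
            if tmin - half < t0 or tmax + half > t_last:
                warnings.warn(
                    f"absorber {i} at {ab.center} has arrivals spanning "
                    f"[{tmin - half:.3f}, {tmax + half:.3f}] µs, partly "
                    f"outside the recorded window [{t0}, {t_last:.3f}] µs",
                    stacklevel=2,
                )
        else:
            warnings.warn(
                f"absorber {i} at {ab.center} is invisible to every element "
                f"under the {model} model",
                stacklevel=2,
            )
        safe_d = np.where(valid, d_eff, 1.0)
        for s in range(trajectory.n_positions):
            # evaluate all elements for this scan line at once
            x = safe_d[:, s][None, :]  # (1, E)
            ok = valid[:, s][None, :]
            tt = times[:, None]  # (T, 1)
            # amplitude multiplies the completed pulse so that scaling all
            # amplitudes by c scales every sample by exactly c
            if ab.radius > 0:
                dev = x - v_s * tt
                contrib = ab.amplitude * np.where(
                    np.abs(dev) <= ab.radius, dev / (2.0 * x), 0.0
                )
            else:
                u = (x / v_s - tt) / pulse_sigma
                contrib = ab.amplitude * (u * np.exp(0.5 - 0.5 * u * u))
            samples[:, :, s] += np.where(ok, contrib, 0.0)

    if phantom.noise_sd > 0:
        rng = np.random.default_rng(phantom.seed)
        samples += rng.normal(0.0, phantom.noise_sd, size=samples.shape)
    return SensorData(samples=samples, sampling_rate=sampling_rate, t0=t0)


# ---------------------------------------------------------------------------
# Deterministic fixtures


class Fixture(NamedTuple):
    """A ready-to-run synthetic experiment."""

    phantom: Phantom
    geometry: ArrayGeometry
    trajectory: ScanTrajectory
    grid: ReconGrid
    sampling_rate: float
    duration: float


def fixture_suite(name: str) -> Fixture:
    """Deterministic desk-scale fixtures used throughout the test suite.

    - ``point_grid``: 16-element unfocused array, 3x3 grid of point
      absorbers — fast localization checks.
    - ``three_tubes``: three parallel sphere-chain tubes at different
      depths — a vasculature-like target for rendering.
    - ``full_array_small``: the validation-experiment array (128
      elements, 2.25 MHz, 86/128 mm pitch, 0.1 mm scan steps) with the scan
      shortened to 50 lines and RF 2 for desk-scale runs.
    """
    if name == "point_grid":
        geometry = ArrayGeometry(n_elements=16, pitch=1.0, focal_length=0.0)
        trajectory = ScanTrajectory(step_size=0.5, n_positions=21)
        grid = build_grid(20.0, 16.0, 10.0, rf=2.0)
        centers = [
            (z, x, 5.0) for z in (8.0, 12.0, 16.0) for x in (-4.0, 0.0, 4.0)
        ]
        phantom = Phantom(absorbers=tuple(Absorber(center=c) for c in centers))
        return Fixture(phantom, geometry, trajectory, grid, sampling_rate=9.0, duration=25.0)
    if name == "three_tubes":
        geometry = ArrayGeometry(n_elements=32, pitch=86.0 / 128.0, focal_length=20.0)
        trajectory = ScanTrajectory(step_size=0.25, n_positions=40)
        grid = build_grid(30.0, 20.0, 10.0, rf=2.0)
        tubes = [
            VesselPhantom(((z, -8.0, 2.0), (z, 8.0, 8.0)), tube_radius=0.5, sphere_spacing=0.5)
            for z in (12.0, 18.0, 24.0)
        ]
        absorbers = tuple(a for tube in tubes for a in tube.to_absorbers())
        return Fixture(
            Phantom(absorbers=absorbers), geometry, trajectory, grid,
            sampling_rate=9.0, duration=35.0,
        )
    if name == "full_array_small":
        geometry = ArrayGeometry(
            n_elements=128, pitch=86.0 / 128.0, center_frequency=2.25, focal_length=20.0
        )
        trajectory = ScanTrajectory(step_size=0.1, n_positions=50)
        grid = build_grid(30.0, 40.0, 5.0, rf=2.0)
        phantom = Phantom(
            absorbers=(
                Absorber(center=(15.0, 0.0, 2.5)),
                Absorber(center=(22.0, -8.0, 1.5)),
                Absorber(center=(25.0, 10.0, 3.5)),
            )
        )
        return Fixture(phantom, geometry, trajectory, grid, sampling_rate=9.0, duration=40.0)
    raise ValueError(
        f"unknown fixture {name!r}; choose from point_grid, three_tubes, "
        "full_array_small"
    )


# ---------------------------------------------------------------------------
# Phantom file


_PHANTOM_KEYS = {"absorbers", "noise_sd", "seed"}
_ABSORBER_KEYS = {"center_mm", "radius_mm", "amplitude"}


def load_phantom(path: str | Path) -> Phantom:
    """Read a phantom description (YAML list of absorber records)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: phantom file must be a mapping")
    unknown = sorted(set(raw) - _PHANTOM_KEYS)
    if unknown:
        warnings.warn(f"{path}: ignoring unknown phantom keys {unknown}", stacklevel=2)
    records = raw.get("absorbers", [])
    if not isinstance(records, list):
        raise ValueError(f"{path}: 'absorbers' must be a list")
    absorbers = []
    for i, rec in enumerate(records):
        if not isinstance(rec, dict) or "center_mm" not in rec:
            raise ValueError(f"{path}: absorber {i} must be a mapping with center_mm")
        unknown = sorted(set(rec) - _ABSORBER_KEYS)
        if unknown:
            warnings.warn(
                f"{path}: absorber {i}: ignoring unknown keys {unknown}", stacklevel=2
            )
        center = tuple(float(c) for c in rec["center_mm"])
        if len(center) != 3:
            raise ValueError(f"{path}: absorber {i}: center_mm must have 3 entries")
        absorbers.append(
            Absorber(
                center=center,
                radius=float(rec.get("radius_mm", 0.0)),
                amplitude=float(rec.get("amplitude", 1.0)),
            )
        )
    return Phantom(
        absorbers=tuple(absorbers),
        noise_sd=float(raw.get("noise_sd", 0.0)),
        seed=int(raw.get("seed", 0)),
    )
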