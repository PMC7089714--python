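"""Signal conditioning: the back-projection integrand and trace sampling.

Universal back-projection does not sum the raw pressure traces but the term

    b(t) = 2 p(t) - 2 t dp/dt,

evaluated at each voxel's time of arrival. This module turns a raw sinogram
into that integrand (``ubp_term``), samples traces at fractional delays
(``sample_at``), and reads/writes sinograms on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np
from scipy import signal as _signal

__all__ = [
    "SensorData",
    "ubp_term",
    "sample_at",
    "bandpass_filter",
    "save_sensor_hdf5",
    "load_sensor_hdf5",
    "save_sensor_raw",
    "load_sensor_raw",
]


@dataclass(frozen=True)
class SensorData:
    """A sinogram: pressure samples indexed (time, element, scan position).

    Attributes
    ----------
    samples : ndarray, shape (n_time, n_elements, n_positions)
    sampling_rate : float
        Samples per µs (MHz).
    t0 : float
        Time of the first sample relative to the laser pulse, µs.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples)
        if samples.ndim != 3:
            raise ValueError(
                f"samples must be (time, element, position), got shape {samples.shape}"
            )
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def n_time(self) -> int:
        return self.samples.shape[0]

    @property
    def n_elements(self) -> int:
        return self.samples.shape[1]

    @property
    def n_positions(self) -> int:
        return self.samples.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Absolute sample times t0 + k / sampling_rate, µs."""
        return self.t0 + np.arange(self.n_time) / self.sampling_rate


def ubp_term(data: SensorData) -> SensorData:
    """The back-projection integrand ``b(t) = 2 p(t) - 2 t dp/dt`` per trace.

    The derivative is a second-order central finite difference at interior
    samples and first-order one-sided at the two ends; ``t`` is the absolute
    time of flight ``t0 + k / sampling_rate``, not the sample index. The
    operation is linear in the input, annihilates linear traces at interior
    samples, and maps a constant trace ``c`` to ``2 c`` everywhere.
    """
    if data.n_time < 2:
        raise ValueError(
            f"ubp_term needs >= 2 time samples for the derivative, got {data.n_time}"
        )
    dt = 1.0 / data.sampling_rate
    deriv = np.gradient(data.samples, dt, axis=0, edge_order=1)
    t = data.times[:, None, None]
    b = 2.0 * data.samples - 2.0 * t * deriv
    return replace(data, samples=b)


def sample_at(trace: np.ndarray, t, sampling_rate: float, t0: float = 0.0):
    """Linearly interpolate a single trace at time(s) ``t`` (µs).

    Times outside ``[t0, t_last]`` return 0 — the trace carries no signal
    before the first or after the last sample. On-grid times reproduce the
    stored samples exactly.
    """
    if sampling_rate <= 0:
        raise ValueError(f"sampling_rate must be > 0, got {sampling_rate}")
    trace = np.asarray(trace, dtype=float)
    times = t0 + np.arange(trace.shape[0]) / sampling_rate
    return np.interp(t, times, trace, left=0.0, right=0.0)


def bandpass_filter(data: SensorData, low_mhz: float, high_mhz: float, order: int = 4) -> SensorData:
    """Optional zero-phase Butterworth band-pass over the time axis.

    Off by default in the pipeline; provided for matching a transducer's
    bandwidth when working with experimental data.
    """
    nyquist = data.sampling_rate / 2.0
    if not 0 < low_mhz < high_mhz < nyquist:
        raise ValueError(
            f"band must satisfy 0 < low < high < Nyquist ({nyquist} MHz), "
            f"got ({low_mhz}, {high_mhz})"
        )
    sos = _signal.butter(order, [low_mhz, high_mhz], btype="band", fs=data.sampling_rate, output="sos")
    filtered = _signal.sosfiltfilt(sos, data.samples, axis=0)
    return replace(data, samples=filtered)


# ---------------------------------------------------------------------------
# On-disk formats


def save_sensor_hdf5(data: SensorData, path: str | Path) -> None:
    """Write a sinogram as HDF5: /samples (little-endian float32) plus
    sampling_rate_mhz and t0_us attributes."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("samples", data=data.samples.astype("<f4"))
        ds.attrs["axes"] = "time,element,position"
        f.attrs["sampling_rate_mhz"] = float(data.sampling_rate)
        f.attrs["t0_us"] = float(data.t0)


def load_sensor_hdf5(path: str | Path) -> SensorData:
    with h5py.File(path, "r") as f:
        if "samples" not in f:
            raise ValueError(f"{path}: missing /samples dataset")
        samples = np.asarray(f["samples"], dtype=float)
        try:
            rate = float(f.attrs["sampling_rate_mhz"])
            t0 = float(f.attrs["t0_us"])
        except KeyError as exc:
            raise ValueError(f"{path}: missing required attribute {exc}") from exc
    return SensorData(samples=samples, sampling_rate=rate, t0=t0)


def save_sensor_raw(data: SensorData, prefix: str | Path) -> tuple[Path, Path]:
    """Raw-binary fallback: <prefix>.raw (little-endian float32, C order)
    plus a <prefix>.json sidecar with shape and the same field names."""
    prefix = Path(prefix)
    raw_path = prefix.with_suffix(".raw")
    meta_path = prefix.with_suffix(".json")
    data.samples.astype("<f4").tofile(raw_path)
    meta = {
        "shape": list(data.samples.shape),
        "dtype": "<f4",
        "axes": "time,element,position",
        "sampling_rate_mhz": float(data.sampling_rate),
        "t0_us": float(data.t0),
    }
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")
    return raw_path, meta_path


def load_sensor_raw(prefix: str | Path) -> SensorData:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    for key in ("shape", "sampling_rate_mhz", "t0_us"):
        if key not in meta:
            raise ValueError(f"{prefix}.json: missing required field {key!r}")
    dtype = meta.get("dtype", "<f4")
    samples = np.fromfile(prefix.with_suffix(".raw"), dtype=dtype)
    samples = samples.reshape(meta["shape"]).astype(float)
    return SensorData(
        samples=samples,
        sampling_rate=float(meta["sampling_rate_mhz"]),
        t0=float(meta["t0_us"]),
    )
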