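"""Array containers for A-line ensembles and velocity fields.

All containers carry the fixture geometry and acquisition metadata so that
downstream operations (cropping around the focus, arrival-time prediction)
need no extra arguments.  Depth is measured in mm from the transducer face,
increasing away from it; slow time in ms with t = 0 at the end of the push.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .errors import ConfigurationError
from .geometry import AcquisitionConfig, FixtureGeometry

__all__ = ["VelocityField", "RFEnsemble", "IQEnsemble", "ScattererRecord"]


def _check_axis(name: str, axis: np.ndarray, n: int) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size != n:
        raise ConfigurationError(f"{name} must be 1-D with {n} entries, got shape {axis.shape}")
    if axis.size > 1 and not np.all(np.diff(axis) > 0):
        raise ConfigurationError(f"{name} must be strictly increasing")
    return axis


@dataclass
class VelocityField:
    """Axial particle-velocity map v(z, t): depth samples x slow-time frames.

    This is the "arrival-time plot": each boundary-reflected shear wave shows
    up as a packet whose depth-time locus encodes its propagation path.
    Values are in mm/ms (= m/s) when produced by the autocorrelation
    estimator, and in arbitrary consistent units when simulated; every
    downstream statistic (slopes, centroids) is invariant to a global scale.
    """

    values: np.ndarray
    depth_axis_mm: np.ndarray
    time_axis_ms: np.ndarray
    geometry: FixtureGeometry
    acquisition: AcquisitionConfig
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("values must be 2-D (depth x slow time)")
        nz, nt = self.values.shape
        self.depth_axis_mm = _check_axis("depth_axis_mm", self.depth_axis_mm, nz)
        self.time_axis_ms = _check_axis("time_axis_ms", self.time_axis_ms, nt)
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("velocity values must be finite")
        dt = np.diff(self.time_axis_ms)
        if dt.size and not np.allclose(dt, self.acquisition.frame_interval_ms, rtol=1e-6):
            raise ConfigurationError("time step must equal 1/prf")

    @property
    def n_depth(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def restricted(self, depth_mask: np.ndarray | None = None,
                   time_mask: np.ndarray | None = None,
                   extra_flags: tuple[str, ...] = ()) -> "VelocityField":
        """Sub-field selected by boolean masks along each axis (no resampling)."""
        zsel = slice(None) if depth_mask is None else depth_mask
        tsel = slice(None) if time_mask is None else time_mask
        return replace(
            self,
            values=self.values[zsel][:, tsel],
            depth_axis_mm=self.depth_axis_mm[zsel],
            time_axis_ms=self.time_axis_ms[tsel],
            flags=self.flags + tuple(extra_flags),
        )


@dataclass
class ScattererRecord:
    """Provenance of the speckle realization used to synthesize RF."""

    positions_mm: np.ndarray
    amplitudes: np.ndarray
    seed: int


def _check_ensemble(values: np.ndarray, n_frames: int, complex_ok: bool) -> np.ndarray:
    values = np.asarray(values)
    if not complex_ok:
        values = values.astype(float, copy=False)
    if values.ndim != 2:
        raise ConfigurationError("values must be 2-D (fast time x frames)")
    if values.shape[1] != n_frames:
        raise ConfigurationError(
            f"frame count {values.shape[1]} must equal acquisition n_frames {n_frames}"
        )
    if not np.all(np.isfinite(values)):
        raise ConfigurationError("ensemble values must be finite")
    return values


@dataclass
class RFEnsemble:
    """Raw pulse-echo RF A-lines: fast-time samples x slow-time frames."""

    values: np.ndarray
    rf_sampling_rate: float
    fast_time_offset_s: float
    geometry: FixtureGeometry
    acquisition: AcquisitionConfig
    scatterers: ScattererRecord | None = None

    def __post_init__(self) -> None:
        self.values = _check_ensemble(self.values, self.acquisition.n_frames, complex_ok=False)

    @property
    def fast_time_s(self) -> np.ndarray:
        return self.fast_time_offset_s + np.arange(self.values.shape[0]) / self.rf_sampling_rate

    @property
    def depth_axis_mm(self) -> np.ndarray:
        c = self.acquisition.compressional_sound_speed
        return 1000.0 * c * self.fast_time_s / 2.0


@dataclass
class IQEnsemble:
    """Complex baseband A-line ensemble after demodulation."""

    values: np.ndarray
    demodulation_frequency: float
    sampling_rate: float
    fast_time_offset_s: float
    geometry: FixtureGeometry
    acquisition: AcquisitionConfig

    def __post_init__(self) -> None:
        self.values = _check_ensemble(self.values, self.acquisition.n_frames, complex_ok=True)
        if not np.iscomplexobj(self.values):
            self.values = self.values.astype(complex)
        if self.demodulation_frequency != self.acquisition.center_frequency:
            raise ConfigurationError(
                "demodulation frequency must equal the acquisition center frequency"
            )

    @property
    def depth_axis_mm(self) -> np.ndarray:
        c = self.acquisition.compressional_sound_speed
        t = self.fast_time_offset_s + np.arange(self.values.shape[0]) / self.sampling_rate
        return 1000.0 * c * t / 2.0


def metadata_dict(obj: Any) -> dict[str, Any]:
    """Flat attribute dict of geometry + acquisition fields (for containers)."""
    out: dict[str, Any] = {}
    g: FixtureGeometry = obj.geometry
    a: AcquisitionConfig = obj.acquisition
    for name in ("one_way_distances", "focal_length", "face_to_container_bottom",
                 "sample_width", "sample_length", "f_number"):
        out[f"geometry.{name}"] = getattr(g, name)
    for name in ("center_frequency", "prf", "n_frames", "rf_sampling_rate",
                 "push_cycles", "push_duration", "compressional_sound_speed"):
        out[f"acquisition.{name}"] = getattr(a, name)
    return out
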