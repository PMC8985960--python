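"""Fixture geometry, acquisition parameters, and time-of-flight arithmetic.

The measurement fixture holds a single-element focused transducer above a
roughly cubic hydrogel sample so that the one-way lateral distances from the
acoustic focus to the four vertical sample boundaries are fixed and known.
A shear wave launched at the focus by an acoustic radiation force (ARF) push
propagates laterally, reflects off each boundary and returns to the focus,
where its arrival time t_i is measured.  With two-way path lengths 2*d_i the
per-boundary speeds are s_i = 2*d_i / t_i and the sample's shear-wave speed
(SWS) is their arithmetic mean::

    SWS = (1/4) * sum_i (2 * d_i) / t_i

Units follow one convention throughout the package: distances in mm, times in
ms, so speeds come out directly in m/s (1 mm/ms == 1 m/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .errors import ConfigurationError, InvalidWavefrontError

__all__ = [
    "FixtureGeometry",
    "AcquisitionConfig",
    "SWSEstimate",
    "two_way_paths",
    "predict_arrival_times",
    "compute_sws",
    "load_config",
    "Config",
]


@dataclass(frozen=True)
class FixtureGeometry:
    """Geometry of the transducer/sample assembly.

    Parameters
    ----------
    one_way_distances
        Focal-point-to-boundary distances of the four vertical sample faces,
        in mm, strictly ascending.
    focal_length
        Transducer focal length in mm; the focus depth below the transducer
        face in the depth coordinate used everywhere else.
    face_to_container_bottom
        Distance from the transducer face to the bottom of the sample
        container, in mm.
    sample_width, sample_length
        Lateral sample dimensions in mm (metadata; opposite-wall distances
        should sum to these).
    f_number
        Focal length over aperture diameter (metadata only).
    """

    one_way_distances: tuple[float, float, float, float] = (3.0, 6.2, 9.2, 12.0)
    focal_length: float = 14.0
    face_to_container_bottom: float = 15.8
    sample_width: float = 15.0
    sample_length: float = 15.4
    f_number: float = 2.0

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.one_way_distances)
        if len(d) != 4:
            raise ConfigurationError(
                f"exactly 4 one-way distances required, got {len(d)}"
            )
        if any(x <= 0 for x in d):
            raise ConfigurationError(f"one-way distances must be positive: {d}")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ConfigurationError(f"one-way distances must be strictly ascending: {d}")
        object.__setattr__(self, "one_way_distances", d)
        for name in ("focal_length", "face_to_container_bottom", "sample_width", "sample_length"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Push and pulse-echo tracking parameters.

    The transducer first emits a long sinusoidal push (``push_cycles`` cycles
    at ``center_frequency``, about ``push_duration`` seconds), then switches
    to pulse-echo mode and fires ``n_frames`` tracking A-lines at the pulse
    repetition frequency ``prf``.
    """

    center_frequency: float = 20e6  # Hz
    prf: float = 5000.0  # Hz
    n_frames: int = 400
    rf_sampling_rate: float = 100e6  # Hz
    push_cycles: int = 2000
    push_duration: float = 1e-4  # s
    compressional_sound_speed: float = 1540.0  # m/s

    def __post_init__(self) -> None:
        if self.prf <= 0:
            raise ConfigurationError("prf must be positive")
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be at least 2")
        if self.rf_sampling_rate <= 2 * self.center_frequency:
            raise ConfigurationError(
                "rf_sampling_rate must exceed twice the center frequency "
                f"({self.rf_sampling_rate:g} <= 2 x {self.center_frequency:g})"
            )
        nominal = self.push_cycles / self.center_frequency
        if not math.isclose(self.push_duration, nominal, rel_tol=0.05):
            raise ConfigurationError(
                f"push_duration {self.push_duration:g} s inconsistent with "
                f"push_cycles/center_frequency = {nominal:g} s (5% tolerance)"
            )

    @property
    def frame_interval_ms(self) -> float:
        """Slow-time sampling interval, ms."""
        return 1000.0 / self.prf

    @property
    def wavelength_mm(self) -> float:
        """Compressional (tracking) wavelength, mm."""
        return 1000.0 * self.compressional_sound_speed / self.center_frequency


@dataclass(frozen=True)
class SWSEstimate:
    """Result of the time-of-flight SWS computation.

    ``per_path_speeds`` are the four boundary speeds s_i = 2*d_i/t_i in m/s,
    ``mean_sws`` their arithmetic mean (the reported SWS) and
    ``speed_variance`` their population variance.  The remaining fields are
    pipeline diagnostics and stay at their defaults when the estimate comes
    from :func:`compute_sws` directly.
    """

    per_path_speeds: tuple[float, float, float, float]
    mean_sws: float
    speed_variance: float
    arrival_times: tuple[float, float, float, float]
    initial_estimate: float | None = None
    n_candidates_considered: int = 0
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        s = self.per_path_speeds
        if not math.isclose(self.mean_sws, sum(s) / 4.0, rel_tol=1e-12, abs_tol=1e-15):
            raise InvalidWavefrontError("mean_sws must equal the mean of per-path speeds")
        if self.speed_variance < 0:
            raise InvalidWavefrontError("speed variance must be non-negative")


def two_way_paths(geometry: FixtureGeometry) -> tuple[float, float, float, float]:
    """Two-way (reflection) path lengths 2*d_i in mm, ascending."""
    return tuple(2.0 * d for d in geometry.one_way_distances)


def predict_arrival_times(geometry: FixtureGeometry, sws: float) -> tuple[float, float, float, float]:
    """Expected reflected-wave arrival times at the focus, in ms.

    t_i = 2*d_i / sws with d_i in mm and ``sws`` in m/s.
    """
    if not sws > 0:
        raise InvalidWavefrontError(f"shear-wave speed must be positive, got {sws!r}")
    return tuple(p / sws for p in two_way_paths(geometry))


def compute_sws(
    geometry: FixtureGeometry,
    arrival_times: tuple[float, float, float, float] | np.ndarray,
) -> SWSEstimate:
    """Time-of-flight SWS from four reflected-wave arrival times (ms).

    Implements the mean of per-path two-way speeds, which is an average of
    four d/t ratios, *not* total distance over total time.
    """
    t = tuple(float(x) for x in arrival_times)
    if len(t) != 4:
        raise InvalidWavefrontError(f"exactly 4 arrival times required, got {len(t)}")
    if any(x <= 0 for x in t):
        raise InvalidWavefrontError(f"arrival times must be positive: {t}")
    if any(b <= a for a, b in zip(t, t[1:])):
        raise InvalidWavefrontError(f"arrival times must be strictly ascending: {t}")
    speeds = tuple(p / ti for p, ti in zip(two_way_paths(geometry), t))
    mean = sum(speeds) / 4.0
    var = sum((s - mean) ** 2 for s in speeds) / 4.0
    return SWSEstimate(
        per_path_speeds=speeds, mean_sws=mean, speed_variance=var, arrival_times=t
    )


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_GEOMETRY_KEYS = {
    "one_way_distances",
    "focal_length",
    "face_to_container_bottom",
    "sample_width",
    "sample_length",
    "f_number",
}
_ACQUISITION_KEYS = {
    "center_frequency",
    "prf",
    "n_frames",
    "rf_sampling_rate",
    "push_cycles",
    "push_duration",
    "compressional_sound_speed",
}
_TOP_LEVEL_KEYS = {"geometry", "acquisition", "simulation", "estimation"}


@dataclass(frozen=True)
class Config:
    """Parsed configuration: typed geometry/acquisition plus free-form
    ``simulation`` and ``estimation`` sections consumed by the CLI."""

    geometry: FixtureGeometry
    acquisition: AcquisitionConfig
    simulation: dict[str, Any] = field(default_factory=dict)
    estimation: dict[str, Any] = field(default_factory=dict)


def _checked_section(raw: Mapping[str, Any], allowed: set[str], section: str) -> dict[str, Any]:
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in '{section}' section: {sorted(unknown)}"
        )
    return dict(raw)


def load_config(path: str | Path | None = None, text: str | None = None) -> Config:
    """Load a YAML config with ``geometry`` and ``acquisition`` sections.

    Unknown keys anywhere in those sections are rejected so that typos fail
    loudly rather than silently falling back to defaults.  Missing sections
    or fields take the package defaults (the fixture values above).
    """
    if (path is None) == (text is None):
        raise ConfigurationError("pass exactly one of path or text")
    if path is not None:
        text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        raise ConfigurationError(f"unknown top-level section(s): {sorted(unknown)}")
    gkw = _checked_section(raw.get("geometry") or {}, _GEOMETRY_KEYS, "geometry")
    if "one_way_distances" in gkw:
        gkw["one_way_distances"] = tuple(float(x) for x in gkw["one_way_distances"])
    akw = _checked_section(raw.get("acquisition") or {}, _ACQUISITION_KEYS, "acquisition")
    try:
        geometry = FixtureGeometry(**gkw)
        acquisition = AcquisitionConfig(**akw)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigurationError(str(exc)) from exc
    return Config(
        geometry=geometry,
        acquisition=acquisition,
        simulation=dict(raw.get("simulation") or {}),
        estimation=dict(raw.get("estimation") or {}),
    )


def with_updates(geometry: FixtureGeometry, **kwargs: Any) -> FixtureGeometry:
    """Return a copy of ``geometry`` with fields replaced (validated)."""
    return replace(geometry, **kwargs)
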