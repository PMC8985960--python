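"""Synthetic shear wavefields and speckle RF ensembles.

The forward model is an image-source construction restricted to the beam
axis (the only line the single-element system ever observes).  An ARF push
at the focus launches:

* a *direct* packet spreading axially from the focus, with depth-time locus
  ``t = |z - z_focus| / c_s``;
* *top/bottom-face* reflections of that axial wave, which appear as sloped
  bands crossing the arrival-time plot at speed ``c_s``;
* four *side-boundary* reflections.  Each vertical boundary at one-way
  distance ``d_i`` acts as an image source at lateral offset ``2 d_i``; its
  on-axis arrival at depth ``z`` is
  ``t_i(z) = sqrt((2 d_i)^2 + (z - z_focus)^2) / c_s`` with amplitude
  ``r_i / path**spreading_exponent`` (cylindrical spreading by default).

Each event is a Gaussian-enveloped velocity packet of temporal FWHM
``packet_width``; white measurement noise is added last.  The same seed and
parameters always produce bit-identical fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import gausspulse

from .errors import ConfigurationError, AliasingWarning, PacketOverlapWarning
from .fields import RFEnsemble, ScattererRecord, VelocityField
from .geometry import AcquisitionConfig, FixtureGeometry, two_way_paths

__all__ = [
    "SimulationTruth",
    "simulate_velocity_field",
    "simulate_rf_ensemble",
    "simulate_longitudinal_series",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters of a simulated acquisition.

    ``packet_width`` (temporal FWHM, ms) defaults to 1.3 ms so that the
    spatial extent of the packet is about 2 mm at 1.5 m/s, the wavelength
    scale of ARF-generated shear waves in soft hydrogels.  Reflection
    coefficients and the geometric-spreading exponent of the agarose buffer
    walls are not independently measurable on this platform and are exposed
    as free parameters.  ``sample_height`` (mm) sets the top-face depth via
    the container bottom; the 6.5 mm default places the top-face echo
    between the first and second side-boundary arrivals.
    """

    true_sws: float = 1.0  # m/s
    packet_width: float = 1.3  # ms, FWHM
    reflection_coefficients: tuple[float, float, float, float] = (0.6, 0.6, 0.6, 0.6)
    top_bottom_amplitude: float = 0.15
    spreading_exponent: float = 0.5
    noise_sigma: float = 0.05  # fraction of the direct-packet peak
    rng_seed: int = 0
    sample_height: float = 6.5  # mm
    broadening_per_mm: float = 0.0  # extra temporal sigma per mm of path (viscosity proxy)
    second_bounce: bool = False

    def __post_init__(self) -> None:
        if not self.true_sws > 0:
            raise ConfigurationError("true_sws must be positive")
        if not self.packet_width > 0:
            raise ConfigurationError("packet_width must be positive")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be non-negative")
        if len(self.reflection_coefficients) != 4 or any(
            not (0 <= r <= 1) for r in self.reflection_coefficients
        ):
            raise ConfigurationError("reflection_coefficients must be four values in [0, 1]")
        if not self.sample_height > 0:
            raise ConfigurationError("sample_height must be positive")


def _packet(
    t: np.ndarray, t_arrival: np.ndarray, sigma: np.ndarray | float, period: float
) -> np.ndarray:
    """Gaussian-enveloped single-cycle velocity packet centered at ``t_arrival``.

    The carrier (one period across the envelope FWHM) gives the packet its
    dominant wavelength ``sws * period`` -- about 2 mm at 1.5 m/s with the
    default width -- and keeps the slow-time signal band-pass, which is what
    the envelope detector downstream assumes.
    """
    x = t - t_arrival
    return np.cos(2.0 * np.pi * x / period) * np.exp(-0.5 * (x / sigma) ** 2)


def _support_mask(z: np.ndarray, z_top: float, z_bot: float, edge: float = 0.2) -> np.ndarray:
    """Smooth indicator of the sample depth interval [z_top, z_bot]."""
    up = np.clip((z - z_top) / edge, 0.0, 1.0)
    down = np.clip((z_bot - z) / edge, 0.0, 1.0)
    ramp = lambda u: 0.5 * (1.0 - np.cos(np.pi * u))
    return ramp(up) * ramp(down)


def simulate_velocity_field(
    geometry: FixtureGeometry,
    acquisition: AcquisitionConfig,
    truth: SimulationTruth,
    depth_span_mm: tuple[float, float] = (-5.0, 4.0),
    depth_step_mm: float = 0.05,
) -> VelocityField:
    """Simulate the on-axis axial-velocity field v(z, t).

    ``depth_span_mm`` is relative to the focus.  The direct packet has unit
    peak amplitude; all other amplitudes and the noise level are relative to
    it.  Emits :class:`PacketOverlapWarning` when two on-axis arrivals at the
    focus are closer than one packet width.
    """
    c = truth.true_sws
    zf = geometry.focal_length
    z = zf + np.arange(depth_span_mm[0], depth_span_mm[1] + 0.5 * depth_step_mm, depth_step_mm)
    t = np.arange(acquisition.n_frames) * acquisition.frame_interval_ms
    zz = z[:, None]
    tt = t[None, :]
    sigma0 = truth.packet_width * _FWHM_TO_SIGMA

    z_bot = geometry.face_to_container_bottom
    z_top = z_bot - truth.sample_height
    if z_top >= zf:
        raise ConfigurationError("sample top face must lie above the focus")

    def sig(path_mm: np.ndarray | float) -> np.ndarray | float:
        if truth.broadening_per_mm <= 0:
            return sigma0
        return np.sqrt(sigma0**2 + (truth.broadening_per_mm * path_mm) ** 2)

    field = np.zeros((z.size, t.size))

    # direct axial packet from the push
    path_direct = np.abs(zz - zf)
    field += _packet(tt, path_direct / c, sig(path_direct), truth.packet_width)

    # top/bottom-face reflections of the axial wave (sloped bands)
    if truth.top_bottom_amplitude != 0.0:
        path_top = (zf - z_top) + (zz - z_top)
        field += truth.top_bottom_amplitude * _packet(tt, path_top / c, sig(path_top), truth.packet_width)
        path_bot = (z_bot - zf) + (z_bot - zz)
        field += truth.top_bottom_amplitude * _packet(tt, path_bot / c, sig(path_bot), truth.packet_width)

    # side-boundary reflections via lateral image sources
    for d, r in zip(geometry.one_way_distances, truth.reflection_coefficients):
        if r == 0.0:
            continue
        path = np.sqrt((2.0 * d) ** 2 + (zz - zf) ** 2)
        field += (r / path**truth.spreading_exponent) * _packet(tt, path / c, sig(path), truth.packet_width)
        if truth.second_bounce:
            path2 = np.sqrt((4.0 * d) ** 2 + (zz - zf) ** 2)
            field += (r**2 / path2**truth.spreading_exponent) * _packet(
                tt, path2 / c, sig(path2), truth.packet_width
            )

    field *= _support_mask(z, z_top, z_bot)[:, None]

    arrivals = np.sort(
        np.concatenate(
            [
                [0.0, 2.0 * (zf - z_top) / c, 2.0 * (z_bot - zf) / c],
                np.asarray(two_way_paths(geometry)) / c,
            ]
        )
    )
    if np.any(np.diff(arrivals) < truth.packet_width):
        warnings.warn(
            "successive on-axis arrivals closer than one packet width; "
            "wave packets overlap at the focus",
            PacketOverlapWarning,
            stacklevel=2,
        )

    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.rng_seed)
        field = field + truth.noise_sigma * rng.standard_normal(field.shape)

    return VelocityField(
        values=field,
        depth_axis_mm=z,
        time_axis_ms=t,
        geometry=geometry,
        acquisition=acquisition,
    )


# ---------------------------------------------------------------------------
# speckle RF synthesis
# ---------------------------------------------------------------------------

def synthesize_frames(
    scatterer_depths_mm: np.ndarray,
    displacements_mm: np.ndarray,
    amplitudes: np.ndarray,
    acquisition: AcquisitionConfig,
    fast_time_s: np.ndarray,
    fractional_bandwidth: float = 0.5,
) -> np.ndarray:
    """Pulse-echo RF frames from point scatterers.

    ``displacements_mm`` has shape (n_scatterers, n_frames); positive values
    move a scatterer toward the transducer (decreasing depth).  Each frame's
    A-line is the sum over scatterers of a Gaussian-modulated sinusoid at the
    transducer center frequency delayed by the two-way travel time.
    """
    c_mm_s = 1000.0 * acquisition.compressional_sound_speed
    n_frames = displacements_mm.shape[1]
    out = np.empty((fast_time_s.size, n_frames))
    for n in range(n_frames):
        depth = scatterer_depths_mm - displacements_mm[:, n]
        tau = 2.0 * depth / c_mm_s  # s, (n_scat,)
        pulses = gausspulse(
            fast_time_s[None, :] - tau[:, None],
            fc=acquisition.center_frequency,
            bw=fractional_bandwidth,
        )
        out[:, n] = amplitudes @ pulses
    return out


def simulate_rf_ensemble(
    geometry: FixtureGeometry,
    acquisition: AcquisitionConfig,
    truth: SimulationTruth,
    n_scatterers: int = 1500,
    depth_window_mm: tuple[float, float] | None = None,
    velocity_scale: float = 5e-3,
    electronic_noise: float = 0.005,
    fractional_bandwidth: float = 0.5,
) -> RFEnsemble:
    """Synthesize a speckle RF ensemble moving with the simulated wavefield.

    Sub-resolution scatterers are drawn uniformly over ``depth_window_mm``
    (defaults to focus +/- 2.2 mm) with circular-Gaussian amplitudes, then
    advanced between frames by integrating the noise-free simulated axial
    velocity at their rest depth.  ``velocity_scale`` converts the
    dimensionless field (direct-packet peak = 1) to physical velocity in
    mm/ms; the default gives ~1 um peak displacement per frame at 5 kHz,
    well inside the +/- lambda/4 unambiguous range of the phase estimator.
    Electronic noise is white, relative to the peak RF amplitude of the
    first frame.  A warning is raised if any per-frame displacement exceeds
    lambda/8, where phase tracking starts to degrade.
    """
    if n_scatterers < 1:
        raise ConfigurationError("n_scatterers must be positive")
    zf = geometry.focal_length
    if depth_window_mm is None:
        # cover both the slope band above the focus and the focal trace band
        depth_window_mm = (zf - 4.7, zf + 2.2)
    z_lo, z_hi = depth_window_mm
    if not z_hi > z_lo:
        raise ConfigurationError("depth window must be non-empty")

    motion = simulate_velocity_field(geometry, acquisition, replace(truth, noise_sigma=0.0))
    rng = np.random.default_rng(truth.rng_seed)
    z0 = rng.uniform(z_lo, z_hi, size=n_scatterers)
    amp = rng.standard_normal(n_scatterers)

    # nearest-row velocity history for each scatterer, integrated to displacement
    rows = np.clip(
        np.searchsorted(motion.depth_axis_mm, z0), 0, motion.depth_axis_mm.size - 1
    )
    v = velocity_scale * motion.values[rows, :]  # mm/ms, (n_scat, n_frames)
    dt_ms = acquisition.frame_interval_ms
    step = v * dt_ms
    lam_mm = acquisition.wavelength_mm
    if np.max(np.abs(step)) > lam_mm / 8.0:
        warnings.warn(
            "per-frame displacement exceeds lambda/8; autocorrelation velocity "
            "estimates will be degraded or aliased",
            AliasingWarning,
            stacklevel=2,
        )
    disp = np.concatenate(
        [np.zeros((n_scatterers, 1)), np.cumsum(step[:, :-1], axis=1)], axis=1
    )

    c_mm_s = 1000.0 * acquisition.compressional_sound_speed
    pad_mm = 0.4
    fs = acquisition.rf_sampling_rate
    t0 = 2.0 * (z_lo - pad_mm) / c_mm_s
    t1 = 2.0 * (z_hi + pad_mm) / c_mm_s
    fast_time = t0 + np.arange(int(np.ceil((t1 - t0) * fs))) / fs

    values = synthesize_frames(z0, disp, amp, acquisition, fast_time, fractional_bandwidth)
    if electronic_noise > 0:
        values = values + electronic_noise * np.max(np.abs(values[:, 0])) * rng.standard_normal(
            values.shape
        )

    return RFEnsemble(
        values=values,
        rf_sampling_rate=fs,
        fast_time_offset_s=t0,
        geometry=geometry,
        acquisition=acquisition,
        scatterers=ScattererRecord(positions_mm=z0, amplitudes=amp, seed=truth.rng_seed),
    )


def simulate_longitudinal_series(
    geometry: FixtureGeometry,
    acquisition: AcquisitionConfig,
    base_truth: SimulationTruth,
    sws_trajectory: Sequence[tuple[str, float]],
) -> list[VelocityField]:
    """One independently seeded velocity field per (label, true_sws) time point.

    Emulates repeated non-destructive interrogation of the same culture as
    its matrix stiffness evolves.  Per-point seeds are spawned
    deterministically from the base seed, so the whole series is reproducible
    while time points remain statistically independent.
    """
    if len(sws_trajectory) == 0:
        raise ConfigurationError("trajectory must contain at least one time point")
    fields = []
    for i, (_label, sws) in enumerate(sws_trajectory):
        seed = int(
            np.random.SeedSequence(entropy=base_truth.rng_seed, spawn_key=(i,)).generate_state(1)[0]
            % (2**31)
        )
        truth_i = replace(base_truth, true_sws=float(sws), rng_seed=seed)
        fields.append(simulate_velocity_field(geometry, acquisition, truth_i))
    return fields
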