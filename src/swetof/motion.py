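"""RF-to-velocity conversion: IQ demodulation and lag-one autocorrelation.

Sub-wavelength axial motion between tracking A-lines shows up as a phase
rotation of the complex baseband signal.  For a scatterer that moves a
distance ``delta`` toward the transducer between frames, the pulse-echo
baseband phase advances by ``4*pi*f0*delta/c``; the lag-one autocorrelation
(Kasai) estimator inverts that identity after averaging the correlation over
a short axial kernel to suppress noise::

    R(z, n)   = conj(IQ(z, n)) * IQ(z, n+1)        (kernel-averaged over z)
    delta(z, n) = c * arg R / (4 * pi * f0)
    v(z, n)   = delta * PRF

Motion toward the transducer is positive.  Phases at +/- pi are ambiguous;
they are flagged, never unwrapped, because ARF-induced micrometer
displacements should not come near the limit in a well-configured system.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, filtfilt

from .errors import AliasingWarning, ConfigurationError, CropWarning
from .fields import IQEnsemble, RFEnsemble, VelocityField
from .geometry import AcquisitionConfig

__all__ = ["demodulate", "autocorrelation_velocity", "crop_around_focus"]


def demodulate(rf: RFEnsemble, cutoff_fraction: float = 0.75, filter_order: int = 5) -> IQEnsemble:
    """Mix each A-line to complex baseband and low-pass filter it.

    The mixer runs at the transducer center frequency; the zero-phase
    low-pass cutoff defaults to 0.75 x f0.  The factor 2 restores the
    envelope magnitude lost to the discarded negative-frequency band.
    """
    acq = rf.acquisition
    f0 = acq.center_frequency
    fs = rf.rf_sampling_rate
    if fs <= 2 * f0:
        raise ConfigurationError("RF sampling rate must exceed twice the center frequency")
    t = rf.fast_time_s
    mixed = rf.values * (2.0 * np.exp(-2j * np.pi * f0 * t)[:, None])
    b, a = butter(filter_order, cutoff_fraction * f0 / (fs / 2.0))
    iq = filtfilt(b, a, mixed, axis=0)
    return IQEnsemble(
        values=iq,
        demodulation_frequency=f0,
        sampling_rate=fs,
        fast_time_offset_s=rf.fast_time_offset_s,
        geometry=rf.geometry,
        acquisition=acq,
    )


def autocorrelation_velocity(
    iq: IQEnsemble,
    acquisition: AcquisitionConfig | None = None,
    kernel_wavelengths: float = 1.5,
    quality_threshold: float = 0.1,
) -> VelocityField:
    """One-dimensional lag-one autocorrelation velocity estimator.

    ``kernel_wavelengths`` sets the axial averaging length in compressional
    wavelengths (default 1.5, about 115 um at 20 MHz in 1540 m/s medium).
    The output has ``n_frames - 1`` slow-time samples; samples whose
    correlation phase reaches +/- pi are aliased and flag the field.

    Depth samples whose time-averaged echo magnitude falls below
    ``quality_threshold`` times the median carry no speckle signal (phase is
    pure noise there); their velocity is zeroed and the field flagged
    ``low_echo_rows`` rather than reporting noise as motion.
    """
    acq = acquisition or iq.acquisition
    if iq.values.shape[1] < 2:
        raise ConfigurationError("at least two frames required")
    f0 = acq.center_frequency
    c = acq.compressional_sound_speed  # m/s

    r = np.conj(iq.values[:, :-1]) * iq.values[:, 1:]
    dz_mm = 1000.0 * c / (2.0 * iq.sampling_rate)
    kernel = max(1, int(round(kernel_wavelengths * acq.wavelength_mm / dz_mm)))
    if kernel > 1:
        r = uniform_filter1d(r.real, kernel, axis=0, mode="nearest") + 1j * uniform_filter1d(
            r.imag, kernel, axis=0, mode="nearest"
        )

    phase = np.angle(r)
    aliased = np.abs(phase) >= np.pi * (1.0 - 1e-9)
    flags: tuple[str, ...] = ()
    if np.any(aliased):
        warnings.warn(
            f"{int(aliased.sum())} velocity sample(s) at the +/- pi phase limit; "
            "displacement ambiguous (not unwrapped)",
            AliasingWarning,
            stacklevel=2,
        )
        flags = ("aliasing",)

    delta_mm = 1000.0 * c * phase / (4.0 * np.pi * f0)  # mm per frame, toward transducer > 0
    v = delta_mm * acq.prf * 1e-3  # mm/ms

    quality = np.mean(np.abs(iq.values), axis=1)
    low = quality < quality_threshold * np.median(quality)
    if np.any(low):
        v[low, :] = 0.0
        flags = flags + ("low_echo_rows",)

    return VelocityField(
        values=v,
        depth_axis_mm=iq.depth_axis_mm,
        time_axis_ms=np.arange(v.shape[1]) * acq.frame_interval_ms,
        geometry=iq.geometry,
        acquisition=acq,
        flags=flags,
    )


def crop_around_focus(
    field: VelocityField,
    depth_halfwidth: float = 2.0,
    time_window: float | None = 40.0,
) -> VelocityField:
    """Restrict the field to depth within +/- ``depth_halfwidth`` mm of the
    focus and slow time in [0, ``time_window``] ms (no resampling).

    The crop discards coupling-medium clutter above the sample and late
    reverberations.  ``time_window=None`` keeps the full duration.  If the
    requested depth interval covers the whole field, the field is returned
    unchanged with a :class:`CropWarning`.
    """
    zf = field.geometry.focal_length
    z = field.depth_axis_mm
    if not (z[0] <= zf <= z[-1]):
        raise ConfigurationError(
            f"focus depth {zf} mm outside field depth range [{z[0]}, {z[-1]}] mm"
        )
    if depth_halfwidth <= 0:
        raise ConfigurationError("depth_halfwidth must be positive")
    zmask = np.abs(z - zf) <= depth_halfwidth
    if zmask.all():
        warnings.warn(
            "depth halfwidth spans the entire field; nothing cropped in depth",
            CropWarning,
            stacklevel=2,
        )
    tmask = (
        np.ones_like(field.time_axis_ms, dtype=bool)
        if time_window is None
        else (field.time_axis_ms >= 0) & (field.time_axis_ms <= time_window)
    )
    if not zmask.any() or not tmask.any():
        raise ConfigurationError("crop produced an empty field")
    return field.restricted(zmask, tmask)
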