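"""Directional wave filtering and the regression-based initial SWS estimate.

In the depth-time (f-k) spectrum of the velocity field, waves travelling
toward the transducer (up-going, depth decreasing with time) occupy the
quadrant pairs where temporal and spatial frequency share a sign, and
down-going waves the complementary pair.  Zeroing one pair with a smooth
raised-cosine taper separates the two families while staying linear; the
two complementary components sum back to the input field exactly.

The top-face reflection of the push travels down through the focal region
at the shear-wave speed, so a weighted linear regression of per-depth packet
arrival time against depth on the down-going component yields the initial
SWS estimate used to predict the side-boundary arrivals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.fft import next_fast_len

from ._signal import envelope, packet_window, smooth_step, windowed_centroid
from .errors import ConfigurationError, ImplausibleSpeedError, NoWavefrontError
from .fields import VelocityField
from .geometry import FixtureGeometry

__all__ = ["DirectionalComponent", "directional_filter", "initial_sws_slope"]


@dataclass
class DirectionalComponent:
    """One directional half of a velocity field.

    ``direction`` is ``"up"`` (toward the transducer) or ``"down"`` (away);
    ``retained_energy_fraction`` is output energy over input energy.
    """

    field: VelocityField
    direction: str
    retained_energy_fraction: float


def _direction_mask(nz: int, nt: int, dz: float, dt: float, direction: str,
                    taper_fraction: float = 0.05) -> np.ndarray:
    kz = np.fft.fftfreq(nz, d=dz)[:, None]
    ft = np.fft.fftfreq(nt, d=dt)[None, :]
    sk = smooth_step(kz, taper_fraction / dz)
    sf = smooth_step(ft, taper_fraction / dt)
    # same-sign quadrants carry waves f(z + c t): depth decreasing with time
    up = sk * sf + (1.0 - sk) * (1.0 - sf)
    return up if direction == "up" else 1.0 - up


def directional_filter(field: VelocityField, direction: str) -> DirectionalComponent:
    """Keep only up-going or down-going wave energy.

    The complementary masks sum to one everywhere, so
    ``filter(f, "up").values + filter(f, "down").values == f.values`` up to
    floating-point roundoff; energy on the DC/Nyquist ridge is split evenly.
    """
    if direction not in ("up", "down"):
        raise ConfigurationError(f"direction must be 'up' or 'down', got {direction!r}")
    nz, nt = field.values.shape
    if nz < 8 or nt < 8:
        raise ConfigurationError("field must have at least 8 samples on each axis")
    dz = float(np.mean(np.diff(field.depth_axis_mm)))
    dt = float(np.mean(np.diff(field.time_axis_ms)))
    # zero-pad 25% per axis so the circular FFT cannot wrap packet tails from
    # one edge of the cropped field onto the other
    pz = next_fast_len(nz + max(8, nz // 4))
    pt = next_fast_len(nt + max(8, nt // 4))
    padded = np.zeros((pz, pt))
    padded[:nz, :nt] = field.values
    spectrum = np.fft.fft2(padded)
    mask = _direction_mask(pz, pt, dz, dt, direction)
    out = np.fft.ifft2(spectrum * mask).real[:nz, :nt]
    e_in = float(np.sum(field.values**2))
    e_out = float(np.sum(out**2))
    filtered = replace(field, values=out, flags=field.flags + (f"directional:{direction}",))
    return DirectionalComponent(
        field=filtered,
        direction=direction,
        retained_energy_fraction=e_out / e_in if e_in > 0 else 0.0,
    )


def initial_sws_slope(
    component: DirectionalComponent,
    geometry: FixtureGeometry,
    min_rows: int = 8,
    max_speed: float = 10.0,
    min_speed: float = 0.1,
    window_cap_ms: float = 1.5,
    weight: str = "energy",
    detectability: float = 3.0,
) -> float:
    """Initial SWS from the slope of the filtered reflected wavefront.

    For every depth row containing a detectable packet (peak envelope above
    ``detectability`` times the row's median envelope level), the arrival
    time is the envelope-energy centroid of the dominant packet.  A weighted
    least-squares line t(z) (weights = row peak energy, one reweighted pass
    dropping >2-sigma residuals) gives the speed as ``|1/slope|`` in m/s.
    """
    field = component.field
    vals = field.values
    if vals.shape[0] < min_rows:
        raise NoWavefrontError(f"need at least {min_rows} depth rows, got {vals.shape[0]}")
    env = envelope(vals, axis=1)
    gmax = env.max()
    if not gmax > 0 or gmax <= detectability * np.median(env):
        raise NoWavefrontError("no detectable wavefront in the directional component")
    dt = float(np.mean(np.diff(field.time_axis_ms)))
    t_axis = field.time_axis_ms

    depths, arrivals, weights = [], [], []
    for i in range(vals.shape[0]):
        row_env = env[i]
        peak_idx = int(np.argmax(row_env))
        peak = row_env[peak_idx]
        if peak <= detectability * np.median(row_env) or peak < 0.05 * gmax:
            continue
        lo, hi = packet_window(row_env, peak_idx, dt, cap=window_cap_ms)
        mask = np.zeros(row_env.size, dtype=bool)
        mask[lo : hi + 1] = True
        arrivals.append(windowed_centroid(t_axis, row_env, mask, weight=weight))
        depths.append(field.depth_axis_mm[i])
        weights.append(peak**2)

    if len(depths) < min_rows:
        raise NoWavefrontError(
            f"only {len(depths)} rows with detectable packets (need {min_rows})"
        )
    z = np.asarray(depths)
    t = np.asarray(arrivals)
    w = np.asarray(weights)

    slope, intercept = np.polyfit(z, t, 1, w=np.sqrt(w))
    resid = t - (slope * z + intercept)
    rms = np.sqrt(np.average(resid**2, weights=w))
    keep = np.abs(resid) <= 2.0 * rms if rms > 0 else np.ones_like(resid, dtype=bool)
    if keep.sum() >= min_rows and not keep.all():
        slope, intercept = np.polyfit(z[keep], t[keep], 1, w=np.sqrt(w[keep]))

    if slope == 0.0:
        raise ImplausibleSpeedError("wavefront arrives simultaneously at all depths")
    # a propagating wavefront must explain most of the arrival-time spread;
    # uncorrelated row arrivals (noise) give near-zero weighted R^2
    t_bar = np.average(t, weights=w)
    ss_tot = np.average((t - t_bar) ** 2, weights=w)
    ss_res = np.average((t - (slope * z + intercept)) ** 2, weights=w)
    if ss_tot > 1e-12 and 1.0 - ss_res / ss_tot < 0.25:
        raise NoWavefrontError(
            "row arrival times are not consistent with a single propagating wavefront"
        )
    speed = abs(1.0 / slope)  # mm/ms == m/s
    if speed > max_speed:
        raise ImplausibleSpeedError(
            f"regression implies {speed:.2f} m/s (> {max_speed} m/s); "
            "wavefront nearly vertical in depth-time"
        )
    if speed < min_speed:
        raise ImplausibleSpeedError(
            f"regression implies {speed:.3f} m/s (< {min_speed} m/s); "
            "no coherent propagating wavefront"
        )
    return float(speed)
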