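"""Shared low-level signal helpers: envelopes, packet windows, centroids."""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert

from .errors import NoWavefrontError


def envelope(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Magnitude of the analytic signal along ``axis``."""
    return np.abs(hilbert(x, axis=axis))


def packet_window(
    env: np.ndarray,
    peak_idx: int,
    dt: float,
    cap: float = 1.5,
    floor_frac: float = 0.2,
    descent_frac: float = 0.95,
) -> tuple[int, int]:
    """Inclusive index bounds of the packet around ``peak_idx``.

    Walking outward from the peak, the window edge is the first sample where
    any of these hold:

    * the envelope has fallen below ``floor_frac`` of the peak value;
    * the envelope starts rising again after having descended below
      ``descent_frac`` of the peak (a valley between adjacent packets);
    * the walk has covered ``cap`` time units.

    The valley rule keeps a strong neighbouring packet from being absorbed
    into the window when the inter-packet envelope never drops below the
    plain amplitude floor.
    """
    n = env.size
    peak = env[peak_idx]
    if peak <= 0:
        raise NoWavefrontError("packet peak has zero amplitude")
    floor = floor_frac * peak
    max_steps = max(1, int(round(cap / dt)))

    def _walk(direction: int) -> int:
        idx = peak_idx
        prev = peak
        for _ in range(max_steps):
            nxt = idx + direction
            if nxt < 0 or nxt >= n:
                break
            val = env[nxt]
            if val < floor:
                idx = nxt  # include the first sub-floor sample as the edge
                break
            if val > prev and prev < descent_frac * peak:
                break  # idx is the valley sample
            idx = nxt
            prev = val
        return idx

    left = _walk(-1)
    right = _walk(+1)
    # guarantee a strictly bracketing window for downstream invariants
    left = min(left, max(peak_idx - 1, 0))
    right = max(right, min(peak_idx + 1, n - 1))
    return left, right


def windowed_centroid(
    times: np.ndarray,
    env: np.ndarray,
    mask: np.ndarray,
    weight: str = "energy",
) -> float:
    """Envelope-weighted temporal centroid over the masked samples."""
    if weight not in ("energy", "amplitude"):
        raise ValueError(f"weight must be 'energy' or 'amplitude', got {weight!r}")
    w = env[mask] ** 2 if weight == "energy" else env[mask]
    total = w.sum()
    if not np.any(mask) or total <= 0:
        raise NoWavefrontError("centroid window is empty or all-zero")
    return float(np.sum(times[mask] * w) / total)


def smooth_step(x: np.ndarray, width: float) -> np.ndarray:
    """Raised-cosine step: 0 for x <= -width/2, 1 for x >= width/2.

    Antisymmetric about 0 (s(-x) = 1 - s(x)), which keeps spectral masks
    built from it Hermitian-symmetric and their two complementary halves
    summing exactly to one.
    """
    if width <= 0:
        return (x > 0).astype(float) + 0.5 * (x == 0)
    return np.clip(0.5 * (1.0 + np.sin(np.pi * x / width)), 0.0, 1.0) * (np.abs(x) < width / 2) \
        + (x >= width / 2)
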