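"""Wavefront detection, two-stage assignment, and the final SWS estimate.

This is the heart of the method.  From the velocity trace at the acoustic
focus, candidate reflected-wave packets are detected on the slow-time
envelope.  Stage 1 assigns one candidate to each of the four side
boundaries by nearest proximity to the arrival times predicted from the
initial slope-based SWS estimate.  Stage 2 finalizes the selection by an
exhaustive search over nearby candidate combinations, minimizing the
variance of the four per-path speeds s_i = 2*d_i / t_i -- a homogeneous
sample must yield the same speed on every path, so the physically correct
assignment is the most self-consistent one.  Arrival times are measured
with the time-to-centroid method (energy-weighted temporal centroid of the
packet envelope), which is robust to packet-shape asymmetry at the coarse
0.2 ms slow-time sampling.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field as dataclass_field, replace

import numpy as np

from ._signal import envelope, packet_window, windowed_centroid
from .errors import (
    AssignmentError,
    ConfigurationError,
    InvalidWavefrontError,
    NoWavefrontError,
    ImplausibleSpeedError,
    RefinementError,
    SwetofError,
)
from .fields import VelocityField
from .geometry import (
    AcquisitionConfig,
    FixtureGeometry,
    SWSEstimate,
    compute_sws,
    predict_arrival_times,
)
from .motion import crop_around_focus
from .separation import directional_filter, initial_sws_slope

__all__ = [
    "Trace",
    "WavefrontCandidate",
    "WavefrontSet",
    "EstimationOptions",
    "focal_trace",
    "detect_candidates",
    "time_to_centroid",
    "stage1_assign",
    "stage2_refine",
    "estimate_sws",
]

logger = logging.getLogger(__name__)


@dataclass
class Trace:
    """Velocity time series at the focus (one value per slow-time sample)."""

    time_axis_ms: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.time_axis_ms = np.asarray(self.time_axis_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_axis_ms.shape != self.values.shape or self.values.ndim != 1:
            raise ConfigurationError("trace axes and values must be matching 1-D arrays")


@dataclass(frozen=True)
class WavefrontCandidate:
    """A candidate reflected-wave packet on the focal trace."""

    peak_time: float  # ms
    window: tuple[float, float]  # ms
    centroid_time: float  # ms
    peak_amplitude: float
    prominence: float

    def __post_init__(self) -> None:
        t0, t1 = self.window
        if not (t0 < self.peak_time < t1):
            raise InvalidWavefrontError(
                f"window {self.window} must strictly bracket peak at {self.peak_time}"
            )
        if not (t0 <= self.centroid_time <= t1):
            raise InvalidWavefrontError("centroid time must lie inside the window")


@dataclass(frozen=True)
class WavefrontSet:
    """Four candidates assigned to the four boundaries, ascending in time."""

    candidates: tuple[WavefrontCandidate, WavefrontCandidate, WavefrontCandidate, WavefrontCandidate]

    def __post_init__(self) -> None:
        if len(self.candidates) != 4:
            raise InvalidWavefrontError("exactly four wavefronts required")
        if len({id(c) for c in self.candidates}) != 4:
            raise InvalidWavefrontError("a candidate may be assigned to only one boundary")
        t = self.arrival_times
        if any(b <= a for a, b in zip(t, t[1:])):
            raise InvalidWavefrontError(f"arrival times must be strictly ascending: {t}")

    @property
    def arrival_times(self) -> tuple[float, float, float, float]:
        return tuple(c.centroid_time for c in self.candidates)


def focal_trace(
    field: VelocityField,
    geometry: FixtureGeometry | None = None,
    depth_halfwidth: float = 0.5,
) -> Trace:
    """Velocity averaged over depth within ``depth_halfwidth`` mm of the focus.

    A halfwidth of zero returns the single depth row nearest the focus.
    """
    geom = geometry or field.geometry
    zf = geom.focal_length
    z = field.depth_axis_mm
    if not (z[0] <= zf <= z[-1]):
        raise ConfigurationError(
            f"focus depth {zf} mm outside field depth range [{z[0]}, {z[-1]}] mm"
        )
    if depth_halfwidth < 0:
        raise ConfigurationError("depth_halfwidth must be non-negative")
    mask = np.abs(z - zf) <= depth_halfwidth
    if not mask.any():
        values = field.values[int(np.argmin(np.abs(z - zf)))]
    else:
        values = field.values[mask].mean(axis=0)
    return Trace(time_axis_ms=field.time_axis_ms.copy(), values=values)


def time_to_centroid(
    trace: Trace, window: tuple[float, float], weight: str = "energy"
) -> float:
    """Arrival time as the envelope-weighted temporal centroid over ``window``.

    t_c = sum(t * E(t)) / sum(E(t)) with E the squared slow-time envelope
    (``weight="amplitude"`` uses the envelope itself).
    """
    t0, t1 = window
    if t1 <= t0:
        raise ConfigurationError(f"window must have positive length, got {window}")
    if t0 > trace.time_axis_ms[-1] or t1 < trace.time_axis_ms[0]:
        raise ConfigurationError(f"window {window} outside trace support")
    env = envelope(trace.values)
    mask = (trace.time_axis_ms >= t0) & (trace.time_axis_ms <= t1)
    # discrete analytic-signal tails never reach exactly zero; a window whose
    # envelope stays below 0.1% of the trace maximum holds no wave energy
    if not np.any(mask) or env[mask].max() <= 1e-3 * env.max():
        raise NoWavefrontError(f"window {window} contains no wave energy")
    return windowed_centroid(trace.time_axis_ms, env, mask, weight=weight)


def detect_candidates(
    trace: Trace,
    min_prominence: float = 0.1,
    exclude_before_ms: float | None = None,
    window_cap_ms: float = 1.5,
    weight: str = "energy",
    detectability: float = 4.0,
    min_relative_amplitude: float = 0.25,
) -> list[WavefrontCandidate]:
    """Local envelope maxima that qualify as reflected-wave packets.

    Peaks need prominence of at least ``min_prominence`` times the global
    envelope maximum.  Peaks before ``exclude_before_ms`` (half the first
    predicted arrival, in the full pipeline) are discarded as the direct
    push packet.  Each surviving peak gets a window extending to the 20 %
    envelope falloff, an inter-packet valley, or +/- ``window_cap_ms``,
    whichever is hit first, and a centroid arrival time inside it.

    Candidates weaker than ``min_relative_amplitude`` times the strongest
    candidate are dropped: boundary reflections of a common push differ by
    geometric spreading only (roughly a factor two across the fixture), while
    envelope maxima of background noise sit far below the strongest
    reflection and would otherwise offer the assignment spurious,
    accidentally self-consistent arrival families.
    """
    from scipy.signal import find_peaks

    if trace.values.size < 16:
        raise ConfigurationError("trace must contain at least 16 samples")
    env = envelope(trace.values)
    # blank the direct/push packet before anything is measured, so the much
    # stronger near-push energy neither sets the prominence scale nor leaks
    # tails into the first reflection's window
    if exclude_before_ms is not None:
        env = np.where(trace.time_axis_ms < exclude_before_ms, 0.0, env)
    gmax = env.max()
    if not gmax > 0 or gmax <= detectability * np.median(env[env > 0]):
        raise NoWavefrontError("trace envelope indistinguishable from its background level")
    dt = float(np.mean(np.diff(trace.time_axis_ms)))
    peaks, props = find_peaks(env, prominence=min_prominence * gmax)

    out: list[WavefrontCandidate] = []
    for peak_idx, prom in zip(peaks, props["prominences"]):
        t_peak = float(trace.time_axis_ms[peak_idx])
        lo, hi = packet_window(env, int(peak_idx), dt, cap=window_cap_ms)
        window = (float(trace.time_axis_ms[lo]), float(trace.time_axis_ms[hi]))
        mask = np.zeros(env.size, dtype=bool)
        mask[lo : hi + 1] = True
        centroid = windowed_centroid(trace.time_axis_ms, env, mask, weight=weight)
        out.append(
            WavefrontCandidate(
                peak_time=t_peak,
                window=window,
                centroid_time=centroid,
                peak_amplitude=float(env[peak_idx]),
                prominence=float(prom / gmax),
            )
        )
    if out and min_relative_amplitude > 0:
        strongest = max(c.peak_amplitude for c in out)
        out = [c for c in out if c.peak_amplitude >= min_relative_amplitude * strongest]
    if not out:
        raise NoWavefrontError("no candidate wavefronts after exclusion and prominence cuts")
    out.sort(key=lambda c: c.peak_time)
    return out


def stage1_assign(
    candidates: list[WavefrontCandidate],
    predicted_times: tuple[float, float, float, float],
) -> WavefrontSet:
    """Assign, boundary by boundary, the unused candidate nearest each
    predicted arrival time."""
    if len(candidates) < 4:
        raise AssignmentError(
            f"need at least 4 candidate wavefronts, found {len(candidates)}"
        )
    if len(predicted_times) != 4:
        raise AssignmentError("exactly four predicted arrival times required")
    remaining = list(candidates)
    chosen: list[WavefrontCandidate] = []
    for t_hat in predicted_times:
        best = min(remaining, key=lambda c: abs(c.centroid_time - t_hat))
        remaining.remove(best)
        chosen.append(best)
    try:
        return WavefrontSet(candidates=tuple(chosen))
    except InvalidWavefrontError as exc:
        raise AssignmentError(f"stage-1 assignment not time-ordered: {exc}") from exc


def stage2_refine(
    candidates: list[WavefrontCandidate],
    stage1_set: WavefrontSet,
    geometry: FixtureGeometry,
    k_alternatives: int = 3,
) -> tuple[WavefrontSet, SWSEstimate]:
    """Finalize the selection by minimizing per-path speed variance.

    For each boundary the ``k_alternatives`` candidates nearest the stage-1
    choice form the alternative pool; the Cartesian product (at most
    ``k_alternatives**4`` combinations) is searched exhaustively, discarding
    combinations that reuse a candidate or are not strictly ascending.  Ties
    in variance break toward the stage-1 arrival times.  The returned
    variance never exceeds the stage-1 variance because the stage-1
    combination is always in the search space.
    """
    if k_alternatives < 1:
        raise ConfigurationError("k_alternatives must be at least 1")
    pools = []
    for ref in stage1_set.candidates:
        ranked = sorted(candidates, key=lambda c: abs(c.centroid_time - ref.centroid_time))
        pools.append(ranked[:k_alternatives])

    stage1_times = stage1_set.arrival_times
    best: tuple[float, float, WavefrontSet, SWSEstimate] | None = None
    for combo in itertools.product(*pools):
        if len({id(c) for c in combo}) != 4:
            continue
        times = [c.centroid_time for c in combo]
        if any(b <= a for a, b in zip(times, times[1:])):
            continue
        estimate = compute_sws(geometry, times)
        proximity = sum(abs(t - s) for t, s in zip(times, stage1_times))
        key = (estimate.speed_variance, proximity)
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], WavefrontSet(candidates=combo), estimate)
    if best is None:
        raise RefinementError("no valid ascending, non-reusing wavefront combination")
    return best[2], best[3]


@dataclass(frozen=True)
class EstimationOptions:
    """Tunable parameters of the end-to-end pipeline.

    ``crop_time_window=None`` keeps the full recorded duration so that slow
    samples (fourth arrival at 60 ms for 0.4 m/s) are not truncated; set it
    when late reverberation clutter is expected.  ``fallback_grid`` is the
    (start, stop, step) m/s scan used when the slope-based initial estimate
    fails; the speed whose stage-2 variance is lowest wins and the result is
    flagged ``fallback_grid``.
    """

    crop_depth_halfwidth: float = 2.0
    slope_crop_halfwidth: float = 4.5
    crop_time_window: float | None = None
    lowpass_cutoff_khz: float | None = 1.4
    slope_depth_smooth_mm: float = 0.3
    direction: str = "down"
    trace_from_component: bool = True
    focal_halfwidth: float = 0.5
    min_prominence: float = 0.1
    min_relative_amplitude: float = 0.25
    window_cap_ms: float = 1.5
    k_alternatives: int = 3
    centroid_weight: str = "energy"
    max_initial_speed: float = 10.0
    slope_focus_margin_mm: float = 1.0
    slope_edge_margin_mm: float = 0.5
    fallback_grid: tuple[float, float, float] = (0.3, 2.0, 0.1)


def _lowpass_slow_time(field: VelocityField, cutoff_khz: float | None) -> VelocityField:
    """Zero-phase low-pass along slow time, matched to the shear-wave band.

    Shear packets on this platform live below ~1 kHz while the measurement
    noise is white up to the 2.5 kHz slow-time Nyquist, so a gentle low-pass
    buys SNR without touching arrival times (zero-phase) or packet shape.
    Skipped when the record is too short for stable filtering.
    """
    from scipy.signal import butter, filtfilt

    if cutoff_khz is None:
        return field
    prf_khz = field.acquisition.prf / 1000.0
    if cutoff_khz >= prf_khz / 2.0 or field.n_times < 40:
        return field
    b, a = butter(4, cutoff_khz / (prf_khz / 2.0))
    return replace(field, values=filtfilt(b, a, field.values, axis=1))


def _smooth_depth(values: np.ndarray, depth_axis: np.ndarray, length_mm: float) -> np.ndarray:
    """Uniform moving average along depth (coherent gain for sloped bands)."""
    from scipy.ndimage import uniform_filter1d

    if length_mm <= 0 or values.shape[0] < 3:
        return values
    dz = float(np.mean(np.diff(depth_axis)))
    n = max(1, int(round(length_mm / dz)))
    return uniform_filter1d(values, n, axis=0, mode="nearest") if n > 1 else values


def _tag(exc: SwetofError, stage: str) -> SwetofError:
    if exc.stage is None:
        exc.stage = stage
        exc.args = (f"[{stage}] {exc.args[0] if exc.args else ''}",) + exc.args[1:]
    return exc


def estimate_sws(
    field: VelocityField,
    geometry: FixtureGeometry | None = None,
    acquisition: AcquisitionConfig | None = None,
    options: EstimationOptions | None = None,
) -> SWSEstimate:
    """End-to-end SWS estimation from a velocity field.

    Composition: crop around the focus -> directional filter -> slope-based
    initial estimate -> predicted arrivals -> focal trace -> candidate
    detection -> stage-1 nearest assignment -> time-to-centroid -> stage-2
    variance minimization -> averaged time-of-flight SWS.  Errors carry the
    failing stage name in their ``stage`` attribute.
    """
    geom = geometry or field.geometry
    opts = options or EstimationOptions()
    flags: list[str] = list(field.flags)

    field = _lowpass_slow_time(field, opts.lowpass_cutoff_khz)

    try:
        cropped = crop_around_focus(field, opts.crop_depth_halfwidth, opts.crop_time_window)
    except SwetofError as exc:
        raise _tag(exc, "crop")

    try:
        component = directional_filter(cropped, opts.direction)
    except SwetofError as exc:
        raise _tag(exc, "directional_filter")

    # Initial estimate from the top-face reflection: fit only rows above the
    # focus, where the down-going energy is the reflected (not direct) wave.
    # The slope stage uses its own, wider depth crop -- the top-face band
    # spans the whole sample above the focus and a long depth lever arm is
    # what makes the regression slope accurate at 0.2 ms slow-time sampling.
    # Margins keep out rows next to the focus (direct-wave leakage: near the
    # source the propagation direction is undefined) and next to the crop
    # edge (Gibbs leakage of the directional filter).
    zf = geom.focal_length
    try:
        slope_cropped = crop_around_focus(field, opts.slope_crop_halfwidth, opts.crop_time_window)
        slope_filtered = directional_filter(slope_cropped, opts.direction)
    except SwetofError as exc:
        raise _tag(exc, "directional_filter")
    z_axis = slope_filtered.field.depth_axis_mm
    if opts.direction == "down":
        row_mask = (z_axis <= zf - opts.slope_focus_margin_mm) & (
            z_axis >= z_axis[0] + opts.slope_edge_margin_mm
        )
    else:
        row_mask = (z_axis >= zf + opts.slope_focus_margin_mm) & (
            z_axis <= z_axis[-1] - opts.slope_edge_margin_mm
        )
    slope_field = slope_filtered.field.restricted(depth_mask=row_mask)
    slope_field = replace(
        slope_field,
        values=_smooth_depth(
            slope_field.values, slope_field.depth_axis_mm, opts.slope_depth_smooth_mm
        ),
    )
    slope_component = replace(slope_filtered, field=slope_field)

    initial: float | None = None
    try:
        initial = initial_sws_slope(
            slope_component,
            geom,
            max_speed=opts.max_initial_speed,
            window_cap_ms=opts.window_cap_ms,
            weight=opts.centroid_weight,
        )
    except (NoWavefrontError, ImplausibleSpeedError) as exc:
        logger.info("initial slope estimate failed (%s); scanning fallback grid", exc)

    trace_field = component.field if opts.trace_from_component else cropped
    try:
        trace = focal_trace(trace_field, geom, opts.focal_halfwidth)
    except SwetofError as exc:
        raise _tag(exc, "focal_trace")

    def _run(initial_speed: float) -> tuple[WavefrontSet, SWSEstimate, int]:
        predicted = predict_arrival_times(geom, initial_speed)
        cands = detect_candidates(
            trace,
            min_prominence=opts.min_prominence,
            exclude_before_ms=predicted[0] / 2.0,
            window_cap_ms=opts.window_cap_ms,
            weight=opts.centroid_weight,
            min_relative_amplitude=opts.min_relative_amplitude,
        )
        s1 = stage1_assign(cands, predicted)
        s2_set, s2_est = stage2_refine(cands, s1, geom, opts.k_alternatives)
        return s2_set, s2_est, len(cands)

    if initial is not None:
        try:
            wavefronts, estimate, n_cands = _run(initial)
        except SwetofError as exc:
            raise _tag(exc, "wavefront_selection")
    else:
        # Slope regression failed: anchor the initial estimate on the
        # strongest candidate packet instead.  The first side-boundary
        # reflection travels the shortest reflected path and dominates the
        # trace, so its arrival time t directly gives c ~ 2*d_1 / t.  The
        # direct push packet is excluded using the fastest speed the
        # fallback considers.
        lo_speed, hi_speed, _ = opts.fallback_grid
        first_path = 2.0 * geom.one_way_distances[0]
        try:
            anchor_cands = detect_candidates(
                trace,
                min_prominence=opts.min_prominence,
                exclude_before_ms=first_path / hi_speed / 2.0,
                window_cap_ms=opts.window_cap_ms,
                weight=opts.centroid_weight,
                min_relative_amplitude=opts.min_relative_amplitude,
            )
            anchor = max(anchor_cands, key=lambda cand: cand.peak_amplitude)
            initial = float(np.clip(first_path / anchor.centroid_time, lo_speed, hi_speed))
            wavefronts, estimate, n_cands = _run(initial)
        except SwetofError as exc:
            raise _tag(exc, "initial_estimate_fallback")
        flags.append("fallback_anchor")

    return replace(
        estimate,
        initial_estimate=initial,
        n_candidates_considered=n_cands,
        flags=tuple(flags),
    )
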