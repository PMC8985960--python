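# Methods

## The measurement model

A focused single-element transducer both pushes and listens. The acoustic
radiation force of a long tone burst (2000 cycles at 20 MHz, ≈ 0.1 ms)
generates a shear wave at the focus of a millimeter-sized hydrogel held in
a fixture that fixes the one-way focal-point-to-boundary distances of the
four vertical sample faces at d = (3.0, 6.2, 9.2, 12.0) mm. Each reflected
wave returns to the focus after travelling 2dᵢ, and the sample's shear-wave
speed is the mean of the four per-path speeds,

SWS = (1/4) Σᵢ 2dᵢ/tᵢ ,

an average of distance/time *ratios* (not total distance over total time):
averaging the paths suppresses the effect of a small transducer mounting
offset, which perturbs the four dᵢ in opposite directions.

Assumptions inherited from the measurement principle: the medium is
homogeneous and isotropic at the millimeter scale (one number per sample);
the axial propagation speed of the top-face reflection equals the lateral
SWS (isotropy again); boundaries are fixed and known; arrivals are
separable in time, which bounds the usable speed range from above for a
given fixture (see separability below).

Unit convention everywhere: depth and distances in mm, slow time in ms, so
speeds are directly in m/s (1 mm/ms = 1 m/s). Depth increases away from
the transducer face; slow time starts at the end of the push.

## Forward simulator

The estimator only ever observes the beam axis (M-mode), so the simulator
is an image-source construction on that line rather than a full
elastodynamic solver:

* **direct packet** with locus t = |z − z_f| / c and unit peak amplitude —
  the amplitude reference for everything else;
* **top/bottom-face reflections** of the axial wave, bands of slope
  ±1/c crossing the plot; default relative amplitude 0.15 (the ARF source
  radiates mainly laterally, so axial shear energy is weak);
* **four side-boundary reflections** via lateral image sources: on-axis
  arrival t(z) = √((2dᵢ)² + (z − z_f)²)/c, amplitude rᵢ/path^0.5
  (cylindrical spreading; reflection coefficients default to 0.6 for the
  gel–agarose buffer walls — both unmeasurable on the platform and exposed
  as parameters);
* optional second wall bounce (off by default) and optional
  distance-proportional Gaussian broadening as a viscosity proxy (off; no
  rheological model is fitted);
* additive white measurement noise, seeded; identical seed + parameters
  give bit-identical fields.

Each event is a Gaussian-enveloped single-cycle packet: envelope FWHM
`packet_width` = 1.3 ms with a carrier of one period per FWHM. At 1.5 m/s
that puts the dominant wavelength near 2 mm, the scale of ARF-generated
shear waves in soft hydrogels, and it keeps the slow-time signal band-pass,
which is what an analytic-signal envelope detector assumes. (A monopolar
packet's Hilbert envelope is skewed by its own DC content; with a carrier
the envelope is symmetric and centroid arrival times are unbiased.)

Geometry details: the container bottom is 15.8 mm from the transducer face;
the simulated sample height defaults to 6.5 mm (one of the phantom heights
used on the physical platform), which places the top-face echo's focal
crossing (9.4 mm two-way) mid-gap between the first and second side
reflections — heights that park face echoes on top of a boundary arrival
are genuinely harder for any estimator, in simulation as in the fixture.
A smooth support mask confines motion to the sample depth interval.

**Speckle RF synthesis.** Point scatterers drawn uniformly over the imaged
depth window (default focus −4.7…+2.2 mm, covering both the focal trace
and the slope-regression band) with circular-Gaussian amplitudes; each
frame's A-line is a sum of Gaussian-modulated sinusoids (20 MHz, 50 %
fractional bandwidth) at the scatterers' two-way delays. Scatterer depths
advance between frames by integrating the noise-free simulated velocity at
their rest depth; `velocity_scale` (default 5·10⁻³) maps the dimensionless
field to ≈ 1 µm peak displacement per frame — well inside the ±λ/4
unambiguous range of the phase estimator (λ/8 triggers a warning).
Electronic noise is white and relative to the first frame's peak RF.

What the generator does **not** emulate: resonant modes of the small
sample, mode conversion, nonlinear ARF magnitude, speckle decorrelation
from lateral motion, transducer bandwidth ripple, reverberation clutter in
the coupling medium. Passing tests therefore demonstrate the estimator's
correctness against the stated wave model, not robustness to every
real-transducer artifact.

## Estimation pipeline and its numerical choices

1. **Band-limiting.** Zero-phase 4th-order Butterworth low-pass along slow
   time, cutoff 1.4 kHz (the default packet's band edge: 0.77 kHz carrier
   plus envelope bandwidth); measurement noise is white to the 2.5 kHz
   Nyquist, so this buys SNR without moving arrival times. Skipped for
   records shorter than 40 frames.
2. **Crop.** ±2 mm in depth around the focus. The full recorded duration
   is kept by default (at 0.4 m/s the fourth reflection lands at 60 ms);
   a 40 ms window remains the standalone default of `crop_around_focus`
   for clutter-heavy data.
3. **Directional filter.** 2-D FFT quadrant masking with a raised-cosine
   taper (5 % of each axis' band); the two components sum exactly to the
   input, and the field is zero-padded 25 % per axis first so the circular
   FFT cannot wrap packet tails across edges. Down-going (away from
   transducer) selects the top-face reflection and removes the bottom-face
   band — important because the bottom echo (3.6 mm two-way) is the first
   side reflection's nearest neighbour on the trace.
4. **Initial estimate.** Per depth row of the down-going component, the
   arrival time is the envelope-energy centroid of the dominant packet;
   weighted least squares of arrival vs depth (weights = row peak energy,
   one re-weighted pass dropping > 2σ residuals) gives speed = |1/slope|.
   Numerical choices that matter: the slope uses its own wider crop
   (±4.5 mm) because the regression's accuracy at 0.2 ms slow-time
   sampling comes from the depth lever arm; rows within 1 mm of the focus
   are excluded (near the source the propagation direction is undefined,
   so direct-wave energy leaks into the down component) as are rows within
   0.5 mm of the crop edge (filter edge effects); the field is averaged
   over 0.3 mm in depth first (coherent gain for a sloped band). Fits with
   weighted R² < 0.25 are rejected — uncorrelated row arrivals are noise,
   not a wavefront. Speeds above 10 m/s or below 0.1 m/s are implausible
   on this platform and raise instead of propagating.
5. **Candidate detection.** Focal trace = down-component velocity averaged
   over ±0.5 mm around the focus. The direct push packet (t below half the
   first predicted arrival) is blanked *before* anything is measured, so
   its much larger amplitude neither sets the prominence scale nor leaks
   into the first reflection's window. Envelope peaks need prominence
   ≥ 0.1 × the (post-blanking) maximum; the trace must clear a
   detectability gate (max > 4 × median envelope — pure noise sits near 3)
   and candidates below 0.25 × the strongest candidate are dropped, since
   boundary reflections of one push differ only by geometric spreading
   (≈ ×2 across this fixture) while noise maxima sit far lower and can
   form accidentally self-consistent arrival families.
6. **Packet windows.** From each peak the window extends to the 20 %
   envelope falloff, capped at ±1.5 ms; it additionally stops at an
   envelope local minimum (a valley against a neighbouring packet). The
   valley stop is what keeps the top/bottom-face echoes from bleeding into
   side-boundary windows at high speeds, where inter-packet gaps shrink
   toward the packet width.
7. **Arrival times.** Time-to-centroid with energy weighting (squared
   envelope; amplitude weighting available). The centroid interpolates far
   below the 0.2 ms sample spacing, which time-to-peak cannot.
8. **Two-stage assignment.** Stage 1: boundaries in ascending order each
   take the unused candidate nearest their predicted arrival. Stage 2:
   exhaustive search over the per-boundary 3 nearest alternatives (≤ 3⁴
   combinations — no heuristic needed), discarding reuse and non-ascending
   sets, minimizing the population variance of the four per-path speeds;
   ties break toward the stage-1 times. The stage-1 set is in the search
   space, so the returned variance never exceeds it.
9. **Fallback.** If the slope stage fails, the initial speed is anchored
   on the strongest candidate: the first side reflection dominates the
   trace, so c ≈ 2d₁ / t_strongest (direct packet excluded using the
   fastest speed considered, 2 m/s). A plain variance-minimizing scan over
   initial speeds was tried and rejected: under noise it locks onto
   low-amplitude, accidentally proportional families of noise peaks at
   late times. Results carry a `fallback_anchor` flag.

Errors at every stage are typed and carry the stage name; a field of pure
noise raises `NoWavefrontError` rather than returning a number.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `one_way_distances` | 3.0, 6.2, 9.2, 12.0 | mm | fixture design; ≥ 3 mm increments separate arrivals up to ≈ 1.3 m/s at 5 kHz |
| `prf` / `n_frames` | 5000 / 400 | Hz / – | 0.2 ms slow-time step; 80 ms covers the slowest arrival (60 ms at 0.4 m/s) |
| `center_frequency` | 20 | MHz | tracking λ = 77 µm; phase ambiguity at λ/4 ≈ 19 µm |
| `rf_sampling_rate` | 100 | MHz | not printed on the physical platform; conventional 5 × f₀ |
| `compressional_sound_speed` | 1540 | m/s | not printed; soft-tissue convention, only scales the depth axis and λ |
| `packet_width` | 1.3 | ms | shear packet FWHM ⇒ ≈ 2 mm wavelength at 1.5 m/s |
| `reflection_coefficients` | 0.6 ×4 | – | gel–buffer walls, unmeasured, free parameter |
| `top_bottom_amplitude` | 0.15 | – | weak axial radiation of the lateral ARF source |
| `noise_sigma` | 0.05 | – | white noise as a fraction of the direct-packet peak |
| `lowpass_cutoff_khz` | 1.4 | kHz | shear band edge; `None` disables |
| `k_alternatives` | 3 | – | stage-2 pool per boundary (≤ 81 combinations) |
| `min_prominence` | 0.1 | – | of the strongest post-blanking envelope value |
| `min_relative_amplitude` | 0.25 | – | of the strongest candidate; rejects noise-peak families |

## Separability and accuracy, as measured here

On noise-free simulations with the default fixture the pipeline recovers
every speed on the 0.4–1.8 m/s grid within 0.3 % (per-path within 1.4 %),
so the measured separability limit of this simulator configuration is the
top of that grid; the fixture's stated design bound (≥ 3 mm increments for
≤ 1.3 m/s) is comfortably inside it. With white measurement noise at 10 %
of the direct-packet peak, ≥ 95 % of seeded replicates at 0.6/1.0/1.4 m/s
recover within 5 %, and the failures are loud errors, not wrong numbers.
These are exactly the quantities `tests/test_acceptance.py` asserts and
`scripts/acceptance.py` re-measures; no number in this note is computed
anywhere else.

## Known limitations

* The image-source model is kinematically exact on-axis but its amplitudes
  are phenomenological; amplitude-dependent conclusions (e.g. the 0.25
  relative-amplitude cut) should be revisited for media with strongly
  different wall impedance contrast.
* One SWS per sample: no spatial elasticity map, no viscoelastic
  dispersion inversion, no group-vs-phase velocity distinction.
* The slope stage assumes the top-face reflection is the dominant
  down-going energy above the focus; unusual sample heights that park a
  face echo on a side-boundary arrival degrade the initial estimate
  (the anchor fallback then carries the pipeline).
* Speckle tracking is 1-D and axial; lateral scatterer motion and
  decorrelation are not modeled, and the speckle Doppler bias (spectral
  centroid ≠ carrier for one realization) is a few percent on velocity
  *amplitude* — it cancels in arrival times and therefore in SWS.
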