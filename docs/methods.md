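# Methods

This note documents the models, defaults and numerical choices behind
slithertrack, and what its synthetic benchmarks do and do not establish
about real microscopy data.

## Evanescent-field model

The optics module treats the evanescent intensity as a pure exponential,
I(z) = I₀ exp(−z/d_p), with d_p = λ/(4π√(n₁² sin²θ − n₂²)). Near-field
emission effects, polarization and the objective's collection efficiency
are neglected. Angles are exposed in degrees and converted internally.
Defaults describe a 473-nm beam through 1.5255-index glass into
1.3635-index medium at 63.5° (d_p = 549 nm); all are configurable.

Depth inversion is z = z_ref − d_p ln(I/I₀) with z_ref = 10 nm, the
closest physical approach of a swimming cell to the wall: the brightest
possible head is *at* 10 nm, not 0. Intensities above the I₀ calibration
(noise) clamp to z_ref with a logged warning rather than returning
negative heights. Heads whose relative intensity falls below 0.1124
(≈ exp(−(1200−10)/549)) are treated as undetectable, reproducing a
~1.2-µm imaging range at the default d_p; the cutoff is a config field.

**I₀ calibration.** Two routes exist. (1) If a stack's metadata carries
`i0_mean_intensity` — synthetic stacks always record the expected mean
head intensity at z_ref — that value is used. (2) Otherwise I₀ is the
brightest background-corrected mean head intensity observed anywhere in
the dataset, a per-dataset (not per-cell) calibration justified by the
few-percent cell-to-cell uniformity of dye loading. Route 2 is only
unbiased when some cell actually reaches the closest approach during the
recording; short recordings of cells hovering high in the field will
underestimate I₀ and shift all heights down by a constant.

## Synthetic swimmers

`speed_um_s` is defined as the **in-plane curvilinear speed**: after the
lateral oscillations are laid onto the average path, the centre-path
progression speed is solved by a scalar root find (Brent) so that the xy
polyline arc length per unit time equals `speed_um_s` exactly at the
ground-truth sampling rate. Motility analysis measures VCL on the 2D
projection, so defining the generator speed in the projection makes
speed recovery an identity check of the kinematics stage instead of a
function of how much of the helix happens to point out of plane. A
consequence: a configuration whose lateral beat alone traces more path
per second than the requested speed is infeasible and raises an error.

Mode mechanics:

* **Bulk**: average path of constant signed curvature plus a rotating
  helical offset (radius `helix_radius_um`, frequency `roll_freq_hz`)
  whose lateral component adds to any planar yaw and whose vertical
  component sweeps z; apparent head area is modulated as
  `head_area · (1 − m sin²(roll phase))`. `head_area_um2` is the
  surface-aligned (maximum) area; the bulk preset (56 µm², m = 0.51)
  therefore averages ≈ 42 µm² with a 24% coefficient of variation —
  the printed statistics of rolling bulk heads. The modulation depth
  follows from CV = m·√(1/8)/(1 − m/2) = 0.24 ⇒ m ≈ 0.51.
* **Slither**: planar sinusoidal yaw about the average path; z is a
  bounded random walk in [0.01, 1] µm driven by an AR(1) velocity capped
  at `z_drift_speed_fraction · speed` (default 0.07 — out-of-plane drift
  is a few percent of the in-plane speed). Area noise is a correlated
  multiplicative process with CV 0.13, the printed aligned-head
  variability.
* **Switching**: alternating exponential dwells (defaults 1119 ms
  slither, 1500 ms off). The off-mode dwell is a free parameter chosen
  so the stationary slither occupancy 1119/2619 ≈ 0.43 sits near the
  observed ~39% slither fraction among near-wall cells. Transitions
  blend bulk and slither offsets with a 100-ms cosine ramp placed
  entirely on the off side, so every slither-labelled sample obeys the
  z < 1 µm confinement.

Preset speeds are the reported bull-sperm group means (bulk 176.0,
slither 74.7 µm/s). The slither yaw amplitude is 1.2 µm rather than the
amplitude implied by the reported ALH: the reported VCL, ALH and BCF are
mutually inconsistent with a pure sinusoidal head yaw (the implied
lateral path speed alone exceeds VCL), so the generator preserves VCL
and BCF (= 2 × beat frequency) and lets ALH fall where the geometry puts
it. Circling handedness is the sign of `path_curvature_per_um`; the
population generator draws counter-clockwise with probability 0.74.
Coordinates: x, y from the bottom-left corner of the field of view, z
normal to the glass, all views from below, so positive winding is
counter-clockwise both in image coordinates and in the biological
convention.

## Rendering

Heads are anisotropic Gaussian spots (default 1.6:1 aspect, long axis
along the instantaneous heading) with σ_a σ_b = area/(2π ln 2), so the
half-maximum ellipse area equals the apparent head area and the
integrated brightness is proportional to it. The peak amplitude is
`peak_brightness` (default 3000 counts) times the evanescent factor
exp(−(z − z_ref)/d_p) for TIRF; epifluorescence renders every head below
a 4-µm focal slab at full brightness with no defocus model. Camera noise
is background offset + Poisson shot noise + Gaussian read noise, applied
frame-wise; frames are 16-bit. The flagellum is not rendered: only the
head is tracked downstream, and tail photons would only matter for
segmentation robustness, which is not what the benchmark isolates.

What the generator does **not** emulate: resolved head shapes (real
heads are paddles, not Gaussians), flagellar waveforms, cell–cell
occlusion and collisions, photobleaching, defocus growth with z in the
epi channel, and sample drift. Passing recovery tests therefore shows
the measurement chain is correct for blob-like heads under the stated
noise, not that segmentation will survive every real-world artifact.

## Tracking

Stacks are background-corrected by per-pixel temporal median (≥3 frames;
otherwise per-frame rolling-ball). Detection thresholds the corrected
frame; the default policy is median + 8% of the median-to-max span of
the stack, chosen over Otsu because the evanescent decay spreads head
brightness over a factor of ~9 and a bimodal criterion can sit above the
dimmest legitimate heads (Otsu remains available). Components touching
the frame border are rejected (clipped blobs bias both centroid and
area). Per blob: area = pixel count of the region above half its own
peak (brightness-independent by construction), centroid =
intensity-weighted mean over that region, mean intensity = mean over
that region (∝ peak, the depth proxy).

Linking is greedy nearest-neighbour with a distance gate of
2 × (250 µm/s)/frame-rate — twice the per-frame displacement at a speed
ceiling comfortably above the fastest swimmers. Ties are broken by
(distance, track id, detection index); detections are sorted by position
within each frame, making linking deterministic and permutation
invariant. Gaps up to 2 frames are bridged by linear interpolation and
flagged; longer gaps split the track (episode statistics are sensitive
to spurious merges, so splitting is the safe failure). Track filtering
keeps tracks of ≥15 frames; the optional `complete` field-of-view policy
additionally requires a track to start and end near an edge or to
appear and disappear strictly inside the recording. Cells that leave and
re-enter the field start new tracks.

## Kinematics

The average path is a centred moving average with shrinking symmetric
windows at the ends (so its endpoints coincide with the raw track's).
The default window spans ~0.1 s of samples — about one flagellar beat,
5 frames at 50 Hz. Definitions: VCL = Σ|Δp|/T on the raw 2D path;
VAP = arc length of the average path / T; VSL = |p_N − p_0|/T;
LIN = 100·VSL/VCL; WOB = 100·VAP/VCL; MCR = mean Menger (three-point
circumscribed-circle) curvature magnitude on raw positions, collinear
triples contributing 0; ALH = mean |perpendicular deviation from the
average path|; BCF = sign changes of the signed deviation per unit time,
exact zeros carrying the previous sign.

ALH is the literal *time-average deviation*, not the 2×max convention of
some CASA instruments — absolute ALH values are ≈ 2/π times a sinusoidal
yaw amplitude and roughly a quarter of what a 2×max convention reports.
Circling uses the net winding of the average path with the first and
last half-window trimmed (the shrinking endpoint windows curl into the
raw beat and add spurious winding); |winding| < π/4 is "straight", a
threshold made explicit because real classifications are always CW/CCW.
Mode classification: slither requires ≥15 consecutive TIRF-visible
frames and area CV < 0.185 (midpoint of the 13%/24% regimes); near-wall
requires presence in the 4-µm slab; otherwise bulk. Episode durations
are (frames in run) × frame interval — unbiased for exponential dwells
sampled on a grid — and boundary-truncated episodes are kept, which is
negligible at the study sizes used. Group statistics use Welch's t-test,
the pooled two-proportion z-test and Pearson correlation, with 0.05
significance.

## Numerical and scale choices

Speed calibration brackets [0, speed] and expands geometrically before
Brent's method (tolerance 1e-10 relative). Test problem sizes are kept
desk-scale: single-swimmer recovery uses 10 s at 500 Hz (~5000 samples);
episode statistics use a few thousand episodes so that a 5% check on an
exponential mean (s.d. = mean) sits at ~3 standard errors; rendered
stacks are a few seconds of 100–200-µm fields at 50 Hz. The end-to-end
study in the test suite uses noise-free rendering for its tight recovery
bounds and a separate noisy run for robustness checks.

## Known limitations

* Greedy linking has no motion model; dense fields or crossing paths
  fragment or swap tracks (crowding is logged, not resolved).
* Max-intensity I₀ calibration biases z upward when no cell approaches
  the wall during the recording (see above).
* The epi channel has no depth information and a hard slab cutoff; mode
  classification of epi-only tracks can only distinguish near-wall from
  (assumed) bulk.
* MCR on noisy real tracks grows with sampling rate (three-point
  curvature amplifies jitter); on noise-free paths it is exact for
  circles at any sampling.
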