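# Methods

This note documents the models inside `motiongate`, the choices that were
genuinely open when they were made, and what the simulations do and do not
show about real camera-gated MRI.

## The phantom and its motion

The insect is modeled as four intensity-weighted ellipses — head, thorax,
abdomen and an internal feature inside the abdomen — on a 30 mm body frame.
Rendering is anti-aliased by 4×4 supersampling of each ellipse indicator, so
the image is exactly linear in segment intensities (a property the tests
exploit). The tracked keypoint sits on the posterior abdomen boundary,
10.2 mm behind the pivot at the thorax–abdomen junction.

Motion is rigid, in-plane and confined to the abdomen (and the feature it
contains); head and thorax are static. This mirrors the experimental regime
the method targets: gross body motion dominated by abdominal flexion, with
negligible thorax displacement and motion mainly constrained to the imaging
plane. Out-of-plane motion, leg motion and non-rigid deformation are
deliberately absent.

The flexion waveform had to be invented — "semi-periodic" constrains the
rhythm, not the shape. Each cycle is a rest (dwell) window followed by a
raised-cosine pulse rest → flexed → rest; per-cycle periods are
`base_period + N(0, jitter_sd)`, truncated at 0.1 × base period, drawn from a
seeded stream so a realisation is a pure function of the seed. The raised
cosine gives a three-phase appearance (rest / flexing / peak) and produces
keypoint trajectories with plateaus punctuated by excursions, the pattern a
behaving tethered insect shows. The dwell window returns the exact identity
transform, which is what makes "gate on the rest pose" a well-posed target.

Defaults (the study conditions, chosen once):

| parameter | default | why |
|---|---|---|
| angular amplitude | 20° | keypoint excursion ≈ 3.5 mm ≈ 15 camera px, large enough to ghost strongly |
| base period | 1.0 s | order of an insect's abdominal pumping cycle |
| period jitter sd | 0.15 s | visibly aperiodic but rhythmic |
| dwell fraction | 0.45 | the animal rests roughly half of each cycle |
| translation amplitude | (0.2, 0.1) mm | small non-rotational component |
| camera | 128×128 @ 30 Hz | 30 Hz is the camera's maximum frame rate |
| pixel pitch (benchmark unit conversion) | 44.6 µm/px | the ratio implied by paired px/µm error reporting (91/2.04) |

Coordinates: x along columns, y along rows (down), pixel-center based;
positive rotation turns +x toward +y. Bilinear interpolation everywhere;
out-of-bounds samples read 0.

## Lucas–Kanade tracking

The tracker is written from the constraint equation up: central-difference
spatial gradients (edge-replicated borders, so the border stencil matches the
interior), one-frame temporal differences, a window system `A v = b` sampled
bilinearly around the point, and the normal-equation solve
`v = (AᵀA)⁻¹Aᵀb`. The smallest eigenvalue of `AᵀA` gates the solve: below
`1e-4 ×` (window pixel count) the window is declared aperture-limited and no
flow is returned — for gating, a missed estimate closes the gate, which is
the safe failure.

The single linearised solve is only first-order, so `track_step` iterates:
warp the target window by the running displacement, re-solve, until the
update falls below 0.01 px or 10 iterations. A Gaussian-blur/decimate pyramid
(default 2 levels, 3 in the demo scenario) seeds large displacements; the
default 15×15 window is a standard sparse-LK size. Per-frame displacements in
the demo scenario reach ~3 px, comfortably inside this configuration's
convergence basin for the phantom's smooth structure.

Failure policy: divergence beyond the window span, border exit,
aperture-limited windows *and* non-convergence at the iteration cap all mark
the frame lost with the position frozen; subsequent frames retry from the
frozen point (no extrapolation). Freezing is conservative by design — a
wrongly extrapolated position could open the gate at the wrong pose.

Flow units are px/frame (one frame is the time unit); multiply by the frame
rate for px/s.

## Gating controller

Per frame: track; if lost, the gate is closed. If the tracked position is
within `tolerance_px` (Euclidean; an axis-wise mode exists but is off by
default) of the reference — by default the first frame's tracked position —
and the engine is idle, a trigger fires. The trigger reaches the scanner
after the modeled latency (default 43 ms, the end-to-end pipeline delay:
camera readout, flow computation, serial link, TTL), so the object is
sampled at `detect + latency`. One trigger releases exactly one shot; the
controller is then refractory for the shot duration (one TR, which also
enforces TR as the minimum shot spacing). Sessions end when all shots are
acquired or at `timeout_s`, in which case the k-space is returned zero-filled
and flagged incomplete.

Session duration is defined as the last fire time plus one shot duration.
The simulation clock advances by camera frame intervals, but fire times fall
between frames and the phantom is evaluated continuously there.

## k-space simulation

Inter-scan motion model: the object is frozen for one shot and moves between
shots. Each shot computes the 2D DFT of the instantaneous phantom at its
fire time and keeps that shot's phase-encode rows. For RARE factor 1 this is
exactly the inter-scan model; for RARE factor > 1 it additionally idealises
intra-train motion — a documented limitation, and the reason the gated
protocol modeled here uses RARE 1 (longer echo trains are the
motion-sensitive regime).

Phase-encode ordering is linear-interleaved by default (shot *s* takes lines
`{s, s+S, s+2S, …}`, `S` = shots per average); sequential block ordering is
available and is what makes the two-state alternating-motion construction
produce its textbook half-FOV ghost, verified against the closed form
`K = (K_A+K_B)/2 + (K_A−K_B)/2·(−1)^m`. `floor(n_pe / rare_factor)` shots
are acquired per average and remainder lines stay zero-filled — the one rule
consistent with all three protocol scan times (256 s, 128 s, 5115 s).
Reported in-plane resolutions use round-half-even (so 312.5 µm prints as
312).

No relaxation physics: proton-density contrast only, no T1/T2 weighting or
echo-train decay, no B0/B1 inhomogeneity, no slice profile, no noise unless
requested (circularly-symmetric complex Gaussian, seeded). k-space is stored
DC-centered (fftshift convention) with phase encoding along axis 0;
reconstruction is the magnitude of the inverse FFT.

## The simulation studies

The demo scenario images the phantom at 128×128 over 30 mm with TR 100 ms.
The TR is a desk-scale choice so that 20-seed studies finish in minutes; the
real protocols' TRs (1000–3000 ms) appear in the sequence calculators, which
are checked exactly. Gating physics is TR-invariant here because no
relaxation is modeled — only the ratio of motion timescale to shot cadence
matters, and the 1 s motion cycle vs 100 ms TR preserves the many-shots-per-
cycle regime of the real experiment.

- **Gating efficacy**: over 20 seeded motion realisations, median RMSE
  (gated, 2 px tolerance, 43 ms latency) vs median RMSE (ungated), both
  against the motion-free reference. Gating reduces the artifact level
  roughly 3–4×.
- **Tolerance sweep**: mean RMSE over common seeds is non-increasing as the
  tolerance shrinks over {∞, 8, 4, 2, 1} px — a tighter gate never hurts
  image quality (it only lengthens the session).
- **Latency cost**: under fast motion (0.35 s cycles, 18% dwell — a rest
  window of ~63 ms, comparable to the 43 ms latency) the gated RMSE with
  43 ms latency exceeds the zero-latency gated RMSE: motion during the
  trigger delay re-introduces inconsistent lines. This is the residual-
  ghosting mechanism of real gated acquisitions.
- **Tracking benchmark**: 100 camera frames with sensor noise sd 0.01,
  scored against the generator's ground truth (standing in for human
  annotation): ≈ 0.9 ± 1.3 px. The sd exceeds the mean because errors
  concentrate in the few fastest flexion frames.

## What passing these tests does not show

The phantom is smooth, high-contrast and noise-controlled; real video has
specular highlights, defocus, occlusion by legs and illumination drift, all
of which degrade optical flow in ways this generator does not emulate. Real
tracking error therefore cannot be inferred from the synthetic benchmark.
Likewise the simulator's artifact levels quantify the *mechanism* (motion-
inconsistent k-space lines), not absolute image quality on any scanner: SNR,
relaxation contrast and susceptibility effects are out of scope. The
latency is a single lumped constant; a real pipeline has jitter.

## Numerical details

- Warping and window sampling: bilinear (`scipy.ndimage.map_coordinates`,
  order 1); integer-pixel translations are exact array shifts.
- FFT conventions: `fftshift(fft2(ifftshift(·)))` and its inverse, so
  acquire → reconstruct is identity to 1e-9 on static objects and Parseval
  holds to 1e-9 relative.
- Sample standard deviation (n−1) in the error benchmark; a single pair
  reports sd 0. Lost frames are excluded and counted separately.
- All stochastic behavior (motion jitter, camera noise, measurement noise)
  derives from one master seed via `numpy.random.SeedSequence([master, i])`
  per subsystem, so runs are bit-reproducible and subsystems are
  decorrelated.
- Degenerate inputs: empty segment lists render zero images; zero-amplitude
  motion is the identity for all t; uniform windows are aperture-limited by
  definition; empty frame streams and mismatched shapes raise.
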