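# motiongate

A closed-loop in-silico testbed for **computer-vision-gated, motion-compensated
MRI** of a small behaving animal.

MRI acquires its data line by line in k-space, so any subject motion *between*
phase-encode lines makes the lines mutually inconsistent and produces ghosting
artifacts along the phase-encode direction. For a tethered insect walking on a
spherical treadmill the dominant motion is semi-periodic abdominal flexion;
between flexions the abdomen rests at a reproducible pose. Prospective gating
exploits this: a camera watches the animal, a markerless tracker follows a
keypoint on the posterior abdomen, and the scanner is triggered to acquire one
shot (one excitation and its echo train) only when the keypoint is within a
tolerance of a reference pose — analogous to respiratory triggering in
clinical MRI, but driven by optical tracking and needing no cross-calibration
between camera and scanner coordinates.

`motiongate` rebuilds that whole loop in software so the method can be
studied, stress-tested and taught without hardware:

- **`phantom`** — a segmented 2D insect phantom (head, thorax, abdomen,
  internal feature as intensity-weighted ellipses) whose abdomen flexes
  rigidly about the thorax–abdomen pivot with per-cycle period jitter;
  rendered both as camera video (with ground-truth keypoint positions) and as
  the instantaneous object seen by the scanner.
- **`optical_flow`** — single-keypoint Lucas–Kanade tracking implemented from
  the optical flow constraint equation `Ix·u + Iy·v + It = 0`: windowed
  least squares `v = (AᵀA)⁻¹Aᵀb` via the Moore–Penrose pseudoinverse, with a
  structure-tensor conditioning guard, iterative warping and an optional
  image pyramid.
- **`gating`** — the prospective trigger controller: Euclidean gate against
  the reference pose, modeled end-to-end system latency (default 43 ms),
  refractory period per shot, discrete-event session loop.
- **`mri`** — Cartesian RARE k-space simulator under the inter-scan motion
  model (object frozen within a shot, free to move between shots), FFT
  reconstruction, and sequence calculators (`scan_time`,
  `in_plane_resolution`, phase-encode scheduling).
- **`metrics`** — Euclidean tracking-error benchmark (mean ± sd in px and µm),
  artifact RMSE, ghost-to-signal ratio, intensity profiles.
- **`studies`** — canned multi-seed experiments: gated vs ungated imaging,
  gate-tolerance sweeps, latency-cost studies.

## Worked example

```python
from motiongate import studies, metrics, mri
from motiongate import phantom as ph

seq   = studies.demo_sequence()            # 128 x 128 over 30 mm, RARE 1, TR 100 ms
spec  = ph.default_phantom_spec()
model = studies.demo_motion(seed=3)        # 20 deg flexion, ~1 s cycles, 45% dwell
ref   = mri.reference_image(seq, spec)     # motion-free target

recon_u, *_          = studies.run_condition(seq, spec, model, gate=None, seed=3)
recon_g, _, log, _   = studies.run_condition(seq, spec, model,
                                             gate=studies.demo_gate(tolerance_px=2.0),
                                             seed=3)
print(f"ungated RMSE: {metrics.rmse(recon_u.magnitude, ref):.4f}")
print(f"gated   RMSE: {metrics.rmse(recon_g.magnitude, ref):.4f}")
print(f"shots: {log.shots_completed}/{log.shots_required}, "
      f"session {log.session_duration_s:.1f} s")
```

prints

```
ungated RMSE: 0.0800
gated   RMSE: 0.0265
shots: 128/128, session 21.1 s
```

Without gating, shots fire on the TR raster regardless of pose and the
abdomen's flexion scatters inconsistent lines through k-space: the RMSE
against the motion-free reference is 0.080 (phantom intensities are order 1).
With a 2 px gate the controller waits for the rest pose before releasing each
of the 128 shots; the artifact level drops ~3×, at the cost of a longer
session (21 s vs the 12.8 s minimum — the waiting time depends on the
animal's behavior). The synthetic tracking benchmark
(`studies.tracking_benchmark(n_frames=100, seed=0)`) scores the tracker
against the generator's ground truth: 0.93 ± 1.29 px on the default scenario.

A CLI mirrors the library for shell use:

```sh
motiongate phantom  --seed 1 --out stack/          # film the phantom
motiongate track    --frames stack/ --out traj.csv # Lucas–Kanade tracking
motiongate acquire  --gated --tolerance 2 --seed 1 --out gated/
motiongate report   --reference ref/ --condition gated gated/ --out figs/
```

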