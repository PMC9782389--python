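# Methods

This note documents the models, conventions and numerical choices behind
`imusep`, and what the synthetic world does and does not emulate.

## Conventions

Quaternions are scalar-first Hamilton quaternions. `q_A^B` is the
orientation of frame B relative to frame A: the columns of its rotation
matrix are B's axes expressed in A, coordinates map as `v_A = R(q_A^B) v_B`,
and frames chain by right-multiplication, `q_A^C = q_A^B ⊗ q_B^C`. Since
`q` and `−q` encode the same rotation, all comparisons use the smallest
angle `θ = 2·arccos|w| ∈ [0°, 180°]`, and series are made sign-continuous
(consecutive dot products ≥ 0) before averaging or differentiation.

Frames:

* **GRF** — camera global frame, Z up;
* **IRF** — the orientation filter's earth frame: Z up from gravity, X
  along the horizontal component of the magnetic field;
* **IMU-sf / RMC-sf** — sensor frame of the IMU / of the marker cluster;
  identical by construction of the rigid cluster;
* body frames follow ISB: X anterior, Y proximal/up, Z to the subject's
  right.

## Pipeline stages

**Sensor offset calibration.** Gyro bias is the channel mean over a
declared static window of the neutral trial; a single accelerometer scale
maps the static mean to one g; triad misalignment is loadable but not
estimated (a full multi-position calibration is out of scope — the
pipeline only needs compensated streams). The magnetometer is normalized
per sample; only its direction matters.

**Orientation filter.** The gradient-descent (MARG) filter integrates the
gyroscope and descends the jointly normalized gradient of the gravity +
earth-field objective, the field reference re-flattened to `(b_x, 0, b_z)`
every step; gain β = 0.043, first-order integration at 500 Hz.
Initialization is a TRIAD solution (gravity + horizontal field) on the
first second of the recording, which the protocol guarantees is static;
the first 5 s of every trial are excluded from all analysis windows as a
convergence margin. With β = 0 the filter reduces exactly to gyro
integration. A config switch disables the magnetometer term for
sensitivity studies. The analytic Jacobians were verified against a
numerical gradient of the objective.

**Marker frames.** Marker trajectories are low-pass filtered with a
fourth-order Butterworth at 8 Hz applied forward and backward (zero phase,
reflected end padding) — phase lag would corrupt sub-degree frame
comparisons. Cluster poses are per-sample least-squares rotations
(batched Kabsch SVD) from the cluster's local coordinates, in which the
IMU axes are the coordinate axes. Anatomical frames: pelvis from the
ASIS/PSIS markers (Z along RASIS−LASIS, X anterior in the marker plane);
thigh from the epicondyle midpoint toward the hip joint centre; shank from
the malleoli midpoint toward the epicondyle midpoint; the hip joint centre
is the Bell regression — fractions (−0.19, −0.30, ±0.36) of the inter-ASIS
distance from the ASIS midpoint, expressed in the pelvic frame. The
regression constants are arguments of one function and can be overridden;
leg length is carried for validation only. Gap filling is refused, not
emulated: NaN samples raise an error naming the marker and span.

**Sensor-body calibration (A/B/C).** The longitudinal (Y) axis is the unit
mean accelerometer direction in a static neutral pose (gravity-parallel
assumption). The flexion (Z) axis is the dominant rotation axis of a
sagittal-plane movement: gyro samples with |ω| ≥ 0.5 rad/s, unit
directions sign-aligned to the dominant direction, magnitude-weighted
mean, longitudinal component projected out. The sign is fixed by protocol
knowledge — a table of the initial rotation direction of each segment
about its own +Z for each calibration movement (e.g. during a squat the
thighs rotate +Z, the shanks and pelvis −Z), evaluated on the first
above-threshold movement stroke. Movements: A = bow (pelvis) + thigh
rises (thighs/shanks), B = squat, C = inclined plank; which window feeds
which segment comes from the trial manifest, not from automatic
segmentation.

**Hand-eye calibration.** GRF and IRF share the gravity vertical, so the
unknown is one heading angle, measured from a static marker-instrumented
compass aligned with magnetic north: a pure yaw mapping the IRF +X
(magnetic north) onto the measured compass heading, averaged over the full
trial.

**Static-trial alignment.** The marker-calibrated body frames are
`q_AL^sensor = normalize( (1/n) Σ_t qrel(q_t,GRF^AL, q_t,GRF^sensor) )` —
the literal arithmetic time average with sign continuity enforced first,
renormalized. In the static-trial regime (dispersion well below 30°) this
agrees with the Markley eigenvector average to far better than 0.1°; the
eigenvector method serves as a test oracle only. Downstream the sensor
series is right-multiplied by the **inverse** of this constant, which is
the unique reading under which the marker-calibrated sensor frames
coincide with the anatomical frame during the static trial and the
filter/STA comparisons measure what they claim to.

**Synchronization and down-sampling.** The integer-sample lag (250 Hz)
maximizing the cross-correlation between the down-sampled gyro magnitude
and the angular-rate magnitude differentiated from the cluster series is
applied before keeping every second filter sample; the residual phase
error of nearest-sample alignment is at most half the 250 Hz period,
0.002 s.

**Comparisons and aggregation.** Per segment and trial, the nine pairings
of the six frames are compared by the per-sample smallest angle; RMSD and
maximum are computed over the manifest's analysis window only. The
frame-definition comparisons (#1–3) share the time-varying factor on both
sides and are therefore constant in time by construction; this constancy
(< 1e−6°) is asserted as a self-check. Aggregation is repetition mean per
subject, then cross-subject mean and sample STD (n−1); a single-subject
group reports STD 0 with a flag.

## The synthetic world

The generator produces, at 500 Hz (markers subsampled to 250 Hz), a
five-segment kinematic chain: pelvis with the hips at the Bell offsets
(inter-ASIS 240 mm), 420 mm thighs, 430 mm shanks. Landmark geometry is
constructed so the ISB marker frames coincide exactly with the bone frames
in the neutral pose — ground truth is then unambiguous. Movement families
are parametric profiles (C¹ ramps, bumps and Hermite segments), not
biomechanical simulations: they supply realistic amplitudes, cadences,
frequency content and impacts, not physiological fidelity. Squat-family
movements anchor the feet (the pelvis translates so the mean ankle stays
put); squat jumps have a true free-fall flight phase (specific force ≈ 0)
with Hermite push-off/landing blends; gait is antiphase hip/knee
oscillation with footstrike impacts; kicks have a stance-leg plant and a
ball-contact impact at peak swing velocity. All amplitudes scale linearly
with the intensity fraction, so intensity 0 is a static pose.

Injected errors:

* **STA** — `skin_t = bone_t ⊗ δ_t`, with δ a rotation about a fixed
  per-segment random axis, angle = 0.08 × the flexion of the nearest joint
  (knee for thigh/shank sensors, lumbar≈2×pelvic tilt for the pelvis) plus
  an exponentially damped 15 Hz oscillation (τ = 0.05 s, 4° scale) at
  impacts. Landmark markers ride the bone, cluster markers the skin, so
  the relative artefact between the marker groups equals the injected STA
  exactly — the ideal-case reading of using bony-landmark frames as the
  bone proxy. (A marker-noise option perturbs both.)
* **Body-frame definition error** — calibration-trial kinematics are
  composed on the right with the inverse of a rotation about the segment's
  longitudinal axis (default 15°): the subject executes the calibration
  movement in a plane rotated about the vertical, which leaves the static
  (gravity) step untouched and biases the functional axis by exactly the
  injected angle. Axial rotation is precisely the component functional
  calibration is least able to observe, which makes this the natural
  realization of a constant frame error.
* **IMU imperfections** — per-subject constant gyro bias (σ = 0.005 rad/s
  per axis), white noise (gyro 0.002 rad/s, accel 0.03 m/s², mag 0.005 of
  a unit field), and an optional local dipole added to the homogeneous
  earth field (declination 20°, dip 60°). IMU signals are derived from the
  poses by five-point finite differences (angular rate from the quaternion
  derivative, specific force from the sensor-position second derivative);
  integrating the emitted gyro reproduces the emitted orientation to
  better than 0.1° over a trial.

What passing tests on this world do **not** show about real data: STA here
is a single-axis, deterministically flexion-coupled rotation, whereas real
STA is translational as well, multi-axial and subject-specific; marker
gaps, relabeling and camera-volume effects are absent; the magnetic
environment is homogeneous unless a dipole is configured; and movement
execution variability between repetitions is not modelled (repetitions
differ only through sensor noise draws).

## Numerical choices and problem sizes

Trials are 8–15 s with a 6 s static lead-in; verification datasets use one
subject and one repetition per movement, which keeps a full nine-trial
decomposition under a minute on one core while leaving every stage
(calibration movements included) dynamically excited. The null
(zero-error) pipeline check uses the static-pose limit of the squat
(intensity 0): with any appreciable movement the filter's genuine,
correctly-implemented response to linear acceleration — a biased,
centripetal disturbance of the gravity reference — contributes on the
order of 1° to the filter-error comparison, which is a measured physical
effect, not a composition error; the null check is meant to bound the
algebra of the calibration/composition chain, and in that regime the
residual is ~0.004°, dominated by numerical integration. Degenerate
inputs (collinear axes, vertical compass, empty series, non-static
windows, missing frames) raise typed exceptions rather than producing
numbers. Determinism: a single integer seed fixes every random draw;
re-running any stage on the same inputs is bit-identical.

## Known limitations

The functional-axis estimator is the simplest consistent with a
sagittal-plane movement (magnitude-weighted mean of sign-aligned unit
rates); principal-component variants would differ at the tenth-degree
level on clean data and more under heavy STA. The arithmetic quaternion
mean degrades beyond ~30° dispersion (warned, not corrected). The filter
is deliberately unaided — no acceleration rejection, no adaptive gain, no
magnetic-disturbance gating — because quantifying the unaided error is the
point; numbers from this pipeline are upper bounds relative to filters
that apply such error-reduction techniques. C3D ingestion is not
implemented; marker data enters via the documented CSV dialect.
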