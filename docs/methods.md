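# Methods

## Physical model and geometry

The electrode plane is modelled as a 2D disc of radius R = 0.10 m with a
piecewise-constant conductivity field on a triangulated mesh. The
electrostatic approximation ∇·(σ∇u) = 0 is solved with linear (P1) finite
elements; current (default 1 mA) is injected at the two drive-electrode
boundary nodes (point/gap electrode model) and the potential gauge is
fixed by grounding the centre node, which never carries an electrode.
Differential voltages between adjacent electrode pairs are
gauge-independent. The point-electrode model is deliberate: the
reconstruction assumes a plain homogeneous circular model, and
contact-impedance modelling (complete electrode model) is out of scope.

Meshing is structured: nodes on concentric rings (alternate rings offset
by half an angular step), Delaunay-triangulated. The outer ring has a
multiple of 16 nodes (at least 32) with a node exactly at angle 0, so the
16 electrodes sit exactly 22.5° apart, counterclockwise from angle 0.
Electrode numbering is 0-based in memory and 1-based in every file
format.

Two meshes are used throughout: a generator ("forward") mesh of ~1600
elements and an independent reconstruction ("inverse") mesh of ~400
elements. Simulating on a ~4× finer mesh than the one the inverse
operator is built on avoids the inverse crime; the localization tests
hold under this mismatch.

## Acquisition scenario

Defaults encode the monitored-hemothorax study conditions:

| parameter | default | unit | note |
|---|---|---|---|
| baseline duration | 300 | s | pre-injection control window |
| injection | 60 ml at 600 ml/h | | 360 s of injection |
| ventilation | 25 | cycles/min | ≈ 0.4167 Hz |
| lung resistivity | 3.82 (deflated) – 9.74 (inflated) | Ω·m | sinusoidal swing, cosine phase, t = 0 at end-expiration |
| blood resistivity | 1.43 | Ω·m | overrides the underlying tissue |
| background conductivity | 0.3 | S/m | soft-tissue order of magnitude at ~100 kHz; not a study-reported value |
| drive current | 1 | mA | |
| frame rate | 10 (default), 2 in long-running tests | frames/s | device class supports up to 12 |
| noise | 1e-3 | relative | zero-mean Gaussian, σ = noise × \|clean voltage\|, independent per channel and frame |

The two lungs are ellipses (semi-axes 0.32R × 0.55R, centres ±0.5R on the
x-axis). The blood pool is a disc centred at 0.75R along the 101.25°
direction — the boundary between electrodes 5 and 6, the puncture site —
whose radius follows the injected volume through an equivalent-area map
r = √(V/(πh)) with slab thickness h = 0.05 m (the effective electrode-band
height). Elements are assigned to a region by centroid membership, so the
blood area is quantized at the element scale; at the default forward mesh
the 60 ml disc covers ~65 elements. Conductivities are real-valued
(quasi-static approximation); cardiac signals, 3D current spreading,
electrode motion and coagulation geometry are not modelled. Passing tests
on this generator therefore demonstrate correctness of the *analysis
chain* under its stated assumptions, not robustness to the contact-
impedance drift, shape mismatch and movement artifacts of real thoracic
recordings.

## Signal separation

Each channel is split into an injection (hemorrhage) component — the
output of a low-pass Butterworth filter of order 4 with −3 dB cutoff
0.15 Hz — and a respiratory component defined as the exact remainder, so
raw = injection + respiration holds elementwise by construction. The
filter is applied forward–backward (zero phase) so the filtered RIV stays
time-aligned with the injection; the effective magnitude response is
squared, attenuating the 0.4167 Hz respiratory line by roughly a factor
4×10⁻⁴ in amplitude. Edges use reflect padding of length 3·fs/cutoff
samples, which suppresses startup transients but leaves a residual
asymmetry of order 10⁻³ relative to signal scale — visible only in the
symmetric-pulse test tolerance. Series must be longer than the padding;
shorter inputs are rejected.

The wording of the filter specification is ambiguous between a stop-band
edge and a cutoff at 0.15 Hz; the −3 dB cutoff interpretation (the
standard design parameter) is implemented, and whether the original
filter was run zero-phase is unstated — zero-phase is this package's own
choice for unbiased timing.

## Reconstruction

The sensitivity matrix S (192 channels × M elements) is the exact
derivative of the discrete forward map at a homogeneous background:
dv_c/dσ_e = −area_e · ∇u_drive·∇w_meas, with w the unit-current adjoint
solution of the measurement pair. Finite differences reproduce sampled
entries to ~10⁻⁸ relative. For imaging, rows are normalized by the
homogeneous-model channel voltages so that B acts on the dimensionless
normalized difference Δv = (v_t − v_ref)/v_ref. The damped-least-squares
operator uses λ = 0.1 with L = diag(SᵀS) (fixed; L-curve selection is
exposed only as a parameter override). B·Δv estimates the conductivity
change, and the stored image is its negation so that a conductive blood
pool reads as a negative impedance change; this sign convention is
recorded on the image objects rather than assumed universal.

The reference voltage vector is the per-channel mean of the injection
component over the final 60 s of the baseline window — averaging
suppresses residual noise; how the original reference frame was chosen is
not documented, so this is a package design choice. Normalization is
refused (with the offending channels listed) when any |v_ref| falls below
10⁻⁶ × median|v_ref|, since the normalized difference is undefined at
zero and opposite-drive geometries can produce small channels.

## ROI, RIV and statistics

The ROI threshold is applied to the hemorrhage-signed magnitude (−Δρ):
Ω = {e : −Δρ_e > 0.1 · max(−Δρ)}. Applying the 10% rule to signed values
would select the wrong region under this sign convention. By default the
ROI is derived once from the final (largest-bleed) image and frozen for
the whole trajectory — one ROI per subject — with a per-frame policy as an
option. An image with no negative element raises a no-anomaly error; the
pipeline also refuses frame series whose metadata contains no
injection-phase frames, since volumes to regress against do not exist.

RIV = Σ_Ω Δρ·area / Σ_all area. Group comparisons use one-way ANOVA over
{baseline, 10, …, 60 ml} groups (baseline = all pre-injection frames;
each volume group = frames within ±30 s of the milestone) with Tukey HSD
post hoc against baseline at α = 0.05 — the original post hoc procedure is
unspecified, Tukey is this package's choice. Degenerate ANOVA inputs with
zero between-group variation return F = 0, p = 1 explicitly. The
RIV–volume relationship over the injection phase is fit by ordinary least
squares; for a simple regression the slope t test equals the model F
test, so `linregress`'s p value is reported as the F-test p.

RIV samples within a group are autocorrelated after low-pass filtering,
which inflates the nominal significance of the group tests; the detection
procedure therefore reports *detection rates over independent replicates*
rather than single p values.

## Detection floor

`minimal_detectable_volume` simulates, per candidate volume, short runs
(60 s baseline + injection to the candidate at 600 ml/h, 2 frames/s,
default noise) with independent sub-seeds, runs the full pipeline, and
Tukey-compares baseline-window RIV against the final 20 s of injection.
A volume is detectable when adjusted p < 0.05 in ≥ 80% of ≥ 20
replicates; the smallest detectable candidate is returned (NaN if none).

## Numerical choices and problem sizes

- Forward solves use a sparse LU factorization per frame (~900 unknowns,
  16 right-hand sides); a full 11-minute scenario at 2 frames/s
  (1321 frames) simulates in a few seconds.
- Long-running suites use 2 frames/s and the 1600/400-element mesh pair;
  the spectral test uses 10 frames/s over a 2-minute baseline so the
  respiratory line is resolved to ~0.008 Hz bins.
- Reconstruction solves the damped normal equations with a symmetric
  positive-definite dense solve (M ≈ 400); a zero diagonal in diag(SᵀS)
  raises an error naming the invisible element.
- Mesh areas always sum to the inscribed-polygon area of the outer ring,
  kept within 2% of πR² by requiring ≥ 32 boundary nodes.
- CSV artifacts are written with 17 significant digits and parsed in
  round-trip mode, so write→read is bit-exact.

## Known limitations

2D circular geometry with point electrodes; no contact impedance, cardiac
band, or electrode-fault modelling; single circular blood pool; RIV is
reported in dimensionless normalized-image units with no absolute Ω·m
calibration (difference imaging). The in-vivo effect sizes and per-subject
variability of real animals are outside what the generator emulates, so
quantitative agreement with any particular recording is not claimed —
only the structural behaviour of the method (spectral separation,
linearity, localization, detection floor) is validated.
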