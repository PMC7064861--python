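# hemoeit

Thoracic electrical impedance tomography (EIT) for real-time detection and
monitoring of hemothorax — blood accumulating in the pleural cavity.

Blood (resistivity 1.43 Ω·m) is far more conductive than lung tissue
(3.82 Ω·m deflated, 9.74 Ω·m inflated), so a growing intrapleural blood
pool produces a localized impedance *reduction* that surface-electrode EIT
can track continuously at the bedside. `hemoeit` implements the full chain
for a 16-electrode belt with opposite current excitation (1 mA) and
adjacent voltage measurement:

1. **Synthetic acquisition** — a P1 finite-element solver for
   ∇·(σ∇u) = 0 on a 2D disc generates boundary-voltage frames for a
   scenario with ventilation at 25 cycles/min, blood injected at 600 ml/h
   up to 60 ml after a 5 min baseline, and multiplicative Gaussian noise
   (default 1‰, the device accuracy class). Measurement pairs containing a
   driving electrode are discarded, leaving 16 × 12 = 192 channels.
2. **Signal separation** — respiration is periodic (~0.4 Hz) while a bleed
   drifts monotonically, so a zero-phase 4th-order low-pass Butterworth
   filter (−3 dB at 0.15 Hz) extracts the hemorrhage component per channel;
   the respiratory component is the exact remainder. Total boundary voltage
   TBV = Σ|vᵢⱼ| and its percent variation TBVV summarize the frames.
3. **Difference imaging** — damped least squares on a homogeneous circular
   model:

   Δρ = [SᵀS + λ·diag(SᵀS)]⁻¹ Sᵀ · Δv = B·Δv,  λ = 0.1,

   with S the adjoint-method sensitivity matrix and
   Δv = (v_t − v_ref)/v_ref the normalized voltage difference against a
   baseline reference. Conductive (blood) anomalies appear as negative Δρ.
4. **Quantification** — the region of interest is every element whose
   hemorrhage-signed value exceeds 10% of the maximum; the regional
   impedance variation

   RIV = Σ_{Ω} Δρ·S_Ω / Σ_{Γ} S_Γ

   (area-weighted ROI sum over total imaging area) is compared across
   injected-volume groups with one-way ANOVA + Tukey HSD and regressed
   against injected volume (OLS with F test).

## Worked example

```python
from hemoeit import Scenario, simulate, analyze_frames
from hemoeit.mesh import build_circular_mesh, make_protocol

protocol = make_protocol()
forward_mesh = build_circular_mesh(0.10, 1600)   # generator mesh
inverse_mesh = build_circular_mesh(0.10, 400)    # reconstruction mesh

frames = simulate(Scenario(frame_rate_hz=2.0, seed=1), forward_mesh, protocol)
result = analyze_frames(frames, inverse_mesh)
print(f"slope {result.regression.slope:.3e} /ml  "
      f"R^2 {result.regression.r_squared:.3f}  "
      f"10 ml vs baseline p = {result.groups.posthoc_p['10 ml']:.3g}")
```

prints

```
slope -1.644e-04 /ml  R^2 0.993  10 ml vs baseline p = 0
```

i.e. RIV falls essentially linearly as blood accumulates (R² = 0.993 for
this seed), and the RIV of the 10 ml group is already overwhelmingly
separated from baseline. The same pipeline is available from the shell:

```
hemoeit simulate --out frames.csv --seed 1
hemoeit analyze frames.csv --out-dir results/
hemoeit detect-threshold --volumes 5,10,20 --replicates 20
```

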