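# mpbnssfp

Quantitative MRI parameter mapping with the transient-state **MP-b-nSSFP**
sequence: a balanced SSFP pulse train operated far from steady state, whose
signal evolution simultaneously encodes T1, T2, off-resonance (B0), the
transmit field (B1), and complex apparent proton density.

The toolkit is aimed at MR-physics researchers who want a self-contained,
simulation-backed implementation of the full chain — sequence model, Bloch
simulation, undersampled spiral acquisition, subspace-constrained
reconstruction with B0 compensation, and dictionary-matching parameter
estimation — runnable end to end on a synthetic digital phantom without
scanner data.

## The method

The sequence repeats an optimized block of four RF pulses
(30°x, 175°y, 30°y, 175°x) at TRp = 30 ms, with a balanced spiral readout
after every pulse.  Twelve blocks give a 1440 ms train with
n_q = 48 *contrasts*, followed by a 3000 ms recovery delay.  Per voxel the
echo-state signal series M(θ) is a Bloch-simulated function of
θ = (Re I₀, Im I₀, T1, T2, Δ, B1).

With extended (22 ms) spiral readouts, off-resonance Δ accrues the
within-readout phase e^(−i2πΔτ_p), so the sample model is

    Y[q,c,p] = Σ_v C[c,v] · M[q,v] · e^(−i2πΔ_v τ_p) · F[q,p,v] + noise,

with coil sensitivities C and the per-contrast non-uniform Fourier operator
F of a golden-ratio-scheduled stack-of-spirals trajectory.  Two truncated
SVDs make the inverse problem tractable:

* a **contrast subspace** U (d₁ = 12) of the simulated signal dictionary,
  M ≈ U S Vᴴ, so only d₁ component images σ are reconstructed
  (subspace-constrained reconstruction, SCR), and
* a **phase subspace** Ũ S̃ Ṽᴴ (rank d₂) of the within-readout phase
  factors e^(−i2πΔ_v τ_p), which folds B0 compensation into the forward
  model at d₂ × the cost of an uncompensated reconstruction.

Both least-squares problems (per-contrast SENSE and joint SCR) are solved
by conjugate gradient on the normal equations with radial density
weighting.  Because the echo-state signal is periodic in Δ with period
1/TRp (33.33 Hz), the fitted Δ map is *wrapped*; the pipeline therefore
runs two passes: uncompensated SCR → dictionary fit → wrapped Δ map →
quality-guided spatial unwrapping → B0-compensated SCR → final fit.
Parameters are estimated per voxel by maximizing the normalized
correlation |⟨d, y⟩|/‖d‖ over a T1/T2/Δ/B1 grid (T1, T2 log-spaced in
100–2500 ms / 20–300 ms) and refined off-grid by iterated quadratic
interpolation; I₀ is the complex projection coefficient onto the matched
atom.

Dictionaries come in two fidelities: **Si** (single spin per voxel,
instantaneous pulses) and **Mu** (an ensemble of sub-spins across 1.8× the
excited slab, propagated through the time-discretized selective RF
envelopes, with balanced z-encode separation by inverse Fourier
transform), which captures the position-dependent inversion efficiency of
short slab-selective pulses.

## Worked example

Reconstruct and fit the 32×32 four-tube digital phantom, undersampled at
acceleration 16/3 (3 spiral interleaves per contrast) with the two-pass
B0-compensated subspace reconstruction:

```python
import numpy as np
from mpbnssfp import PipelineConfig, run_pipeline, tube_rois
from mpbnssfp.config import ReconConfig, SamplingConfig

cfg = PipelineConfig(recon=ReconConfig(method="scr-b0", max_iter=60),
                     sampling=SamplingConfig(acceleration=16 / 3),
                     seed=1, out_dir="maps")
out = run_pipeline(cfg)

nominal = {"t1": (300, 600, 1000, 1500), "t2": (50, 80, 120, 200)}
for i, roi in enumerate(tube_rois((32, 32))):
    print(f"tube {i}: T1 = {np.nanmean(out['maps']['t1'][roi]):6.0f} ms "
          f"(nominal {nominal['t1'][i]:4d}), "
          f"T2 = {np.nanmean(out['maps']['t2'][roi]):5.1f} ms "
          f"(nominal {nominal['t2'][i]:3d})")
```

Output (about a minute on one CPU):

```
tube 0: T1 =    302 ms (nominal  300), T2 =  48.7 ms (nominal  50)
tube 1: T1 =    583 ms (nominal  600), T2 =  82.7 ms (nominal  80)
tube 2: T1 =   1017 ms (nominal 1000), T2 = 116.6 ms (nominal 120)
tube 3: T1 =   1556 ms (nominal 1500), T2 = 202.5 ms (nominal 200)
```

The tube-ROI means recover the nominal relaxation times within a few
percent at 5.33-fold in-plane undersampling; `maps/` receives the fitted
T1/T2/Δ/B1/|I₀| maps as NIfTI volumes plus a provenance log.  The same
pipeline is available from the shell:

```
mpbnssfp pipeline --config config.yaml --seed 1 --out-dir maps
```

with subcommands `phantom`, `dict`, `synth`, `recon`, `fit` for the
individual stages (see `mpbnssfp --help`).

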