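# Methods

This note documents the models, numerical choices, and limitations of the
toolkit, in the spirit of a methods appendix.

## Sequence and signal model

The pulse train repeats a block of four RF pulses — 30°x, 175°y, 30°y,
175°x — at an inter-pulse time TRp (default 30 ms), with a balanced
readout after every pulse.  The default 3D protocol uses 12 blocks
(48 contrasts, 1440 ms) followed by a 3000 ms recovery delay, so roughly
67% of each repetition is dead time.  The transient response of this
train, starting from thermal equilibrium, is what encodes the tissue
parameters; no steady state is ever reached.

The magnetization *state* M(q) of contrast q is defined at a fixed offset
after each pulse center (`readout_start_offset`, default 2 ms), the
instant of the first readout sample; within-readout time offsets τ count
from there (τ₁ = 0).  The echo timing inside TRp is not independently
constrained — only consistency between the synthesizer, the
reconstruction, and the dictionary matters, since the constant phase
e^(−i2πΔ·offset) is absorbed into complex I₀.

Off-resonance convention: positive Δ in Hz accrues transverse phase
e^(−i2πΔt) (left-handed), matching the within-readout factor e^(−iΔτ) of
the sample model.  Equilibrium magnetization is normalized to 1; apparent
proton density is a purely multiplicative complex factor on the recorded
transverse signal, which is why matching can be made scale-invariant.

Within-readout relaxation is neglected: the extended-readout model applies
only the Δ phase during the readout.  This is a fidelity limit shared by
synthesis and reconstruction, so it cannot be detected by the internal
consistency tests; against real data it would appear as T2* blurring.

## Bloch simulation

Two modes:

* **Si** — one isochromat per voxel, instantaneous rotations at the pulse
  centers, closed-form relaxation/precession between pulses.  Used for
  dictionary grids (vectorized over atoms).
* **Mu** — sub-spins on a uniform lattice spanning `slab_factor` (1.8)
  times the slab width.  Selective pulses are windowed-sinc surrogates
  (time-bandwidth 16 by default) for the scanner's SLR designs; they are
  played through a hard-pulse decomposition in which no sub-step rotates
  more than `hard_pulse_max_deg` (2°) at the largest B1 on the grid, with
  the slice-select gradient entering as a position-dependent off-resonance
  and symmetric rephasing lobes keeping the net gradient moment per TR at
  zero.  One simulation yields all balanced z-encodes: the encode phase
  e^(−i2πk_z z) is applied per sub-spin and an inverse DFT across encodes
  separates the per-slice series.  With non-selective pulses every
  sub-spin sees an identical history, so the implementation short-circuits
  to the Si path and the two modes agree exactly — this identity is used
  as a consistency oracle in the tests.

Production-scale ensembles (5000 sub-spins, 44 z-encodes) are
configuration values; the desk-scale default is 64 sub-spins and 8
z-encodes, which reproduces the slab-profile phenomenology (inversion
efficiency falling toward the slab edges, slice-dependent signal
evolution) at CI cost.

The Si simulator is verified against a brute-force fixed-step (10 µs)
Bloch integrator to ~1e−12 relative RMS.

## Dictionaries, subspaces, matching

The default grid is T1 log-spaced in 100–2500 ms, T2 log-spaced in
20–300 ms (combinations with T2 > T1 excluded on physical grounds), Δ
linear, B1 linear in 0.8–1.2.  The contrast subspace is the SVD of the
(n_q × n_atoms) signal matrix truncated to d₁ = 12, computed via the
small n_q × n_q Gram matrix.

**Δ aliasing.** The echo-state series is exactly periodic in Δ with
period 1/TRp = 33.33 Hz (instantaneous pulses; the residual readout-offset
phase is absorbed by I₀).  A Δ axis spanning ±200 Hz with 50 Hz steps
therefore contains exact duplicate atoms.  Such wide axes are fine for
subspace construction but ill-posed for matching, so all *fitting* grids
restrict Δ to a single wrap band, half-open — (−16.67, +16.67] Hz at
TRp 30 ms — because the two band edges alias onto each other.  This is
precisely why the first-pass B0 map is wrapped and a spatial unwrapping
step exists.

**Matching.** The winning atom maximizes |⟨d, y⟩|/‖d‖.  When a contrast
subspace is supplied the argmax search runs in the compressed d₁ domain
(exact for series in span(U), the standard accurate approximation
otherwise); near-duplicate neighbors can swap under compression, which the
subsequent refinement re-resolves with full-length metrics.

**Refinement.** A single coordinate-wise parabola fit at the winning node
proved insufficient: the match metric has shallow curved ridges coupling
T2–B1 and T1–B1 (at an off-node B1 the best grid atom sits at a visibly
wrong T2/T1), and a one-shot vertex cannot cross them.  The implemented
refinement is an iterated quadratic-interpolation coordinate descent:
directions are the four parameter axes plus the degenerate-pair diagonals
(T1±B1, T2±B1, T1±T2); each direction is probed at ± one grid step with
re-simulated atoms, a parabola proposes a vertex, and the best candidate
is kept; four full-step "walk" sweeps let the estimate travel along
ridges, then three halving sweeps give sub-grid precision.  T1/T2 move
multiplicatively (log axes).  On noiseless off-grid parameters this
recovers T1/T2 with ~0.1% median error; isolated voxels deep on the T1–B1
ridge can remain several percent off, an identifiability property of the
sequence rather than of the optimizer.  The single-pass parabola
(`interpolate_refine`) remains available.  I₀ is re-estimated at the final
point as ⟨d, y⟩/⟨d, d⟩.

## Trajectory, schedule, NUFFT

The stack-of-spirals design is fully sampled along z, so slices decouple
after an inverse FFT along the slice axis and everything in-plane is 2D.
The in-plane interleave is a constant-density Archimedean spiral-out
reaching k_max = matrix/2 cycles/FOV at the end of the readout, with the
turn count chosen so the complete n_s = 16-arm design exactly meets
Nyquist radially; the analytic form stands in for the scanner's
slew-limited waveform.

The golden-ratio undersampling schedule rotates the interleave set per
contrast by round(q·frac(2φ)·n_s) mod n_s and spreads the shots of one
contrast evenly (round(j·n_s/shots) apart).  A literal per-shot
golden increment was rejected: at acceleration 2 the per-shot increment
48·frac(2φ)·16 mod 16 ≈ 5.32 is nearly 3-cyclic, so 8 scheduled shots hit
only ~3 distinct interleaves.  The implemented rule keeps the
golden-rotation-per-contrast character, gives exactly 3 evenly spaced
interleaves at acceleration 16/3, all 16 at acceleration 1, and visits
every arm within a few times the acceleration factor of consecutive
contrasts.

The non-uniform Fourier operator is a Kaiser–Bessel gridding NUFFT
(oversampling 2, width-8 kernel, Beatty β), accurate to ~1e−7 relative
against a dense non-uniform DFT; its adjoint is the exact algebraic
transpose of the discrete forward, so adjointness holds to machine
precision independent of kernel accuracy.  Convention: image indices are
0-based FOV-centered, k in cycles/FOV, forward phase
e^(−i2πk·(r−N/2)/N).

## Reconstruction

Per-contrast SENSE (optionally B0-compensated) and joint SCR / B0-SCR are
least-squares problems solved by CGLS (conjugate gradient on the normal
equations; the data-residual norm is monotonically non-increasing by
construction).  Defaults: max 40 iterations, relative tolerance 1e−6,
zero initialization, all configurable.  No additional regularization is
used — redundancy across the contrast dimension is the only prior.

Two numerical choices matter:

* **Density weighting.** Spiral-out readouts oversample the k-space
  center heavily; the unweighted normal equations converge impractically
  slowly.  All reconstructions therefore weight the data term by a radial
  density estimate (~|k|, floored near the center, unit mean).  For
  consistent (noiseless) data the solution is unchanged; for noisy data
  this is the conventional DCF-weighted least squares.
* **d₂ selection.** By default the phase subspace keeps the smallest d₂
  whose squared-singular-value energy reaches 99.9% of the phase matrix,
  capped at 16; for the smooth fields of the digital phantom this is
  typically 3–6.  When the grid is large the SVD runs on an evenly
  strided voxel subsample and the spatial factors are re-projected
  exactly on the full grid.

A structural caveat for exactness tests: the spiral samples only the
inscribed k-space disk, so the corner spatial frequencies of the image
grid are (nearly) invisible.  Sharp-edged objects are therefore not
recoverable to machine precision even fully sampled; the
exact-recovery oracles use spectrally band-limited truth images, and the
digital phantom's tubes taper their proton density over ~1.2 px
(raised cosine) for the same reason.  Parameter estimates are much less
sensitive: matching is a normalized correlation per voxel.

## B0 pipeline

Pass 1 reconstructs without compensation (SCR), fits, and takes the Δ
component as the wrapped map with |I₀| as a per-voxel quality.  Unwrapping
is quality-guided region growing: each connected mask component starts at
its highest-quality voxel; voxels join in decreasing quality order,
receiving the integer multiple of the 1/TRp period that best matches the
mean of their already-unwrapped neighbors; the component is finally
re-centered by the integer number of periods bringing its median into the
base band (the absolute B0 reference is ambiguous modulo the period —
centering the distribution is the conventional resolution; offsets
between disconnected components are otherwise unresolved, which is why
the default phantom immerses its tubes in a weak connected background
medium, as physical phantoms do).  Pass 2 builds the phase subspace from
the unwrapped map, reconstructs with compensation, and refits; the final
Δ map re-applies the unwrapped integer offsets to the band-limited
second-pass fit.

## Synthetic study conditions

The digital phantom is a 32×32 slice with four soft-edged tubes
(T1 = 300/600/1000/1500 ms, T2 = 50/80/120/200 ms — toolkit-defined
synthetic values in the spirit of calibrated-tube phantoms; the tubes'
datasheet values are not published with the method) on a weak background
(I₀ = 0.3, T1 = 2000 ms, T2 = 250 ms), a smooth polynomial B0 field
(roughly −10…+45 Hz over the object, exercising the wrap band), and a
radial B1 profile within 0.85–1.05.  Coil maps are 4 synthetic Gaussian
lobes on a ring with smooth phase (a single coil gives a uniform map).
Sampling uses 16 arms, 22 ms readouts, 336 samples per arm.  Noise, when
requested, is i.i.d. complex Gaussian per sample and coil with a stored
seed; every pipeline run is bit-reproducible from its configuration and
seed.

These conditions emulate the *structure* of a phantom experiment —
undersampling, off-resonance blurring, coil encoding, parameter
heterogeneity — but not scanner non-idealities (gradient delays, eddy
currents, concomitant fields, magnetization transfer, within-readout
relaxation, drift).  Passing tests therefore demonstrate correctness of
the algorithmic chain and its internal consistency, not accuracy on real
hardware.

Problem sizes used by the test suite and acceptance script (reduced
dictionary densities, 64 sub-spins, 16–32 voxel grids, tens of CG
iterations) were chosen as sensible desk-scale conditions for a
single-CPU run; production values are configuration overrides.

## Known limitations

* Magnetization transfer and diffusion/flow are not modeled; in vivo T1
  underestimation attributable to MT is out of scope.
* Coil sensitivity estimation is not included — maps are synthetic or
  user-supplied.
* The unwrapper is a documented substitute with the contract
  wrapped → spatially consistent; it is not a reimplementation of any
  specific published algorithm.
* The automatic step-count selection for interpolation refinement is
  replaced by fixed defaults (40/40/15/9 for T1/T2/Δ/B1) with config
  overrides.
* 2D in-plane only after z-decoupling; no z-undersampling.
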