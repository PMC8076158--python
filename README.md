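# sgddm — squared-gradient differential dynamic microscopy

Small anisotropic colloids tumble as well as translate, but once a particle
is comparable to the microscope resolution its rotation can no longer be
tracked frame by frame: an in-plane rotation merely rotates the image, and
an out-of-plane rotation barely changes it.  **Squared-gradient differential
dynamic microscopy (SG-DDM)** recovers the rotational dynamics anyway, from
plain bright-field movies, by inserting one nonlinear preprocessing step
before a standard DDM analysis.  This package implements the full method —
simulator, DDM and SG-DDM structure functions, intermediate-scattering-
function (ISF) model fits, a single-particle-tracking (SPT) validation path,
and rigid-rod reference theory — for researchers who analyse time-lapse
microscopy of diffusing anisotropic particles.

## The method

Standard DDM computes the image structure function from frame differences,

    D(q, τ) = ⟨ |FFT₂[I(x, t+τ) − I(x, t)]|² ⟩ₜ ,

azimuthally averaged onto the radial wavevector q, and related to the ISF by
D(q, τ) = A(q)[1 − f(q, τ)] + B(q) with camera-noise baseline B.  For
Brownian particles f = exp(−D_T q² τ): translation only.

The squared-gradient map of each frame,

    c_μ(x, t) = [∂_μ I(x, t)]²,   μ = x, y  (single-pixel differences),

converts particle orientation into local image intensity: squaring is the
essential nonlinearity that turns the orientation-dependent spatial
modulation into a *q-independent* intensity fluctuation.  Running the DDM
machinery on the SG maps (summing the two directions mode-by-mode) yields
D_SG(q, τ), whose ISF carries two branches,

    f(q, τ) = α(q) e^{−(6 D_R + D_T q²) τ} + [1 − α(q)] e^{−D_T q² τ} ,

with 6·D_R the l = 2 relaxation rate of isotropic rotational diffusion.
Fitting the two branches and their rate laws Γ₁ = 6 D_R + D_T q²,
Γ₂ = D_T q² gives both diffusion coefficients; the slow branch must agree
with standard DDM on the same movie, which is the method's built-in quality
check.

Because no experimental accessions exist, the package ships a ground-truth
simulator of quasi-2D translating, 3D-rotating Brownian particles rendered
as bivariate Gaussian blobs whose apparent shape and peak contrast follow
the projected orientation — the movies every validation number in this
repository is computed from.

## Worked example

```python
from sgddm import (SimulationConfig, generate_movie, structure_function,
                   sg_structure_function, StructureFunctionFit)

cfg = SimulationConfig(n_particles=64, n_frames=6000, image_shape=(256, 256),
                       D_T=0.24, D_R=0.30, seed=102)
seq, truth = generate_movie(cfg)                  # 0.1625 µm/px, 25 fps

ddm = StructureFunctionFit(structure_function(seq, q_max=8.0),
                           model="single").fit()
sg  = StructureFunctionFit(sg_structure_function(seq, q_max=8.0),
                           model="double").fit()

print(ddm.translational_diffusion())
print(sg.rotational_diffusion())
```

prints (for this seed)

```
[DDM] D_T = 0.247 ± 0.0014 µm²/s (q ≤ 7.85 µm⁻¹, n = 51)
[SG-DDM] D_T = 0.2523 ± 0.0015 µm²/s D_R = 0.3077 ± 0.01 1/s (q ≤ 2.42 µm⁻¹, n = 16)
```

i.e. the translational coefficient from standard DDM (ground truth
0.24 µm²/s) and both coefficients from SG-DDM (rotational ground truth
0.30 s⁻¹).  `summary()`, `plot_rates()` and `plot_isf()` on the results
objects give the per-q fit table, the Γ(q) branches and the reconstructed
ISFs.  The same pipeline runs from the shell:

```sh
sgddm simulate --config sim.yaml --out movie --seed 1
sgddm ddm --in movie.tif --px 0.1625 --dt 0.04 --out ddm.csv
sgddm sg  --in movie.tif --px 0.1625 --dt 0.04 --out sgddm.csv
sgddm fit --in sgddm.csv --model double --out fits
sgddm track --in movie.tif --px 0.1625 --dt 0.04 --out spt
sgddm theory rod --L 1723 --d 740 --eta 1.0 --T 22
```

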