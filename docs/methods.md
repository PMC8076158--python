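# Models and methods

This note documents the models implemented in `sgddm`, the estimators and
their numerical choices, what the synthetic movies do and do not emulate,
and the known limitations.  Units throughout: µm, s, µm⁻¹ (angular
wavevectors, q = 2π × spatial frequency).

## Brownian movie simulator (`sgddm.simulate`)

**Dynamics.**  Particle centres perform 2D Brownian motion with
translational coefficient `D_T` (Gaussian increments of variance 2·D_T·dt
per coordinate; periodic boundaries by default so the particle number and
the Fourier periodicity of the field are exact).  The particle axis u is a
unit 3-vector undergoing isotropic rotational diffusion with coefficient
`D_R`: a tangent-plane Gaussian increment followed by renormalisation.  A
single such step carries a relative rate bias of about 5·D_R·dt (the
renormalisation systematically shortens excursions), which is not
negligible at ordinary frame rates — at D_R·dt = 0.012 it shifts the l = 2
relaxation rate by −5%.  The update therefore substeps internally until
D_R·dt′ ≤ 10⁻³, leaving a residual bias below a percent; the Legendre
correlators ⟨P₁(u·u₀)⟩ = e^(−2 D_R τ) and ⟨P₂(u·u₀)⟩ = e^(−6 D_R τ) are
property-tested against this.

**Rendering.**  Each particle is a bivariate Gaussian blob sampled at pixel
centres: short-axis std σ_b = `sigma_perp` always; apparent long-axis std
σ_a² = σ_par²(u_x²+u_y²) + σ_perp²·u_z², at the in-plane angle of u.  The
*integrated* intensity of a blob is held fixed at `amplitude`, so the peak
height varies with apparent area: an out-of-plane rotation modulates the
local contrast.  This is the mechanism SG-DDM exploits, chosen as a simple
stand-in for the out-of-focus contrast physics of a real bright-field
microscope — it is a model of *that an* orientation-dependent contrast
exists, not of the actual optics.  Blobs wrap across periodic boundaries;
additive white Gaussian camera noise (`noise_sigma`) is applied per pixel.

**Defaults** mirror a 40×/0.60 NA bright-field experiment on 1723 × 740 nm
peanut-shaped particles: 0.1625 µm/px, dt = 0.04 s, 512 × 512 px
(6.9·10³ µm², holding 35 particles at 5·10³ mm⁻² areal density), 10⁴
frames, D_T = 0.24 µm²/s, D_R = 0.30 s⁻¹, σ_par = 0.5 µm and
σ_perp = 0.3 µm (body dimensions convolved with a ≈0.2 µm PSF width),
blob amplitude 120 on background 100 with noise σ = 3.

**Known model property.**  Because the contrast modulation is a smooth
function of the projected shape, the SG-map intensity of a particle is a
mixture of even orientational harmonics, not a pure l = 2 observable.  On a
translation-free control movie the SG structure function relaxes ≈6% above
the trajectory-level 6·D_R, flat in q; at finite q the higher-harmonic
(l = 4, rate 20·D_R) admixture grows.  Any analysis assuming the pure
two-branch ISF therefore reads D_R systematically high by roughly 5–15% on
these movies.  This is a property of the imaging model, documented rather
than corrected, and it bounds what "exact recovery" can mean here.

## Structure functions (`sgddm.ddm`, `sgddm.sgmap`)

`difference_spectrum` is the reference implementation (full-plane FFT of
frame differences, averaged over an evenly strided, deterministic subset of
reference times, default `max_pairs = 300` per lag).  `structure_function`
is the production engine: per-frame real FFTs in float32, computed in
512-frame blocks and immediately truncated to the analysis band
`q_max` (all signal in the default conditions lives below ≈6 µm⁻¹; the
truncation is exactly equal to the full computation on the retained bins
and cuts memory and time several-fold).  Azimuthal averaging uses annuli
one fundamental mode wide (the larger fundamental for rectangular frames),
DC excluded, empty bins NaN; counts record full-plane mode multiplicities ×
reference pairs.  The half-plane (rfft) path carries conjugate-multiplicity
weights and is property-tested to equal a brute-force O(N⁴) DFT oracle and
a direct loop-binning oracle.  Lag grids are log-spaced, ≈25 per decade,
capped at a quarter of the record.  No window is applied by default
(periodic synthetic fields need none); a Blackman–Harris option exists for
non-periodic data.

The SG path forward-differences each frame by one pixel along each axis
(zero-filling the last line to preserve shape), squares, and runs the same
engine on both maps, summing the two spectra mode-by-mode before the
azimuthal average.  An optional static-background subtraction (temporal
mean image) precedes the gradient for inhomogeneous backgrounds; it is off
by default for the clean synthetic fields.  `gradient_structure_function`
(the *unsquared* control) guards the mechanism: the plain gradient is
linear and translation-equivariant, so it must show no rotational signal at
low q.

## ISF fits and diffusion estimators (`sgddm.fitmodels`)

Per-q fits minimise least squares of D(τ) = A(1 − f) + B with uniform lag
weights (count-based relative weighting is available but emphasises the
earliest lags, where the higher-harmonic admixture lives, and was found to
bias rates upward).  The single-exponential model initialises B from the
minimum, A from the plateau and Γ from the (1−1/e) crossing; the
double-exponential model multi-starts around the single-exponential rate
(3 brackets) to avoid the well-known local-minimum degeneracy, enforces
Γ₁ ≥ Γ₂ and 0 ≤ α ≤ 1.  Fits are flagged `converged` only when the decay
completes within the lag window (Γ·τ_max ≥ 1.6), the rise is resolved, and
the amplitude is significant; double fits are `resolved` when additionally
Γ₁/Γ₂ ≥ 2, the 1σ intervals are disjoint, and α is interior.  The usable q
range ends at the last resolved bin before three consecutive unresolved
bins — beyond the branch crossover (empirically q ≈ 2.5–3.5 µm⁻¹ at the
default conditions) resolution is lost for good and isolated spuriously
resolved bins must not re-open the range.

**Translational coefficient**: weighted least squares of the (slow-branch)
rates on q² through the origin; a significant intercept on refitting with
an offset flags non-quadratic input.

**Rotational coefficient**: the classic two-stage recipe — per-q
double-exponential fits, then an affine-in-q² regression of Γ₁ with
intercept 6·D_R — is implemented (`extract_DR`, WLS or Theil–Sen robust
variants; `rotational_diffusion(method="two-stage")`) but is *not* the
default, because at the small roto-translational amplitude of the default
movies (α ≈ 0.15) the per-bin fast rate is heavily ill-conditioned: A, B,
α and two rates trade off along flat likelihood valleys, producing
heavy-tailed, occasionally confidently-wrong rates that no weighting of the
second-stage regression survives (verified over many seeds; the data
themselves are consistent with the two-branch model when the true rates are
imposed).  The default `method="joint"` instead fits all usable low-q bins
simultaneously, sharing (D_T, D_R) with the rate law imposed and the per-bin
amplitudes (A, B, α) profiled out by linear least squares; a Nelder–Mead
search over the two shared parameters with multi-start, residuals scaled by
each bin's dynamic range.  Uncertainties come from the curvature of the
profiled sum of squares (nominal: residuals are correlated).

**Statistical scatter.**  At 256×256 px the low-q annuli hold few Fourier
modes, and a single movie's joint D_R estimate scatters ~10–15% between
seeds even at 10⁴ frames.  The package's measurement protocol for a
simulation-recovery study therefore averages the coefficient over
independent replicate movies of the same conditions; the validation suite
and the acceptance script use 3 and 6 replicates respectively.

## Tracking path (`sgddm.tracking`)

Crocker–Grier-style localisation (difference-of-Gaussians bandpass, local
maxima with pairwise minimum separation, intensity-weighted centroid),
greedy nearest-neighbour linking (no gap closing; ties to the lowest id;
`max_disp` should be a few rms steps — default 3 px at the default
conditions), and per-observation elliptical-Gaussian fits with analytic
Jacobian.  The fitted centre is constrained to ±3 px of the detection so
the fit cannot migrate onto a neighbouring particle; observations whose ROI
clips the frame border are dropped, and all lag bookkeeping is
frame-gap-aware.  Validity requires a sparse field: at inter-particle
spacings comparable to the fit ROI (≈25 px) the shape estimators degrade
badly, so tracking-based validation runs at the experiment's dilution
(tens of particles per 512×512 field).

Estimators:

* **MSD**: time/ensemble-averaged, count-weighted linear fit through the
  origin over the first decade of lags, D_T = slope/4; a log-log exponent
  far from 1 flags non-diffusive input.
* **In-plane angular MSD**: the nematic image angle (mod π, minimal-step
  unwrapping) of a 3D rotational diffuser has step variance
  2·D_R·dt/sin²θ — divergent near the optical axis and *not* cured by
  short lags — so angular steps are only accumulated inside runs of frames
  whose apparent aspect ratio implies sin²θ ≥ 0.75 (the in-plane axis ratio
  is estimated robustly from the 85th percentile of a²/b², which for an
  isotropically tumbling axis equals 0.98 of the fully-in-plane value).
  With this restriction the short-lag slope (free intercept absorbing
  static angle noise; range τ ≤ 0.2/D_R, iterated once) recovers D_R to a
  few percent on clean input.  Without it the estimator reads ≈2.9× high.
* **Aspect-ratio autocorrelation**: ε = b²/a², per-trajectory
  mean-subtracted, pooled normalised autocorrelation; a single exponential
  is fitted over C_ε > 0.1 with free amplitude *and* free offset — the
  offset absorbs the negative bias that finite-record mean subtraction
  (records of tens of correlation times) would otherwise fold into the
  rate, which inflated γ by >20% on 25 s trajectories.  For isotropic
  rotation γ = 6·D_R (the ε observable is close enough to l = 2 that its
  residual harmonic bias is ≲2%).

## Rod theory (`sgddm.theory`)

End-corrected cylinder expressions (Tirado–García de la Torre form) for
D_T and D_R of a rigid rod, with the end-correction polynomials in 1/p
(p = L/d); validity warned below p = 2.  For the 1723 × 740 nm geometry in
water at 22 °C this gives D_R ≈ 0.432 s⁻¹.  The translational value from
the same expressions (≈0.35 µm²/s) sits well above the measured ≈0.24—0.25
µm²/s; near-wall hydrodynamic slowing of the sedimented particles and the
cylindrical approximation both plausibly contribute, and no agreement is
claimed for D_T from theory.  `diffraction_limit` returns λ/(2·NA).

## Reproducibility and problem sizes

Everything is seeded: one integer seed reproduces movies bit-for-bit, and
the pipeline writes provenance (configuration echo, package version, seed)
beside every result.  The validation suite and acceptance script use
scaled-down problem sizes chosen to keep the full study convenient on one
CPU: 256×256 px replicate movies of 6000 frames with 64 particles for the
DDM/SG-DDM recoveries, and 512×512 px sparse movies of 1250–1500 frames for
the tracking estimators.

## Limitations

* The optical model is a Gaussian-blob stand-in; no diffraction PSF, shot
  noise, defocus or illumination structure.  Its contrast harmonic
  impurity (above) caps rotational-recovery accuracy near 5–15%.
* Monodisperse, uniaxial, non-interacting particles only; no hydrodynamic
  walls, no orientation–translation coupling term in the ISF model.
* The SG step requires non-overlapping particle images; dense fields break
  both the tracking estimators and, eventually, the SG mapping itself.
* Sector-resolved (anisotropic-q) analysis and alternative orientation
  preprocessors (structure tensors, steerable filters) are out of scope.
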