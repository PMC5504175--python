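# Methods

This note records the mathematical conventions, default parameters and
design choices behind `nuscs`, and what the synthetic test bed does and does
not establish about real data.

## Signal model and transform conventions

Synthetic FIDs are sums of decaying complex exponentials
`a·e^{iφ}·e^{2πi f t/n − r t}` plus circular complex Gaussian noise with
standard deviation `noise_sigma` per real/imaginary component.  Frequencies
are in grid units (cycles per full grid, `[0, n)`) and may be off-grid; an
off-grid line produces an approximately sparse spectrum, which is the
realistic regime for NMR.  Decay rates are per sample, so a rate `r` gives
a discrete Lorentzian of half-width ≈ `r·n/(2π)` bins.  All randomness is
seeded; APIs that draw random numbers require the seed explicitly.

The DFT is unitary in both directions (`1/√n`), with frequency bin `k`
associated with `e^{+2πi k t/n}` in the time domain.  Consequences used
throughout:

* the transform pair preserves ℓ2 norms, so residual-norm stopping rules
  are scale-free;
* the rows of the restricted inverse-DFT matrix `F̃` are orthonormal
  (`F̃ F̃^H = I`), so Tikhonov regularisation has the matrix-free form
  `FT(ỹ₀)/(1+λ)` and only the *reweighted* solve needs an m×m system;
* restricted-DFT columns all have norm `√(m/n)`; coherence quantities are
  defined after normalising columns to unit norm, which makes `μ` of full
  sampling exactly 0 and `μ = max_{ω≠0}|PSF(ω)|` with `PSF(0) = 1`.

Because the normalised column inner products depend only on the index
difference modulo n, `μ_s` collapses to the sum of the s largest PSF
artifact magnitudes; the explicit Gram-matrix evaluation survives only in
test oracles.

Indices are zero-based and half-open everywhere, including schedule files.

## Virtual Echo

The Virtual Echo doubles the grid and appends the conjugated time reversal
so the spectrum becomes purely real; for phased data this roughly halves
the number of unknowns and makes decaying-line spectra dramatically
sparser.  The discrete construction halves the `t = 0` sample before
mirroring (the point maps to itself under reflection and must not be
counted twice); this choice is not forced by any continuous-time argument,
but it is the symmetrisation that makes the output exactly conjugate-
symmetric, hence the spectrum exactly real.  The first point of a lifted
NUS data set keeps only its real part — for correctly phased signals the
imaginary part is zero anyway, and the solvers restore measured values on
the way back.  IST accepts `use_ve=True` and handles the lift/unlift
internally; the returned FID lives on the original grid with measured
points restored exactly.

Extrapolation workflows default to the VE route in the examples because
without it the dispersive imaginary part of a truncated Lorentzian is far
from sparse and IST converges to visibly biased line shapes (small-peak
errors of ~40% instead of ~7% on the two-line fixture used in the tests).

## Greedy methods

CLEAN adds `gain ×` the observed height of the globally highest artifact
bin per iteration and never re-fits it; with `gain = 1` and full sampling a
1-sparse spectrum is exact after one iteration, and under NUS the residual
at a peak contracts geometrically by `(1 − m/n)` per visit.  The default
gain is 1 (the classic fractional gain is available).  Ties in the maximum
search break to the lowest bin index, making runs bit-reproducible.

OMP re-fits all support values by solving the normal equations of the
restricted-DFT columns; a ridge of 1e−12 is added only if the Gram matrix
is numerically singular (condition number > 1e12), which is flagged in the
result diagnostics and stops the iteration.  Both stopping rules are always
active: residual ℓ2 ≤ ε and the iteration cap (= maximum support size).
Guidance for ε: set it to the ℓ2 norm of the noise;
`noise_epsilon(sigma, m) = sigma·√(2m)` computes that for the generator's
noise convention, and the CLI exposes it as `--noise-sigma`.

## Iterative soft thresholding

The shrinkage operator reduces each bin's magnitude by the threshold,
floors at zero and preserves phase — the proximal operator of the complex
ℓ1 norm, and the operator that makes IST-D solve the `p = 1` penalised
problem.  Thresholds are dimensionless fractions in (0, 1) of the *current
iteration's* maximum spectral magnitude (an absolute threshold would need
knowledge of the intensity scale; a global-max-relative variant would
behave identically on the first iteration and more aggressively later).

IST-D subtracts the masked time-domain image of each thresholded spectrum
from the residual and accumulates the increments; its residual norm is
provably non-increasing under this convention.  IST-S thresholds the
current full spectrum, inverse-transforms, and *replaces* the measured
points with the data; its threshold must decrease across iterations
(geometric schedule, default factor 0.98/iteration) or the iteration
stalls.  Ending on the replacement step gives exact data agreement at
every measured point (to machine precision); ending on the threshold step
gives the output that coincides with converged IST-D — the two-peak
fixture in the tests agrees to ~1e−7 relative.

## IRLS

The weighted closed form `x = W^{-2} F̃^H (F̃ W^{-2} F̃^H + λI)^{-1} ỹ` is
evaluated exactly via a Cholesky solve of the m×m Hermitian system.  The
iteration starts from identity weights — the first iterate therefore *is*
the Tikhonov solution — and then re-derives `d_i = max(|x_i|, ε)^{p−2}`
from the current iterate (the floor ε is clamped inside the power, which
is what keeps the weights finite at exact zeros).  Useful algebra checked
in the tests: scaling the weights `W → cW` is equivalent to scaling the
balance `λ → c²λ`.

`δ`-annealing lowers `p` each iteration (floored at 0.05 for the stability
of the power), steering the fixed point towards ℓ0 after ≈ 1/δ iterations.
The adaptive floor rule sets ε to the `i₀`-th largest magnitude of the
current iterate with `i₀ = round(m/(4 ln(n/m)))` (natural logarithm,
floored at 1, and `ε₀` when `m = n`), tracking the number of points the
sampling budget can support.  Default iteration count is 20.  A divergence
guard stops after five consecutive data-residual increases and flags the
result as non-converged.  Cost is dominated by the m×m factorisation —
fine for 1D problems up to a few thousand points, not intended for large
multidimensional grids.

## Low-rank Hankel reconstruction

A FID of K exponentials lifts to a Hankel matrix of rank exactly K
regardless of line width, so nuclear-norm minimisation of the lift with a
data-agreement term `α‖ỹ − Ux‖²` recovers broad lines that point-sparsity
methods treat as dense.  The solver is a scaled ADMM on the splitting
`Z = Rx`:

* `Z ← svt(Rx + D/(2β), 1/(2β))` — singular-value soft thresholding, the
  proximal operator of the nuclear norm (verified against direct
  minimisation and the Moreau decomposition in the tests);
* `x ← (α ỹ₀ + β R^H Z − ½ R^H D) / (α·ind + β·w)` entrywise, where `ind`
  is the schedule indicator and `w` the anti-diagonal multiplicities —
  both `U^H U` and `R^H R` are diagonal, so the x-update is exact;
* `D ← D + τ (Rx − Z)` with `τ = β` by default.

Matrix inner products are the real part of the trace inner product.  The
SVD phase ambiguity is fixed by rotating each singular pair so the largest
entry of the left vector is real positive, making traces reproducible.
Defaults: near-square lift `Q = n//2 + 1` (best-conditioned; `Q` must
exceed the number of peaks), `α = 1000`, `β = 1`, 500 iterations or
relative x-change below 1e−9.  On the 2-exponential half-sampling fixture
(n = 128, m = 64) the median missing-point error is ~1.5e−3 after 300
iterations.  The output is the completed FID; its spectrum is attached for
convenience.

## Experiment drivers

The "residue" plotted by the sweep driver is the ℓ2 distance between the
reconstructed spectrum and the full-data reference spectrum; its absolute
scale is arbitrary (it depends on the model amplitudes), so only curve
shapes and crossings are meaningful.  The empirical sampling requirement of
a sweep is defined as the smallest level whose mean residue falls below 10%
of the truth-spectrum norm.  On strictly sparse fixtures with OMP this
transition is sharp and reproduces the `K log(n/K)` law: tripling K
(1 → 3 peaks at n = 512) raises the requirement from 2 to ~16 points,
while doubling n at fixed K leaves it essentially unchanged — the clearest
argument against percentage-of-n sampling rules.

L-curve selection runs the method over a λ grid, records
(data misfit, sparsity term) pairs and picks the point of maximum discrete
curvature in log–log coordinates (ties towards the larger, sparser λ; a
flat curve falls back to the grid midpoint and is flagged).  For NUS the
restricted Fourier operator is well-conditioned, so the classic "solution
norm explodes as λ → 0" branch does not exist; the corner is only
informative when the sparsity term actually separates noise-fitting from
clean solutions.  With `p = 1` it barely does; with `p = 0.5` and the
matching penalty `Σ|x|^{1/2}` the corner lands at the noise level and the
selected λ performs within ~5% of the grid optimum on the noisy two-line
fixture.  The CLI therefore passes the method's own `Σ|x|^p` as the
penalty.

Cross-validation holds out a seeded uniform fraction (default 25%) of the
*measured* points, reconstructs from the rest per candidate parameter set,
and scores by ℓ2 misfit at the held-out points.  Residual re-addition adds
the Fourier transform of the zero-filled final residual back onto the
output spectrum, restoring exact data consistency and any signal the
sparse solver stopped short of; the per-point weighting hook for
non-uniform sampling densities defaults to identity, as only uniform
densities are in scope.

The tail-decay diagnostic of the extrapolation driver fits
`log|y[t]| ≈ a − r t` over the first half of the extrapolated region; the
trailing quarter is excluded because reconstruction edge effects (e.g.
leakage from the Virtual Echo mirror image) contaminate it.  With
two-level truncation the known qualitative behaviours reproduce: 2×
extrapolation at a sensible threshold recovers a 5× smaller line to ~7%,
while extreme truncation with an over-sparse threshold returns a nearly
decay-free (artificially narrowed) line.

## What the synthetic test bed does not show

The generator emulates 1D cross-sections: isolated Lorentzian lines,
white circular Gaussian noise, uniform sampling density, perfect phase.
It does not model multidimensional interferograms
(hypercomplex/States-TPPI bookkeeping), rolling baselines, t1-noise,
solvent ridges, temperature drift, or decaying/weighted sampling
densities.  Passing tests therefore certify the algorithms and their
documented failure modes under the stated model — not performance on any
particular spectrometer data set.  Problem sizes in the tests
(n ≤ 1024, 20 schedules per sampling level, 20 seeds per completion
experiment) were chosen so the full suite runs in about a minute on one
CPU while keeping every statistical check comfortably away from its
threshold.

## File formats

FIDs: two-column (real, imaginary) delimited text, `#` comments, optional
`# n <int>` header; an HDF5 container mirror (`fid` dataset, `n`/`sw`
attributes) for binary exchange.  Schedules: nuslist-style, one zero-based
index per line with a mandatory `# n` header; readers accept unsorted
input, reject duplicates and out-of-range indices, and writers emit sorted
indices.  Peak models: YAML/JSON mappings with per-peak
frequency/amplitude/phase/decay.  Every CLI run writes a JSON manifest
(method, configuration, seeds, input digests, package version, timing)
sufficient to replay it exactly.
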