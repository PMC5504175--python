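# nuscs — compressed-sensing reconstruction for non-uniformly sampled NMR signals

Multidimensional NMR experiments routinely skip most of the Nyquist time
grid in their indirect dimensions (non-uniform sampling, NUS) and recover
the spectrum afterwards under a sparsity assumption.  `nuscs` implements the
standard compressed-sensing reconstruction algorithms for this setting,
together with the diagnostics that predict how hard a given schedule will
be, and seeded workflows that reproduce the classic ways these algorithms
fail when their parameters are misset.  It is aimed at spectroscopists and
methods developers who want transparent, well-tested reference
implementations to experiment with — everything runs on synthetic
Lorentzian signals, no spectrometer data required.

## The model

A free-induction decay (FID) on a grid of `n` points is a sum of `K`
decaying complex exponentials

    y[t] = Σ_k a_k e^{iφ_k} e^{2πi f_k t / n} e^{−r_k t} + ε[t],

whose unitary DFT `x = F y` is an (approximately) sparse spectrum of
Lorentzian lines.  NUS keeps only `m < n` time points: with the restricted
inverse-DFT matrix `F̃` the system `F̃ x = ỹ` is underdetermined, and the
spectrum is recovered by ℓp-norm minimisation (`0 < p ≤ 1`),

    min_x ‖F̃ x − ỹ‖₂ + λ ‖x‖_p .

Implemented solvers:

| method | idea |
|---|---|
| `clean` / `omp` | greedy: pick the highest bin of the artifact spectrum per iteration; OMP re-fits all support heights by least squares |
| `ist_d` | iterative soft thresholding, accumulating thresholded spectra (sparsity/data balance) |
| `ist_s` | IST keeping the measured time points exactly fixed; only omitted points are reconstructed |
| `irls` | iteratively reweighted least squares for ℓp with `p ≤ 1`, with δ-annealing of `p` towards ℓ0 |
| `lowrank_reconstruct` | nuclear-norm minimisation of the FID's Hankel lift (rank = number of exponentials), solved by ADMM with singular-value soft thresholding |

Diagnostics: the point spread function `PSF(ω)` (DFT of the schedule
indicator), the mutual coherence `μ = max_{ω≠0}|PSF(ω)|`, the s-column
coherence `μ_s`, and the exact-recovery guarantee for OMP,
`μ_s + μ_{s−1} < 1`.  Experiment drivers: residual-vs-m curves (the
`K log(n/K)` sampling law), truncated-FID extrapolation, L-curve and
cross-validation selection of λ, and residual re-addition.

## Worked example

```python
import numpy as np
from nuscs import *

# truth: a strong and a 4x-weaker Lorentzian line, mild noise
model = PeakList([(60.0, 1.0, 0.0, 0.02), (200.0, 0.25, 0.0, 0.03)])
fid = synth_fid(model, n=512, noise_sigma=0.005, seed=7)

# keep 128 of 512 points, drawn uniformly; inspect the schedule first
sched = uniform_schedule(n=512, m=128, seed=11)
rep = coherence_report(sched, s_max=3)
print(f"mu = {rep.mu:.3f}, mu_2 = {rep.mu_s[2]:.3f}, guaranteed s = {rep.guarantee_s}")

# reconstruct with IST-D; epsilon set to the noise l2 norm
nus = restrict(fid, sched)
result = ist_d(nus, IstConfig(threshold=0.9,
                              epsilon=noise_epsilon(0.005, 128), n_iter=2000))
truth = fft_spectrum(fid)
for bin_ in (60, 200):
    print(f"bin {bin_}: reconstructed |x| = {abs(result.spectrum.values[bin_]):.3f}, "
          f"full-data |x| = {abs(truth.values[bin_]):.3f}")
print(f"converged = {result.converged} after {result.iterations} iterations, "
      f"final residual = {result.residual_trace[-1]:.4f}")
```

Output:

```
mu = 0.205, mu_2 = 0.409, guaranteed s = 3
bin 60: reconstructed |x| = 2.139, full-data |x| = 2.236
bin 200: reconstructed |x| = 0.349, full-data |x| = 0.399
converged = True after 163 iterations, final residual = 0.0798
```

The coherence report says this schedule's worst artifact is ~20% of a peak,
low enough that greedy recovery of up to 3 peaks is guaranteed; IST-D then
recovers both line heights to within a few percent of the fully sampled
spectrum and stops once the residual reaches the noise level (0.08 ≈
0.005·√(2·128)).

The same pipeline is available from the shell:

```sh
nus-cs simulate --peaks peaks.yaml -n 512 --seed 7 -o fid.txt
nus-cs sample -n 512 -m 128 --seed 11 -o sched.txt
nus-cs diagnose --schedule sched.txt
nus-cs reconstruct --fid fid.txt --schedule sched.txt --method ist-d \
    --threshold 0.9 --n-iter 2000 -o spec.txt
```

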