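"""Iterative soft thresholding (IST) in its two NMR variants.

IST-D ("data-balance") generalises CLEAN: instead of picking the single
highest bin, every bin of the artifact spectrum is shrunk towards zero by a
threshold, the shrunk spectrum is accumulated into the output, its masked
time-domain image is subtracted from the residual, and the loop repeats until
the residual norm falls below ``epsilon``.  The accumulated output balances
sparsity against data agreement; for an l1 penalty the soft-shrinkage
operator is exactly the proximal map, so IST-D solves the penalised
least-squares problem with p = 1.

IST-S ("strict") keeps the measured time-domain points untouched and only
reconstructs the omitted ones: threshold the current spectrum, inverse-FT,
put the measured values back in place, FT again.  The threshold must decrease
from iteration to iteration.  Ending on the replacement step gives exact
agreement with the measured data; ending on the threshold step gives the
spectrum that, at convergence, coincides with IST-D's output.

Thresholds are dimensionless fractions in (0, 1) of the current iteration's
maximum spectral magnitude.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .result import ReconstructionResult
from .sampling import NusData
from .signal_model import Fid, Spectrum, fft_spectrum, ifft_fid

__all__ = ["IstConfig", "soft_threshold", "ist_d", "ist_s"]


@dataclass
class IstConfig:
    """IST settings.

    ``threshold`` is the shrinkage level as a fraction of the current
    spectrum's maximum magnitude.  ``epsilon`` stops IST-D once the residual
    l2 norm drops below it; ``n_iter`` caps IST-D and is the fixed iteration
    count of IST-S.  ``schedule_factor`` < 1 decays the threshold
    geometrically per iteration (mandatory for IST-S, where a constant
    threshold would stall); 1.0 keeps it constant (IST-D only).
    ``final_replacement`` makes IST-S output the post-replacement spectrum
    (exact data agreement) instead of the post-threshold one.  ``use_ve``
    lifts the problem into the Virtual Echo domain before solving (phased
    data only), which makes decaying-peak spectra markedly sparser.
    """

    threshold: float = 0.9
    epsilon: float = 0.0
    n_iter: int = 200
    schedule_factor: float = 1.0
    variant: str = "D"  # "D" | "S"
    final_replacement: bool = True
    use_ve: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not (0 < self.schedule_factor <= 1):
            raise ValueError("schedule_factor must lie in (0, 1]")
        if self.variant not in ("D", "S"):
            raise ValueError(f"unknown variant {self.variant!r}")


def soft_threshold(spec: Spectrum, tau_abs: float) -> Spectrum:
    """Complex soft shrinkage: magnitudes reduced by ``tau_abs``, phase kept.

    The proximal operator of ``tau_abs * ||.||_1`` on complex vectors.
    """
    if tau_abs < 0:
        raise ValueError("tau_abs must be >= 0")
    v = spec.values
    mag = np.abs(v)
    scale = np.zeros_like(mag)
    nz = mag > 0
    scale[nz] = np.maximum(mag[nz] - tau_abs, 0.0) / mag[nz]
    return Spectrum(v * scale)


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr.view(float))):
        raise FloatingPointError(f"non-finite values in {what}; aborting IST")


def _ve_unlift(result: ReconstructionResult, nus: NusData) -> ReconstructionResult:
    """Map a Virtual-Echo-domain result back to the original n-point grid.

    The leading half of the VE-domain FID is the completed signal; measured
    points are restored exactly (index 0 loses its imaginary part in the VE
    construction, so it is put back from the data).
    """
    n = nus.n
    rec = result.fid.samples[:n].copy()
    rec[nus.schedule.indices] = nus.measured
    fid = Fid(rec)
    return ReconstructionResult(
        spectrum=fft_spectrum(fid), fid=fid, support=None,
        residual_trace=result.residual_trace, iterations=result.iterations,
        converged=result.converged,
        diagnostics=dict(result.diagnostics, ve_domain=True))


def ist_d(nus: NusData, cfg: IstConfig) -> ReconstructionResult:
    """IST-D: accumulate thresholded artifact spectra until the residual is small."""
    if cfg.variant != "D":
        raise ValueError("cfg.variant must be 'D'")
    if cfg.use_ve:
        from .sampling import virtual_echo_nus

        inner = ist_d(virtual_echo_nus(nus),
                      dataclasses.replace(cfg, use_ve=False))
        return _ve_unlift(inner, nus)
    n = nus.n
    mask = nus.schedule.indicator().astype(bool)
    residual = nus.zero_filled
    x = np.zeros(n, dtype=complex)
    trace = [float(np.linalg.norm(residual))]
    converged = trace[0] <= cfg.epsilon
    iterations = 0
    rel_thresh = cfg.threshold
    while not converged and iterations < cfg.n_iter:
        artifact_spec = np.fft.fft(residual, norm="ortho")
        tau = rel_thresh * float(np.max(np.abs(artifact_spec)))
        increment = soft_threshold(Spectrum(artifact_spec), tau).values
        _check_finite(increment, "thresholded spectrum")
        x += increment
        t_inc = np.fft.ifft(increment, norm="ortho")
        residual[mask] -= t_inc[mask]
        iterations += 1
        trace.append(float(np.linalg.norm(residual)))
        converged = trace[-1] <= cfg.epsilon
        rel_thresh *= cfg.schedule_factor
    spec = Spectrum(x)
    return ReconstructionResult(
        spectrum=spec, fid=ifft_fid(spec), support=None,
        residual_trace=np.array(trace), iterations=iterations,
        converged=converged)


def ist_s(nus: NusData, cfg: IstConfig) -> ReconstructionResult:
    """IST-S: threshold / inverse-FT / replace measured points, fixed count.

    The threshold decays geometrically (``schedule_factor`` must be < 1).
    With ``final_replacement`` the output's inverse FT matches the measured
    data exactly at every scheduled point; without it the output is the last
    post-threshold spectrum, which at convergence coincides with IST-D's.
    """
    if cfg.variant != "S":
        raise ValueError("cfg.variant must be 'S'")
    if cfg.use_ve:
        from .sampling import virtual_echo_nus

        inner = ist_s(virtual_echo_nus(nus),
                      dataclasses.replace(cfg, use_ve=False))
        return _ve_unlift(inner, nus)
    if cfg.schedule_factor >= 1.0:
        raise ValueError("IST-S requires a decreasing threshold "
                         "(schedule_factor < 1)")
    mask = nus.schedule.indicator().astype(bool)
    measured = nus.measured
    current = nus.zero_filled  # full-length time vector; measured points fixed
    trace = []
    rel_thresh = cfg.threshold
    x_thresh = np.fft.fft(current, norm="ortho")
    for _ in range(cfg.n_iter):
        spec = np.fft.fft(current, norm="ortho")
        tau = rel_thresh * float(np.max(np.abs(spec)))
        x_thresh = soft_threshold(Spectrum(spec), tau).values
        _check_finite(x_thresh, "thresholded spectrum")
        t_est = np.fft.ifft(x_thresh, norm="ortho")
        # replacement: measured points are never modified
        t_est[mask] = measured
        current = t_est
        trace.append(float(np.linalg.norm(
            np.fft.ifft(x_thresh, norm="ortho")[mask] - measured)))
        rel_thresh *= cfg.schedule_factor
    if cfg.final_replacement:
        spec_out = Spectrum(np.fft.fft(current, norm="ortho"))
    else:
        spec_out = Spectrum(x_thresh)
    return ReconstructionResult(
        spectrum=spec_out, fid=ifft_fid(spec_out), support=None,
        residual_trace=np.array(trace), iterations=cfg.n_iter,
        converged=True)
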