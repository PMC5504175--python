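"""Greedy sparse reconstruction: CLEAN (matching pursuit) and OMP.

Both methods iteratively deconvolve the sampling artifacts from the direct
Fourier transform of the zero-filled NUS data.  Each iteration finds the
global maximum-magnitude bin of the current artifact spectrum and adds it to
the sparse estimate ``x``; the estimate's time-domain image is then masked to
the measured points and subtracted from the data, and the loop continues on
the residual.

CLEAN keeps the height of a once-found peak fixed.  OMP instead re-fits the
heights of *all* support bins after every addition, by orthogonally
projecting the measured data onto the span of the restricted-DFT columns of
the support — which is what buys the exact-recovery guarantee
``mu_s + mu_{s-1} < 1`` (see :mod:`nuscs.sampling`).

Stopping follows the two standard criteria, applied together: residual l2
norm below ``epsilon`` (best set to the l2 norm of the noise) or the
iteration cap (equal to the maximum support size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .result import ReconstructionResult
from .sampling import NusData
from .signal_model import Fid, Spectrum, fft_spectrum, ifft_fid

__all__ = ["GreedyConfig", "ReconstructionResult", "clean", "omp",
           "apodize_output", "noise_epsilon"]

_RIDGE = 1e-12  # jitter added to near-singular Gram matrices in OMP


@dataclass
class GreedyConfig:
    """Settings shared by CLEAN and OMP.

    ``epsilon`` is the residual-norm stopping threshold; ``max_iter`` caps
    the number of iterations and hence the support size.  ``gain`` (CLEAN
    only) is the classic loop-gain fraction of the found peak that is
    subtracted per iteration; 1 subtracts the full observed height.
    ``apodize_lw`` applies exponential weighting ``exp(-lw * t)`` to the
    output FID, smoothing the stick-like peaks greedy methods produce.
    """

    epsilon: float = 0.0
    max_iter: int = 50
    mode: str = "omp"  # "clean" | "omp"
    gain: float = 1.0
    apodize_lw: float = 0.0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (0 < self.gain <= 1):
            raise ValueError("gain must lie in (0, 1]")
        if self.mode not in ("clean", "omp"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.apodize_lw < 0:
            raise ValueError("apodize_lw must be >= 0")


def noise_epsilon(noise_sigma: float, m: int) -> float:
    """Residual threshold matching the expected l2 norm of the noise.

    Complex Gaussian noise with std ``sigma`` per real/imaginary component on
    ``m`` measured points has expected squared l2 norm ``2 m sigma^2``.
    """
    return float(noise_sigma * np.sqrt(2 * m))


def _finish(x: np.ndarray, support: list[int], trace: list[float],
            iterations: int, converged: bool, cfg: GreedyConfig,
            diagnostics: dict | None = None) -> ReconstructionResult:
    spec = Spectrum(x)
    result = ReconstructionResult(
        spectrum=spec,
        fid=ifft_fid(spec),
        support=np.array(sorted(support), dtype=int),
        residual_trace=np.array(trace),
        iterations=iterations,
        converged=converged,
        diagnostics=diagnostics or {},
    )
    if cfg.apodize_lw > 0:
        result = apodize_output(result, cfg.apodize_lw)
    return result


def clean(nus: NusData, cfg: GreedyConfig) -> ReconstructionResult:
    """CLEAN / matching pursuit on zero-filled NUS data.

    Per iteration: (1) locate the global max-magnitude bin of the FT of the
    current zero-filled residual and add ``gain`` times its complex value to
    ``x``; (2) inverse-FT ``x``'s increment; (3) zero the non-measured time
    points; (4) subtract from the residual.  Once-found heights are never
    re-fit.  Ties in the maximum search break to the lowest bin index.
    """
    if cfg.mode != "clean":
        raise ValueError("cfg.mode must be 'clean'")
    n = nus.n
    mask = nus.schedule.indicator().astype(bool)
    residual = nus.zero_filled  # residual lives on the full grid, zeros off-schedule
    x = np.zeros(n, dtype=complex)
    support: set[int] = set()
    trace = [float(np.linalg.norm(residual))]
    converged = trace[0] <= cfg.epsilon
    iterations = 0
    while not converged and iterations < cfg.max_iter:
        artifact_spec = np.fft.fft(residual, norm="ortho")
        k = int(np.argmax(np.abs(artifact_spec)))  # argmax takes the first = lowest index
        delta = cfg.gain * artifact_spec[k]
        x[k] += delta
        support.add(k)
        # time-domain image of the increment, masked to measured points
        increment = np.zeros(n, dtype=complex)
        increment[k] = delta
        t_inc = np.fft.ifft(increment, norm="ortho")
        residual[mask] -= t_inc[mask]
        iterations += 1
        trace.append(float(np.linalg.norm(residual)))
        converged = trace[-1] <= cfg.epsilon
    return _finish(x, list(support), trace, iterations, converged, cfg)


def omp(nus: NusData, cfg: GreedyConfig) -> ReconstructionResult:
    """Orthogonal matching pursuit on zero-filled NUS data.

    As :func:`clean`, but after each support addition the values on the whole
    support are re-set by least squares: the orthogonal projection of the
    measured data onto the span of the restricted-DFT columns indexed by the
    support.  The residual norm is therefore non-increasing, and under
    ``mu_s + mu_{s-1} < 1`` an s-sparse spectrum is recovered exactly in at
    most s iterations.
    """
    if cfg.mode != "omp":
        raise ValueError("cfg.mode must be 'omp'")
    n = nus.n
    sched_idx = nus.schedule.indices
    y = nus.measured
    mask = nus.schedule.indicator().astype(bool)
    # Columns of the restricted inverse DFT are built lazily, per support bin.
    t = sched_idx.astype(float)

    def column(k: int) -> np.ndarray:
        return np.exp(2j * np.pi * t * k / n) / np.sqrt(n)

    support: list[int] = []
    cols: list[np.ndarray] = []
    coeffs = np.zeros(0, dtype=complex)
    residual_full = nus.zero_filled
    trace = [float(np.linalg.norm(y))]
    converged = trace[0] <= cfg.epsilon
    iterations = 0
    diagnostics: dict = {}
    while not converged and iterations < cfg.max_iter:
        artifact_spec = np.fft.fft(residual_full, norm="ortho")
        order = np.argsort(-np.abs(artifact_spec), kind="stable")
        k = next(int(b) for b in order if int(b) not in support)
        support.append(k)
        cols.append(column(k))
        A = np.column_stack(cols)
        gram = A.conj().T @ A
        rhs = A.conj().T @ y
        try:
            cond = np.linalg.cond(gram)
        except np.linalg.LinAlgError:
            cond = np.inf
        if not np.isfinite(cond) or cond > 1e12:
            gram = gram + _RIDGE * np.eye(gram.shape[0])
            diagnostics["degenerate_support"] = True
            diagnostics["ridge"] = _RIDGE
        coeffs = np.linalg.solve(gram, rhs)
        r = y - A @ coeffs
        residual_full = np.zeros(n, dtype=complex)
        residual_full[sched_idx] = r
        iterations += 1
        trace.append(float(np.linalg.norm(r)))
        converged = trace[-1] <= cfg.epsilon
        if diagnostics.get("degenerate_support"):
            break
    x = np.zeros(n, dtype=complex)
    x[support] = coeffs
    return _finish(x, support, trace, iterations, converged, cfg, diagnostics)


def apodize_output(result: ReconstructionResult, lw: float) -> ReconstructionResult:
    """Exponentially weight the output FID by ``exp(-lw * t)`` and re-transform.

    Turns the stick spectrum greedy methods produce into Lorentzian lines of
    half-width set by ``lw``; ``lw = 0`` is the identity.
    """
    if lw < 0:
        raise ValueError("lw must be >= 0")
    if lw == 0:
        return result
    t = np.arange(result.fid.n)
    fid = Fid(result.fid.samples * np.exp(-lw * t), label=result.fid.label)
    return ReconstructionResult(
        spectrum=fft_spectrum(fid),
        fid=fid,
        support=result.support,
        residual_trace=result.residual_trace,
        iterations=result.iterations,
        converged=result.converged,
        diagnostics=dict(result.diagnostics),
    )
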