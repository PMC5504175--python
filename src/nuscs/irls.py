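"""Regularised least squares and iteratively reweighted least squares (IRLS).

The NUS system ``F~ x = y~`` is underdetermined, so a unique solution needs a
prior.  Tikhonov regularisation minimises
``||F~ x - y~||^2 + lambda ||x||^2`` and has the closed form
``x = F~^H (F~ F~^H + lambda I)^{-1} y~``; its weighted generalisation
minimises ``||F~ x - y~||^2 + lambda ||W x||^2`` with

    x = W^{-2} F~^H (F~ W^{-2} F~^H + lambda I)^{-1} y~.

Neither is sparse.  IRLS reaches the sparse l_p solution (0 < p <= 1) by
iterating the weighted form with weights ``d_i = |x_i|^{p-2}`` taken from the
previous iterate, so that ``||W x||^2`` successively approximates
``||x||_p^p``.  A floor ``eps`` inside the power keeps the weights finite
where ``x_i`` is (near) zero; the delta modification lowers ``p`` a little
every iteration, steering the limit towards l0 after about ``1/delta``
iterations.

Under the unitary DFT convention the rows of ``F~`` are orthonormal, so
``F~ F~^H = I`` and Tikhonov reduces to the artifact spectrum divided by
``1 + lambda`` — no matrix is ever formed for it.  The reweighted solve is a
genuine m x m Hermitian positive-definite system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .result import ReconstructionResult
from .sampling import NusData, restricted_dft_matrix
from .signal_model import Spectrum, ifft_fid

__all__ = ["IrlsConfig", "tikhonov", "reweighted_solve", "irls", "eps_k_rule"]

_P_FLOOR = 0.05  # smallest p reached by delta-annealing


@dataclass
class IrlsConfig:
    """IRLS settings.

    ``p`` is the norm exponent in (0, 1]; ``lam`` the sparsity/data-agreement
    balance; ``eps0`` the floor regulariser for the weights; ``delta`` the
    per-iteration decrease of ``p`` (0 keeps p fixed); ``eps_rule`` chooses
    between the fixed floor and the order-statistic update that tracks the
    expected number of recoverable points (see :func:`eps_k_rule`).
    """

    p: float = 1.0
    lam: float = 1e-3
    eps0: float = 1e-8
    delta: float = 0.0
    n_iter: int = 20
    eps_rule: str = "fixed"  # "fixed" | "k_rule"

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError("p must lie in (0, 1]")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.eps0 <= 0:
            raise ValueError("eps0 must be > 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.eps_rule not in ("fixed", "k_rule"):
            raise ValueError(f"unknown eps_rule {self.eps_rule!r}")


def tikhonov(nus: NusData, lam: float) -> Spectrum:
    """Closed-form Tikhonov-regularised spectrum, matrix-free.

    ``F~ F~^H = I`` under the unitary convention, so the solution is the
    Fourier transform of the zero-filled data scaled by ``1 / (1 + lambda)``.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    return Spectrum(np.fft.fft(nus.zero_filled, norm="ortho") / (1.0 + lam))


def reweighted_solve(nus: NusData, lam: float, W_diag: np.ndarray) -> Spectrum:
    """Weighted-l2 regularised spectrum (explicit m x m Hermitian solve).

    ``W_diag`` holds the positive diagonal of ``W``; the penalty is
    ``lambda ||W x||^2``.  With ``W = I`` this reduces to :func:`tikhonov`.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    W_diag = np.asarray(W_diag, dtype=float)
    if W_diag.shape != (nus.n,) or np.any(W_diag <= 0):
        raise ValueError("W_diag must be a positive vector of length n")
    F = restricted_dft_matrix(nus.schedule)
    w2inv = 1.0 / W_diag**2
    # G = F~ W^-2 F~^H  (m x m, Hermitian positive definite)
    G = (F * w2inv[None, :]) @ F.conj().T
    G[np.diag_indices_from(G)] += lam
    try:
        c, low = scipy.linalg.cho_factor(G)
        z = scipy.linalg.cho_solve((c, low), nus.measured)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"reweighted system is singular (lam={lam}): {exc}") from exc
    return Spectrum(w2inv * (F.conj().T @ z))


def eps_k_rule(x: Spectrum, m: int, n: int, eps0: float) -> float:
    """Order-statistic update of the IRLS floor parameter.

    With ``m`` samples on a grid of ``n``, roughly ``K ~ m / log(n/m)``
    spectral points can be recovered, so the floor is set to the magnitude of
    the ``i0``-th largest point of the current iterate,
    ``i0 = round(m / (4 ln(n/m)))`` (natural log, floored at 1), never below
    ``eps0``.
    """
    if m >= n:
        return float(eps0)
    i0 = max(1, round(m / (4.0 * np.log(n / m))))
    mags = np.sort(np.abs(x.values))[::-1]
    return float(max(mags[i0 - 1], eps0))


def irls(nus: NusData, cfg: IrlsConfig) -> ReconstructionResult:
    """Delta-modified IRLS: iterate the reweighted closed form.

    The first iteration uses identity weights (hence equals Tikhonov); each
    subsequent iteration re-derives the weights
    ``d_i = max(|x_i|, eps)^{p-2}`` from the current iterate, decreasing
    ``p`` by ``delta`` (floored at 0.05) as it goes.  A divergence guard
    stops after five consecutive residual increases.
    """
    n = nus.n
    x = np.fft.fft(nus.zero_filled, norm="ortho")  # artifact spectrum seeds eps/trace
    F = restricted_dft_matrix(nus.schedule)

    def data_residual(xv: np.ndarray) -> float:
        return float(np.linalg.norm(F @ xv - nus.measured))

    trace = [data_residual(x)]
    p = cfg.p
    eps = cfg.eps0
    W = np.ones(n)
    increases = 0
    converged = True
    iterations = 0
    for it in range(cfg.n_iter):
        if it > 0:
            if cfg.eps_rule == "k_rule":
                eps = eps_k_rule(Spectrum(x), nus.m, n, cfg.eps0)
            W = np.maximum(np.abs(x), eps) ** ((p - 2.0) / 2.0)
        x = reweighted_solve(nus, cfg.lam, W).values
        iterations += 1
        trace.append(data_residual(x))
        if trace[-1] > trace[-2]:
            increases += 1
            if increases >= 5:
                converged = False
                break
        else:
            increases = 0
        p = max(_P_FLOOR, p - cfg.delta)
    spec = Spectrum(x)
    return ReconstructionResult(
        spectrum=spec, fid=ifft_fid(spec), support=None,
        residual_trace=np.array(trace), iterations=iterations,
        converged=converged)
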