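"""Synthetic NMR signal model: Lorentzian FIDs, DFT conventions, Hankel lifts.

The free-induction decay (FID) is modelled as a sum of decaying complex
exponentials

    y[t] = sum_k a_k * exp(i*phi_k) * exp(i*2*pi*f_k*t/n) * exp(-r_k*t)

with frequency ``f_k`` in grid units (cycles per full grid, in ``[0, n)``),
non-negative amplitude ``a_k``, phase ``phi_k`` in radians and per-sample
decay rate ``r_k >= 0``.  The spectrum of an on-grid, non-decaying peak is a
single stick; decay broadens it into a discrete Lorentzian, and off-grid
frequencies make the spectrum only approximately sparse — both regimes matter
for stress-testing sparse reconstruction.

DFT convention
--------------
Unitary in both directions (``1/sqrt(n)``), with frequency bin ``k``
corresponding to ``exp(+i*2*pi*k*t/n)`` in the time domain.  Concretely,

    spectrum = fft(fid) / sqrt(n)       (``numpy.fft.fft(..., norm="ortho")``)
    fid      = ifft(spectrum) * sqrt(n)

so the transform pair preserves the l2 norm, which keeps coherence values and
residual-norm stopping criteria scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Peak",
    "PeakList",
    "Fid",
    "Spectrum",
    "synth_fid",
    "fft_spectrum",
    "ifft_fid",
    "zero_fill",
    "virtual_echo",
    "hankel_lift",
    "hankel_adjoint",
    "hankel_weights",
]

TRANSFORM_CONVENTION = "unitary:+2pi k t/n"


@dataclass(frozen=True)
class Peak:
    """One Lorentzian component of the spectral model."""

    frequency: float  # cycles per full grid, in [0, n)
    amplitude: float  # >= 0
    phase: float = 0.0  # radians
    decay: float = 0.0  # per-sample relaxation rate, >= 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.decay < 0:
            raise ValueError(f"decay must be >= 0, got {self.decay}")


@dataclass(frozen=True)
class PeakList:
    """Ground-truth spectral model: K peaks with frequency, amplitude, phase, decay."""

    peaks: tuple[Peak, ...]

    def __init__(self, peaks) -> None:
        object.__setattr__(self, "peaks", tuple(
            p if isinstance(p, Peak) else Peak(*p) for p in peaks
        ))

    @property
    def K(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class Fid:
    """Complex time-domain signal on a regular grid of ``n`` points."""

    samples: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("Fid requires a 1-D complex vector of length >= 1")
        if not np.all(np.isfinite(self.samples.view(float))):
            raise ValueError("Fid samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size


@dataclass
class Spectrum:
    """Complex spectrum; the DFT of a :class:`Fid` under the unitary convention."""

    values: np.ndarray
    transform_convention: str = TRANSFORM_CONVENTION

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("Spectrum requires a 1-D complex vector of length >= 1")

    @property
    def n(self) -> int:
        return self.values.size


def synth_fid(model: PeakList, n: int, noise_sigma: float = 0.0,
              seed: int | None = None, label: str = "") -> Fid:
    """Synthesise a Lorentzian FID from a peak model.

    Parameters
    ----------
    model : PeakList
        Peak frequencies, amplitudes, phases and decay rates.
    n : int
        Grid size (number of time-domain samples), >= 1.
    noise_sigma : float
        Standard deviation of the additive complex Gaussian noise per
        real/imaginary component.  0 gives a noiseless signal.
    seed : int, optional
        Seed for the noise generator; required when ``noise_sigma > 0``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0, got {noise_sigma}")
    t = np.arange(n)
    samples = np.zeros(n, dtype=complex)
    for p in model:
        if not (0 <= p.frequency < n):
            raise ValueError(
                f"peak frequency {p.frequency} outside the grid [0, {n})")
        samples += (p.amplitude * np.exp(1j * p.phase)
                    * np.exp((2j * np.pi * p.frequency / n - p.decay) * t))
    if noise_sigma > 0:
        if seed is None:
            raise ValueError("seed is required when noise_sigma > 0")
        rng = np.random.default_rng(seed)
        samples = samples + noise_sigma * (rng.standard_normal(n)
                                           + 1j * rng.standard_normal(n))
    return Fid(samples, label=label)


def fft_spectrum(fid: Fid) -> Spectrum:
    """Unitary DFT of a FID (time -> frequency)."""
    return Spectrum(np.fft.fft(fid.samples, norm="ortho"))


def ifft_fid(spec: Spectrum) -> Fid:
    """Unitary inverse DFT of a spectrum (frequency -> time)."""
    return Fid(np.fft.ifft(spec.values, norm="ortho"))


def zero_fill(fid: Fid, factor: int = 2) -> Fid:
    """Append zeros so the signal has ``factor * n`` points."""
    if int(factor) != factor or factor < 1:
        raise ValueError(f"factor must be an integer >= 1, got {factor}")
    out = np.zeros(int(factor) * fid.n, dtype=complex)
    out[:fid.n] = fid.samples
    return Fid(out, label=fid.label)


def virtual_echo(fid: Fid) -> Fid:
    """Symmetrise the zero-filled FID with its conjugated time reversal.

    The output has length ``2n``; its spectrum is purely real provided the
    input is phased so that the ideal spectrum's real part is absorptive
    (phase 0 — the caller's responsibility).  The first point appears on both
    ends of the reflection, so it is halved before mirroring to avoid double
    counting; this is a discretisation choice, see the methods note.
    """
    n = fid.n
    out = np.zeros(2 * n, dtype=complex)
    out[:n] = fid.samples
    out[0] = fid.samples[0] / 2.0
    # conjugated reflection: out[2n - t] = conj(out[t]) for t = 1..n-1
    out[2 * n - np.arange(1, n)] += np.conj(out[np.arange(1, n)])
    out[0] += np.conj(out[0])
    return Fid(out, label=fid.label)


def hankel_lift(fid: Fid, Q: int) -> np.ndarray:
    """Arrange the FID into an ``(n - Q + 1) x Q`` Hankel matrix.

    Entry ``(i, j)`` is ``samples[i + j]`` (zero-based), i.e. the matrix is
    constant along anti-diagonals.  Its rank equals the number of decaying
    complex exponentials in the signal, which is what low-rank reconstruction
    exploits.  ``Q`` must lie in ``[2, n - 1]`` and should exceed the
    expected number of peaks.
    """
    n = fid.n
    if not (2 <= Q <= n - 1):
        raise ValueError(f"Q must satisfy 2 <= Q <= n - 1 = {n - 1}, got {Q}")
    from scipy.linalg import hankel

    return hankel(fid.samples[: n - Q + 1], fid.samples[n - Q:])


def hankel_adjoint(M: np.ndarray) -> Fid:
    """Exact adjoint of :func:`hankel_lift`: sum each anti-diagonal.

    For an ``(n - Q + 1) x Q`` matrix the output has length ``n``; entry ``t``
    is the sum of ``M[i, j]`` over ``i + j = t``.
    """
    M = np.asarray(M, dtype=complex)
    if M.ndim != 2 or min(M.shape) < 1:
        raise ValueError(f"expected a 2-D matrix, got shape {M.shape}")
    rows, cols = M.shape
    n = rows + cols - 1
    out = np.zeros(n, dtype=complex)
    # anti-diagonals of M are diagonals of the column-reversed matrix
    flipped = M[:, ::-1]
    for t in range(n):
        out[t] = np.trace(flipped, offset=cols - 1 - t)
    return Fid(out)


def hankel_weights(n: int, Q: int) -> np.ndarray:
    """Anti-diagonal multiplicities ``w[t]`` with ``H* (H(f)) = w * f``."""
    rows = n - Q + 1
    t = np.arange(n)
    return np.minimum.reduce([t + 1, n - t, np.full(n, Q), np.full(n, rows)]).astype(float)
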