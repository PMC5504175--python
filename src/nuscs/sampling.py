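"""NUS schedules and sampling diagnostics: PSF, coherence, OMP guarantee.

A non-uniform sampling (NUS) schedule keeps ``m`` of the ``n`` Nyquist-grid
time points.  The direct Fourier transform of the zero-filled data then shows
every peak convolved with the point spread function (PSF) of the schedule —
the DFT of its indicator vector — and the off-centre PSF maxima are the
sampling artifacts.

With the restricted inverse-DFT matrix's columns normalised to unit l2 norm,
the mutual coherence mu equals the highest PSF artifact, and the s-column
coherence mu_s bounds the worst-case pile-up of s overlapping artifact
patterns.  Orthogonal matching pursuit provably recovers every s-sparse
spectrum in at most s iterations when ``mu_s + mu_{s-1} < 1``.

Because the normalised column inner products depend only on the index
difference ``(j - i) mod n``, both mu and mu_s reduce to order statistics of
``|PSF|`` away from zero frequency; the explicit-matrix evaluation is kept to
the test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_model import Fid, Spectrum

__all__ = [
    "Schedule",
    "NusData",
    "CoherenceReport",
    "uniform_schedule",
    "virtual_echo_nus",
    "restrict",
    "zero_fill_nus",
    "psf",
    "coherence",
    "s_coherence",
    "omp_guarantee",
    "coherence_report",
    "restricted_dft_matrix",
]


@dataclass(frozen=True)
class Schedule:
    """Sorted unique zero-based sample indices on a grid of size ``n``."""

    indices: np.ndarray
    n: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1 or idx.size < 1:
            raise ValueError("schedule must contain at least one index")
        if np.any(idx < 0) or np.any(idx >= self.n):
            raise ValueError(f"schedule indices must lie in [0, {self.n})")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("schedule indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)

    @property
    def m(self) -> int:
        return self.indices.size

    def indicator(self) -> np.ndarray:
        ind = np.zeros(self.n)
        ind[self.indices] = 1.0
        return ind


@dataclass
class NusData:
    """Measured NUS values ``y~`` together with their zero-filled embedding ``y~0``."""

    schedule: Schedule
    measured: np.ndarray

    def __post_init__(self) -> None:
        self.measured = np.asarray(self.measured, dtype=complex)
        if self.measured.shape != (self.schedule.m,):
            raise ValueError(
                f"measured must have length m = {self.schedule.m}, "
                f"got shape {self.measured.shape}")

    @property
    def n(self) -> int:
        return self.schedule.n

    @property
    def m(self) -> int:
        return self.schedule.m

    @property
    def zero_filled(self) -> np.ndarray:
        z = np.zeros(self.n, dtype=complex)
        z[self.schedule.indices] = self.measured
        return z


@dataclass
class CoherenceReport:
    """PSF plus the coherence diagnostics derived from it."""

    psf: Spectrum
    mu: float
    mu_s: dict[int, float]
    guarantee_s: int


def uniform_schedule(n: int, m: int, seed: int, keep_first: bool = False) -> Schedule:
    """Draw ``m`` of ``n`` grid indices uniformly without replacement.

    ``keep_first=True`` forces index 0 (the first FID point) into the
    schedule, a common practitioner habit; the default leaves the draw fully
    uniform.
    """
    if not (1 <= m <= n):
        raise ValueError(f"need 1 <= m <= n, got m={m}, n={n}")
    rng = np.random.default_rng(seed)
    if keep_first:
        rest = 1 + rng.choice(n - 1, size=m - 1, replace=False)
        idx = np.concatenate([[0], rest])
    else:
        idx = rng.choice(n, size=m, replace=False)
    return Schedule(np.sort(idx), n)


def restrict(fid: Fid, sched: Schedule) -> NusData:
    """Keep only the scheduled time points of a fully sampled FID."""
    if sched.n != fid.n:
        raise ValueError(f"schedule grid {sched.n} != fid length {fid.n}")
    return NusData(sched, fid.samples[sched.indices])


def zero_fill_nus(nus: NusData) -> Fid:
    """Embed the measured points in a full-length vector, zeros elsewhere."""
    return Fid(nus.zero_filled)


def virtual_echo_nus(nus: NusData) -> NusData:
    """Lift NUS data into the Virtual Echo domain (grid ``2n``).

    Every measured point ``t`` also pins its conjugated mirror ``2n - t``;
    index 0 maps to the real part of its measurement (the half-and-mirror
    construction of :func:`nuscs.signal_model.virtual_echo`).  The lifted
    spectrum of the underlying signal is purely real, which makes phased
    spectra markedly sparser for reconstruction.
    """
    n = nus.n
    idx = nus.schedule.indices
    vals = nus.measured
    lifted: dict[int, complex] = {}
    for t, v in zip(idx, vals):
        if t == 0:
            lifted[0] = complex(v.real)
        else:
            lifted[int(t)] = v
            lifted[2 * n - int(t)] = np.conj(v)
    keys = np.array(sorted(lifted))
    return NusData(Schedule(keys, 2 * n),
                   np.array([lifted[k] for k in keys]))


def psf(sched: Schedule) -> Spectrum:
    """Point spread function: DFT of the schedule indicator, PSF(0) = 1."""
    return Spectrum(np.fft.fft(sched.indicator()) / sched.m)


def _artifact_magnitudes(sched: Schedule) -> np.ndarray:
    """|PSF| at the n - 1 nonzero frequency offsets."""
    return np.abs(psf(sched).values[1:])


def coherence(sched: Schedule) -> float:
    """Mutual coherence mu of the restricted DFT matrix (unit-norm columns).

    Equals ``max_{omega != 0} |PSF(omega)|``.
    """
    if sched.n == 1:
        return 0.0
    return float(np.max(_artifact_magnitudes(sched)))


def s_coherence(sched: Schedule, s: int) -> float:
    """s-column coherence mu_s: worst-case sum of the s largest column overlaps.

    By translation invariance of the restricted-DFT Gram matrix this is the
    sum of the s largest PSF artifact magnitudes.  ``mu_0 = 0`` by convention.
    """
    if s == 0:
        return 0.0
    if not (1 <= s <= sched.n - 1):
        raise ValueError(f"need 1 <= s <= n - 1 = {sched.n - 1}, got s={s}")
    mags = np.sort(_artifact_magnitudes(sched))[::-1]
    return float(np.sum(mags[:s]))


def omp_guarantee(sched: Schedule, s: int) -> bool:
    """Exact-recovery condition for s-sparse spectra: mu_s + mu_{s-1} < 1."""
    return s_coherence(sched, s) + s_coherence(sched, s - 1) < 1.0


def coherence_report(sched: Schedule, s_max: int = 5) -> CoherenceReport:
    """PSF, mu and mu_s for s = 1..s_max, plus the largest guaranteed s."""
    s_max = min(s_max, sched.n - 1)
    mu_s = {s: s_coherence(sched, s) for s in range(1, s_max + 1)}
    guarantee = 0
    for s in range(1, s_max + 1):
        if omp_guarantee(sched, s):
            guarantee = s
    return CoherenceReport(psf=psf(sched), mu=coherence(sched),
                           mu_s=mu_s, guarantee_s=guarantee)


def restricted_dft_matrix(sched: Schedule, normalize: bool = False) -> np.ndarray:
    """Explicit ``m x n`` restricted inverse-DFT matrix F~.

    Maps a spectrum to its time-domain samples at the scheduled points under
    the unitary convention.  With ``normalize=True`` the columns are scaled to
    unit l2 norm (the convention under which mu is defined).  Intended for
    small problems and oracles; the solvers use FFTs instead.
    """
    n = sched.n
    t = sched.indices[:, None]
    k = np.arange(n)[None, :]
    F = np.exp(2j * np.pi * t * k / n) / np.sqrt(n)
    if normalize:
        F = F * np.sqrt(n / sched.m)
    return F
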