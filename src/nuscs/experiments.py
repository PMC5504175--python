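"""Pitfall studies as reusable, seeded workflows.

These drivers reproduce, on synthetic Lorentzian signals, the qualitative
behaviours that matter when choosing a sampling level or a sparsity
constraint in practice:

* residual-vs-m curves — how reconstruction fidelity improves with the
  number of NUS points, and how the required m scales like ``K log(n/K)``
  with the number of significant points rather than as a percentage of n;
* truncated-FID extrapolation — completing the missing tail of a truncated
  signal, where the hard part is getting the decay rate right;
* remedies — L-curve selection of the sparsity weight, cross-validation on
  held-out measured points, and re-adding the final residual to the
  spectrum.

A "method" below is any callable ``method(nus) -> ReconstructionResult``;
the residue metric is the l2 distance between the reconstructed spectrum and
the full-data reference spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .ist import IstConfig, ist_d, ist_s
from .result import ReconstructionResult
from .sampling import NusData, Schedule, restrict, uniform_schedule
from .signal_model import Fid, Spectrum, fft_spectrum

__all__ = [
    "SweepSpec", "CurveResult", "residual_curve", "required_m",
    "first_sufficient_level", "extrapolate", "fit_tail_decay", "l_curve",
    "cross_validate", "readd_residual",
]

Method = Callable[[NusData], ReconstructionResult]


@dataclass
class SweepSpec:
    """One residual-vs-sampling-level experiment.

    ``truth`` is the fully sampled FID; ``levels`` the m values to test
    (ascending); ``n_schedules`` how many independent schedules to average
    per level; ``method`` the reconstruction callable; ``seed`` drives every
    schedule draw.
    """

    truth: Fid
    levels: Sequence[int]
    method: Method
    n_schedules: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        levels = list(self.levels)
        if levels != sorted(levels) or len(set(levels)) != len(levels):
            raise ValueError("levels must be strictly ascending")
        if any(m > self.truth.n for m in levels):
            raise ValueError("levels cannot exceed the grid size")
        if self.n_schedules < 1:
            raise ValueError("n_schedules must be >= 1")


@dataclass
class CurveResult:
    """Per-level residual statistics of a sweep."""

    levels: np.ndarray
    mean_residual: np.ndarray
    std_residual: np.ndarray
    mean_data_residual: np.ndarray
    examples: dict[int, ReconstructionResult]
    n_failed: np.ndarray


def residual_curve(spec: SweepSpec) -> CurveResult:
    """Average reconstruction residue over seeded schedules at each level."""
    ref = fft_spectrum(spec.truth).values
    seed_seq = np.random.SeedSequence(spec.seed)
    child_seeds = seed_seq.generate_state(len(spec.levels) * spec.n_schedules)
    means, stds, data_means, failed = [], [], [], []
    examples: dict[int, ReconstructionResult] = {}
    for li, m in enumerate(spec.levels):
        residues, data_res = [], []
        n_fail = 0
        for si in range(spec.n_schedules):
            seed = int(child_seeds[li * spec.n_schedules + si] % (2**31))
            sched = uniform_schedule(spec.truth.n, m, seed)
            nus = restrict(spec.truth, sched)
            try:
                result = spec.method(nus)
            except (FloatingPointError, np.linalg.LinAlgError):
                n_fail += 1
                continue
            residues.append(np.linalg.norm(result.spectrum.values - ref))
            data_res.append(float(result.residual_trace[-1]))
            if si == 0:
                examples[m] = result
        means.append(np.mean(residues) if residues else np.nan)
        stds.append(np.std(residues) if residues else np.nan)
        data_means.append(np.mean(data_res) if data_res else np.nan)
        failed.append(n_fail)
    return CurveResult(
        levels=np.array(spec.levels), mean_residual=np.array(means),
        std_residual=np.array(stds), mean_data_residual=np.array(data_means),
        examples=examples, n_failed=np.array(failed))


def first_sufficient_level(curve: CurveResult, reference_norm: float,
                           frac: float = 0.1) -> int | None:
    """Smallest sampling level whose mean residual is below ``frac * reference``.

    ``reference_norm`` is normally the l2 norm of the truth spectrum; the
    returned m is the empirical sampling requirement of the sweep (``None``
    if no level suffices).
    """
    for m, r in zip(curve.levels, curve.mean_residual):
        if np.isfinite(r) and r < frac * reference_norm:
            return int(m)
    return None


def required_m(K: int, n: int, c: float = 1.0) -> int:
    """Compressed-sensing sampling-budget rule of thumb: ``ceil(c K ln(n/K))``.

    The number of NUS points needed to recover K significant spectral points
    grows with K and only logarithmically with the grid size n — not as a
    fixed percentage of n.
    """
    if not (1 <= K < n):
        raise ValueError(f"need 1 <= K < n, got K={K}, n={n}")
    if c <= 0:
        raise ValueError("c must be > 0")
    return int(np.ceil(c * K * np.log(n / K)))


def extrapolate(fid_full: Fid, keep: int, cfg: IstConfig) -> ReconstructionResult:
    """Complete a truncated FID: keep the first ``keep`` points, reconstruct the tail.

    Builds the truncation schedule ``{0..keep-1}`` and runs the configured
    IST variant (Virtual Echo lifting per ``cfg.use_ve`` — recommended for
    phased decaying signals, whose complex spectra are otherwise far from
    sparse).  The fitted decay rate of the extrapolated tail is stored in
    ``diagnostics["tail_decay"]`` (see :func:`fit_tail_decay`).
    """
    n = fid_full.n
    if not (1 <= keep <= n):
        raise ValueError(f"need 1 <= keep <= n, got keep={keep}")
    sched = Schedule(np.arange(keep), n)
    nus = restrict(fid_full, sched)
    if cfg.variant == "S":
        result = ist_s(nus, cfg)
    else:
        result = ist_d(nus, cfg)
    if keep < n:
        result.diagnostics["tail_decay"] = fit_tail_decay(result.fid, keep)
    return result


def fit_tail_decay(fid: Fid, start: int) -> float:
    """Least-squares exponential decay rate of the extrapolated tail.

    Fits ``log |y[t]| ~ a - r t`` over the first half of ``t >= start`` and
    returns ``r`` (0 for a flat or growing tail).  The trailing samples are
    excluded because edge effects of the reconstruction (e.g. leakage from
    the Virtual Echo mirror image) contaminate them.
    """
    stop = start + max((fid.n - start) // 2, 2)
    tail = np.abs(fid.samples[start:stop])
    t = np.arange(start, stop)
    keep = tail > 1e-12 * max(np.max(np.abs(fid.samples)), np.finfo(float).tiny)
    if np.count_nonzero(keep) < 2:
        return 0.0
    slope = np.polyfit(t[keep], np.log(tail[keep]), 1)[0]
    return float(max(-slope, 0.0))


def l_curve(nus: NusData, method_factory: Callable[[float], Method],
            lam_grid: Sequence[float],
            penalty: Callable[[Spectrum], float] | None = None,
            ) -> tuple[float, np.ndarray]:
    """Select the sparsity weight at the corner of the L-shaped trade-off curve.

    Runs ``method_factory(lam)`` for every grid value and records the pair
    (data misfit, penalty term); the corner is the point of maximum curvature
    of the log-log curve (three-point finite differences), with ties broken
    towards the larger, i.e. sparser, lambda.  Returns the selected lambda
    and the ``(lam, misfit, penalty)`` table.  A degenerate (flat) curve
    falls back to the grid midpoint.
    """
    lam_grid = sorted(lam_grid)
    if len(lam_grid) < 4:
        raise ValueError("l_curve needs at least 4 grid points")
    if penalty is None:
        penalty = lambda s: float(np.sum(np.abs(s.values)))
    rows = []
    for lam in lam_grid:
        result = method_factory(lam)(nus)
        misfit = float(result.residual_trace[-1])
        rows.append((lam, misfit, penalty(result.spectrum)))
    table = np.array(rows)
    tiny = np.finfo(float).tiny
    lx = np.log10(np.maximum(table[:, 1], tiny))
    ly = np.log10(np.maximum(table[:, 2], tiny))
    if np.ptp(lx) < 1e-12 or np.ptp(ly) < 1e-12:
        return float(lam_grid[len(lam_grid) // 2]), table
    # curvature of (lx, ly) parametrised by the grid index
    d1x, d1y = np.gradient(lx), np.gradient(ly)
    d2x, d2y = np.gradient(d1x), np.gradient(d1y)
    denom = (d1x**2 + d1y**2) ** 1.5
    curvature = np.abs(d1x * d2y - d1y * d2x) / np.maximum(denom, tiny)
    best = np.flatnonzero(curvature == curvature.max())[-1]  # tie -> larger lam
    return float(table[best, 0]), table


def cross_validate(nus: NusData, method_factory: Callable[..., Method],
                   param_grid: Sequence[dict], holdout_frac: float = 0.25,
                   seed: int = 0) -> tuple[dict, np.ndarray]:
    """Pick reconstruction parameters by misfit on held-out measured points.

    A ``holdout_frac`` share of the scheduled points is set aside (uniformly,
    seeded); each candidate in ``param_grid`` (a dict of keyword arguments
    for ``method_factory``) is used to reconstruct from the remaining points
    and scored by the l2 misfit of its FID at the held-out points.  Returns
    the winning parameters and the per-candidate score vector.
    """
    if not (0 < holdout_frac <= 0.5):
        raise ValueError("holdout_frac must lie in (0, 0.5]")
    m = nus.m
    n_hold = int(round(holdout_frac * m))
    if m - n_hold < 1:
        raise ValueError("training set would be empty")
    rng = np.random.default_rng(seed)
    hold_pos = np.sort(rng.choice(m, size=n_hold, replace=False))
    train_pos = np.setdiff1d(np.arange(m), hold_pos)
    train = NusData(Schedule(nus.schedule.indices[train_pos], nus.n),
                    nus.measured[train_pos])
    hold_idx = nus.schedule.indices[hold_pos]
    hold_vals = nus.measured[hold_pos]
    scores = []
    for params in param_grid:
        result = method_factory(**params)(train)
        scores.append(float(np.linalg.norm(
            result.fid.samples[hold_idx] - hold_vals)))
    scores = np.array(scores)
    return dict(param_grid[int(np.argmin(scores))]), scores


def readd_residual(result: ReconstructionResult, nus: NusData,
                   density_weights: np.ndarray | None = None) -> Spectrum:
    """Add the spectrum of the zero-filled final residual back to the output.

    Restores signal that the sparse solver stopped short of reconstructing
    (at the price of re-admitting some artifacts and noise), and makes the
    output exactly consistent with the measured data.  ``density_weights``
    is a per-point scaling hook for non-uniform sampling densities; identity
    by default, as only uniform densities are in scope here.
    """
    residual = nus.measured - result.fid.samples[nus.schedule.indices]
    if density_weights is not None:
        residual = residual * np.asarray(density_weights)
    r0 = np.zeros(nus.n, dtype=complex)
    r0[nus.schedule.indices] = residual
    return Spectrum(result.spectrum.values + np.fft.fft(r0, norm="ortho"))
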