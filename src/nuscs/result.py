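"""Shared reconstruction-result container used by every solver module."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_model import Fid, Spectrum

__all__ = ["ReconstructionResult"]


@dataclass
class ReconstructionResult:
    """Outcome of a NUS reconstruction.

    Attributes
    ----------
    spectrum : Spectrum
        The reconstructed spectrum ``x``.
    fid : Fid
        Its inverse Fourier transform (the reconstructed time-domain signal).
    support : ndarray of int, or None
        Support ``I = supp x`` for solvers that build one explicitly
        (CLEAN/OMP); ``None`` for dense solvers.
    residual_trace : ndarray of float
        Data-domain residual l2 norm per iteration, starting from the norm of
        the measured data before the first iteration.
    iterations : int
        Number of iterations actually performed.
    converged : bool
        Whether the solver met its stopping tolerance (as opposed to running
        into its iteration cap or a divergence guard).
    diagnostics : dict
        Free-form solver notes (degenerate supports, guard activations, ...).
    """

    spectrum: Spectrum
    fid: Fid
    support: np.ndarray | None
    residual_trace: np.ndarray
    iterations: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)
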