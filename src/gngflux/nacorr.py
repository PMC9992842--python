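"""Natural-abundance correction of mass isotopomer distributions.

At natural abundance ~1.07% of carbon is 13C, so an entirely unlabeled
C-carbon metabolite still shows M+1 and M+2 signal.  The forward model is a
column-stochastic lower-triangular matrix A with

    A[j, i] = Binom(C - i, j - i) * p**(j - i) * (1 - p)**(C - j),  j >= i,

the probability of observing M+j when i carbons are tracer-labeled and the
remaining C - i carbons pick up 13C at the natural rate p.  Correction
deconvolves the observed MID by solving ``min ||A x - observed||`` subject to
x >= 0 (the default), or by plain matrix inversion with negative clipping
(``inverse_clip``) kept for cross-checks.  Only carbon is corrected; H/N/O
isotopes are ignored, which is adequate for the small gluconeogenic
metabolites this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom

from .io import IsotopologueSpectrum

#: Standard terrestrial natural abundance of 13C.
NATURAL_ABUNDANCE_13C = 0.0107

CORRECTION_MODES = ("constrained", "inverse_clip")


@dataclass(frozen=True)
class CorrectionMatrix:
    """Forward natural-abundance convolution matrix for a C-carbon metabolite."""

    carbon_count: int
    p: float
    A: np.ndarray


def build_correction_matrix(C: int, p: float = NATURAL_ABUNDANCE_13C) -> CorrectionMatrix:
    """Build the (C+1)x(C+1) natural-abundance matrix for carbon count ``C``.

    Each column i is the binomial distribution of extra natural 13C atoms on
    the C - i unlabeled positions, so every column sums to one.
    """
    if C < 1:
        raise ValueError(f"carbon count must be >= 1, got {C}")
    if not 0.0 <= p < 1.0:
        raise ValueError(f"natural abundance p must be in [0, 1), got {p}")
    j = np.arange(C + 1)[:, None]
    i = np.arange(C + 1)[None, :]
    A = binom.pmf(j - i, C - i, p)
    A = np.where(j >= i, A, 0.0)
    return CorrectionMatrix(carbon_count=C, p=p, A=A)


def convolve_natural_abundance(
    true_spectrum: IsotopologueSpectrum, p: float = NATURAL_ABUNDANCE_13C
) -> IsotopologueSpectrum:
    """Forward-apply natural abundance to a tracer-labeled fractional MID."""
    if not true_spectrum.is_fraction:
        raise ValueError("convolve_natural_abundance expects a fractional spectrum")
    A = build_correction_matrix(true_spectrum.carbon_count, p).A
    return true_spectrum.with_values(A @ true_spectrum.values, is_fraction=True)


def correct_spectrum(
    observed: IsotopologueSpectrum,
    p: float = NATURAL_ABUNDANCE_13C,
    mode: str = "constrained",
) -> IsotopologueSpectrum:
    """Remove natural-abundance signal from an observed fractional MID.

    ``constrained`` solves ``min ||A x - observed||, x >= 0`` and renormalises;
    plain inversion can go negative under noise, so ``inverse_clip`` (invert,
    clip negatives, renormalise) exists only as an oracle path.
    """
    if not observed.is_fraction:
        raise ValueError("correct_spectrum expects a fractional spectrum")
    if mode not in CORRECTION_MODES:
        raise ValueError(f"correction mode must be one of {CORRECTION_MODES}, got {mode!r}")
    A = build_correction_matrix(observed.carbon_count, p).A
    if mode == "constrained":
        x, _ = nnls(A, observed.values)
    else:
        x = np.linalg.solve(A, observed.values)
        x = np.clip(x, 0.0, None)
    total = x.sum()
    if total <= 0:
        raise ValueError(f"{observed.metabolite}: corrected spectrum vanished")
    return observed.with_values(x / total, is_fraction=True)
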