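"""Spectral similarity and coverage metrics.

The central score is a tolerance-matched cosine similarity on square-root
transformed intensities, evaluated with and without the precursor peak.
Coverage measures the fraction of experimental intensity that falls on peaks
explainable by the prediction; because a single perfectly placed peak can at
best capture all covered intensity, the cosine of any prediction is bounded
by sqrt(coverage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum

__all__ = [
    "SimilarityResult",
    "spectral_cosine",
    "spectral_coverage",
    "max_cosine_bound",
    "compare_spectra",
]

DEFAULT_TOL_DA = 0.01


@dataclass
class SimilarityResult:
    cosine: float
    cosine_no_precursor: float
    coverage: float
    n_matched: int
    bias: float  # largest single matched product term / total dot product


def _tol_da(tol: float, unit: str, mz: float) -> float:
    return tol if unit == "da" else mz * tol * 1e-6


def _prepare(s: Spectrum, sqrt_transform: bool, exclude_precursor: bool,
             tol: float, unit: str) -> tuple[np.ndarray, np.ndarray]:
    mz, inten = s.mz, s.intensity
    if exclude_precursor and s.precursor_mz:
        keep = np.abs(mz - s.precursor_mz) > _tol_da(tol, unit, s.precursor_mz)
        mz, inten = mz[keep], inten[keep]
    if sqrt_transform:
        inten = np.sqrt(inten)
    return mz, inten


def _matched_products(mz_a, int_a, mz_b, int_b, tol, unit):
    """Per-pair intensity products I_k * I_l for all peak pairs within tolerance."""
    products = []
    matched_a = np.zeros(len(mz_a), dtype=bool)
    for k, (mk, ik) in enumerate(zip(mz_a, int_a)):
        t = _tol_da(tol, unit, mk)
        close = np.abs(mz_b - mk) <= t
        if np.any(close):
            matched_a[k] = True
            products.extend(ik * int_b[close])
    return np.array(products), matched_a


def spectral_cosine(
    s_a: Spectrum,
    s_b: Spectrum,
    tol: float = DEFAULT_TOL_DA,
    tol_unit: str = "da",
    sqrt_transform: bool = True,
    exclude_precursor: bool = False,
) -> float:
    """Tolerance-matched cosine similarity between two spectra, in [0, 1].

    Peaks of the two spectra are paired whenever their m/z differ by at most
    ``tol`` (Da, or ppm of the first spectrum's peak m/z); intensity products
    are summed within the tolerance window, so the score reflects the cosine
    angle exactly only when matches are unique.  The square-root transform is
    applied before everything; with ``exclude_precursor`` peaks within
    tolerance of each spectrum's own precursor m/z are removed first.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    mz_a, int_a = _prepare(s_a, sqrt_transform, exclude_precursor, tol, tol_unit)
    mz_b, int_b = _prepare(s_b, sqrt_transform, exclude_precursor, tol, tol_unit)
    norm = np.linalg.norm(int_a) * np.linalg.norm(int_b)
    if norm == 0:
        warnings.warn("cosine of empty spectrum defined as 0", stacklevel=2)
        return 0.0
    products, _ = _matched_products(mz_a, int_a, mz_b, int_b, tol, tol_unit)
    return float(min(1.0, products.sum() / norm))


def spectral_coverage(
    s_exp: Spectrum,
    s_pred: Spectrum,
    tol: float = DEFAULT_TOL_DA,
    tol_unit: str = "da",
) -> float:
    """Fraction of experimental intensity on peaks with a predicted peak in
    tolerance.  Raw (untransformed) intensities, normalized to unit sum."""
    if s_exp.n_peaks == 0:
        raise ValueError("empty experimental spectrum")
    total = s_exp.intensity.sum()
    if total <= 0:
        raise ValueError("experimental spectrum has zero total intensity")
    covered = 0.0
    for mk, ik in zip(s_exp.mz, s_exp.intensity):
        t = _tol_da(tol, tol_unit, mk)
        if np.any(np.abs(s_pred.mz - mk) <= t):
            covered += ik
    return float(min(1.0, covered / total))


def max_cosine_bound(coverage: float) -> float:
    """Optimistic upper bound on achievable cosine at a given intensity
    coverage: sqrt(coverage), attained when all covered intensity sits on a
    single predicted peak."""
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    return float(np.sqrt(coverage))


def compare_spectra(
    s_exp: Spectrum,
    s_pred: Spectrum,
    tol: float = DEFAULT_TOL_DA,
    tol_unit: str = "da",
) -> SimilarityResult:
    """Full similarity report between an experimental and a predicted spectrum."""
    mz_a, int_a = _prepare(s_exp, True, False, tol, tol_unit)
    mz_b, int_b = _prepare(s_pred, True, False, tol, tol_unit)
    norm = np.linalg.norm(int_a) * np.linalg.norm(int_b)
    products, matched = _matched_products(mz_a, int_a, mz_b, int_b, tol, tol_unit)
    dot = products.sum()
    return SimilarityResult(
        cosine=float(min(1.0, dot / norm)) if norm > 0 else 0.0,
        cosine_no_precursor=spectral_cosine(
            s_exp, s_pred, tol=tol, tol_unit=tol_unit, exclude_precursor=True
        ),
        coverage=spectral_coverage(s_exp, s_pred, tol=tol, tol_unit=tol_unit),
        n_matched=int(matched.sum()),
        bias=float(products.max() / dot) if dot > 0 else 0.0,
    )
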