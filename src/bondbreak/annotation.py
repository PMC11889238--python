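"""Peak-to-fragment matching, training targets and curation filters.

Experimental peaks are matched to the enumerated fragment ion space at a ppm
tolerance.  Matched peaks define a ground-truth probability distribution over
fragment ions plus the precursor (square-root intensities; ambiguous matches
split equally), which is what the model is trained against.  Curation filters
then decide which spectra carry enough explainable signal to train on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fragments import FragmentIonSpace
from .spectra import Spectrum

__all__ = [
    "PeakMatch",
    "TargetDistribution",
    "FilterReport",
    "match_peaks",
    "assign_target_probabilities",
    "apply_training_filters",
    "nce_to_ev",
    "UnassignableSpectrumError",
]

DEFAULT_TOL_PPM = 50.0

# Thermo-convention charge factors for converting normalized collision energy
# (NCE, %) to eV: eV = NCE * (precursor_mz / 500) * factor(charge).
NCE_CHARGE_FACTORS = {1: 1.0, 2: 0.9, 3: 0.85}
NCE_CHARGE_FACTOR_HIGH = 0.8  # charge >= 4


class UnassignableSpectrumError(ValueError):
    """No peak could be assigned to any fragment ion or the precursor."""


@dataclass
class PeakMatch:
    peak_index: int
    matched_ion_keys: list[tuple[int, str, int]]
    ppm_errors: list[float]
    is_precursor: bool = False


@dataclass
class TargetDistribution:
    """Ground-truth probability vector over fragment ions + precursor."""

    probabilities: dict[tuple[int, str, int], float]
    precursor_probability: float
    coverage: float  # matched fraction of raw (untransformed) total intensity
    precursor_fraction: float  # precursor peak's share of raw total intensity
    n_matched_peaks: int  # fragment-matched peaks, precursor excluded
    n_peaks: int

    def as_vector(self, space: FragmentIonSpace):
        import numpy as np

        vec = np.zeros(len(space) + 1)
        for key, p in self.probabilities.items():
            vec[space.index[key]] = p
        vec[-1] = self.precursor_probability
        return vec


@dataclass
class FilterReport:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    statistics: dict = field(default_factory=dict)


def match_peaks(
    spectrum: Spectrum,
    space: FragmentIonSpace,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> list[PeakMatch]:
    """Match every peak against every fragment ion at ``tol_ppm``.

    All qualifying ions are recorded per peak (no greedy one-to-one
    assignment).  The peak closest to the declared precursor m/z within
    tolerance is flagged as the precursor; precursor assignment wins over any
    fragment-ion match on that peak.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if spectrum.n_peaks == 0:
        raise ValueError("empty spectrum")

    prec_mz = spectrum.precursor_mz
    prec_idx: int | None = None
    if prec_mz and prec_mz > 0:
        best = None
        for k, mz in enumerate(spectrum.mz):
            ppm = abs(mz - prec_mz) / prec_mz * 1e6
            if ppm <= tol_ppm and (best is None or ppm < best[0]):
                best = (ppm, k)
        if best is not None:
            prec_idx = best[1]

    matches: list[PeakMatch] = []
    for k, mz in enumerate(spectrum.mz):
        if k == prec_idx:
            matches.append(PeakMatch(k, [], [], is_precursor=True))
            continue
        keys, errs = [], []
        for ion in space.ions:
            ppm = abs(mz - ion.mz) / ion.mz * 1e6
            if ppm <= tol_ppm:
                keys.append(ion.key)
                errs.append(ppm)
        if keys:
            matches.append(PeakMatch(k, keys, errs))
    return matches


def assign_target_probabilities(
    spectrum: Spectrum, matches: list[PeakMatch]
) -> TargetDistribution:
    """Derive the training target distribution from peak matches.

    Each matched peak contributes its square-root intensity, split equally
    among the ions that can explain it; the precursor peak contributes its
    square-root intensity to the precursor slot.  Contributions are normalized
    to sum 1; unmatched peaks are dropped before normalization.  Coverage is
    the matched share of the raw (untransformed) total intensity, precursor
    included.
    """
    import math

    raw_total = float(spectrum.intensity.sum())
    if raw_total <= 0:
        raise UnassignableSpectrumError("spectrum has zero total intensity")

    probs: dict[tuple[int, str, int], float] = {}
    precursor_mass = 0.0
    matched_raw = 0.0
    precursor_raw = 0.0
    n_matched_peaks = 0
    for m in matches:
        inten = float(spectrum.intensity[m.peak_index])
        w = math.sqrt(inten)
        if m.is_precursor:
            precursor_mass += w
            precursor_raw += inten
            matched_raw += inten
        elif m.matched_ion_keys:
            n_matched_peaks += 1
            matched_raw += inten
            share = w / len(m.matched_ion_keys)
            for key in m.matched_ion_keys:
                probs[key] = probs.get(key, 0.0) + share

    total = sum(probs.values()) + precursor_mass
    if total <= 0:
        raise UnassignableSpectrumError(
            "no peak matches any fragment ion and no precursor peak found"
        )
    return TargetDistribution(
        probabilities={k: v / total for k, v in probs.items()},
        precursor_probability=precursor_mass / total,
        coverage=matched_raw / raw_total,
        precursor_fraction=precursor_raw / raw_total,
        n_matched_peaks=n_matched_peaks,
        n_peaks=spectrum.n_peaks,
    )


def apply_training_filters(
    spectrum: Spectrum,
    target: TargetDistribution,
    weight_da: float,
    collision_energy_ev: float | None,
    max_weight_da: float = 1000.0,
    max_collision_energy_ev: float = 100.0,
    min_matched_peaks: int = 2,
    min_coverage: float = 0.5,
    max_precursor_fraction: float = 0.9,
    soft_min_matched_fraction: float = 0.5,
    soft_min_matched_peaks: int = 5,
    soft_min_coverage: float = 0.8,
) -> FilterReport:
    """Decide whether a matched spectrum qualifies as training data.

    Hard rules (all must hold): molecular weight <= 1000 Da, collision energy
    <= 100 eV, >= 2 fragment-matched peaks, intensity coverage >= 50%, and
    precursor share of raw intensity <= 90%.  Soft rules (at least one must
    hold): >= 50% of all peaks matched, or >= 5 peaks matched, or coverage
    >= 0.8.
    """
    reasons: list[str] = []
    if weight_da > max_weight_da:
        reasons.append("max_weight")
    if collision_energy_ev is None or collision_energy_ev > max_collision_energy_ev:
        reasons.append("max_collision_energy")
    if target.n_matched_peaks < min_matched_peaks:
        reasons.append("min_matched_peaks")
    if target.coverage < min_coverage:
        reasons.append("min_coverage")
    if target.precursor_fraction > max_precursor_fraction:
        reasons.append("max_precursor_fraction")

    matched_fraction = target.n_matched_peaks / target.n_peaks if target.n_peaks else 0.0
    soft_ok = (
        matched_fraction >= soft_min_matched_fraction
        or target.n_matched_peaks >= soft_min_matched_peaks
        or target.coverage >= soft_min_coverage
    )
    if not soft_ok:
        reasons.append("soft_rules")

    return FilterReport(
        passed=not reasons,
        reasons=reasons,
        statistics={
            "coverage": target.coverage,
            "precursor_fraction": target.precursor_fraction,
            "n_matched_peaks": target.n_matched_peaks,
            "n_peaks": target.n_peaks,
            "matched_fraction": matched_fraction,
            "weight_da": weight_da,
            "collision_energy_ev": collision_energy_ev,
        },
    )


def nce_to_ev(nce_percent: float, precursor_mz: float, charge: int = 1) -> float:
    """Convert normalized collision energy (%) to eV.

    eV = NCE * (precursor_mz / 500) * charge_factor with the Thermo-convention
    charge factors {1: 1.0, 2: 0.9, 3: 0.85, >=4: 0.8}.
    """
    if nce_percent <= 0:
        raise ValueError("NCE must be positive")
    if precursor_mz is None or precursor_mz <= 0:
        raise ValueError("precursor m/z required to convert NCE to eV")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    factor = NCE_CHARGE_FACTORS.get(charge, NCE_CHARGE_FACTOR_HIGH)
    return nce_percent * (precursor_mz / 500.0) * factor
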