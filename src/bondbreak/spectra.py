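"""Spectrum container, spectral reconstruction and merging.

A spectrum is a centroided peak list (m/z, intensity) with precursor m/z and
acquisition metadata.  Reconstruction turns a probability vector over the
fragment ion space (plus the precursor) into a stick spectrum: ions falling on
the same exact m/z are summed, because distinct ions can produce the same
peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fragments import FragmentIonSpace

__all__ = ["Spectrum", "reconstruct_spectrum", "merge_stepped", "consensus_merge"]


@dataclass
class Spectrum:
    mz: np.ndarray  # sorted ascending
    intensity: np.ndarray  # >= 0, same length
    precursor_mz: float
    ion_mode: str = "+"  # "+" or "-"
    collision_energy_ev: float | None = None
    instrument: str | None = None
    adduct: str | None = None
    retention_time_s: float | None = None
    ccs: float | None = None
    smiles: str | None = None
    inchikey: str | None = None
    name: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return len(self.mz)

    def normalized(self, to: str = "sum") -> "Spectrum":
        """Copy with intensities scaled to unit sum ('sum') or unit max ('max')."""
        total = self.intensity.sum() if to == "sum" else self.intensity.max(initial=0.0)
        scale = 1.0 / total if total > 0 else 1.0
        return replace(self, mz=self.mz.copy(), intensity=self.intensity * scale)

    def without_precursor(self, tol_da: float | None = None, tol_ppm: float | None = 20.0) -> "Spectrum":
        """Copy with peaks within tolerance of the precursor m/z removed."""
        if tol_da is None:
            tol_da = self.precursor_mz * (tol_ppm or 0.0) * 1e-6
        keep = np.abs(self.mz - self.precursor_mz) > tol_da
        return replace(self, mz=self.mz[keep], intensity=self.intensity[keep])


def _group_peaks(mz: np.ndarray, intensity: np.ndarray, tol_da: float,
                 weighted_mz: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Cluster sorted peaks whose consecutive gaps are <= tol_da; sum intensities."""
    if len(mz) == 0:
        return mz, intensity
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    out_mz, out_int = [], []
    start = 0
    for i in range(1, len(mz) + 1):
        if i == len(mz) or mz[i] - mz[i - 1] > tol_da:
            chunk_mz, chunk_int = mz[start:i], intensity[start:i]
            total = chunk_int.sum()
            if weighted_mz and total > 0:
                out_mz.append(float((chunk_mz * chunk_int).sum() / total))
            else:
                out_mz.append(float(chunk_mz[0]))
            out_int.append(float(total))
            start = i
    return np.array(out_mz), np.array(out_int)


def reconstruct_spectrum(
    probabilities: np.ndarray,
    space: FragmentIonSpace,
    precursor_mz: float,
    **metadata,
) -> Spectrum:
    """Build a stick spectrum from ion probabilities plus precursor probability.

    ``probabilities`` has length ``len(space) + 1``; the last entry is the
    precursor probability.  Ions within 1e-6 Da are treated as the same peak
    and their probabilities summed.  Output intensities sum to 1.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.shape != (len(space) + 1,):
        raise ValueError("probability vector must have length |ion space| + 1")
    mzs = np.array(space.mz_array() + [precursor_mz])
    mz, intensity = _group_peaks(mzs, probabilities, tol_da=1e-6)
    return Spectrum(
        mz=mz,
        intensity=intensity,
        precursor_mz=precursor_mz,
        ion_mode=space.ion_mode,
        **metadata,
    )


def _check_same_compound(spectra: list[Spectrum]) -> None:
    keys = {(s.inchikey or s.smiles or s.name, s.ion_mode) for s in spectra}
    if len(keys) > 1:
        raise ValueError(f"cannot merge spectra from different compounds/modes: {keys}")


def merge_stepped(spectra: list[Spectrum], tol_da: float = 1e-6,
                  tol_ppm: float | None = None) -> Spectrum:
    """Merge spectra acquired (or predicted) at several collision energies.

    Peaks agreeing within tolerance are averaged over the number of input
    spectra (a peak absent from a spectrum counts as zero), then the result is
    renormalized to maximum intensity 1.  Cosine comparisons are
    scale-invariant, so the sum/mean choice only fixes the output scale.
    """
    if not spectra:
        raise ValueError("cannot merge an empty list of spectra")
    _check_same_compound(spectra)
    all_mz = np.concatenate([s.mz for s in spectra])
    all_int = np.concatenate([s.intensity for s in spectra])
    if tol_ppm is not None and len(all_mz):
        tol_da = float(np.median(all_mz)) * tol_ppm * 1e-6
    mz, intensity = _group_peaks(all_mz, all_int / len(spectra), tol_da=tol_da)
    ces = [s.collision_energy_ev for s in spectra if s.collision_energy_ev is not None]
    merged = Spectrum(
        mz=mz,
        intensity=intensity,
        precursor_mz=spectra[0].precursor_mz,
        ion_mode=spectra[0].ion_mode,
        instrument=spectra[0].instrument,
        adduct=spectra[0].adduct,
        smiles=spectra[0].smiles,
        inchikey=spectra[0].inchikey,
        name=spectra[0].name,
        collision_energy_ev=float(np.mean(ces)) if ces else None,
        extra={"stepped_collision_energies_ev": ces},
    )
    return merged.normalized(to="max")


def consensus_merge(replicates: list[Spectrum], tol_ppm: float = 10.0) -> Spectrum:
    """Consensus of replicate acquisitions at the same collision energy.

    Peaks are clustered at ``tol_ppm``; a cluster's m/z is the
    intensity-weighted mean of its members and its intensity the mean across
    replicates (replicates missing the peak contribute zero).
    """
    if not replicates:
        raise ValueError("cannot build a consensus from an empty list")
    _check_same_compound(replicates)
    all_mz = np.concatenate([s.mz for s in replicates])
    all_int = np.concatenate([s.intensity for s in replicates])
    if len(all_mz) == 0:
        return replace(replicates[0], mz=all_mz, intensity=all_int)
    tol_da = float(np.median(all_mz)) * tol_ppm * 1e-6
    mz, intensity = _group_peaks(
        all_mz, all_int / len(replicates), tol_da=tol_da, weighted_mz=True
    )
    return replace(replicates[0], mz=mz, intensity=intensity)
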