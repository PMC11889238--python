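"""NIST-style .msp spectral library reading, writing and harmonization.

An .msp library is a sequence of key/value metadata blocks, each followed by
"Num Peaks: N" and N peak lines of "mz intensity [annotation]", separated by
blank lines.  The reader is streaming (one record in memory at a time),
case-insensitive on keys and tolerant of the common NIST/GNPS alias spellings;
malformed records are collected into a report instead of aborting the parse.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .annotation import nce_to_ev
from .chem import SmilesParseError, inchikey as compute_inchikey, parse_smiles
from .spectra import Spectrum

__all__ = [
    "LibraryRecord",
    "read_msp",
    "write_msp",
    "harmonize_metadata",
    "Exclusion",
    "parse_collision_energy",
]

# canonical key <- accepted alias spellings (compared lowercase, no separators)
_KEY_ALIASES = {
    "name": ("name",),
    "precursor_mz": ("precursormz", "precursorm/z", "pepmass"),
    "precursor_type": ("precursortype", "adduct", "precursor_type"),
    "collision_energy": ("collisionenergy", "ce", "collision_energy"),
    "instrument": ("instrumenttype", "instrument"),
    "smiles": ("smiles",),
    "inchikey": ("inchikey",),
    "retention_time": ("retentiontime", "rt"),
    "ccs": ("ccs",),
    "ion_mode": ("ionmode", "ionization", "ion_mode"),
    "num_peaks": ("numpeaks", "num_peaks"),
    "comment": ("comment", "comments"),
}
_ALIAS_TO_KEY = {
    alias: key for key, aliases in _KEY_ALIASES.items() for alias in aliases
}

SUPPORTED_ADDUCTS = {
    "[M+H]+": ("+", "[M+H]+"),
    "[M+H]": ("+", "[M+H]+"),
    "M+H": ("+", "[M+H]+"),
    "[M-H]-": ("-", "[M-H]-"),
    "[M-H]": ("-", "[M-H]-"),
    "M-H": ("-", "[M-H]-"),
}


@dataclass
class LibraryRecord:
    spectrum: Spectrum | None
    raw_metadata: dict[str, str]
    source_file: str
    record_index: int
    errors: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return self.spectrum is not None and not self.errors


@dataclass
class Exclusion:
    record_index: int
    reason: str
    name: str | None = None


def _normalize_key(key: str) -> str | None:
    flat = re.sub(r"[\s_\-/]", "", key).lower()
    return _ALIAS_TO_KEY.get(flat)


def _build_record(
    meta: dict[str, str], peaks: list[tuple[float, float]],
    path: str, index: int, errors: list[str],
) -> LibraryRecord:
    declared = meta.get("num_peaks")
    if declared is not None:
        try:
            if int(float(declared)) != len(peaks):
                errors.append(
                    f"Num Peaks mismatch: declared {declared}, found {len(peaks)}"
                )
        except ValueError:
            errors.append(f"unreadable Num Peaks value {declared!r}")
    spectrum = None
    if not errors:
        try:
            prec = float(meta.get("precursor_mz", "nan"))
        except ValueError:
            prec = float("nan")
        mode = meta.get("ion_mode", "").strip().lower()
        ion_mode = "-" if mode.startswith(("n", "-")) else "+"
        if "precursor_type" in meta and "-" in meta["precursor_type"].replace("[M", ""):
            ion_mode = "-" if "]-" in meta["precursor_type"] else ion_mode
        mz = np.array([p[0] for p in peaks])
        inten = np.array([p[1] for p in peaks])
        spectrum = Spectrum(
            mz=mz,
            intensity=inten,
            precursor_mz=prec,
            ion_mode=ion_mode,
            adduct=meta.get("precursor_type"),
            instrument=meta.get("instrument"),
            smiles=meta.get("smiles"),
            inchikey=meta.get("inchikey"),
            name=meta.get("name"),
            retention_time_s=_maybe_float(meta.get("retention_time")),
            ccs=_maybe_float(meta.get("ccs")),
            extra={"collision_energy_raw": meta.get("collision_energy")},
        )
    return LibraryRecord(
        spectrum=spectrum,
        raw_metadata=dict(meta),
        source_file=path,
        record_index=index,
        errors=errors,
    )


def _maybe_float(v: str | None) -> float | None:
    if v is None:
        return None
    try:
        return float(v.split()[0])
    except (ValueError, IndexError):
        return None


def read_msp(path: str) -> Iterator[LibraryRecord]:
    """Stream records from an .msp file, one at a time.

    Records with structural problems (unreadable peak lines, peak-count
    mismatch) are yielded with ``errors`` set and ``spectrum=None`` rather
    than raising, so callers can collect a parse report while continuing.
    """
    meta: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    errors: list[str] = []
    index = 0
    in_record = False

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                if in_record:
                    yield _build_record(meta, peaks, path, index, errors)
                    index += 1
                    meta, peaks, errors, in_record = {}, [], [], False
                continue
            in_record = True
            if ":" in line and not line[0].isdigit():
                raw_key, _, value = line.partition(":")
                key = _normalize_key(raw_key)
                if key is not None:
                    meta[key] = value.strip()
                continue
            parts = line.replace(",", " ").split()
            try:
                peaks.append((float(parts[0]), float(parts[1])))
            except (ValueError, IndexError):
                errors.append(f"unreadable peak line: {line!r}")
    if in_record:
        yield _build_record(meta, peaks, path, index, errors)


_FIELD_ORDER = [
    ("name", "Name"),
    ("precursor_mz", "PrecursorMZ"),
    ("precursor_type", "Precursor_type"),
    ("ion_mode", "Ion_mode"),
    ("collision_energy", "Collision_energy"),
    ("instrument", "Instrument_type"),
    ("smiles", "SMILES"),
    ("inchikey", "InChIKey"),
    ("retention_time", "RETENTIONTIME"),
    ("ccs", "CCS"),
]


def write_msp(records, path: str) -> None:
    """Write records (LibraryRecord or Spectrum) as a .msp library.

    Deterministic field order; m/z at 6 decimals and intensity at 4
    significant figures.
    """
    with open(path, "w") as fh:
        for rec in records:
            spec = rec.spectrum if isinstance(rec, LibraryRecord) else rec
            if spec is None:
                continue
            meta = {
                "name": spec.name,
                "precursor_mz": f"{spec.precursor_mz:.6f}" if spec.precursor_mz else None,
                "precursor_type": spec.adduct,
                "ion_mode": "P" if spec.ion_mode == "+" else "N",
                "collision_energy": (
                    f"{spec.collision_energy_ev:g} eV"
                    if spec.collision_energy_ev is not None
                    else None
                ),
                "instrument": spec.instrument,
                "smiles": spec.smiles,
                "inchikey": spec.inchikey,
                "retention_time": (
                    f"{spec.retention_time_s:g}" if spec.retention_time_s is not None else None
                ),
                "ccs": f"{spec.ccs:g}" if spec.ccs is not None else None,
            }
            for key, label in _FIELD_ORDER:
                if meta.get(key) is not None:
                    fh.write(f"{label}: {meta[key]}\n")
            fh.write(f"Num Peaks: {spec.n_peaks}\n")
            for mz, inten in zip(spec.mz, spec.intensity):
                fh.write(f"{mz:.6f} {inten:.4g}\n")
            fh.write("\n")


_CE_PATTERNS = [
    (re.compile(r"^(?:nce\s*)?(\d+(?:\.\d+)?)\s*%(?:\s*\(nominal\))?$", re.I), "nce"),
    (re.compile(r"^nce\s*(\d+(?:\.\d+)?)\s*%?$", re.I), "nce"),
    (re.compile(r"^(\d+(?:\.\d+)?)\s*(?:ev)?$", re.I), "ev"),
]


def parse_collision_energy(text: str | None) -> tuple[float, str] | None:
    """Parse a collision-energy string into (value, unit) with unit 'ev' or
    'nce'.  Accepts "35", "35 eV", "NCE 35%", "35% (nominal)"; anything else
    is an unclear format and returns None."""
    if text is None or not text.strip():
        return None
    text = text.strip()
    for pattern, unit in _CE_PATTERNS:
        m = pattern.match(text)
        if m:
            return float(m.group(1)), unit
    return None


def harmonize_metadata(
    record: LibraryRecord,
    check_structure: bool = True,
) -> LibraryRecord | Exclusion:
    """Normalize a record's metadata or exclude it with a reason.

    Adducts are restricted to [M+H]+ / [M-H]-; collision energy is normalized
    to eV (converting NCE via the precursor m/z); a SMILES/InChIKey
    inconsistency or an unparsable structure excludes the record.  Exclusions
    are returned as data, not raised.
    """
    def exclude(reason: str) -> Exclusion:
        return Exclusion(
            record_index=record.record_index,
            reason=reason,
            name=record.raw_metadata.get("name"),
        )

    if record.spectrum is None or record.errors:
        return exclude("malformed record: " + "; ".join(record.errors))
    spec = record.spectrum

    adduct = (spec.adduct or "").strip()
    if adduct not in SUPPORTED_ADDUCTS:
        return exclude("unsupported adduct")
    ion_mode, canonical_adduct = SUPPORTED_ADDUCTS[adduct]

    ce = parse_collision_energy(spec.extra.get("collision_energy_raw"))
    if ce is None:
        return exclude("missing or unclear collision energy")
    value, unit = ce
    if unit == "nce":
        if not spec.precursor_mz or spec.precursor_mz != spec.precursor_mz:
            return exclude("NCE given but precursor m/z missing")
        value = nce_to_ev(value, spec.precursor_mz, charge=1)

    if check_structure and spec.smiles:
        try:
            graph = parse_smiles(spec.smiles)
        except SmilesParseError:
            return exclude("structure error")
        if spec.inchikey:
            try:
                computed = compute_inchikey(graph)
            except Exception:
                computed = None
            # compare connectivity block only; protonation/stereo may differ
            if computed and computed.split("-")[0] != spec.inchikey.split("-")[0]:
                return exclude("SMILES/InChIKey inconsistency")

    spec.ion_mode = ion_mode
    spec.adduct = canonical_adduct
    spec.collision_energy_ev = value
    return record


def write_exclusion_report(exclusions: list[Exclusion], path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {"record_index": e.record_index, "reason": e.reason, "name": e.name}
                for e in exclusions
            ],
            fh,
            indent=2,
        )
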