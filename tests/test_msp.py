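import numpy as np
import pytest

from bondbreak.msp import (
    Exclusion,
    harmonize_metadata,
    parse_collision_energy,
    read_msp,
    write_msp,
)
from bondbreak.spectra import Spectrum
from bondbreak.synthetic import make_library

FIXTURE = """\
Name: alpha
PRECURSORMZ: 147.0441
Precursor_type: [M+H]+
Collision_energy: 35 eV
Instrument_type: QTOF
SMILES: CCO
Num Peaks: 3
29.0386 10.5
31.0178 100
47.0491 55.1

Name: beta
PrecursorMZ: 181.0707
Precursor_type: [M-H]-
Collision_energy: NCE 35%
SMILES: OCC(O)CO
Num Peaks: 2
59.013 12
89.024 80

Name: gamma
PRECURSORMZ: 100.1
Precursor_type: [M+H]+
Collision_energy: 20
Num Peaks: 5
50.0 1
60.0 2
70.0 3
80.0 4
"""


@pytest.fixture()
def fixture_path(tmp_path):
    p = tmp_path / "lib.msp"
    p.write_text(FIXTURE)
    return str(p)


class TestReadMsp:
    def test_record_count_and_peaks(self, fixture_path):
        records = list(read_msp(fixture_path))
        assert len(records) == 3
        assert records[0].spectrum.n_peaks == 3
        assert records[0].spectrum.name == "alpha"
        assert records[0].spectrum.precursor_mz == pytest.approx(147.0441)
        assert records[1].spectrum.ion_mode == "-"

    def test_num_peaks_mismatch_flagged(self, fixture_path):
        records = list(read_msp(fixture_path))
        assert not records[2].valid
        assert any("Num Peaks mismatch" in e for e in records[2].errors)
        # parsing continued past the bad record
        assert records[0].valid and records[1].valid

    def test_case_insensitive_key_aliases(self, fixture_path):
        records = list(read_msp(fixture_path))
        # PRECURSORMZ and PrecursorMZ spellings both land on precursor_mz
        assert records[0].spectrum.precursor_mz > 0
        assert records[1].spectrum.precursor_mz > 0

    def test_streaming_is_lazy(self, tmp_path):
        path = tmp_path / "big.msp"
        block = "Name: x\nPrecursorMZ: 100.0\nNum Peaks: 1\n50.0 1\n\n"
        path.write_text(block * 1000)
        it = read_msp(str(path))
        first = next(it)
        assert first.valid
        assert sum(1 for _ in it) == 999


class TestWriteMsp:
    def test_round_trip_preserves_fields(self, tmp_path):
        spectra = make_library(5, 2, seed=3)
        path = tmp_path / "out.msp"
        write_msp(spectra, str(path))
        back = [r.spectrum for r in read_msp(str(path))]
        assert len(back) == len(spectra)
        for orig, rt in zip(spectra, back):
            assert rt.name == orig.name
            assert rt.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-6)
            assert rt.n_peaks == orig.n_peaks
            assert np.allclose(rt.mz, orig.mz, atol=1e-6)
            # intensities kept to 4 significant figures
            assert np.allclose(rt.intensity, orig.intensity, rtol=1e-3)

    def test_empty_list_gives_empty_file(self, tmp_path):
        path = tmp_path / "empty.msp"
        write_msp([], str(path))
        assert path.read_text() == ""
        assert list(read_msp(str(path))) == []

    def test_one_record_one_block(self, tmp_path):
        spec = Spectrum(
            mz=[100.0], intensity=[1.0], precursor_mz=150.0, name="solo",
            adduct="[M+H]+", collision_energy_ev=30.0,
        )
        path = tmp_path / "solo.msp"
        write_msp([spec], str(path))
        text = path.read_text()
        assert text.endswith("\n\n")
        assert text.count("Name:") == 1

    def test_cross_check_against_matchms_reader(self, tmp_path):
        matchms = pytest.importorskip("matchms")
        from matchms.importing import load_from_msp

        spectra = make_library(4, 1, seed=8)
        path = tmp_path / "xcheck.msp"
        write_msp(spectra, str(path))
        theirs = list(load_from_msp(str(path)))
        assert len(theirs) == 4
        for orig, other in zip(spectra, theirs):
            assert len(other.peaks.mz) == orig.n_peaks
            assert np.allclose(other.peaks.mz, orig.mz, atol=1e-6)


class TestCollisionEnergyGrammar:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("35", (35.0, "ev")),
            ("35 eV", (35.0, "ev")),
            ("NCE 35%", (35.0, "nce")),
            ("35% (nominal)", (35.0, "nce")),
            ("35%", (35.0, "nce")),
            ("HCD ramp 20-50", None),
            ("", None),
            (None, None),
        ],
    )
    def test_grammar(self, text, expected):
        assert parse_collision_energy(text) == expected


class TestHarmonize:
    def _record(self, fixture_path, idx):
        return list(read_msp(fixture_path))[idx]

    def test_nce_converted_to_ev(self, tmp_path):
        p = tmp_path / "a.msp"
        p.write_text(
            "Name: t\nPrecursorMZ: 500.0\nPrecursor_type: [M+H]+\n"
            "Collision_energy: NCE 35%\nSMILES: CCO\nNum Peaks: 1\n100.0 1\n\n"
        )
        rec = harmonize_metadata(next(read_msp(str(p))), check_structure=False)
        assert not isinstance(rec, Exclusion)
        assert rec.spectrum.collision_energy_ev == pytest.approx(35.0)

    def test_unsupported_adduct_excluded(self, tmp_path):
        p = tmp_path / "b.msp"
        p.write_text(
            "Name: t\nPrecursorMZ: 500.0\nPrecursor_type: [M+Na]+\n"
            "Collision_energy: 30 eV\nNum Peaks: 1\n100.0 1\n\n"
        )
        res = harmonize_metadata(next(read_msp(str(p))))
        assert isinstance(res, Exclusion)
        assert res.reason == "unsupported adduct"

    def test_structure_error_excluded(self, tmp_path):
        p = tmp_path / "c.msp"
        p.write_text(
            "Name: t\nPrecursorMZ: 500.0\nPrecursor_type: [M+H]+\n"
            "Collision_energy: 30 eV\nSMILES: C(\nNum Peaks: 1\n100.0 1\n\n"
        )
        res = harmonize_metadata(next(read_msp(str(p))))
        assert isinstance(res, Exclusion)
        assert res.reason == "structure error"

    def test_inchikey_mismatch_excluded(self, tmp_path):
        p = tmp_path / "d.msp"
        p.write_text(
            "Name: t\nPrecursorMZ: 500.0\nPrecursor_type: [M+H]+\n"
            "Collision_energy: 30 eV\nSMILES: CCO\n"
            "InChIKey: XXXXXXXXXXXXXX-UHFFFAOYSA-N\nNum Peaks: 1\n100.0 1\n\n"
        )
        res = harmonize_metadata(next(read_msp(str(p))))
        assert isinstance(res, Exclusion)
        assert res.reason == "SMILES/InChIKey inconsistency"

    def test_unclear_collision_energy_excluded(self, tmp_path):
        p = tmp_path / "e.msp"
        p.write_text(
            "Name: t\nPrecursorMZ: 500.0\nPrecursor_type: [M+H]+\n"
            "Collision_energy: ramp\nNum Peaks: 1\n100.0 1\n\n"
        )
        res = harmonize_metadata(next(read_msp(str(p))))
        assert isinstance(res, Exclusion)
        assert "collision energy" in res.reason

    def test_synthetic_library_passes_harmonization(self, tmp_path):
        path = tmp_path / "synth.msp"
        make_library(10, 2, path=str(path), seed=4)
        results = [harmonize_metadata(r) for r in read_msp(str(path))]
        assert len(results) == 20
        assert not any(isinstance(r, Exclusion) for r in results)
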