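import pytest

from bondbreak.annotation import (
    UnassignableSpectrumError,
    apply_training_filters,
    assign_target_probabilities,
    match_peaks,
    nce_to_ev,
)
from bondbreak.chem import parse_smiles
from bondbreak.fragments import enumerate_ion_space, ion_mz
from bondbreak.metrics import spectral_coverage
from bondbreak.spectra import Spectrum


@pytest.fixture(scope="module")
def pentanol_space():
    return enumerate_ion_space(parse_smiles("CCCCCO"))


def distinct_ion_mzs(space, n, exclude_near=()):
    """n ion m/z values, pairwise >200 ppm apart and away from excluded m/z."""
    chosen = []
    for mz in sorted({round(i.mz, 6) for i in space.ions}):
        if all(abs(mz - c) / mz * 1e6 > 200 for c in chosen) and all(
            abs(mz - e) / mz * 1e6 > 200 for e in exclude_near
        ):
            chosen.append(mz)
        if len(chosen) == n:
            return chosen
    raise AssertionError("fixture molecule too small for requested peak count")


def unmatched_mzs(space, n, precursor_mz):
    """m/z values guaranteed >50 ppm away from every ion and the precursor."""
    refs = [i.mz for i in space.ions] + [precursor_mz]
    out, mz = [], 120.0
    while len(out) < n:
        mz += 0.7173
        if all(abs(mz - r) / r * 1e6 > 500 for r in refs):
            out.append(round(mz, 4))
    return out


class TestMatchPeaks:
    def test_ppm_window_inclusion_and_exclusion(self, pentanol_space):
        ion = pentanol_space.ions[0]
        spec = Spectrum(
            mz=[ion.mz * (1 + 3e-6), 16.05], intensity=[1.0, 1.0], precursor_mz=0.0
        )
        matches = match_peaks(spec, pentanol_space, tol_ppm=50)
        matched_peaks = {m.peak_index for m in matches}
        assert any(ion.key in m.matched_ion_keys for m in matches)
        assert 1 not in matched_peaks or not matches[-1].matched_ion_keys

    def test_all_qualifying_ions_recorded(self):
        # propane: the two terminal CH3 fragments are distinct ions at one m/z
        space = enumerate_ion_space(parse_smiles("CCC"))
        mz = ion_mz([("C", 3)], 0, 1)
        spec = Spectrum(mz=[mz], intensity=[1.0], precursor_mz=0.0)
        (match,) = match_peaks(spec, space, tol_ppm=50)
        assert len(match.matched_ion_keys) == 2

    def test_precursor_flag_wins_over_fragment_match(self, pentanol_space):
        g = pentanol_space.molecule
        prec = ion_mz(g.subset_composition(range(g.n_atoms)), 1, 1)
        spec = Spectrum(mz=[prec], intensity=[1.0], precursor_mz=prec)
        (match,) = match_peaks(spec, pentanol_space, tol_ppm=50)
        assert match.is_precursor
        assert match.matched_ion_keys == []

    def test_empty_spectrum_rejected(self, pentanol_space):
        with pytest.raises(ValueError):
            match_peaks(Spectrum(mz=[], intensity=[], precursor_mz=100.0), pentanol_space)


class TestTargetProbabilities:
    def test_sqrt_intensity_weighting(self, pentanol_space):
        mz = distinct_ion_mzs(pentanol_space, 2)
        spec = Spectrum(mz=mz, intensity=[1.0, 4.0], precursor_mz=0.0)
        target = assign_target_probabilities(
            spec, match_peaks(spec, pentanol_space, tol_ppm=50)
        )
        probs = sorted(
            (sum(p for k, p in target.probabilities.items()
                 if abs(pentanol_space.ions[pentanol_space.index[k]].mz - m) < 1e-3)
             for m in mz)
        )
        assert probs == pytest.approx([1 / 3, 2 / 3])

    def test_ambiguous_match_split_equally(self):
        space = enumerate_ion_space(parse_smiles("CCC"))
        mz = ion_mz([("C", 3)], 0, 1)
        spec = Spectrum(mz=[mz], intensity=[1.0], precursor_mz=0.0)
        target = assign_target_probabilities(spec, match_peaks(spec, space, tol_ppm=50))
        assert sorted(target.probabilities.values()) == pytest.approx([0.5, 0.5])

    def test_precursor_sqrt_share(self, pentanol_space):
        g = pentanol_space.molecule
        prec = ion_mz(g.subset_composition(range(g.n_atoms)), 1, 1)
        frag = distinct_ion_mzs(pentanol_space, 1, exclude_near=[prec])[0]
        spec = Spectrum(mz=[frag, prec], intensity=[1.0, 9.0], precursor_mz=prec)
        target = assign_target_probabilities(
            spec, match_peaks(spec, pentanol_space, tol_ppm=50)
        )
        assert target.precursor_probability == pytest.approx(0.75)
        assert sum(target.probabilities.values()) == pytest.approx(0.25)

    def test_distribution_sums_to_one(self, pentanol_space, rng):
        mzs = distinct_ion_mzs(pentanol_space, 6)
        for _ in range(20):
            inten = rng.uniform(0.1, 5.0, size=6)
            spec = Spectrum(mz=mzs, intensity=inten, precursor_mz=0.0)
            t = assign_target_probabilities(
                spec, match_peaks(spec, pentanol_space, tol_ppm=50)
            )
            assert sum(t.probabilities.values()) + t.precursor_probability == pytest.approx(
                1.0, abs=1e-9
            )

    def test_unassignable_spectrum_raises(self, pentanol_space):
        spec = Spectrum(mz=[500.123], intensity=[1.0], precursor_mz=0.0)
        with pytest.raises(UnassignableSpectrumError):
            assign_target_probabilities(
                spec, match_peaks(spec, pentanol_space, tol_ppm=50)
            )

    def test_coverage_equals_metric_against_matched_stick_spectrum(self, pentanol_space):
        g = pentanol_space.molecule
        prec = ion_mz(g.subset_composition(range(g.n_atoms)), 1, 1)
        matched = distinct_ion_mzs(pentanol_space, 3, exclude_near=[prec])
        unmatched = unmatched_mzs(pentanol_space, 2, prec)
        spec = Spectrum(
            mz=matched + unmatched + [prec],
            intensity=[0.2, 0.3, 0.1, 0.15, 0.05, 0.2],
            precursor_mz=prec,
        )
        target = assign_target_probabilities(
            spec, match_peaks(spec, pentanol_space, tol_ppm=50)
        )
        stick = Spectrum(
            mz=matched + [prec], intensity=[1.0] * 4, precursor_mz=prec
        )
        assert target.coverage == pytest.approx(
            spectral_coverage(spec, stick, tol=0.01), abs=1e-9
        )


# ---------------------------------------------------------------------------
# Curation filter truth table: 12 constructed spectra, each hard/soft rule
# violated exactly once (fixture built by the synthetic module).

from bondbreak.synthetic import make_filter_fixture as build_filter_fixture  # noqa: E402


class TestTrainingFilters:
    def test_truth_table(self):
        space, cases = build_filter_fixture()
        for label, spec, weight, ce, expect_pass, reasons in cases:
            target = assign_target_probabilities(
                spec, match_peaks(spec, space, tol_ppm=50)
            )
            report = apply_training_filters(spec, target, weight, ce)
            assert report.passed == expect_pass, (label, report.reasons)
            assert report.reasons == reasons, label

    def test_each_rule_fails_exactly_once(self):
        _, cases = build_filter_fixture()
        failed = [r for _, _, _, _, _, reasons in cases for r in reasons]
        assert sorted(failed) == sorted(
            ["max_weight", "max_collision_energy", "min_matched_peaks",
             "min_coverage", "max_precursor_fraction", "soft_rules"]
        )
        assert sum(1 for _, _, _, _, p, _ in cases if p) == 6

    def test_missing_collision_energy_fails(self):
        space, cases = build_filter_fixture()
        _, spec, weight, _, _, _ = cases[0]
        target = assign_target_probabilities(spec, match_peaks(spec, space, tol_ppm=50))
        report = apply_training_filters(spec, target, weight, None)
        assert "max_collision_energy" in report.reasons


class TestNceConversion:
    @pytest.mark.parametrize(
        "nce,mz,charge,expected",
        [
            (35, 500, 1, 35.0),
            (35, 250, 1, 17.5),
            (35, 500, 2, 31.5),
            (40, 500, 3, 34.0),
            (40, 500, 5, 32.0),
        ],
    )
    def test_conversion_formula(self, nce, mz, charge, expected):
        assert nce_to_ev(nce, mz, charge) == pytest.approx(expected)

    def test_missing_precursor_rejected(self):
        with pytest.raises(ValueError):
            nce_to_ev(35, 0, 1)
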