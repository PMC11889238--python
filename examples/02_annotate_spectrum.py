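"""Match an experimental spectrum to the fragment ion space and derive
training targets.

Simulates a "measured" spectrum of butanol with the planted ground-truth
rule, matches its peaks to the enumerated ion space at 50 ppm, and prints
the resulting target probability distribution and curation-filter verdict.
"""

from bondbreak import (
    apply_training_filters,
    assign_target_probabilities,
    enumerate_ion_space,
    match_peaks,
    parse_smiles,
    simulate_spectrum,
)

g = parse_smiles("CCCCO")
spectrum = simulate_spectrum(g, collision_energy_ev=30.0, noise_sd=0.02, seed=7)
print(f"simulated spectrum: {spectrum.n_peaks} peaks, "
      f"precursor m/z {spectrum.precursor_mz:.4f}")

space = enumerate_ion_space(g, ion_mode="+")
matches = match_peaks(spectrum, space, tol_ppm=50.0)
target = assign_target_probabilities(spectrum, matches)

print(f"fragment-matched peaks: {target.n_matched_peaks} of {target.n_peaks}")
print(f"intensity coverage: {target.coverage:.3f} "
      f"(fraction of raw intensity explained by fragments + precursor)")
print(f"precursor probability target: {target.precursor_probability:.4f}")
top = sorted(target.probabilities.items(), key=lambda kv: -kv[1])[:5]
print("top fragment targets (edge, side, H-shift) -> probability:")
for key, p in top:
    print(f"  {key} -> {p:.4f}")

report = apply_training_filters(spectrum, target, g.molecular_weight, 30.0)
print(f"training filters: {'PASS' if report.passed else 'FAIL ' + str(report.reasons)}")
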