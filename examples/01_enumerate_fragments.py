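"""Enumerate the single-break fragment ion space of a molecule.

Parses 1-pentanol, finds the bonds whose cleavage can produce fragment
pairs (bridges; ring bonds never qualify), and prints every fragment ion
with its hydrogen shift and exact m/z.
"""

from bondbreak import breakable_edges, enumerate_ion_space, parse_smiles
from bondbreak.fragments import ion_space_table

g = parse_smiles("CCCCCO")
print(f"1-pentanol: {g.n_atoms} heavy atoms, {g.n_bonds} bonds, "
      f"monoisotopic mass {g.molecular_weight:.6f} Da")

edges = breakable_edges(g)
print(f"breakable (bridge) bonds: {edges}")

space = enumerate_ion_space(g, ion_mode="+")
print(f"fragment ion space: {len(space)} ions "
      f"(each break yields two fragments at hydrogen shifts +1..-3,\n"
      f"shifts needing more hydrogens than the fragment carries are dropped)")
print(ion_space_table(space).to_string(index=False))
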