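"""Synthetic molecules and spectra from a planted fragmentation rule.

The generator supplies everything needed to exercise the full pipeline
without external downloads: small drug-like molecules (an embedded list plus
random acyclic alkyl/ether/amine chains) and MS/MS spectra produced by a
*planted rule* — a linear scoring of each fragment ion from interpretable
bond/neighbor/shift features, pushed through the same softmax the model uses.
Because the rule is linear in features a shallow network can represent, a
trained model can be checked for parameter recovery against known ground
truth.

What this emulates: clean centroided spectra whose intensities follow a
smooth function of bond type, fragment chemistry and collision energy, with
optional multiplicative intensity noise.  What it does not emulate: ring
openings, multi-step fragmentation, adducts other than [M+H]+/[M-H]-,
isotope envelopes, chimeric/noise peaks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .chem import MolecularGraph, inchikey, parse_smiles
from .fragments import enumerate_ion_space, ion_mz
from .spectra import Spectrum, reconstruct_spectrum

__all__ = [
    "PlantedRule",
    "sample_molecules",
    "simulate_spectrum",
    "make_library",
    "make_filter_fixture",
]

# Embedded drug-like / metabolite-like structures: small, neutral, connected,
# all with at least one breakable (bridge) bond.
DRUGLIKE_SMILES: tuple[str, ...] = (
    "CCO", "CC(=O)O", "CC(N)C(=O)O", "NCC(=O)O", "CC(C)CC(N)C(=O)O",
    "OCC(O)CO", "CC(=O)C", "CCOC(=O)C", "CCCCO", "CC(C)O",
    "OCC1OC(O)C(O)C(O)C1O", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "CC(=O)Oc1ccccc1C(=O)O", "CC(=O)Nc1ccc(O)cc1",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "c1ccccc1CO", "c1ccccc1CCN",
    "COc1ccccc1", "Cc1ccccc1C", "Oc1ccccc1C(=O)O",
    "NC(=O)c1ccccc1", "O=C(O)c1ccccc1", "Nc1ccccc1", "Cc1ccc(C)cc1",
    "OCCc1ccccc1", "COC(=O)c1ccccc1", "CN(C)CCc1ccccc1",
    "NC(Cc1ccccc1)C(=O)O", "NC(Cc1ccc(O)cc1)C(=O)O",
    "NC(CO)C(=O)O", "NC(CS)C(=O)O", "NC(CCSC)C(=O)O",
    "CC(O)C(N)C(=O)O", "NC(CC(=O)O)C(=O)O", "NC(CCC(=O)O)C(=O)O",
    "NC(CCCNC(N)=N)C(=O)O", "NC(Cc1c[nH]cn1)C(=O)O",
    "NC(Cc1c[nH]c2ccccc12)C(=O)O", "OC(=O)CCC(=O)O", "OC(=O)C=CC(=O)O",
    "OC(=O)CC(O)C(=O)O", "OC(=O)C(O)C(O)C(=O)O", "CC(O)C(=O)O",
    "OC(=O)CCCCC(=O)O", "CCCCCCCCC(=O)O", "CCCCCCCC(=O)O",
    "CCCCCC(=O)O", "CCCC(=O)O", "CCC(=O)O",
    "CCCCCCCCCCCC(=O)O", "CCCCCCCCCCCCCC(=O)O", "CCCCCCCCCCCCCCCC(=O)O",
    "OCCN", "OCCO", "NCCN", "NCCO", "OCCOCCO", "COCCOC",
    "CC(C)(C)O", "CC(C)(C)N", "CCN(CC)CC", "CCOCC", "CCCOCCC",
    "CC(=O)NC", "CC(=O)NCC", "CNC(=O)NC", "NC(=O)N",
    "Cc1ccc(O)cc1", "COc1ccc(CCN)cc1", "COc1ccc(CC(=O)O)cc1",
    "Oc1ccc(CCO)cc1", "Oc1ccc(C=CC(=O)O)cc1", "COc1cc(C=CC(=O)O)ccc1O",
    "Cc1cccc(C)c1", "CCc1ccccc1", "CCCc1ccccc1", "CC(C)c1ccccc1",
    "Clc1ccccc1CO", "Fc1ccc(CCN)cc1", "Brc1ccc(CO)cc1",
    "CSc1ccccc1", "CS(=O)(=O)c1ccccc1", "NS(=O)(=O)c1ccccc1",
    "CCOc1ccccc1", "CN1CCCC1c1cccnc1", "c1ccncc1CO", "Cc1ccncc1",
    "c1ccc2[nH]ccc2c1CC", "OCC1CCCCC1", "NC1CCCCC1", "OC1CCCCC1C",
    "CC1CCCCC1O", "O=C1CCCCC1C", "CC(=O)C1CCCCC1",
    "CCOC(=O)c1ccccc1", "CN(C)c1ccccc1", "CC(=O)c1ccccc1",
    "OCc1ccco1", "Cc1ccco1", "Cc1cccs1", "OCc1cccs1",
    "CC(C)CO", "CC(C)CN", "CCC(C)O", "CCCCN", "CCCCCN",
    "CCCCCCO", "CCOCCN", "COCCN", "COCCO", "CC(O)CN",
    "CC(=O)OCC", "CCOC(=O)CC", "COC(=O)CCC(=O)OC",
    "CC(C)=CCO", "CC(C)=CCCC(C)=CCO", "CC(=O)CC(=O)C",
    "OC(=O)c1ccc(O)cc1", "OC(=O)c1ccc(N)cc1", "COC(=O)c1ccc(O)cc1",
)

_CHAIN_ELEMENTS = ("C", "O", "N")
_CHAIN_WEIGHTS = (0.7, 0.15, 0.15)
_MAX_VALENCE = {"C": 4, "O": 2, "N": 3}


def _random_chain_smiles(rng: np.random.Generator) -> str:
    """Random acyclic alkyl/ether/amine molecule with 4-15 heavy atoms."""
    from rdkit import Chem

    n_atoms = int(rng.integers(4, 16))
    mol = Chem.RWMol()
    symbols = ["C"]  # start on carbon so ethers/amines stay internal
    mol.AddAtom(Chem.Atom("C"))
    open_valence = [_MAX_VALENCE["C"]]
    for _ in range(n_atoms - 1):
        candidates = [i for i, v in enumerate(open_valence) if v >= 1]
        parent = int(candidates[rng.integers(len(candidates))])
        sym = str(rng.choice(_CHAIN_ELEMENTS, p=_CHAIN_WEIGHTS))
        if symbols[parent] in ("O", "N") and sym in ("O", "N"):
            sym = "C"  # avoid N-O / O-O chains, rare in this compound class
        idx = mol.AddAtom(Chem.Atom(sym))
        mol.AddBond(parent, idx, Chem.BondType.SINGLE)
        open_valence[parent] -= 1
        symbols.append(sym)
        open_valence.append(_MAX_VALENCE[sym] - 1)
    return Chem.MolToSmiles(mol.GetMol())


def sample_molecules(n: int, seed: int = 0) -> list[str]:
    """Deterministically sample ``n`` SMILES: the embedded drug-like list
    first (shuffled), then random acyclic chains.  All outputs are parseable,
    connected and neutral, with at least one breakable bond."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    pool = list(DRUGLIKE_SMILES)
    rng.shuffle(pool)
    out = pool[:n]
    seen = set(out)
    while len(out) < n:
        smi = _random_chain_smiles(rng)
        if smi not in seen:
            seen.add(smi)
            out.append(smi)
    return out


@dataclass
class PlantedRule:
    """Linear ground-truth scoring of fragment ions.

    The abundance logit of an ion is
    ``w_bond[bond order] + w_element[fragment-side endpoint element] +
    sum over the endpoint's neighbors inside the fragment of
    w_neighbor[element] + w_shift[hydrogen shift]``; the precursor stability
    is ``sigma0 - sigma_ce_slope * collision_energy_ev`` — strictly
    decreasing in collision energy, so the precursor peak decays as energy
    rises.  The neighbor term makes the rule depend on the bond's molecular
    neighborhood one hop beyond the broken bond itself, so a model with no
    message passing cannot represent it.
    """

    w_bond: tuple[float, ...] = (0.5, 0.0, -0.5, 0.0)  # single/double/triple/aromatic
    w_shift: dict[int, float] = field(
        default_factory=lambda: {1: 1.0, 0: 1.5, -1: 0.0, -2: -1.5, -3: -3.0}
    )
    w_element: dict[str, float] = field(
        default_factory=lambda: {"C": 0.0, "N": 0.3, "O": 0.5, "S": 0.2}
    )
    w_neighbor: dict[str, float] = field(
        default_factory=lambda: {"C": 0.0, "N": 0.5, "O": 0.8, "S": 0.4}
    )
    sigma0: float = 4.0
    sigma_ce_slope: float = 0.1

    def ion_logit(self, graph: MolecularGraph, ion) -> float:
        bond = graph.bonds[ion.edge_id]
        u, v = bond.endpoints
        endpoint = u if u in ion.atom_subset else v
        elem = graph.atoms[endpoint].symbol
        neighbor_term = sum(
            self.w_neighbor.get(graph.atoms[j].symbol, 0.0)
            for j in graph.neighbors(endpoint)
            if j in ion.atom_subset
        )
        return (
            self.w_bond[bond.bond_order_code]
            + self.w_element.get(elem, 0.0)
            + neighbor_term
            + self.w_shift[ion.hydrogen_shift]
        )

    def precursor_logit(self, collision_energy_ev: float) -> float:
        return self.sigma0 - self.sigma_ce_slope * collision_energy_ev

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "w_bond": list(self.w_bond),
                    "w_shift": {str(k): v for k, v in self.w_shift.items()},
                    "w_element": self.w_element,
                    "w_neighbor": self.w_neighbor,
                    "sigma0": self.sigma0,
                    "sigma_ce_slope": self.sigma_ce_slope,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str) -> "PlantedRule":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            w_bond=tuple(d["w_bond"]),
            w_shift={int(k): v for k, v in d["w_shift"].items()},
            w_element=d["w_element"],
            w_neighbor=d["w_neighbor"],
            sigma0=d["sigma0"],
            sigma_ce_slope=d["sigma_ce_slope"],
        )


def simulate_spectrum(
    graph: MolecularGraph,
    ion_mode: str = "+",
    collision_energy_ev: float = 30.0,
    rule: PlantedRule | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    instrument: str = "QTOF",
) -> Spectrum:
    """Ground-truth spectrum of a molecule under the planted rule.

    Ion logits and the precursor logit go through the same softmax as the
    model.  The planted softmax lives in the square-root intensity domain —
    the domain in which training targets are defined — so raw peak
    intensities are the squared probabilities (renormalized to unit sum);
    sqrt-normalizing the simulated spectrum therefore recovers the planted
    distribution exactly.  With ``noise_sd > 0`` intensities are perturbed
    multiplicatively with a Gaussian truncated at -1 and renormalized.
    """
    rule = rule or PlantedRule()
    space = enumerate_ion_space(graph, ion_mode=ion_mode)
    logits = np.array(
        [rule.ion_logit(graph, ion) for ion in space.ions]
        + [rule.precursor_logit(collision_energy_ev)]
    )
    z = logits - logits.max()
    probs = np.exp(z) / np.exp(z).sum()
    probs = probs ** 2
    probs = probs / probs.sum()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eps = np.maximum(rng.normal(0.0, noise_sd, size=probs.shape), -1.0)
        probs = probs * (1.0 + eps)
        probs = probs / probs.sum()
    sign = 1 if ion_mode == "+" else -1
    comp = graph.subset_composition(range(graph.n_atoms))
    precursor_mz = ion_mz(comp, sign, sign)
    spec = reconstruct_spectrum(probs, space, precursor_mz)
    spec.collision_energy_ev = collision_energy_ev
    spec.instrument = instrument
    spec.adduct = "[M+H]+" if ion_mode == "+" else "[M-H]-"
    spec.smiles = graph.canonical_smiles
    return spec


def make_library(
    n_compounds: int,
    spectra_per_compound: int,
    rule: PlantedRule | None = None,
    path: str | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    ion_mode: str = "+",
    ce_grid: tuple[float, float] = (10.0, 60.0),
    with_inchikey: bool = True,
) -> list[Spectrum]:
    """Simulate a spectral library on a collision-energy grid of 10-60 eV.

    Returns the spectra and, when ``path`` is given, writes an .msp file with
    full metadata plus the serialized ground-truth rule next to it
    (``<path>.rule.json``).  Byte-identical output for a fixed seed.
    """
    from .msp import write_msp

    rule = rule or PlantedRule()
    smiles = sample_molecules(n_compounds, seed=seed)
    energies = np.linspace(ce_grid[0], ce_grid[1], spectra_per_compound)
    spectra: list[Spectrum] = []
    for i, smi in enumerate(smiles):
        graph = parse_smiles(smi)
        key = inchikey(graph) if with_inchikey else None
        for j, ce in enumerate(energies):
            spec = simulate_spectrum(
                graph,
                ion_mode=ion_mode,
                collision_energy_ev=float(ce),
                rule=rule,
                noise_sd=noise_sd,
                seed=seed + 7919 * i + j,
            )
            spec.name = f"synthetic_{i:05d}_ce{ce:g}"
            spec.inchikey = key
            spectra.append(spec)
    if path is not None:
        write_msp(spectra, path)
        rule.to_json(str(path) + ".rule.json")
    return spectra


def _distinct_ion_mzs(space, n, exclude_near=()):
    """n ion m/z values pairwise >200 ppm apart and away from excluded m/z."""
    chosen = []
    for mz in sorted({round(i.mz, 6) for i in space.ions}):
        if all(abs(mz - c) / mz * 1e6 > 200 for c in chosen) and all(
            abs(mz - e) / mz * 1e6 > 200 for e in exclude_near
        ):
            chosen.append(mz)
        if len(chosen) == n:
            return chosen
    raise ValueError("fixture molecule too small for requested peak count")


def _unmatched_mzs(space, n, precursor_mz):
    """m/z values guaranteed far (>500 ppm) from every ion and the precursor."""
    refs = [i.mz for i in space.ions] + [precursor_mz]
    out, mz = [], 120.0
    while len(out) < n:
        mz += 0.7173
        if all(abs(mz - r) / r * 1e6 > 500 for r in refs):
            out.append(round(mz, 4))
    return out


def make_filter_fixture():
    """Constructed 12-spectrum curation fixture with a hand-written truth table.

    Returns ``(ion_space, cases)`` where each case is
    ``(label, spectrum, weight_da, collision_energy_ev, expect_pass,
    expected_failed_rules)``.  Six spectra pass; six fail with each hard/soft
    curation rule violated exactly once.  Matched peaks sit exactly on
    fragment ion m/z of 1-pentanol; unmatched peaks are placed far from every
    ion and the precursor.
    """
    space = enumerate_ion_space(parse_smiles("CCCCCO"))
    g = space.molecule
    prec = ion_mz(g.subset_composition(range(g.n_atoms)), 1, 1)
    m = _distinct_ion_mzs(space, 6, exclude_near=[prec])
    u = _unmatched_mzs(space, 18, prec)
    weight, ce = 300.0, 30.0

    def spec(mzs, intens):
        return Spectrum(mz=mzs, intensity=intens, precursor_mz=prec)

    cases = [
        ("pass_basic", spec(m[:5] + [u[0], prec], [0.1] * 5 + [0.2, 0.3]),
         weight, ce, True, []),
        ("fail_weight", spec(m[:5] + [u[0], prec], [0.1] * 5 + [0.2, 0.3]),
         1200.0, ce, False, ["max_weight"]),
        ("fail_ce", spec(m[:5] + [u[0], prec], [0.1] * 5 + [0.2, 0.3]),
         weight, 120.0, False, ["max_collision_energy"]),
        ("fail_min_matched", spec([m[0], u[0]], [0.9, 0.1]),
         weight, ce, False, ["min_matched_peaks"]),
        ("fail_coverage", spec(m[:5] + u[:3], [0.08] * 5 + [0.2] * 3),
         weight, ce, False, ["min_coverage"]),
        ("fail_precursor", spec(m[:2] + [u[0], prec], [0.02, 0.02, 0.01, 0.95]),
         weight, ce, False, ["max_precursor_fraction"]),
        ("fail_soft_only", spec(m[:2] + u[:18], [0.3, 0.3] + [0.4 / 18] * 18),
         weight, ce, False, ["soft_rules"]),
        ("pass_soft_fraction", spec(m[:2] + u[:2], [0.3, 0.25, 0.25, 0.2]),
         weight, ce, True, []),
        ("pass_soft_coverage", spec(m[:2] + u[:8], [0.45, 0.40] + [0.15 / 8] * 8),
         weight, ce, True, []),
        ("pass_soft_n_matched", spec(m[:5] + u[:14] + [prec],
                                     [0.06] * 5 + [0.1 / 14] * 14 + [0.3]),
         weight, ce, True, []),
        ("pass_precursor_heavy", spec(m[:3] + [u[0], prec],
                                      [0.05] * 3 + [0.05, 0.8]),
         weight, ce, True, []),
        ("pass_fully_matched", spec(m[:6], [1 / 6] * 6),
         weight, ce, True, []),
    ]
    return space, cases
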