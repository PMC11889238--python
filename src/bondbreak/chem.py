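"""Molecular structure graphs and structural descriptors.

A molecule is represented as a heavy-atom graph: nodes are non-hydrogen atoms
carrying an implicit-hydrogen count, edges are covalent bonds.  Atom and bond
attributes are integer-coded against fixed vocabularies so that downstream
models can embed them with lookup tables.  Stereochemistry is ignored
throughout — the model is purely graph-topological.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import AllChem, DataStructs

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "AtomRecord",
    "BondRecord",
    "MolecularGraph",
    "SmilesParseError",
    "UnknownElementError",
    "parse_smiles",
    "monoisotopic_mass",
    "morgan_tanimoto",
    "max_train_similarity",
    "inchikey",
    "ELEMENT_VOCABULARY",
    "PROTON_MASS",
    "HYDROGEN_MASS",
    "ELECTRON_MASS",
]

# Monoisotopic (most-abundant isotope) atomic masses in Da, CODATA/AME values.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "I": 126.904473,
    "Si": 27.9769265325,
    "B": 11.0093054,
    "Se": 73.9224764,
}

HYDROGEN_MASS = MONOISOTOPIC_MASS["H"]
ELECTRON_MASS = 0.00054857990907
PROTON_MASS = HYDROGEN_MASS - ELECTRON_MASS

# Fixed element vocabulary for model embeddings.  Hydrogens never appear as
# nodes (they are implicit counts), so "H" is absent.  Anything outside the
# list maps to the trailing "other" bucket with a warning.
ELEMENT_VOCABULARY: tuple[str, ...] = (
    "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "Si", "B", "Se", "other",
)
_ELEMENT_CODE = {sym: i for i, sym in enumerate(ELEMENT_VOCABULARY)}
OTHER_ELEMENT_CODE = _ELEMENT_CODE["other"]

_BOND_ORDER_CODE = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}
N_BOND_ORDER_CODES = 4

# ring_code: 0 = acyclic; otherwise 1 + 2*size_bucket + aromatic_flag where
# size_bucket indexes the smallest ring {3,4,5,6,>=7} containing the atom/bond.
_RING_SIZE_BUCKETS = (3, 4, 5, 6)
N_RING_CODES = 1 + 2 * (len(_RING_SIZE_BUCKETS) + 1)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be turned into a valid graph."""


class UnknownElementError(KeyError):
    """Raised when a mass is requested for an element outside the mass table."""


@dataclass(frozen=True)
class AtomRecord:
    element_code: int
    hydrogen_count: int
    ring_code: int
    symbol: str  # element symbol, kept for mass arithmetic even when coded "other"


@dataclass(frozen=True)
class BondRecord:
    bond_order_code: int
    ring_code: int
    endpoints: tuple[int, int]  # ordered (u, v), u < v


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph with integer-coded features.

    Invariants: atom indices are contiguous 0..n-1, every bond joins two
    distinct existing atoms, the graph is connected, and ``molecular_weight``
    equals the monoisotopic mass of the whole molecule (implicit hydrogens
    included).
    """

    atoms: list[AtomRecord]
    bonds: list[BondRecord]
    molecular_weight: float
    source_smiles: str
    canonical_smiles: str = ""
    _adjacency: list[list[int]] = field(default_factory=list, repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def neighbors(self, i: int) -> list[int]:
        return self._adjacency[i]

    def total_hydrogens(self, atom_subset=None) -> int:
        idx = range(self.n_atoms) if atom_subset is None else atom_subset
        return sum(self.atoms[i].hydrogen_count for i in idx)

    def subset_composition(self, atom_subset) -> list[tuple[str, int]]:
        """(element symbol, hydrogen count) multiset for a set of atom indices."""
        return [(self.atoms[i].symbol, self.atoms[i].hydrogen_count) for i in sorted(atom_subset)]


def _ring_code(in_ring: bool, aromatic: bool, smallest: int | None) -> int:
    if not in_ring:
        return 0
    if smallest is None or smallest >= 7:
        bucket = len(_RING_SIZE_BUCKETS)
    else:
        bucket = _RING_SIZE_BUCKETS.index(smallest)
    return 1 + 2 * bucket + (1 if aromatic else 0)


def _smallest_ring_size(entity, max_probe: int = 12) -> int | None:
    for size in range(3, max_probe + 1):
        if entity.IsInRingSize(size):
            return size
    return 7  # in a ring but larger than anything probed: ">=7" bucket


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Hydrogens are collapsed to per-atom counts.  Multi-component (salt) and
    net-charged inputs are rejected: the fragmentation model operates on
    neutral, connected molecular structures.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise SmilesParseError(f"disconnected multi-component SMILES: {smiles!r}")
    if Chem.GetFormalCharge(mol) != 0:
        raise SmilesParseError(f"net-charged structure rejected: {smiles!r}")
    mol = Chem.RemoveHs(mol)
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"no heavy atoms in SMILES: {smiles!r}")

    atoms: list[AtomRecord] = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        code = _ELEMENT_CODE.get(sym)
        if code is None:
            warnings.warn(
                f"element {sym!r} outside the model vocabulary; coded as 'other'",
                stacklevel=2,
            )
            code = OTHER_ELEMENT_CODE
        atoms.append(
            AtomRecord(
                element_code=code,
                hydrogen_count=atom.GetTotalNumHs(),
                ring_code=_ring_code(
                    atom.IsInRing(),
                    atom.GetIsAromatic(),
                    _smallest_ring_size(atom) if atom.IsInRing() else None,
                ),
                symbol=sym,
            )
        )

    bonds: list[BondRecord] = []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if u > v:
            u, v = v, u
        bonds.append(
            BondRecord(
                bond_order_code=_BOND_ORDER_CODE.get(bond.GetBondType(), 0),
                ring_code=_ring_code(
                    bond.IsInRing(),
                    bond.GetIsAromatic(),
                    _smallest_ring_size(bond) if bond.IsInRing() else None,
                ),
                endpoints=(u, v),
            )
        )
    bonds.sort(key=lambda b: b.endpoints)

    adjacency: list[list[int]] = [[] for _ in atoms]
    for b in bonds:
        u, v = b.endpoints
        adjacency[u].append(v)
        adjacency[v].append(u)

    mw = sum(
        _atom_monoisotopic(a.symbol) + a.hydrogen_count * HYDROGEN_MASS for a in atoms
    )
    return MolecularGraph(
        atoms=atoms,
        bonds=bonds,
        molecular_weight=mw,
        source_smiles=smiles,
        canonical_smiles=Chem.MolToSmiles(mol),
        _adjacency=adjacency,
    )


def _atom_monoisotopic(symbol: str) -> float:
    """Mass of one heavy atom; falls back to the periodic table for elements
    outside the embedded vocabulary (coded "other" for the model)."""
    mass = MONOISOTOPIC_MASS.get(symbol)
    if mass is None:
        pt = Chem.GetPeriodicTable()
        mass = pt.GetMostCommonIsotopeMass(symbol)
    return mass


def monoisotopic_mass(fragment_atoms) -> float:
    """Monoisotopic mass in Da of a multiset of ``(element, hydrogen_count)``.

    Sums most-abundant-isotope masses including implicit hydrogens.  An empty
    multiset has mass 0.
    """
    total = 0.0
    for symbol, h_count in fragment_atoms:
        mass = MONOISOTOPIC_MASS.get(symbol)
        if mass is None:
            raise UnknownElementError(f"no monoisotopic mass tabulated for element {symbol!r}")
        if h_count < 0:
            raise ValueError("negative hydrogen count")
        total += mass + h_count * HYDROGEN_MASS
    return total


def _rdkit_mol(graph: MolecularGraph):
    mol = Chem.MolFromSmiles(graph.canonical_smiles or graph.source_smiles)
    if mol is None:  # pragma: no cover - guarded at parse time
        raise SmilesParseError(graph.source_smiles)
    return mol


def morgan_fingerprint(graph: MolecularGraph, bits: int = 2048, radius: int = 3):
    """Morgan (ECFP-like) bit-vector fingerprint of the molecule."""
    if bits <= 0 or radius < 0:
        raise ValueError("bits must be > 0 and radius >= 0")
    return AllChem.GetMorganFingerprintAsBitVect(_rdkit_mol(graph), radius, nBits=bits)


def morgan_tanimoto(
    a: MolecularGraph, b: MolecularGraph, bits: int = 2048, radius: int = 3
) -> float:
    """Tanimoto (Jaccard) similarity of Morgan fingerprints, in [0, 1]."""
    fa = morgan_fingerprint(a, bits=bits, radius=radius)
    fb = morgan_fingerprint(b, bits=bits, radius=radius)
    return DataStructs.TanimotoSimilarity(fa, fb)


def max_train_similarity(
    test_mol: MolecularGraph,
    train_set,
    bits: int = 2048,
    radius: int = 3,
) -> float:
    """Maximum Tanimoto similarity of ``test_mol`` to any training molecule.

    Used to quantify how structurally novel a test compound is relative to the
    training library.
    """
    train_set = list(train_set)
    if not train_set:
        raise ValueError("train_set must be non-empty")
    fp = morgan_fingerprint(test_mol, bits=bits, radius=radius)
    fps = [morgan_fingerprint(m, bits=bits, radius=radius) for m in train_set]
    return max(DataStructs.TanimotoSimilarity(fp, f) for f in fps)


def inchikey(graph: MolecularGraph) -> str:
    """InChIKey of the molecule (used for compound-level split bookkeeping)."""
    return Chem.MolToInchiKey(_rdkit_mol(graph))
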