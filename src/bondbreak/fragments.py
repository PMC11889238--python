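"""Single-edge-break fragment ion enumeration.

Fragmentation is modeled as the removal of exactly one bond from the molecular
graph.  Only bridges (cut edges) are breakable: removing a ring bond leaves
the graph connected, so no fragment pair exists and rings are never opened.
Each break yields two fragments; every fragment is considered at hydrogen
rearrangements of {+1, 0, -1, -2, -3} hydrogen atoms relative to the homolytic
(radical) fragment, and the charge is carried by removing (positive mode) or
adding (negative mode) one electron.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .chem import ELECTRON_MASS, HYDROGEN_MASS, MolecularGraph, monoisotopic_mass

__all__ = [
    "HYDROGEN_SHIFTS",
    "FragmentIon",
    "FragmentIonSpace",
    "breakable_edges",
    "split_at_edge",
    "enumerate_ion_space",
    "ion_mz",
]

# Hydrogen rearrangement set: [F+H], [F], [F-H], [F-2H], [F-3H].
HYDROGEN_SHIFTS: tuple[int, ...] = (1, 0, -1, -2, -3)
SIDES: tuple[str, str] = ("left", "right")


@dataclass(frozen=True)
class FragmentIon:
    """One charged fragment: a connected component of G minus one edge,
    shifted by ``hydrogen_shift`` hydrogen atoms."""

    edge_id: int
    side: str  # "left" = component containing the lower-indexed endpoint
    atom_subset: frozenset[int]
    hydrogen_shift: int
    charge_sign: int  # +1 or -1
    mz: float

    @property
    def key(self) -> tuple[int, str, int]:
        return (self.edge_id, self.side, self.hydrogen_shift)


@dataclass
class FragmentIonSpace:
    """Ordered enumeration of all single-break fragment ions of a molecule.

    Ordering is (edge_id, side, descending shift), fixed so that model logit
    positions are reproducible.  |ions| <= 10 x number of breakable edges;
    hydrogen-infeasible ions (fragment hydrogen budget + shift < 0) are
    dropped.
    """

    molecule: MolecularGraph
    ion_mode: str  # "+" or "-"
    ions: list[FragmentIon]
    index: dict[tuple[int, str, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {ion.key: i for i, ion in enumerate(self.ions)}

    def __len__(self) -> int:
        return len(self.ions)

    def mz_array(self):
        return [ion.mz for ion in self.ions]


def _graph_view(G: MolecularGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(G.n_atoms))
    g.add_edges_from(b.endpoints for b in G.bonds)
    return g


def breakable_edges(G: MolecularGraph) -> list[int]:
    """Indices of bonds whose removal disconnects the graph (bridges).

    These are exactly the bonds not lying on any cycle; ring structures are
    never cleaved.  Order follows the bond list and is deterministic.
    """
    bridges = set(nx.bridges(_graph_view(G)))
    out = []
    for i, b in enumerate(G.bonds):
        u, v = b.endpoints
        if (u, v) in bridges or (v, u) in bridges:
            out.append(i)
    return out


def split_at_edge(G: MolecularGraph, edge_id: int) -> tuple[frozenset[int], frozenset[int]]:
    """The two connected components after removing bond ``edge_id``.

    Returns (left, right) where "left" contains the lower-indexed endpoint of
    the removed bond.  Raises for ring (non-bridge) bonds.
    """
    u, v = G.bonds[edge_id].endpoints
    g = _graph_view(G)
    g.remove_edge(u, v)
    left = frozenset(nx.node_connected_component(g, u))
    if v in left:
        raise ValueError(f"bond {edge_id} is not a bridge (lies on a ring); cannot split")
    right = frozenset(nx.node_connected_component(g, v))
    return left, right


def ion_mz(
    composition,
    hydrogen_shift: int,
    charge_sign: int,
) -> float:
    """Exact m/z of a singly charged fragment ion.

    ``composition`` is a multiset of (element, hydrogen_count).  The shift
    moves neutral hydrogen atoms; the single charge is carried by an electron
    removed (positive mode) or added (negative mode).
    """
    composition = list(composition)
    h_budget = sum(h for _, h in composition)
    if h_budget + hydrogen_shift < 0:
        raise ValueError(
            f"hydrogen-infeasible shift {hydrogen_shift:+d} for fragment with {h_budget} H"
        )
    if charge_sign not in (1, -1):
        raise ValueError("charge_sign must be +1 or -1")
    mass = monoisotopic_mass(composition) + hydrogen_shift * HYDROGEN_MASS
    return mass - charge_sign * ELECTRON_MASS


def enumerate_ion_space(G: MolecularGraph, ion_mode: str = "+") -> FragmentIonSpace:
    """Enumerate all single-break fragment ions of ``G``.

    For every bridge bond, both fragments are emitted at hydrogen shifts
    {+1, 0, -1, -2, -3}, skipping shifts that would require more hydrogens
    than the fragment carries.  A molecule with no bridges (pure ring, or a
    single atom) yields an empty ion list.
    """
    if ion_mode not in ("+", "-"):
        raise ValueError("ion_mode must be '+' or '-'")
    sign = 1 if ion_mode == "+" else -1
    ions: list[FragmentIon] = []
    for edge_id in breakable_edges(G):
        left, right = split_at_edge(G, edge_id)
        for side, subset in zip(SIDES, (left, right)):
            comp = G.subset_composition(subset)
            h_budget = sum(h for _, h in comp)
            for shift in HYDROGEN_SHIFTS:
                if h_budget + shift < 0:
                    continue
                ions.append(
                    FragmentIon(
                        edge_id=edge_id,
                        side=side,
                        atom_subset=subset,
                        hydrogen_shift=shift,
                        charge_sign=sign,
                        mz=ion_mz(comp, shift, sign),
                    )
                )
    return FragmentIonSpace(molecule=G, ion_mode=ion_mode, ions=ions)


def ion_space_table(space: FragmentIonSpace):
    """Ion space as a pandas DataFrame (edge_id, side, shift, formula, mz)."""
    import pandas as pd

    rows = []
    for ion in space.ions:
        comp = space.molecule.subset_composition(ion.atom_subset)
        heavy: dict[str, int] = {}
        n_h = ion.hydrogen_shift
        for sym, h in comp:
            heavy[sym] = heavy.get(sym, 0) + 1
            n_h += h
        formula = "".join(
            f"{s}{c if c > 1 else ''}" for s, c in sorted(heavy.items())
        ) + (f"H{n_h}" if n_h else "")
        rows.append(
            {
                "edge_id": ion.edge_id,
                "side": ion.side,
                "shift": ion.hydrogen_shift,
                "formula": formula,
                "mz": round(ion.mz, 6),
            }
        )
    return pd.DataFrame(rows, columns=["edge_id", "side", "shift", "formula", "mz"])
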