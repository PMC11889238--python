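import numpy as np
import pytest

from bondbreak import parse_smiles
from bondbreak.nn.model import Covariates, GraphTensors


@pytest.fixture(scope="session")
def ethanol():
    return parse_smiles("CCO")


@pytest.fixture(scope="session")
def benzene():
    return parse_smiles("c1ccccc1")


@pytest.fixture(scope="session")
def toluene():
    return parse_smiles("Cc1ccccc1")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_covariates(graph, ce=30.0, ion_mode="+"):
    return Covariates(
        molecular_weight=graph.molecular_weight,
        ion_mode=ion_mode,
        collision_energy_ev=ce,
    )


@pytest.fixture(scope="session")
def ethanol_tensors(ethanol):
    return GraphTensors(ethanol)


# ---------------------------------------------------------------------------
# Brute-force oracles, independent of the implementation under test.

def oracle_components(n_atoms, edges):
    """Connected components by pure-python BFS over an edge list."""
    adj = {i: [] for i in range(n_atoms)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    seen, comps = set(), []
    for start in range(n_atoms):
        if start in seen:
            continue
        comp, queue = set(), [start]
        while queue:
            node = queue.pop()
            if node in comp:
                continue
            comp.add(node)
            queue.extend(adj[node])
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def oracle_bridges(graph):
    """Edges whose removal increases the component count (brute force)."""
    edges = [b.endpoints for b in graph.bonds]
    base = len(oracle_components(graph.n_atoms, edges))
    out = []
    for i in range(len(edges)):
        rest = edges[:i] + edges[i + 1:]
        if len(oracle_components(graph.n_atoms, rest)) > base:
            out.append(i)
    return out


def oracle_ion_set(graph, ion_mode="+"):
    """Full enumeration oracle: set of (edge, side, shift, rounded mz)."""
    from bondbreak.chem import ELECTRON_MASS, HYDROGEN_MASS, monoisotopic_mass

    sign = 1 if ion_mode == "+" else -1
    edges = [b.endpoints for b in graph.bonds]
    result = set()
    for e in oracle_bridges(graph):
        rest = edges[:e] + edges[e + 1:]
        comps = oracle_components(graph.n_atoms, rest)
        u, v = edges[e]
        left = next(c for c in comps if u in c)
        right = next(c for c in comps if v in c)
        for side, comp in (("left", left), ("right", right)):
            comp_atoms = [(graph.atoms[i].symbol, graph.atoms[i].hydrogen_count) for i in comp]
            h_budget = sum(h for _, h in comp_atoms)
            for shift in (1, 0, -1, -2, -3):
                if h_budget + shift < 0:
                    continue
                mz = (
                    monoisotopic_mass(comp_atoms)
                    + shift * HYDROGEN_MASS
                    - sign * ELECTRON_MASS
                )
                result.add((e, side, shift, round(mz, 6)))
    return result
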