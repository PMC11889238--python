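"""Message-passing model for fragment ion abundance prediction.

The network embeds integer-coded atom and bond features, refines node states
with a stack of graph-convolution layers (GCN or relational GCN with one
relation per bond order), and feeds two heads:

* an edge head that, for every breakable bond and both endpoint orderings,
  maps (h_u, h_v, bond embedding, covariates) through a shared two-layer MLP
  to five abundance logits — one per hydrogen shift — for the fragment
  containing the first endpoint;
* a precursor head that mean-pools the node states, concatenates the same
  covariates, and produces a single precursor-stability logit.

All logits are combined with a softmax over the feasible fragment ion space
plus the precursor, yielding a probability distribution whose entries sum
to 1 and which is reconstructed into a spectrum at exact fragment m/z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ..chem import ELEMENT_VOCABULARY, MolecularGraph, N_BOND_ORDER_CODES
from ..chem import N_RING_CODES
from ..fragments import (
    FragmentIonSpace,
    HYDROGEN_SHIFTS,
    breakable_edges,
    enumerate_ion_space,
)
from . import autodiff as ad

__all__ = ["ModelConfig", "Covariates", "PredictionOutput", "FragmentationModel"]

MAX_H_COUNT = 8  # implicit hydrogen counts above this share the top code


@dataclass
class ModelConfig:
    layer_type: str = "rgcn"  # "rgcn" or "gcn"
    depth: int = 6
    embedding_dim: int = 300
    head_hidden: int = 512
    instrument_vocab: tuple[str, ...] = ("QTOF", "Orbitrap", "QQQ")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0 or self.embedding_dim <= 0 or self.head_hidden <= 0:
            raise ValueError("depth >= 0 and positive embedding/head sizes required")
        if self.layer_type not in ("rgcn", "gcn"):
            raise ValueError(f"unsupported layer_type {self.layer_type!r}")

    @property
    def n_covariates(self) -> int:
        # MW, ion mode, collision energy + instrument one-hot (with unknown bucket)
        return 3 + len(self.instrument_vocab) + 1


@dataclass
class Covariates:
    """Acquisition covariates entering the prediction heads.

    Molecular weight is scaled by 1/1000 and collision energy by 1/100 for
    conditioning; the instrument is one-hot over the configured vocabulary
    with a trailing "unknown" bucket.
    """

    molecular_weight: float
    ion_mode: str = "+"
    collision_energy_ev: float = 30.0
    instrument: str | None = None

    def to_vector(self, config: ModelConfig) -> np.ndarray:
        vec = np.zeros(config.n_covariates)
        vec[0] = self.molecular_weight / 1000.0
        vec[1] = 1.0 if self.ion_mode == "+" else -1.0
        vec[2] = self.collision_energy_ev / 100.0
        vocab = config.instrument_vocab
        try:
            idx = vocab.index(self.instrument)
        except ValueError:
            idx = len(vocab)  # unknown bucket
        vec[3 + idx] = 1.0
        return vec


@dataclass
class PredictionOutput:
    space: FragmentIonSpace
    edge_logits: np.ndarray  # [n_breakable_edges, 10]; 2 sides x 5 shifts
    precursor_logit: float
    probabilities: np.ndarray  # length |space| + 1; last entry = precursor
    pooled_embedding: np.ndarray
    prob_tensor: "ad.Tensor | None" = field(default=None, repr=False)

    @property
    def precursor_probability(self) -> float:
        return float(self.probabilities[-1])


class GraphTensors:
    """Pre-computed constant tensors for one molecule (reused across passes)."""

    def __init__(self, graph: MolecularGraph, ion_mode: str = "+"):
        self.graph = graph
        self.atom_elem = np.array([a.element_code for a in graph.atoms])
        self.atom_h = np.array(
            [min(a.hydrogen_count, MAX_H_COUNT) for a in graph.atoms]
        )
        self.atom_ring = np.array([a.ring_code for a in graph.atoms])
        self.bond_order = np.array([b.bond_order_code for b in graph.bonds])
        self.bond_ring = np.array([b.ring_code for b in graph.bonds])
        self.breakable = breakable_edges(graph)
        self.space = enumerate_ion_space(graph, ion_mode=ion_mode)
        n = graph.n_atoms

        # Per-relation row-normalized adjacency (RGCN) and symmetric-normalized
        # adjacency with self loops (GCN).
        self.rel_adj = []
        for r in range(N_BOND_ORDER_CODES):
            a = np.zeros((n, n))
            for b in graph.bonds:
                if b.bond_order_code == r:
                    u, v = b.endpoints
                    a[u, v] = a[v, u] = 1.0
            deg = a.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                a = np.where(deg > 0, a / deg, 0.0)
            self.rel_adj.append(a)
        a = np.eye(n)
        for b in graph.bonds:
            u, v = b.endpoints
            a[u, v] = a[v, u] = 1.0
        d = 1.0 / np.sqrt(a.sum(axis=1))
        self.gcn_adj = a * d[:, None] * d[None, :]

        # Row/bond gathering plan for the edge head: for breakable edge i,
        # row 2i uses ordering (u, v) -> "left" fragment logits, row 2i+1 the
        # reverse.  Feasible flat positions select ion-space entries in order.
        first, second, bond_rows = [], [], []
        for e in self.breakable:
            u, v = graph.bonds[e].endpoints
            first += [u, v]
            second += [v, u]
            bond_rows += [e, e]
        self.edge_first = np.array(first, dtype=int)
        self.edge_second = np.array(second, dtype=int)
        self.edge_bond_rows = np.array(bond_rows, dtype=int)

        flat = []
        sides = ("left", "right")
        for i, e in enumerate(self.breakable):
            for s_idx, side in enumerate(sides):
                for k, shift in enumerate(HYDROGEN_SHIFTS):
                    if (e, side, shift) in self.space.index:
                        flat.append((2 * i + s_idx) * len(HYDROGEN_SHIFTS) + k)
        self.feasible_flat = np.array(flat, dtype=int)
        assert len(self.feasible_flat) == len(self.space)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class FragmentationModel:
    """Graph network predicting fragment ion probabilities for a molecule."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.params: dict[str, ad.Tensor] = {}
        self._init_params()

    # ------------------------------------------------------------------ setup
    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        d, hid, cov = cfg.embedding_dim, cfg.head_hidden, cfg.n_covariates
        p = self.params

        def emb(name, vocab_size):
            # +1 reserved "unknown" row at the end of every table
            p[name] = ad.parameter(rng.normal(0.0, 0.1, size=(vocab_size + 1, d)))

        emb("emb.element", len(ELEMENT_VOCABULARY))
        emb("emb.hcount", MAX_H_COUNT + 1)
        emb("emb.atom_ring", N_RING_CODES)
        emb("emb.bond_order", N_BOND_ORDER_CODES)
        emb("emb.bond_ring", N_RING_CODES)

        for layer in range(cfg.depth):
            if cfg.layer_type == "rgcn":
                p[f"layer{layer}.W_self"] = ad.parameter(_glorot(rng, d, d))
                for r in range(N_BOND_ORDER_CODES):
                    p[f"layer{layer}.W_rel{r}"] = ad.parameter(_glorot(rng, d, d))
            else:
                p[f"layer{layer}.W"] = ad.parameter(_glorot(rng, d, d))
            p[f"layer{layer}.b"] = ad.parameter(np.zeros(d))

        edge_in = 3 * d + cov
        p["edge.W1"] = ad.parameter(_glorot(rng, edge_in, hid))
        p["edge.b1"] = ad.parameter(np.zeros(hid))
        p["edge.W2"] = ad.parameter(_glorot(rng, hid, len(HYDROGEN_SHIFTS)))
        p["edge.b2"] = ad.parameter(np.zeros(len(HYDROGEN_SHIFTS)))

        prec_in = d + cov
        p["prec.W1"] = ad.parameter(_glorot(rng, prec_in, hid))
        p["prec.b1"] = ad.parameter(np.zeros(hid))
        p["prec.W2"] = ad.parameter(_glorot(rng, hid, 1))
        p["prec.b2"] = ad.parameter(np.zeros(1))

    # --------------------------------------------------------------- building
    def embed_features(self, gt: GraphTensors) -> tuple[ad.Tensor, ad.Tensor]:
        """Initial node and bond hidden states: per-feature table lookups
        summed.  Out-of-vocabulary codes map to the reserved last row."""
        p = self.params

        def clip(codes, table):
            limit = table.data.shape[0] - 1
            return np.minimum(codes, limit)

        x = ad.add(
            ad.add(
                ad.take_rows(p["emb.element"], clip(gt.atom_elem, p["emb.element"])),
                ad.take_rows(p["emb.hcount"], clip(gt.atom_h, p["emb.hcount"])),
            ),
            ad.take_rows(p["emb.atom_ring"], clip(gt.atom_ring, p["emb.atom_ring"])),
        )
        if gt.graph.n_bonds:
            e = ad.add(
                ad.take_rows(p["emb.bond_order"], clip(gt.bond_order, p["emb.bond_order"])),
                ad.take_rows(p["emb.bond_ring"], clip(gt.bond_ring, p["emb.bond_ring"])),
            )
        else:
            e = ad.constant(np.zeros((0, self.config.embedding_dim)))
        return x, e

    def graph_update(self, h: ad.Tensor, gt: GraphTensors, layer: int) -> ad.Tensor:
        """One message-passing layer followed by an ELU nonlinearity.

        RGCN: h_i' = ELU(W_self h_i + sum_r mean_{j in N_r(i)} W_r h_j + b);
        a node with no neighbors keeps only its self term.  GCN uses the
        symmetric-normalized adjacency with self loops.
        """
        p = self.params
        if self.config.layer_type == "rgcn":
            out = ad.matmul(h, p[f"layer{layer}.W_self"])
            for r, adj in enumerate(gt.rel_adj):
                if adj.any():
                    msg = ad.const_matmul(adj, ad.matmul(h, p[f"layer{layer}.W_rel{r}"]))
                    out = ad.add(out, msg)
        else:
            out = ad.const_matmul(gt.gcn_adj, ad.matmul(h, p[f"layer{layer}.W"]))
        return ad.elu(ad.add(out, p[f"layer{layer}.b"]))

    def _heads(self, h: ad.Tensor, e: ad.Tensor, gt: GraphTensors, cov: np.ndarray):
        p = self.params
        n_rows = len(gt.edge_first)
        pooled = ad.reshape(ad.mean_rows(h), (1, -1))
        z = ad.concat([pooled, ad.constant(cov.reshape(1, -1))], axis=1)
        z = ad.elu(ad.add(ad.matmul(z, p["prec.W1"]), p["prec.b1"]))
        sigma = ad.add(ad.matmul(z, p["prec.W2"]), p["prec.b2"])  # [1,1]

        if n_rows == 0:
            return None, sigma, pooled
        cov_rows = ad.constant(np.broadcast_to(cov, (n_rows, len(cov))).copy())
        z = ad.concat(
            [
                ad.take_rows(h, gt.edge_first),
                ad.take_rows(h, gt.edge_second),
                ad.take_rows(e, gt.edge_bond_rows),
                cov_rows,
            ],
            axis=1,
        )
        z = ad.elu(ad.add(ad.matmul(z, p["edge.W1"]), p["edge.b1"]))
        logits = ad.add(ad.matmul(z, p["edge.W2"]), p["edge.b2"])  # [n_rows, 5]
        return logits, sigma, pooled

    # ---------------------------------------------------------------- forward
    def forward(self, gt: GraphTensors, covariates: Covariates) -> PredictionOutput:
        cov = covariates.to_vector(self.config)
        x, e = self.embed_features(gt)
        h = x
        for layer in range(self.config.depth):
            h = self.graph_update(h, gt, layer)
        logits, sigma, pooled = self._heads(h, e, gt, cov)

        n_be = len(gt.breakable)
        if logits is None:
            # no breakable edge: the precursor survives with probability 1
            probs = ad.constant(np.ones(1))
            edge_logits = np.zeros((0, 10))
        else:
            flat = ad.reshape(logits, (-1,))
            ion_logits = ad.take_rows(flat, gt.feasible_flat)
            all_logits = ad.concat([ion_logits, ad.reshape(sigma, (-1,))], axis=0)
            probs = ad.softmax(all_logits)
            edge_logits = logits.data.reshape(n_be, 10)
        return PredictionOutput(
            space=gt.space,
            edge_logits=edge_logits,
            precursor_logit=float(sigma.data.reshape(())),
            probabilities=probs.data.copy(),
            pooled_embedding=pooled.data.reshape(-1).copy(),
            prob_tensor=probs,
        )

    def predict(
        self, graph_or_smiles, covariates: Covariates | None = None, **cov_kwargs
    ) -> PredictionOutput:
        """Predict fragment probabilities for a molecule (SMILES or graph)."""
        from ..chem import parse_smiles

        graph = (
            parse_smiles(graph_or_smiles)
            if isinstance(graph_or_smiles, str)
            else graph_or_smiles
        )
        ion_mode = cov_kwargs.pop("ion_mode", covariates.ion_mode if covariates else "+")
        gt = GraphTensors(graph, ion_mode=ion_mode)
        if covariates is None:
            covariates = Covariates(
                molecular_weight=graph.molecular_weight, ion_mode=ion_mode, **cov_kwargs
            )
        return self.forward(gt, covariates)

    def predict_spectrum(self, graph_or_smiles, covariates=None, **cov_kwargs):
        """Predict and reconstruct the full MS/MS spectrum."""
        from ..fragments import ion_mz
        from ..spectra import reconstruct_spectrum

        out = self.predict(graph_or_smiles, covariates, **cov_kwargs)
        g = out.space.molecule
        sign = 1 if out.space.ion_mode == "+" else -1
        comp = g.subset_composition(range(g.n_atoms))
        precursor_mz = ion_mz(comp, sign, sign)  # [M+H]+ or [M-H]-
        ce = covariates.collision_energy_ev if covariates else cov_kwargs.get(
            "collision_energy_ev"
        )
        return reconstruct_spectrum(
            out.probabilities,
            out.space,
            precursor_mz,
            collision_energy_ev=ce,
            smiles=g.canonical_smiles,
        )

    # ------------------------------------------------------------ persistence
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k not in self.params:
                raise KeyError(f"unexpected parameter {k}")
            self.params[k].data = np.asarray(v, dtype=float).reshape(
                self.params[k].data.shape
            )

    def save(self, path: str) -> None:
        payload = {
            "format_version": 1,
            "config": asdict(self.config),
            "params": {k: v.tolist() for k, v in self.state_dict().items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "FragmentationModel":
        with open(path) as fh:
            payload = json.load(fh)
        cfg_dict = payload["config"]
        cfg_dict["instrument_vocab"] = tuple(cfg_dict["instrument_vocab"])
        model = cls(ModelConfig(**cfg_dict))
        model.load_state_dict({k: np.array(v) for k, v in payload["params"].items()})
        return model


def fragment_probabilities(edge_ion_logits: np.ndarray, sigma: float) -> np.ndarray:
    """Softmax combination of fragment ion logits with the precursor logit.

    Returns a vector of length ``len(edge_ion_logits) + 1`` whose last entry
    is the precursor probability; an empty logit vector yields precursor
    probability exactly 1.
    """
    logits = np.append(np.asarray(edge_ion_logits, dtype=float), sigma)
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def weighted_mse_loss(
    predicted: np.ndarray, target: np.ndarray, spectra_per_compound: int = 1
) -> float:
    """Mean squared error between predicted and target probability vectors
    (precursor slot included), weighted by 1 / spectra-per-compound."""
    predicted = np.asarray(predicted, dtype=float)
    target = np.asarray(target, dtype=float)
    if predicted.shape != target.shape:
        raise ValueError("predicted and target vectors are misaligned")
    return float(((predicted - target) ** 2).mean() / spectra_per_compound)
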