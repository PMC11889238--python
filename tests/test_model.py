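import numpy as np
import pytest

from bondbreak.chem import parse_smiles
from bondbreak.nn.model import (
    Covariates,
    FragmentationModel,
    GraphTensors,
    ModelConfig,
    fragment_probabilities,
    weighted_mse_loss,
)
from bondbreak.nn.train import (
    Adam,
    PlateauScheduler,
    build_dataset,
    split_compounds,
    train,
    evaluate_loss,
)
from bondbreak.synthetic import make_library


def small_config(**kw):
    defaults = dict(depth=2, embedding_dim=16, head_hidden=24, seed=7)
    defaults.update(kw)
    return ModelConfig(**defaults)


def cov_for(graph, ce=30.0, ion_mode="+"):
    return Covariates(
        molecular_weight=graph.molecular_weight, ion_mode=ion_mode,
        collision_energy_ev=ce,
    )


class TestFeatureEmbedding:
    def test_identical_codes_identical_vectors(self):
        model = FragmentationModel(small_config())
        gt = GraphTensors(parse_smiles("CCCC"))
        x, _ = model.embed_features(gt)
        # the two terminal CH3 carbons share (element, H-count, ring) codes
        assert np.allclose(x.data[0], x.data[3])
        assert np.allclose(x.data[1], x.data[2])

    def test_out_of_vocabulary_code_maps_to_reserved_row(self):
        model = FragmentationModel(small_config())
        gt = GraphTensors(parse_smiles("CCO"))
        gt.atom_h = np.array([50, 2, 1])  # absurd H-count code
        x, _ = model.embed_features(gt)  # must not crash
        assert np.all(np.isfinite(x.data))

    def test_permuted_atom_order_permutes_states(self):
        model = FragmentationModel(small_config())
        a = GraphTensors(parse_smiles("CCO"))
        b = GraphTensors(parse_smiles("OCC"))
        xa, _ = model.embed_features(a)
        xb, _ = model.embed_features(b)
        assert np.allclose(np.sort(xa.data, axis=0), np.sort(xb.data, axis=0))


class TestGraphUpdate:
    def test_rgcn_layer_matches_dense_oracle(self):
        # independent numpy re-computation of one relational layer
        model = FragmentationModel(small_config(depth=1))
        g = parse_smiles("CC=O")
        gt = GraphTensors(g)
        x, _ = model.embed_features(gt)
        h = model.graph_update(x, gt, 0)

        W_self = model.params["layer0.W_self"].data
        b = model.params["layer0.b"].data
        expected = x.data @ W_self + b
        for r in range(4):
            W_r = model.params[f"layer{0}.W_rel{r}"].data
            neigh = [[] for _ in range(g.n_atoms)]
            for bond in g.bonds:
                if bond.bond_order_code == r:
                    u, v = bond.endpoints
                    neigh[u].append(v)
                    neigh[v].append(u)
            for i, js in enumerate(neigh):
                if js:
                    expected[i] += np.mean([x.data[j] @ W_r for j in js], axis=0)
        expected = np.where(expected > 0, expected, np.exp(np.minimum(expected, 0)) - 1)
        assert np.allclose(h.data, expected, atol=1e-12)

    def test_isolated_node_keeps_self_term_only(self):
        model = FragmentationModel(small_config(depth=1))
        gt = GraphTensors(parse_smiles("C"))  # methane: single node, no bonds
        x, _ = model.embed_features(gt)
        h = model.graph_update(x, gt, 0)
        W_self = model.params["layer0.W_self"].data
        b = model.params["layer0.b"].data
        z = x.data @ W_self + b
        expected = np.where(z > 0, z, np.exp(np.minimum(z, 0)) - 1)
        assert np.allclose(h.data, expected)

    @pytest.mark.parametrize("layer_type", ["rgcn", "gcn"])
    def test_end_to_end_permutation_invariance(self, layer_type):
        model = FragmentationModel(small_config(layer_type=layer_type, depth=3))
        s1 = model.predict_spectrum("CCOC(=O)C", collision_energy_ev=25.0)
        s2 = model.predict_spectrum("CC(=O)OCC", collision_energy_ev=25.0)
        assert np.allclose(s1.mz, s2.mz, atol=1e-9)
        assert np.allclose(s1.intensity, s2.intensity, atol=1e-6)


class TestEdgeHead:
    def test_symmetric_molecule_equal_side_logits(self):
        # central bond of butane: both endpoints have identical environments
        model = FragmentationModel(small_config(depth=3))
        out = model.predict("CCCC", collision_energy_ev=30.0)
        central = out.edge_logits[1]
        assert np.allclose(central[:5], central[5:], atol=1e-9)

    def test_hydrogen_infeasible_ions_absent_from_support(self):
        model = FragmentationModel(small_config())
        out = model.predict("CCO", collision_energy_ev=30.0)
        keys = {ion.key for ion in out.space.ions}
        # hydroxyl fragment (1 H) cannot lose 2 or 3 hydrogens
        oh_edge = 1
        assert (oh_edge, "right", -2) not in keys
        assert (oh_edge, "right", -3) not in keys
        assert len(out.probabilities) == len(out.space) + 1

    def test_zeroed_head_gives_zero_logits(self):
        model = FragmentationModel(small_config())
        for name in ("edge.W1", "edge.b1", "edge.W2", "edge.b2"):
            model.params[name].data[:] = 0.0
        out = model.predict("CCO", collision_energy_ev=30.0)
        assert np.allclose(out.edge_logits, 0.0)


class TestPrecursorHead:
    def test_single_atom_pooled_embedding_is_node_state(self):
        model = FragmentationModel(small_config(depth=0))
        gt = GraphTensors(parse_smiles("C"))
        x, _ = model.embed_features(gt)
        out = model.forward(gt, cov_for(gt.graph))
        assert np.allclose(out.pooled_embedding, x.data[0])

    def test_deterministic_repeat(self):
        model = FragmentationModel(small_config())
        a = model.predict("CC(=O)O", collision_energy_ev=40.0)
        b = model.predict("CC(=O)O", collision_energy_ev=40.0)
        assert a.precursor_logit == b.precursor_logit
        assert np.array_equal(a.probabilities, b.probabilities)

    def test_zeroed_head_gives_zero_sigma(self):
        model = FragmentationModel(small_config())
        for name in ("prec.W1", "prec.b1", "prec.W2", "prec.b2"):
            model.params[name].data[:] = 0.0
        out = model.predict("CCO", collision_energy_ev=30.0)
        assert out.precursor_logit == 0.0


class TestFragmentProbabilities:
    def test_uniform_logits_uniform_probabilities(self):
        p = fragment_probabilities(np.zeros(4), 0.0)
        assert np.allclose(p, 0.2)

    def test_large_sigma_limit(self):
        p = fragment_probabilities(np.zeros(4), 50.0)
        assert p[-1] > 0.999999

    def test_handworked_softmax(self):
        p = fragment_probabilities(np.array([np.log(2.0), 0.0]), 0.0)
        assert p == pytest.approx([0.5, 0.25, 0.25])

    def test_empty_ion_space_precursor_exactly_one(self):
        model = FragmentationModel(small_config())
        out = model.predict("c1ccccc1", collision_energy_ev=30.0)
        assert out.probabilities.tolist() == [1.0]

    def test_forward_probabilities_normalized(self):
        model = FragmentationModel(small_config())
        for smi in ("CCO", "CC(N)C(=O)O", "Cc1ccccc1"):
            out = model.predict(smi, collision_energy_ev=35.0)
            assert out.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(out.probabilities >= 0)


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        t = np.array([0.2, 0.8])
        assert weighted_mse_loss(t, t) == 0.0

    def test_per_compound_weighting(self):
        p, t = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert weighted_mse_loss(p, t, spectra_per_compound=1) == pytest.approx(1.0)
        assert weighted_mse_loss(p, t, spectra_per_compound=4) == pytest.approx(0.25)

    def test_misaligned_vectors_rejected(self):
        with pytest.raises(ValueError):
            weighted_mse_loss(np.zeros(3), np.zeros(4))


class TestTraining:
    def test_plateau_scheduler_reduces_lr(self):
        opt = Adam({}, lr=1.0)
        sched = PlateauScheduler(opt, factor=0.5, patience=2)
        sched.step(1.0)
        for _ in range(3):
            sched.step(1.0)  # no improvement
        assert opt.lr == 0.5

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train([], small_config())

    def test_memorizes_tiny_dataset(self):
        spectra = make_library(2, 2, seed=30, noise_sd=0.0)
        cfg = small_config(depth=1)
        samples = build_dataset(spectra, cfg)
        assert len(samples) == 4
        model, hist = train(samples, cfg, epochs=120, lr=1e-2, batch_size=4)
        assert hist.train_loss[-1] < hist.train_loss[0] * 0.05
        assert hist.train_loss[-1] < 1e-4

    def test_best_checkpoint_restored(self):
        spectra = make_library(6, 2, seed=31, noise_sd=0.05)
        cfg = small_config(depth=1)
        samples = build_dataset(spectra, cfg)
        tr, va = samples[:8], samples[8:]
        model, hist = train(tr, cfg, val_samples=va, epochs=15, lr=5e-3, batch_size=4)
        assert evaluate_loss(model, va) == pytest.approx(min(hist.val_loss), rel=1e-9)

    def test_reproducible_given_seed(self):
        spectra = make_library(3, 1, seed=32)
        cfg = small_config(depth=1, seed=11)
        samples = build_dataset(spectra, cfg)
        m1, h1 = train(samples, cfg, epochs=5, batch_size=2)
        m2, h2 = train(samples, cfg, epochs=5, batch_size=2)
        assert h1.train_loss == h2.train_loss
        for k in m1.params:
            assert np.array_equal(m1.params[k].data, m2.params[k].data)

    def test_compound_level_split_is_disjoint(self):
        spectra = make_library(20, 3, seed=33)
        samples = build_dataset(spectra, small_config())
        tr, va, te = split_compounds(samples, seed=1)
        groups = [
            {s.compound_key for s in part} for part in (tr, va, te)
        ]
        assert not (groups[0] & groups[1])
        assert not (groups[0] & groups[2])
        assert not (groups[1] & groups[2])
        assert len(tr) + len(va) + len(te) == len(samples)


class TestDepthMatters:
    def test_depth0_weaker_than_depth4_on_planted_task(self):
        # with no message passing the edge head cannot see beyond raw atom
        # codes, so a deeper model must reach a lower validation loss
        spectra = make_library(80, 2, seed=44, noise_sd=0.0)
        losses = {}
        for depth in (0, 4):
            cfg = ModelConfig(
                layer_type="rgcn", depth=depth, embedding_dim=16,
                head_hidden=24, seed=2,
            )
            samples = build_dataset(spectra, cfg)
            tr, va, _ = split_compounds(samples, seed=2, fractions=(0.8, 0.2, 0.0))
            _, hist = train(tr, cfg, val_samples=va, epochs=40, lr=5e-3)
            losses[depth] = hist.best_val_loss
        assert losses[4] < losses[0]


class TestCheckpointIO:
    def test_save_load_round_trip(self, tmp_path):
        model = FragmentationModel(small_config())
        path = tmp_path / "model.json"
        model.save(str(path))
        clone = FragmentationModel.load(str(path))
        a = model.predict("CC(=O)O", collision_energy_ev=30.0)
        b = clone.predict("CC(=O)O", collision_energy_ev=30.0)
        assert np.array_equal(a.probabilities, b.probabilities)
        assert clone.config == model.config
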