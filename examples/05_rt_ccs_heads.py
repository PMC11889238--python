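"""Predict retention time and collision cross section from the pooled
graph embedding.

Trains RT and CCS heads on synthetic labels (RT linear in molecular weight,
CCS following a mass-to-the-2/3 surface law) on top of a frozen
fragmentation model, then predicts both properties for new molecules.
Only the heads' dense weights are fitted; the fragmentation model is
bit-identical before and after (asserted internally by parameter hashing).
"""

import numpy as np

from bondbreak import ModelConfig, parse_smiles, predict_property, train_property_head
from bondbreak.nn.model import Covariates, FragmentationModel, GraphTensors
from bondbreak.synthetic import sample_molecules

model = FragmentationModel(ModelConfig(depth=2, embedding_dim=32, head_hidden=64, seed=1))
rng = np.random.default_rng(0)

samples_rt, samples_ccs = [], []
for smi in sample_molecules(200, seed=9):
    g = parse_smiles(smi)
    gt = GraphTensors(g)
    cov = Covariates(molecular_weight=g.molecular_weight, collision_energy_ev=30.0)
    samples_rt.append((gt, cov, 1.8 * g.molecular_weight + 120 + rng.normal(0, 5)))
    samples_ccs.append((gt, cov, 3.0 * g.molecular_weight ** (2 / 3) + rng.normal(0, 1)))

rt_head = train_property_head(model, samples_rt, "rt", epochs=200, seed=2)
ccs_head = train_property_head(model, samples_ccs, "ccs", epochs=200, seed=2)

print("molecule                       RT pred (s)   CCS pred (A^2)")
for smi in ("CCO", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "OCC1OC(O)C(O)C(O)C1O"):
    g = parse_smiles(smi)
    gt = GraphTensors(g)
    cov = Covariates(molecular_weight=g.molecular_weight, collision_energy_ev=30.0)
    rt = predict_property(model, rt_head, gt, cov)
    ccs = predict_property(model, ccs_head, gt, cov)
    print(f"{smi:30s} {rt:10.1f}   {ccs:10.1f}")
print("(RT grows linearly with mass and CCS with mass^(2/3) by construction;")
print(" CCS is regressed on a log scale, so predictions are always positive)")
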