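"""Retention time and collision cross section prediction heads.

Both properties are regressed from the mean-pooled graph embedding of a
trained fragmentation model, concatenated with the acquisition covariates —
the same inputs the precursor-stability head sees, but with a distinct set
of dense weights.  Only the head parameters are trained; every graph-layer
and fragment-head parameter of the underlying model stays bit-identical
(verified by hashing), so property training can never disturb spectrum
prediction.

Targets are z-scored for training.  CCS is regressed on a log scale and
exponentiated back, which keeps predictions strictly positive; RT is
regressed directly in seconds (minutes are converted on input).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .nn import autodiff as ad
from .nn.model import Covariates, FragmentationModel, GraphTensors
from .nn.train import Adam

__all__ = ["PropertyHead", "train_property_head", "predict_property", "parameter_hash"]

_TARGETS = ("rt", "ccs")


def parameter_hash(model: FragmentationModel) -> str:
    """SHA-256 over all model parameter bytes, for freezing assertions."""
    h = hashlib.sha256()
    for name in sorted(model.params):
        h.update(name.encode())
        h.update(np.ascontiguousarray(model.params[name].data).tobytes())
    return h.hexdigest()


@dataclass
class PropertyHead:
    target: str  # "rt" (seconds) or "ccs" (A^2, regressed in log space)
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    target_mean: float
    target_sd: float

    def _forward(self, features: np.ndarray) -> float:
        z = features @ self.W1 + self.b1
        z = np.where(z > 0, z, np.exp(np.minimum(z, 0.0)) - 1.0)  # ELU
        return float((z @ self.W2 + self.b2).item())


def _pooled_features(
    model: FragmentationModel, gt: GraphTensors, cov: Covariates
) -> np.ndarray:
    out = model.forward(gt, cov)
    return np.concatenate([out.pooled_embedding, cov.to_vector(model.config)])


def train_property_head(
    model: FragmentationModel,
    samples: list[tuple[GraphTensors, Covariates, float]],
    target: str,
    hidden: int = 64,
    epochs: int = 300,
    lr: float = 1e-2,
    seed: int = 0,
) -> PropertyHead:
    """Fit a two-layer dense head for RT or CCS on frozen model embeddings.

    ``samples`` are (graph tensors, covariates, target value) triples; target
    values in native units (RT seconds, CCS squared angstroms).  The
    fragmentation model itself is only evaluated, never updated.
    """
    if target not in _TARGETS:
        raise ValueError(f"target must be one of {_TARGETS}")
    if len(samples) < 10:
        raise ValueError("need at least 10 labeled molecules to fit a property head")

    before = parameter_hash(model)
    feats = np.stack([_pooled_features(model, gt, cov) for gt, cov, _ in samples])
    y = np.array([v for _, _, v in samples], dtype=float)
    if target == "ccs":
        if np.any(y <= 0):
            raise ValueError("CCS targets must be positive")
        y = np.log(y)
    mean, sd = float(y.mean()), float(y.std())
    # degenerate constant target: head output is irrelevant, predict the mean
    y_std = (y - mean) / sd if sd > 0 else np.zeros_like(y)

    rng = np.random.default_rng(seed)
    dim = feats.shape[1]
    params = {
        "W1": ad.parameter(rng.uniform(-1, 1, (dim, hidden)) * np.sqrt(6.0 / (dim + hidden))),
        "b1": ad.parameter(np.zeros(hidden)),
        "W2": ad.parameter(rng.uniform(-1, 1, (hidden, 1)) * np.sqrt(6.0 / (hidden + 1))),
        "b2": ad.parameter(np.zeros(1)),
    }
    opt = Adam(params, lr=lr)
    x = ad.constant(feats)
    for _ in range(epochs):
        opt.zero_grad()
        z = ad.elu(ad.add(ad.matmul(x, params["W1"]), params["b1"]))
        pred = ad.reshape(ad.add(ad.matmul(z, params["W2"]), params["b2"]), (-1,))
        loss = ad.mse(pred, y_std)
        loss.backward()
        opt.step()

    after = parameter_hash(model)
    assert before == after, "fragmentation model parameters changed during head training"
    return PropertyHead(
        target=target,
        W1=params["W1"].data.copy(),
        b1=params["b1"].data.copy(),
        W2=params["W2"].data.copy(),
        b2=params["b2"].data.copy(),
        target_mean=mean,
        target_sd=sd,
    )


def predict_property(
    model: FragmentationModel,
    head: PropertyHead,
    gt: GraphTensors,
    covariates: Covariates,
) -> float:
    """Predict RT (s) or CCS (A^2) for one molecule; deterministic."""
    feats = _pooled_features(model, gt, covariates)
    value = head._forward(feats) * head.target_sd + head.target_mean
    return float(np.exp(value)) if head.target == "ccs" else float(value)
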