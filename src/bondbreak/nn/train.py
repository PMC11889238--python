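"""Training loop: dataset assembly, ADAM, plateau scheduling, checkpointing.

Spectra are turned into training samples by enumerating the fragment ion
space of their compound, matching peaks at a ppm tolerance, deriving the
target probability distribution and applying the curation filters.  Losses
are weighted by 1 over the number of spectra available per compound so that
heavily re-measured compounds do not dominate.  Splits are at the compound
level (InChIKey), never at the spectrum level.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from ..annotation import (
    UnassignableSpectrumError,
    apply_training_filters,
    assign_target_probabilities,
    match_peaks,
)
from ..chem import parse_smiles, SmilesParseError
from ..spectra import Spectrum
from . import autodiff as ad
from .model import Covariates, FragmentationModel, GraphTensors, ModelConfig

__all__ = [
    "TrainingSample",
    "Adam",
    "PlateauScheduler",
    "build_dataset",
    "split_compounds",
    "train",
    "TrainingHistory",
]


@dataclass
class TrainingSample:
    gt: GraphTensors
    covariates: Covariates
    target: np.ndarray  # length |ion space| + 1, last = precursor
    weight: float  # 1 / spectra-per-compound
    compound_key: str
    spectrum: Spectrum | None = None


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_val_loss(self) -> float:
        return min(self.val_loss) if self.val_loss else math.nan


class Adam:
    """ADAM optimizer over the model's parameter dictionary."""

    def __init__(self, params: dict[str, ad.Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1 ** self.t)
            v_hat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class PlateauScheduler:
    """Multiply the learning rate by ``factor`` after ``patience`` epochs
    without validation-loss improvement."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 10,
                 min_lr: float = 1e-6, threshold: float = 1e-6):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.threshold = threshold
        self.best = math.inf
        self.stale = 0

    def step(self, val_loss: float) -> None:
        if val_loss < self.best - self.threshold:
            self.best = val_loss
            self.stale = 0
        else:
            self.stale += 1
            if self.stale > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.stale = 0


def build_dataset(
    spectra: list[Spectrum],
    config: ModelConfig,
    tol_ppm: float = 50.0,
    apply_filters: bool = True,
) -> list[TrainingSample]:
    """Assemble training samples from annotated spectra.

    Each spectrum must carry a SMILES, ion mode and collision energy.  Spectra
    failing to parse, match, or pass the curation filters are silently
    dropped; per-compound loss weights are set from the surviving counts.
    """
    graph_cache: dict[str, GraphTensors | None] = {}
    samples: list[TrainingSample] = []
    for s in spectra:
        if not s.smiles:
            continue
        cache_key = f"{s.smiles}|{s.ion_mode}"
        if cache_key not in graph_cache:
            try:
                graph_cache[cache_key] = GraphTensors(parse_smiles(s.smiles), ion_mode=s.ion_mode)
            except SmilesParseError:
                graph_cache[cache_key] = None
        gt = graph_cache[cache_key]
        if gt is None:
            continue
        try:
            matches = match_peaks(s, gt.space, tol_ppm=tol_ppm)
            target = assign_target_probabilities(s, matches)
        except (ValueError, UnassignableSpectrumError):
            continue
        if apply_filters:
            report = apply_training_filters(
                s, target, gt.graph.molecular_weight, s.collision_energy_ev
            )
            if not report.passed:
                continue
        samples.append(
            TrainingSample(
                gt=gt,
                covariates=Covariates(
                    molecular_weight=gt.graph.molecular_weight,
                    ion_mode=s.ion_mode,
                    collision_energy_ev=s.collision_energy_ev or 0.0,
                    instrument=s.instrument,
                ),
                target=target.as_vector(gt.space),
                weight=1.0,
                compound_key=s.inchikey or gt.graph.canonical_smiles,
                spectrum=s,
            )
        )
    counts: dict[str, int] = {}
    for sample in samples:
        counts[sample.compound_key] = counts.get(sample.compound_key, 0) + 1
    for sample in samples:
        sample.weight = 1.0 / counts[sample.compound_key]
    return samples


def split_compounds(
    samples: list[TrainingSample],
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> tuple[list[TrainingSample], list[TrainingSample], list[TrainingSample]]:
    """Compound-level train/validation/test split: all spectra of a compound
    land in the same partition."""
    keys = sorted({s.compound_key for s in samples})
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    n = len(keys)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    train_keys = set(keys[:n_train])
    val_keys = set(keys[n_train:n_train + n_val])
    buckets = ([], [], [])
    for s in samples:
        if s.compound_key in train_keys:
            buckets[0].append(s)
        elif s.compound_key in val_keys:
            buckets[1].append(s)
        else:
            buckets[2].append(s)
    return buckets


def _sample_loss(model: FragmentationModel, sample: TrainingSample) -> ad.Tensor:
    out = model.forward(sample.gt, sample.covariates)
    loss = ad.mse(out.prob_tensor, sample.target)
    return ad.scale(loss, sample.weight)


def evaluate_loss(model: FragmentationModel, samples: list[TrainingSample]) -> float:
    if not samples:
        return math.nan
    return float(np.mean([_sample_loss(model, s).data for s in samples]))


def train(
    train_samples: list[TrainingSample],
    config: ModelConfig | None = None,
    val_samples: list[TrainingSample] | None = None,
    epochs: int = 200,
    lr: float = 1e-3,
    batch_size: int = 32,
    plateau_factor: float = 0.5,
    plateau_patience: int = 10,
    seed: int | None = None,
    verbose: bool = False,
) -> tuple[FragmentationModel, TrainingHistory]:
    """Train a fragmentation model with ADAM and a plateau LR scheduler.

    The checkpoint with the lowest validation loss is restored at the end
    (training loss is used when no validation set is given).  Fully
    reproducible for a fixed config seed: parameter initialization and batch
    order both derive from it.
    """
    if not train_samples:
        raise ValueError("empty training set")
    config = config or ModelConfig()
    model = FragmentationModel(config)
    opt = Adam(model.params, lr=lr)
    sched = PlateauScheduler(opt, factor=plateau_factor, patience=plateau_patience)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    history = TrainingHistory()
    best_state: dict | None = None
    best_val = math.inf

    n = len(train_samples)
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, batch_size):
            batch = [train_samples[i] for i in order[start:start + batch_size]]
            opt.zero_grad()
            losses = [_sample_loss(model, s) for s in batch]
            total = losses[0]
            for l in losses[1:]:
                total = ad.add(total, l)
            total = ad.scale(total, 1.0 / len(batch))
            total.backward()
            opt.step()
            epoch_losses.append(float(total.data))
        train_loss = float(np.mean(epoch_losses))
        val_loss = (
            evaluate_loss(model, val_samples) if val_samples else train_loss
        )
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.learning_rate.append(opt.lr)
        sched.step(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = copy.deepcopy(model.state_dict())
            history.best_epoch = epoch
        if verbose:
            print(
                f"epoch {epoch + 1:4d}  train {train_loss:.3e}  "
                f"val {val_loss:.3e}  lr {opt.lr:.2e}"
            )
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history
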