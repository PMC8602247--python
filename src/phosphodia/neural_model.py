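"""Hybrid recurrent + attention regression models for phosphopeptides.

Two tasks share one architecture family:

* **Fragment-ion intensity** — token embedding (amino-acid embedding
  concatenated with a broadcast precursor-charge embedding) -> two stacked
  bidirectional LSTM layers -> linear projection to the model width ->
  sinusoidal position encoding -> a stack of Transformer encoder layers ->
  a per-position linear head emitting the 8 intensity channels.
* **Indexed retention time (iRT)** — amino-acid embedding -> the same
  biLSTM/Transformer trunk -> an instance-specific attention pooling
  (softmax-normalized per-position weights over non-pad positions) -> a
  linear head emitting one scalar on the normalized [0, 1] RT scale.
  The deployed model is an ensemble over several Transformer depths whose
  predictions are averaged.

Training uses masked mean-squared error (ion task; the ``-1`` sentinel
cells carry no gradient) or RMSE (RT task), Adam, step learning-rate decay,
and best-on-validation checkpoint selection (median PCC maximized for the
ion task, delta-t95 minimized for RT).  Transfer learning = initializing
from a previous checkpoint and continuing at a lower learning rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autodiff import Tensor, Adam, concat, lstm_seq
from .peptide_codec import (
    VOCAB,
    ModifiedPeptide,
    Precursor,
    Vocabulary,
    encode_ion_input,
    encode_rt_input,
    format_compact,
)
from .ion_space import validity_mask, SENTINEL
from . import metrics as _metrics

__all__ = [
    "IonModelConfig",
    "RTModelConfig",
    "RTScale",
    "TrainConfig",
    "ModelCheckpoint",
    "IonModel",
    "RTEnsemble",
    "build_ion_model",
    "build_rt_ensemble",
    "masked_mse",
    "rt_loss",
    "split_dataset",
    "train",
    "predict",
    "predict_ion_matrices",
    "predict_irt",
]


# --------------------------------------------------------------------- configs
@dataclass
class IonModelConfig:
    """Fragment-intensity model hyper-parameters (defaults = full size)."""

    aa_embed_dim: int = 192
    charge_embed_dim: int = 64
    lstm_hidden: int = 512
    lstm_layers: int = 2
    encoder_layers: int = 8
    attention_heads: int = 8
    d_model: int = 512
    ff_dim: int | None = None  # default 2 * d_model
    output_dim: int = 8
    max_len: int = 52

    def __post_init__(self):
        if self.ff_dim is None:
            self.ff_dim = 2 * self.d_model
        if self.d_model % self.attention_heads:
            raise ValueError("d_model must be divisible by attention_heads")

    @classmethod
    def reduced(cls, max_len: int = 32) -> "IonModelConfig":
        """A small CPU-friendly variant used in tests and demonstrations."""
        return cls(
            aa_embed_dim=32,
            charge_embed_dim=16,
            lstm_hidden=64,
            encoder_layers=2,
            attention_heads=2,
            d_model=64,
            max_len=max_len,
        )


@dataclass
class RTModelConfig:
    """iRT model hyper-parameters; the ensemble varies Transformer depth."""

    aa_embed_dim: int = 256
    lstm_hidden: int = 512
    lstm_layers: int = 2
    attention_heads: int = 8
    d_model: int = 512
    ff_dim: int | None = None
    ensemble_depths: tuple = (4, 5, 6, 7, 8)
    max_len: int = 52

    def __post_init__(self):
        if self.ff_dim is None:
            self.ff_dim = 2 * self.d_model
        if not self.ensemble_depths:
            raise ValueError("ensemble_depths must be nonempty")
        if any(not 1 <= d <= 12 for d in self.ensemble_depths):
            raise ValueError("ensemble depths must lie in 1..12")
        if self.d_model % self.attention_heads:
            raise ValueError("d_model must be divisible by attention_heads")

    @classmethod
    def reduced(cls, max_len: int = 32, depths: tuple = (2, 3)) -> "RTModelConfig":
        return cls(
            aa_embed_dim=32,
            lstm_hidden=64,
            attention_heads=2,
            d_model=64,
            ensemble_depths=depths,
            max_len=max_len,
        )


@dataclass
class RTScale:
    """Linear map between the RT/iRT axis and the model's [0, 1] scale."""

    rt_min: float = -100.0
    rt_max: float = 200.0

    def __post_init__(self):
        if self.rt_max <= self.rt_min:
            raise ValueError("rt_max must exceed rt_min")

    @property
    def span(self) -> float:
        return self.rt_max - self.rt_min

    def normalize(self, rt):
        return (np.asarray(rt, dtype=float) - self.rt_min) / self.span

    def denormalize(self, z):
        return np.asarray(z, dtype=float) * self.span + self.rt_min


@dataclass
class TrainConfig:
    """Optimization settings: Adam with step learning-rate decay."""

    learning_rate: float = 1e-4
    lr_decay_factor: float = 0.1
    decay_milestones: tuple | None = None  # default [ceil(2/3 E), ceil(5/6 E)]
    max_epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    stop_at_metric: float | None = None  # early stop once validation crosses this

    def milestones(self) -> tuple:
        if self.decay_milestones is not None:
            return tuple(self.decay_milestones)
        return (
            math.ceil(2 * self.max_epochs / 3),
            math.ceil(5 * self.max_epochs / 6),
        )


@dataclass
class ModelCheckpoint:
    """Trained weights + config + the validation metric they were chosen by."""

    task: str  # 'ion' | 'rt'
    config: object
    weights: dict
    metric: float | None = None
    provenance: str = "trained"
    rt_scale: RTScale = field(default_factory=RTScale)

    def save(self, path: str):
        """Single .npz weight blob plus a sidecar JSON config."""
        np.savez(path, **{k: v for k, v in self.weights.items()})
        cfg = asdict(self.config)
        meta = {
            "task": self.task,
            "config": cfg,
            "metric": self.metric,
            "provenance": self.provenance,
            "rt_scale": asdict(self.rt_scale),
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "ModelCheckpoint":
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        cfg_cls = IonModelConfig if meta["task"] == "ion" else RTModelConfig
        cfg = meta["config"]
        if "ensemble_depths" in cfg:
            cfg["ensemble_depths"] = tuple(cfg["ensemble_depths"])
        npz = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        weights = {k: npz[k] for k in npz.files}
        return cls(
            task=meta["task"],
            config=cfg_cls(**cfg),
            weights=weights,
            metric=meta["metric"],
            provenance=meta["provenance"],
            rt_scale=RTScale(**meta["rt_scale"]),
        )


# ------------------------------------------------------------------ primitives
def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class _Params:
    """Named parameter registry shared by all submodules of one model."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.by_name: dict[str, Tensor] = {}

    def weight(self, name, fan_in, fan_out) -> Tensor:
        t = Tensor(_glorot(self.rng, fan_in, fan_out), requires_grad=True)
        self.by_name[name] = t
        return t

    def zeros(self, name, *shape) -> Tensor:
        t = Tensor(np.zeros(shape), requires_grad=True)
        self.by_name[name] = t
        return t

    def const(self, name, value) -> Tensor:
        t = Tensor(np.asarray(value, dtype=float), requires_grad=True)
        self.by_name[name] = t
        return t

    def all(self) -> list[Tensor]:
        return list(self.by_name.values())

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.by_name.items()}

    def load_state_dict(self, state: dict):
        missing = set(self.by_name) - set(state)
        if missing:
            raise ValueError(f"checkpoint is missing parameters: {sorted(missing)[:5]}")
        for k, t in self.by_name.items():
            if t.data.shape != state[k].shape:
                raise ValueError(
                    f"shape mismatch for {k}: {t.data.shape} vs {state[k].shape}"
                )
            t.data = state[k].astype(float).copy()


class _LSTM:
    """One unidirectional LSTM layer (batch, time, features)."""

    def __init__(self, params: _Params, name: str, d_in: int, hidden: int):
        self.h = hidden
        self.wx = params.weight(f"{name}.wx", d_in, 4 * hidden)
        self.wh = params.weight(f"{name}.wh", hidden, 4 * hidden)
        b0 = np.zeros(4 * hidden)
        b0[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = params.const(f"{name}.b", b0)

    def __call__(self, x: Tensor) -> Tensor:
        return lstm_seq(x, self.wx, self.wh, self.b)


class _BiLSTMStack:
    """Stacked bidirectional LSTM; pads stay at the sequence tail."""

    def __init__(self, params, name, d_in, hidden, layers):
        self.layers = []
        for k in range(layers):
            d = d_in if k == 0 else 2 * hidden
            self.layers.append(
                (
                    _LSTM(params, f"{name}.l{k}.fwd", d, hidden),
                    _LSTM(params, f"{name}.l{k}.bwd", d, hidden),
                )
            )

    @staticmethod
    def _reverse_index(lengths: np.ndarray, T: int) -> np.ndarray:
        """Per-row permutation reversing the first ``len`` positions."""
        perm = np.tile(np.arange(T), (len(lengths), 1))
        for r, n in enumerate(lengths):
            perm[r, :n] = np.arange(n - 1, -1, -1)
        return perm

    def __call__(self, x: Tensor, lengths: np.ndarray) -> Tensor:
        B, T, _ = x.shape
        rows = np.arange(B)[:, None]
        perm = self._reverse_index(lengths, T)
        for fwd, bwd in self.layers:
            rev = x[rows, perm]
            x = concat([fwd(x), bwd(rev)[rows, perm]], axis=-1)
        return x


def _sinusoidal_pe(T: int, d: int) -> np.ndarray:
    pos = np.arange(T)[:, None]
    k = np.arange(d // 2)[None, :]
    angle = pos / np.power(10000.0, 2 * k / d)
    pe = np.zeros((T, d))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


class _EncoderLayer:
    """Post-norm Transformer encoder layer with multi-head self-attention."""

    def __init__(self, params, name, d_model, heads, ff_dim):
        self.d = d_model
        self.h = heads
        self.dk = d_model // heads
        p = params
        self.wq = p.weight(f"{name}.wq", d_model, d_model)
        self.wk = p.weight(f"{name}.wk", d_model, d_model)
        self.wv = p.weight(f"{name}.wv", d_model, d_model)
        self.wo = p.weight(f"{name}.wo", d_model, d_model)
        self.ln1_g = p.const(f"{name}.ln1.g", np.ones(d_model))
        self.ln1_b = p.zeros(f"{name}.ln1.b", d_model)
        self.w1 = p.weight(f"{name}.ff.w1", d_model, ff_dim)
        self.b1 = p.zeros(f"{name}.ff.b1", ff_dim)
        self.w2 = p.weight(f"{name}.ff.w2", ff_dim, d_model)
        self.b2 = p.zeros(f"{name}.ff.b2", d_model)
        self.ln2_g = p.const(f"{name}.ln2.g", np.ones(d_model))
        self.ln2_b = p.zeros(f"{name}.ln2.b", d_model)

    def __call__(self, x: Tensor, attn_mask: np.ndarray) -> Tensor:
        B, T, D = x.shape

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, T, self.h, self.dk).swapaxes(1, 2)

        q, k, v = heads(x @ self.wq), heads(x @ self.wk), heads(x @ self.wv)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.dk))
        attn = scores.softmax_last(additive_mask=attn_mask)
        ctx = (attn @ v).swapaxes(1, 2).reshape(B, T, D)
        x = (x + ctx @ self.wo).layer_norm(self.ln1_g, self.ln1_b)
        ff = (x @ self.w1 + self.b1).relu() @ self.w2 + self.b2
        return (x + ff).layer_norm(self.ln2_g, self.ln2_b)


def _attention_mask(valid: np.ndarray) -> np.ndarray:
    """(B, T) validity -> additive (B, 1, 1, T) mask of 0 / -1e9."""
    return np.where(valid, 0.0, -1e9)[:, None, None, :]


# ----------------------------------------------------------------- ion model
class IonModel:
    """Fragment-ion intensity network; see the module docstring."""

    def __init__(self, cfg: IonModelConfig, seed: int = 0, vocab: Vocabulary = VOCAB):
        self.cfg = cfg
        self.vocab = vocab
        rng = np.random.default_rng(seed)
        p = self.params = _Params(rng)
        self.aa_embed = p.weight("aa_embed", len(vocab), cfg.aa_embed_dim)
        self.charge_embed = p.weight("charge_embed", vocab.max_charge, cfg.charge_embed_dim)
        d_in = cfg.aa_embed_dim + cfg.charge_embed_dim
        self.lstm = _BiLSTMStack(p, "lstm", d_in, cfg.lstm_hidden, cfg.lstm_layers)
        self.proj = p.weight("proj", 2 * cfg.lstm_hidden, cfg.d_model)
        self.proj_b = p.zeros("proj_b", cfg.d_model)
        self.encoders = [
            _EncoderLayer(p, f"enc{k}", cfg.d_model, cfg.attention_heads, cfg.ff_dim)
            for k in range(cfg.encoder_layers)
        ]
        self.head = p.weight("head", cfg.d_model, cfg.output_dim)
        self.head_b = p.zeros("head_b", cfg.output_dim)
        self.pe = _sinusoidal_pe(cfg.max_len + 1, cfg.d_model)

    # batches: ids (B, 1+L) pad-filled, lengths = n per peptide, charges (B,)
    def forward(self, ids: np.ndarray, lengths: np.ndarray, charges: np.ndarray) -> Tensor:
        B, T = ids.shape
        aa = self.aa_embed.gather_rows(ids)
        qe = self.charge_embed.gather_rows(charges - 1)  # (B, dq)
        qe = qe.reshape(B, 1, self.cfg.charge_embed_dim) * np.ones((B, T, 1))
        x = concat([aa, qe], axis=-1)
        x = self.lstm(x, lengths + 1)
        x = x @ self.proj + self.proj_b
        x = x + self.pe[:T]
        valid = np.arange(T)[None, :] < (lengths + 1)[:, None]
        mask = _attention_mask(valid)
        for enc in self.encoders:
            x = enc(x, mask)
        out = x @ self.head + self.head_b  # (B, T, 8)
        return out[:, 1:]  # rows aligned with residues 1..L

    def encode_batch(self, precursors: list[Precursor]):
        """Token ids / lengths / charges for a batch, padded to max_len."""
        L = self.cfg.max_len
        B = len(precursors)
        ids = np.full((B, L + 1), self.vocab.pad_id, dtype=int)
        lengths = np.zeros(B, dtype=int)
        charges = np.zeros(B, dtype=int)
        for r, pr in enumerate(precursors):
            seq = encode_ion_input(pr.peptide, pr.charge, self.vocab)
            toks = seq.ids[:-1]  # charge handled by its own embedding
            if len(toks) > L + 1:
                raise ValueError(
                    f"peptide longer ({len(toks) - 1}) than model max_len {L}"
                )
            ids[r, : len(toks)] = toks
            lengths[r] = len(pr.peptide)
            charges[r] = pr.charge
        return ids, lengths, charges


def build_ion_model(cfg: IonModelConfig, seed: int = 0) -> IonModel:
    return IonModel(cfg, seed=seed)


# ------------------------------------------------------------------ RT model
class _RTMember:
    def __init__(self, cfg: RTModelConfig, depth: int, seed: int, vocab: Vocabulary):
        self.cfg = cfg
        self.vocab = vocab
        rng = np.random.default_rng(seed)
        p = self.params = _Params(rng)
        self.aa_embed = p.weight("aa_embed", len(vocab), cfg.aa_embed_dim)
        self.lstm = _BiLSTMStack(p, "lstm", cfg.aa_embed_dim, cfg.lstm_hidden, cfg.lstm_layers)
        self.proj = p.weight("proj", 2 * cfg.lstm_hidden, cfg.d_model)
        self.proj_b = p.zeros("proj_b", cfg.d_model)
        self.encoders = [
            _EncoderLayer(p, f"enc{k}", cfg.d_model, cfg.attention_heads, cfg.ff_dim)
            for k in range(depth)
        ]
        self.pool_w = p.weight("pool_w", cfg.d_model, 1)
        self.head = p.weight("head", cfg.d_model, 1)
        self.head_b = p.zeros("head_b", 1)
        self.pe = _sinusoidal_pe(cfg.max_len + 1, cfg.d_model)

    def forward(self, ids: np.ndarray, lengths: np.ndarray) -> Tensor:
        B, T = ids.shape
        x = self.aa_embed.gather_rows(ids)
        x = self.lstm(x, lengths + 1)
        x = x @ self.proj + self.proj_b
        x = x + self.pe[:T]
        valid = np.arange(T)[None, :] < (lengths + 1)[:, None]
        for enc in self.encoders:
            x = enc(x, _attention_mask(valid))
        # instance-specific pooling weights, zero on pads
        w = (x @ self.pool_w).reshape(B, T)
        w = w.softmax_last(additive_mask=np.where(valid, 0.0, -1e9))
        pooled = (w.reshape(B, T, 1) * x).sum(axis=1)
        return (pooled @ self.head + self.head_b).reshape(B)


class RTEnsemble:
    """Ensemble of RT networks differing in Transformer depth."""

    def __init__(self, cfg: RTModelConfig, seed: int = 0, vocab: Vocabulary = VOCAB):
        self.cfg = cfg
        self.vocab = vocab
        self.members = [
            _RTMember(cfg, depth, seed + 1000 * j, vocab)
            for j, depth in enumerate(cfg.ensemble_depths)
        ]

    def forward(self, ids, lengths) -> Tensor:
        preds = [m.forward(ids, lengths) for m in self.members]
        out = preds[0]
        for t in preds[1:]:
            out = out + t
        return out * (1.0 / len(preds))

    def encode_batch(self, peptides: list[ModifiedPeptide]):
        L = self.cfg.max_len
        B = len(peptides)
        ids = np.full((B, L + 1), self.vocab.pad_id, dtype=int)
        lengths = np.zeros(B, dtype=int)
        for r, pep in enumerate(peptides):
            seq = encode_rt_input(pep, self.vocab)
            if len(seq.ids) > L + 1:
                raise ValueError(f"peptide longer ({len(seq.ids) - 1}) than max_len {L}")
            ids[r, : len(seq.ids)] = seq.ids
            lengths[r] = len(pep)
        return ids, lengths

    # parameter plumbing over all members
    def all_params(self) -> list[Tensor]:
        return [t for m in self.members for t in m.params.all()]

    def state_dict(self) -> dict:
        return {
            f"m{j}.{k}": v
            for j, m in enumerate(self.members)
            for k, v in m.params.state_dict().items()
        }

    def load_state_dict(self, state: dict):
        for j, m in enumerate(self.members):
            prefix = f"m{j}."
            sub = {k[len(prefix):]: v for k, v in state.items() if k.startswith(prefix)}
            m.params.load_state_dict(sub)


def build_rt_ensemble(cfg: RTModelConfig, seed: int = 0) -> RTEnsemble:
    return RTEnsemble(cfg, seed=seed)


# -------------------------------------------------------------------- losses
def masked_mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """MSE over cells valid in the target (sentinel ``-1`` cells excluded)."""
    valid = (target != SENTINEL).astype(float)
    n_valid = valid.sum()
    if n_valid == 0:
        raise ValueError("no valid cells in batch")
    diff = (pred - np.where(valid > 0, target, 0.0)) * valid
    return (diff * diff).sum() * (1.0 / n_valid)


def rt_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Root-mean-square error on the normalized RT scale."""
    target = np.asarray(target, dtype=float)
    if target.size == 0:
        raise ValueError("empty batch")
    diff = pred - target
    return ((diff * diff).mean() + 1e-12) ** 0.5


# ------------------------------------------------------------------ splitting
def split_dataset(entries: list, ratios=(0.8, 0.1, 0.1), seed: int = 0):
    """Partition entries into train/val/test grouped by modified sequence.

    All charge states (and duplicate records) of one modified peptide land
    in the same split, preventing leakage across splits.
    """
    total = float(sum(ratios))
    fracs = [r / total for r in ratios]
    groups: dict[str, list] = {}
    for e in entries:
        pep = _peptide_of(e)
        groups.setdefault(format_compact(pep), []).append(e)
    keys = sorted(groups)
    if len(keys) < len(ratios):
        raise ValueError(f"{len(keys)} peptide groups cannot fill {len(ratios)} splits")
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    bounds = np.floor(np.cumsum(fracs[:-1]) * len(keys)).astype(int)
    parts = np.split(np.array(keys, dtype=object), bounds)
    return tuple([e for k in part for e in groups[k]] for part in parts)


def _peptide_of(entry):
    if isinstance(entry, ModifiedPeptide):
        return entry
    if isinstance(entry, Precursor):
        return entry.peptide
    if hasattr(entry, "peptide"):
        pep = entry.peptide
        return pep.peptide if isinstance(pep, Precursor) else pep
    if isinstance(entry, tuple):
        return _peptide_of(entry[0])
    raise TypeError(f"cannot extract a peptide from {type(entry)!r}")


# ------------------------------------------------------------------- training
@dataclass
class _IonData:
    precursors: list
    targets: np.ndarray  # (N, L, 8)


@dataclass
class _RTData:
    peptides: list
    z: np.ndarray  # normalized targets


def _iter_batches(n, batch_size, rng):
    order = rng.permutation(n)
    for lo in range(0, n, batch_size):
        yield order[lo : lo + batch_size]


def train(
    model,
    train_data,
    val_data,
    cfg: TrainConfig,
    init: ModelCheckpoint | None = None,
    rt_scale: RTScale | None = None,
    verbose: bool = False,
):
    """Train an :class:`IonModel` or :class:`RTEnsemble`.

    ``train_data`` / ``val_data`` are ``(precursors, target_matrices)`` for
    the ion task or ``(peptides, rt_values)`` (already on the iRT axis) for
    the RT task.  Returns ``(ModelCheckpoint, history)`` where the
    checkpoint holds the weights with the best validation metric seen, not
    the final epoch, and history records per-epoch loss and metric.
    """
    is_ion = isinstance(model, IonModel)
    params_obj = model.params if is_ion else None
    if init is not None:
        if is_ion:
            model.params.load_state_dict(init.weights)
        else:
            model.load_state_dict(init.weights)
    rt_scale = rt_scale or RTScale()

    if is_ion:
        data = _IonData(list(train_data[0]), np.asarray(train_data[1], dtype=float))
        vdata = _IonData(list(val_data[0]), np.asarray(val_data[1], dtype=float))
        params = params_obj.all()
    else:
        data = _RTData(list(train_data[0]), rt_scale.normalize(train_data[1]))
        vdata = _RTData(list(val_data[0]), rt_scale.normalize(val_data[1]))
        params = model.all_params()

    opt = Adam(params, lr=cfg.learning_rate)
    milestones = set(cfg.milestones())
    rng = np.random.default_rng(cfg.seed)
    history = {"loss": [], "val_metric": [], "lr": []}
    best_metric, best_state = None, None

    n = len(data.precursors) if is_ion else len(data.peptides)
    for epoch in range(1, cfg.max_epochs + 1):
        if epoch in milestones:
            opt.lr *= cfg.lr_decay_factor
        losses = []
        for idx in _iter_batches(n, cfg.batch_size, rng):
            if is_ion:
                batch = [data.precursors[i] for i in idx]
                ids, lengths, charges = model.encode_batch(batch)
                pred = model.forward(ids, lengths, charges)
                loss = masked_mse(pred, data.targets[idx])
            else:
                batch = [data.peptides[i] for i in idx]
                ids, lengths = model.encode_batch(batch)
                pred = model.forward(ids, lengths)
                loss = rt_loss(pred, data.z[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged at epoch {epoch} (non-finite loss)")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        metric = _validation_metric(model, vdata, is_ion)
        history["loss"].append(float(np.mean(losses)))
        history["val_metric"].append(metric)
        history["lr"].append(opt.lr)
        improved = (
            best_metric is None
            or (is_ion and metric > best_metric)
            or (not is_ion and metric < best_metric)
        )
        if improved:
            best_metric = metric
            best_state = (
                params_obj.state_dict() if is_ion else model.state_dict()
            )
        if verbose:
            print(f"epoch {epoch:4d} loss {history['loss'][-1]:.5f} val {metric:.4f}")
        if cfg.stop_at_metric is not None and (
            (is_ion and best_metric >= cfg.stop_at_metric)
            or (not is_ion and best_metric <= cfg.stop_at_metric)
        ):
            break

    checkpoint = ModelCheckpoint(
        task="ion" if is_ion else "rt",
        config=model.cfg,
        weights=best_state,
        metric=best_metric,
        provenance="fine-tuned" if init is not None else "trained",
        rt_scale=rt_scale,
    )
    # leave the model holding its best weights
    if is_ion:
        params_obj.load_state_dict(best_state)
    else:
        model.load_state_dict(best_state)
    return checkpoint, history


def _validation_metric(model, vdata, is_ion: bool) -> float:
    if is_ion:
        mats = _forward_matrices(model, vdata.precursors)
        pccs = [
            _metrics.pearson_cc(pred, tgt)
            for pred, tgt in zip(mats, vdata.targets)
        ]
        med, _ = _metrics.median_summary(pccs)
        return med
    ids, lengths = model.encode_batch(vdata.peptides)
    pred = model.forward(ids, lengths).data
    return _metrics.delta_t95(pred, vdata.z)


def _forward_matrices(model: IonModel, precursors, batch_size: int = 128) -> np.ndarray:
    outs = []
    for lo in range(0, len(precursors), batch_size):
        batch = precursors[lo : lo + batch_size]
        ids, lengths, charges = model.encode_batch(batch)
        outs.append(model.forward(ids, lengths, charges).data)
    return np.concatenate(outs, axis=0)


# ----------------------------------------------------------------- prediction
def predict_ion_matrices(
    model: IonModel, precursors: list[Precursor]
) -> np.ndarray:
    """Predicted fragment matrices with impossible channels forced to -1,
    valid cells clipped to [0, 1] and renormalized so the max is 1."""
    raw = _forward_matrices(model, precursors)
    L = model.cfg.max_len
    out = np.full_like(raw, SENTINEL)
    for r, pr in enumerate(precursors):
        mask = validity_mask(pr.peptide, L)
        vals = np.clip(raw[r], 0.0, 1.0)
        top = vals[mask].max(initial=0.0)
        if top > 0:
            vals = vals / top
        out[r] = np.where(mask, np.clip(vals, 0.0, 1.0), SENTINEL)
    return out


def predict_irt(
    ensemble: RTEnsemble, peptides: list[ModifiedPeptide], rt_scale: RTScale | None = None,
    batch_size: int = 128,
) -> np.ndarray:
    """Ensemble iRT predictions rescaled from [0, 1] back to the RT axis."""
    rt_scale = rt_scale or RTScale()
    zs = []
    for lo in range(0, len(peptides), batch_size):
        ids, lengths = ensemble.encode_batch(peptides[lo : lo + batch_size])
        zs.append(ensemble.forward(ids, lengths).data)
    return rt_scale.denormalize(np.concatenate(zs))


def predict(checkpoint: ModelCheckpoint, inputs, seed: int = 0):
    """Rebuild the model from a checkpoint and predict for ``inputs``."""
    if checkpoint.task == "ion":
        model = IonModel(checkpoint.config, seed=seed)
        model.params.load_state_dict(checkpoint.weights)
        return predict_ion_matrices(model, inputs)
    ensemble = RTEnsemble(checkpoint.config, seed=seed)
    ensemble.load_state_dict(checkpoint.weights)
    return predict_irt(ensemble, inputs, checkpoint.rt_scale)
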