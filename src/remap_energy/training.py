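"""Objectives and training for the recurrent active-vision network.

The primary objective is metabolic energy efficiency: the mean absolute (L1)
preactivation over all units, all T within-fixation steps, all fixations and
the batch,

    L = 1/(T·N) Σ_t Σ_i |preactivation_{i,t}|,

applied across all layers (the warm-up step is excluded).  Two control
objectives — multi-hot categorization through a sigmoid readout with binary
cross-entropy, and temporal InfoNCE contrastive learning on the top hidden
layer — share the identical architecture and input regime.

Gradients are derived analytically and propagated through the full recurrent
trace (backpropagation through time over the whole fixation sequence); the
optimizer is Adam with a per-matrix learning-rate rescaling by source-layer
width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import SequenceDataset
from .network import FixationTrace, NetworkConfig, NetworkWeights, init_weights, run_batch

__all__ = [
    "TrainingConfig",
    "ObjectiveSpec",
    "TrainingLog",
    "energy_loss",
    "bce_categorization_loss",
    "infonce_loss",
    "scaled_learning_rates",
    "energy_gradients",
    "train_model",
]


@dataclass(frozen=True)
class TrainingConfig:
    base_lr: float = 0.0005
    batch_size: int = 1024
    epochs: int = 50
    objective: str = "energy"  # energy | categorization | contrastive | none
    seed: int = 0
    min_epochs: int = 5
    patience: int | None = None  # early stop on held-out plateau; None = off
    val_sequences: int = 64  # held-out sequences used per-epoch for monitoring
    truncate_bptt: int | None = None  # steps; None = full-sequence gradients
    dtype: str = "float32"  # training arithmetic; weights returned as float64
    lr_schedule: str = "constant"  # constant | cosine
    warmup_epochs: int = 0  # linear warmup from base_lr/10
    final_lr_fraction: float = 0.1  # cosine floor, as a fraction of base_lr

    def __post_init__(self) -> None:
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be ≥ 1")


@dataclass(frozen=True)
class ObjectiveSpec:
    temperature: float = 0.1
    n_negatives: int = 8
    positive_lag: int = 2
    n_classes: int = 91

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.positive_lag < 1:
            raise ValueError("positive_lag must be ≥ 1")


@dataclass
class TrainingLog:
    records: list[dict] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def append(self, **kw) -> None:
        self.records.append(kw)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)


# --------------------------------------------------------------------------
# losses


def energy_loss(trace: FixationTrace) -> float:
    """Mean |preactivation| over all units, fixation steps and sequences.

    All layers enter the unit count N; the warm-up step is excluded.
    """
    if trace.n_sequences == 0:
        raise ValueError("empty batch")
    N = trace.config.n_units_total
    total = sum(np.abs(p[:, 1:, :]).sum() for p in trace.pre)
    B, S = trace.pre[0].shape[0], trace.pre[0].shape[1] - 1
    return float(total / (B * S * N))


def bce_categorization_loss(
    probabilities: np.ndarray, labels: np.ndarray, eps: float = 1e-7
) -> float:
    """Mean binary cross-entropy over classes and batch (multi-hot labels)."""
    labels = np.asarray(labels, dtype=np.float64)
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be multi-hot (entries in {0, 1})")
    p = np.clip(probabilities, eps, 1 - eps)
    return float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p)))


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm representation: cosine similarity undefined")
    return float(a @ b / (na * nb))


def infonce_loss(
    anchor: np.ndarray,
    positive: np.ndarray,
    negatives: np.ndarray,
    temperature: float = 0.1,
) -> float:
    """InfoNCE with cosine similarity for a single anchor.

    −log( e^{sim(a,p)/τ} / (e^{sim(a,p)/τ} + Σ_i e^{sim(a,n_i)/τ}) ).
    """
    negatives = np.atleast_2d(negatives)
    if negatives.shape[0] < 1:
        raise ValueError("need at least one negative sample")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    logits = np.array(
        [_cosine(anchor, positive)] + [_cosine(anchor, n) for n in negatives]
    ) / temperature
    logits -= logits.max()
    return float(-logits[0] + math.log(np.exp(logits).sum()))


# --------------------------------------------------------------------------
# learning-rate scaling


def scaled_learning_rates(
    weights: NetworkWeights, base_lr: float
) -> dict[str, float]:
    """Per-matrix learning rates rescaled by source-layer width.

    A matrix from a source layer wider than its target gets
    lr = base_lr · W_target / W_source; all other matrices keep base_lr.  At
    paper scale this yields the 0.125·base_lr factor for the first bottom-up
    matrix and an unchanged rate everywhere else.
    """
    out = {}
    for name, w in weights.named().items():
        if w.ndim < 2:  # bias vectors keep the base rate
            out[name] = base_lr
            continue
        n_target, n_source = w.shape
        factor = n_target / n_source if n_source > n_target else 1.0
        out[name] = base_lr * factor
    return out


# --------------------------------------------------------------------------
# backward pass (BPTT)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _bptt(
    trace: FixationTrace,
    weights: NetworkWeights,
    d_pre: list[np.ndarray | None],
    d_act_top: dict[int, np.ndarray] | None = None,
    truncate: int | None = None,
) -> NetworkWeights:
    """Backpropagate through the recorded trace.

    ``d_pre[l]`` is the direct loss gradient w.r.t. the preactivations of
    layer l, shape (B, S, n_l) (or None).  ``d_act_top`` maps step index →
    direct gradient w.r.t. the TOP hidden layer's activations at that step.
    Returns weight gradients in a NetworkWeights-shaped container.
    """
    config = weights.config
    L = config.n_hidden_layers
    S = trace.pre[0].shape[1]
    grads = weights.zero_like()
    acts = [_relu(p) for p in trace.pre]
    g = [np.zeros_like(p) for p in trace.pre]  # dL/dpre for every step

    def fill_step(s: int, with_backflow: bool) -> None:
        for l in range(L + 1):
            ga = None
            if with_backflow:
                nxt = s + 1
                if l == 0:
                    ga = g[1][:, nxt] @ weights.bu[0]
                else:
                    ga = g[l - 1][:, nxt] @ weights.td[l - 1]
                    ga += g[l][:, nxt] @ weights.lat[l - 1]
                    if l < L:
                        ga += g[l + 1][:, nxt] @ weights.bu[l]
            if d_act_top is not None and l == L and s in d_act_top:
                ga = d_act_top[s] if ga is None else ga + d_act_top[s]
            total = 0.0 if d_pre[l] is None else d_pre[l][:, s].copy()
            if ga is not None:
                total = total + ga * (trace.pre[l][:, s] > 0)
            g[l][:, s] = total

    horizon = S if truncate is None else min(S, truncate)
    fill_step(S - 1, with_backflow=False)
    for s in range(S - 2, max(-1, S - 1 - horizon), -1):
        fill_step(s, with_backflow=True)
    # weight gradients for every (s → s+1) transition, as single large GEMMs
    ax = ([0, 1], [0, 1])
    for i in range(L):
        grads.bu[i] += np.tensordot(g[i + 1][:, 1:], acts[i][:, :-1], axes=ax)
        grads.lat[i] += np.tensordot(g[i + 1][:, 1:], acts[i + 1][:, :-1], axes=ax)
        grads.td[i] += np.tensordot(g[i][:, 1:], acts[i + 1][:, :-1], axes=ax)
    for l in range(len(grads.bias)):  # biases act at every step
        grads.bias[l] += g[l].sum(axis=(0, 1))
    return grads


def energy_gradients(
    trace: FixationTrace, weights: NetworkWeights, truncate: int | None = None
) -> tuple[float, NetworkWeights]:
    """Energy loss and its analytic gradient w.r.t. every weight matrix."""
    B = trace.n_sequences
    S = trace.pre[0].shape[1] - 1  # fixation steps (warm-up excluded)
    N = trace.config.n_units_total
    scale = 1.0 / (B * S * N)
    d_pre = []
    for p in trace.pre:
        g = np.sign(p) * scale
        g[:, 0, :] = 0.0  # warm-up step outside the loss
        d_pre.append(g)
    loss = energy_loss(trace)
    return loss, _bptt(trace, weights, d_pre, truncate=truncate)


def _categorization_gradients(
    trace: FixationTrace,
    weights: NetworkWeights,
    labels: np.ndarray,
    spec: ObjectiveSpec,
    truncate: int | None = None,
) -> tuple[float, NetworkWeights]:
    """BCE on a sigmoid readout of the top layer at the final step."""
    w_out = weights.extra["readout"]
    S = trace.pre[0].shape[1]
    a_top = _relu(trace.pre[-1][:, S - 1])
    z = a_top @ w_out.T
    labels = np.asarray(labels, dtype=np.float64)
    # BCE computed from logits (softplus form): stable, exact gradient
    loss = float(np.mean(np.logaddexp(0.0, z) - labels * z))
    B, K = z.shape
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    dz = (p - labels) / (B * K)
    grads = _bptt(
        trace,
        weights,
        d_pre=[None] * (weights.config.n_hidden_layers + 1),
        d_act_top={S - 1: dz @ w_out},
        truncate=truncate,
    )
    grads.extra["readout"] = dz.T @ a_top
    return loss, grads


def _contrastive_gradients(
    trace: FixationTrace,
    weights: NetworkWeights,
    spec: ObjectiveSpec,
    rng: np.random.Generator,
    truncate: int | None = None,
) -> tuple[float, NetworkWeights]:
    """Temporal InfoNCE on top-layer activations.

    Anchor = representation at step t, positive = step t − lag of the same
    sequence (across fixation boundaries), negatives = the same step t of
    ``n_negatives`` other sequences in the batch (different scenes).  Zero
    norms are clamped for training robustness.
    """
    R = _relu(trace.pre[-1])  # (B, S, H)
    B, S, H = R.shape
    lag, tau = spec.positive_lag, spec.temperature
    n_neg = min(spec.n_negatives, B - 1)
    if n_neg < 1:
        raise ValueError("contrastive training needs a batch of at least 2 sequences")
    dR = np.zeros_like(R)
    total, count = 0.0, 0
    eps = 1e-12
    anchor_steps = range(1 + lag, S)
    for s in anchor_steps:
        A, P = R[:, s], R[:, s - lag]
        # negatives: n_neg distinct other sequences per anchor
        neg_idx = np.empty((B, n_neg), dtype=np.intp)
        for b in range(B):
            choices = rng.choice(B - 1, size=n_neg, replace=False)
            neg_idx[b] = choices + (choices >= b)
        Nmat = R[neg_idx, s]  # (B, n_neg, H)
        na = np.maximum(np.linalg.norm(A, axis=1), eps)
        npos = np.maximum(np.linalg.norm(P, axis=1), eps)
        nneg = np.maximum(np.linalg.norm(Nmat, axis=2), eps)
        Ahat = A / na[:, None]
        Phat = P / npos[:, None]
        Nhat = Nmat / nneg[:, :, None]
        sim = np.concatenate(
            [(Ahat * Phat).sum(1)[:, None], (Nhat * Ahat[:, None, :]).sum(2)], axis=1
        )  # (B, 1 + n_neg)
        logits = sim / tau
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        soft = e / e.sum(axis=1, keepdims=True)
        total += float(-np.log(soft[:, 0] + eps).sum())
        count += B
        dsim = soft.copy()
        dsim[:, 0] -= 1.0
        dsim /= tau
        # chain through cosine similarity
        dA = (
            dsim[:, 0:1] * (Phat - sim[:, 0:1] * Ahat) / na[:, None]
            + ((dsim[:, 1:, None] * (Nhat - sim[:, 1:, None] * Ahat[:, None, :])).sum(1))
            / na[:, None]
        )
        dP = dsim[:, 0:1] * (Ahat - sim[:, 0:1] * Phat) / npos[:, None]
        dN = dsim[:, 1:, None] * (Ahat[:, None, :] - sim[:, 1:, None] * Nhat) / nneg[:, :, None]
        dR[:, s] += dA
        dR[:, s - lag] += dP
        np.add.at(dR[:, s], neg_idx.ravel(), dN.reshape(-1, H))
    n_anchor_steps = max(1, len(list(anchor_steps)))
    dR /= count
    loss = total / count if count else 0.0
    d_act_top = {s: dR[:, s] for s in range(S) if np.any(dR[:, s])}
    grads = _bptt(
        trace,
        weights,
        d_pre=[None] * (weights.config.n_hidden_layers + 1),
        d_act_top=d_act_top,
        truncate=truncate,
    )
    return loss, grads


# --------------------------------------------------------------------------
# optimizer


class _Adam:
    def __init__(self, weights: NetworkWeights, lrs: dict[str, float],
                 betas=(0.9, 0.999), eps=1e-8):
        self.lrs = lrs
        self.scale = 1.0  # schedule multiplier, set per epoch
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(w) for k, w in weights.named().items()}
        self.v = {k: np.zeros_like(w) for k, w in weights.named().items()}

    def step(self, weights: NetworkWeights, grads: NetworkWeights) -> None:
        self.t += 1
        named_w = weights.named()
        named_g = grads.named()
        for k, w in named_w.items():
            g = named_g[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            w -= self.scale * self.lrs[k] * mhat / (np.sqrt(vhat) + self.eps)


def _lr_factor(epoch: int, config: TrainingConfig) -> float:
    """Schedule multiplier on the base learning rate for one epoch."""
    if epoch < config.warmup_epochs:
        return 0.1 + 0.9 * (epoch + 1) / config.warmup_epochs
    if config.lr_schedule == "constant":
        return 1.0
    if config.lr_schedule == "cosine":
        span = max(1, config.epochs - config.warmup_epochs)
        progress = min(1.0, (epoch - config.warmup_epochs) / span)
        lo = config.final_lr_fraction
        return lo + (1 - lo) * 0.5 * (1 + math.cos(math.pi * progress))
    if config.lr_schedule == "late-cosine":
        # constant for the first 60% of epochs, cosine decay over the rest;
        # the L1 objective needs the low-noise tail to settle (see methods)
        start = int(0.6 * config.epochs)
        if epoch < start:
            return 1.0
        span = max(1, config.epochs - start)
        progress = min(1.0, (epoch - start) / span)
        lo = config.final_lr_fraction
        return lo + (1 - lo) * 0.5 * (1 + math.cos(math.pi * progress))
    raise ValueError(f"unknown lr schedule {config.lr_schedule!r}")


# --------------------------------------------------------------------------
# training loop


def _scene_sequence_index(dataset: SequenceDataset) -> dict[str, list[int]]:
    by_scene: dict[str, list[int]] = {}
    for i, seq in enumerate(dataset.sequences):
        by_scene.setdefault(seq.scene_id, []).append(i)
    return by_scene


def train_model(
    train_dataset: SequenceDataset,
    net_config: NetworkConfig,
    train_config: TrainingConfig,
    objective_spec: ObjectiveSpec | None = None,
    val_dataset: SequenceDataset | None = None,
    verbose: bool = False,
) -> tuple[NetworkWeights, TrainingLog]:
    """Train the network; per epoch one scanpath per scene is drawn at random.

    Gradients flow through the entire recorded sequence (full BPTT) unless
    truncation is configured.  The 'none' objective returns the initialized
    weights untouched (the untrained baseline).  Held-out energy loss is
    monitored every epoch; with ``patience`` set, training stops once it has
    not improved for that many epochs (after ``min_epochs``).
    """
    spec = objective_spec or ObjectiveSpec()
    ss = np.random.SeedSequence(train_config.seed)
    init_seed, loop_seed = (int(x) for x in ss.generate_state(2, dtype=np.uint32))
    weights = init_weights(net_config, init_seed)
    if train_config.objective == "categorization":
        rng_out = np.random.default_rng(init_seed + 1)
        bound = math.sqrt(6.0 / net_config.hidden_size)
        weights.extra["readout"] = rng_out.uniform(
            -bound, bound, size=(spec.n_classes, net_config.hidden_size)
        )
    log = TrainingLog(manifest={
        "objective": train_config.objective,
        "seed": train_config.seed,
        "net_config": net_config.__dict__,
    })
    if train_config.objective == "none":
        return weights, log
    dtype = np.dtype(train_config.dtype)
    if dtype != np.float64:
        weights = _cast_weights(weights, dtype)

    rng = np.random.default_rng(loop_seed)
    lrs = scaled_learning_rates(weights, train_config.base_lr)
    adam = _Adam(weights, lrs)
    by_scene = _scene_sequence_index(train_dataset)
    scene_ids = sorted(by_scene)
    val_idx = None
    val_ds = val_dataset
    if val_ds is not None:
        v_by_scene = _scene_sequence_index(val_ds)
        val_idx = [v_by_scene[s][0] for s in sorted(v_by_scene)][: train_config.val_sequences]
        val_arrays = val_ds.batch_arrays(val_idx)

    def held_out_loss() -> float:
        if val_idx is None:
            return float("nan")
        trace = run_batch(val_arrays[0], val_arrays[1], weights)
        return energy_loss(trace)

    best_val, since_best = np.inf, 0
    for epoch in range(train_config.epochs):
        adam.scale = _lr_factor(epoch, train_config)
        chosen = np.array(
            [by_scene[s][rng.integers(len(by_scene[s]))] for s in scene_ids]
        )
        rng.shuffle(chosen)
        epoch_losses = []
        for start in range(0, len(chosen), train_config.batch_size):
            idx = chosen[start : start + train_config.batch_size]
            crops, effs, _ = train_dataset.batch_arrays(idx)
            trace = run_batch(crops, effs, weights)
            if train_config.objective == "energy":
                loss, grads = energy_gradients(trace, weights, train_config.truncate_bptt)
            elif train_config.objective == "categorization":
                labels = np.stack(
                    [train_dataset.labels_for(train_dataset.sequences[i]) for i in idx]
                )
                loss, grads = _categorization_gradients(
                    trace, weights, labels, spec, train_config.truncate_bptt
                )
            elif train_config.objective == "contrastive":
                loss, grads = _contrastive_gradients(
                    trace, weights, spec, rng, train_config.truncate_bptt
                )
            else:
                raise ValueError(f"unknown objective {train_config.objective!r}")
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss = {loss}"
                )
            adam.step(weights, grads)
            epoch_losses.append(loss)
        val = held_out_loss()
        log.append(epoch=epoch, train_loss=float(np.mean(epoch_losses)), val_energy=val)
        if verbose:
            print(f"epoch {epoch:3d}  train {np.mean(epoch_losses):.5f}  val-energy {val:.5f}")
        if train_config.patience is not None and np.isfinite(val):
            if val < best_val - 1e-6:
                best_val, since_best = val, 0
            else:
                since_best += 1
                if epoch + 1 >= train_config.min_epochs and since_best >= train_config.patience:
                    break
    if dtype != np.float64:
        weights = _cast_weights(weights, np.float64)
    return weights, log


def _cast_weights(weights: NetworkWeights, dtype) -> NetworkWeights:
    return NetworkWeights(
        bu=[w.astype(dtype) for w in weights.bu],
        lat=[w.astype(dtype) for w in weights.lat],
        td=[w.astype(dtype) for w in weights.td],
        config=weights.config,
        bias=[w.astype(dtype) for w in weights.bias],
        extra={k: w.astype(dtype) for k, w in weights.extra.items()},
    )
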