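"""Recurrent network of active vision with a fixed excitatory input drive.

Layer 1 receives the input drive (flattened crop plus, when enabled, the two
efference-copy slots) with no learnable input weights; it additionally
receives top-down feedback from the first hidden layer.  Hidden layers carry
bottom-up, lateral and top-down connections.  All connections read the
PREVIOUS step's rectified activations (fully synchronous one-step-delay
update), there are no bias terms, and the preactivation of every unit is the
quantity the energy objective penalizes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkConfig",
    "NetworkWeights",
    "NetworkState",
    "FixationTrace",
    "init_weights",
    "assemble_input",
    "network_step",
    "run_sequence",
    "run_batch",
    "extract_feedback_image",
]


@dataclass(frozen=True)
class NetworkConfig:
    crop_side: int = 128
    n_hidden_layers: int = 2
    hidden_size: int = 2048
    steps_per_fixation: int = 6
    efference_onset_fraction: float = 0.5
    use_efference: bool = True
    use_bias: bool = True  # per-layer bias on the preactivation
    scale_efference: bool = False  # divide Δp by scene side (off: raw pixels)
    scene_side: int = 256

    def __post_init__(self) -> None:
        if self.steps_per_fixation < 2:
            raise ValueError("steps_per_fixation must be ≥ 2")
        if not (0.0 < self.efference_onset_fraction < 1.0):
            raise ValueError("efference_onset_fraction must lie in (0, 1)")

    @property
    def n_image_units(self) -> int:
        return self.crop_side**2

    @property
    def input_dim(self) -> int:
        return self.n_image_units + (2 if self.use_efference else 0)

    @property
    def efference_onset(self) -> int:
        """First within-fixation step index at which Δp is visible."""
        return math.ceil(self.efference_onset_fraction * self.steps_per_fixation)

    @property
    def layer_sizes(self) -> list[int]:
        return [self.input_dim] + [self.hidden_size] * self.n_hidden_layers

    @property
    def n_units_total(self) -> int:
        return sum(self.layer_sizes)

    @property
    def n_hidden_total(self) -> int:
        return self.n_hidden_layers * self.hidden_size


@dataclass
class NetworkWeights:
    """Connection matrices, indexed by target layer.

    ``bu[l]`` maps layer l-1 → layer l (l = 1..L), ``lat[l-1]`` is the lateral
    matrix of hidden layer l, and ``td[l]`` maps layer l+1 → layer l
    (l = 0..L-1).  Matrices are stored (n_target, n_source).  ``bias[l]`` is
    the per-layer preactivation offset (layer 0 = the input layer); the list
    is empty when the configuration disables biases.
    """

    bu: list[np.ndarray]
    lat: list[np.ndarray]
    td: list[np.ndarray]
    config: NetworkConfig
    bias: list[np.ndarray] = field(default_factory=list)
    extra: dict = field(default_factory=dict)  # e.g. categorization readout

    def named(self) -> dict[str, np.ndarray]:
        out = {}
        for i, w in enumerate(self.bu):
            out[f"bu{i + 1}"] = w
        for i, w in enumerate(self.lat):
            out[f"lat{i + 1}"] = w
        for i, w in enumerate(self.td):
            out[f"td{i}"] = w
        for i, w in enumerate(self.bias):
            out[f"bias{i}"] = w
        for k, w in self.extra.items():
            out[f"extra_{k}"] = w
        return out

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            bu=[w.copy() for w in self.bu],
            lat=[w.copy() for w in self.lat],
            td=[w.copy() for w in self.td],
            config=self.config,
            bias=[w.copy() for w in self.bias],
            extra={k: w.copy() for k, w in self.extra.items()},
        )

    def zero_like(self) -> "NetworkWeights":
        return NetworkWeights(
            bu=[np.zeros_like(w) for w in self.bu],
            lat=[np.zeros_like(w) for w in self.lat],
            td=[np.zeros_like(w) for w in self.td],
            config=self.config,
            bias=[np.zeros_like(w) for w in self.bias],
            extra={k: np.zeros_like(w) for k, w in self.extra.items()},
        )

    def save(self, path: str | Path, meta: dict | None = None) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, **self.named())
        sidecar = {"config": self.config.__dict__, "meta": meta or {}}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkWeights":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        config = NetworkConfig(**sidecar["config"])
        data = np.load(path)
        L = config.n_hidden_layers
        return cls(
            bu=[data[f"bu{i + 1}"] for i in range(L)],
            lat=[data[f"lat{i + 1}"] for i in range(L)],
            td=[data[f"td{i}"] for i in range(L)],
            config=config,
            bias=[data[f"bias{i}"] for i in range(L + 1) if f"bias{i}" in data],
            extra={
                k[len("extra_") :]: data[k] for k in data.files if k.startswith("extra_")
            },
        )


def init_weights(config: NetworkConfig, seed: int) -> NetworkWeights:
    """He-style uniform initialization, U(−√(6/N_in), +√(6/N_in)).

    N_in is the width of each matrix's source layer; the gain 2 in
    2·3/N_in suits the rectified-linear units.  Biases (when enabled) start
    at U(−1/√N_in, +1/√N_in) with N_in the width of the layer's main source,
    the standard linear-layer convention.
    """
    rng = np.random.default_rng(seed)
    sizes = config.layer_sizes
    L = config.n_hidden_layers

    def uniform(n_target: int, n_source: int) -> np.ndarray:
        bound = math.sqrt(6.0 / n_source)
        return rng.uniform(-bound, bound, size=(n_target, n_source))

    bu = [uniform(sizes[l + 1], sizes[l]) for l in range(L)]
    lat = [uniform(sizes[l + 1], sizes[l + 1]) for l in range(L)]
    td = [uniform(sizes[l], sizes[l + 1]) for l in range(L)]
    bias = []
    if config.use_bias:
        # layer 0's feedback source is hidden 1; hidden l's source is layer l-1
        src = [sizes[1]] + [sizes[l] for l in range(L)]
        bias = [
            rng.uniform(-1 / math.sqrt(s), 1 / math.sqrt(s), size=sizes[l])
            for l, s in enumerate(src)
        ]
    return NetworkWeights(bu=bu, lat=lat, td=td, config=config, bias=bias)


def assemble_input(
    crop: np.ndarray,
    efference: np.ndarray,
    step_index: int,
    config: NetworkConfig,
) -> np.ndarray:
    """Input vector x_t = [v_t, Δp_t] for one within-fixation step.

    The efference slots hold Δp only from ``config.efference_onset`` onward
    (with the default 6 steps and onset fraction 0.5, the last three steps);
    earlier steps carry zeros.  Without efference the vector is the crop
    alone.
    """
    if not 0 <= step_index < config.steps_per_fixation:
        raise ValueError(f"step_index {step_index} outside [0, {config.steps_per_fixation})")
    crop = np.asarray(crop, dtype=np.float64).ravel()
    if crop.size != config.n_image_units:
        raise ValueError(f"crop has {crop.size} values, expected {config.n_image_units}")
    if np.any(crop < 0):
        raise ValueError("crop values must be non-negative")
    if not config.use_efference:
        return crop.copy()
    x = np.zeros(config.input_dim)
    x[: config.n_image_units] = crop
    if step_index >= config.efference_onset:
        eff = np.asarray(efference, dtype=np.float64)
        if config.scale_efference:
            eff = eff / config.scene_side
        x[config.n_image_units :] = eff
    return x


@dataclass
class NetworkState:
    """Per-layer preactivations and rectified activations at one step."""

    pre: list[np.ndarray]  # [layer1, hidden1, ..., hiddenL]
    act: list[np.ndarray]
    step_index: int = 0
    fixation_index: int = -1

    @classmethod
    def zeros(
        cls, config: NetworkConfig, batch: int | None = None, dtype=np.float64
    ) -> "NetworkState":
        shape = (lambda n: (batch, n) if batch is not None else (n,))
        return cls(
            pre=[np.zeros(shape(n), dtype=dtype) for n in config.layer_sizes],
            act=[np.zeros(shape(n), dtype=dtype) for n in config.layer_sizes],
        )


def network_step(
    state: NetworkState,
    input_drive: np.ndarray,
    weights: NetworkWeights,
    lesion_mask: np.ndarray | None = None,
) -> NetworkState:
    """One synchronous update; all pathways read the previous step's ReLU.

    Layer-1 preactivation = input drive + top-down feedback from hidden 1.
    Hidden-layer preactivation = bottom-up + lateral + top-down (where a layer
    above exists).  Units flagged by ``lesion_mask`` (over the concatenated
    hidden population) have their activation forced to zero after the update.
    """
    config = weights.config
    L = config.n_hidden_layers
    a = state.act
    pre = [np.asarray(input_drive) + a[1] @ weights.td[0].T]
    for l in range(1, L + 1):
        p = a[l - 1] @ weights.bu[l - 1].T + a[l] @ weights.lat[l - 1].T
        if l < L:
            p = p + a[l + 1] @ weights.td[l].T
        pre.append(p)
    if weights.bias:
        pre = [p + b for p, b in zip(pre, weights.bias)]
    act = [np.maximum(p, 0.0) for p in pre]
    if lesion_mask is not None:
        mask = np.asarray(lesion_mask, dtype=bool)
        if mask.size != config.n_hidden_total:
            raise ValueError(
                f"lesion mask has {mask.size} entries, expected {config.n_hidden_total}"
            )
        H = config.hidden_size
        for l in range(1, L + 1):
            act[l] = act[l] * ~mask[(l - 1) * H : l * H]
    return NetworkState(
        pre=pre, act=act, step_index=state.step_index + 1, fixation_index=state.fixation_index
    )


@dataclass
class FixationTrace:
    """Recorded preactivations for a batch of sequences.

    ``pre[l]`` has shape (B, 1 + F·T, n_l): one warm-up step (all-zero input
    vector from a zero state) followed by T steps per fixation.  Crops and
    efferences are kept so feedback images (top-down drive to the layer-1
    image units = layer-1 preactivation minus the input drive) can be
    reconstructed for any step.
    """

    pre: list[np.ndarray]
    crops: np.ndarray  # (B, F, C²)
    efferences: np.ndarray  # (B, F, 2)
    config: NetworkConfig
    lesion_mask: np.ndarray | None = None

    @property
    def n_sequences(self) -> int:
        return self.pre[0].shape[0]

    @property
    def n_fixations(self) -> int:
        return self.crops.shape[1]

    def step_of(self, fixation_index: int, step_index: int) -> int:
        return 1 + fixation_index * self.config.steps_per_fixation + step_index

    def activations(self, layer: int) -> np.ndarray:
        act = np.maximum(self.pre[layer], 0.0)
        if self.lesion_mask is not None and layer >= 1:
            H = self.config.hidden_size
            m = self.lesion_mask[(layer - 1) * H : layer * H]
            act = act * ~m
        return act

    def feedback_to_layer1(self) -> np.ndarray:
        """Top-down drive to the layer-1 image units, (B, 1 + F·T, C²).

        Layer-1 preactivation minus the input drive; the efference slots are
        excluded.  At the warm-up step the drive is zero, so the feedback is
        the preactivation itself.
        """
        T = self.config.steps_per_fixation
        C2 = self.config.n_image_units
        fb = self.pre[0][:, :, :C2].copy()
        for f in range(self.n_fixations):
            s0 = self.step_of(f, 0)
            fb[:, s0 : s0 + T, :] -= self.crops[:, f][:, None, :]
        return fb


def run_batch(
    crops: np.ndarray,
    efferences: np.ndarray,
    weights: NetworkWeights,
    lesion_mask: np.ndarray | None = None,
) -> FixationTrace:
    """Run a batch of sequences; state starts at zeros (fresh per batch).

    A warm-up step with an all-zero input vector precedes the first fixation;
    then each fixation is processed for T steps with the efference copy
    entering at the configured onset step.
    """
    config = weights.config
    B, F, _ = crops.shape
    if F < 1:
        raise ValueError("empty sequence batch")
    if np.any(crops < 0):
        raise ValueError("crop values must be non-negative")
    dtype = weights.bu[0].dtype
    crops = crops.astype(dtype, copy=False)
    efferences = efferences.astype(dtype, copy=False)
    T = config.steps_per_fixation
    S = 1 + F * T
    pre = [np.empty((B, S, n), dtype=dtype) for n in config.layer_sizes]
    L = config.n_hidden_layers
    if lesion_mask is not None:
        lesion_mask = np.asarray(lesion_mask, dtype=bool)
        if lesion_mask.size != config.n_hidden_total:
            raise ValueError(
                f"lesion mask has {lesion_mask.size} entries, "
                f"expected {config.n_hidden_total}"
            )
        keep = ~lesion_mask
        keeps = [keep[l * config.hidden_size : (l + 1) * config.hidden_size]
                 for l in range(L)]
    drive = np.zeros((B, config.input_dim), dtype=dtype)
    eff_scale = 1.0 / config.scene_side if config.scale_efference else 1.0
    act = [np.zeros((B, n), dtype=dtype) for n in config.layer_sizes]
    C2 = config.n_image_units

    def step_into(s: int) -> None:
        pre[0][:, s] = drive
        pre[0][:, s] += act[1] @ weights.td[0].T
        for l in range(1, L + 1):
            p = act[l - 1] @ weights.bu[l - 1].T
            p += act[l] @ weights.lat[l - 1].T
            if l < L:
                p += act[l + 1] @ weights.td[l].T
            pre[l][:, s] = p
        if weights.bias:
            for l in range(L + 1):
                pre[l][:, s] += weights.bias[l]
        for l in range(L + 1):
            np.maximum(pre[l][:, s], 0.0, out=act[l])
            if lesion_mask is not None and l >= 1:
                act[l] *= keeps[l - 1]

    step_into(0)  # warm-up: all-zero input vector
    s = 1
    for f in range(F):
        for t in range(T):
            drive[:, :C2] = crops[:, f]
            if config.use_efference:
                if t >= config.efference_onset:
                    drive[:, C2:] = efferences[:, f] * eff_scale
                else:
                    drive[:, C2:] = 0.0
            step_into(s)
            s += 1
    return FixationTrace(
        pre=pre, crops=crops, efferences=efferences, config=config, lesion_mask=lesion_mask
    )


def run_sequence(
    samples,
    weights: NetworkWeights,
    lesion_mask: np.ndarray | None = None,
) -> FixationTrace:
    """Run one sequence of FixationSamples (thin wrapper over ``run_batch``)."""
    if len(samples) == 0:
        raise ValueError("empty sample list")
    crops = np.stack([s.crop for s in samples])[None, :, :]
    effs = np.stack([s.efference for s in samples])[None, :, :]
    return run_batch(crops, effs, weights, lesion_mask)


def extract_feedback_image(
    trace: FixationTrace, fixation_index: int, step_index: int, sequence: int = 0
) -> tuple[np.ndarray, float]:
    """Feedback image (crop_side × crop_side) and its spatial mean at one step.

    Efference-slot feedback is excluded from both the image and the mean.
    """
    C = trace.config.crop_side
    s = trace.step_of(fixation_index, step_index)
    fb = trace.pre[0][sequence, s, : C * C] .copy()
    fb -= trace.crops[sequence, fixation_index]
    img = fb.reshape(C, C)
    return img, float(img.mean())
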