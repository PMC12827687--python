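"""Control predictors and per-fixation energy comparison.

All conditions — networks and static templates — are compared on one common
metric: the mean absolute layer-1 preactivation over the image units at each
fixation's FIRST model step (the transition moment across the saccade).  For
a template, the implied preactivation is crop − prediction, i.e. the loss the
network would incur if its feedback exactly equaled the negative prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import FixationSample, SequenceDataset, extract_crop
from .network import FixationTrace, NetworkWeights, run_batch

__all__ = [
    "ControlTemplate",
    "ComparisonResult",
    "build_static_templates",
    "control_fixation_loss",
    "model_fixation_loss",
    "template_loss_vector",
    "evaluate_all_conditions",
    "compare_conditions",
    "default_eval_indices",
]

STATIC_TEMPLATE_KINDS = ("avg_luminance", "avg_crop", "location_specific")
ALL_CONDITIONS = (
    "model",
    "small_crop",
    "no_efference",
    "shuffled",
    "location_specific",
    "avg_crop",
    "avg_luminance",
    "previous_crop",
)


@dataclass
class ControlTemplate:
    kind: str
    payload: np.ndarray | float

    def __post_init__(self) -> None:
        arr = np.asarray(self.payload)
        if arr.min() < 0 or arr.max() > 1:
            raise ValueError("template values must lie in [0, 1]")


@dataclass
class ComparisonResult:
    condition_a: str
    condition_b: str
    t_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    n: int


def build_static_templates(train_dataset: SequenceDataset) -> dict[str, ControlTemplate]:
    """Static predictors derived from the TRAINING split only.

    avg_luminance — scalar mean over all training-scene pixels;
    avg_crop — element-wise mean over all training fixation crops;
    location_specific — pixel-wise mean image over training scenes, cropped at
    the current fixation at evaluation time.
    """
    if any(s.split == "test" for s in train_dataset.scenes.values()):
        raise ValueError("static templates must be built from the training split only")
    scenes = np.stack([s.pixels for s in train_dataset.scenes.values()])
    crop_sum = None
    n_crops = 0
    for seq in train_dataset.sequences:
        crops = train_dataset.crops(seq)
        crop_sum = crops.sum(axis=0) if crop_sum is None else crop_sum + crops.sum(axis=0)
        n_crops += crops.shape[0]
    return {
        "avg_luminance": ControlTemplate("avg_luminance", float(scenes.mean())),
        "avg_crop": ControlTemplate("avg_crop", crop_sum / n_crops),
        "location_specific": ControlTemplate("location_specific", scenes.mean(axis=0)),
    }


def control_fixation_loss(sample: FixationSample, prediction: np.ndarray | float) -> float:
    """Mean |crop − prediction| over the image units.

    The layer-1 preactivation that would result if the network's feedback
    exactly equaled the negative prediction.
    """
    return float(np.abs(sample.crop - np.asarray(prediction).ravel()).mean())


def model_fixation_loss(trace: FixationTrace) -> np.ndarray:
    """Per-fixation onset loss, (B, F): mean |layer-1 image-unit preactivation|
    at each fixation's first step."""
    T = trace.config.steps_per_fixation
    C2 = trace.config.n_image_units
    onset_steps = 1 + np.arange(trace.n_fixations) * T
    return np.abs(trace.pre[0][:, onset_steps, :C2]).mean(axis=2)


def template_loss_vector(
    dataset: SequenceDataset,
    kind: str,
    template: ControlTemplate | None = None,
    indices=None,
    include_first_fixation: bool = True,
) -> np.ndarray:
    """Loss per (sequence, fixation) for one template condition, shape (B, F).

    ``previous_crop`` uses the prior fixation's crop as the prediction; the
    first fixation is compared against a zero prediction (or NaN-masked when
    ``include_first_fixation`` is false).
    """
    if indices is None:
        indices = range(len(dataset.sequences))
    crop_side = dataset.config.crop_side
    rows = []
    for i in indices:
        seq = dataset.sequences[i]
        crops = dataset.crops(seq)
        losses = np.empty(seq.n_fixations)
        for f in range(seq.n_fixations):
            if kind == "avg_luminance":
                pred = np.full(crops.shape[1], template.payload)
            elif kind == "avg_crop":
                pred = template.payload
            elif kind == "location_specific":
                pred = extract_crop(template.payload, tuple(seq.crop_centers[f]), crop_side)
            elif kind == "previous_crop":
                if f == 0:
                    if not include_first_fixation:
                        losses[f] = np.nan
                        continue
                    pred = np.zeros(crops.shape[1])
                else:
                    pred = crops[f - 1]
            else:
                raise ValueError(f"unknown template kind {kind!r}")
            losses[f] = np.abs(crops[f] - pred).mean()
        rows.append(losses)
    return np.stack(rows)


def default_eval_indices(dataset: SequenceDataset) -> list[int]:
    """First sequence of each scene: one scanpath per test scene."""
    seen: dict[str, int] = {}
    for i, seq in enumerate(dataset.sequences):
        seen.setdefault(seq.scene_id, i)
    return sorted(seen.values())


def _loss_frame(dataset, indices, losses: np.ndarray, condition: str) -> pd.DataFrame:
    recs = []
    for row, i in enumerate(indices):
        seq = dataset.sequences[i]
        for f in range(losses.shape[1]):
            recs.append(
                dict(
                    condition=condition,
                    scene_id=seq.scene_id,
                    sequence=i,
                    fixation=f,
                    loss=losses[row, f],
                )
            )
    return pd.DataFrame(recs)


def evaluate_all_conditions(
    models: dict[str, NetworkWeights],
    test_dataset: SequenceDataset,
    shuffled_dataset: SequenceDataset,
    templates: dict[str, ControlTemplate],
    indices=None,
) -> pd.DataFrame:
    """Per-fixation onset losses for the model and all seven controls.

    ``models`` must hold 'model' (the efference-trained energy network) and
    may hold 'no_efference' and 'small_crop'.  The shuffled condition runs the
    SAME energy model on the shuffled-efference dataset; the small-crop model
    is evaluated over its own (smaller) image units.
    """
    if indices is None:
        indices = default_eval_indices(test_dataset)
    frames = []

    def run_model(weights: NetworkWeights, ds: SequenceDataset) -> np.ndarray:
        crops, effs, _ = ds.batch_arrays(indices)
        return model_fixation_loss(run_batch(crops, effs, weights))

    frames.append(_loss_frame(test_dataset, indices, run_model(models["model"], test_dataset), "model"))
    frames.append(
        _loss_frame(
            shuffled_dataset, indices, run_model(models["model"], shuffled_dataset), "shuffled"
        )
    )
    if "no_efference" in models:
        frames.append(
            _loss_frame(
                test_dataset, indices, run_model(models["no_efference"], test_dataset), "no_efference"
            )
        )
    if "small_crop" in models:
        small_side = models["small_crop"].config.crop_side
        small_ds = replace(
            test_dataset, config=replace(test_dataset.config, crop_side=small_side)
        )
        frames.append(
            _loss_frame(small_ds, indices, run_model(models["small_crop"], small_ds), "small_crop")
        )
    for kind in STATIC_TEMPLATE_KINDS:
        frames.append(
            _loss_frame(
                test_dataset,
                indices,
                template_loss_vector(test_dataset, kind, templates[kind], indices),
                kind,
            )
        )
    frames.append(
        _loss_frame(
            test_dataset,
            indices,
            template_loss_vector(test_dataset, "previous_crop", None, indices),
            "previous_crop",
        )
    )
    table = pd.concat(frames, ignore_index=True)
    counts = table.groupby("condition")["fixation"].count()
    if counts.nunique() != 1:
        raise ValueError(f"misaligned fixation counts across conditions: {dict(counts)}")
    return table


def _mean_ci(x: np.ndarray, level: float = 0.99) -> tuple[float, float]:
    x = np.asarray(x, dtype=np.float64)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0
    if len(x) > 1 and x.std(ddof=1) == 0:
        half = 0.0
    return float(x.mean() - half), float(x.mean() + half)


def compare_conditions(
    loss_a: np.ndarray,
    loss_b: np.ndarray,
    name_a: str = "a",
    name_b: str = "b",
) -> ComparisonResult:
    """Welch two-sample t test plus 99% normal CIs of each condition's mean."""
    loss_a, loss_b = np.ravel(loss_a), np.ravel(loss_b)
    if len(loss_a) != len(loss_b):
        raise ValueError("condition loss vectors must have equal length")
    if len(loss_a) < 2:
        raise ValueError("need at least 2 fixations for a t test")
    if np.allclose(loss_a, loss_b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(loss_a, loss_b, equal_var=False)
    return ComparisonResult(
        condition_a=name_a,
        condition_b=name_b,
        t_statistic=float(t),
        p_value=float(p),
        mean_a=float(loss_a.mean()),
        mean_b=float(loss_b.mean()),
        ci_a=_mean_ci(loss_a),
        ci_b=_mean_ci(loss_b),
        n=len(loss_a),
    )
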