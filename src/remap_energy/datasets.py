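"""Synthetic scenes, scanpaths and fixation-crop sequences.

The training stimuli are gray-scale scenes with naturalistic (1/f) spatial
statistics, sampled by scanpaths of fixations.  Each fixation contributes a
square crop (the visual input), the relative saccade vector toward the next
fixation (the efference copy), and the allocentric coordinates of the current
fixation center.  A shuffled-efference control decouples the efference copies
from the visual input while keeping the crop sequence intact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "WorldConfig",
    "Scene",
    "Scanpath",
    "FixationSample",
    "Sequence",
    "SequenceDataset",
    "generate_scene",
    "generate_scanpath",
    "extract_crop",
    "build_sequence_dataset",
    "shuffle_efference",
    "make_scene_sets",
    "make_datasets",
    "reduced_crop_side",
    "load_image_directory",
]


@dataclass(frozen=True)
class WorldConfig:
    """Geometry and statistics of the synthetic visual world.

    Parameters
    ----------
    side : int
        Scene side length in pixels.
    crop_side : int
        Side length of the square fixation crop, in pixels.
    n_fixations : int
        Number of fixations per scanpath.
    sequences_per_scene : int
        Independent scanpaths generated per scene.
    saccade_sigma : float or None
        Standard deviation (pixels) of the isotropic Gaussian saccade-step
        distribution.  ``None`` means ``side / 4``, which mixes short
        refixation-range steps with saccades spanning most of the valid
        region.
    spectrum_exponent : float
        Amplitude-spectrum decay exponent; 1.0 gives 1/f (pink) scenes whose
        power spectrum falls as f^-2, matching natural-image statistics.
    n_texture_classes : int
        If > 0, scenes additionally contain a random subset of this many
        global texture components (oriented gratings); the subset is recorded
        as a multi-hot label used by the supervised-categorization objective.
    texture_prob : float
        Per-class inclusion probability for texture components.
    """

    side: int = 256
    crop_side: int = 128
    n_fixations: int = 7
    sequences_per_scene: int = 10
    saccade_sigma: float | None = None
    spectrum_exponent: float = 1.0
    n_texture_classes: int = 0
    texture_prob: float = 0.25

    @property
    def sigma(self) -> float:
        return self.side / 4 if self.saccade_sigma is None else self.saccade_sigma

    @property
    def valid_lo(self) -> int:
        return self.crop_side // 2

    @property
    def valid_hi(self) -> int:
        return self.side - self.crop_side // 2

    def validate(self) -> None:
        if self.side < 2 * self.crop_side:
            raise ValueError(
                f"scene side {self.side} must be at least twice the crop side "
                f"{self.crop_side}"
            )
        if self.n_fixations < 2:
            raise ValueError("need at least 2 fixations per scanpath")


@dataclass
class Scene:
    pixels: np.ndarray  # (S, S) float64 in [0, 1]
    scene_id: str
    split: str = "train"
    labels: np.ndarray | None = None  # multi-hot texture labels, optional

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("scene must be a square 2-D array")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("scene pixel values must lie in [0, 1]")


@dataclass
class Scanpath:
    coords: np.ndarray  # (F, 2) int, (x, y) pixel centers
    scene_id: str


@dataclass
class FixationSample:
    """One fixation: crop (v_t), efference copy (Δp_t) and allocentric center."""

    crop: np.ndarray  # (C²,) flattened, row-major
    efference: np.ndarray  # (2,) Δp toward the NEXT fixation; zeros at the end
    alloc_xy: np.ndarray  # (2,) allocentric center of the current fixation


@dataclass
class Sequence:
    """A scanpath bound to a scene, with precomputed efference copies.

    ``coords`` are the coordinates the efference copies are derived from;
    ``crop_centers`` are where the crops are actually taken.  The two are
    identical except in the shuffled-efference control, where the coordinate
    order is permuted while the crop order is preserved.
    """

    scene_id: str
    coords: np.ndarray  # (F, 2)
    crop_centers: np.ndarray  # (F, 2)
    efferences: np.ndarray  # (F, 2); last row is (0, 0)

    @property
    def n_fixations(self) -> int:
        return len(self.coords)


def _efferences_from_coords(coords: np.ndarray) -> np.ndarray:
    eff = np.zeros_like(coords, dtype=np.float64)
    eff[:-1] = coords[1:] - coords[:-1]
    return eff


@dataclass
class SequenceDataset:
    scenes: dict[str, Scene]
    sequences: list[Sequence]
    config: WorldConfig
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_fixations(self) -> int:
        return self.config.n_fixations

    def scene_pixels(self, scene_id: str) -> np.ndarray:
        return self.scenes[scene_id].pixels

    def crops(self, seq: Sequence) -> np.ndarray:
        """All crops of one sequence, shape (F, crop_side²)."""
        scene = self.scenes[seq.scene_id]
        return np.stack(
            [
                extract_crop(scene, tuple(c), self.config.crop_side)
                for c in seq.crop_centers
            ]
        )

    def samples(self, seq: Sequence) -> list[FixationSample]:
        crops = self.crops(seq)
        return [
            FixationSample(
                crop=crops[f],
                efference=seq.efferences[f].astype(np.float64),
                alloc_xy=seq.crop_centers[f].astype(np.float64),
            )
            for f in range(seq.n_fixations)
        ]

    def batch_arrays(
        self, indices: np.ndarray | list[int] | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stack sequences into (crops, efferences, alloc) arrays.

        Returns arrays of shape (B, F, C²), (B, F, 2) and (B, F, 2).
        """
        if indices is None:
            indices = range(len(self.sequences))
        crops, effs, alloc = [], [], []
        for i in indices:
            seq = self.sequences[i]
            crops.append(self.crops(seq))
            effs.append(seq.efferences)
            alloc.append(seq.crop_centers.astype(np.float64))
        return np.stack(crops), np.stack(effs).astype(np.float64), np.stack(alloc)

    def labels_for(self, seq: Sequence) -> np.ndarray | None:
        return self.scenes[seq.scene_id].labels

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for sid in sorted(self.scenes):
            h.update(sid.encode())
            h.update(np.ascontiguousarray(self.scenes[sid].pixels))
        for seq in self.sequences:
            h.update(seq.scene_id.encode())
            h.update(np.ascontiguousarray(seq.coords.astype(np.int64)))
            h.update(np.ascontiguousarray(seq.crop_centers.astype(np.int64)))
        return h.hexdigest()

    # ------------------------------------------------------------------ I/O
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        scene_ids = sorted(self.scenes)
        arrays = {
            "scene_pixels": np.stack([self.scenes[s].pixels for s in scene_ids]),
            "seq_scene_index": np.array(
                [scene_ids.index(q.scene_id) for q in self.sequences]
            ),
            "coords": np.stack([q.coords for q in self.sequences]),
            "crop_centers": np.stack([q.crop_centers for q in self.sequences]),
            "efferences": np.stack([q.efferences for q in self.sequences]),
        }
        labels = [self.scenes[s].labels for s in scene_ids]
        if labels[0] is not None:
            arrays["labels"] = np.stack(labels)
        np.savez_compressed(directory / "dataset.npz", **arrays)
        manifest = {
            "scene_ids": scene_ids,
            "splits": [self.scenes[s].split for s in scene_ids],
            "config": self.config.__dict__,
            "seed": self.seed,
            "content_hash": self.content_hash(),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "SequenceDataset":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        data = np.load(directory / "dataset.npz")
        config = WorldConfig(**manifest["config"])
        scene_ids = manifest["scene_ids"]
        labels = data["labels"] if "labels" in data else [None] * len(scene_ids)
        scenes = {
            sid: Scene(
                pixels=data["scene_pixels"][i],
                scene_id=sid,
                split=manifest["splits"][i],
                labels=None if labels[i] is None else labels[i],
            )
            for i, sid in enumerate(scene_ids)
        }
        sequences = [
            Sequence(
                scene_id=scene_ids[data["seq_scene_index"][i]],
                coords=data["coords"][i],
                crop_centers=data["crop_centers"][i],
                efferences=data["efferences"][i],
            )
            for i in range(len(data["seq_scene_index"]))
        ]
        return cls(scenes, sequences, config, seed=manifest["seed"])


# --------------------------------------------------------------------------
# generation


def _pink_noise(side: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal((side, side))
    fx = np.fft.fftfreq(side)[:, None]
    fy = np.fft.fftfreq(side)[None, :]
    freq = np.sqrt(fx * fx + fy * fy)
    freq[0, 0] = 1.0  # leave DC untouched
    amplitude = freq ** (-exponent)
    amplitude[0, 0] = 0.0  # zero-mean before rescaling
    img = np.real(np.fft.ifft2(np.fft.fft2(white) * amplitude))
    return img


def _texture_bank(side: int, n_classes: int) -> np.ndarray:
    """Fixed dictionary of oriented global gratings, one per class."""
    rng = np.random.default_rng(123456789)
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    bank = np.empty((n_classes, side, side))
    for k in range(n_classes):
        theta = rng.uniform(0, np.pi)
        freq = rng.uniform(2.0, 8.0) / side
        phase = rng.uniform(0, 2 * np.pi)
        bank[k] = np.sin(
            2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)) + phase
        )
    return bank


def generate_scene(
    side: int,
    seed: int,
    spectrum_exponent: float = 1.0,
    *,
    min_crop_side: int | None = None,
    scene_id: str | None = None,
    split: str = "train",
    n_texture_classes: int = 0,
    texture_prob: float = 0.25,
) -> Scene:
    """Generate a 1/f-filtered gray-scale scene, min–max rescaled to [0, 1].

    Deterministic given ``seed``.  If ``n_texture_classes`` > 0, a random
    subset of fixed oriented gratings is mixed in and recorded as a multi-hot
    label (the synthetic stand-in for scene object categories).
    """
    if min_crop_side is not None and side < 2 * min_crop_side:
        raise ValueError(
            f"scene side {side} must be at least twice the crop side {min_crop_side}"
        )
    rng = np.random.default_rng(seed)
    img = _pink_noise(side, spectrum_exponent, rng)
    labels = None
    if n_texture_classes > 0:
        present = rng.random(n_texture_classes) < texture_prob
        bank = _texture_bank(side, n_texture_classes)
        scale = 0.6 * img.std()
        for k in np.flatnonzero(present):
            img = img + scale * bank[k]
        labels = present.astype(np.float64)
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    return Scene(
        pixels=img,
        scene_id=scene_id if scene_id is not None else f"scene-{seed}",
        split=split,
        labels=labels,
    )


def generate_scanpath(
    scene: Scene,
    n_fix: int,
    crop_side: int,
    seed: int,
    sigma: float | None = None,
) -> Scanpath:
    """Scanpath starting at the scene center with Gaussian saccade steps.

    Steps are drawn i.i.d. from an isotropic 2-D Gaussian and clamped to the
    region where a crop of side ``crop_side`` stays inside the scene.
    """
    side = scene.pixels.shape[0]
    if n_fix < 2:
        raise ValueError("a scanpath needs at least 2 fixations")
    if crop_side > side:
        raise ValueError(
            f"crop side {crop_side} exceeds scene side {side}: valid region is empty"
        )
    sigma = side / 4 if sigma is None else sigma
    lo, hi = crop_side // 2, side - crop_side // 2
    rng = np.random.default_rng(seed)
    coords = np.empty((n_fix, 2), dtype=np.int64)
    coords[0] = (side // 2, side // 2)
    for f in range(1, n_fix):
        step = rng.normal(0.0, sigma, size=2)
        nxt = np.rint(coords[f - 1] + step).astype(np.int64)
        coords[f] = np.clip(nxt, lo, hi)
    return Scanpath(coords=coords, scene_id=scene.scene_id)


def extract_crop(
    scene: Scene | np.ndarray, center: tuple[int, int], crop_side: int
) -> np.ndarray:
    """Axis-aligned square crop of side ``crop_side`` centered at ``center``.

    ``center`` is (x, y) with x the column and y the row; the crop covers the
    half-open square [c - C/2, c + C/2) in both axes and is returned flattened
    row-major.  Centers whose crop would leave the scene raise — generation
    must pre-clamp; extraction never pads.
    """
    pixels = scene.pixels if isinstance(scene, Scene) else scene
    side = pixels.shape[0]
    half = crop_side // 2
    x, y = int(center[0]), int(center[1])
    if x - half < 0 or y - half < 0 or x - half + crop_side > side or y - half + crop_side > side:
        raise ValueError(
            f"crop center {(x, y)} with side {crop_side} leaves the {side}px scene"
        )
    return pixels[y - half : y - half + crop_side, x - half : x - half + crop_side].ravel()


def make_scene_sets(
    n_train: int,
    n_test: int,
    config: WorldConfig,
    seed: int,
) -> tuple[list[Scene], list[Scene]]:
    """Disjoint train/test scene lists with deterministic per-scene seeds."""
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(n_train + n_test, dtype=np.uint32)
    scenes = []
    for i in range(n_train + n_test):
        split = "train" if i < n_train else "test"
        scenes.append(
            generate_scene(
                config.side,
                int(child[i]),
                config.spectrum_exponent,
                min_crop_side=config.crop_side,
                scene_id=f"{split}-{i if i < n_train else i - n_train:05d}",
                split=split,
                n_texture_classes=config.n_texture_classes,
                texture_prob=config.texture_prob,
            )
        )
    return scenes[:n_train], scenes[n_train:]


def build_sequence_dataset(
    scenes: list[Scene], config: WorldConfig, seed: int
) -> SequenceDataset:
    """Per scene, ``sequences_per_scene`` scanpaths with efference copies.

    The efference of fixation f is ``coords[f+1] - coords[f]``; the final
    fixation's efference is the zero vector (no upcoming saccade).
    """
    config.validate()
    ids = [s.scene_id for s in scenes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate scene_id in dataset (possible split leakage)")
    ss = np.random.SeedSequence(seed)
    path_seeds = ss.generate_state(len(scenes) * config.sequences_per_scene, dtype=np.uint32)
    sequences = []
    k = 0
    for scene in scenes:
        for _ in range(config.sequences_per_scene):
            sp = generate_scanpath(
                scene,
                config.n_fixations,
                config.crop_side,
                int(path_seeds[k]),
                sigma=config.sigma,
            )
            k += 1
            sequences.append(
                Sequence(
                    scene_id=scene.scene_id,
                    coords=sp.coords,
                    crop_centers=sp.coords.copy(),
                    efferences=_efferences_from_coords(sp.coords),
                )
            )
    return SequenceDataset(
        scenes={s.scene_id: s for s in scenes},
        sequences=sequences,
        config=config,
        seed=seed,
    )


def make_datasets(
    n_train: int, n_test: int, config: WorldConfig, seed: int
) -> tuple[SequenceDataset, SequenceDataset]:
    """Convenience: disjoint train/test scene sets and their sequence datasets."""
    train_scenes, test_scenes = make_scene_sets(n_train, n_test, config, seed)
    ss = np.random.SeedSequence([seed, 1])
    s_train, s_test = (int(x) for x in ss.generate_state(2, dtype=np.uint32))
    return (
        build_sequence_dataset(train_scenes, config, s_train),
        build_sequence_dataset(test_scenes, config, s_test),
    )


def shuffle_efference(dataset: SequenceDataset, seed: int) -> SequenceDataset:
    """Decouple efference copies from the visual input.

    Within each sequence the coordinate order is permuted (never the identity,
    when more than two distinct orders exist) while the crops keep their
    original order; efference copies are recomputed from the permuted
    coordinates.  Crop content is byte-identical to the source dataset.
    """
    if dataset.config.n_fixations < 2:
        raise ValueError("shuffling requires at least 2 fixations per sequence")
    rng = np.random.default_rng(seed)
    shuffled = []
    for seq in dataset.sequences:
        n = seq.n_fixations
        perm = rng.permutation(n)
        while n > 2 and np.array_equal(perm, np.arange(n)):
            perm = rng.permutation(n)
        coords = seq.coords[perm]
        shuffled.append(
            Sequence(
                scene_id=seq.scene_id,
                coords=coords,
                crop_centers=seq.crop_centers.copy(),
                efferences=_efferences_from_coords(coords),
            )
        )
    return SequenceDataset(
        scenes=dataset.scenes,
        sequences=shuffled,
        config=dataset.config,
        seed=seed,
        extras={"shuffled_from": dataset.seed},
    )


def reduced_crop_side(crop_side: int, reduction: float = 0.56) -> int:
    """Side of a crop whose pixel count is reduced by ``reduction``.

    A 128 px crop reduced by 56% gives 85 px (85² / 128² ≈ 0.44).
    """
    return int(round(crop_side * np.sqrt(1.0 - reduction)))


def load_image_directory(
    image_dir: str | Path,
    fixation_csv: str | Path,
    config: WorldConfig,
    split: str = "test",
) -> SequenceDataset:
    """Adapter for user-supplied data: PNG scenes + CSV fixation table.

    The CSV must have columns scene_id, sequence_index, fixation_index, x, y.
    Images are converted to gray scale and rescaled to [0, 1].
    """
    import pandas as pd
    from matplotlib.image import imread

    image_dir = Path(image_dir)
    table = pd.read_csv(fixation_csv)
    scenes: dict[str, Scene] = {}
    for sid in table["scene_id"].unique():
        arr = imread(image_dir / f"{sid}.png").astype(np.float64)
        if arr.ndim == 3:
            arr = arr[..., :3].mean(axis=-1)
        if arr.max() > 1:
            arr = arr / 255.0
        scenes[sid] = Scene(pixels=arr, scene_id=str(sid), split=split)
    sequences = []
    for (sid, _), grp in table.groupby(["scene_id", "sequence_index"]):
        grp = grp.sort_values("fixation_index")
        coords = grp[["x", "y"]].to_numpy(dtype=np.int64)
        sequences.append(
            Sequence(
                scene_id=str(sid),
                coords=coords,
                crop_centers=coords.copy(),
                efferences=_efferences_from_coords(coords),
            )
        )
    return SequenceDataset(scenes=scenes, sequences=sequences, config=config)
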