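"""Emergent-property analyses: allocentric decoding, lesioning, feedback
statistics, similarity matrices, spatial memory, and unit clustering.

The decoding analysis asks whether the hidden layers re-code the egocentric
saccade vectors into an allocentric (scene-centered) position signal.  The
lesioning analysis zeroes the units that carry that code at runtime and
measures the energy cost; the similarity analysis asks whether the top-down
drive to layer 1 anticipates the upcoming crop (predictive remapping) or
merely echoes the current one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .controls import _mean_ci, compare_conditions, default_eval_indices, model_fixation_loss
from .datasets import FixationSample, SequenceDataset
from .estimators import AllocentricDecoder
from .network import FixationTrace, NetworkWeights, run_batch

__all__ = [
    "ActivationMatrix",
    "DecoderFit",
    "LesionReport",
    "SimilarityAnalysis",
    "FeedbackStats",
    "collect_activations",
    "fit_allocentric_decoder",
    "select_units_by_beta",
    "lesion_experiment",
    "feedback_inhibition_stats",
    "ideal_inhibition",
    "similarity_matrix",
    "hypothesis_matrices",
    "hypothesis_correlation",
    "spatial_memory_analysis",
    "cluster_allocentric_units",
    "unit_spatial_profiles",
]


# --------------------------------------------------------------------------
# activation collection and decoding


@dataclass
class ActivationMatrix:
    """Hidden activations per fixation.

    Rows are fixations of test sequences; columns are hidden units
    concatenated over all hidden layers and all T within-fixation steps
    (step-major: all units at step 0, then step 1, ...).  ``X`` is raw here;
    z-scoring parameters are fitted on the decoder's fit split.
    """

    X: np.ndarray  # (n_rows, H_total · T) float32
    alloc: np.ndarray  # (n_rows, 2)
    scene_ids: np.ndarray  # (n_rows,) str
    sequence_index: np.ndarray
    fixation_index: np.ndarray
    n_hidden_total: int
    steps_per_fixation: int


def collect_activations(
    weights: NetworkWeights,
    dataset: SequenceDataset,
    indices=None,
    max_sequences_per_scene: int | None = None,
    batch_size: int = 64,
) -> ActivationMatrix:
    """One row per fixation; hidden activations at all T steps, both layers."""
    config = weights.config
    T = config.steps_per_fixation
    H = config.n_hidden_total
    if indices is None:
        if max_sequences_per_scene is None:
            indices = list(range(len(dataset.sequences)))
        else:
            per_scene: dict[str, int] = {}
            indices = []
            for i, seq in enumerate(dataset.sequences):
                c = per_scene.get(seq.scene_id, 0)
                if c < max_sequences_per_scene:
                    indices.append(i)
                    per_scene[seq.scene_id] = c + 1
    F = dataset.config.n_fixations
    rows = np.empty((len(indices) * F, H * T), dtype=np.float32)
    alloc = np.empty((len(indices) * F, 2))
    scene_ids, seq_idx, fix_idx = [], [], []
    r = 0
    for start in range(0, len(indices), batch_size):
        chunk = indices[start : start + batch_size]
        crops, effs, centers = dataset.batch_arrays(chunk)
        trace = run_batch(crops, effs, weights)
        acts = [trace.activations(l) for l in range(1, config.n_hidden_layers + 1)]
        for b, i in enumerate(chunk):
            for f in range(F):
                blocks = []
                for t in range(T):
                    s = trace.step_of(f, t)
                    blocks.append(np.concatenate([a[b, s] for a in acts]))
                rows[r] = np.concatenate(blocks)
                alloc[r] = centers[b, f]
                scene_ids.append(dataset.sequences[i].scene_id)
                seq_idx.append(i)
                fix_idx.append(f)
                r += 1
    return ActivationMatrix(
        X=rows,
        alloc=alloc,
        scene_ids=np.array(scene_ids),
        sequence_index=np.array(seq_idx),
        fixation_index=np.array(fix_idx),
        n_hidden_total=H,
        steps_per_fixation=T,
    )


@dataclass
class DecoderFit:
    decoder: AllocentricDecoder
    r2: np.ndarray  # held-out R² for (x, y)
    unit_betas: np.ndarray  # (H_total,) aggregated |weight| per hidden unit
    column_mean: np.ndarray
    column_sd: np.ndarray
    kept_columns: np.ndarray
    eval_scenes: np.ndarray
    n_fit_rows: int


def fit_allocentric_decoder(
    matrix: ActivationMatrix,
    eval_fraction: float = 0.3,
    seed: int = 0,
    alpha: float | None = None,
) -> DecoderFit:
    """Linear decoding of allocentric coordinates from hidden activations.

    Held-out SCENES (not rows) form the evaluation split so that no scene
    contributes to both fit and evaluation.  Columns are z-scored with
    parameters estimated on the fit rows; constant columns are dropped with a
    warning.  Per-unit beta magnitudes aggregate |standardized weight| over
    the unit's T columns and both coordinates.
    """
    if matrix.X.shape[0] < 10:
        raise ValueError(f"refusing to decode from {matrix.X.shape[0]} rows (< 10)")
    scenes = np.unique(matrix.scene_ids)
    rng = np.random.default_rng(seed)
    n_eval = max(1, int(round(eval_fraction * len(scenes))))
    eval_scenes = rng.choice(scenes, size=n_eval, replace=False)
    is_eval = np.isin(matrix.scene_ids, eval_scenes)
    X_fit, X_eval = matrix.X[~is_eval], matrix.X[is_eval]
    y_fit, y_eval = matrix.alloc[~is_eval], matrix.alloc[is_eval]
    mean = X_fit.mean(axis=0, dtype=np.float64)
    sd = X_fit.std(axis=0, dtype=np.float64)
    kept = sd > 0
    if not kept.all():
        warnings.warn(f"dropping {int((~kept).sum())} constant activation columns")
    Z_fit = (X_fit[:, kept] - mean[kept]) / sd[kept]
    Z_eval = (X_eval[:, kept] - mean[kept]) / sd[kept]
    decoder = AllocentricDecoder(alpha=alpha).fit(Z_fit, y_fit)
    r2 = decoder.r2_per_coordinate(Z_eval, y_eval)
    H, T = matrix.n_hidden_total, matrix.steps_per_fixation
    beta_cols = np.zeros(H * T)
    beta_cols[kept] = np.abs(decoder.coef_).sum(axis=0)
    unit_betas = beta_cols.reshape(T, H).sum(axis=0)
    return DecoderFit(
        decoder=decoder,
        r2=np.asarray(r2, dtype=np.float64),
        unit_betas=unit_betas,
        column_mean=mean,
        column_sd=sd,
        kept_columns=kept,
        eval_scenes=eval_scenes,
        n_fit_rows=int((~is_eval).sum()),
    )


def select_units_by_beta(fit: DecoderFit, k: int) -> np.ndarray:
    """The k hidden units with the largest aggregated beta magnitude.

    Deterministic: ties break toward the lower unit index.
    """
    if k > fit.unit_betas.size:
        raise ValueError(f"k={k} exceeds the {fit.unit_betas.size}-unit hidden population")
    order = np.argsort(-fit.unit_betas, kind="stable")
    return np.sort(order[:k])


# --------------------------------------------------------------------------
# lesioning


@dataclass
class LesionReport:
    targeted_ids: np.ndarray
    random_ids: np.ndarray
    loss_intact: np.ndarray  # per (sequence, fixation)
    loss_targeted: np.ndarray
    loss_random: np.ndarray
    comparisons: dict
    targeted_mean_activity: float
    population_mean_activity: float
    activity_p_value: float


def _lesion_mask(ids: np.ndarray, n_hidden_total: int) -> np.ndarray:
    mask = np.zeros(n_hidden_total, dtype=bool)
    mask[ids] = True
    return mask


def lesion_experiment(
    weights: NetworkWeights,
    dataset: SequenceDataset,
    targeted_ids: np.ndarray,
    seed: int = 0,
    indices=None,
) -> LesionReport:
    """Runtime lesioning of targeted vs. size-matched random hidden units.

    Loss vectors (onset layer-1 image-unit loss per fixation) are computed on
    identical test fixations for the intact, targeted-lesioned, and
    random-lesioned networks, with Welch tests between them.  Also reports
    the mean activity of the targeted units against the population mean.
    """
    H = weights.config.n_hidden_total
    targeted_ids = np.asarray(targeted_ids)
    if targeted_ids.size and (targeted_ids.min() < 0 or targeted_ids.max() >= H):
        raise ValueError("targeted unit ids out of range")
    rng = np.random.default_rng(seed)
    pool = np.setdiff1d(np.arange(H), targeted_ids)
    random_ids = np.sort(rng.choice(pool, size=targeted_ids.size, replace=False))
    if indices is None:
        indices = default_eval_indices(dataset)
    crops, effs, _ = dataset.batch_arrays(indices)

    trace_intact = run_batch(crops, effs, weights)
    loss_intact = model_fixation_loss(trace_intact)
    loss_targeted = model_fixation_loss(
        run_batch(crops, effs, weights, _lesion_mask(targeted_ids, H))
    )
    loss_random = model_fixation_loss(
        run_batch(crops, effs, weights, _lesion_mask(random_ids, H))
    )

    acts = np.concatenate(
        [trace_intact.activations(l)[:, 1:, :] for l in range(1, weights.config.n_hidden_layers + 1)],
        axis=2,
    )  # (B, S-1, H)
    per_unit = acts.mean(axis=(0, 1))
    t_act, p_act = stats.ttest_ind(
        per_unit[targeted_ids], per_unit, equal_var=False
    ) if targeted_ids.size else (np.nan, np.nan)
    comparisons = {
        "targeted_vs_intact": compare_conditions(
            loss_targeted, loss_intact, "targeted", "intact"
        ),
        "targeted_vs_random": compare_conditions(
            loss_targeted, loss_random, "targeted", "random"
        ),
        "random_vs_intact": compare_conditions(
            loss_random, loss_intact, "random", "intact"
        ),
    }
    return LesionReport(
        targeted_ids=targeted_ids,
        random_ids=random_ids,
        loss_intact=loss_intact,
        loss_targeted=loss_targeted,
        loss_random=loss_random,
        comparisons=comparisons,
        targeted_mean_activity=float(per_unit[targeted_ids].mean()) if targeted_ids.size else np.nan,
        population_mean_activity=float(per_unit.mean()),
        activity_p_value=float(p_act),
    )


# --------------------------------------------------------------------------
# feedback statistics


@dataclass
class FeedbackStats:
    mean: float
    ci: tuple[float, float]
    sd: float
    n: int


def feedback_inhibition_stats(
    weights: NetworkWeights, dataset: SequenceDataset, indices=None, batch_size: int = 64
) -> FeedbackStats:
    """Distribution of per-crop-per-step spatial means of the layer-1 feedback.

    n = n_sequences × F × T (warm-up excluded); the 99% CI is the
    normal-approximation interval of the grand mean.
    """
    if indices is None:
        indices = default_eval_indices(dataset)
    means = []
    for start in range(0, len(indices), batch_size):
        chunk = indices[start : start + batch_size]
        crops, effs, _ = dataset.batch_arrays(chunk)
        trace = run_batch(crops, effs, weights)
        fb = trace.feedback_to_layer1()[:, 1:, :]  # exclude warm-up
        means.append(fb.mean(axis=2).ravel())
    means = np.concatenate(means)
    return FeedbackStats(
        mean=float(means.mean()),
        ci=_mean_ci(means),
        sd=float(means.std(ddof=1)) if means.size > 1 else 0.0,
        n=int(means.size),
    )


# --------------------------------------------------------------------------
# similarity analysis


def ideal_inhibition(sample: FixationSample | np.ndarray, crop_side: int | None = None) -> np.ndarray:
    """The negative of the fixation crop, as an image (crop_side × crop_side)."""
    crop = sample.crop if isinstance(sample, FixationSample) else np.asarray(sample)
    side = int(np.sqrt(crop.size)) if crop_side is None else crop_side
    return -crop.reshape(side, side)


@dataclass
class SimilarityAnalysis:
    matrices: list[np.ndarray]  # per sequence, (F·T, F)
    n_fixations: int
    steps_per_fixation: int
    undefined_entries: int = 0


def similarity_matrix(trace: FixationTrace, sequence: int = 0) -> tuple[np.ndarray, int]:
    """M[t, j] = Pearson r(feedback image at step t, ideal inhibition of crop j).

    The warm-up step is excluded; a constant feedback image yields undefined
    correlations, recorded as 0 and counted.
    """
    F, T = trace.n_fixations, trace.config.steps_per_fixation
    fb = trace.feedback_to_layer1()[sequence, 1:, :]  # (F·T, C²)
    ideals = -trace.crops[sequence]  # (F, C²)
    M = np.zeros((F * T, F))
    undefined = 0
    fb_c = fb - fb.mean(axis=1, keepdims=True)
    id_c = ideals - ideals.mean(axis=1, keepdims=True)
    fb_n = np.linalg.norm(fb_c, axis=1)
    id_n = np.linalg.norm(id_c, axis=1)
    # a constant image has zero centered norm up to reconstruction round-off
    tiny_fb = 1e-9 * max(1.0, float(np.abs(fb).max()))
    tiny_id = 1e-9 * max(1.0, float(np.abs(ideals).max()))
    for t in range(F * T):
        if fb_n[t] <= tiny_fb:
            undefined += F
            continue
        for j in range(F):
            if id_n[j] <= tiny_id:
                undefined += 1
                continue
            M[t, j] = fb_c[t] @ id_c[j] / (fb_n[t] * id_n[j])
    return M, undefined


def compute_similarity(
    weights: NetworkWeights,
    dataset: SequenceDataset,
    indices=None,
    lesion_mask: np.ndarray | None = None,
    batch_size: int = 64,
) -> SimilarityAnalysis:
    if indices is None:
        indices = default_eval_indices(dataset)
    mats, undef = [], 0
    for start in range(0, len(indices), batch_size):
        chunk = indices[start : start + batch_size]
        crops, effs, _ = dataset.batch_arrays(chunk)
        trace = run_batch(crops, effs, weights, lesion_mask)
        for b in range(len(chunk)):
            M, u = similarity_matrix(trace, b)
            mats.append(M)
            undef += u
    if undef:
        warnings.warn(f"{undef} similarity entries undefined (constant images), set to 0")
    cfg = weights.config
    return SimilarityAnalysis(
        matrices=mats,
        n_fixations=dataset.config.n_fixations,
        steps_per_fixation=cfg.steps_per_fixation,
        undefined_entries=undef,
    )


def hypothesis_matrices(n_fixations: int, steps_per_fixation: int) -> tuple[np.ndarray, np.ndarray]:
    """Binary indicator hypotheses over the (F·T, F) similarity matrix.

    H_future marks cells where step t belongs to the fixation PRECEDING crop
    j (the drive predicts the upcoming input); H_current marks cells where
    step t belongs to crop j itself.
    """
    F, T = n_fixations, steps_per_fixation
    H_future = np.zeros((F * T, F))
    H_current = np.zeros((F * T, F))
    for f in range(F):
        rows = slice(f * T, (f + 1) * T)
        H_current[rows, f] = 1.0
        if f + 1 < F:
            H_future[rows, f + 1] = 1.0
    return H_future, H_current


@dataclass
class HypothesisFit:
    r_future: np.ndarray  # per sequence
    r_current: np.ndarray
    mean_r_future: float
    mean_r_current: float
    t_future: float
    p_future: float
    t_current: float
    p_current: float


def hypothesis_correlation(analysis: SimilarityAnalysis) -> HypothesisFit:
    """Per-sequence Pearson r between the similarity matrix and each
    hypothesis, with one-sample t tests of the r distributions against 0."""
    if len(analysis.matrices) < 2:
        raise ValueError("need at least 2 sequences for group statistics")
    H_future, H_current = hypothesis_matrices(
        analysis.n_fixations, analysis.steps_per_fixation
    )
    hf, hc = H_future.ravel(), H_current.ravel()
    r_f, r_c = [], []
    for M in analysis.matrices:
        m = M.ravel()
        r_f.append(stats.pearsonr(m, hf)[0] if m.std() > 0 else 0.0)
        r_c.append(stats.pearsonr(m, hc)[0] if m.std() > 0 else 0.0)
    r_f, r_c = np.array(r_f), np.array(r_c)
    t_f, p_f = stats.ttest_1samp(r_f, 0.0)
    t_c, p_c = stats.ttest_1samp(r_c, 0.0)
    return HypothesisFit(
        r_future=r_f,
        r_current=r_c,
        mean_r_future=float(r_f.mean()),
        mean_r_current=float(r_c.mean()),
        t_future=float(t_f),
        p_future=float(p_f),
        t_current=float(t_c),
        p_current=float(p_c),
    )


# --------------------------------------------------------------------------
# spatial memory


@dataclass
class SpatialMemoryTable:
    table: np.ndarray  # (3 distance classes, 3 lags), NaN where empty
    thresholds: tuple[float, float]
    counts: np.ndarray

    def cell(self, distance_class: str, lag: int) -> float:
        i = ("short", "medium", "long").index(distance_class)
        return float(self.table[i, lag - 1])


def spatial_memory_analysis(
    losses: np.ndarray, coords: np.ndarray, max_lag: int = 3
) -> SpatialMemoryTable:
    """Mean z-scored loss by (distance class, lag) over fixation pairs.

    ``losses`` and ``coords`` have shapes (B, F) and (B, F, 2).  Distance
    classes cut the distribution of all within-sequence pairwise distances at
    its 33.3/66.7 percentiles; for a pair (i, j = i + lag ≤ i + 3) the
    z-scored loss of the SECOND fixation enters the (class, lag) cell.
    Z-scoring is over all test-fixation losses.
    """
    B, F = losses.shape
    all_d = []
    for b in range(B):
        for i in range(F):
            for j in range(i + 1, F):
                all_d.append(np.linalg.norm(coords[b, j] - coords[b, i]))
    lo, hi = np.percentile(all_d, [100 / 3, 200 / 3])
    mu, sd = losses.mean(), losses.std(ddof=1)
    degenerate = sd <= 1e-12 * max(1.0, abs(mu))  # constant losses: z ≡ 0
    z = np.zeros_like(losses) if degenerate else (losses - mu) / sd
    sums = np.zeros((3, max_lag))
    counts = np.zeros((3, max_lag), dtype=int)
    for b in range(B):
        for i in range(F):
            for lag in range(1, max_lag + 1):
                j = i + lag
                if j >= F:
                    continue
                d = np.linalg.norm(coords[b, j] - coords[b, i])
                cls = 0 if d <= lo else (1 if d <= hi else 2)
                sums[cls, lag - 1] += z[b, j]
                counts[cls, lag - 1] += 1
    with np.errstate(invalid="ignore"):
        table = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return SpatialMemoryTable(table=table, thresholds=(float(lo), float(hi)), counts=counts)


# --------------------------------------------------------------------------
# clustering of allocentric units


@dataclass
class ClusterReport:
    assignments: np.ndarray
    k: int
    silhouette_by_k: dict[int, float]
    representatives: np.ndarray
    tuning_maps: np.ndarray | None  # (k, n_coords) normalized activation
    tuning_coords: np.ndarray | None
    degenerate: bool = False


def unit_spatial_profiles(
    weights: NetworkWeights,
    dataset: SequenceDataset,
    unit_ids: np.ndarray,
    grid: int = 8,
    indices=None,
    batch_size: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean activation of each unit per fixation-coordinate bin (grid × grid).

    Returns (profiles (n_units, grid²), coords (n_samples, 2) of all
    fixations seen) — the activation profile construction behind the
    allocentric-unit clustering.
    """
    if indices is None:
        indices = list(range(len(dataset.sequences)))
    side = dataset.config.side
    H = weights.config.hidden_size
    L = weights.config.n_hidden_layers
    sums = np.zeros((len(unit_ids), grid * grid))
    counts = np.zeros(grid * grid)
    all_coords = []
    edges = np.linspace(0, side, grid + 1)
    for start in range(0, len(indices), batch_size):
        chunk = indices[start : start + batch_size]
        crops, effs, centers = dataset.batch_arrays(chunk)
        trace = run_batch(crops, effs, weights)
        acts = np.concatenate(
            [trace.activations(l) for l in range(1, L + 1)], axis=2
        )  # (B, S, H_total)
        T = weights.config.steps_per_fixation
        for b in range(len(chunk)):
            for f in range(dataset.config.n_fixations):
                s0 = trace.step_of(f, 0)
                a = acts[b, s0 : s0 + T][:, unit_ids].mean(axis=0)
                x, y = centers[b, f]
                bx = min(grid - 1, np.searchsorted(edges, x, side="right") - 1)
                by = min(grid - 1, np.searchsorted(edges, y, side="right") - 1)
                cell = by * grid + bx
                sums[:, cell] += a
                counts[cell] += 1
                all_coords.append((x, y))
    with np.errstate(invalid="ignore"):
        profiles = sums / np.maximum(counts, 1)
    return profiles, np.array(all_coords)


def cluster_allocentric_units(
    profiles: np.ndarray,
    coords: np.ndarray | None = None,
    k_range=range(2, 11),
    n_components: int = 10,
    seed: int = 0,
    n_subsample_coords: int = 4000,
) -> ClusterReport:
    """k-means over PCA-projected, z-scored unit profiles; k by silhouette.

    Representative units are those most correlated with their cluster
    centroid.  Identical profiles are degenerate: reported as a single
    cluster.
    """
    n_units = profiles.shape[0]
    if n_units < 2:
        raise ValueError("need at least 2 units to cluster")
    sd = profiles.std(axis=1, keepdims=True)
    if np.all(sd == 0) or np.allclose(profiles, profiles[0]):
        return ClusterReport(
            assignments=np.zeros(n_units, dtype=int),
            k=1,
            silhouette_by_k={},
            representatives=np.array([0]),
            tuning_maps=None,
            tuning_coords=None,
            degenerate=True,
        )
    z = (profiles - profiles.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    n_comp = min(n_components, n_units - 1, z.shape[1])
    proj = PCA(n_components=n_comp, random_state=seed).fit_transform(z)
    k_range = [k for k in k_range if 2 <= k <= n_units - 1]
    if not k_range:
        warnings.warn("k_range exceeds unit count; truncated to k = 2")
        k_range = [min(2, n_units - 1)]
    sil, models = {}, {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(proj)
        if len(np.unique(km.labels_)) < 2:
            continue
        sil[k] = float(silhouette_score(proj, km.labels_))
        models[k] = km
    if not sil:
        return ClusterReport(
            assignments=np.zeros(n_units, dtype=int),
            k=1,
            silhouette_by_k={},
            representatives=np.array([0]),
            tuning_maps=None,
            tuning_coords=None,
            degenerate=True,
        )
    best_k = max(sil, key=sil.get)
    km = models[best_k]
    reps = np.empty(best_k, dtype=int)
    for c in range(best_k):
        members = np.flatnonzero(km.labels_ == c)
        centroid = km.cluster_centers_[c]
        corr = [
            stats.pearsonr(proj[m], centroid)[0] if proj[m].std() > 0 else -np.inf
            for m in members
        ]
        reps[c] = members[int(np.argmax(corr))]
    tuning_maps = tuning_coords = None
    if coords is not None and len(coords):
        rng = np.random.default_rng(seed)
        n_sub = min(n_subsample_coords, len(coords))
        pick = rng.choice(len(coords), size=n_sub, replace=False)
        tuning_coords = np.asarray(coords)[pick]
        # normalized mean cluster profile rendered at the subsampled coords
        tuning_maps = np.empty((best_k, n_sub))
        side = tuning_coords.max() + 1
        grid = int(np.sqrt(profiles.shape[1]))
        edges = np.linspace(0, side, grid + 1)
        for c in range(best_k):
            prof = z[km.labels_ == c].mean(axis=0)
            rng_span = prof.max() - prof.min()
            prof = (prof - prof.min()) / rng_span if rng_span > 0 else prof * 0
            for i, (x, y) in enumerate(tuning_coords):
                bx = min(grid - 1, np.searchsorted(edges, x, side="right") - 1)
                by = min(grid - 1, np.searchsorted(edges, y, side="right") - 1)
                tuning_maps[c, i] = prof[by * grid + bx]
    return ClusterReport(
        assignments=km.labels_.copy(),
        k=best_k,
        silhouette_by_k=sil,
        representatives=reps,
        tuning_maps=tuning_maps,
        tuning_coords=tuning_coords,
    )
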