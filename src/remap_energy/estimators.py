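"""Scikit-learn-style estimators wrapping the recurrent model and decoder.

``SaccadeRNN`` is the trainable active-vision network (fit on a
SequenceDataset, transform to per-fixation hidden-unit features, score by
negative energy loss).  ``AllocentricDecoder`` is the linear diagnostic
readout of allocentric fixation coordinates.  Both follow sklearn estimator
conventions (constructor parameters, fitted attributes with a trailing
underscore, ``get_params``/``set_params``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.linear_model import LinearRegression, Ridge, RidgeCV

from .datasets import SequenceDataset
from .network import NetworkConfig, NetworkWeights, run_batch
from .training import ObjectiveSpec, TrainingConfig, energy_loss, train_model

__all__ = ["SaccadeRNN", "AllocentricDecoder"]


class SaccadeRNN(BaseEstimator, TransformerMixin):
    """Recurrent network trained on saccadic crop sequences.

    Parameters mirror the network architecture (crop side, hidden layers and
    width, steps per fixation, efference handling) and the training regime
    (objective, learning rate, batch size, epochs).  ``objective='none'``
    yields the untrained He-initialized baseline.
    """

    def __init__(
        self,
        crop_side: int = 32,
        n_hidden_layers: int = 2,
        hidden_size: int = 256,
        steps_per_fixation: int = 6,
        efference_onset_fraction: float = 0.5,
        use_efference: bool = True,
        scene_side: int = 64,
        scale_efference: bool = False,
        objective: str = "energy",
        base_lr: float = 0.0005,
        batch_size: int = 64,
        epochs: int = 50,
        min_epochs: int = 5,
        patience: int | None = None,
        lr_schedule: str = "constant",
        warmup_epochs: int = 0,
        final_lr_fraction: float = 0.1,
        truncate_bptt: int | None = None,
        temperature: float = 0.1,
        n_negatives: int = 8,
        positive_lag: int = 2,
        n_classes: int = 91,
        seed: int = 0,
        verbose: bool = False,
    ):
        self.crop_side = crop_side
        self.n_hidden_layers = n_hidden_layers
        self.hidden_size = hidden_size
        self.steps_per_fixation = steps_per_fixation
        self.efference_onset_fraction = efference_onset_fraction
        self.use_efference = use_efference
        self.scene_side = scene_side
        self.scale_efference = scale_efference
        self.objective = objective
        self.base_lr = base_lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.min_epochs = min_epochs
        self.patience = patience
        self.lr_schedule = lr_schedule
        self.warmup_epochs = warmup_epochs
        self.final_lr_fraction = final_lr_fraction
        self.truncate_bptt = truncate_bptt
        self.temperature = temperature
        self.n_negatives = n_negatives
        self.positive_lag = positive_lag
        self.n_classes = n_classes
        self.seed = seed
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _network_config(self) -> NetworkConfig:
        return NetworkConfig(
            crop_side=self.crop_side,
            n_hidden_layers=self.n_hidden_layers,
            hidden_size=self.hidden_size,
            steps_per_fixation=self.steps_per_fixation,
            efference_onset_fraction=self.efference_onset_fraction,
            use_efference=self.use_efference,
            scale_efference=self.scale_efference,
            scene_side=self.scene_side,
        )

    def fit(self, X: SequenceDataset, y=None, val_dataset: SequenceDataset | None = None):
        """Train on a SequenceDataset; per epoch one scanpath per scene."""
        net_config = self._network_config()
        train_config = TrainingConfig(
            base_lr=self.base_lr,
            batch_size=self.batch_size,
            epochs=self.epochs,
            objective=self.objective,
            seed=self.seed,
            min_epochs=self.min_epochs,
            patience=self.patience,
            lr_schedule=self.lr_schedule,
            warmup_epochs=self.warmup_epochs,
            final_lr_fraction=self.final_lr_fraction,
            truncate_bptt=self.truncate_bptt,
        )
        spec = ObjectiveSpec(
            temperature=self.temperature,
            n_negatives=self.n_negatives,
            positive_lag=self.positive_lag,
            n_classes=self.n_classes,
        )
        self.weights_, self.log_ = train_model(
            X, net_config, train_config, spec, val_dataset=val_dataset,
            verbose=self.verbose,
        )
        self.config_ = net_config
        self.n_features_out_ = net_config.n_hidden_total * self.steps_per_fixation
        return self

    def trace(self, dataset: SequenceDataset, indices=None, lesion_mask=None):
        crops, effs, _ = dataset.batch_arrays(indices)
        return run_batch(crops, effs, self.weights_, lesion_mask)

    def transform(self, X: SequenceDataset, indices=None) -> np.ndarray:
        """Hidden-unit features per fixation, (n_fixations_total, H_total·T)."""
        from .analysis import collect_activations

        return collect_activations(self.weights_, X, indices=indices).X

    def score(self, X: SequenceDataset, y=None, indices=None) -> float:
        """Negative held-out energy loss (greater is better)."""
        return -energy_loss(self.trace(X, indices))

    @classmethod
    def from_weights(cls, weights: NetworkWeights) -> "SaccadeRNN":
        c = weights.config
        est = cls(
            crop_side=c.crop_side,
            n_hidden_layers=c.n_hidden_layers,
            hidden_size=c.hidden_size,
            steps_per_fixation=c.steps_per_fixation,
            efference_onset_fraction=c.efference_onset_fraction,
            use_efference=c.use_efference,
            scene_side=c.scene_side,
            scale_efference=c.scale_efference,
        )
        est.weights_ = weights
        est.config_ = c
        est.n_features_out_ = c.n_hidden_total * c.steps_per_fixation
        return est


class AllocentricDecoder(BaseEstimator, RegressorMixin):
    """Linear readout of allocentric fixation coordinates.

    Ordinary least squares when the design has more rows than columns, ridge
    otherwise (rank-deficient regime).  Inputs are expected z-scored; targets
    are the (x, y) fixation centers in pixels.
    """

    def __init__(self, alpha: float | None = None):
        self.alpha = alpha

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.shape[0] < 10:
            raise ValueError(f"refusing to fit a decoder on {X.shape[0]} rows (< 10)")
        if self.alpha is not None:
            self.model_ = Ridge(alpha=self.alpha)
        elif X.shape[0] > X.shape[1]:
            self.model_ = LinearRegression()
        else:
            # rank-deficient regime: ridge with leave-one-out-validated penalty
            self.model_ = RidgeCV(alphas=np.logspace(-2, 6, 17))
        self.model_.fit(X, y)
        self.coef_ = np.atleast_2d(self.model_.coef_)
        self.intercept_ = np.atleast_1d(self.model_.intercept_)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict(X)

    def r2_per_coordinate(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        pred = self.predict(X)
        y = np.asarray(y)
        ss_res = ((y - pred) ** 2).sum(axis=0)
        ss_tot = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
        return 1.0 - ss_res / ss_tot
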