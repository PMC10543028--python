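"""Tranche regressors and the direct classifier.

Each tranche of genes with similar median expression is predicted jointly by
one multi-task MLP: 512 compressed-feature inputs, one 512-node ReLU hidden
layer shared across the genes of the tranche, and one linear output node per
gene.  Every tile inherits its slide's bulk expression vector as the
regression target; tile-level predictions are averaged to slides and slide
predictions to patients.  Training uses Adam on MSE (lr 1e-4, mini-batches
of 32 tiles, dropout 0.2) and stops early when the mean per-gene validation
correlation has not improved for 50 consecutive epochs (cap 500), restoring
the best-epoch weights.

The direct-supervised variant replaces the regression head with a single
logistic output trained with binary cross-entropy on slide-inherited
response labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import SeededMLP, mean_per_gene_correlation
from .expr_prep import GeneTranche

__all__ = [
    "TrainingConfig",
    "TrancheRegressor",
    "DirectClassifier",
    "train_tranche_model",
    "predict_tiles",
    "aggregate_tiles_to_slide",
    "aggregate_slides_to_patient",
    "train_direct_classifier",
]

INPUT_WIDTH = 512


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 50
    dropout: float = 0.2
    hidden: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("learning_rate, batch_size, max_epochs, patience must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class TrancheRegressor:
    """One fitted multi-task head plus the affine input/target scalers.

    Inputs and targets are standardized with training-set statistics before
    the network sees them (compressed features have tiny between-tile
    variance on top of a large shared component, and log2-CPM targets have
    gene means an order of magnitude larger than their biological spread;
    both would otherwise dominate the MSE).  Predictions are mapped back to
    the expression scale, so the scaling is invisible to callers.
    """

    tranche: GeneTranche
    net: SeededMLP = field(repr=False)
    x_center: np.ndarray = field(default=None, repr=False)
    x_scale: np.ndarray = field(default=None, repr=False)
    y_center: np.ndarray = field(default=None, repr=False)
    y_scale: np.ndarray = field(default=None, repr=False)
    fitted: bool = False

    @property
    def gene_ids(self) -> list[str]:
        return self.tranche.gene_ids

    @property
    def validation_trace(self) -> list[float]:
        return self.net.history.get("val_metric_trace", [])


@dataclass
class DirectClassifier:
    net: SeededMLP = field(repr=False)
    x_center: np.ndarray = field(default=None, repr=False)
    x_scale: np.ndarray = field(default=None, repr=False)
    fitted: bool = False


def _target_matrix(expr_values: pd.DataFrame, gene_ids: list[str], sample_ids: list[str]) -> np.ndarray:
    missing = [g for g in gene_ids if g not in expr_values.index]
    if missing:
        raise ValueError(f"tranche genes absent from expression matrix: {missing}")
    return expr_values.loc[gene_ids, sample_ids].to_numpy().T


def train_tranche_model(
    train_features: np.ndarray,
    train_expr: np.ndarray,
    val_features: np.ndarray,
    val_expr: np.ndarray,
    tranche: GeneTranche,
    config: TrainingConfig,
) -> TrancheRegressor:
    """Fit one multi-task regressor for a gene tranche.

    ``train_expr``/``val_expr`` are tiles x tranche-genes targets (every
    tile carrying its slide's bulk expression).  Early stopping maximises
    the mean per-gene Pearson correlation on the validation tiles.
    """
    train_expr = np.asarray(train_expr, dtype=float)
    if train_expr.shape[1] != len(tranche):
        raise ValueError(
            f"target width {train_expr.shape[1]} != tranche size {len(tranche)}"
        )
    if np.asarray(val_features).shape[0] == 0:
        raise ValueError("validation set must be non-empty")
    x_tr = np.asarray(train_features, dtype=float)
    x_va = np.asarray(val_features, dtype=float)
    y_va = np.asarray(val_expr, dtype=float)
    xc, xs = x_tr.mean(axis=0), x_tr.std(axis=0)
    xs = np.where(xs < 1e-8, 1.0, xs)
    yc, ys = train_expr.mean(axis=0), train_expr.std(axis=0)
    ys = np.where(ys < 1e-8, 1.0, ys)
    net = SeededMLP(
        (INPUT_WIDTH, config.hidden, len(tranche)),
        out_activation="linear",
        dropout=config.dropout,
        seed=config.seed,
    )
    net.fit(
        (x_tr - xc) / xs, (train_expr - yc) / ys,
        (x_va - xc) / xs, (y_va - yc) / ys,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        metric=mean_per_gene_correlation,
    )
    return TrancheRegressor(
        tranche=tranche, net=net,
        x_center=xc, x_scale=xs, y_center=yc, y_scale=ys,
        fitted=True,
    )


def predict_tiles(model: TrancheRegressor, features: np.ndarray) -> np.ndarray:
    """Tiles x tranche-genes predictions."""
    if not model.fitted:
        raise ValueError("regressor is not fitted")
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] != INPUT_WIDTH:
        raise ValueError(f"features must be tiles x {INPUT_WIDTH}")
    z = model.net.predict((x - model.x_center) / model.x_scale)
    return z * model.y_scale + model.y_center


def _group_mean(preds: np.ndarray, groups: list[str], kind: str) -> pd.DataFrame:
    preds = np.asarray(preds, dtype=float)
    if preds.shape[0] != len(groups):
        raise ValueError("prediction rows and group labels differ in length")
    df = pd.DataFrame(preds)
    df.insert(0, "_g", groups)
    out = df.groupby("_g", sort=True).mean()
    out.index.name = kind
    return out


def aggregate_tiles_to_slide(tile_preds: np.ndarray, tile_slides: list[str]) -> pd.DataFrame:
    """Unweighted mean of tile predictions per slide (rows sorted by slide)."""
    if len(tile_slides) == 0:
        raise ValueError("no tiles to aggregate")
    return _group_mean(tile_preds, tile_slides, "slide_id")


def aggregate_slides_to_patient(
    slide_preds: pd.DataFrame, slide_patients: dict[str, str]
) -> pd.DataFrame:
    """Unweighted mean of slide predictions per patient."""
    missing = [s for s in slide_preds.index if s not in slide_patients]
    if missing:
        raise ValueError(f"slides without patient mapping: {missing}")
    groups = [slide_patients[s] for s in slide_preds.index]
    return _group_mean(slide_preds.to_numpy(), groups, "patient_id")


def train_direct_classifier(
    train_features: np.ndarray,
    labels: np.ndarray,
    config: TrainingConfig,
    val_features: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> DirectClassifier:
    """Fit the direct-supervised response classifier on tile features.

    Tiles inherit their slide's binary label.  Single sigmoid output,
    binary cross-entropy; scores are bounded in [0, 1] by the link.
    """
    y = np.asarray(labels, dtype=float).reshape(-1, 1)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    x_tr = np.asarray(train_features, dtype=float)
    xc, xs = x_tr.mean(axis=0), x_tr.std(axis=0)
    xs = np.where(xs < 1e-8, 1.0, xs)
    if val_features is None:
        val_features, val_labels = x_tr, y
    else:
        val_labels = np.asarray(val_labels, dtype=float).reshape(-1, 1)
    net = SeededMLP(
        (INPUT_WIDTH, config.hidden, 1),
        out_activation="sigmoid",
        dropout=config.dropout,
        seed=config.seed,
    )

    def neg_bce(y_true: np.ndarray, y_prob: np.ndarray) -> float:
        p = np.clip(y_prob, 1e-12, 1 - 1e-12)
        return float(np.mean(y_true * np.log(p) + (1 - y_true) * np.log(1 - p)))

    net.fit(
        (x_tr - xc) / xs, y,
        (np.asarray(val_features, dtype=float) - xc) / xs, val_labels,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        metric=neg_bce,
    )
    return DirectClassifier(net=net, x_center=xc, x_scale=xs, fitted=True)


def classify_tiles(model: DirectClassifier, features: np.ndarray) -> np.ndarray:
    """Per-tile response scores in [0, 1]."""
    if not model.fitted:
        raise ValueError("classifier is not fitted")
    x = (np.asarray(features, dtype=float) - model.x_center) / model.x_scale
    return model.net.predict(x).ravel()
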