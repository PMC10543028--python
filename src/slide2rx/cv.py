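"""Patient-level nested cross-validation and ensembling.

The evaluation protocol is 5x5 nested cross-validation: patients are split
into five outer folds; within each outer training set, five inner
training/validation splits each train one member model (autoencoder + one
regressor per gene tranche), giving 25 members in total.  Held-out
predictions for an outer fold average that fold's five inner members;
external cohorts are predicted by averaging all 25.  All splits are at the
patient level, so slides (and tiles) of one patient never appear on both
sides of any split.

Also provided: 90-degree rotation augmentation (average of the four slide
symmetries), leave-one-out evaluation of the direct classifier with 30
bootstrap models per held-out patient, and a cheaper k-fold cross-fitting
imputer used for large synthetic cohorts.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expr_prep import ExpressionMatrix, GeneTranche
from .features import AutoencoderModel, FeatureMatrix, compress_features, train_autoencoder
from .regressor import (
    DirectClassifier,
    TrainingConfig,
    TrancheRegressor,
    aggregate_slides_to_patient,
    aggregate_tiles_to_slide,
    classify_tiles,
    predict_tiles,
    train_direct_classifier,
    train_tranche_model,
)
from .slide_tiler import SlideImage, rotate_slide

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "Dataset",
    "EnsembleMember",
    "TrainedEnsemble",
    "make_fold_plan",
    "validate_fold_plan",
    "nested_cv_train",
    "ensemble_predict",
    "augment_and_predict",
    "loocv_direct",
    "crossfit_impute",
]


@dataclass
class FoldPlan:
    """outer[k] lists the patients of outer fold k; inner[k][j] lists the
    validation patients of inner split j within outer-training set k."""

    outer: list[list[str]]
    inner: list[list[list[str]]]
    seed: int


@dataclass
class Dataset:
    """A cohort ready for training: raw tile features with slide/patient
    lineage, normalized expression (genes x patients) and tranches."""

    features: FeatureMatrix            # tiles x 2048, raw backend features
    tile_slides: list[str]             # slide id per feature row
    slide_patients: dict[str, str]     # slide id -> patient id
    expr: ExpressionMatrix             # genes x patients
    tranches: list[GeneTranche]

    def __post_init__(self) -> None:
        if len(self.tile_slides) != self.features.features.shape[0]:
            raise ValueError("tile_slides must align with feature rows")

    @property
    def patients(self) -> list[str]:
        return sorted(set(self.slide_patients.values()))

    @property
    def tile_patients(self) -> np.ndarray:
        return np.array([self.slide_patients[s] for s in self.tile_slides])

    @property
    def gene_order(self) -> list[str]:
        return [g for tr in self.tranches for g in tr.gene_ids]


@dataclass
class EnsembleMember:
    outer_idx: int
    inner_idx: int
    autoencoder: AutoencoderModel
    regressors: list[TrancheRegressor]


@dataclass
class TrainedEnsemble:
    members: list[EnsembleMember]
    tranches: list[GeneTranche]
    backend_tag: str
    cohort_tag: str = ""

    @property
    def gene_order(self) -> list[str]:
        return [g for tr in self.tranches for g in tr.gene_ids]


def make_fold_plan(patients: list[str], k_outer: int = 5, k_inner: int = 5, seed: int = 0) -> FoldPlan:
    """Deterministic patient-level 5x5 nested fold plan.

    Outer folds partition the patients into near-equal sets (sizes differ by
    at most one); each outer training set is likewise partitioned into
    ``k_inner`` validation sets.
    """
    patients = list(patients)
    if len(set(patients)) != len(patients):
        raise ValueError("patient ids must be unique")
    if len(patients) < k_outer:
        raise ValueError(f"need at least {k_outer} patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    shuffled = list(np.array(sorted(patients))[rng.permutation(len(patients))])
    outer = [list(chunk) for chunk in np.array_split(shuffled, k_outer)]
    inner: list[list[list[str]]] = []
    for k in range(k_outer):
        train = [p for p in shuffled if p not in set(outer[k])]
        if len(train) < k_inner:
            raise ValueError("outer training set smaller than the inner fold count")
        perm = list(np.array(train)[rng.permutation(len(train))])
        inner.append([list(chunk) for chunk in np.array_split(perm, k_inner)])
    return FoldPlan(outer=outer, inner=inner, seed=seed)


def validate_fold_plan(plan: FoldPlan, slide_patients: dict[str, str] | None = None) -> None:
    """Assert the plan's partition and leakage invariants; raise otherwise."""
    all_outer = [p for fold in plan.outer for p in fold]
    if len(all_outer) != len(set(all_outer)):
        raise AssertionError("outer folds overlap")
    universe = set(all_outer)
    for k, fold in enumerate(plan.outer):
        train = universe - set(fold)
        inner_all = [p for split in plan.inner[k] for p in split]
        if set(inner_all) != train or len(inner_all) != len(train):
            raise AssertionError(f"inner folds of outer {k} do not partition its training set")
        if set(fold) & set(inner_all):
            raise AssertionError(f"patient leakage between test and training of outer fold {k}")
    if slide_patients is not None and set(slide_patients.values()) - universe:
        raise AssertionError("dataset contains patients absent from the fold plan")


def _member_seed(base: int, outer: int, inner: int) -> int:
    return (base * 1_000_003 + outer * 29 + inner * 7 + 1) % (2**31)


def _train_member(
    dataset: Dataset,
    train_patients: set[str],
    val_patients: set[str],
    config: TrainingConfig,
    ae_config: TrainingConfig,
    outer_idx: int,
    inner_idx: int,
) -> EnsembleMember:
    tp = dataset.tile_patients
    tr_mask = np.isin(tp, list(train_patients))
    va_mask = np.isin(tp, list(val_patients))
    if tr_mask.sum() == 0:
        raise ValueError(f"outer {outer_idx} / inner {inner_idx}: no training tiles")
    seed = _member_seed(config.seed, outer_idx, inner_idx)
    raw = dataset.features
    ae = train_autoencoder(
        FeatureMatrix([raw.tile_ids[i] for i in np.where(tr_mask)[0]],
                      raw.features[tr_mask], raw.backend_tag),
        replace(ae_config, seed=seed),
    )
    z_tr = ae.encode(raw.features[tr_mask])
    z_va = ae.encode(raw.features[va_mask])
    expr = dataset.expr.values
    regs: list[TrancheRegressor] = []
    for t_idx, tranche in enumerate(dataset.tranches):
        y_tr = expr.loc[tranche.gene_ids, tp[tr_mask]].to_numpy().T
        y_va = expr.loc[tranche.gene_ids, tp[va_mask]].to_numpy().T
        regs.append(
            train_tranche_model(
                z_tr, y_tr, z_va, y_va, tranche,
                replace(config, seed=(seed + 13 * t_idx) % (2**31)),
            )
        )
    return EnsembleMember(outer_idx, inner_idx, ae, regs)


def _member_patient_preds(
    member: EnsembleMember,
    raw: np.ndarray,
    tile_slides: list[str],
    slide_patients: dict[str, str],
) -> pd.DataFrame:
    z = member.autoencoder.encode(raw)
    tile_preds = np.concatenate([predict_tiles(r, z) for r in member.regressors], axis=1)
    slide = aggregate_tiles_to_slide(tile_preds, tile_slides)
    return aggregate_slides_to_patient(slide, slide_patients)


def nested_cv_train(
    dataset: Dataset,
    plan: FoldPlan,
    config: TrainingConfig,
    ae_config: TrainingConfig | None = None,
) -> tuple[TrainedEnsemble, pd.DataFrame]:
    """Train the full 5x5 ensemble and collect out-of-fold predictions.

    For each outer fold, the five inner members' predictions on the fold's
    held-out patients are averaged; concatenating over outer folds yields
    exactly one out-of-fold prediction vector per patient (patients x genes,
    genes in tranche order).  The 25 members are retained for external use.
    """
    validate_fold_plan(plan, dataset.slide_patients)
    if ae_config is None:
        ae_config = config
    members: list[EnsembleMember] = []
    oof_blocks: list[pd.DataFrame] = []
    universe = set(p for fold in plan.outer for p in fold)
    for k, test_patients in enumerate(plan.outer):
        outer_train = universe - set(test_patients)
        test_mask = np.isin(dataset.tile_patients, list(test_patients))
        fold_preds: list[pd.DataFrame] = []
        for j, val_patients in enumerate(plan.inner[k]):
            train_patients = outer_train - set(val_patients)
            member = _train_member(
                dataset, train_patients, set(val_patients), config, ae_config, k, j
            )
            members.append(member)
            fold_preds.append(
                _member_patient_preds(
                    member,
                    dataset.features.features[test_mask],
                    [s for s, m in zip(dataset.tile_slides, test_mask) if m],
                    dataset.slide_patients,
                )
            )
        oof_blocks.append(sum(fold_preds) / len(fold_preds))
    oof = pd.concat(oof_blocks).sort_index()
    oof.columns = dataset.gene_order
    ensemble = TrainedEnsemble(
        members=members, tranches=list(dataset.tranches),
        backend_tag=dataset.features.backend_tag,
    )
    return ensemble, oof


def ensemble_predict(
    ensemble: TrainedEnsemble,
    features: FeatureMatrix,
    tile_slides: list[str],
    slide_patients: dict[str, str],
    members: str = "all",
) -> pd.DataFrame:
    """Patient x genes predictions for new slides.

    ``members`` is ``"all"`` (mean over the 25 members — the external-cohort
    mode) or ``"outer:k"`` (mean over the 5 inner members of outer fold k,
    the held-out mode).
    """
    if features.backend_tag.split("+")[0] != ensemble.backend_tag.split("+")[0]:
        raise ValueError(
            f"feature backend {features.backend_tag!r} does not match "
            f"ensemble backend {ensemble.backend_tag!r}"
        )
    if members == "all":
        chosen = ensemble.members
    elif members.startswith("outer:"):
        k = int(members.split(":")[1])
        chosen = [m for m in ensemble.members if m.outer_idx == k]
    else:
        raise ValueError(f"unknown member selection {members!r}")
    if not chosen:
        raise ValueError("no ensemble members selected")
    preds = [
        _member_patient_preds(m, features.features, tile_slides, slide_patients)
        for m in chosen
    ]
    out = sum(preds) / len(preds)
    out.columns = ensemble.gene_order
    return out


def augment_and_predict(slide: SlideImage, predict_slide) -> np.ndarray:
    """Average a slide-level prediction over the four 90-degree symmetries.

    ``predict_slide`` maps a :class:`SlideImage` to a prediction vector;
    rotation happens at the slide level before tiling, so each symmetry
    yields a tile set of equal cardinality for square slides.
    """
    preds = [np.asarray(predict_slide(rotate_slide(slide, k)), dtype=float) for k in range(4)]
    return np.mean(preds, axis=0)


def loocv_direct(
    dataset: Dataset,
    labels: dict[str, int],
    config: TrainingConfig,
    ae_config: TrainingConfig | None = None,
    n_models: int = 30,
) -> pd.Series:
    """Leave-one-out evaluation of the direct-supervised classifier.

    For each held-out patient the remaining patients are split 80/20 into
    training/validation sets ``n_models`` times (stratified by class; a
    degenerate split is redrawn with a fresh seed and logged); the held-out
    score is the mean of the resulting models' slide scores.
    """
    if ae_config is None:
        ae_config = config
    patients = dataset.patients
    y = {p: int(labels[p]) for p in patients}
    for cls in (0, 1):
        if sum(1 for v in y.values() if v == cls) < 3:
            raise ValueError("need at least 3 patients per class")
    tp = dataset.tile_patients
    raw = dataset.features.features
    scores = {}
    for held_out in patients:
        rest = [p for p in patients if p != held_out]
        rest_mask = np.isin(tp, rest)
        ae = train_autoencoder(
            FeatureMatrix(
                [dataset.features.tile_ids[i] for i in np.where(rest_mask)[0]],
                raw[rest_mask], dataset.features.backend_tag,
            ),
            replace(ae_config, seed=config.seed),
        )
        z_rest = ae.encode(raw[rest_mask])
        z_held = ae.encode(raw[np.isin(tp, [held_out])])
        tp_rest = tp[rest_mask]
        model_scores = []
        for b in range(n_models):
            attempt = 0
            while True:
                rng = np.random.default_rng(
                    (config.seed * 7919 + zlib.crc32(held_out.encode()) % 10007
                     + b * 101 + attempt) % (2**31)
                )
                pos = [p for p in rest if y[p] == 1]
                neg = [p for p in rest if y[p] == 0]
                val = set()
                for group in (pos, neg):
                    n_val = max(1, round(0.2 * len(group)))
                    val |= set(np.array(group)[rng.permutation(len(group))][:n_val])
                train = [p for p in rest if p not in val]
                train_classes = {y[p] for p in train}
                if len(train_classes) == 2:
                    break
                attempt += 1
                logger.info("degenerate 80/20 split redrawn (held-out %s, model %d)", held_out, b)
            tr_mask = np.isin(tp_rest, train)
            va_mask = np.isin(tp_rest, list(val))
            clf = train_direct_classifier(
                z_rest[tr_mask],
                np.array([y[p] for p in tp_rest[tr_mask]]),
                replace(config, seed=(config.seed + b) % (2**31)),
                z_rest[va_mask],
                np.array([y[p] for p in tp_rest[va_mask]]),
            )
            model_scores.append(float(np.mean(classify_tiles(clf, z_held))))
        scores[held_out] = float(np.mean(model_scores))
    return pd.Series(scores).sort_index()


def crossfit_impute(
    dataset: Dataset,
    config: TrainingConfig,
    ae_config: TrainingConfig | None = None,
    n_folds: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """k-fold cross-fitted imputation (one member model per fold).

    A cheaper alternative to :func:`nested_cv_train` for large cohorts:
    patients are split into ``n_folds`` folds; each fold is predicted by a
    single model trained on the other folds (with an internal 20% patient
    validation split for early stopping).  Patient-level splits, so the
    no-leakage guarantee is identical.
    """
    if ae_config is None:
        ae_config = config
    patients = dataset.patients
    if len(patients) < 2 * n_folds:
        raise ValueError("too few patients for the requested fold count")
    rng = np.random.default_rng(seed)
    shuffled = list(np.array(patients)[rng.permutation(len(patients))])
    folds = [list(c) for c in np.array_split(shuffled, n_folds)]
    blocks = []
    for k, fold in enumerate(folds):
        train_all = [p for p in shuffled if p not in set(fold)]
        n_val = max(1, len(train_all) // 5)
        val_patients = set(train_all[:n_val])
        train_patients = set(train_all[n_val:])
        member = _train_member(dataset, train_patients, val_patients, config, ae_config, k, 0)
        test_mask = np.isin(dataset.tile_patients, fold)
        blocks.append(
            _member_patient_preds(
                member,
                dataset.features.features[test_mask],
                [s for s, m in zip(dataset.tile_slides, test_mask) if m],
                dataset.slide_patients,
            )
        )
    out = pd.concat(blocks).sort_index()
    out.columns = dataset.gene_order
    return out
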