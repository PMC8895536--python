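"""Binary MIE classifiers: eligibility, training sets, cross-validated training.

For each MIE a balanced binary classifier separates "MIE-active" profiles
(treatments with a high-support link to the MIE) from "MIE-inactive"
profiles (treatments with a high-support link to some *other* MIE and no
link at all — any mode, any support — to the one being modelled).  20% of
each class is withheld as holdout; the rest is used for 5-fold
cross-validated grid search over a small per-algorithm hyperparameter grid.

Accuracy is the proportion of correct assignments, appropriate because the
class design is balanced by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .annotations import ChemProtRecord, MIECluster
from .profiles import ExpressionMatrix

__all__ = [
    "ALGORITHMS",
    "default_grid",
    "ClassifierSpec",
    "TrainingSet",
    "ClassifierResult",
    "eligible_mies",
    "assemble_training_set",
    "accuracy",
    "cross_validated_train",
    "predict_scores",
]

ALGORITHMS = ("SVM_L", "SVM_P", "SVM_R", "KNN", "MLP", "NB")

#: small explicit per-algorithm hyperparameter grids (recorded in run manifests)
_DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "SVM_L": {"C": [0.25, 0.5, 1.0]},
    "SVM_P": {"C": [0.25, 0.5, 1.0]},
    "SVM_R": {"C": [0.25, 0.5, 1.0]},
    "KNN": {"n_neighbors": [5, 7, 9]},
    "MLP": {"hidden_layer_sizes": [(3,), (5,), (9,)]},
    "NB": {"var_smoothing": [1e-9, 1e-6]},
}


def default_grid(algorithm: str) -> dict[str, list]:
    if algorithm not in _DEFAULT_GRIDS:
        raise ValueError(f"unknown algorithm: {algorithm!r}")
    return {k: list(v) for k, v in _DEFAULT_GRIDS[algorithm].items()}


def _make_estimator(algorithm: str, params: Mapping, seed: int):
    if algorithm == "SVM_L":
        return SVC(kernel="linear", **params)
    if algorithm == "SVM_P":
        return SVC(kernel="poly", degree=3, **params)
    if algorithm == "SVM_R":
        return SVC(kernel="rbf", **params)
    if algorithm == "KNN":
        return KNeighborsClassifier(**params)
    if algorithm == "MLP":
        return MLPClassifier(max_iter=1000, random_state=seed, **params)
    if algorithm == "NB":
        return GaussianNB(**params)
    raise ValueError(f"unknown algorithm: {algorithm!r}")


@dataclass
class ClassifierSpec:
    """Algorithm, hyperparameter grid and fold configuration for one classifier."""

    algorithm: str
    grid: Optional[dict[str, list]] = None
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm: {self.algorithm!r}")
        if self.grid is None:
            self.grid = default_grid(self.algorithm)
        if not self.grid or not all(self.grid.values()):
            raise ValueError("hyperparameter grid must be nonempty")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def grid_points(self) -> list[dict]:
        """Cartesian product of the grid, in insertion order of keys and values."""
        points: list[dict] = [{}]
        for key, values in self.grid.items():
            points = [{**p, key: v} for p in points for v in values]
        return points


@dataclass
class TrainingSet:
    """Balanced active/inactive profile partition with a 20% holdout split."""

    mie_label: str
    cell_line: str
    active_profiles: list[str]
    inactive_profiles: list[str]
    holdout_active: list[str]
    holdout_inactive: list[str]

    def __post_init__(self) -> None:
        train = set(self.active_profiles) | set(self.inactive_profiles)
        hold = set(self.holdout_active) | set(self.holdout_inactive)
        if train & hold:
            raise ValueError("training and holdout profiles overlap")
        n_act = len(self.active_profiles) + len(self.holdout_active)
        n_inact = len(self.inactive_profiles) + len(self.holdout_inactive)
        if n_act != n_inact:
            raise ValueError(
                f"unbalanced classes before the holdout split: {n_act} active "
                f"vs {n_inact} inactive"
            )

    @property
    def all_profiles(self) -> set[str]:
        return (
            set(self.active_profiles)
            | set(self.inactive_profiles)
            | set(self.holdout_active)
            | set(self.holdout_inactive)
        )


@dataclass
class ClassifierResult:
    mie_label: str
    algorithm: str
    best_hyperparameters: dict
    internal_accuracy: float
    holdout_accuracy: float
    fold_accuracies: list[float]
    model_handle: object
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fold_accuracies and not math.isclose(
            self.internal_accuracy,
            float(np.mean(self.fold_accuracies)),
            abs_tol=1e-12,
        ):
            raise ValueError("internal accuracy != mean of fold accuracies")


# ---------------------------------------------------------------------------
# eligibility and training-set assembly


def eligible_mies(
    mie_clusters: Sequence[MIECluster],
    profile_meta: pd.DataFrame,
    cell_line: str,
    min_chemicals: int = 5,
    min_support: int = 5,
    min_profiles: int = 50,
) -> list[str]:
    """MIEs with enough high-confidence chemicals and profiles to model.

    An MIE cluster is eligible iff it has at least ``min_chemicals``
    chemicals at support >= ``min_support`` and those chemicals together
    contribute at least ``min_profiles`` (already capped) profiles in
    ``cell_line``.  Returns the display names of eligible clusters.
    """
    in_line = profile_meta[profile_meta["cell_line"] == cell_line]
    counts = in_line.groupby("chemical_id")["profile_id"].count()
    out = []
    for cluster in mie_clusters:
        chems = cluster.chemicals_at(min_support)
        if len(chems) < min_chemicals:
            continue
        n_prof = int(counts.reindex(sorted(chems)).fillna(0).sum())
        if n_prof < min_profiles:
            continue
        out.append(cluster.display_name)
    return out


def _profiles_of(
    meta: pd.DataFrame, chemicals: set[str], cell_line: str
) -> pd.DataFrame:
    mask = (meta["cell_line"] == cell_line) & meta["chemical_id"].isin(chemicals)
    return meta.loc[mask]


def forbidden_chemicals(
    cluster: MIECluster, records: Sequence[ChemProtRecord]
) -> frozenset[str]:
    """Chemicals linked to any of the cluster's targets at any support or mode."""
    targets = cluster.targets
    return frozenset(r.chemical_id for r in records if r.target in targets)


def annotated_chemicals(
    clusters: Sequence[MIECluster], min_support: int = 5
) -> dict[str, set[str]]:
    """Map chemical_id -> set of cluster display names it supports at >= min_support."""
    out: dict[str, set[str]] = {}
    for c in clusters:
        for chem in c.chemicals_at(min_support):
            out.setdefault(chem, set()).add(c.display_name)
    return out


def holdout_split(
    profiles: Sequence[str], rng: np.random.Generator, fraction: float = 0.2
) -> tuple[list[str], list[str]]:
    """Split profiles into (training, holdout) with floor(fraction * n) held out."""
    profiles = list(profiles)
    n_hold = int(math.floor(fraction * len(profiles)))
    idx = rng.permutation(len(profiles))
    hold = sorted(profiles[i] for i in idx[:n_hold])
    train = sorted(profiles[i] for i in idx[n_hold:])
    return train, hold


def assemble_training_set(
    cluster: MIECluster,
    clusters: Sequence[MIECluster],
    records: Sequence[ChemProtRecord],
    profile_meta: pd.DataFrame,
    cell_line: str,
    exemplar_exclusions: frozenset[str] = frozenset(),
    rng_seed: int = 0,
    min_support: int = 5,
    holdout_fraction: float = 0.2,
    active_profile_ids: Optional[Sequence[str]] = None,
) -> TrainingSet:
    """Assemble a balanced, holdout-split training set for one MIE cluster.

    Active profiles come from the cluster's high-support chemicals (exemplar
    chemicals excluded).  An equal number of inactive profiles is drawn
    without replacement from chemicals that (a) carry no annotation to any
    of the cluster's targets at any support or mode, (b) support a different
    MIE at support >= ``min_support``, and (c) are not excluded exemplars.
    20% of each class (floored) is then withheld as holdout.

    ``active_profile_ids`` overrides the active side (used by the
    replacement-null construction, which swaps in decoy chemicals).
    """
    rng = np.random.default_rng(rng_seed)
    forbidden = forbidden_chemicals(cluster, records)

    if active_profile_ids is None:
        active_chems = cluster.chemicals_at(min_support) - exemplar_exclusions
        active = _profiles_of(profile_meta, set(active_chems), cell_line)
        active_ids = sorted(active["profile_id"])
    else:
        active_ids = sorted(active_profile_ids)
        lookup = profile_meta.set_index("profile_id")
        active_chems = frozenset(lookup.loc[active_ids, "chemical_id"])
    if not active_ids:
        raise ValueError(f"{cluster.display_name}: no active profiles available")

    by_chem = annotated_chemicals(clusters, min_support)
    pool_chems = {
        chem
        for chem, mies in by_chem.items()
        if chem not in forbidden
        and chem not in exemplar_exclusions
        and chem not in active_chems
        and mies - {cluster.display_name}
    }
    pool = _profiles_of(profile_meta, pool_chems, cell_line)
    pool_ids = sorted(pool["profile_id"])
    n = len(active_ids)
    if len(pool_ids) < n:
        raise ValueError(
            f"{cluster.display_name}: inactive pool has {len(pool_ids)} profiles "
            f"from {len(pool_chems)} chemicals but {n} are required"
        )
    inactive_ids = sorted(
        np.asarray(pool_ids, dtype=object)[
            rng.choice(len(pool_ids), size=n, replace=False)
        ]
    )

    train_act, hold_act = holdout_split(active_ids, rng, holdout_fraction)
    train_inact, hold_inact = holdout_split(inactive_ids, rng, holdout_fraction)
    return TrainingSet(
        mie_label=cluster.display_name,
        cell_line=cell_line,
        active_profiles=train_act,
        inactive_profiles=train_inact,
        holdout_active=hold_act,
        holdout_inactive=hold_inact,
    )


# ---------------------------------------------------------------------------
# training


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """Proportion of correct assignments (TP + TN) / (TP + TN + FP + FN)."""
    total = tp + tn + fp + fn
    if total < 1:
        raise ValueError("accuracy is undefined for zero predictions")
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    return (tp + tn) / total


def _design(
    features: ExpressionMatrix, active: Sequence[str], inactive: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    ids = list(active) + list(inactive)
    sub = features.subset_profiles(ids)
    X = sub.data.to_numpy().T
    y = np.concatenate([np.ones(len(active)), np.zeros(len(inactive))])
    return X, y, ids


def cross_validated_train(
    training_set: TrainingSet,
    features: ExpressionMatrix,
    spec: ClassifierSpec,
) -> ClassifierResult:
    """Grid search with a fixed, seeded, stratified 5-fold assignment.

    Every grid point is evaluated on the same fold assignment; the best
    point maximizes mean fold accuracy (ties resolved by grid order).  The
    winning configuration is refit on all training profiles and scored on
    the holdout split.
    """
    X, y, _ = _design(
        features, training_set.active_profiles, training_set.inactive_profiles
    )
    class_counts = np.bincount(y.astype(int))
    if class_counts.min() < spec.n_folds:
        raise ValueError(
            f"smallest class has {class_counts.min()} profiles; "
            f"cannot stratify into {spec.n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
    folds = list(skf.split(X, y))

    best_params: Optional[dict] = None
    best_mean = -np.inf
    best_fold_accs: list[float] = []
    for params in spec.grid_points():
        fold_accs = []
        for train_idx, test_idx in folds:
            est = _make_estimator(spec.algorithm, params, spec.seed)
            est.fit(X[train_idx], y[train_idx])
            fold_accs.append(float(np.mean(est.predict(X[test_idx]) == y[test_idx])))
        mean_acc = float(np.mean(fold_accs))
        if mean_acc > best_mean:  # strict: ties keep the earlier grid point
            best_mean = mean_acc
            best_params = params
            best_fold_accs = fold_accs

    model = _make_estimator(spec.algorithm, best_params, spec.seed)
    model.fit(X, y)

    Xh, yh, _ = _design(
        features, training_set.holdout_active, training_set.holdout_inactive
    )
    holdout_acc = float(np.mean(model.predict(Xh) == yh)) if len(yh) else float("nan")

    return ClassifierResult(
        mie_label=training_set.mie_label,
        algorithm=spec.algorithm,
        best_hyperparameters=dict(best_params),
        internal_accuracy=best_mean,
        holdout_accuracy=holdout_acc,
        fold_accuracies=best_fold_accs,
        model_handle=model,
        feature_ids=list(features.feature_ids),
    )


def predict_scores(
    result: ClassifierResult, features: ExpressionMatrix
) -> pd.Series:
    """Score every profile in ``features``; higher = more MIE-active.

    Uses the fitted model's class probability when available, otherwise a
    logistic squash of the decision value.  Only the rank order of scores is
    consumed downstream, so any strictly monotone choice is equivalent.
    """
    missing = [f for f in result.feature_ids if f not in features.feature_ids]
    if missing:
        raise ValueError(
            f"feature space mismatch; {len(missing)} training features missing, "
            f"e.g. {missing[:5]}"
        )
    X = features.subset_features(result.feature_ids).data.to_numpy().T
    model = result.model_handle
    if hasattr(model, "predict_proba"):
        pos = list(model.classes_).index(1.0)
        scores = model.predict_proba(X)[:, pos]
    else:
        decision = model.decision_function(X)
        scores = 1.0 / (1.0 + np.exp(-decision))
    return pd.Series(scores, index=features.profile_ids, name=result.mie_label)
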