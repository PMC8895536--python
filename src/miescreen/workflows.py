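"""End-to-end screening workflow: annotations -> classifiers -> significance.

Composes the module-level operations into the standard run: derive and
cluster MIE labels, cap and standardize profiles, select a feature space,
assemble balanced training sets for every eligible MIE, train classifiers,
and (optionally) attach replacement-null ensembles with empirical p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotations import (
    ChemProtRecord,
    MIECluster,
    build_mies,
    cluster_mies,
    derive_mie_records,
)
from .modeling import (
    ClassifierResult,
    ClassifierSpec,
    TrainingSet,
    assemble_training_set,
    cross_validated_train,
    eligible_mies,
)
from .profiles import ExpressionMatrix, cap_profiles, select_feature_space, standardize
from .significance import NullEnsemble, train_null_ensemble
from .validation import ExemplarAssignment, select_exemplars

__all__ = ["ScreenResult", "run_screen"]


@dataclass
class ScreenResult:
    """Everything a screening run produced, keyed by MIE display name."""

    cell_line: str
    clusters: list[MIECluster]
    eligible: list[str]
    exemplars: list[ExemplarAssignment]
    training_sets: dict[str, TrainingSet]
    results: dict[str, ClassifierResult]
    ensembles: dict[str, NullEnsemble] = field(default_factory=dict)

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for mie, r in self.results.items():
            ts = self.training_sets[mie]
            row = {
                "mie": mie,
                "cell_line": self.cell_line,
                "algorithm": r.algorithm,
                "internal_accuracy": r.internal_accuracy,
                "holdout_accuracy": r.holdout_accuracy,
                "n_active_profiles": len(ts.active_profiles)
                + len(ts.holdout_active),
                "best_params": repr(r.best_hyperparameters),
            }
            if mie in self.ensembles:
                e = self.ensembles[mie]
                row["mean_null_accuracy"] = float(
                    np.mean(e.null_internal_accuracies)
                )
                row["empirical_p"] = e.empirical_p
            rows.append(row)
        return pd.DataFrame(rows)


def run_screen(
    records: Sequence[ChemProtRecord],
    meta: pd.DataFrame,
    matrix: ExpressionMatrix,
    cell_line: str,
    algorithm: str = "SVM_L",
    feature_space: str = "landmark",
    gene_sets: Optional[Sequence] = None,
    n_null: int = 0,
    seed: int = 0,
    min_support: int = 5,
    min_chemicals: int = 5,
    min_profiles: int = 50,
    max_profiles_per_chemical: int = 20,
    cut_height: float = 0.7,
    with_exemplars: bool = False,
    grid: Optional[dict] = None,
    n_folds: int = 5,
) -> ScreenResult:
    """Run the full screen for one cell line and one algorithm.

    ``meta`` must already carry chemical identifiers (see
    :func:`miescreen.profiles.join_chemicals`).  With ``n_null > 0`` a
    replacement-null ensemble and empirical p-value are attached to every
    trained classifier; with ``with_exemplars`` exemplar chemicals are
    selected first and excluded from all training and null sets.
    """
    mie_records = derive_mie_records(records, min_support=min_support)
    mies = build_mies(mie_records, min_support=min_support)
    clusters = cluster_mies(mies, cut_height=cut_height)

    capped = cap_profiles(meta, max_profiles_per_chemical, rng_seed=seed)
    in_line = capped[capped["cell_line"] == cell_line].reset_index(drop=True)
    features = standardize(matrix.subset_profiles(list(in_line["profile_id"])))
    features = select_feature_space(features, feature_space, gene_sets=gene_sets)

    eligible = eligible_mies(
        clusters, in_line, cell_line,
        min_chemicals=min_chemicals, min_support=min_support,
        min_profiles=min_profiles,
    )
    modeled = [c for c in clusters if c.display_name in eligible]

    exemplars: list[ExemplarAssignment] = []
    exclusions: frozenset[str] = frozenset()
    if with_exemplars:
        profile_counts = (
            in_line.groupby("chemical_id")["profile_id"].count().to_dict()
        )
        exemplars = select_exemplars(
            modeled, profile_counts,
            min_chemicals=min_chemicals, min_profiles=min_profiles,
            min_support=min_support,
        )
        exclusions = frozenset(
            e.chemical_id for e in exemplars if e.chemical_id
        )

    seeds = np.random.SeedSequence(seed).spawn(len(modeled))
    training_sets: dict[str, TrainingSet] = {}
    results: dict[str, ClassifierResult] = {}
    ensembles: dict[str, NullEnsemble] = {}
    for cluster, seq in zip(modeled, seeds):
        child = seq.generate_state(3)
        spec = ClassifierSpec(
            algorithm=algorithm, grid=grid, n_folds=n_folds,
            seed=int(child[0] % 2**31),
        )
        ts = assemble_training_set(
            cluster, clusters, records, in_line, cell_line,
            exemplar_exclusions=exclusions,
            rng_seed=int(child[1] % 2**31),
            min_support=min_support,
        )
        result = cross_validated_train(ts, features, spec)
        training_sets[cluster.display_name] = ts
        results[cluster.display_name] = result
        if n_null > 0:
            ensembles[cluster.display_name] = train_null_ensemble(
                cluster, clusters, records, in_line, cell_line,
                features, spec, result,
                n_null=n_null, rng_seed=int(child[2] % 2**31),
                exemplar_exclusions=exclusions, min_support=min_support,
            )
    return ScreenResult(
        cell_line=cell_line,
        clusters=clusters,
        eligible=eligible,
        exemplars=exemplars,
        training_sets=training_sets,
        results=results,
        ensembles=ensembles,
    )
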