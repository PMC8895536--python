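"""Empirical significance testing via chemical-replacement null classifiers.

A classifier trained on profiles from a handful of chemicals can score well
simply because replicate profiles of the same treatment resemble each
other.  To measure that bias, each MIE classifier is compared against an
ensemble of *null* classifiers: the MIE-active chemicals are swapped for
random decoy chemicals (annotated to some other MIE, never to this one),
each decoy contributing exactly as many profiles as the chemical it
replaces, and the full training procedure is re-run.  The empirical p-value
is the fraction of null classifiers whose internal accuracy reaches the
original's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotations import ChemProtRecord, MIECluster
from .modeling import (
    ClassifierResult,
    ClassifierSpec,
    annotated_chemicals,
    assemble_training_set,
    cross_validated_train,
    forbidden_chemicals,
)
from .profiles import ExpressionMatrix

__all__ = [
    "NullEnsemble",
    "build_null_active_set",
    "empirical_p",
    "train_null_ensemble",
    "select_candidates",
]


@dataclass
class NullEnsemble:
    mie_label: str
    algorithm: str
    null_internal_accuracies: list[float]
    original_internal_accuracy: float

    def __post_init__(self) -> None:
        if not self.null_internal_accuracies:
            raise ValueError("null ensemble must contain at least one accuracy")

    @property
    def n_null(self) -> int:
        return len(self.null_internal_accuracies)

    @property
    def empirical_p(self) -> float:
        return empirical_p(
            self.original_internal_accuracy, self.null_internal_accuracies
        )


def empirical_p(original_accuracy: float, null_accuracies: Sequence[float]) -> float:
    """Proportion of null accuracies at or above the original's.

    The >= convention makes the smallest attainable p-value 0 only when
    every null falls strictly below the original.
    """
    nulls = np.asarray(null_accuracies, dtype=float)
    if nulls.size == 0:
        raise ValueError("empirical p-value is undefined for an empty null list")
    return float(np.count_nonzero(nulls >= original_accuracy) / nulls.size)


def build_null_active_set(
    original_active: Mapping[str, int],
    availability: Mapping[str, Sequence[str]],
    eligible: frozenset[str],
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Swap every MIE-active chemical for a random decoy with matched volume.

    ``original_active`` maps each original chemical to its profile count;
    ``availability`` maps candidate chemicals to their available (capped)
    profile ids; ``eligible`` restricts candidates to chemicals annotated to
    at least one other MIE but never to the modelled one.  Each decoy must
    have at least as many available profiles as the chemical it replaces
    and contributes exactly that many (sampled at random); no chemical
    fills two slots.  Chemical count and total profile count are therefore
    preserved exactly.
    """
    used: set[str] = set()
    out: dict[str, list[str]] = {}
    # hardest slots first so feasible decoys are not squandered on easy slots
    slots = sorted(original_active.items(), key=lambda kv: (-kv[1], kv[0]))
    for chem, count in slots:
        candidates = sorted(
            c
            for c in eligible
            if c not in used and len(availability.get(c, ())) >= count
        )
        if not candidates:
            raise ValueError(
                f"no eligible replacement with >= {count} profiles for "
                f"slot {chem!r}"
            )
        pick = candidates[int(rng.integers(len(candidates)))]
        used.add(pick)
        profs = sorted(availability[pick])
        chosen = rng.choice(len(profs), size=count, replace=False)
        out[pick] = sorted(np.asarray(profs, dtype=object)[chosen])
    return out


def null_eligible_chemicals(
    cluster: MIECluster,
    clusters: Sequence[MIECluster],
    records: Sequence[ChemProtRecord],
    exemplar_exclusions: frozenset[str] = frozenset(),
    min_support: int = 5,
) -> frozenset[str]:
    """Chemicals usable as decoys for ``cluster``'s null training sets."""
    forbidden = forbidden_chemicals(cluster, records)
    by_chem = annotated_chemicals(clusters, min_support)
    return frozenset(
        chem
        for chem, mies in by_chem.items()
        if chem not in forbidden
        and chem not in exemplar_exclusions
        and mies - {cluster.display_name}
    )


def train_null_ensemble(
    cluster: MIECluster,
    clusters: Sequence[MIECluster],
    records: Sequence[ChemProtRecord],
    profile_meta: pd.DataFrame,
    cell_line: str,
    features: ExpressionMatrix,
    spec: ClassifierSpec,
    original: ClassifierResult,
    n_null: int = 100,
    rng_seed: int = 0,
    exemplar_exclusions: frozenset[str] = frozenset(),
    min_support: int = 5,
) -> NullEnsemble:
    """Train ``n_null`` replacement-null classifiers and collect accuracies.

    Null training sets follow the original procedure end to end: the active
    side is the chemical-swapped set, the inactive side is re-drawn under
    the original rules, the holdout split and the cross-validated grid
    search are identical.
    """
    in_line = profile_meta[
        (profile_meta["cell_line"] == cell_line)
        & profile_meta["chemical_id"].notna()
    ]
    availability = {
        chem: sorted(grp["profile_id"])
        for chem, grp in in_line.groupby("chemical_id")
    }
    active_chems = cluster.chemicals_at(min_support) - exemplar_exclusions
    original_active = {
        chem: len(availability.get(chem, ()))
        for chem in sorted(active_chems)
        if availability.get(chem)
    }
    eligible = null_eligible_chemicals(
        cluster, clusters, records, exemplar_exclusions, min_support
    )

    seeds = np.random.SeedSequence(rng_seed).spawn(n_null)
    accs: list[float] = []
    for seq in seeds:
        rng = np.random.default_rng(seq)
        null_active = build_null_active_set(
            original_active, availability, eligible, rng
        )
        null_profiles = [p for profs in null_active.values() for p in profs]
        ts = assemble_training_set(
            cluster,
            clusters,
            records,
            profile_meta,
            cell_line,
            exemplar_exclusions=exemplar_exclusions,
            rng_seed=int(rng.integers(2**31)),
            min_support=min_support,
            active_profile_ids=null_profiles,
        )
        total = len(ts.all_profiles)
        expected = 2 * sum(original_active.values())
        assert total == expected, "null set does not preserve profile counts"
        result = cross_validated_train(ts, features, spec)
        accs.append(result.internal_accuracy)
    return NullEnsemble(
        mie_label=cluster.display_name,
        algorithm=spec.algorithm,
        null_internal_accuracies=accs,
        original_internal_accuracy=original.internal_accuracy,
    )


def select_candidates(
    results: Sequence[ClassifierResult],
    ensembles: Sequence[NullEnsemble],
    alpha: float = 0.05,
    excluded_algorithms: frozenset[str] = frozenset({"SVM_P"}),
) -> pd.DataFrame:
    """Per MIE, the best-accuracy algorithm among those passing the null test.

    Algorithms in ``excluded_algorithms`` are never considered (the
    polynomial-kernel SVM shows holdout degradation consistent with
    overfitting).  MIEs where no algorithm reaches ``empirical_p <= alpha``
    are omitted.  Returns columns ``mie, algorithm, internal_accuracy,
    holdout_accuracy, empirical_p``.
    """
    p_by_key = {(e.mie_label, e.algorithm): e.empirical_p for e in ensembles}
    rows = []
    for r in results:
        if r.algorithm in excluded_algorithms:
            continue
        key = (r.mie_label, r.algorithm)
        if key not in p_by_key:
            continue
        p = p_by_key[key]
        if p <= alpha:
            rows.append(
                {
                    "mie": r.mie_label,
                    "algorithm": r.algorithm,
                    "internal_accuracy": r.internal_accuracy,
                    "holdout_accuracy": r.holdout_accuracy,
                    "empirical_p": p,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=[
                "mie",
                "algorithm",
                "internal_accuracy",
                "holdout_accuracy",
                "empirical_p",
            ]
        )
    table = pd.DataFrame(rows)
    best = (
        table.sort_values(
            ["mie", "internal_accuracy", "algorithm"],
            ascending=[True, False, True],
        )
        .groupby("mie", sort=True)
        .head(1)
        .reset_index(drop=True)
    )
    return best
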