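"""Expression matrices and profile metadata.

Profiles are replicate-collapsed differential-expression signatures
(moderated z-scores) of cells treated with a perturbagen, one column per
profile.  Features are either *landmark* genes (directly measured),
*inferred* genes (imputed from landmarks), or *pathway* scores derived from
gene sets.

Operations here cover the standard pre-modelling steps: joining perturbagen
identifiers to harmonized chemical identifiers, capping the number of
profiles any one chemical may contribute, per-feature standardization, and
feature-space selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_CLASSES",
    "ExpressionMatrix",
    "read_profile_meta",
    "write_profile_meta",
    "join_chemicals",
    "cap_profiles",
    "standardize",
    "select_feature_space",
]

FEATURE_CLASSES = ("landmark", "inferred", "pathway")

#: columns a profile-metadata table must carry
META_COLUMNS = ("profile_id", "chemical_id", "cell_line")


@dataclass
class ExpressionMatrix:
    """Features x profiles matrix with a per-feature class annotation.

    ``data`` is a float DataFrame indexed by feature id with one column per
    profile id; ``feature_class`` is a Series aligned with ``data.index``
    taking values in :data:`FEATURE_CLASSES`.
    """

    data: pd.DataFrame
    feature_class: pd.Series

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("feature ids are not unique")
        if not self.data.columns.is_unique:
            raise ValueError("profile ids are not unique")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.feature_class = self.feature_class.reindex(self.data.index)
        if self.feature_class.isna().any():
            missing = self.feature_class.index[self.feature_class.isna()]
            raise ValueError(f"features lack a class annotation: {list(missing[:5])}")
        bad = set(self.feature_class.unique()) - set(FEATURE_CLASSES)
        if bad:
            raise ValueError(f"unknown feature classes: {sorted(bad)}")
        self.data = self.data.astype(float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_profiles(self) -> int:
        return self.data.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def profile_ids(self) -> pd.Index:
        return self.data.columns

    def subset_profiles(self, profile_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [p for p in profile_ids if p not in self.data.columns]
        if missing:
            raise KeyError(f"profiles absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(profile_ids)], self.feature_class)

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        sub = self.data.loc[list(feature_ids)]
        return ExpressionMatrix(sub, self.feature_class.loc[sub.index])

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "feature_class", self.feature_class)
        out.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        table = pd.read_csv(path, sep="\t", index_col="feature_id")
        if "feature_class" not in table.columns:
            raise ValueError("expression TSV lacks a feature_class column")
        fclass = table.pop("feature_class")
        table.index.name = None
        return cls(table, fclass)


def read_profile_meta(path) -> pd.DataFrame:
    """Read profile metadata TSV.

    Expected columns: ``profile_id chemical_id cell_line dose dose_unit
    duration_h`` (dose columns optional).  Empty chemical_id marks a
    non-chemical perturbagen.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"profile_id": str, "chemical_id": str})
    _check_meta(meta)
    return meta


def write_profile_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def _check_meta(meta: pd.DataFrame) -> None:
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"profile metadata missing columns: {sorted(missing)}")
    if meta["profile_id"].duplicated().any():
        dup = meta.loc[meta["profile_id"].duplicated(), "profile_id"].iloc[0]
        raise ValueError(f"duplicate profile_id in metadata: {dup}")


def join_chemicals(meta: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Attach harmonized chemical identifiers to profile metadata.

    ``meta`` must carry a ``perturbagen_id`` column; ``mapping`` has columns
    ``perturbagen_id`` and ``chemical_id``.  Profiles whose perturbagen is
    not in the mapping keep a null chemical_id and are flagged
    ``trainable == False`` (they can never carry a training label).
    """
    if "perturbagen_id" not in meta.columns:
        raise ValueError("metadata lacks a perturbagen_id column")
    dup = mapping[mapping["perturbagen_id"].duplicated(keep=False)]
    if not dup.empty:
        conflicting = dup.groupby("perturbagen_id")["chemical_id"].nunique()
        conflicting = conflicting[conflicting > 1]
        if not conflicting.empty:
            raise ValueError(
                "perturbagen mapped to multiple chemical_ids: "
                f"{list(conflicting.index[:5])}"
            )
        mapping = mapping.drop_duplicates("perturbagen_id")
    out = meta.drop(columns=["chemical_id"], errors="ignore").merge(
        mapping[["perturbagen_id", "chemical_id"]], on="perturbagen_id", how="left"
    )
    out["trainable"] = out["chemical_id"].notna()
    return out


def cap_profiles(
    meta: pd.DataFrame,
    max_per_chemical: int = 20,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Cap the number of profiles per chemical within each cell line.

    Chemicals with more than ``max_per_chemical`` profiles in a cell line
    retain a random subset of exactly that size (reproducible for a fixed
    seed); all other profiles — including non-chemical perturbagens — are
    kept.  Row order of the input is preserved.
    """
    if max_per_chemical < 1:
        raise ValueError("max_per_chemical must be >= 1")
    _check_meta(meta)
    meta = meta.reset_index(drop=True)
    rng = np.random.default_rng(rng_seed)
    keep = np.ones(len(meta), dtype=bool)
    chem = meta["chemical_id"]
    groups = meta[chem.notna()].groupby(["cell_line", "chemical_id"], sort=True)
    for _, grp in groups:
        if len(grp) > max_per_chemical:
            chosen = rng.choice(len(grp), size=max_per_chemical, replace=False)
            drop = np.setdiff1d(np.arange(len(grp)), chosen)
            keep[grp.index[drop]] = False
    return meta.loc[keep].reset_index(drop=True)


def standardize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale every feature across profiles.

    Each feature's mean across profiles is subtracted and the result divided
    by the sample standard deviation (n - 1 denominator).  Constant features
    map to all zeros so matrix shapes stay stable.
    """
    if matrix.n_profiles < 2:
        raise ValueError("standardization needs at least 2 profiles")
    values = matrix.data.to_numpy()
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    centered = values - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, centered / sd, 0.0)
    out = pd.DataFrame(scaled, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(out, matrix.feature_class)


def select_feature_space(
    matrix: ExpressionMatrix,
    space: str,
    gene_sets: Optional[Sequence] = None,
    ssgsea_weight: float = 0.25,
    ssgsea_stat: str = "integral",
) -> ExpressionMatrix:
    """Select the feature representation used for classifier training.

    ``space`` is one of ``"landmark"`` (directly measured genes only),
    ``"all_genes"`` (landmark + inferred), or ``"pathway"`` (single-sample
    gene-set enrichment scores over all genes, standardized like genes).
    """
    if space == "landmark":
        mask = matrix.feature_class == "landmark"
        if not mask.any():
            raise ValueError("no landmark features present in matrix")
        return matrix.subset_features(matrix.feature_ids[mask])
    if space == "all_genes":
        mask = matrix.feature_class.isin(["landmark", "inferred"])
        if not mask.any():
            raise ValueError("no gene features present in matrix")
        return matrix.subset_features(matrix.feature_ids[mask])
    if space == "pathway":
        if gene_sets is None:
            raise ValueError("pathway feature space requires gene sets")
        from .pathways import pathway_matrix

        gene_mask = matrix.feature_class.isin(["landmark", "inferred"])
        genes = matrix.subset_features(matrix.feature_ids[gene_mask])
        return pathway_matrix(
            genes, gene_sets, weight=ssgsea_weight, stat=ssgsea_stat
        )
    raise ValueError(f"unknown feature space: {space!r}")
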