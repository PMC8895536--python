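"""Single-sample gene-set enrichment (ssGSEA) pathway scores.

A pathway score summarizes the coordinated expression of a gene set within
one profile via a rank-based running sum: genes are walked in descending
expression order, accumulating a weighted in-set ECDF against a uniform
out-set ECDF.  The aggregate statistic is either the integral (sum of the
running difference, the default) or the supremum, configurable because the
exact variant used in published LINCS analyses differs between papers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .profiles import ExpressionMatrix

__all__ = ["GeneSet", "read_gmt", "write_gmt", "ssgsea_score", "pathway_matrix"]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets in GMT format (name, description, genes...).

    The description column is discarded; duplicate gene symbols within a
    line are collapsed.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} tab-separated "
                    "fields; GMT requires name, description and >=1 gene"
                )
            name = fields[0]
            if name in seen:
                raise ValueError(f"{path}: duplicate gene set name {name!r}")
            seen.add(name)
            genes = frozenset(g for g in fields[2:] if g)
            sets.append(GeneSet(name=name, genes=genes))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.genes)]) + "\n")


def ssgsea_score(
    values: Sequence[float],
    gene_ids: Sequence[str],
    gene_set: GeneSet,
    weight: float = 0.25,
    stat: str = "integral",
) -> float:
    """Running-sum enrichment score of ``gene_set`` in one profile.

    Genes are ranked by descending expression value (ties broken by original
    feature order, so scores are deterministic).  At each rank the in-set
    cumulative fraction — increments proportional to |value|**weight,
    normalized to sum 1 — is compared with the uniform out-set cumulative
    fraction.  ``stat="integral"`` sums the running difference over all
    ranks; ``stat="sup"`` takes its maximum.
    """
    values = np.asarray(values, dtype=float)
    gene_ids = list(gene_ids)
    if len(values) != len(gene_ids):
        raise ValueError("values and gene_ids differ in length")
    in_set = np.array([g in gene_set.genes for g in gene_ids])
    n_in = int(in_set.sum())
    n_out = len(gene_ids) - n_in
    if n_in == 0:
        raise ValueError(
            f"gene set {gene_set.name!r} does not intersect the measured genes"
        )
    if n_out == 0:
        raise ValueError(
            f"gene set {gene_set.name!r} covers every measured gene; "
            "the out-set ECDF is undefined"
        )
    order = np.argsort(-values, kind="stable")
    in_ordered = in_set[order]
    weights = np.abs(values[order]) ** weight
    in_weights = np.where(in_ordered, weights, 0.0)
    total = in_weights.sum()
    if total > 0:
        in_steps = in_weights / total
    else:  # all in-set values zero under a positive weight: fall back to uniform
        in_steps = np.where(in_ordered, 1.0 / n_in, 0.0)
    out_steps = np.where(in_ordered, 0.0, 1.0 / n_out)
    diff = np.cumsum(in_steps) - np.cumsum(out_steps)
    if stat == "integral":
        return float(diff.sum())
    if stat == "sup":
        return float(diff.max())
    raise ValueError(f"unknown ssGSEA statistic: {stat!r}")


def pathway_matrix(
    matrix: ExpressionMatrix,
    sets: Sequence[GeneSet],
    weight: float = 0.25,
    stat: str = "integral",
) -> ExpressionMatrix:
    """Score every gene set in every profile, then standardize rows.

    Sets with no measured member are skipped; the resulting score rows are
    centered and scaled exactly like gene features (feature class
    ``"pathway"``).
    """
    from .profiles import standardize

    measured = set(matrix.feature_ids)
    usable = [s for s in sets if s.genes & measured]
    if not usable:
        raise ValueError("no gene set intersects the measured genes")
    gene_ids = list(matrix.feature_ids)
    values = matrix.data.to_numpy()
    scores = np.empty((len(usable), matrix.n_profiles))
    for j in range(matrix.n_profiles):
        col = values[:, j]
        for i, s in enumerate(usable):
            scores[i, j] = ssgsea_score(col, gene_ids, s, weight=weight, stat=stat)
    data = pd.DataFrame(
        scores, index=[s.name for s in usable], columns=matrix.profile_ids
    )
    fclass = pd.Series("pathway", index=data.index)
    return standardize(ExpressionMatrix(data, fclass))
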