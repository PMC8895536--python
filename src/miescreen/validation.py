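"""Classifier validation beyond holdout accuracy.

Four independent checks:

* *Exemplar chemicals* — one high-support reference chemical per MIE is
  withheld from every training, holdout and null set; a trustworthy
  classifier should rank it near the top of all chemicals.
* *Percentile ranks* — per-chemical median prediction scores are ranked
  (rank 1 = highest) and converted to percentiles by (n - rank) / (n - 1).
* *KS enrichment* — chemicals annotated to the MIE at moderate support
  (3-4 sources, never used in training) should score higher than background,
  tested with a one-sided two-sample Kolmogorov-Smirnov test.
* *Cross-cell-line comparison* — accuracies of MIE-matched classifiers
  trained in two cell lines are correlated and contrasted against baseline
  target expression (NX values, log2 fold change with a 0.1 pseudocount).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import MIECluster
from .modeling import TrainingSet

logger = logging.getLogger(__name__)

__all__ = [
    "ExemplarAssignment",
    "select_exemplars",
    "chemical_percentiles",
    "confirm_high_performance",
    "ks_enrichment",
    "mie_nx",
    "nx_l2fc",
    "compare_cell_lines",
    "paired_rank_comparison",
    "audit_exemplar_exclusion",
]


@dataclass
class ExemplarAssignment:
    """An MIE's training-excluded reference chemical (or None if infeasible)."""

    mie_label: str
    chemical_id: Optional[str]
    support: Optional[int]


def _top_candidates(
    cluster: MIECluster, min_support: int, k: int = 10
) -> list[tuple[str, int]]:
    chems = [(c, s) for c, s in cluster.chemicals.items() if s >= min_support]
    chems.sort(key=lambda cs: (-cs[1], cs[0]))
    return chems[:k]


def select_exemplars(
    clusters: Sequence[MIECluster],
    profile_counts: Mapping[str, int],
    min_chemicals: int = 5,
    min_profiles: int = 50,
    min_support: int = 5,
    top_k: int = 10,
) -> list[ExemplarAssignment]:
    """Iteratively assign exemplar chemicals to modelled MIEs.

    Candidates are the union of each MIE's top ``top_k`` chemicals by
    support.  A chemical is feasible only if excluding all its profiles
    (on top of exemplars already chosen) leaves *every* modelled MIE with
    at least ``min_chemicals`` chemicals and ``min_profiles`` profiles.
    A chemical appearing in several MIEs' candidate lists is assigned to
    all of them at once.  MIEs with no feasible candidate get None.

    MIEs are processed in descending order of their best candidate's
    support (ties by label), a fixed order logged for reproducibility.
    """
    tops = {c.display_name: _top_candidates(c, min_support, top_k) for c in clusters}
    order = sorted(
        clusters,
        key=lambda c: (
            -(tops[c.display_name][0][1] if tops[c.display_name] else 0),
            c.display_name,
        ),
    )
    excluded: set[str] = set()
    assigned: dict[str, ExemplarAssignment] = {}

    def feasible(extra_excluded: set[str]) -> bool:
        gone = excluded | extra_excluded
        for c in clusters:
            chems = c.chemicals_at(min_support) - gone
            if len(chems) < min_chemicals:
                return False
            n_prof = sum(profile_counts.get(chem, 0) for chem in chems)
            if n_prof < min_profiles:
                return False
        return True

    for cluster in order:
        name = cluster.display_name
        if name in assigned:
            continue
        choice: Optional[tuple[str, int]] = None
        for chem, support in tops[name]:
            if chem in excluded:
                continue
            if feasible({chem}):
                choice = (chem, support)
                break
        if choice is None:
            assigned[name] = ExemplarAssignment(name, None, None)
            continue
        chem, _ = choice
        excluded.add(chem)
        logger.info("exemplar %s assigned to %s", chem, name)
        for other in clusters:
            oname = other.display_name
            if oname in assigned:
                continue
            support_here = dict(tops[oname]).get(chem)
            if support_here is not None:
                assigned[oname] = ExemplarAssignment(oname, chem, support_here)
    return [assigned[c.display_name] for c in clusters]


def chemical_percentiles(
    scores: pd.Series,
    meta: pd.DataFrame,
    exclusions: frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Collapse profile scores to per-chemical percentile ranks.

    Profiles of non-chemical perturbagens (null chemical_id) and of excluded
    chemicals (e.g. a classifier's own training chemicals) are dropped; the
    per-chemical median score is ranked (1 = highest median, ties share the
    mean of their ranks) and the percentile is (n - rank) / (n - 1), so the
    top chemical scores 1.0 and the bottom 0.0.
    """
    lookup = meta.set_index("profile_id")["chemical_id"]
    chem = lookup.reindex(scores.index)
    keep = chem.notna() & ~chem.isin(exclusions)
    if keep.sum() == 0:
        raise ValueError("no chemical-linked profiles left after exclusions")
    table = (
        pd.DataFrame({"chemical_id": chem[keep], "score": scores[keep]})
        .groupby("chemical_id")["score"]
        .median()
        .rename("median_score")
        .reset_index()
    )
    n = len(table)
    if n < 2:
        raise ValueError(f"need >= 2 chemicals to rank, got {n}")
    table["rank"] = table["median_score"].rank(ascending=False, method="average")
    table["n_chemicals"] = n
    table["percentile"] = (n - table["rank"]) / (n - 1)
    return table.sort_values("rank", ignore_index=True)


def percentile_from_rank(rank: float, n: int) -> float:
    """Percentile implied by a rank among n chemicals (1 = highest)."""
    if n < 2:
        raise ValueError("need >= 2 chemicals")
    return (n - rank) / (n - 1)


def confirm_high_performance(
    candidates: pd.DataFrame,
    exemplars: Sequence[ExemplarAssignment],
    rank_tables: Mapping[str, pd.DataFrame],
    threshold: float = 0.90,
) -> pd.DataFrame:
    """Confirm candidate classifiers by their exemplar's percentile rank.

    A candidate is confirmed iff its exemplar chemical's percentile is at
    least ``threshold``; candidates without an exemplar pass through with
    status ``"unconfirmable"``.
    """
    by_mie = {e.mie_label: e for e in exemplars}
    rows = []
    for r in candidates.itertuples(index=False):
        exemplar = by_mie.get(r.mie)
        if exemplar is None or exemplar.chemical_id is None:
            rows.append(
                {"mie": r.mie, "exemplar": None, "exemplar_percentile": np.nan,
                 "status": "unconfirmable"}
            )
            continue
        table = rank_tables[r.mie]
        hit = table.loc[table["chemical_id"] == exemplar.chemical_id]
        if hit.empty:
            raise ValueError(
                f"exemplar {exemplar.chemical_id} of {r.mie} absent from its "
                "rank table"
            )
        pct = float(hit["percentile"].iloc[0])
        status = "confirmed" if pct >= threshold else "rejected"
        rows.append(
            {"mie": r.mie, "exemplar": exemplar.chemical_id,
             "exemplar_percentile": pct, "status": status}
        )
    return pd.DataFrame(
        rows, columns=["mie", "exemplar", "exemplar_percentile", "status"]
    )


def ks_enrichment(
    subset_scores: Sequence[float], background_scores: Sequence[float]
) -> tuple[float, float]:
    """One-sided two-sample KS test that the subset scores are higher.

    The statistic is the largest excess of the background ECDF over the
    subset ECDF; small p-values indicate the subset (e.g. moderate-support
    chemicals) is shifted toward higher prediction scores.  Returns
    (statistic, p_value).
    """
    subset = np.asarray(subset_scores, dtype=float)
    background = np.asarray(background_scores, dtype=float)
    if subset.size == 0:
        raise ValueError("subset of scores is empty")
    if background.size <= subset.size:
        raise ValueError("background must be larger than the subset")
    res = stats.ks_2samp(background, subset, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def mie_nx(
    nx: pd.DataFrame, targets: Sequence[str], cell_line: str
) -> float:
    """Representative baseline expression of an MIE in one cell line.

    ``nx`` has columns ``gene, cell_line, nx``; the MIE's value is the
    median NX over its target genes (missing targets are skipped with a
    warning).
    """
    sub = nx[(nx["cell_line"] == cell_line) & nx["gene"].isin(set(targets))]
    found = set(sub["gene"])
    missing = set(targets) - found
    if not found:
        raise ValueError(
            f"no NX values for targets {sorted(targets)} in {cell_line}"
        )
    if missing:
        logger.warning(
            "NX values missing for %s in %s; using %d of %d targets",
            sorted(missing), cell_line, len(found), len(set(targets)),
        )
    return float(sub["nx"].median())


def nx_l2fc(nx_a: float, nx_b: float, pseudocount: float = 0.1) -> float:
    """log2 fold change of baseline expression between two cell lines.

    A pseudocount keeps the ratio defined when a gene is undetectable in
    one line.  Values are never capped here; any +/-4 capping is a plotting
    convention only.
    """
    if nx_a < 0 or nx_b < 0:
        raise ValueError("NX values must be non-negative")
    return float(np.log2((nx_a + pseudocount) / (nx_b + pseudocount)))


def compare_cell_lines(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    suffixes: tuple[str, str] = ("_a", "_b"),
) -> dict:
    """Pair MIE-matched classifier accuracies from two cell lines.

    Inputs are DataFrames with columns ``mie`` and ``internal_accuracy``.
    Returns the inner-joined table (with an accuracy-difference column
    a - b), the Pearson correlation with its two-sided t-test p-value, and
    the least-squares line.
    """
    table = results_a[["mie", "internal_accuracy"]].merge(
        results_b[["mie", "internal_accuracy"]], on="mie", suffixes=suffixes
    )
    if len(table) < 3:
        raise ValueError(
            f"need >= 3 MIEs modelled in both cell lines, got {len(table)}"
        )
    a = table[f"internal_accuracy{suffixes[0]}"].to_numpy()
    b = table[f"internal_accuracy{suffixes[1]}"].to_numpy()
    table["accuracy_difference"] = a - b
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        r, p = np.nan, np.nan
    else:
        r, p = stats.pearsonr(a, b)
    fit = stats.linregress(a, b)
    return {
        "table": table.sort_values("accuracy_difference", ascending=False,
                                   ignore_index=True),
        "pearson_r": float(r),
        "p_value": float(p),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
    }


def paired_rank_comparison(
    accuracies_a: Sequence[float],
    accuracies_b: Sequence[float],
    alternative: str = "two_sided",
) -> float:
    """Paired Wilcoxon signed-rank p-value for MIE-matched accuracy vectors.

    ``alternative="greater"`` tests whether the first vector is shifted
    above the second.  All-zero differences give the degenerate p = 1.
    """
    a = np.asarray(accuracies_a, dtype=float)
    b = np.asarray(accuracies_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need equal-length paired vectors of length >= 5")
    alt = {"two_sided": "two-sided", "greater": "greater"}.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative: {alternative!r}")
    if np.all(a == b):
        return 1.0
    return float(stats.wilcoxon(a, b, alternative=alt).pvalue)


def audit_exemplar_exclusion(
    exemplars: Sequence[ExemplarAssignment],
    training_sets: Sequence[TrainingSet],
    meta: pd.DataFrame,
) -> list[str]:
    """Global audit: no exemplar chemical's profile in any training/holdout set.

    Returns a list of human-readable violations (empty when the exclusion
    is total).  Null-model training sets can be audited by passing them in
    the same list.
    """
    exemplar_chems = {e.chemical_id for e in exemplars if e.chemical_id}
    profile_chem = meta.set_index("profile_id")["chemical_id"]
    violations = []
    for ts in training_sets:
        chems = set(profile_chem.reindex(sorted(ts.all_profiles)).dropna())
        bad = chems & exemplar_chems
        for chem in sorted(bad):
            violations.append(
                f"exemplar chemical {chem} appears in the {ts.mie_label} "
                f"({ts.cell_line}) training set"
            )
    return violations
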