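"""Chemical-protein annotations and molecular initiating event (MIE) labels.

An MIE is the first direct interaction between a chemical and a protein
target, expressed here as a (target gene, mode) pair: activation ``(+)`` or
inhibition ``(-)``.  Annotation records carry a *support level* — the number
of independent literature sources backing the chemical-target-mode link.

This module ingests annotation tables, derives MIE labels, resolves
opposing-mode conflicts, and merges MIEs with near-identical chemical sets
via hierarchical clustering on Jaccard dissimilarity, so that paralogous
targets (e.g. ESR1/ESR2 inhibition) are modelled jointly.
"""

from __future__ import annotations

import logging
import os
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "Mode",
    "ChemProtRecord",
    "MIE",
    "MIECluster",
    "read_annotations",
    "derive_mie_records",
    "build_mies",
    "jaccard",
    "cluster_mies",
    "name_cluster",
    "write_cluster_table",
]


class Mode(str, Enum):
    """Direction of a chemical's action on its target."""

    positive = "+"
    negative = "-"
    unspecified = "unspecified"


_MODE_ALIASES = {
    "+": Mode.positive,
    "positive": Mode.positive,
    "-": Mode.negative,
    "negative": Mode.negative,
    "unspecified": Mode.unspecified,
}


def parse_mode(text: str) -> Mode:
    if isinstance(text, Mode):
        return text
    try:
        return _MODE_ALIASES[str(text).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown mode string: {text!r}") from None


@dataclass(frozen=True)
class ChemProtRecord:
    """One chemical-target-mode annotation with its literature support."""

    chemical_id: str
    target: str
    mode: Mode
    support: int

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError(
                f"support must be >= 1, got {self.support} for "
                f"({self.chemical_id}, {self.target})"
            )


def mie_label(target: str, mode: Mode) -> str:
    """MIE label formed from target gene symbol and mode, e.g. ``"ESR1 (-)"``."""
    if mode is Mode.unspecified:
        raise ValueError("an MIE label cannot carry the unspecified mode")
    return f"{target} ({mode.value})"


def parse_mie_label(label: str) -> tuple[str, Mode]:
    target, _, tail = label.rpartition(" (")
    if not target or not tail.endswith(")"):
        raise ValueError(f"malformed MIE label: {label!r}")
    return target, parse_mode(tail[:-1])


@dataclass
class MIE:
    """A molecular initiating event with its associated chemicals.

    ``chemicals`` maps chemical_id -> support level for the link between the
    chemical and this (target, mode) pair.
    """

    label: str
    mode: Mode
    targets: frozenset[str]
    chemicals: dict[str, int]

    def __post_init__(self) -> None:
        if self.mode is Mode.unspecified:
            raise ValueError("MIE mode must be positive or negative")
        if not self.targets:
            raise ValueError("MIE must name at least one target")
        if not self.chemicals:
            raise ValueError(f"MIE {self.label} has no chemicals")

    def chemicals_at(self, min_support: int) -> frozenset[str]:
        return frozenset(
            c for c, s in self.chemicals.items() if s >= min_support
        )


@dataclass
class MIECluster:
    """A group of MIEs with near-identical chemical sets, modelled jointly."""

    cluster_id: int
    members: frozenset[str]
    mode: Mode
    targets: frozenset[str]
    chemicals: dict[str, int]
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have members")
        if not self.display_name:
            self.display_name = name_cluster(self.members)

    @property
    def combined_chemicals(self) -> frozenset[str]:
        return frozenset(self.chemicals)

    def chemicals_at(self, min_support: int) -> frozenset[str]:
        return frozenset(
            c for c, s in self.chemicals.items() if s >= min_support
        )


# ---------------------------------------------------------------------------
# ingestion


def read_annotations(path) -> list[ChemProtRecord]:
    """Read a chemical-protein annotation TSV.

    Expected header: ``chemical_id  target  mode  support`` with mode encoded
    as ``+`` / ``-`` / ``unspecified``.  Duplicate (chemical, target, mode)
    rows are collapsed keeping the maximum support.
    """
    table = pd.read_csv(path, sep="\t", dtype={"chemical_id": str, "target": str})
    required = {"chemical_id", "target", "mode", "support"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    records: dict[tuple[str, str, Mode], int] = {}
    for i, row in enumerate(table.itertuples(index=False)):
        try:
            mode = parse_mode(row.mode)
        except ValueError as exc:
            raise ValueError(f"row {i + 2} of {path}: {exc}") from None
        key = (row.chemical_id, row.target, mode)
        support = int(row.support)
        records[key] = max(records.get(key, 0), support)
    return [
        ChemProtRecord(chemical_id=c, target=t, mode=m, support=s)
        for (c, t, m), s in records.items()
    ]


def write_annotations(records: Iterable[ChemProtRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "chemical_id": r.chemical_id,
                "target": r.target,
                "mode": r.mode.value,
                "support": r.support,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MIE derivation


def derive_mie_records(
    records: Sequence[ChemProtRecord], min_support: int = 5
) -> pd.DataFrame:
    """Derive per-chemical MIE records from raw annotations.

    Unspecified-mode records are excluded.  When a chemical carries both an
    activation and an inhibition record for the same target, the record with
    the strictly highest support survives; an exact support tie drops both
    records with a warning.  Records below ``min_support`` are retained but
    flagged (``high_support == False``) — they are needed later for the
    moderate-support enrichment validation.

    Returns a DataFrame with columns
    ``chemical_id, target, mode, mie_label, support, high_support``.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    # collapse duplicates keeping max support, drop unspecified
    best: dict[tuple[str, str, Mode], int] = {}
    for r in records:
        if not isinstance(r.mode, Mode):
            raise ValueError(f"record has non-enum mode: {r!r}")
        if r.mode is Mode.unspecified:
            continue
        key = (r.chemical_id, r.target, r.mode)
        best[key] = max(best.get(key, 0), r.support)

    by_pair: dict[tuple[str, str], dict[Mode, int]] = defaultdict(dict)
    for (chem, target, mode), support in best.items():
        by_pair[(chem, target)][mode] = support

    rows = []
    for (chem, target), modes in by_pair.items():
        if len(modes) == 2:
            s_pos = modes[Mode.positive]
            s_neg = modes[Mode.negative]
            if s_pos == s_neg:
                logger.warning(
                    "opposing modes with tied support (%d) for (%s, %s); "
                    "dropping both records",
                    s_pos,
                    chem,
                    target,
                )
                continue
            mode = Mode.positive if s_pos > s_neg else Mode.negative
            support = max(s_pos, s_neg)
        else:
            ((mode, support),) = modes.items()
        rows.append(
            {
                "chemical_id": chem,
                "target": target,
                "mode": mode.value,
                "mie_label": mie_label(target, mode),
                "support": support,
                "high_support": support >= min_support,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "chemical_id",
            "target",
            "mode",
            "mie_label",
            "support",
            "high_support",
        ],
    )
    return out.sort_values(["mie_label", "chemical_id"], ignore_index=True)


def build_mies(mie_records: pd.DataFrame, min_support: int = 5) -> list[MIE]:
    """Group derived MIE records into MIE objects.

    Only chemicals at ``support >= min_support`` define an MIE's chemical set
    (high-confidence links); an MIE whose high-support set is empty is
    dropped.
    """
    mies: list[MIE] = []
    for label, grp in mie_records.groupby("mie_label", sort=True):
        chems = {
            r.chemical_id: int(r.support)
            for r in grp.itertuples(index=False)
            if r.support >= min_support
        }
        if not chems:
            continue
        target, mode = parse_mie_label(label)
        mies.append(
            MIE(label=label, mode=mode, targets=frozenset({target}), chemicals=chems)
        )
    return mies


# ---------------------------------------------------------------------------
# similarity and clustering


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """Jaccard index |A ∩ B| / |A ∪ B| between two chemical sets."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValueError("Jaccard index is undefined for two empty sets")
    return len(a & b) / len(union)


def cluster_mies(
    mies: Sequence[MIE],
    cut_height: float = 0.7,
    method: str = "complete",
) -> list[MIECluster]:
    """Merge MIEs with similar chemical sets by hierarchical clustering.

    Pairwise dissimilarity is 1 - Jaccard index of the chemical sets; the
    dendrogram (default complete linkage) is cut at ``cut_height``.
    Clustering is performed within mode only: a target's activation and
    inhibition are never merged.
    """
    if not mies:
        raise ValueError("need at least one MIE to cluster")
    clusters: list[MIECluster] = []
    next_id = 0
    for mode in (Mode.positive, Mode.negative):
        group = [m for m in mies if m.mode is mode]
        if not group:
            continue
        if len(group) == 1:
            assignment = np.array([1])
        else:
            n = len(group)
            dist = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d = 1.0 - jaccard(group[i].chemicals, group[j].chemicals)
                    dist[i, j] = dist[j, i] = d
            z = linkage(squareform(dist, checks=False), method=method)
            assignment = fcluster(z, t=cut_height, criterion="distance")
        for cid in sorted(set(assignment)):
            members = [group[i] for i in range(len(group)) if assignment[i] == cid]
            chemicals: dict[str, int] = {}
            for m in members:
                for chem, support in m.chemicals.items():
                    chemicals[chem] = max(chemicals.get(chem, 0), support)
            clusters.append(
                MIECluster(
                    cluster_id=next_id,
                    members=frozenset(m.label for m in members),
                    mode=mode,
                    targets=frozenset().union(*(m.targets for m in members)),
                    chemicals=chemicals,
                )
            )
            next_id += 1
    return clusters


def _suffix_sort_key(s: str):
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def name_cluster(members: Iterable[str]) -> str:
    """Deterministic display name for a set of MIE labels sharing one mode.

    Gene families with a shared symbol prefix collapse to
    ``prefix-S1/S2 (mode)`` (e.g. ESR1/ESR2 inhibition -> ``"ESR-1/2 (-)"``);
    otherwise symbols are joined with ``/``.
    """
    parsed = sorted(parse_mie_label(label) for label in set(members))
    if not parsed:
        raise ValueError("cluster has no members")
    modes = {mode for _, mode in parsed}
    if len(modes) > 1:
        raise ValueError(f"cluster mixes modes: {sorted(m.value for m in modes)}")
    mode = modes.pop()
    genes = sorted({gene for gene, _ in parsed})
    if len(genes) == 1:
        stem = genes[0]
    else:
        prefix = os.path.commonprefix(genes)
        suffixes = [g[len(prefix) :] for g in genes]
        if prefix and all(suffixes):
            stem = prefix + "-" + "/".join(sorted(suffixes, key=_suffix_sort_key))
        else:
            stem = "/".join(genes)
    return f"{stem} ({mode.value})"


def write_cluster_table(clusters: Sequence[MIECluster], path) -> None:
    """Write clusters as TSV: cluster_id, display_name, member_labels, chemical_ids."""
    pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "display_name": c.display_name,
                "member_labels": "|".join(sorted(c.members)),
                "chemical_ids": "|".join(sorted(c.chemicals)),
            }
            for c in clusters
        ]
    ).to_csv(path, sep="\t", index=False)
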