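"""Synthetic LINCS-like benchmark data with planted MIE structure.

The generator emits the exact inputs the rest of the package consumes — a
chemical-protein annotation table, an expression matrix (landmark +
inferred features) with profile metadata, gene sets, and a per-cell-line
baseline-expression (NX) table — together with the ground truth needed for
parameter-recovery tests.

The planted structure mirrors the features of real annotation/expression
corpora that the pipeline must cope with: many profiles per chemical (a few
chemicals exceeding the 20-profile cap), a landmark/inferred feature split,
high- and moderate-support annotations, paralog target pairs with
near-identical chemical sets, opposing-mode conflicts, unspecified-mode
records, non-chemical control profiles, and cell-line-dependent
responsiveness.

The signal model is deliberately simple: a treated profile is the sum of
signed gene signatures of the chemical's true MIEs, scaled by effect size
and the cell line's responsiveness multiplier, plus i.i.d. Gaussian noise.
Inferred features are fixed random linear combinations of landmark values
plus extra noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotations import ChemProtRecord, Mode, mie_label, name_cluster, write_annotations
from .pathways import GeneSet, write_gmt
from .profiles import ExpressionMatrix, write_profile_meta

__all__ = ["SimConfig", "SimTruth", "SimulatedDataset", "simulate_annotations",
           "simulate_expression", "simulate_gene_sets", "simulate_dataset",
           "write_dataset"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults describe a desk-scale corpus: 120 chemicals, 8 planted MIEs,
    100 landmark + 200 inferred genes, two cell lines, ~8 profiles per
    chemical per cell line, with one over-the-cap chemical per MIE.
    """

    n_chemicals: int = 120
    n_mies: int = 8
    chemicals_per_mie: int = 8
    n_landmark: int = 100
    n_inferred: int = 200
    genes_per_signature: int = 10
    effect_size: float = 2.0          # signal amplitude, z-score units
    noise_sd: float = 1.0
    inferred_noise_sd: float = 0.5
    profiles_per_chemical_mean: float = 8.0
    heavy_per_mie: int = 1            # chemicals exceeding the 20-profile cap
    heavy_range: tuple[int, int] = (22, 28)
    support_range: tuple[int, int] = (5, 30)
    moderate_per_mie: int = 4         # chemicals annotated only at support 3-4
    fraction_unspecified_mode: float = 0.05
    conflict_count: int = 3           # opposing-mode conflict record pairs
    paralog_pair_count: int = 2
    cell_lines: tuple[str, ...] = ("MCF7like", "PC3like")
    # cell_line -> mie index -> multiplier in [0, 1]; None = all responsive in
    # the first line, MIE 0 silent in the second (the planted cross-cell contrast)
    cell_line_responsiveness: Optional[dict[str, dict[int, float]]] = None
    n_control_profiles: int = 10      # non-chemical perturbagen profiles per line
    n_random_gene_sets: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chemicals, self.n_mies, self.chemicals_per_mie,
               self.n_landmark, self.n_inferred, self.genes_per_signature) < 1:
            raise ValueError("all counts must be positive")
        if self.genes_per_signature > self.n_landmark:
            raise ValueError("more signature genes than landmark genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        n_high = self.n_high_support_chemicals
        n_mod = self.n_mies * self.moderate_per_mie
        if n_high + n_mod > self.n_chemicals:
            raise ValueError(
                f"config needs {n_high + n_mod} annotated chemicals but only "
                f"{self.n_chemicals} exist"
            )
        if self.paralog_pair_count > self.n_mies:
            raise ValueError("more paralog pairs than MIEs")
        for line, by_mie in (self.cell_line_responsiveness or {}).items():
            for m, v in by_mie.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("responsiveness multipliers must be in [0,1]")

    @property
    def n_high_support_chemicals(self) -> int:
        # paralog MIEs get two extra chemicals so a one-chemical difference
        # between the pair still leaves a Jaccard index >= 0.9
        return (
            self.n_mies * self.chemicals_per_mie + 2 * self.paralog_pair_count
        )

    @property
    def tail_probability(self) -> float:
        """Configured fraction of chemicals exceeding the 20-profile cap."""
        return self.n_mies * self.heavy_per_mie / self.n_chemicals

    def responsiveness(self, cell_line: str, mie_index: int) -> float:
        if self.cell_line_responsiveness is not None:
            return self.cell_line_responsiveness.get(cell_line, {}).get(
                mie_index, 1.0
            )
        if cell_line == self.cell_lines[0]:
            return 1.0
        return 0.0 if mie_index == 0 else 1.0


@dataclass
class SimTruth:
    """Planted ground truth: who responds to what, and through which genes."""

    mie_names: list[str]                       # expected cluster display names
    mie_targets: dict[str, list[str]]
    mie_modes: dict[str, str]
    signatures: dict[str, dict[str, float]]    # mie -> gene_id -> signed weight
    chemical_mies: dict[str, list[str]]        # chem -> true signal-carrying MIEs
    high_support_chemicals: dict[str, list[str]]   # mie -> chems at support >= 5
    moderate_chemicals: dict[str, list[str]]       # mie -> chems at support 3-4
    responsiveness: dict[str, dict[str, float]]    # cell_line -> mie -> multiplier


@dataclass
class SimulatedDataset:
    config: SimConfig
    records: list[ChemProtRecord]
    truth: SimTruth
    matrix: ExpressionMatrix
    meta: pd.DataFrame
    mapping: pd.DataFrame          # perturbagen_id -> chemical_id
    nx: pd.DataFrame               # gene, cell_line, nx
    gene_sets: list[GeneSet]


def _landmark_ids(config: SimConfig) -> list[str]:
    return [f"L{i:04d}" for i in range(config.n_landmark)]


def _inferred_ids(config: SimConfig) -> list[str]:
    return [f"I{i:04d}" for i in range(config.n_inferred)]


def simulate_annotations(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[ChemProtRecord], SimTruth]:
    """Generate the annotation table and the planted ground truth.

    Each planted MIE is one signature; paralog MIEs are emitted as two
    target symbols over near-identical chemical sets (Jaccard >= 0.9) so the
    clustering step must merge them back into a single modelling unit.
    """
    chems = [f"CHEM{i:03d}" for i in range(config.n_chemicals)]
    landmark = _landmark_ids(config)

    mie_names: list[str] = []
    mie_targets: dict[str, list[str]] = {}
    mie_modes: dict[str, str] = {}
    signatures: dict[str, dict[str, float]] = {}
    high_chems: dict[str, list[str]] = {}
    moderate_chems: dict[str, list[str]] = {}
    chemical_mies: dict[str, list[str]] = {}
    records: list[ChemProtRecord] = []

    cursor = 0
    lo, hi = config.support_range
    for m in range(config.n_mies):
        is_paralog = m < config.paralog_pair_count
        if is_paralog:
            targets = [f"PRL{m}A", f"PRL{m}B"]
            n_chem = config.chemicals_per_mie + 2
        else:
            targets = [f"TGT{m}"]
            n_chem = config.chemicals_per_mie
        mode = Mode.positive if rng.integers(2) else Mode.negative
        labels = [mie_label(t, mode) for t in targets]
        name = name_cluster(labels)
        mie_names.append(name)
        mie_targets[name] = targets
        mie_modes[name] = mode.value

        genes = rng.choice(config.n_landmark, size=config.genes_per_signature,
                           replace=False)
        signs = rng.choice([-1.0, 1.0], size=config.genes_per_signature)
        signatures[name] = {landmark[g]: float(s) for g, s in zip(genes, signs)}

        members = chems[cursor : cursor + n_chem]
        cursor += n_chem
        high_chems[name] = list(members)
        for chem in members:
            chemical_mies.setdefault(chem, []).append(name)
            support = int(rng.integers(lo, hi + 1))
            records.append(ChemProtRecord(chem, targets[0], mode, support))
            if is_paralog and chem != members[-1]:
                # second paralog target shares all chemicals but one
                records.append(
                    ChemProtRecord(chem, targets[1], mode,
                                   int(rng.integers(lo, hi + 1)))
                )

        mods = chems[
            config.n_high_support_chemicals + m * config.moderate_per_mie :
            config.n_high_support_chemicals + (m + 1) * config.moderate_per_mie
        ]
        moderate_chems[name] = list(mods)
        for chem in mods:
            chemical_mies.setdefault(chem, []).append(name)
            records.append(
                ChemProtRecord(chem, targets[0], mode, int(rng.integers(3, 5)))
            )

    # opposing-mode conflicts: a weaker record with the opposite mode; the
    # derivation step must keep the stronger (true) one
    conflict_pool = [r for r in records if r.support >= lo + 3]
    for i in range(min(config.conflict_count, len(conflict_pool))):
        r = conflict_pool[i]
        flipped = Mode.negative if r.mode is Mode.positive else Mode.positive
        records.append(
            ChemProtRecord(r.chemical_id, r.target, flipped, r.support - 2)
        )

    # unspecified-mode records over decoy targets; excluded by derivation
    n_unspec = int(round(config.fraction_unspecified_mode * len(records)))
    for j in range(n_unspec):
        chem = chems[int(rng.integers(config.n_chemicals))]
        records.append(
            ChemProtRecord(chem, f"UNS{j}", Mode.unspecified,
                           int(rng.integers(1, 11)))
        )

    responsiveness = {
        line: {name: config.responsiveness(line, m)
               for m, name in enumerate(mie_names)}
        for line in config.cell_lines
    }
    truth = SimTruth(
        mie_names=mie_names,
        mie_targets=mie_targets,
        mie_modes=mie_modes,
        signatures=signatures,
        chemical_mies=chemical_mies,
        high_support_chemicals=high_chems,
        moderate_chemicals=moderate_chems,
        responsiveness=responsiveness,
    )
    return records, truth


def _profile_counts(config: SimConfig, rng: np.random.Generator) -> dict[str, int]:
    """Profiles per chemical per cell line; heavy chemicals exceed the cap.

    Heavy status is allocated by quota, one chemical per MIE (round-robin
    over each MIE's first chemicals), so replacement nulls always find a
    volume-matched decoy in another MIE.
    """
    chems = [f"CHEM{i:03d}" for i in range(config.n_chemicals)]
    counts = {}
    for chem in chems:
        n = int(rng.poisson(config.profiles_per_chemical_mean))
        counts[chem] = int(np.clip(n, 1, 20))
    # overwrite the quota of heavy chemicals
    cursor = 0
    for m in range(config.n_mies):
        n_chem = config.chemicals_per_mie + (2 if m < config.paralog_pair_count else 0)
        members = chems[cursor : cursor + n_chem]
        cursor += n_chem
        for h in range(min(config.heavy_per_mie, len(members))):
            lo, hi = config.heavy_range
            counts[members[h]] = int(rng.integers(lo, hi + 1))
    return counts


def simulate_expression(
    config: SimConfig, truth: SimTruth, rng: np.random.Generator
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the expression matrix, profile metadata, mapping and NX table.

    Returns ``(matrix, meta, mapping, nx)``.  Profile values follow the
    additive signature model; control profiles carry a null chemical_id.
    """
    landmark = _landmark_ids(config)
    inferred = _inferred_ids(config)
    gene_index = {g: i for i, g in enumerate(landmark)}
    mie_index = {name: i for i, name in enumerate(truth.mie_names)}

    # fixed linear map from landmark to inferred features
    W = rng.normal(size=(config.n_inferred, config.n_landmark))
    W /= np.sqrt(config.n_landmark)

    sig_vectors = {}
    for name, sig in truth.signatures.items():
        v = np.zeros(config.n_landmark)
        for g, w in sig.items():
            v[gene_index[g]] = w
        sig_vectors[name] = v

    columns: list[np.ndarray] = []
    meta_rows: list[dict] = []
    pid = 0
    for line in config.cell_lines:
        counts = _profile_counts(config, rng)
        for chem in sorted(counts):
            mies = truth.chemical_mies.get(chem, [])
            mean = np.zeros(config.n_landmark)
            for name in mies:
                mult = truth.responsiveness[line][name]
                mean += config.effect_size * mult * sig_vectors[name]
            for _ in range(counts[chem]):
                lm = mean + rng.normal(scale=config.noise_sd,
                                       size=config.n_landmark)
                inf = W @ lm + rng.normal(scale=config.inferred_noise_sd,
                                          size=config.n_inferred)
                columns.append(np.concatenate([lm, inf]))
                meta_rows.append(
                    {
                        "profile_id": f"P{pid:06d}",
                        "perturbagen_id": f"BRD_{chem}",
                        "chemical_id": chem,
                        "cell_line": line,
                        "dose": float(rng.choice([0.1, 1.0, 10.0])),
                        "dose_unit": "uM",
                        "duration_h": float(rng.choice([6.0, 24.0])),
                    }
                )
                pid += 1
        for k in range(config.n_control_profiles):
            lm = rng.normal(scale=config.noise_sd, size=config.n_landmark)
            inf = W @ lm + rng.normal(scale=config.inferred_noise_sd,
                                      size=config.n_inferred)
            columns.append(np.concatenate([lm, inf]))
            meta_rows.append(
                {
                    "profile_id": f"P{pid:06d}",
                    "perturbagen_id": f"CTRL_{line}_{k:03d}",
                    "chemical_id": None,
                    "cell_line": line,
                    "dose": 0.0,
                    "dose_unit": "uM",
                    "duration_h": 24.0,
                }
            )
            pid += 1

    meta = pd.DataFrame(meta_rows)
    data = pd.DataFrame(
        np.column_stack(columns),
        index=landmark + inferred,
        columns=meta["profile_id"].tolist(),
    )
    fclass = pd.Series(
        ["landmark"] * config.n_landmark + ["inferred"] * config.n_inferred,
        index=data.index,
    )
    matrix = ExpressionMatrix(data, fclass)

    mapping = (
        meta.loc[meta["chemical_id"].notna(), ["perturbagen_id", "chemical_id"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )

    # NX baseline expression tracks responsiveness: silent target -> NX 0
    nx_rows = []
    for name in truth.mie_names:
        for line in config.cell_lines:
            mult = truth.responsiveness[line][name]
            for gene in truth.mie_targets[name]:
                nx_rows.append({"gene": gene, "cell_line": line,
                                "nx": round(10.0 * mult, 1)})
    nx = pd.DataFrame(nx_rows)
    return matrix, meta, mapping, nx


def simulate_gene_sets(
    config: SimConfig, truth: SimTruth, rng: np.random.Generator
) -> list[GeneSet]:
    """One gene set per planted signature plus random decoy sets."""
    sets = [
        GeneSet(name=f"SIG_{name.replace(' ', '_')}",
                genes=frozenset(truth.signatures[name]))
        for name in truth.mie_names
    ]
    all_genes = _landmark_ids(config) + _inferred_ids(config)
    for j in range(config.n_random_gene_sets):
        picked = rng.choice(len(all_genes), size=config.genes_per_signature,
                            replace=False)
        sets.append(
            GeneSet(name=f"RANDOM_{j:02d}",
                    genes=frozenset(all_genes[i] for i in picked))
        )
    return sets


def simulate_dataset(config: Optional[SimConfig] = None) -> SimulatedDataset:
    """Generate a full benchmark dataset, bit-identical for a fixed seed."""
    config = config or SimConfig()
    root = np.random.SeedSequence(config.seed)
    ann_rng, expr_rng, sets_rng = (np.random.default_rng(s) for s in root.spawn(3))
    records, truth = simulate_annotations(config, ann_rng)
    matrix, meta, mapping, nx = simulate_expression(config, truth, expr_rng)
    gene_sets = simulate_gene_sets(config, truth, sets_rng)
    return SimulatedDataset(
        config=config, records=records, truth=truth, matrix=matrix,
        meta=meta, mapping=mapping, nx=nx, gene_sets=gene_sets,
    )


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Emit the dataset in the TSV/GMT formats the pipeline consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_annotations(dataset.records, out / "annotations.tsv")
    dataset.matrix.to_tsv(out / "expression.tsv")
    write_profile_meta(dataset.meta, out / "profile_meta.tsv")
    dataset.mapping.to_csv(out / "mapping.tsv", sep="\t", index=False)
    dataset.nx.to_csv(out / "nx.tsv", sep="\t", index=False)
    write_gmt(dataset.gene_sets, out / "gene_sets.gmt")
    with open(out / "truth.json", "w") as fh:
        json.dump(asdict(dataset.truth), fh, indent=1)
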