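import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from miescreen.annotations import MIECluster, Mode
from miescreen.validation import (
    ExemplarAssignment,
    chemical_percentiles,
    compare_cell_lines,
    confirm_high_performance,
    ks_enrichment,
    mie_nx,
    nx_l2fc,
    paired_rank_comparison,
    percentile_from_rank,
    select_exemplars,
)


def cluster(name, chems, mode=Mode.negative):
    return MIECluster(
        cluster_id=0, members=frozenset({name}), mode=mode,
        targets=frozenset({name.split()[0]}), chemicals=dict(chems),
        display_name=name,
    )


class TestSelectExemplars:
    def test_shared_top_chemical_assigned_to_both(self):
        chems_a = {f"a{i}": 10 for i in range(5)} | {"shared": 30}
        chems_b = {f"b{i}": 10 for i in range(5)} | {"shared": 30}
        clusters = [cluster("A (-)", chems_a), cluster("B (-)", chems_b)]
        counts = {c: 10 for c in set(chems_a) | set(chems_b)}
        out = select_exemplars(clusters, counts)
        assert [e.chemical_id for e in out] == ["shared", "shared"]
        assert [e.support for e in out] == [30, 30]

    def test_minimum_size_mie_gets_no_exemplar(self):
        # exactly 5 chemicals: any exclusion violates the chemical floor
        chems = {f"c{i}": 10 for i in range(5)}
        out = select_exemplars([cluster("A (-)", chems)], {c: 20 for c in chems})
        assert out[0].chemical_id is None and out[0].support is None

    def test_profile_floor_blocks_greedy_choice(self):
        # excluding the 30-profile top candidate would leave 48 < 50 profiles,
        # so the next-best feasible candidate is chosen instead
        chems = {"big": 30, **{f"c{i}": 10 + i for i in range(5)}}
        counts = {"big": 30} | {f"c{i}": 9 for i in range(5)}
        out = select_exemplars([cluster("A (-)", chems)], counts)
        assert out[0].chemical_id == "c4"

    def test_cumulative_exclusions_respected(self):
        # after A takes "top", B cannot afford to lose another chemical
        chems_a = {f"s{i}": 10 for i in range(5)} | {"top": 30}
        chems_b = {f"s{i}": 10 for i in range(5)} | {"top": 29}
        clusters = [cluster("A (-)", chems_a), cluster("B (-)", chems_b)]
        counts = {c: 12 for c in set(chems_a) | set(chems_b)}
        out = select_exemplars(clusters, counts)
        # "top" is in both top-10 lists so one pass covers both MIEs
        assert all(e.chemical_id == "top" for e in out)


class TestChemicalPercentiles:
    def make(self, medians, exclusions=frozenset()):
        rows, scores = [], {}
        for i, (chem, med) in enumerate(medians.items()):
            pid = f"p{i}"
            rows.append({"profile_id": pid, "chemical_id": chem,
                         "cell_line": "X"})
            scores[pid] = med
        meta = pd.DataFrame(rows)
        return chemical_percentiles(pd.Series(scores), meta, exclusions)

    def test_rank_and_percentile_bounds(self):
        table = self.make({"a": 0.9, "b": 0.5, "c": 0.1})
        assert list(table["chemical_id"]) == ["a", "b", "c"]
        assert table["percentile"].tolist() == [1.0, 0.5, 0.0]

    def test_ties_share_mean_rank(self):
        table = self.make({"a": 0.9, "b": 0.5, "c": 0.5, "d": 0.1})
        tied = table.loc[table["chemical_id"].isin({"b", "c"}), "rank"]
        assert tied.tolist() == [2.5, 2.5]

    def test_median_over_profiles(self):
        meta = pd.DataFrame(
            {"profile_id": ["p0", "p1", "p2", "p3"],
             "chemical_id": ["a", "a", "a", "b"], "cell_line": "X"}
        )
        scores = pd.Series({"p0": 0.1, "p1": 0.2, "p2": 0.9, "p3": 0.15})
        table = chemical_percentiles(scores, meta)
        a = table.set_index("chemical_id").loc["a", "median_score"]
        assert a == pytest.approx(0.2)

    def test_exclusions_and_non_chemical_profiles_dropped(self):
        meta = pd.DataFrame(
            {"profile_id": ["p0", "p1", "p2", "p3"],
             "chemical_id": ["a", "b", "train", None], "cell_line": "X"}
        )
        scores = pd.Series({"p0": 0.3, "p1": 0.2, "p2": 0.99, "p3": 0.98})
        table = chemical_percentiles(scores, meta, frozenset({"train"}))
        assert set(table["chemical_id"]) == {"a", "b"}

    def test_fewer_than_two_chemicals_errors(self):
        with pytest.raises(ValueError):
            self.make({"a": 0.5})

    @pytest.mark.parametrize(
        "rank, n, expected",
        [(357, 11589, 0.97), (2826, 11666, 0.76), (8838, 11630, 0.24)],
    )
    def test_printed_percentile_convention(self, rank, n, expected):
        assert round(percentile_from_rank(rank, n), 2) == expected


class TestConfirmHighPerformance:
    def run(self, pct):
        candidates = pd.DataFrame({"mie": ["A"]})
        exemplars = [ExemplarAssignment("A", "ex", 12)]
        table = pd.DataFrame(
            {"chemical_id": ["ex", "other"], "median_score": [0.9, 0.1],
             "rank": [1.0, 2.0], "n_chemicals": 2, "percentile": [pct, 0.0]}
        )
        return confirm_high_performance(candidates, exemplars, {"A": table})

    @pytest.mark.parametrize(
        "pct, status",
        [(0.92, "confirmed"), (0.24, "rejected"), (0.90, "confirmed")],
    )
    def test_threshold(self, pct, status):
        assert self.run(pct)["status"].iloc[0] == status

    def test_missing_exemplar_is_unconfirmable(self):
        candidates = pd.DataFrame({"mie": ["A"]})
        out = confirm_high_performance(
            candidates, [ExemplarAssignment("A", None, None)], {}
        )
        assert out["status"].iloc[0] == "unconfirmable"


class TestKsEnrichment:
    def test_top_slice_is_strongly_enriched(self):
        rng = np.random.default_rng(0)
        background = np.sort(rng.normal(size=1000))
        subset = background[-20:]  # the top 5% of background scores
        stat, p = ks_enrichment(subset, background)
        assert p < 0.01 and stat > 0.5

    def test_unshifted_subset_not_flagged(self):
        rng = np.random.default_rng(1)
        background = rng.normal(size=2000)
        subset = rng.normal(size=50)  # same distribution, drawn independently
        _, p = ks_enrichment(subset, background)
        assert p > 0.01

    def test_empty_subset_errors(self):
        with pytest.raises(ValueError):
            ks_enrichment([], [1.0, 2.0])


class TestNx:
    nx = pd.DataFrame(
        {"gene": ["A", "B", "C", "A"], "cell_line": ["X", "X", "X", "Y"],
         "nx": [1.0, 3.0, 5.0, 7.0]}
    )

    def test_median_of_targets(self):
        assert mie_nx(self.nx, ["A", "B", "C"], "X") == 3.0

    def test_single_target_passthrough(self):
        assert mie_nx(self.nx, ["A"], "Y") == 7.0

    def test_missing_target_warns_and_uses_rest(self, caplog):
        with caplog.at_level("WARNING"):
            value = mie_nx(self.nx, ["A", "ZZ"], "X")
        assert value == 1.0 and "missing" in caplog.text

    def test_no_values_errors(self):
        with pytest.raises(ValueError):
            mie_nx(self.nx, ["ZZ"], "X")

    @pytest.mark.parametrize(
        "a, b, expected", [(1.2, 0.0, 3.70), (0.0, 10.5, -6.73), (2.0, 2.0, 0.0)]
    )
    def test_l2fc_worked_examples(self, a, b, expected):
        assert round(nx_l2fc(a, b), 2) == expected

    @given(st.floats(0, 100), st.floats(0, 100))
    def test_l2fc_antisymmetric(self, a, b):
        assert nx_l2fc(a, b) == pytest.approx(-nx_l2fc(b, a), abs=1e-9)

    def test_negative_nx_errors(self):
        with pytest.raises(ValueError):
            nx_l2fc(-0.1, 1.0)


class TestCompareCellLines:
    def frame(self, accs):
        return pd.DataFrame(
            {"mie": [f"m{i}" for i in range(len(accs))],
             "internal_accuracy": accs}
        )

    def test_identical_vectors(self):
        a = self.frame([0.5, 0.7, 0.9, 0.6])
        out = compare_cell_lines(a, a)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(1.0)
        assert out["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_vectors(self):
        a = self.frame([0.2, 0.4, 0.6, 0.8])
        b = self.frame([0.8, 0.6, 0.4, 0.2])
        out = compare_cell_lines(a, b)
        assert out["pearson_r"] == pytest.approx(-1.0)

    def test_accuracy_difference_column(self):
        a = self.frame([0.9, 0.5, 0.7])
        b = self.frame([0.4, 0.5, 0.8])
        out = compare_cell_lines(a, b)
        top = out["table"].iloc[0]
        assert top["mie"] == "m0"
        assert top["accuracy_difference"] == pytest.approx(0.5)

    def test_too_few_shared_mies_errors(self):
        with pytest.raises(ValueError, match=">= 3"):
            compare_cell_lines(self.frame([0.5, 0.6]), self.frame([0.5, 0.6]))


class TestPairedRankComparison:
    def test_identical_vectors_degenerate(self):
        a = [0.5] * 6
        assert paired_rank_comparison(a, a) == 1.0

    def test_uniform_shift_is_significant(self):
        a = np.linspace(0.4, 0.8, 20)
        b = a + 0.1
        assert paired_rank_comparison(a, b, "two_sided") < 0.01

    def test_sign_flip_leaves_two_sided_p_unchanged(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(size=12)
        d = rng.normal(scale=0.1, size=12)
        p1 = paired_rank_comparison(a, a + d, "two_sided")
        p2 = paired_rank_comparison(a, a - d, "two_sided")
        assert p1 == pytest.approx(p2)

    def test_one_sided_direction(self):
        a = np.linspace(0.4, 0.8, 10)
        assert paired_rank_comparison(a + 0.1, a, "greater") < 0.01
        assert paired_rank_comparison(a, a + 0.1, "greater") > 0.9
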