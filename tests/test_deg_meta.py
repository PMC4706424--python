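import numpy as np
import pandas as pd
import pytest

from _oracles import exhaustive_pfp
from conftest import make_study, studies_with_ranks
from metanet import deg_meta as dm
from metanet import synthetic as syn


class TestFoldChanges:
    @pytest.mark.parametrize(
        "tumor,control,expected",
        [((3.0, 3.0), (1.0, 1.0), 4.0), ((2.0, 2.0), (2.0, 2.0), 1.0),
         ((1.0, 1.0), (3.0, 3.0), 0.25)],
    )
    def test_linear_fc_from_log2_class_means(self, tumor, control, expected):
        study = make_study({"A": [*tumor, *control]}, n_tumor=len(tumor))
        assert dm.study_fold_changes(study)["A"] == pytest.approx(expected)

    def test_requires_both_classes(self):
        study = make_study({"A": [1.0, 2.0]}, n_tumor=2)
        with pytest.raises(ValueError, match="control"):
            dm.study_fold_changes(study)


class TestRanking:
    @pytest.mark.parametrize(
        "fcs,direction,expected",
        [
            ((4.0, 1.0, 0.5), "up", (1.0, 2.0, 3.0)),
            ((4.0, 1.0, 0.5), "down", (3.0, 2.0, 1.0)),
            ((2.0, 2.0, 1.0), "up", (1.5, 1.5, 3.0)),
        ],
    )
    def test_rank_within_study(self, fcs, direction, expected):
        fc = pd.Series(fcs, index=["a", "b", "c"])
        assert tuple(dm.rank_within_study(fc, direction)) == expected

    @pytest.mark.parametrize(
        "ranks,expected", [((1, 2, 4), 2.0), ((3, 3, 3), 3.0), ((1, 1), 1.0)]
    )
    def test_rank_product_geometric_mean(self, ranks, expected):
        assert dm.rank_product(ranks) == pytest.approx(expected)

    def test_empty_rank_list_rejected(self):
        with pytest.raises(ValueError):
            dm.rank_product([])


class TestEstimatePfp:
    def test_matches_exhaustive_enumeration_on_three_genes_two_studies(self):
        # all 36 joint permutations of two 3-gene rankings form the exact
        # null; sampled pfp must agree within Monte-Carlo error
        rank_rows = [[1, 2, 3], [3, 1, 2]]
        studies = studies_with_ranks(rank_rows)
        est = dm.estimate_pfp(studies, "up", n_perm=10_000, seed=42)
        exact = exhaustive_pfp(np.array(rank_rows))
        for j, gene in enumerate([f"G{i}" for i in range(3)]):
            assert est.loc[gene, "pfp"] == pytest.approx(exact[j], abs=0.02)

    def test_minimal_rp_gene_has_smallest_pfp(self):
        studies = studies_with_ranks([[1, 2, 3, 4], [1, 3, 2, 4]])
        est = dm.estimate_pfp(studies, "up", n_perm=500, seed=0)
        assert est["pfp"].idxmin() == "G0"
        assert est.loc["G0", "rp"] == pytest.approx(1.0)

    def test_pfp_monotone_along_rp_ordering(self):
        cfg = syn.SimulationConfig(
            n_genes=50, n_studies_per_group=2, samples_per_study=(5, 5), seed=2
        )
        studies = [
            s for s in syn.simulate_expression_studies(cfg)
            if s.platform_group == "I"
        ]
        est = dm.estimate_pfp(studies, "up", n_perm=200, seed=1).sort_values("rp")
        assert (est["pfp"].diff().dropna() >= -1e-12).all()

    def test_too_few_permutations_rejected(self):
        studies = studies_with_ranks([[1, 2], [2, 1]])
        with pytest.raises(ValueError, match="100"):
            dm.estimate_pfp(studies, "up", n_perm=50, seed=0)

    def test_directional_symmetry_on_negated_data(self):
        cfg = syn.SimulationConfig(
            n_genes=40, n_studies_per_group=2, samples_per_study=(6, 4),
            planted_up={0: 2.0}, seed=8,
        )
        studies = [
            s for s in syn.simulate_expression_studies(cfg)
            if s.platform_group == "I"
        ]
        negated = [
            type(s)(s.study_id, s.platform_group, -s.values, s.classes)
            for s in studies
        ]
        up = dm.estimate_pfp(studies, "up", n_perm=200, seed=3)
        down_neg = dm.estimate_pfp(negated, "down", n_perm=200, seed=3)
        pd.testing.assert_frame_equal(up, down_neg)

    def test_rp_invariant_to_study_relabeling(self):
        studies = studies_with_ranks([[1, 2, 3], [2, 3, 1], [3, 1, 2]])
        a = dm.estimate_pfp(studies, "up", n_perm=100, seed=0)["rp"]
        b = dm.estimate_pfp(studies[::-1], "up", n_perm=100, seed=0)["rp"]
        pd.testing.assert_series_equal(a, b)

    def test_gene_in_single_study_reported_unranked(self):
        s1 = make_study({"A": [3, 1], "B": [2, 1], "C": [1, 2]}, 1, "s1")
        s2 = make_study({"A": [3, 1], "B": [2, 1]}, 1, "s2")
        est = dm.estimate_pfp([s1, s2], "up", n_perm=100, seed=0)
        assert est.loc["C", "k"] == 1
        assert np.isnan(est.loc["C", "rp"])
        assert np.isnan(est.loc["C", "pfp"])


class TestCallsAndIntersection:
    def _result(self, rows):
        table = pd.DataFrame(
            rows,
            columns=["rp_up", "pfp_up", "rp_down", "pfp_down", "fc", "k"],
            index=[f"g{i}" for i in range(len(rows))],
        )
        return dm.RankProductResult("I", table, n_perm=100, seed=0)

    @pytest.mark.parametrize(
        "pfp_up,fc,called",
        [(0.005, 2.5, True), (0.005, 1.5, False), (0.005, 2.0, True),
         (0.02, 2.5, False)],
    )
    def test_up_call_thresholds_with_inclusive_fc(self, pfp_up, fc, called):
        res = self._result([[1.0, pfp_up, 9.0, 0.9, fc, 3]])
        assert (("g0" in dm.call_degs(res).up) is called)

    def test_down_call_uses_reciprocal_fc(self):
        res = self._result([[9.0, 0.9, 1.0, 0.005, 0.5, 3]])
        assert dm.call_degs(res).down == {"g0"}

    def test_intersection_requires_same_direction(self):
        a = dm.DEGSet(up={"X", "Y"}, down={"Z"})
        b = dm.DEGSet(up={"X"}, down={"Y", "W"})
        combined = dm.intersect_groups(a, b)
        assert combined.up == {"X"}  # Y flips direction, Z/W unmatched
        assert combined.down == set()

    def test_conflicting_directions_rejected(self):
        with pytest.raises(ValueError, match="both"):
            dm.DEGSet(up={"A"}, down={"A"})


class TestGroupMeta:
    def test_group_fc_is_geometric_mean_across_studies(self):
        s1 = make_study({"A": [4.0, 0.0], "B": [0.0, 0.0]}, 1, "s1")
        s2 = make_study({"A": [1.0, 0.0], "B": [0.0, 0.0]}, 1, "s2")
        res = dm.group_meta([s1, s2], n_perm=100, seed=0)
        # log2 FCs are 4 and 1 -> geometric mean 2^((4+1)/2)
        assert res.table.loc["A", "fc"] == pytest.approx(2 ** 2.5)

    def test_mixed_platform_groups_rejected(self):
        s1 = make_study({"A": [1, 0], "B": [0, 1]}, 1, "s1", group="I")
        s2 = make_study({"A": [1, 0], "B": [0, 1]}, 1, "s2", group="II")
        with pytest.raises(ValueError, match="platform"):
            dm.group_meta([s1, s2], n_perm=100, seed=0)

    def test_planted_signal_called_in_both_groups(self):
        cfg = syn.SimulationConfig(
            n_genes=150, n_studies_per_group=3, samples_per_study=(10, 8),
            planted_up={0: 2.0, 1: 2.0}, planted_down={2: 2.0},
            noise_sd=0.5, seed=13,
        )
        studies = syn.simulate_expression_studies(cfg)
        by_group = {
            g: [s for s in studies if s.platform_group == g] for g in ("I", "II")
        }
        degs = dm.intersect_groups(
            dm.call_degs(dm.group_meta(by_group["I"], 500, 1)),
            dm.call_degs(dm.group_meta(by_group["II"], 500, 7)),
        )
        up_true, down_true = syn.planted_gene_names(cfg)
        assert up_true <= degs.up
        assert down_true <= degs.down
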