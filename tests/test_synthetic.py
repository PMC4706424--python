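import numpy as np
import pandas as pd
import pytest

from metanet import synthetic as syn


def small_cfg(**kw):
    base = dict(
        n_genes=60,
        n_studies_per_group=2,
        samples_per_study=(8, 6),
        noise_sd=0.5,
        batch_sd=1.0,
        seed=11,
    )
    base.update(kw)
    return syn.SimulationConfig(**base)


class TestExpressionSimulator:
    def test_seed_determinism(self):
        cfg = small_cfg(planted_up={0: 1.5})
        a = syn.simulate_expression_studies(cfg)
        b = syn.simulate_expression_studies(cfg)
        for sa, sb in zip(a, b):
            pd.testing.assert_frame_equal(sa.values, sb.values)
            assert sa.study_id == sb.study_id

    def test_planted_effect_recovered_within_standard_error(self):
        # difference of class means has SE = noise_sd*sqrt(1/nt + 1/nc)
        # per study; averaging over all studies shrinks it by sqrt(k)
        effect, noise, nt, nc = 1.5, 0.7, 20, 10
        cfg = small_cfg(
            n_studies_per_group=3,
            samples_per_study=(nt, nc),
            noise_sd=noise,
            planted_up={0: effect},
            seed=5,
        )
        studies = syn.simulate_expression_studies(cfg)
        diffs = []
        for s in studies:
            t = s.values.loc[syn.gene_name(0), s.samples_of("tumor")].mean()
            c = s.values.loc[syn.gene_name(0), s.samples_of("control")].mean()
            diffs.append(t - c)
        se = noise * np.sqrt(1 / nt + 1 / nc) / np.sqrt(len(studies))
        assert abs(np.mean(diffs) - effect) < 3 * se

    def test_batch_offset_cancels_in_within_study_contrast(self):
        cfg = small_cfg(batch_sd=5.0, planted_up={0: 2.0}, seed=9)
        studies = syn.simulate_expression_studies(cfg)
        # huge batch offsets shift whole matrices but not tumor-control diffs
        for s in studies:
            diff = (
                s.values[s.samples_of("tumor")].mean(axis=1)
                - s.values[s.samples_of("control")].mean(axis=1)
            )
            assert abs(diff.drop(syn.gene_name(0)).mean()) < 0.5

    def test_panel_always_contains_planted_genes(self):
        cfg = small_cfg(panel_overlap=0.5, planted_up={3: 1.0}, planted_down={7: 1.0})
        for s in syn.simulate_expression_studies(cfg):
            assert syn.gene_name(3) in s.values.index
            assert syn.gene_name(7) in s.values.index
            assert len(s.values) == 30

    @pytest.mark.parametrize(
        "kw",
        [
            {"samples_per_study": (0, 5)},
            {"planted_up": {999: 1.0}},
            {"panel_overlap": 0.0},
            {"planted_up": {1: np.inf}},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            syn.simulate_expression_studies(small_cfg(**kw))


class TestNetworkSimulator:
    def test_planted_module_density_exceeds_background(self):
        # 8 nodes at p=0.9: Binomial(28, 0.9) rarely drops below
        # 0.3*28 = 8.4 edges (tail probability < 1e-10)
        cfg = syn.NetworkSimConfig(
            n_nodes=60,
            background_degree=1.2,
            planted_modules=[(list(range(8)), 0.9)],
            seed=21,
        )
        G = syn.simulate_network(cfg)
        nodes = [syn.node_name(i) for i in range(8)]
        m = G.subgraph(nodes).number_of_edges()
        assert 2 * m / (8 * 7) >= 0.3

    def test_seed_determinism(self):
        cfg = syn.NetworkSimConfig(n_nodes=40, background_degree=2.0, seed=3)
        assert set(syn.simulate_network(cfg).edges) == set(
            syn.simulate_network(cfg).edges
        )

    def test_zero_nodes_gives_empty_graph(self):
        G = syn.simulate_network(syn.NetworkSimConfig(n_nodes=0))
        assert G.number_of_nodes() == 0

    def test_planted_probability_must_beat_background(self):
        cfg = syn.NetworkSimConfig(
            n_nodes=10,
            background_degree=5.0,
            planted_modules=[([0, 1, 2], 0.3)],
        )
        with pytest.raises(ValueError, match="exceed background"):
            syn.simulate_network(cfg)

    def test_hub_wired_to_targets(self):
        cfg = syn.NetworkSimConfig(
            n_nodes=20,
            background_degree=1.0,
            planted_hub=0,
            hub_targets=list(range(1, 9)),
            seed=4,
        )
        G = syn.simulate_network(cfg)
        assert G.degree(syn.node_name(0)) >= 8


class TestIhcSimulator:
    PARAMS = {
        ("OSCC", "MMP9"): dict(
            intensity_mean=3, intensity_sd=0.0, percent_mean=100, percent_sd=0.0
        ),
        ("NOM", "MMP9"): dict(
            intensity_mean=1, intensity_sd=0.5, percent_mean=20, percent_sd=10.0
        ),
    }

    def test_degenerate_group_gives_maximal_irs(self):
        from metanet.ihc_stats import add_irs

        table = syn.simulate_ihc_cohort(self.PARAMS, {"OSCC": 5, "NOM": 0}, seed=1)
        scored = add_irs(table)
        assert (scored["irs"] == 300.0).all()

    def test_zero_n_group_absent(self):
        table = syn.simulate_ihc_cohort(self.PARAMS, {"OSCC": 3, "NOM": 0}, seed=1)
        assert set(table["group"]) == {"OSCC"}

    def test_seed_determinism(self):
        a = syn.simulate_ihc_cohort(self.PARAMS, {"OSCC": 4, "NOM": 4}, seed=7)
        b = syn.simulate_ihc_cohort(self.PARAMS, {"OSCC": 4, "NOM": 4}, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_sd_rejected(self):
        params = {
            ("NOM", "X"): dict(
                intensity_mean=1, intensity_sd=-1.0, percent_mean=10, percent_sd=1.0
            )
        }
        with pytest.raises(ValueError, match="negative SD"):
            syn.simulate_ihc_cohort(params, {"NOM": 2}, seed=0)

    def test_values_clipped_to_valid_ranges(self):
        params = {
            ("OLK", "X"): dict(
                intensity_mean=3, intensity_sd=5.0, percent_mean=90, percent_sd=50.0
            )
        }
        t = syn.simulate_ihc_cohort(params, {"OLK": 50}, seed=2)
        assert t["intensity"].isin([0, 1, 2, 3]).all()
        assert t["percent_positive"].between(0, 100).all()
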