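"""Yule trees, Brownian traits and process-specific community assembly."""

import numpy as np
import pytest

import phylocascade as pc
from phylocascade.simulate import ScenarioSpec, assemble_community


def split_waiting_times(tree):
    """Interval lengths between successive splits, by lineage count."""
    depths = sorted(
        node.accumulate_to_ancestor(tree)
        for node in tree.non_tips(include_self=True)
        if node.parent is not None
    )
    # the crown (root split) is time 0, when 2 lineages exist; element i of
    # the diff is therefore the waiting time while 2+i lineages existed
    depths = [0.0] + depths
    return np.diff(depths)


class TestSimulateTree:
    def test_two_taxa_is_a_cherry(self):
        tree = pc.simulate_tree(2, seed=0)
        tips = list(tree.tips())
        assert len(tips) == 2
        assert all(t.length > 0 for t in tips)

    @pytest.mark.parametrize("n", [5, 17])
    def test_tip_count_and_unique_labels(self, n):
        tree = pc.simulate_tree(n, seed=3)
        labels = [t.name for t in tree.tips()]
        assert len(labels) == n
        assert len(set(labels)) == n

    def test_deterministic_given_seed(self):
        a = pc.simulate_tree(9, seed=4)
        b = pc.simulate_tree(9, seed=4)
        assert str(a) == str(b)

    def test_all_branch_lengths_positive(self):
        tree = pc.simulate_tree(20, seed=5)
        for node in tree.traverse(include_self=False):
            assert node.length > 0

    def test_waiting_times_match_yule_expectation(self):
        """With birth rate 1, the wait while k lineages exist is Exp(k)."""
        n, reps = 10, 300
        waits = np.array([split_waiting_times(pc.simulate_tree(n, seed=s))
                          for s in range(reps)])
        for k in range(2, n):
            col = waits[:, k - 2]
            mean, se = col.mean(), col.std(ddof=1) / np.sqrt(reps)
            assert abs(mean - 1.0 / k) < 3 * se + 1e-9


class TestEvolveTrait:
    def test_zero_rate_keeps_root_value(self, toy_tree):
        traits = pc.evolve_trait(toy_tree, sigma2=0.0, root_value=1.5, seed=0)
        assert (traits == 1.5).all()

    def test_variance_and_covariance_laws(self, toy_tree):
        # toy tree: A and B at depth 2 sharing a length-1 root edge; C at depth 2
        reps = 1500
        draws = np.array([
            pc.evolve_trait(toy_tree, sigma2=0.7, root_value=0.0, seed=s)[
                ["A", "B", "C"]
            ].to_numpy()
            for s in range(reps)
        ])
        var = draws.var(axis=0, ddof=1)
        se_var = var * np.sqrt(2.0 / (reps - 1))  # SE of a normal variance estimate
        for v, s in zip(var, se_var):
            assert abs(v - 0.7 * 2.0) < 3 * s
        cov_ab = np.cov(draws[:, 0], draws[:, 1], ddof=1)[0, 1]
        assert abs(cov_ab - 0.7 * 1.0) < 4 * np.sqrt(2.0 / (reps - 1)) * 1.4
        cov_ac = np.cov(draws[:, 0], draws[:, 2], ddof=1)[0, 1]
        assert abs(cov_ac) < 0.15  # no shared path


class TestAssembleCommunity:
    def test_output_sums_to_community_size(self):
        pool = np.full(5, 0.2)
        traits = np.linspace(-1, 1, 5)
        out = assemble_community(pool, traits, 0.0, 1.0, 137, rng=3)
        assert out.sum() == 137

    def test_flat_filter_recovers_pool_proportions(self):
        pool = np.array([0.5, 0.3, 0.2])
        draws = np.array([
            assemble_community(pool, np.zeros(3), 0.0, np.inf, 2000, rng=s)
            for s in range(200)
        ])
        props = draws.mean(axis=0) / 2000
        se = np.sqrt(pool * (1 - pool) / (2000 * 200))
        assert (np.abs(props - pool) < 4 * se).all()

    def test_narrow_filter_concentrates_on_nearest_trait(self):
        pool = np.full(4, 0.25)
        traits = np.array([-2.0, -1.0, 0.5, 2.0])
        out = assemble_community(pool, traits, 0.4, 0.01, 500, rng=0)
        assert out[2] == 500

    def test_unreachable_environment_is_error(self):
        pool = np.full(3, 1 / 3)
        traits = np.zeros(3)
        with pytest.raises(pc.InvariantViolation):
            assemble_community(pool, traits, 1e6, 1e-3, 10, rng=0)


class TestScenarios:
    def test_invalid_process_and_selection_without_filter(self):
        with pytest.raises(pc.InputFormatError):
            ScenarioSpec("speciation")
        with pytest.raises(pc.InputFormatError, match="finite filter"):
            ScenarioSpec("selection", filter_width=float("inf"))

    def test_duplicate_pair_control_is_degenerate(self):
        ds = pc.generate_scenario(
            ScenarioSpec("drift", n_taxa=30, community_size=300,
                         duplicate_pair=True, seed=8)
        )
        df = ds.table.to_dataframe()
        np.testing.assert_array_equal(df.loc["A"], df.loc["B"])

    def test_zero_offset_selection_gives_exchangeable_pair(self):
        ds = pc.generate_scenario(
            ScenarioSpec("selection", n_taxa=60, community_size=800,
                         env_offset=0.0, seed=8)
        )
        df = ds.table.to_dataframe()
        # both communities pass the same filter: abundance profiles correlate
        a, b = df.loc["A"].to_numpy(), df.loc["B"].to_numpy()
        r = np.corrcoef(a, b)[0, 1]
        assert r > 0.9

    def test_truth_labels_and_determinism(self):
        for proc in ("selection", "homogenizing_dispersal",
                     "dispersal_limitation", "drift"):
            spec = ScenarioSpec(proc, n_taxa=30, community_size=200, seed=4)
            ds1, ds2 = pc.generate_scenario(spec), pc.generate_scenario(spec)
            assert ds1.truth["process"].iloc[0] == proc
            np.testing.assert_array_equal(ds1.table.counts, ds2.table.counts)
            assert str(ds1.tree) == str(ds2.tree)

    def test_table_taxa_are_tree_tips(self):
        ds = pc.generate_scenario(ScenarioSpec("drift", n_taxa=25,
                                               community_size=200, seed=1))
        tips = {t.name for t in ds.tree.tips()}
        assert set(ds.table.taxon_ids) <= tips


class TestCascadeStudy:
    def test_layout_is_four_by_six(self, cascade_small):
        assert cascade_small.table.n_samples == 24
        meta = cascade_small.metadata.frame
        assert set(meta["reservoir"]) == {"BB", "Pr", "NA", "TI"}
        assert set(meta["event"]) == {"D1", "D2", "D3", "R1", "R2", "R3"}
        assert len(cascade_small.truth) == 18

    def test_trophic_state_monotone_along_cascade(self, cascade_small):
        env = cascade_small.env
        meta = cascade_small.metadata.frame
        for event in meta["event"].unique():
            sids = [f"{r}_{event}" for r in ("BB", "Pr", "NA", "TI")]
            vals = env.loc[sids, "trophic_state"].to_numpy()
            assert (np.diff(vals) < 0).all()

    def test_deterministic_and_round_trips_through_files(self, tmp_path, cascade_small):
        again = pc.generate_cascade_study(seed=5, n_taxa=60, community_size=800)
        np.testing.assert_array_equal(cascade_small.table.counts, again.table.counts)

        pc.write_otu_table(cascade_small.table, tmp_path / "t.tsv")
        pc.write_tree(cascade_small.tree, tmp_path / "tree.nwk")
        pc.write_metadata(cascade_small.metadata, tmp_path / "m.tsv")
        table = pc.read_otu_table(tmp_path / "t.tsv")
        tree = pc.read_tree(tmp_path / "tree.nwk")
        meta = pc.read_metadata(tmp_path / "m.tsv")
        np.testing.assert_allclose(table.counts, cascade_small.table.counts)
        meta.require_samples(table.sample_ids)
        assert {t.name for t in tree.tips()} >= set(table.taxon_ids)
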