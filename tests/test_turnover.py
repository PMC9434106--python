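"""Patristic distances and βMNTD against hand values and independent oracles."""

import shutil
import subprocess

import numpy as np
import pytest

import phylocascade as pc

from conftest import random_table


# -- independent oracles ----------------------------------------------------


def path_walk_distance(tree, a, b):
    """Brute-force patristic distance: climb to the common ancestor."""
    def ancestors(tip):
        chain, node = [], tree.find(tip)
        while node is not None:
            chain.append(node)
            node = node.parent
        return chain

    pa, pb = ancestors(a), ancestors(b)
    common = next(x for x in pa if any(x is y for y in pb))

    def climb(chain):
        total = 0.0
        for node in chain:
            if node is common:
                return total
            total += node.length or 0.0
        raise AssertionError("common ancestor not reached")

    return climb(pa) + climb(pb)


def brute_force_beta_mntd(fa, fb, dist):
    """Direct double loop over taxa implementing the nearest-taxon average."""
    a = [i for i, v in enumerate(fa) if v > 0]
    b = [j for j, v in enumerate(fb) if v > 0]
    term_a = sum(fa[i] * min(dist[i][j] for j in b) for i in a)
    term_b = sum(fb[j] * min(dist[i][j] for i in a) for j in b)
    return 0.5 * (term_a + term_b)


# -- cophenetic -------------------------------------------------------------


class TestCophenetic:
    def test_toy_tree_hand_values(self, toy_dist):
        df = toy_dist.to_dataframe()
        assert df.loc["A", "B"] == 2
        assert df.loc["A", "C"] == 4
        assert df.loc["B", "C"] == 4
        assert (np.diag(toy_dist.distances) == 0).all()

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_path_walker_on_random_trees(self, seed):
        tree = pc.simulate_tree(10, seed=seed)
        dist = pc.cophenetic_distances(tree)
        df = dist.to_dataframe()
        tips = dist.taxon_ids
        for i, a in enumerate(tips):
            for b in tips[i + 1:]:
                assert df.loc[a, b] == pytest.approx(
                    path_walk_distance(tree, a, b), abs=1e-10
                )

    def test_symmetry_and_triangle_inequality(self):
        dist = pc.cophenetic_distances(pc.simulate_tree(8, seed=3))
        d = dist.distances
        np.testing.assert_allclose(d, d.T)
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


# -- relative abundances ----------------------------------------------------


class TestRelativeAbundances:
    def test_examples(self):
        table = pc.OtuTable(["s", "t"], ["a", "b"], [[2, 2], [1, 0]])
        f = pc.relative_abundances(table)
        np.testing.assert_allclose(f, [[0.5, 0.5], [1.0, 0.0]])

    def test_rows_sum_to_one(self, rng):
        f = pc.relative_abundances(random_table(rng, 5, 7))
        np.testing.assert_allclose(f.sum(axis=1), 1.0)

    def test_zero_total_sample_rejected(self):
        table = pc.OtuTable(["s", "z"], ["a", "b"], [[1, 1], [0, 0]])
        with pytest.raises(pc.InvariantViolation, match="'z'"):
            pc.relative_abundances(table)


# -- βMNTD ------------------------------------------------------------------


class TestBetaMntd:
    def test_toy_hand_value(self, toy_dist):
        # A = {tip A: 1.0}; B = {tip B: 0.5, tip C: 0.5}
        table = pc.OtuTable(["x", "y"], ["A", "B", "C"], [[4, 0, 0], [0, 3, 3]])
        bm = pc.beta_mntd(table, toy_dist)
        assert bm.values[0, 1] == pytest.approx(2.5)
        assert bm.values[1, 0] == pytest.approx(2.5)

    def test_identical_communities_have_zero_turnover(self, toy_dist, rng):
        counts = rng.integers(1, 9, size=3).astype(float)
        table = pc.OtuTable(["x", "y"], ["A", "B", "C"], [counts, counts])
        bm = pc.beta_mntd(table, toy_dist)
        assert bm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        tree = pc.simulate_tree(15, seed=seed + 100)
        dist = pc.cophenetic_distances(tree)
        counts = rng.integers(0, 12, size=(4, 15)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1
        table = pc.OtuTable([f"s{i}" for i in range(4)], dist.taxon_ids, counts)
        bm = pc.beta_mntd(table, dist)
        freq = pc.relative_abundances(table)
        d = dist.distances.tolist()
        for i in range(4):
            for j in range(i + 1, 4):
                expected = brute_force_beta_mntd(freq[i].tolist(), freq[j].tolist(), d)
                assert bm.values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_invariances(self, rng):
        tree = pc.simulate_tree(9, seed=42)
        dist = pc.cophenetic_distances(tree)
        counts = rng.integers(0, 10, size=(2, 9)).astype(float)
        counts[:, 0] += 1
        table = pc.OtuTable(["x", "y"], dist.taxon_ids, counts)
        base = pc.beta_mntd(table, dist).values[0, 1]

        # rescaling one sample's abundances by a constant
        scaled = pc.OtuTable(["x", "y"], dist.taxon_ids, counts * [[7.0], [1.0]])
        assert pc.beta_mntd(scaled, dist).values[0, 1] == pytest.approx(base)

        # permuting taxon order (columns and matrix together)
        perm = rng.permutation(9)
        table_p = pc.OtuTable(
            ["x", "y"], [dist.taxon_ids[k] for k in perm], counts[:, perm]
        )
        assert pc.beta_mntd(table_p, dist).values[0, 1] == pytest.approx(base)

        # scaling all branch lengths by c scales βMNTD by c
        dist_scaled = pc.PatristicMatrix(dist.taxon_ids, dist.distances * 3.5)
        assert pc.beta_mntd(table, dist_scaled).values[0, 1] == pytest.approx(3.5 * base)

    def test_shared_taxon_contributes_zero_distance(self, toy_dist):
        # adding to B a taxon already in A cannot increase A-side nearest distances
        table1 = pc.OtuTable(["x", "y"], ["A", "B", "C"], [[2, 0, 0], [0, 1, 1]])
        table2 = pc.OtuTable(["x", "y"], ["A", "B", "C"], [[2, 0, 0], [2, 1, 1]])
        v1 = pc.beta_mntd(table1, toy_dist, abundance_weighted=False).values[0, 1]
        v2 = pc.beta_mntd(table2, toy_dist, abundance_weighted=False).values[0, 1]
        assert v2 <= v1

    def test_empty_community_rejected(self, toy_dist):
        with pytest.raises(pc.InvariantViolation):
            pc.beta_mntd_pair(
                np.array([0.0, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]),
                toy_dist.distances,
            )


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_beta_mntd_matches_picante_comdistnt(tmp_path):
    """Cross-check the weighted βMNTD against picante::comdistnt in R."""
    rng = np.random.default_rng(11)
    tree = pc.simulate_tree(6, seed=2)
    dist = pc.cophenetic_distances(tree)
    counts = rng.integers(0, 8, size=(3, 6)).astype(float)
    counts[:, 0] += 1
    table = pc.OtuTable(["s1", "s2", "s3"], dist.taxon_ids, counts)

    pc.write_tree(tree, tmp_path / "tree.nwk")
    table.to_dataframe().to_csv(tmp_path / "comm.tsv", sep="\t")
    script = tmp_path / "oracle.R"
    script.write_text(
        """
        suppressMessages(library(picante))
        tree <- read.tree(commandArgs(TRUE)[1])
        comm <- as.matrix(read.table(commandArgs(TRUE)[2], header=TRUE,
                                     row.names=1, sep="\t", check.names=FALSE))
        d <- comdistnt(comm, cophenetic(tree), abundance.weighted=TRUE)
        m <- as.matrix(d)
        write.table(m, stdout(), sep="\t", quote=FALSE)
        """
    )
    res = subprocess.run(
        ["Rscript", "--vanilla", str(script), str(tmp_path / "tree.nwk"),
         str(tmp_path / "comm.tsv")],
        capture_output=True, text=True, timeout=300,
    )
    assert res.returncode == 0, res.stderr
    import io

    import pandas as pd

    oracle = pd.read_csv(io.StringIO(res.stdout), sep="\t", index_col=0)
    mine = pc.beta_mntd(table, dist).to_dataframe()
    np.testing.assert_allclose(
        mine.loc[oracle.index, oracle.columns].to_numpy(),
        oracle.to_numpy(),
        atol=1e-8,
    )
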