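"""Diversity, FST, PCA, isolation by distance, distances, and NJ trees."""

import numpy as np
import pandas as pd
import pytest

import paracline as pc
from paracline.popgen import (
    haversine_km,
    hudson_fst_components,
    neighbor_joining,
    to_newick,
    tree_path_lengths,
)
from paracline.variants_io import MISSING

from conftest import env_per_sample
from test_variants_io import make_gm


class TestDiversity:
    def test_single_het_site_pi_hand_value(self):
        # genotypes {0, 2}: 4 chromosomes, p = 0.5 -> pi = (4/3)*2*0.25
        gm = make_gm([[0], [2]])
        s = pc.nucleotide_diversity(gm, [0, 1], n_callable_sites=1)
        assert s.pi_per_site == pytest.approx(4.0 / 3.0 * 0.5)

    def test_monomorphic_data_has_zero_diversity(self):
        gm = make_gm(np.zeros((4, 10), dtype=np.int8))
        s = pc.nucleotide_diversity(gm, range(4), n_callable_sites=10)
        assert s.pi_per_site == 0.0 and s.theta_w_per_site == 0.0

    def test_watterson_theta_hand_value(self):
        # 5 segregating sites among 10 chromosomes, 1000 callable sites:
        # theta = 5 / a_9 / 1000 with a_9 = sum(1/i, i=1..9) = 2.828968...
        calls = np.zeros((5, 5), dtype=np.int8)
        calls[0, :] = 1  # one het sample -> each site segregates
        gm = make_gm(calls)
        s = pc.nucleotide_diversity(gm, range(5), n_callable_sites=1000)
        assert s.n_segregating == 5
        assert s.theta_w_per_site == pytest.approx(5 / 2.828968 / 1000, rel=1e-5)

    def test_zero_callable_sites_rejected(self):
        gm = make_gm([[0], [2]])
        with pytest.raises(ValueError):
            pc.nucleotide_diversity(gm, [0, 1], n_callable_sites=0)

    def test_pi_and_theta_agree_under_neutral_equilibrium_scale(self, ds_default):
        table = pc.diversity_table(
            ds_default.gm, ds_default.samples, n_callable_sites=ds_default.gm.n_sites
        )
        assert (table["pi_per_site"] >= 0).all()
        assert (table["theta_w_per_site"] >= 0).all()


class TestFst:
    def test_fixed_difference_gives_fst_one(self):
        calls = np.vstack([np.zeros((5, 20)), np.full((5, 20), 2)]).astype(np.int8)
        gm = make_gm(calls)
        assert pc.pairwise_fst(gm, range(5), range(5, 10)) == pytest.approx(1.0)

    def test_identical_populations_give_fst_near_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, 10_000)
        calls = rng.binomial(2, p, size=(20, 10_000)).astype(np.int8)
        gm = make_gm(calls)
        assert abs(pc.pairwise_fst(gm, range(10), range(10, 20))) < 0.01

    def test_ratio_of_averages_is_order_and_duplication_invariant(self, ds_default):
        gm = ds_default.gm
        idx_a = np.arange(10)
        idx_b = np.arange(10, 20)
        base = pc.pairwise_fst(gm, idx_a, idx_b)
        perm = np.random.default_rng(1).permutation(gm.n_sites)
        # shuffled site order: reuse components (take_sites requires sorted pos)
        n1, d1 = hudson_fst_components(gm.take_sites(np.arange(gm.n_sites)), idx_a, idx_b)
        doubled = pc.GenotypeMatrix(
            sample_ids=gm.sample_ids,
            sites=pd.DataFrame(
                {
                    "chrom": ["chrZ"] * (2 * gm.n_sites),
                    "pos": np.arange(2 * gm.n_sites) + 1,
                    "ref": "A",
                    "alt": "G",
                }
            ),
            calls=np.concatenate([gm.calls, gm.calls[:, perm]], axis=1),
        )
        assert pc.pairwise_fst(doubled, idx_a, idx_b) == pytest.approx(base, rel=1e-12)
        assert n1 / d1 == pytest.approx(base, rel=1e-12)

    def test_fst_matrix_is_symmetric_with_zero_diagonal(self, ds_default):
        m = pc.fst_matrix(ds_default.gm, ds_default.samples)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0.0)
        assert (m.values <= 1.0).all()


class TestPca:
    def test_pc1_separates_the_two_transect_clades(self, ds_default):
        scores, _ = pc.genetic_pca(ds_default.gm, n_components=2)
        west = ds_default.samples["transect"].to_numpy() == "west"
        pc1 = scores[:, 0]
        # silhouette of the two clusters along PC1
        sep = (
            min(pc1[west].max(), pc1[~west].max())
            < max(pc1[west].min(), pc1[~west].min())
        )
        assert sep  # no overlap between clades on PC1
        a, b = pc1[west], pc1[~west]
        within = (a.std() + b.std()) / 2
        between = abs(a.mean() - b.mean())
        assert between / within > 5

    def test_variance_fractions_are_decreasing_and_bounded(self, ds_default):
        _, frac = pc.genetic_pca(ds_default.gm, n_components=8)
        assert frac.sum() <= 1.0 + 1e-9
        assert np.all(np.diff(frac) <= 1e-12)


class TestIbd:
    def test_haversine_equator_degree(self):
        # one degree of longitude on the equator
        assert haversine_km(0, 0, 0, 1) == pytest.approx(111.19, abs=0.05)

    def fst_frame(self, pops, values):
        m = pd.DataFrame(0.0, index=pops, columns=pops)
        for (a, b), v in values.items():
            m.loc[a, b] = m.loc[b, a] = v
        return m

    def coords(self, pops, lats):
        return pd.DataFrame(
            {"population": pops, "latitude": lats, "longitude": [0.0] * len(pops)}
        )

    def test_linear_fst_gives_perfect_fit(self):
        pops = ["A", "B", "C"]
        coords = self.coords(pops, [0.0, 1.0, 3.0])
        d = {}
        for i, a in enumerate(pops):
            for b in pops[i + 1:]:
                d[(a, b)] = haversine_km(
                    coords.set_index("population").loc[a, "latitude"], 0,
                    coords.set_index("population").loc[b, "latitude"], 0,
                ) * 1e-5
        fst = self.fst_frame(pops, d)
        _, _, r2 = pc.ibd_regression(fst, coords)
        assert r2 == pytest.approx(1.0)

    def test_three_pair_hand_regression(self):
        # distances 100, 200, 300 km and FST 0.01, 0.02, 0.04 -> R^2 = 0.9643
        km_per_deg = haversine_km(0, 0, 1, 0)
        pops = ["A", "B", "C"]
        coords = self.coords(pops, [0.0, 100 / km_per_deg, 300 / km_per_deg])
        fst = self.fst_frame(
            pops, {("A", "B"): 0.01, ("B", "C"): 0.02, ("A", "C"): 0.04}
        )
        _, _, r2 = pc.ibd_regression(fst, coords)
        assert r2 == pytest.approx(0.9643, abs=1e-3)

    def test_identical_coordinates_rejected(self):
        pops = ["A", "B", "C"]
        fst = self.fst_frame(pops, {("A", "B"): 0.1, ("B", "C"): 0.1, ("A", "C"): 0.1})
        with pytest.raises(ValueError):
            pc.ibd_regression(fst, self.coords(pops, [1.0, 1.0, 1.0]))


class TestDistanceMatrix:
    def test_identical_samples_have_zero_distance(self):
        gm = make_gm(np.tile([0, 1, 2], (2, 4)).astype(np.int8))
        d = pc.distance_matrix(gm)
        assert d.iloc[0, 1] == 0.0

    def test_opposite_homozygotes_have_distance_one(self):
        gm = make_gm(np.vstack([np.zeros(6), np.full(6, 2)]).astype(np.int8))
        assert pc.distance_matrix(gm).iloc[0, 1] == 1.0

    def test_het_versus_hom_single_site(self):
        gm = make_gm([[1], [0]])
        assert pc.distance_matrix(gm).iloc[0, 1] == 0.5

    def test_pair_without_shared_sites_rejected(self):
        gm = make_gm([[0, MISSING], [MISSING, 0]])
        with pytest.raises(ValueError):
            pc.distance_matrix(gm)


class TestNeighborJoining:
    ADDITIVE = pd.DataFrame(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        index=list("ABCD"),
        columns=list("ABCD"),
        dtype=float,
    )

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        tree = neighbor_joining(self.ADDITIVE)
        paths = tree_path_lengths(tree)
        assert np.allclose(
            paths.loc[list("ABCD"), list("ABCD")].values, self.ADDITIVE.values,
            atol=1e-9,
        )
        assert frozenset("AB") in tree.bipartitions()

    def test_three_taxa_solve_path_equations(self):
        d = pd.DataFrame(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]],
            index=list("XYZ"), columns=list("XYZ"), dtype=float,
        )
        tree = neighbor_joining(d)
        paths = tree_path_lengths(tree)
        assert np.allclose(paths.loc[list("XYZ"), list("XYZ")].values, d.values)

    def test_taxon_order_permutation_leaves_tree_invariant(self):
        order = ["C", "A", "D", "B"]
        perm = self.ADDITIVE.loc[order, order]
        t1 = neighbor_joining(self.ADDITIVE)
        t2 = neighbor_joining(perm)
        assert t1.bipartitions() == t2.bipartitions()
        p1 = tree_path_lengths(t1).loc[list("ABCD"), list("ABCD")]
        p2 = tree_path_lengths(t2).loc[list("ABCD"), list("ABCD")]
        assert np.allclose(p1.values, p2.values, atol=1e-9)

    def test_random_additive_matrices_reproduced(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = 7
            # random binary tree -> additive matrix via random branch lengths
            import itertools
            leaves = [f"L{i}" for i in range(n)]
            from paracline.popgen import TreeNode, Tree
            nodes = [TreeNode(name=x, length=rng.uniform(0.1, 2.0)) for x in leaves]
            while len(nodes) > 3:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                new = TreeNode(children=[nodes[i], nodes[j]],
                               length=rng.uniform(0.1, 2.0))
                nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
                nodes.append(new)
            true = Tree(root=TreeNode(children=nodes))
            d = tree_path_lengths(true)
            rec = neighbor_joining(d)
            assert np.allclose(
                tree_path_lengths(rec).loc[d.index, d.columns].values,
                d.values, atol=1e-9,
            )

    def test_topology_matches_independent_implementation(self, ds_default):
        biopython = pytest.importorskip("Bio.Phylo.TreeConstruction")
        pops = ds_default.samples["population"].unique()[:6]
        rows = np.flatnonzero(ds_default.samples["population"].isin(pops))[:12]
        gm = ds_default.gm.take_samples(rows)
        d = pc.distance_matrix(gm)
        ours = neighbor_joining(d).bipartitions()
        names = list(d.index)
        lower = [[float(d.iloc[i, j]) for j in range(i + 1)] for i in range(len(names))]
        dm = biopython.DistanceMatrix(names, lower)
        ref_tree = biopython.DistanceTreeConstructor().nj(dm)
        universe = frozenset(names)
        ref = set()
        for cl in ref_tree.get_nonterminals():
            side = frozenset(t.name for t in cl.get_terminals())
            if 2 <= len(side) <= len(universe) - 2:
                from paracline.popgen import _canon
                ref.add(_canon(side, universe))
        assert ours == ref

    def test_asymmetric_matrix_rejected(self):
        bad = self.ADDITIVE.copy()
        bad.iloc[0, 1] = 99.0
        with pytest.raises(ValueError):
            neighbor_joining(bad)


class TestBootstrapAndNewick:
    def test_supports_bounded_and_seed_reproducible(self):
        ds = pc.simulate_dataset(
            pc.SimConfig(seed=21, n_genes=60, samples_per_pop=2)
        )
        t1 = pc.bootstrap_support(ds.gm, n_boot=20, seed=5)
        t2 = pc.bootstrap_support(ds.gm, n_boot=20, seed=5)
        assert to_newick(t1) == to_newick(t2)
        sup = []
        def collect(node):
            if node.support is not None:
                sup.append(node.support)
            for c in node.children:
                collect(c)
        collect(t1.root)
        assert sup and all(0.0 <= s <= 100.0 for s in sup)

    def test_newick_round_trips_through_standard_parser(self, tmp_path):
        dendropy = pytest.importorskip("dendropy")
        tree = neighbor_joining(TestNeighborJoining.ADDITIVE)
        path = tmp_path / "t.nwk"
        pc.write_newick(tree, str(path))
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        assert {x.taxon.label for x in parsed.leaf_node_iter()} == set("ABCD")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        assert pdm.distance(taxa["A"], taxa["B"]) == pytest.approx(3.0, abs=1e-9)
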