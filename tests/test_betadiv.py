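import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from betascape import betadiv, read_newick
from betascape.betadiv import (PairComponents, PhyloPairComponents,
                               dissimilarity_matrix, faith_pd,
                               pair_components, phylo_pair_components,
                               phylosor_total, phylosor_turnover,
                               sorensen_nestedness, sorensen_total,
                               sorensen_turnover)
from conftest import make_community, star_newick


class TestPairComponents:
    @pytest.mark.parametrize("si,sj,expected", [
        ({"A", "B", "C"}, {"B", "C", "D"}, (2, 1, 1)),
        ({"A", "B"}, {"A", "B"}, (2, 0, 0)),
        ({"A"}, {"B", "C"}, (0, 1, 2)),
    ])
    def test_set_counts(self, si, sj, expected):
        comm = make_community([si, sj], sorted(si | sj))
        pc = pair_components(comm, 0, 1)
        assert (pc.a, pc.b, pc.c) == expected

    def test_plot_lookup_by_id_and_error(self):
        comm = make_community([{"A"}, {"B"}], ["A", "B"])
        assert pair_components(comm, "p1", "p2").a == 0
        with pytest.raises(KeyError):
            pair_components(comm, "p1", "nope")


class TestTaxonomicIndices:
    @pytest.mark.parametrize("pc,total,turn", [
        (PairComponents(1, 1, 1), 0.5, 0.5),
        (PairComponents(2, 1, 0), 0.2, 0.0),   # nested pair: pure nestedness
        (PairComponents(3, 0, 0), 0.0, 0.0),
    ])
    def test_printed_examples(self, pc, total, turn):
        assert sorensen_total(pc) == pytest.approx(total)
        assert sorensen_turnover(pc) == pytest.approx(turn)
        assert sorensen_nestedness(pc) == pytest.approx(total - turn)

    def test_empty_pair_undefined(self):
        with pytest.raises(ValueError):
            sorensen_total(PairComponents(0, 0, 0))

    def test_random_tables_match_set_oracle(self):
        rng = np.random.default_rng(7)
        species = [f"s{i}" for i in range(25)]
        plots = oracles.random_community(rng, 12, species)
        comm = make_community(plots, species)
        for i in range(12):
            for j in range(i + 1, 12):
                pc = pair_components(comm, i, j)
                assert sorensen_total(pc) == pytest.approx(
                    oracles.sorensen_oracle(plots[i], plots[j]), abs=1e-12)
                assert sorensen_turnover(pc) == pytest.approx(
                    oracles.turnover_oracle(plots[i], plots[j]), abs=1e-12)

    @given(st.integers(1, 20), st.integers(0, 10), st.integers(0, 10))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_decomposition_nonnegative(self, a, b, c):
        pc = PairComponents(a, b, c)
        tot, turn = sorensen_total(pc), sorensen_turnover(pc)
        assert 0.0 <= turn <= tot <= 1.0

    @given(st.integers(0, 8), st.integers(0, 8), st.integers(1, 8))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_adding_shared_species_never_increases_total(self, b, c, a):
        before = sorensen_total(PairComponents(a, b, c))
        after = sorensen_total(PairComponents(a + 1, b, c))
        assert after <= before + 1e-15


class TestFaithPD:
    def test_path_enumeration_examples(self, balanced4):
        assert faith_pd({"A", "B"}, balanced4) == 3.0
        assert faith_pd({"A"}, balanced4) == 2.0
        assert faith_pd({"A", "B", "C", "D"}, balanced4) == 6.0

    def test_unknown_tip(self, balanced4):
        with pytest.raises(KeyError):
            faith_pd({"Z"}, balanced4)

    def test_matches_edge_enumeration_oracle_small_trees(
            self, balanced4_newick):
        rng = np.random.default_rng(5)
        phy = read_newick(balanced4_newick)
        tips = list(phy.tip_labels)
        for _ in range(30):
            k = int(rng.integers(1, 5))
            subset = set(rng.choice(tips, size=k, replace=False))
            assert faith_pd(subset, phy) == pytest.approx(
                oracles.pd_oracle(subset, balanced4_newick), abs=1e-12)


class TestPhyloIndices:
    def test_disjoint_cherries(self, balanced4):
        comm = make_community([{"A", "B"}, {"C", "D"}], "ABCD")
        ppc = phylo_pair_components(comm, balanced4, 0, 1)
        assert (ppc.pd_i, ppc.pd_j, ppc.pd_tot) == (3.0, 3.0, 6.0)
        assert ppc.a_pd == 0.0
        assert phylosor_total(ppc) == 1.0
        assert phylosor_turnover(ppc) == 1.0

    def test_identical_plots_zero(self, balanced4):
        comm = make_community([{"A", "C"}, {"A", "C"}], "AC")
        ppc = phylo_pair_components(comm, balanced4, 0, 1)
        assert ppc.b_pd == ppc.c_pd == 0.0
        assert ppc.a_pd == ppc.pd_i
        assert phylosor_total(ppc) == 0.0

    def test_sister_singletons_share_stem(self, balanced4):
        comm = make_community([{"A"}, {"B"}], "AB")
        ppc = phylo_pair_components(comm, balanced4, 0, 1)
        assert ppc.pd_tot == 3.0
        assert ppc.a_pd == 1.0  # shared stem branch

    def test_nested_pair_zero_turnover(self, balanced4):
        comm = make_community([{"A", "B"}, {"A"}], "AB")
        ppc = phylo_pair_components(comm, balanced4, 0, 1)
        assert ppc.c_pd == 0.0
        assert phylosor_turnover(ppc) == 0.0

    def test_star_tree_reduces_to_taxonomic(self):
        rng = np.random.default_rng(13)
        species = [f"s{i}" for i in range(10)]
        phy = read_newick(star_newick(species))
        for _ in range(25):
            plots = oracles.random_community(rng, 4, species)
            comm = make_community(plots, species)
            for i in range(4):
                for j in range(i + 1, 4):
                    pc = pair_components(comm, i, j)
                    ppc = phylo_pair_components(comm, phy, i, j)
                    assert phylosor_total(ppc) == pytest.approx(
                        sorensen_total(pc), abs=1e-12)
                    assert phylosor_turnover(ppc) == pytest.approx(
                        sorensen_turnover(pc), abs=1e-12)


class TestDissimilarityMatrix:
    def test_identical_plots_zero_matrix(self, balanced4):
        comm = make_community([{"A", "B"}] * 3, "AB")
        for tag in betadiv.METRIC_TAGS:
            dm = dissimilarity_matrix(comm, tag, balanced4)
            assert (dm.values == 0).all()

    def test_entries_match_per_pair_operations(self, small_synthetic):
        ds = small_synthetic.dataset
        comm, phy = ds.community, ds.phylogeny
        rng = np.random.default_rng(2)
        pairs = [(int(rng.integers(comm.n_plots)),
                  int(rng.integers(comm.n_plots))) for _ in range(12)]
        dm_t = dissimilarity_matrix(comm, "sorensen")
        dm_pt = dissimilarity_matrix(comm, "phylosor_turnover", phy)
        for i, j in pairs:
            if i == j:
                continue
            assert dm_t.values[i, j] == pytest.approx(
                sorensen_total(pair_components(comm, i, j)), abs=1e-12)
            assert dm_pt.values[i, j] == pytest.approx(
                phylosor_turnover(phylo_pair_components(comm, phy, i, j)),
                abs=1e-12)

    def test_missing_phylogeny_rejected(self):
        comm = make_community([{"A"}, {"B"}], "AB")
        with pytest.raises(ValueError, match="phylogeny"):
            dissimilarity_matrix(comm, "phylosor")

    def test_symmetry_and_bounds(self, small_synthetic):
        ds = small_synthetic.dataset
        dm = dissimilarity_matrix(ds.community, "phylosor", ds.phylogeny)
        assert (dm.values == dm.values.T).all()
        assert dm.values.min() >= 0 and dm.values.max() <= 1


class TestMultipleSite:
    def test_matches_direct_enumeration(self):
        rng = np.random.default_rng(21)
        species = [f"s{i}" for i in range(15)]
        plots = oracles.random_community(rng, 6, species)
        comm = make_community(plots, species)
        smin = smax = 0.0
        for i in range(6):
            for j in range(i + 1, 6):
                b = len(plots[i] - plots[j])
                c = len(plots[j] - plots[i])
                smin += min(b, c)
                smax += max(b, c)
        core = sum(len(p) for p in plots) - len(set().union(*plots))
        expected = (smin + smax) / (2 * core + smin + smax)
        assert betadiv.multiple_site_sorensen_turnover(comm) == \
            pytest.approx(expected, abs=1e-12)
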