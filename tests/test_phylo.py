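import numpy as np
import pytest

from slc6kit.align import MultipleAlignment
from slc6kit.phylo import (
    DistanceMatrix,
    SupportedTree,
    bootstrap_support,
    cluster_assignment,
    internal_bipartitions,
    msa_distances,
    nj,
    root_by_outgroup,
    same_topology,
)
from slc6kit.synthetic import FamilyConfig, random_tree, simulate_family


def patristic(st):
    """Taxon-sorted patristic DistanceMatrix of a SupportedTree."""
    pdm = st.tree.phylogenetic_distance_matrix()
    taxa = sorted(st.tree.taxon_namespace, key=lambda t: t.label)
    d = np.array([
        [0.0 if a is b else pdm.patristic_distance(a, b) for b in taxa]
        for a in taxa
    ])
    return DistanceMatrix(tuple(t.label for t in taxa), d)


class TestDistances:
    def test_identical_rows_distance_zero(self):
        msa = MultipleAlignment(("a", "b"), ("MKVL", "MKVL"))
        assert msa_distances(msa, "p_distance").d[0, 1] == 0.0

    def test_p_distance_arithmetic(self):
        row_a = "A" * 100
        row_b = "W" * 5 + "A" * 95
        msa = MultipleAlignment(("a", "b"), (row_a, row_b))
        dm = msa_distances(msa, "p_distance")
        assert dm.d[0, 1] == pytest.approx(0.05)
        corrected = msa_distances(msa, "poisson_corrected")
        assert corrected.d[0, 1] == pytest.approx(-np.log(0.95))

    def test_gap_columns_excluded(self):
        msa = MultipleAlignment(("a", "b"), ("AAW--", "AA-WW"))
        dm = msa_distances(msa, "p_distance")
        assert dm.d[0, 1] == 0.0  # only 2 overlap columns, both identical

    def test_saturated_pair_errors_under_poisson(self):
        msa = MultipleAlignment(("a", "b"), ("AAAA", "WWWW"))
        with pytest.raises(ValueError, match="[Ss]aturated"):
            msa_distances(msa, "poisson_corrected")

    def test_matches_column_scan_oracle(self, rng):
        n, L = 5, 60
        rows = ["".join(rng.choice(list("ACDE-"), size=L)) for _ in range(n)]
        rows = [r if r.strip("-") else "A" * L for r in rows]
        msa = MultipleAlignment(tuple(f"s{i}" for i in range(n)), tuple(rows))
        dm = msa_distances(msa, "p_distance")
        for i in range(n):
            for j in range(i + 1, n):
                pairs = [(x, y) for x, y in zip(rows[i], rows[j])
                         if x != "-" and y != "-"]
                p = sum(x != y for x, y in pairs) / len(pairs)
                assert dm.d[i, j] == pytest.approx(p)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 5.0, 9.0], [5.0, 0.0, 8.0], [9.0, 8.0, 0.0]])
        st = nj(DistanceMatrix(("a", "b", "c"), d))
        lengths = {
            l.taxon.label: l.edge.length for l in st.tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((5 + 9 - 8) / 2)
        assert lengths["b"] == pytest.approx((5 + 8 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 8 - 5) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError):
            nj(DistanceMatrix(("a", "b"), d))

    def test_recovers_known_six_leaf_topology(self):
        newick = ("((A:0.2,B:0.3):0.4,(C:0.25,D:0.15):0.35,"
                  "(E:0.2,F:0.3):0.3);")
        truth = SupportedTree.from_newick(newick)
        rec = nj(patristic(truth))
        assert same_topology(rec, truth)
        # branch lengths of an additive matrix are recovered too
        assert rec.total_length() == pytest.approx(truth.total_length())

    def test_recovers_random_additive_matrices(self):
        for seed in range(20):
            n = 5 + seed % 6
            truth = random_tree(n, seed=seed, length_scale=0.3)
            assert same_topology(nj(patristic(truth)), truth)

    def test_total_length_invariant_under_taxon_reordering(self, rng):
        truth = random_tree(7, seed=42, length_scale=0.4)
        dm = patristic(truth)
        perm = rng.permutation(len(dm.taxa))
        permuted = DistanceMatrix(
            tuple(dm.taxa[k] for k in perm), dm.d[np.ix_(perm, perm)]
        )
        assert nj(dm).total_length() == pytest.approx(
            nj(permuted).total_length()
        )

    def test_branch_lengths_non_negative(self, rng):
        # noisy (non-additive) matrix: clamping must keep lengths >= 0
        truth = random_tree(8, seed=5, length_scale=0.2)
        dm = patristic(truth)
        noisy = dm.d + rng.uniform(0, 0.2, size=dm.d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        st = nj(DistanceMatrix(dm.taxa, noisy))
        assert all(
            (e.length or 0.0) >= 0.0 for e in st.tree.preorder_edge_iter()
        )

    def test_matches_scikit_bio_topology(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        truth = random_tree(7, seed=9, length_scale=0.3)
        dm = patristic(truth)
        sk_tree = sknj(SkDM(dm.d, ids=list(dm.taxa)))
        ref = SupportedTree.from_newick(str(sk_tree))
        assert same_topology(nj(dm), ref)


class TestBootstrap:
    @staticmethod
    def _two_block_msa():
        rows = (
            "A" * 30 + "C" * 30,
            "A" * 30 + "C" * 30,
            "W" * 30 + "C" * 30,
            "W" * 30 + "C" * 30,
            "A" * 30 + "Y" * 30,
            "A" * 30 + "Y" * 30,
        )
        # two families distinguished by disjoint column blocks
        return MultipleAlignment(("a1", "a2", "b1", "b2", "c1", "c2"), rows)

    def test_clean_split_has_full_support(self):
        msa = self._two_block_msa()
        st = bootstrap_support(msa, n_reps=30, seed=1, model="p_distance")
        pair_splits = [
            frozenset(p) for p in (("a1", "a2"), ("b1", "b2"), ("c1", "c2"))
        ]
        for split in pair_splits:
            key = split if "a1" not in split else \
                frozenset(msa.ids) - split
            assert st.supports[key] == pytest.approx(1.0)

    def test_single_rep_supports_are_zero_or_one(self):
        msa = self._two_block_msa()
        st = bootstrap_support(msa, n_reps=1, seed=3, model="p_distance")
        assert set(st.supports.values()) <= {0.0, 1.0}

    def test_supports_invariant_to_taxon_input_order(self, rng):
        records, _ = simulate_family(
            FamilyConfig(n_taxa=6, length=200, seed=13, length_scale=0.2)
        )
        msa = MultipleAlignment.from_records(records)
        perm = list(rng.permutation(msa.n_rows))
        shuffled = MultipleAlignment(
            tuple(msa.ids[k] for k in perm), tuple(msa.rows[k] for k in perm)
        )
        a = bootstrap_support(msa, n_reps=25, seed=7)
        b = bootstrap_support(shuffled, n_reps=25, seed=7)
        assert a.supports == b.supports

    def test_supports_are_proportions(self):
        msa = self._two_block_msa()
        st = bootstrap_support(msa, n_reps=10, seed=0, model="p_distance")
        assert all(0.0 <= v <= 1.0 for v in st.supports.values())


class TestRootingAndAssignment:
    def test_root_on_internal_edge(self):
        st = SupportedTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rooted = root_by_outgroup(st, ["C", "D"])
        children = rooted.tree.seed_node.child_nodes()
        sides = [frozenset(l.taxon.label for l in c.leaf_iter())
                 for c in children]
        assert frozenset({"C", "D"}) in sides
        assert frozenset({"A", "B"}) in sides

    def test_single_leaf_outgroup(self):
        st = SupportedTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rooted = root_by_outgroup(st, ["A"])
        sides = [frozenset(l.taxon.label for l in c.leaf_iter())
                 for c in rooted.tree.seed_node.child_nodes()]
        assert frozenset({"A"}) in sides

    def test_non_monophyletic_outgroup_errors(self):
        st = SupportedTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError, match="monophyletic"):
            root_by_outgroup(st, ["A", "C"])

    def test_rooting_preserves_bipartitions(self):
        truth = random_tree(8, seed=21, length_scale=0.3)
        st = nj(patristic(truth))
        rooted = root_by_outgroup(st, ["T1"])
        assert internal_bipartitions(rooted.tree) == \
            internal_bipartitions(st.tree)

    def test_query_nested_in_single_label_clade(self):
        st = SupportedTree.from_newick(
            "((OG:1,((N1:1,(N2:1,Q:1):1):1,N3:1):1):1,(G1:1,G2:1):1);"
        )
        st.tree.is_rooted = True
        labels = {"OG": "outgroup", "N1": "NAT", "N2": "NAT", "N3": "NAT",
                  "G1": "NTT-GABAT", "G2": "NTT-GABAT", "Q": "query"}
        out = cluster_assignment(st, labels)
        assert out.label == "NAT"
        assert out.is_nested is True
        assert out.sister_taxa == ("N2",)

    def test_query_sister_to_mixed_clade_majority_label(self):
        st = SupportedTree.from_newick(
            "((Q:1,((A1:1,A2:1):1,(A3:1,B1:1):1):1):1,(B2:1,B3:1):1);"
        )
        st.tree.is_rooted = True
        labels = {"A1": "NAT", "A2": "NAT", "A3": "NAT", "B1": "NTT-DAT",
                  "B2": "NTT-DAT", "B3": "NTT-DAT", "Q": "query"}
        out = cluster_assignment(st, labels)
        assert out.label == "NAT"  # 3 NAT vs 1 NTT-DAT in the clade
        assert out.is_nested is False
        assert set(out.sister_taxa) == {"A1", "A2", "A3", "B1"}

    def test_query_missing_or_unlabelled_leaves_error(self):
        st = SupportedTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError):
            cluster_assignment(st, {"A": "NAT", "B": "NAT", "C": "NAT",
                                    "D": "NAT"})
        with pytest.raises(ValueError):
            cluster_assignment(st, {"A": "query", "B": "NAT"})


class TestNewickIO:
    def test_supports_roundtrip(self):
        msa = TestBootstrap._two_block_msa()
        st = bootstrap_support(msa, n_reps=20, seed=2, model="p_distance")
        back = SupportedTree.from_newick(st.newick())
        assert same_topology(st, back)
        for bp, val in back.supports.items():
            assert st.supports[bp] == pytest.approx(val, abs=0.005)

    def test_labels_with_spaces_quoted(self):
        st = SupportedTree.from_newick("(('taxon A':1,B:1):1,(C:1,D:1):1);")
        text = st.newick()
        assert "'taxon A'" in text
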