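import itertools
import math
import random

import dendropy
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pocketphylo.errors import (
    GroupAssignmentError,
    NoComparableColumnsError,
    SaturationError,
)
from pocketphylo.io_formats import AMINO_ACIDS, Msa
from pocketphylo.phylogeny import (
    DistanceMatrix,
    assign_groups,
    bootstrap_support,
    distance_matrix,
    neighbor_joining,
    p_distance,
    pairwise_identity,
    poisson_correct,
    progressive_align,
    robinson_foulds,
    supports_by_clade,
    tree_bipartitions,
)
from pocketphylo.synthetic_data import simulate_family


def random_tree(n, seed):
    taxa = [f"t{i}" for i in range(n)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        taxon_namespace=tns, rng=random.Random(seed),
    )
    rng = np.random.default_rng(seed)
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = float(rng.uniform(0.01, 0.5))
    return tree, tns


def path_distance_matrix(tree, tns):
    pdm = tree.phylogenetic_distance_matrix()
    labels = [t.label for t in tns]
    d = np.array([
        [pdm.distance(tns.get_taxon(a), tns.get_taxon(b)) for b in labels]
        for a in labels
    ])
    return DistanceMatrix(labels, d)


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("AAAA", "AAAA", 0.0), ("AAAA", "AAAT", 0.25), ("A-CD", "ABCD", 0.0)],
    )
    def test_hand_counts(self, a, b, expected):
        assert p_distance(a, b) == expected

    def test_all_gap_columns_error(self):
        with pytest.raises(NoComparableColumnsError):
            p_distance("A---", "-AAA")


class TestPoissonCorrect:
    def test_values(self):
        assert poisson_correct(0.0) == 0.0
        assert poisson_correct(0.5) == pytest.approx(math.log(2), abs=1e-12)

    def test_saturation(self):
        with pytest.raises(SaturationError):
            poisson_correct(0.9999999999)

    def test_strictly_increasing_and_dominates_p(self):
        grid = np.linspace(0.0, 0.95, 60)
        d = [poisson_correct(p) for p in grid]
        assert all(x2 > x1 for x1, x2 in zip(d, d[1:]))
        assert all(x >= p for x, p in zip(d, grid))


class TestDistanceMatrix:
    def test_identical_rows(self):
        msa = Msa(["a", "b"], ["MKVL", "MKVL"])
        dm = distance_matrix(msa)
        assert np.allclose(dm.d, 0.0)

    def test_hand_counted_three_rows(self):
        msa = Msa(["a", "b", "c"], ["AAAA", "AAAT", "ATTT"])
        dm = distance_matrix(msa)
        expected = np.array([
            [0.0, -math.log(0.75), -math.log(0.25)],
            [-math.log(0.75), 0.0, -math.log(0.5)],
            [-math.log(0.25), -math.log(0.5), 0.0],
        ])
        assert np.allclose(dm.d, expected)

    def test_complete_deletion_drops_gapped_columns(self):
        msa = Msa(["a", "b"], ["AK-L", "ATAL"])
        dm = distance_matrix(msa, gap_policy="complete_deletion")
        # 3 kept columns, 1 difference
        assert dm.d[0, 1] == pytest.approx(-math.log(1 - 1 / 3))

    def test_symmetry_random(self, rng):
        base = rng.integers(0, 20, 60)
        rows = []
        for _ in range(6):
            mutated = base.copy()
            sites = rng.random(60) < 0.3
            mutated[sites] = rng.integers(0, 20, int(sites.sum()))
            rows.append("".join(AMINO_ACIDS[j] for j in mutated))
        dm = distance_matrix(Msa([f"s{i}" for i in range(6)], rows))
        assert np.allclose(dm.d, dm.d.T)


def _ls_quartet_fit(d, split):
    """Least-squares edge fit of a quartet topology; returns residual."""
    (a, b), (c, e) = split
    # 5 edges: one pendant per leaf plus the middle edge
    pairs = list(itertools.combinations(range(4), 2))
    rows, rhs = [], []
    for i, j in pairs:
        row = [0.0] * 5
        row[i] = 1.0
        row[j] = 1.0
        if {i, j} not in ({a, b}, {c, e}):
            row[4] = 1.0  # pair spans the middle edge
        rows.append(row)
        rhs.append(d[i, j])
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    resid = np.array(rows) @ sol - np.array(rhs)
    return float(resid @ resid)


class TestNeighborJoining:
    def test_three_leaf_closed_form(self):
        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
        )
        tree = neighbor_joining(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(0.05)
        assert lengths["b"] == pytest.approx(0.15)
        assert lengths["c"] == pytest.approx(0.25)

    def test_quartet_matches_least_squares_oracle(self, rng):
        """NJ picks the same quartet split as brute-force LS topology fit."""
        for trial in range(20):
            tree, tns = random_tree(4, 1000 + trial)
            dm = path_distance_matrix(tree, tns)
            nj = neighbor_joining(dm)
            # oracle: the topology with zero LS residual on additive input
            best = min(
                [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))],
                key=lambda s: _ls_quartet_fit(dm.d, s),
            )
            labels = dm.labels
            want = frozenset({
                frozenset({labels[best[0][0]], labels[best[0][1]]}),
                frozenset({labels[best[1][0]], labels[best[1][1]]}),
            })
            got = tree_bipartitions(nj)
            assert len(got) == 1
            got_split = {frozenset(side) for side in next(iter(got))}
            assert frozenset(got_split) == want

    def test_additivity_recovers_topology(self):
        for trial in range(20):
            n = 6 + trial % 5
            tree, tns = random_tree(n, 2000 + trial)
            nj = neighbor_joining(path_distance_matrix(tree, tns))
            assert robinson_foulds(nj, tree) == 0

    def test_label_permutation_gives_isomorphic_tree(self, rng):
        tree, tns = random_tree(8, 77)
        dm = path_distance_matrix(tree, tns)
        perm = rng.permutation(8)
        dm2 = DistanceMatrix(
            [dm.labels[i] for i in perm], dm.d[np.ix_(perm, perm)]
        )
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(dm2)
        assert tree_bipartitions(t1) == tree_bipartitions(t2)

    def test_matches_reference_nj_implementation(self):
        """Cross-check topology against scikit-bio's neighbour joining."""
        import skbio

        from pocketphylo.io_formats import read_newick

        for trial in range(5):
            tree, tns = random_tree(7, 3000 + trial)
            dm = path_distance_matrix(tree, tns)
            ours = neighbor_joining(dm)
            sk_tree = skbio.tree.nj(
                skbio.DistanceMatrix(dm.d, ids=dm.labels)
            )
            theirs = read_newick(str(sk_tree), is_string=True)
            assert tree_bipartitions(ours) == tree_bipartitions(theirs)

    def test_requires_three_labels(self):
        from pocketphylo.errors import TreeError

        with pytest.raises(TreeError):
            neighbor_joining(
                DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]]))
            )


@pytest.fixture(scope="module")
def clade_msa():
    tree = dendropy.Tree.get(
        data="((a1:0.02,a2:0.02):0.3,(b1:0.02,b2:0.02):0.3,"
             "((c1:0.02,c2:0.02):0.3,(d1:0.02,d2:0.02):0.3):0.3);",
        schema="newick", preserve_underscores=True,
    )
    _, msa = simulate_family(tree, 500, rates=1.0, seed=5)
    return msa


class TestBootstrap:
    def test_clear_clades_high_support(self, clade_msa):
        tree = bootstrap_support(clade_msa, 50, seed=9)
        supports = supports_by_clade(tree)
        assert supports and all(v >= 0.95 for v in supports.values())

    def test_single_replicate_supports_are_binary(self, clade_msa):
        tree = bootstrap_support(clade_msa, 1, seed=4)
        assert set(supports_by_clade(tree).values()) <= {0.0, 1.0}

    def test_same_seed_reproducible(self, clade_msa):
        s1 = supports_by_clade(bootstrap_support(clade_msa, 20, seed=3))
        s2 = supports_by_clade(bootstrap_support(clade_msa, 20, seed=3))
        assert s1 == s2

    def test_column_permutation_invariance(self, clade_msa, rng):
        perm = rng.permutation(clade_msa.n_columns)
        shuffled = Msa(
            list(clade_msa.sequence_ids),
            ["".join(row[i] for i in perm) for row in clade_msa.rows],
        )
        s1 = supports_by_clade(bootstrap_support(clade_msa, 20, seed=3))
        s2 = supports_by_clade(bootstrap_support(shuffled, 20, seed=3))
        assert s1 == s2

    def test_replicate_count_validated(self, clade_msa):
        with pytest.raises(ValueError):
            bootstrap_support(clade_msa, 0, seed=1)


class TestAssignGroups:
    def test_two_clades_of_four(self):
        tree = dendropy.Tree.get(
            data="(((a1:0.1,a2:0.1):0.1,(a3:0.1,a4:0.1):0.1):0.5,"
                 "((b1:0.1,b2:0.1):0.1,(b3:0.1,b4:0.1):0.1):0.5);",
            schema="newick", preserve_underscores=True,
        )
        out = assign_groups(tree, {"A": ["a1"], "B": ["b1"]})
        assert out == {f"a{i}": "A" for i in range(1, 5)} | {
            f"b{i}": "B" for i in range(1, 5)
        }

    def test_every_leaf_its_own_group(self):
        tree = dendropy.Tree.get(
            data="((x:0.1,y:0.1):0.1,z:0.2);", schema="newick",
            preserve_underscores=True,
        )
        out = assign_groups(tree, {"gx": ["x"], "gy": ["y"], "gz": ["z"]})
        assert out == {"x": "gx", "y": "gy", "z": "gz"}

    def test_interleaved_seeds_error(self):
        tree = dendropy.Tree.get(
            data="(((a1:0.1,b1:0.1):0.1,(a2:0.1,b2:0.1):0.1):0.3,c:0.4);",
            schema="newick", preserve_underscores=True,
        )
        with pytest.raises(GroupAssignmentError):
            assign_groups(tree, {"A": ["a1", "a2"], "B": ["b1", "b2"]})

    def test_unseeded_outlier_is_unassigned(self):
        tree = dendropy.Tree.get(
            data="(((a1:0.1,a2:0.1):0.1,(b1:0.1,b2:0.1):0.1):0.3,far:2.0);",
            schema="newick", preserve_underscores=True,
        )
        out = assign_groups(tree, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert out["far"] == "unassigned"


class TestProgressiveAlign:
    def test_identical_sequences_gap_free(self):
        msa = progressive_align([("a", "MKVL"), ("b", "MKVL"), ("c", "MKVL")])
        assert msa.rows == ["MKVL"] * 3

    def test_two_sequences_single_mismatch_column(self):
        msa = progressive_align([("a", "MKV"), ("b", "MAV")])
        assert msa.n_columns == 3
        assert msa.rows == ["MKV", "MAV"]

    def test_gap_placement(self):
        msa = progressive_align([("a", "MKVLL"), ("b", "MKVILL")])
        assert msa.ungapped("a") == "MKVLL"
        assert msa.ungapped("b") == "MKVILL"
        assert msa.n_columns == 6

    @given(
        st.lists(
            st.text(alphabet="ACDEFG", min_size=3, max_size=12),
            min_size=2, max_size=5,
        )
    )
    def test_rows_degap_to_inputs(self, seqs):
        records = [(f"s{i}", s) for i, s in enumerate(seqs)]
        msa = progressive_align(records)
        for sid, seq in records:
            assert msa.ungapped(sid) == seq

    def test_pairwise_identity_bounds(self):
        assert pairwise_identity("MKV", "MKV") == 1.0
        assert 0.0 <= pairwise_identity("MKV", "WWW") <= 1.0
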