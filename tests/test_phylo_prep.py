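import itertools

import dendropy
import numpy as np
import pytest

from mitochar.phylo_prep import (
    SuperMatrix,
    TrimRules,
    build_supermatrix,
    neighbor_joining,
    nj_tree,
    p_distance_matrix,
    trim_blocks,
)
from mitochar.synthetic_data import simulate_alignment


def _tree_distances(newick, labels):
    tns = dendropy.TaxonNamespace()
    t = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
    pdm = t.phylogenetic_distance_matrix()
    taxa = {x.label: x for x in tns}
    n = len(labels)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return D


def _rf(nwk1, nwk2):
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


class TestBuildSupermatrix:
    def test_concatenation_and_partitions(self):
        genes = {
            "g1": {t: "A" * 30 for t in "ABCD"},
            "g2": {t: "C" * 60 for t in "ABCD"},
        }
        m = build_supermatrix(genes)
        assert m.n_columns == 90
        assert m.partitions == {"g1": (1, 30), "g2": (31, 90)}

    def test_missing_taxon_gap_padded(self):
        genes = {
            "g1": {"A": "ACGT", "B": "ACGT"},
            "g2": {"A": "GGGG"},
        }
        with pytest.warns(UserWarning, match="gap-padded"):
            m = build_supermatrix(genes)
        assert m.row("B") == "ACGT----"

    def test_duplicate_taxa_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SuperMatrix(taxa=["A", "A"], alignment=["AC", "AC"], partitions={})

    def test_ragged_rows_rejected(self):
        with pytest.raises(ValueError):
            SuperMatrix(taxa=["A", "B"], alignment=["AC", "ACG"], partitions={})


def _random_matrix(rng, n_taxa=6, width=80, noise_cols=0):
    taxa = [f"t{i}" for i in range(n_taxa)]
    base = rng.choice(list("ACGT"), size=width)
    rows = {}
    for t in taxa:
        row = base.copy()
        flip = rng.random(width) < 0.05
        row[flip] = rng.choice(list("ACGT"), size=int(flip.sum()))
        rows[t] = "".join(row)
    return build_supermatrix({"g": rows})


class TestTrimBlocks:
    def test_conserved_gapless_matrix_unchanged(self):
        m = build_supermatrix({"g": {t: "ACGT" * 10 for t in "ABCD"}})
        out = trim_blocks(m)
        assert out.alignment == m.alignment

    def test_gappy_column_removed(self):
        rows = {"A": "A" * 20, "B": "A" * 20, "C": "A" * 20, "D": "A" * 20}
        rows["A"] = "-" + rows["A"][1:]
        rows["B"] = "-" + rows["B"][1:]
        rows["C"] = "-" + rows["C"][1:]  # column 1: 75% gaps
        m = build_supermatrix({"g": rows})
        out = trim_blocks(m, TrimRules(max_gap_fraction=0.5))
        assert out.n_columns == 19

    def test_planted_ambiguous_columns_removed(self):
        rng = np.random.default_rng(4)
        width, n = 120, 8
        taxa = [f"t{i}" for i in range(n)]
        base = rng.choice(list("ACGT"), size=width)
        noisy = set(rng.choice(width, size=12, replace=False))
        rows = {}
        for k, t in enumerate(taxa):
            row = [
                rng.choice(list("ACGT")) if j in noisy else base[j]
                for j in range(width)
            ]
            rows[t] = "".join(row)
        # force true ambiguity: make every taxon differ in noisy columns
        for j in noisy:
            for k, t in enumerate(taxa):
                rows[t] = rows[t][:j] + "ACGT"[k % 4] + rows[t][j + 1 :]
        m = build_supermatrix({"g": rows})
        out = trim_blocks(m, TrimRules(min_conserved_fraction=0.6, min_block_length=2))
        kept_cols = set(zip(*out.alignment))
        for j in noisy:
            col = tuple(rows[t][j] for t in taxa)
            assert col not in kept_cols

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = _random_matrix(rng)
        once = trim_blocks(m)
        twice = trim_blocks(once)
        assert once.alignment == twice.alignment

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(1)
        g1 = {f"t{i}": "".join(rng.choice(list("ACGT"), 40)) for i in range(4)}
        g2 = {f"t{i}": "".join(rng.choice(list("ACGT"), 50)) for i in range(4)}
        m12 = trim_blocks(build_supermatrix({"g1": g1, "g2": g2}))
        m21 = trim_blocks(build_supermatrix({"g2": g2, "g1": g1}))
        cols = lambda m: sorted(zip(*m.alignment))
        assert cols(m12) == cols(m21)

    def test_all_removed_warns(self):
        m = build_supermatrix({"g": {"A": "ACGT", "B": "TGCA", "C": "GATC", "D": "CTAG"}})
        with pytest.warns(UserWarning, match="all columns"):
            out = trim_blocks(m)
        assert out.n_columns == 0


class TestNeighborJoining:
    def test_three_taxa(self):
        D = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        nwk = neighbor_joining(D, ["A", "B", "C"])
        got = _tree_distances(nwk, ["A", "B", "C"])
        assert np.allclose(got, D)

    def test_four_taxon_additive_topology_by_brute_force(self):
        # distances additive on ((A,B),(C,D)); brute force over the three
        # unrooted quartets via the four-point condition
        D = np.array(
            [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]], float
        )
        sums = {
            "AB|CD": D[0, 1] + D[2, 3],
            "AC|BD": D[0, 2] + D[1, 3],
            "AD|BC": D[0, 3] + D[1, 2],
        }
        expected_split = min(sums, key=sums.get)
        assert expected_split == "AB|CD"
        nwk = neighbor_joining(D, ["A", "B", "C", "D"])
        assert _rf(nwk, "((A,B),(C,D));") == 0
        assert np.allclose(_tree_distances(nwk, list("ABCD")), D)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_random_additive_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        labels = [f"t{i}" for i in range(n)]
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=n,
            rng=__import__("random").Random(seed),
        )
        for i, leaf in enumerate(tree.leaf_node_iter()):
            leaf.taxon.label = labels[i]
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = float(rng.uniform(0.1, 1.0))
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in tree.taxon_namespace}
        D = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
        nwk = neighbor_joining(D, labels)
        assert np.allclose(_tree_distances(nwk, labels), D, atol=1e-8)

    def test_identical_sequences_zero_branches(self):
        m = build_supermatrix({"g": {t: "ACGTACGT" for t in "ABC"}})
        nwk = nj_tree(m)
        assert nwk.endswith(";")
        assert _tree_distances(nwk, list("ABC")).max() == 0

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["A", "B"])


class TestPDistance:
    def test_pairwise_deletion(self):
        m = SuperMatrix(
            taxa=["A", "B"], alignment=["AC-T", "AG-T"], partitions={"g": (1, 4)}
        )
        D = p_distance_matrix(m)
        assert D[0, 1] == pytest.approx(1 / 3)


def test_simulated_eight_taxon_topology_recovered():
    tree = (
        "((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05,"
        "((E:0.05,F:0.05):0.05,(G:0.05,H:0.05):0.05):0.05);"
    )
    aln = simulate_alignment(tree, rate=1.0, seed=7)
    est = nj_tree(build_supermatrix(aln))
    assert _rf(tree, est) == 0
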