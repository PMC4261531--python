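import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kallima import synthdata
from kallima.treeio import (
    POLYMORPHIC,
    CharacterMatrix,
    DEFAULT_CODEBOOK,
    MatrixParseError,
    Tree,
    TreeParseError,
    TreeSample,
    find_mrca,
    parse_newick,
    read_character_matrix,
    read_tree_sample,
    scale_branch_lengths,
    subsample_trees,
    write_character_matrix,
    write_tree_sample,
)


class TestParseNewick:
    def test_three_leaf_structure(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        assert t.n_leaves == 3
        assert len(t.children[t.root]) == 2
        assert t.taxon_set == {"A", "B", "C"}

    def test_single_leaf_accepted(self):
        t = parse_newick("(A:1);")
        assert t.taxon_set == {"A"}

    def test_malformed_parentheses(self):
        with pytest.raises(TreeParseError):
            parse_newick("((A:1,B:1:1,C:2);")

    def test_duplicate_leaf_labels(self):
        with pytest.raises(TreeParseError, match="duplicate"):
            parse_newick("((A:1,A:1):1,C:2);")

    def test_negative_branch_length_names_value(self):
        with pytest.raises(TreeParseError, match="-1"):
            parse_newick("((A:1,B:-1):1,C:2);")

    def test_explicitly_unrooted_rejected(self):
        with pytest.raises(TreeParseError, match="unrooted"):
            parse_newick("[&U] ((A:1,B:1):1,C:2);")

    @pytest.mark.parametrize("seed", range(10))
    def test_roundtrip_random_yule_trees(self, seed):
        # ten random pure-birth trees of varied size; 100 total trips would be
        # slow for no extra power, the property is per-tree anyway
        n = 5 + seed * 4
        t = synthdata.simulate_yule_tree(n, 1.0, seed=seed)
        t2 = parse_newick(t.to_newick())
        t3 = parse_newick(t2.to_newick())
        assert t2.taxon_set == t.taxon_set
        # same topology: identical clade sets; same lengths to 1e-12 relative
        def clades(tree):
            return {
                tree.leaf_set(i): tree.blen[i]
                for i in range(tree.n_nodes)
                if tree.parent[i] >= 0
            }
        c1, c2, c3 = clades(t), clades(t2), clades(t3)
        assert set(c1) == set(c2) == set(c3)
        for k in c1:
            assert c1[k] == pytest.approx(c2[k], rel=1e-12)
            assert c2[k] == pytest.approx(c3[k], rel=1e-12)


class TestTreeSample:
    def test_nexus_with_translate(self, tmp_path):
        nex = """#NEXUS
BEGIN TREES;
    TRANSLATE 1 SpecA, 2 SpecB, 3 SpecC;
    TREE t1 = [&R] ((1:1,2:1):1,3:2);
    TREE t2 = [&R] ((1:2,3:1):1,2:2);
    TREE t3 = [&R] ((2:1,3:1):1,1:2);
END;
"""
        p = tmp_path / "trees.nex"
        p.write_text(nex)
        sample = read_tree_sample(p, format="nexus")
        assert len(sample) == 3
        assert sample.taxon_set == {"SpecA", "SpecB", "SpecC"}

    def test_newick_lines_single_tree(self, tmp_path):
        p = tmp_path / "one.nwk"
        p.write_text("((A:1,B:1):1,C:2);\n")
        assert len(read_tree_sample(p, format="newick-lines")) == 1

    def test_mismatched_taxa_lists_difference(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A:1,B:1):1,C:2);\n((A:1,B:1):1,D:2);\n")
        with pytest.raises(TreeParseError, match="C.*D|D.*C"):
            read_tree_sample(p, format="newick-lines")

    def test_write_read_roundtrip(self, tmp_path):
        trees = [synthdata.simulate_yule_tree(6, 1.0, seed=s) for s in range(3)]
        # same seed means same labels; different seeds differ in topology only
        trees = TreeSample([trees[0]] * 2 + [trees[0]])
        for fmt in ("newick-lines", "nexus"):
            p = tmp_path / f"s.{fmt}"
            write_tree_sample(trees, p, format=fmt)
            back = read_tree_sample(p, format=fmt)
            assert len(back) == 3
            assert back.taxon_set == trees.taxon_set


class TestCharacterMatrix:
    def test_tsv_with_polymorphic_cell(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("taxon\tCh1\tCh2\nA\t0\t1\nB\t0/1\t0\nC\t1\t1\n")
        m = read_character_matrix(p)
        assert m.n_taxa == 3 and m.n_characters == 2
        assert m.cell("B", "Ch1") == POLYMORPHIC
        assert m.cell("A", "Ch2") == 1

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(MatrixParseError):
            read_character_matrix(p)

    def test_unknown_code_names_row_and_column(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("taxon\tCh1\nA\t2\n")
        with pytest.raises(MatrixParseError, match="'A'.*'Ch1'"):
            read_character_matrix(p)

    def test_roundtrip(self, tmp_path):
        codes = np.array([[0, 1], [POLYMORPHIC, 0], [1, 1]], dtype=np.int8)
        m = CharacterMatrix(["A", "B", "C"], ["Ch1", "Ch2"], codes)
        p = tmp_path / "m.tsv"
        write_character_matrix(m, p)
        assert read_character_matrix(p) == m

    def test_nexus_characters_block(self, tmp_path):
        nex = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=3 NCHAR=2;
FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;
MATRIX
A 01
B (01)0
C 11
;
END;
"""
        p = tmp_path / "m.nex"
        p.write_text(nex)
        m = read_character_matrix(p, format="nexus")
        assert m.cell("B", "Ch1") == POLYMORPHIC
        assert m.cell("A", "Ch1") == 0


class TestFindMrca:
    def test_cherry(self, small_tree):
        node = find_mrca(small_tree, {"A", "B"})
        assert small_tree.leaf_set(node) == {"A", "B"}

    def test_minimal_containing_node_includes_extra(self, small_tree):
        # the exact clade {A, C} does not exist: the minimal containing node
        # is the root, which also subtends B
        assert find_mrca(small_tree, {"A", "C"}) == small_tree.root

    def test_single_taxon_is_the_leaf(self, small_tree):
        node = find_mrca(small_tree, {"A"})
        assert small_tree.labels[node] == "A"

    def test_absent_taxon_named(self, small_tree):
        with pytest.raises(KeyError, match="ZZZ"):
            find_mrca(small_tree, {"A", "ZZZ"})

    def test_invariant_to_child_rotation(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_newick("((D:1,C:1):1,(B:1,A:1):1);")
        for taxa in ({"A", "B"}, {"C", "D"}, {"A", "D"}):
            assert t1.leaf_set(find_mrca(t1, taxa)) == t2.leaf_set(find_mrca(t2, taxa))


class TestSubsample:
    def test_full_size_is_permutation(self, single_tree_sample):
        t = synthdata.simulate_yule_tree(5, 1.0, seed=0)
        sample = TreeSample([t] * 4)
        out = subsample_trees(sample, 4, seed=0)
        assert len(out) == 4

    def test_same_seed_identical(self):
        trees = TreeSample([synthdata.simulate_yule_tree(5, 1.0, seed=0)] * 10)
        a = subsample_trees(trees, 3, seed=7)
        b = subsample_trees(trees, 3, seed=7)
        assert [id(x) for x in a.trees] == [id(x) for x in b.trees]

    def test_oversample_errors(self):
        trees = TreeSample([synthdata.simulate_yule_tree(5, 1.0, seed=0)])
        with pytest.raises(ValueError):
            subsample_trees(trees, 2, seed=0)

    def test_uniformity_over_draws(self):
        base = synthdata.simulate_yule_tree(4, 1.0, seed=0)
        trees = [base.copy() for _ in range(10)]  # distinct objects, same tree
        sample = TreeSample(trees)
        index = {id(t): i for i, t in enumerate(trees)}
        counts = np.zeros(10)
        for s in range(400):
            for t in subsample_trees(sample, 3, seed=s).trees:
                counts[index[id(t)]] += 1
        freq = counts / 400
        assert np.all(np.abs(freq - 0.3) < 0.08)  # MC tolerance


def test_codebook_structure():
    assert len(DEFAULT_CODEBOOK.entries) == 11
    wings = [e.wing for e in DEFAULT_CODEBOOK.entries]
    assert wings[:6] == ["fore"] * 6 and wings[6:] == ["hind"] * 5
    assert DEFAULT_CODEBOOK["Ch10"].elements == ("Cd",)


def test_scale_branch_lengths():
    t = parse_newick("((A:1,B:1):1,C:2);")
    scaled = scale_branch_lengths(t, target_mean=0.1)
    nonroot = scaled.parent >= 0
    assert scaled.blen[nonroot].mean() == pytest.approx(0.1)
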