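"""Trees, posterior tree samples, and binary character matrices.

The analysis is conditional on a sample of rooted, branch-length trees over a
fixed taxon set (typically a subsample of a Bayesian posterior) together with
a taxa x characters matrix of binary wing-pattern characters, where a cell may
be polymorphic/ambiguous (both states observed, coded ``0/1``).

Parsing of Newick and NEXUS goes through :mod:`dendropy`; internally a tree is
held as flat parent/branch-length arrays, which is what the likelihood and
simulation machinery consume.
"""

from __future__ import annotations

import re
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Tree",
    "TreeSample",
    "CharacterMatrix",
    "CharacterCodebook",
    "DEFAULT_CODEBOOK",
    "TreeParseError",
    "MatrixParseError",
    "parse_newick",
    "read_tree_sample",
    "write_tree_sample",
    "read_character_matrix",
    "write_character_matrix",
    "find_mrca",
    "subsample_trees",
    "scale_branch_lengths",
    "POLYMORPHIC",
]

#: cell code for a polymorphic/ambiguous observation ({0, 1})
POLYMORPHIC = 2


class TreeParseError(ValueError):
    """Raised for malformed, unrooted, or otherwise invalid tree input."""


class MatrixParseError(ValueError):
    """Raised for invalid character-matrix input."""


class Tree:
    """A rooted tree with branch lengths, stored as flat arrays.

    Parameters
    ----------
    parent : array of int
        ``parent[i]`` is the node index of the parent of node ``i``; the root
        has parent ``-1``.  Exactly one root is required.
    blen : array of float
        Length of the branch above each node (ignored/zero for the root).
        All lengths must be nonnegative.
    labels : dict[int, str]
        Taxon name for every leaf node (nodes without children).  Labels must
        be unique.
    """

    def __init__(self, parent, blen, labels, validate: bool = True):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=float)
        self.labels = dict(labels)
        self._children: list[list[int]] | None = None
        self._postorder: np.ndarray | None = None
        if validate:
            self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Tree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        blen = np.zeros(n, dtype=float)
        labels: dict[int, str] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                length = nd.edge.length
                if length is None:
                    raise TreeParseError(
                        "branch without a length above node "
                        f"{nd.taxon.label if nd.taxon else i!r}"
                    )
                if length < 0:
                    raise TreeParseError(f"negative branch length: {length!r}")
                blen[i] = float(length)
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeParseError(f"leaf node {i} has no taxon label")
                labels[i] = nd.taxon.label
        return cls(parent, blen, labels)

    def _validate(self) -> None:
        n = self.parent.size
        if n == 0:
            raise TreeParseError("empty tree")
        if self.blen.size != n:
            raise TreeParseError("parent and branch-length arrays differ in size")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeParseError(f"expected exactly one root, found {roots.size}")
        if np.any(self.blen < 0):
            bad = float(self.blen[self.blen < 0][0])
            raise TreeParseError(f"negative branch length: {bad!r}")
        has_child = np.zeros(n, dtype=bool)
        has_child[self.parent[self.parent >= 0]] = True
        leaves = set(np.flatnonzero(~has_child).tolist())
        if set(self.labels) != leaves:
            raise TreeParseError("leaf labels do not cover exactly the leaf nodes")
        names = list(self.labels.values())
        if len(set(names)) != len(names):
            dupe = next(x for x in names if names.count(x) > 1)
            raise TreeParseError(f"duplicate leaf label: {dupe!r}")
        # cycle guard: climbing to the root must terminate within n steps
        for i in range(n):
            j, steps = i, 0
            while self.parent[j] >= 0:
                j = int(self.parent[j])
                steps += 1
                if steps > n:
                    raise TreeParseError("parent links contain a cycle")

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return int(self.parent.size)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def children(self) -> list[list[int]]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = ch
        return self._children

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    def postorder(self) -> np.ndarray:
        """Node indices in postorder (children before parents)."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            while stack:
                node = stack.pop()
                order.append(node)
                stack.extend(self.children[node])
            self._postorder = np.asarray(order[::-1], dtype=np.int64)
        return self._postorder

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1]

    @property
    def leaf_nodes(self) -> list[int]:
        return sorted(self.labels)

    @property
    def taxon_set(self) -> frozenset:
        return frozenset(self.labels.values())

    @property
    def label_to_node(self) -> dict[str, int]:
        return {name: node for node, name in self.labels.items()}

    def leaf_set(self, node: int) -> frozenset:
        """Taxon names of the leaves descending from ``node``."""
        out = []
        stack = [node]
        while stack:
            i = stack.pop()
            if self.is_leaf(i):
                out.append(self.labels[i])
            else:
                stack.extend(self.children[i])
        return frozenset(out)

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        for node in self.preorder():
            p = self.parent[node]
            if p >= 0:
                d[node] = d[p] + self.blen[node]
        return d

    def copy(self) -> "Tree":
        return Tree(self.parent.copy(), self.blen.copy(), dict(self.labels), validate=False)

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        children = self.children

        def fmt_label(name: str) -> str:
            if re.search(r"[\s(),:;\[\]']", name):
                return "'" + name.replace("'", "''") + "'"
            return name

        def rec(i: int) -> str:
            if not children[i]:
                s = fmt_label(self.labels[i])
            else:
                s = "(" + ",".join(rec(c) for c in children[i]) + ")"
            if self.parent[i] >= 0:
                s += f":{float(self.blen[i])!r}"  # repr: exact round-trip
            return s

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree: {self.n_leaves} leaves, {self.n_nodes} nodes>"


def parse_newick(text: str) -> Tree:
    """Parse a single Newick string into a rooted :class:`Tree`.

    Plain Newick is taken as rooted at its outermost node; input explicitly
    flagged unrooted (``[&U]``) is rejected, because the downstream analysis
    requires a root and silent re-rooting would change likelihoods.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="default-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except TreeParseError:
        raise
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"malformed newick: {exc}") from exc
    if not dtree.is_rooted:
        raise TreeParseError("tree is explicitly unrooted ([&U]); a rooted tree is required")
    return Tree.from_dendropy(dtree)


class TreeSample(Sequence):
    """An ordered sample of trees over a common taxon set.

    Optionally carries per-tree weights (default: equal).
    """

    def __init__(self, trees: Sequence[Tree], weights=None):
        trees = list(trees)
        if not trees:
            raise TreeParseError("a tree sample must contain at least one tree")
        ref = trees[0].taxon_set
        for k, t in enumerate(trees[1:], start=1):
            if t.taxon_set != ref:
                diff = sorted(ref ^ t.taxon_set)
                raise TreeParseError(
                    f"tree {k} has a different taxon set; symmetric difference: {diff}"
                )
        self.trees = trees
        if weights is None:
            weights = np.full(len(trees), 1.0 / len(trees))
        else:
            weights = np.asarray(weights, dtype=float)
            if weights.size != len(trees) or np.any(weights < 0):
                raise ValueError("weights must be nonnegative, one per tree")
            weights = weights / weights.sum()
        self.weights = weights

    @property
    def taxon_set(self) -> frozenset:
        return self.trees[0].taxon_set

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return TreeSample(self.trees[i])
        return self.trees[i]

    def __iter__(self):
        return iter(self.trees)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TreeSample: {len(self)} trees, {len(self.taxon_set)} taxa>"


def read_tree_sample(path, format: str = "nexus") -> TreeSample:
    """Read a posterior tree sample from NEXUS or a one-Newick-per-line file.

    NEXUS translate tables are resolved to taxon names.
    """
    path = Path(path)
    if format == "nexus":
        try:
            tlist = dendropy.TreeList.get(
                path=str(path), schema="nexus", preserve_underscores=True,
                rooting="default-rooted",
            )
        except Exception as exc:
            raise TreeParseError(f"cannot read NEXUS trees from {path}: {exc}") from exc
        trees = [Tree.from_dendropy(t) for t in tlist]
    elif format in ("newick-lines", "newick"):
        trees = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    else:
        raise ValueError(f"unknown tree format: {format!r}")
    return TreeSample(trees)


def write_tree_sample(sample: TreeSample, path, format: str = "newick-lines") -> None:
    path = Path(path)
    if format in ("newick-lines", "newick"):
        path.write_text("".join(t.to_newick() + "\n" for t in sample))
    elif format == "nexus":
        lines = ["#NEXUS", "BEGIN TREES;"]
        for i, t in enumerate(sample):
            lines.append(f"    TREE tree_{i} = [&R] {t.to_newick()}")
        lines.append("END;")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown tree format: {format!r}")


# ---------------------------------------------------------------------------
# character matrices


class CharacterMatrix:
    """A taxa x characters matrix of binary states with polymorphism.

    Cell codes are ``0``, ``1``, and :data:`POLYMORPHIC` (= 2), the last
    standing for {0, 1}: both states observed or the observation ambiguous.
    In likelihood computations a polymorphic cell contributes a partial
    likelihood of one for each allowed state.
    """

    def __init__(self, taxa: Sequence[str], characters: Sequence[str], codes):
        self.taxa = list(taxa)
        self.characters = list(characters)
        self.codes = np.asarray(codes, dtype=np.int8)
        if self.codes.shape != (len(self.taxa), len(self.characters)):
            raise MatrixParseError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.characters)} characters"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise MatrixParseError("duplicate taxon names in matrix")
        if len(set(self.characters)) != len(self.characters):
            raise MatrixParseError("duplicate character ids in matrix")
        bad = ~np.isin(self.codes, (0, 1, POLYMORPHIC))
        if np.any(bad):
            r, c = np.argwhere(bad)[0]
            raise MatrixParseError(
                f"invalid cell code at taxon {self.taxa[r]!r}, "
                f"character {self.characters[c]!r}"
            )
        self._taxon_index = {t: i for i, t in enumerate(self.taxa)}
        self._char_index = {c: i for i, c in enumerate(self.characters)}

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def column(self, character: str) -> np.ndarray:
        if character not in self._char_index:
            raise KeyError(f"unknown character id: {character!r}")
        return self.codes[:, self._char_index[character]]

    def cell(self, taxon: str, character: str) -> int:
        return int(self.codes[self._taxon_index[taxon], self._char_index[character]])

    def to_dataframe(self) -> pd.DataFrame:
        strings = np.where(
            self.codes == POLYMORPHIC, "0/1", self.codes.astype(str)
        )
        return pd.DataFrame(strings, index=self.taxa, columns=self.characters)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CharacterMatrix)
            and self.taxa == other.taxa
            and self.characters == other.characters
            and np.array_equal(self.codes, other.codes)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"<CharacterMatrix: {self.n_taxa} taxa x {self.n_characters} characters>"


_TSV_CODES = {"0": 0, "1": 1, "0/1": POLYMORPHIC, "1/0": POLYMORPHIC}


def read_character_matrix(path, format: str = "tsv") -> CharacterMatrix:
    """Read a character matrix from TSV (canonical) or a NEXUS characters block.

    The TSV dialect has a header row, a leading taxon column, and one column
    per character; polymorphism is spelled ``0/1``.
    """
    path = Path(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
        except pd.errors.EmptyDataError as exc:
            raise MatrixParseError(f"empty character matrix file: {path}") from exc
        if df.shape[1] == 0:
            raise MatrixParseError(f"no character columns in {path}")
        codes = np.empty(df.shape, dtype=np.int8)
        for r, taxon in enumerate(df.index):
            for c, char in enumerate(df.columns):
                raw = str(df.iat[r, c]).strip()
                if raw not in _TSV_CODES:
                    raise MatrixParseError(
                        f"unknown code {raw!r} at taxon {taxon!r}, character {char!r}"
                    )
                codes[r, c] = _TSV_CODES[raw]
        return CharacterMatrix(list(df.index), list(df.columns), codes)
    if format == "nexus":
        try:
            dmat = dendropy.StandardCharacterMatrix.get(
                path=str(path), schema="nexus", preserve_underscores=True
            )
        except Exception as exc:
            raise MatrixParseError(f"cannot read NEXUS characters from {path}: {exc}") from exc
        taxa = [t.label for t in dmat.taxon_namespace]
        n_chars = dmat.max_sequence_size
        characters = [f"Ch{i + 1}" for i in range(n_chars)]
        codes = np.empty((len(taxa), n_chars), dtype=np.int8)
        for r, taxon in enumerate(dmat.taxon_namespace):
            seq = dmat[taxon]
            if len(seq) != n_chars:
                raise MatrixParseError(f"ragged matrix: taxon {taxon.label!r}")
            for c, state in enumerate(seq):
                syms = {s.symbol for s in state.fundamental_states}
                if syms == {"0"}:
                    codes[r, c] = 0
                elif syms == {"1"}:
                    codes[r, c] = 1
                elif syms == {"0", "1"}:
                    codes[r, c] = POLYMORPHIC
                else:
                    raise MatrixParseError(
                        f"unknown code {state.symbol!r} at taxon {taxon.label!r}, "
                        f"character {characters[c]!r}"
                    )
        return CharacterMatrix(taxa, characters, codes)
    raise ValueError(f"unknown matrix format: {format!r}")


def write_character_matrix(matrix: CharacterMatrix, path) -> None:
    matrix.to_dataframe().to_csv(Path(path), sep="\t", index_label="taxon")


# ---------------------------------------------------------------------------
# character codebook


@dataclass(frozen=True)
class CodebookEntry:
    char_id: str
    wing: str  # "fore" | "hind"
    elements: tuple
    state1: str  # description of the derived (leaf-mimic-like) condition


@dataclass(frozen=True)
class CharacterCodebook:
    """The 11-character codebook for the wing-pattern ground-plan elements.

    State 1 is the leaf-mimic-like condition of the element(s); state 0
    collapses every other condition.  Characters 1-6 are forewing, 7-11
    hindwing.
    """

    entries: tuple = ()

    def __post_init__(self):
        ids = [e.char_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate character ids in codebook")

    def __getitem__(self, char_id: str) -> CodebookEntry:
        for e in self.entries:
            if e.char_id == char_id:
                return e
        raise KeyError(char_id)

    @property
    def character_ids(self) -> list:
        return [e.char_id for e in self.entries]


DEFAULT_CODEBOOK = CharacterCodebook(
    entries=(
        CodebookEntry("Ch1", "fore", ("DS", "B"), "DS and B parallel"),
        CodebookEntry("Ch2", "fore", ("DS", "Cp"), "DS attached to Cp"),
        CodebookEntry("Ch3", "fore", ("Cd",), "Cd a single broken straight line"),
        CodebookEntry("Ch4", "fore", ("BOp",), "BOp bends to the distal side"),
        CodebookEntry("Ch5", "fore", ("BOp",), "upper side of BOp straight"),
        CodebookEntry("Ch6", "fore", ("ESs",), "ESs vestigial"),
        CodebookEntry("Ch7", "hind", ("B",), "B vestigial"),
        CodebookEntry("Ch8", "hind", ("Cp",), "Cp fragmented"),
        CodebookEntry("Ch9", "hind", ("DS",), "DS vestigial"),
        CodebookEntry("Ch10", "hind", ("Cd",), "Cd straight"),
        CodebookEntry("Ch11", "hind", ("ESs",), "ESs vestigial"),
    )
)


# ---------------------------------------------------------------------------
# clade resolution and subsampling


def find_mrca(tree: Tree, taxa) -> int:
    """Most recent common ancestor of a set of taxon names.

    Returns the unique deepest node whose leaf descendants include all of
    ``taxa``.  When the exact clade does not exist in this tree the node may
    subtend extra taxa (the minimal containing node).
    """
    taxa = set(taxa)
    if not taxa:
        raise ValueError("taxa set must be nonempty")
    lookup = tree.label_to_node
    for name in taxa:
        if name not in lookup:
            raise KeyError(f"taxon not in tree: {name!r}")
    k = len(taxa)
    counts = np.zeros(tree.n_nodes, dtype=np.int64)
    for name in taxa:
        counts[lookup[name]] = 1
    for node in tree.postorder():
        p = tree.parent[node]
        if p >= 0:
            counts[p] += counts[node]
    node = tree.root
    while True:
        nxt = None
        for c in tree.children[node]:
            if counts[c] == k:
                nxt = c
                break
        if nxt is None:
            return node
        node = nxt


def subsample_trees(sample: TreeSample, n: int, seed: int) -> TreeSample:
    """Uniform without-replacement subsample of ``n`` trees, reproducible."""
    if n > len(sample):
        raise ValueError(f"cannot subsample {n} trees from a sample of {len(sample)}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(sample), size=n, replace=False)
    return TreeSample([sample[int(i)] for i in idx])


def scale_branch_lengths(tree: Tree, target_mean: float = 0.1) -> Tree:
    """Rescale all branch lengths so their mean equals ``target_mean``.

    Optional global normalization for trees in unfamiliar units; the analysis
    itself takes branch lengths as-is.
    """
    out = tree.copy()
    nonroot = out.parent >= 0
    mean = out.blen[nonroot].mean()
    if mean > 0:
        out.blen[nonroot] *= target_mean / mean
    return out
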