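"""Continuous-time Markov models for binary characters and character pairs.

A single binary character evolves under a 2-state CTMC with a gain rate
(0 -> 1) and a loss rate (1 -> 0).  A pair of binary characters evolves under
a 4-state CTMC over the joint states (0,0), (0,1), (1,0), (1,1) — in
first-character-major order — in which simultaneous changes of both
characters are impossible, leaving eight permitted transitions named
q12, q13, q21, q24, q31, q34, q42, q43 (1-based state indices).  The
*dependent* model gives all eight rates freely; the *independent* model ties
each character's gain and loss rates across the other's background state
(q12 = q34, q13 = q24, q21 = q43, q31 = q42), leaving four free rates.

Likelihoods use the standard postorder pruning recursion; a brute-force
enumeration over internal-node states serves as an oracle on small trees.
Marginal node-state probabilities come from an outside-inside (up-down) pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import scipy.linalg

from . import _kernels
from .treeio import POLYMORPHIC, CharacterMatrix, Tree

__all__ = [
    "RateMatrix",
    "RootPrior",
    "TipData",
    "PAIR_STATES",
    "DEP_RATE_NAMES",
    "INDEP_RATE_NAMES",
    "BINARY_RATE_NAMES",
    "build_dependent_Q",
    "build_independent_Q",
    "build_binary_Q",
    "transition_probabilities",
    "prune_loglik",
    "brute_force_loglik",
    "pair_tipdata",
    "binary_tipdata",
    "node_state_probs",
    "TreeLikelihood",
    "uniform_root",
    "stationary_root",
]

#: joint states of a character pair, first-character-major
PAIR_STATES = ((0, 0), (0, 1), (1, 0), (1, 1))

#: the eight free transition rates of the dependent (correlated) model
DEP_RATE_NAMES = ("q12", "q13", "q21", "q24", "q31", "q34", "q42", "q43")

#: free rates of the independent model: gain/loss of each character
INDEP_RATE_NAMES = ("gain1", "loss1", "gain2", "loss2")

BINARY_RATE_NAMES = ("gain", "loss")

# (row, col) position of each named rate in the 4x4 generator (0-based)
_DEP_POSITIONS = {
    "q12": (0, 1),
    "q13": (0, 2),
    "q21": (1, 0),
    "q24": (1, 3),
    "q31": (2, 0),
    "q34": (2, 3),
    "q42": (3, 1),
    "q43": (3, 2),
}

# entries fixed to zero: both characters changing in one instant
_FORBIDDEN = ((0, 3), (3, 0), (1, 2), (2, 1))


class RateMatrix:
    """A CTMC generator: nonnegative off-diagonals, rows summing to zero."""

    def __init__(self, Q, states=None):
        Q = np.asarray(Q, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError("Q must be square")
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be nonnegative")
        if np.max(np.abs(Q.sum(axis=1))) > 1e-12 * max(1.0, np.max(np.abs(Q))):
            raise ValueError("generator rows must sum to zero")
        self.Q = Q
        if states is None:
            states = tuple(range(Q.shape[0]))
        self.states = tuple(states)

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]

    def to_tsv(self, path) -> None:
        import pandas as pd

        labels = [str(s) for s in self.states]
        pd.DataFrame(self.Q, index=labels, columns=labels).to_csv(
            Path(path), sep="\t", float_format="%.12g"
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"<RateMatrix {self.n_states}x{self.n_states}>"


def _generator_from_rates(positions, rates, n):
    Q = np.zeros((n, n))
    for name, (i, j) in positions.items():
        r = float(rates[name])
        if r < 0:
            raise ValueError(f"rate {name} must be nonnegative, got {r}")
        Q[i, j] = r
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def build_dependent_Q(
    q12, q13, q21, q24, q31, q34, q42, q43
) -> RateMatrix:
    """4x4 generator of the dependent (correlated-evolution) model.

    Double-change transitions (1<->4 and 2<->3) are structurally zero.
    """
    rates = dict(
        q12=q12, q13=q13, q21=q21, q24=q24, q31=q31, q34=q34, q42=q42, q43=q43
    )
    Q = _generator_from_rates(_DEP_POSITIONS, rates, 4)
    return RateMatrix(Q, states=PAIR_STATES)


def build_independent_Q(gain1, loss1, gain2, loss2) -> RateMatrix:
    """Dependent generator with the four independence equalities imposed.

    ``gain1``/``loss1`` are the 0->1 / 1->0 rates of the first character
    (q13 = q24 and q31 = q42); ``gain2``/``loss2`` those of the second
    (q12 = q34 and q21 = q43).
    """
    return build_dependent_Q(
        q12=gain2, q13=gain1, q21=loss2, q24=gain1,
        q31=loss1, q34=gain2, q42=loss1, q43=loss2,
    )


def build_binary_Q(gain, loss) -> RateMatrix:
    if gain < 0 or loss < 0:
        raise ValueError("rates must be nonnegative")
    Q = np.array([[-gain, gain], [loss, -loss]], dtype=float)
    return RateMatrix(Q, states=(0, 1))


def _dep_rates_array(Q: np.ndarray) -> np.ndarray:
    return np.array([Q[i, j] for i, j in (_DEP_POSITIONS[n] for n in DEP_RATE_NAMES)])


# ---------------------------------------------------------------------------
# transition probabilities


def _edge_probs(Q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """exp(Q t) for a vector of branch lengths; shape (len(t), S, S).

    2-state generators use the closed form; larger ones an eigendecomposition
    with an expm fallback when the eigenvector matrix is ill-conditioned.
    """
    t = np.asarray(t, dtype=float)
    S = Q.shape[0]
    if S == 2:
        a, b = Q[0, 1], Q[1, 0]
        s = a + b
        P = np.empty((t.size, 2, 2))
        if s == 0.0:
            P[:] = np.eye(2)
            return P
        e = np.exp(-s * t)
        P[:, 0, 0] = (b + a * e) / s
        P[:, 0, 1] = (a - a * e) / s
        P[:, 1, 0] = (b - b * e) / s
        P[:, 1, 1] = (a + b * e) / s
        return np.clip(P, 0.0, 1.0)
    try:
        w, V = np.linalg.eig(Q)
        Vi = np.linalg.inv(V)
        # validate the decomposition itself (cheap, and t-independent)
        scale = max(1.0, float(np.max(np.abs(Q))))
        err = np.max(np.abs((V * w) @ Vi - Q))
        if not np.isfinite(err) or err > 1e-9 * scale:
            raise np.linalg.LinAlgError("ill-conditioned eigendecomposition")
        if np.isrealobj(w):
            E = np.exp(np.multiply.outer(t, w))
            P = (V[None, :, :] * E[:, None, :]) @ Vi
        else:
            E = np.exp(np.multiply.outer(t, w))
            P = ((V[None, :, :] * E[:, None, :]) @ Vi).real
    except np.linalg.LinAlgError:
        P = np.empty((t.size, S, S))
        uniq, inv = np.unique(t, return_inverse=True)
        mats = [scipy.linalg.expm(Q * tt) for tt in uniq]
        for k, idx in enumerate(inv):
            P[k] = mats[idx]
    np.clip(P, 0.0, None, out=P)
    return P


def transition_probabilities(Q, t: float) -> np.ndarray:
    """Stochastic matrix exp(Qt) for one branch length ``t >= 0``."""
    if isinstance(Q, RateMatrix):
        Q = Q.Q
    if t < 0:
        raise ValueError(f"branch length must be nonnegative, got {t}")
    P = _edge_probs(np.asarray(Q, dtype=float), np.array([t]))[0]
    rowsum = P.sum(axis=1, keepdims=True)
    if np.max(np.abs(rowsum - 1.0)) > 1e-10:
        raise ArithmeticError("transition probability rows do not sum to 1")
    return P


# ---------------------------------------------------------------------------
# root priors and tip data


def uniform_root(n_states: int) -> np.ndarray:
    return np.full(n_states, 1.0 / n_states)


def stationary_root(Q) -> np.ndarray:
    """Stationary distribution of the generator (left null vector)."""
    if isinstance(Q, RateMatrix):
        Q = Q.Q
    S = Q.shape[0]
    A = np.vstack([Q.T, np.ones(S)])
    b = np.zeros(S + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


class RootPrior:
    """Probability vector over states at the root."""

    def __init__(self, probs):
        probs = np.asarray(probs, dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("root prior must be nonnegative and sum to 1")
        self.probs = probs

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.probs, dtype=dtype)


def _as_root(root, n_states: int) -> np.ndarray:
    if root is None:
        return uniform_root(n_states)
    arr = np.asarray(root, dtype=float)
    if arr.size != n_states:
        raise ValueError(f"root prior has {arr.size} entries, expected {n_states}")
    if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-12:
        raise ValueError("root prior must be nonnegative and sum to 1")
    return arr


class TipData:
    """Per-taxon partial-likelihood indicator vectors over states.

    An observed state maps to an indicator; a polymorphic/ambiguous cell to a
    vector of ones over the allowed states (each allowed state enters the
    pruning recursion with equal weight).
    """

    def __init__(self, partials: dict, n_states: int):
        self.n_states = int(n_states)
        self.partials = {}
        for taxon, vec in partials.items():
            vec = np.asarray(vec, dtype=float)
            if vec.size != self.n_states:
                raise ValueError(f"tip vector for {taxon!r} has wrong length")
            if not np.all(np.isin(vec, (0.0, 1.0))) or vec.sum() < 1:
                raise ValueError(f"tip vector for {taxon!r} must be a 0/1 mask with >=1 one")
            self.partials[taxon] = vec

    @property
    def taxa(self):
        return set(self.partials)

    def __getitem__(self, taxon):
        return self.partials[taxon]


_BINARY_VECS = {0: (1.0, 0.0), 1: (0.0, 1.0), POLYMORPHIC: (1.0, 1.0)}


def binary_tipdata(matrix: CharacterMatrix, character: str) -> TipData:
    """2-state tip data for a single character column."""
    col = matrix.column(character)
    return TipData(
        {t: np.array(_BINARY_VECS[int(v)]) for t, v in zip(matrix.taxa, col)}, 2
    )


def _allowed(code: int):
    return (0, 1) if code == POLYMORPHIC else (int(code),)


def pair_tipdata(matrix: CharacterMatrix, char_i: str, char_j: str) -> TipData:
    """4-state joint tip data for a character pair.

    A polymorphic cell in either character expands to ones over every
    consistent joint state.
    """
    ci = matrix.column(char_i)
    cj = matrix.column(char_j)
    partials = {}
    for taxon, a, b in zip(matrix.taxa, ci, cj):
        vec = np.zeros(4)
        for x in _allowed(int(a)):
            for y in _allowed(int(b)):
                vec[PAIR_STATES.index((x, y))] = 1.0
        partials[taxon] = vec
    return TipData(partials, 4)


# ---------------------------------------------------------------------------
# pruning likelihood


class TreeLikelihood:
    """Precompiled pruning machinery for one tree and one tip-data set.

    Builds the flat postorder/child arrays once so repeated likelihood
    evaluations (as in MCMC) only pay for the matrix exponentials and the
    pruning pass itself.
    """

    def __init__(self, tree: Tree, tips: TipData, root=None):
        missing = tree.taxon_set - tips.taxa
        if missing:
            raise ValueError(f"tip data missing for taxa: {sorted(missing)}")
        self.tree = tree
        self.n_states = tips.n_states
        n = tree.n_nodes
        children = tree.children
        counts = np.array([len(c) for c in children], dtype=np.int64)
        self.child_ptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(counts, out=self.child_ptr[1:])
        self.child_idx = np.concatenate(
            [np.asarray(c, dtype=np.int64) for c in children if c]
        ) if counts.sum() else np.zeros(0, dtype=np.int64)
        post = tree.postorder()
        self.post_internal = np.asarray(
            [i for i in post if counts[i] > 0], dtype=np.int64
        )
        self.blen = tree.blen
        self.root_node = tree.root
        self.L = np.ones((n, self.n_states))
        for node, name in tree.labels.items():
            self.L[node] = tips[name]
        self.default_root = _as_root(root, self.n_states)

    def loglik(self, Q, root=None) -> float:
        if isinstance(Q, RateMatrix):
            Q = Q.Q
        prior = self.default_root if root is None else _as_root(root, self.n_states)
        P = _edge_probs(Q, self.blen)
        return float(
            _kernels.prune(
                self.post_internal, self.child_ptr, self.child_idx,
                P, self.L, self.root_node, prior,
            )
        )


def prune_loglik(tree: Tree, tips: TipData, Q, root=None) -> float:
    """Log-likelihood of the tip data by the pruning recursion."""
    return TreeLikelihood(tree, tips, root=root).loglik(Q)


def brute_force_loglik(tree: Tree, tips: TipData, Q, root=None, clamp=None) -> float:
    """Log-likelihood by explicit summation over internal-node states.

    Test oracle only: refuses trees with more than 8 internal nodes.
    ``clamp`` optionally fixes {node: state} for internal nodes, which turns
    the sum into the joint probability of the data and those node states —
    the basis of the clamped-node check of marginal reconstructions.
    """
    if isinstance(Q, RateMatrix):
        Q = Q.Q
    S = Q.shape[0]
    prior = _as_root(root, S)
    clamp = dict(clamp or {})
    internal = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
    if len(internal) > 8:
        raise ValueError("brute force limited to <= 8 internal nodes")
    P = {i: transition_probabilities(Q, float(tree.blen[i])) for i in range(tree.n_nodes)}
    leaf_vec = {i: tips[tree.labels[i]] for i in tree.leaf_nodes}
    total = 0.0
    root_node = tree.root
    ranges = [(clamp[i],) if i in clamp else range(S) for i in internal]
    pos = {node: k for k, node in enumerate(internal)}
    for assign in product(*ranges):
        p = prior[assign[pos[root_node]]] if root_node in pos else 1.0
        for node in internal:
            s_par = assign[pos[node]]
            for c in tree.children[node]:
                if tree.is_leaf(c):
                    p *= float(P[c][s_par] @ leaf_vec[c])
                else:
                    p *= P[c][s_par, assign[pos[c]]]
        total += p
    if tree.n_nodes == 1:
        # degenerate single-node "tree": the root is itself a leaf
        total = float(prior @ leaf_vec[root_node])
    if total <= 0:
        return -np.inf
    return float(np.log(total))


# ---------------------------------------------------------------------------
# marginal node-state probabilities


def node_state_probs(tree: Tree, tips: TipData, Q, root=None, node=None) -> np.ndarray:
    """Marginal conditional probability of each state at a node.

    Runs the inside (pruning) pass and an outside pass; the marginal at a
    node is proportional to the product of its inside and outside partials.
    If ``node`` is None, returns an (n_nodes, S) matrix for all nodes.
    """
    if isinstance(Q, RateMatrix):
        Q = Q.Q
    S = Q.shape[0]
    prior = _as_root(root, S)
    if node is not None and not (0 <= node < tree.n_nodes):
        raise KeyError(f"node {node} not in tree")
    P = _edge_probs(Q, tree.blen)
    n = tree.n_nodes
    # inside pass with per-node normalization (scale factors cancel at the end)
    L = np.ones((n, S))
    for i, name in tree.labels.items():
        L[i] = tips[name]
    for i in tree.postorder():
        ch = tree.children[i]
        if not ch:
            continue
        vec = np.ones(S)
        for c in ch:
            vec *= P[c] @ L[c]
        m = vec.max()
        if m <= 0:
            raise ArithmeticError("data has zero likelihood under this model")
        L[i] = vec / m
    # outside pass
    U = np.zeros((n, S))
    U[tree.root] = prior
    for i in tree.preorder():
        ch = tree.children[i]
        if not ch:
            continue
        msgs = [P[c] @ L[c] for c in ch]
        for k, c in enumerate(ch):
            others = U[i].copy()
            for kk, m in enumerate(msgs):
                if kk != k:
                    others *= m
            out = others @ P[c]
            tot = out.sum()
            U[c] = out / tot if tot > 0 else out
    M = U * L
    M /= M.sum(axis=1, keepdims=True)
    return M if node is None else M[node]
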