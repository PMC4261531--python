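"""Synthetic trees, tree samples, and character data.

The generators reproduce the statistical shape the analysis assumes — a
posterior-like sample of rooted ultrametric trees over ~47 taxa and a matrix
of 11 binary characters — including scenarios with planted dependent pairs
and planted temporal orders of gains (a character whose gain rate is a
structural zero until its predecessor has reached state 1).  Every generator
is a deterministic function of its parameters and seed, and simulations keep
a full event log so planted structure can be audited exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ctmc
from .treeio import POLYMORPHIC, CharacterMatrix, Tree, TreeSample

__all__ = [
    "SimulationScenario",
    "simulate_yule_tree",
    "perturb_tree_sample",
    "simulate_character",
    "simulate_pair",
    "simulate_contingent_chain",
    "make_fixture_study",
    "FIXTURE_PRESETS",
]


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of a synthetic study."""

    n_taxa: int = 47
    n_chars: int = 11
    birth_rate: float = 1.0
    n_trees: int = 50
    jitter_sd: float = 0.1
    nni_fraction: float = 0.1
    baseline_gain: float = 0.3
    baseline_loss: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        for r in (self.baseline_gain, self.baseline_loss):
            if r < 0:
                raise ValueError("rates must be >= 0")


def _rng(seed, rng):
    if rng is not None:
        return rng
    if seed is None:
        raise ValueError("a seed (or rng) is mandatory for reproducibility")
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# trees


def simulate_yule_tree(n_taxa: int, birth_rate: float, seed=None, rng=None) -> Tree:
    """Pure-birth (Yule) tree with ``n_taxa`` tips; ultrametric.

    Starting from two lineages at the root, with k lineages the next split
    waits Exp(k * birth_rate); after the n-th lineage appears one further
    Exp(n * birth_rate) interval runs to the present, so the expected
    root-to-tip depth is sum_{k=2..n} 1/(k * birth_rate).
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = _rng(seed, rng)
    parent: list[int] = [-1]
    start: dict[int, float] = {}
    blen: list[float] = [0.0]
    # active lineages: (pending node id, birth time of the lineage)
    t = 0.0
    next_id = 1
    active: list[tuple[int, float]] = []
    for _ in range(2):
        active.append((next_id, 0.0))
        parent.append(0)
        blen.append(0.0)
        next_id += 1
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node, born = active.pop(i)
        blen[node] = t - born
        for _ in range(2):
            active.append((next_id, t))
            parent.append(node)
            blen.append(0.0)
            next_id += 1
    t += rng.exponential(1.0 / (n_taxa * birth_rate))
    labels = {}
    width = len(str(n_taxa))
    for j, (node, born) in enumerate(active):
        blen[node] = t - born
        labels[node] = f"t{j + 1:0{width}d}"
    return Tree(np.asarray(parent), np.asarray(blen), labels)


def _nni(tree: Tree, rng) -> Tree:
    """One random nearest-neighbour interchange (in place on a copy)."""
    out = tree.copy()
    children = [list(c) for c in out.children]
    # internal, non-root nodes whose parent has another child
    cand = [
        v for v in range(out.n_nodes)
        if children[v] and out.parent[v] >= 0 and len(children[out.parent[v]]) >= 2
    ]
    if not cand:
        return out
    v = cand[int(rng.integers(len(cand)))]
    u = int(out.parent[v])
    sibs = [c for c in children[u] if c != v]
    s = sibs[int(rng.integers(len(sibs)))]
    c = children[v][int(rng.integers(len(children[v])))]
    out.parent[c] = u
    out.parent[s] = v
    out._children = None
    out._postorder = None
    return out


def perturb_tree_sample(
    tree: Tree, m: int, jitter_sd: float, seed=None, rng=None,
    nni_fraction: float = 0.0,
) -> TreeSample:
    """Emulate posterior tree uncertainty around a single tree.

    Produces ``m`` copies with lognormal branch-length jitter (mean-corrected
    so the expected length equals the original) and, optionally, a single
    NNI move on a fraction of the trees.  The taxon set is preserved.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = _rng(seed, rng)
    trees = []
    for _ in range(m):
        out = tree.copy()
        if nni_fraction > 0 and rng.random() < nni_fraction:
            out = _nni(out, rng)
        if jitter_sd > 0:
            mult = rng.lognormal(-0.5 * jitter_sd**2, jitter_sd, out.blen.size)
            nonroot = out.parent >= 0
            out.blen[nonroot] = out.blen[nonroot] * mult[nonroot]
        trees.append(out)
    return TreeSample(trees)


# ---------------------------------------------------------------------------
# character simulation


def _evolve(tree: Tree, Q: np.ndarray, root_state: int, rng):
    """Simulate a CTMC down every branch by exponential waiting times.

    Returns (node_states, events) where events[node] is the list of
    (time_along_edge, new_state) changes on the branch above the node.
    """
    S = Q.shape[0]
    states = np.empty(tree.n_nodes, dtype=np.int64)
    states[tree.root] = root_state
    events: dict[int, list] = {n: [] for n in range(tree.n_nodes)}
    for node in tree.preorder():
        p = tree.parent[node]
        if p < 0:
            continue
        s = int(states[p])
        t = 0.0
        T = float(tree.blen[node])
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= T:
                break
            probs = Q[s].copy()
            probs[s] = 0.0
            probs /= rate
            s = int(rng.choice(S, p=probs))
            events[node].append((t, s))
        states[node] = s
    return states, events


def simulate_character(tree: Tree, Q, root_state: int = 0, seed=None, rng=None,
                       return_events: bool = False):
    """Evolve one binary character; returns {taxon: state} at the tips."""
    if isinstance(Q, ctmc.RateMatrix):
        Q = Q.Q
    rng = _rng(seed, rng)
    states, events = _evolve(tree, np.asarray(Q, float), root_state, rng)
    tips = {name: int(states[node]) for node, name in tree.labels.items()}
    if return_events:
        return tips, states, events
    return tips


def simulate_pair(tree: Tree, Q, root_state=(0, 0), seed=None, rng=None,
                  return_events: bool = False):
    """Evolve a character pair under a 4-state generator.

    ``root_state`` is a joint state tuple.  Returns {taxon: (a, b)}; with
    ``return_events`` also the per-node joint states and the event log.
    """
    if isinstance(Q, ctmc.RateMatrix):
        Q = Q.Q
    Q = np.asarray(Q, float)
    for i, j in ((0, 3), (3, 0), (1, 2), (2, 1)):
        if Q[i, j] != 0:
            raise ValueError("pair generator must forbid double changes")
    rng = _rng(seed, rng)
    root_idx = ctmc.PAIR_STATES.index(tuple(root_state))
    states, events = _evolve(tree, Q, root_idx, rng)
    tips = {
        name: ctmc.PAIR_STATES[int(states[node])]
        for node, name in tree.labels.items()
    }
    if return_events:
        return tips, states, events
    return tips


def _background_segments(tree, states, events, node):
    """(time, state) breakpoints of a reference character along one edge."""
    p = tree.parent[node]
    segs = [(0.0, int(states[p]))]
    segs.extend((t, s) for t, s in events[node])
    return segs


def simulate_contingent_chain(
    tree: Tree,
    chain: list,
    seed=None,
    rng=None,
):
    """Simulate a chain of contingent gains c0 -> c1 -> ... -> c_{m-1}.

    ``chain`` is a list of dicts with keys ``gain``, ``loss`` (per-character
    rates); for every character after the first, the gain rate applies only
    while the *predecessor* is in state 1 and is a structural zero otherwise.
    This is exactly the temporal-dependency structure the contingency
    analysis is designed to detect.

    Returns (tip_dicts, histories) where histories[j] = (states, events).
    """
    rng = _rng(seed, rng)
    tip_dicts = []
    histories = []
    prev = None
    for j, spec in enumerate(chain):
        gain, loss = float(spec["gain"]), float(spec["loss"])
        if prev is None:
            Q = np.array([[-gain, gain], [loss, -loss]])
            states, events = _evolve(tree, Q, 0, rng)
        else:
            pstates, pevents = prev
            states = np.empty(tree.n_nodes, dtype=np.int64)
            states[tree.root] = 0
            events = {n: [] for n in range(tree.n_nodes)}
            for node in tree.preorder():
                par = tree.parent[node]
                if par < 0:
                    continue
                s = int(states[par])
                T = float(tree.blen[node])
                segs = _background_segments(tree, pstates, pevents, node)
                bounds = [t for t, _ in segs[1:]] + [T]
                t = 0.0
                for (t0, bg), t1 in zip(segs, bounds):
                    t = max(t, t0)
                    while t < t1:
                        rate = (gain if bg == 1 else 0.0) if s == 0 else loss
                        if rate <= 0:
                            break
                        t += rng.exponential(1.0 / rate)
                        if t >= t1:
                            break
                        s = 1 - s
                        events[node].append((t, s))
                    t = t1
                states[node] = s
        tip_dicts.append({name: int(states[n]) for n, name in tree.labels.items()})
        histories.append((states, events))
        prev = histories[-1]
    return tip_dicts, histories


def first_gain_times(tree: Tree, histories) -> dict:
    """Per-tip time of the first 0->1 change of each chained character.

    Walks the root-to-tip path of every leaf and records the absolute time of
    the first gain; ``inf`` if the character never reaches 1 on that path.
    Used to audit that planted orders hold lineage by lineage.
    """
    depths = tree.depths()
    out = {}
    for leaf, name in tree.labels.items():
        path = []
        n = leaf
        while n >= 0:
            path.append(n)
            n = int(tree.parent[n]) if tree.parent[n] >= 0 else -1
        path.reverse()
        times = []
        for states, events in histories:
            t_gain = np.inf
            for node in path[1:]:
                base = depths[int(tree.parent[node])]
                for t, s in events[node]:
                    if s == 1:
                        t_gain = base + t
                        break
                if np.isfinite(t_gain):
                    break
            times.append(t_gain)
        out[name] = times
    return out


# ---------------------------------------------------------------------------
# fixture studies

FIXTURE_PRESETS = ("null", "planted-pairs", "planted-order")

# dependent-pair generator used by the planted-pairs preset: the second
# character can only be gained on the background of the first (q12 = 0),
# and gains it quickly there (q34 >> 0), a strong-dependence regime
PLANTED_PAIR_RATES = dict(
    q12=0.0, q13=0.8, q21=1.0, q24=0.8, q31=0.3, q34=2.0, q42=0.3, q43=0.1
)

# contingent-chain rates for the planted-order preset: slow, near-persistent
# early characters (so the background state is phylogenetically resolved and
# rarely lost while a dependent character is present) and fast gains once
# unlocked
PLANTED_CHAIN = [
    dict(gain=0.4, loss=0.05),
    dict(gain=2.5, loss=0.1),
    dict(gain=2.5, loss=0.5),
]


def make_fixture_study(preset: str, seed: int, scenario: SimulationScenario | None = None):
    """Build a complete synthetic study: tree sample, matrix, truth record.

    Presets
    -------
    ``null``
        All characters evolve independently at the baseline rates.
    ``planted-pairs``
        Character pairs (Ch1, Ch2) and (Ch3, Ch4) evolve under a shared
        dependent generator with a structural zero (gain of the second
        character impossible until the first is in state 1); the rest are
        independent.
    ``planted-order``
        Characters Ch1 -> Ch2 -> Ch3 form a contingent chain of gains; the
        rest are independent.

    The truth record stores the generators, the planted structure, and a
    per-lineage audit of first-gain times for planted-order runs.
    """
    if preset not in FIXTURE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {FIXTURE_PRESETS}")
    sc = scenario or SimulationScenario(seed=seed)
    rng = np.random.default_rng(seed)
    base_tree = simulate_yule_tree(sc.n_taxa, sc.birth_rate, rng=rng)
    trees = perturb_tree_sample(
        base_tree, sc.n_trees, sc.jitter_sd, rng=rng, nni_fraction=sc.nni_fraction
    )
    chars = [f"Ch{i + 1}" for i in range(sc.n_chars)]
    taxa = sorted(base_tree.taxon_set)
    codes = np.zeros((len(taxa), sc.n_chars), dtype=np.int8)
    baseQ = np.array(
        [[-sc.baseline_gain, sc.baseline_gain], [sc.baseline_loss, -sc.baseline_loss]]
    )
    truth: dict = {
        "preset": preset,
        "seed": seed,
        "n_taxa": sc.n_taxa,
        "n_chars": sc.n_chars,
        "dependent_pairs": [],
        "order_chain": [],
        "generators": {"baseline": {"gain": sc.baseline_gain, "loss": sc.baseline_loss}},
    }

    def fill(char_idx, tip_dict):
        for r, taxon in enumerate(taxa):
            codes[r, char_idx] = tip_dict[taxon]

    planted: set = set()
    if preset == "planted-pairs":
        Qdep = ctmc.build_dependent_Q(**PLANTED_PAIR_RATES).Q
        for i, j in ((0, 1), (2, 3)):
            if j >= sc.n_chars:
                continue
            tips = simulate_pair(base_tree, Qdep, (0, 0), rng=rng)
            for r, taxon in enumerate(taxa):
                a, b = tips[taxon]
                codes[r, i] = a
                codes[r, j] = b
            planted.update((i, j))
            truth["dependent_pairs"].append((chars[i], chars[j]))
        truth["generators"]["dependent"] = dict(PLANTED_PAIR_RATES)
    elif preset == "planted-order":
        tip_dicts, histories = simulate_contingent_chain(
            base_tree, PLANTED_CHAIN, rng=rng
        )
        for k, tips in enumerate(tip_dicts):
            fill(k, tips)
            planted.add(k)
        truth["order_chain"] = chars[: len(PLANTED_CHAIN)]
        truth["generators"]["chain"] = list(PLANTED_CHAIN)
        truth["first_gain_times"] = {
            taxon: [None if not np.isfinite(t) else float(t) for t in times]
            for taxon, times in first_gain_times(base_tree, histories).items()
        }
    for k in range(sc.n_chars):
        if k not in planted:
            fill(k, simulate_character(base_tree, baseQ, 0, rng=rng))
    matrix = CharacterMatrix(taxa, chars, codes)
    return trees, matrix, truth
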