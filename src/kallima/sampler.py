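"""Reversible-jump MCMC over rate models on a posterior tree sample.

The model space is richer than a fixed-dimension rate vector: each named
transition rate is either assigned to the *zero bin* (the transition is
forbidden) or to one of a set of rate classes, every class carrying a single
positive value.  The sampler therefore jumps between models — groupings of
rates and patterns of structural zeros — in proportion to their posterior
probability, which is what makes the zero-bin occupancy of a rate (its
Z-score) a meaningful measure of evolutionary restriction.

Move kernel (all moves Metropolis-Hastings corrected; the model prior is
uniform over assignments and class values carry the rate prior):

* value update — sliding-window perturbation of one class value, window
  width ``ratedev`` tuned during burn-in to a target acceptance rate;
* split / merge — a class with >= 2 members is split by uniform allocation
  of its members, the new class drawing a fresh value from the prior; the
  reverse merge pools an ordered pair of classes;
* zero toggle — a rate moves between the zero bin and a fresh singleton
  class (eligibility restricted to zero-bin rates and singleton classes,
  which makes the move self-inverse);
* tree move — the tree index is a latent variable proposed uniformly from
  the tree sample, so phylogenetic uncertainty is integrated per iteration
  at the cost of a single-tree likelihood;
* hyperparameter move — under the gamma hyperprior, the gamma mean and
  shape are themselves resampled.

Marginal likelihoods are estimated by the harmonic mean of the sampled
likelihoods (computed stably in log space); because that estimator is noisy
the higher-level analyses always aggregate several independent runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import ctmc
from .treeio import TreeSample

__all__ = [
    "Prior",
    "ChainSettings",
    "PROFILES",
    "RateModel",
    "MODELS",
    "get_model",
    "PosteriorSample",
    "run_rjmcmc",
    "autotune_ratedev",
    "harmonic_mean_logL",
    "chain_diagnostics",
    "effective_sample_size",
]


# ---------------------------------------------------------------------------
# priors and settings


@dataclass(frozen=True)
class Prior:
    """Prior on rate-class values: uniform bounds or a gamma hyperprior.

    The gamma hyperprior places gamma(shape, scale = mean/shape) on class
    values with the shape and mean themselves uniform on configurable ranges,
    resampled within the chain.
    """

    kind: str = "uniform"  # "uniform" | "gamma"
    lo: float = 0.0
    hi: float = 100.0
    gamma_mean_range: tuple = (0.0, 10.0)
    gamma_shape_range: tuple = (0.0, 10.0)

    def __post_init__(self):
        if self.kind not in ("uniform", "gamma"):
            raise ValueError(f"unknown prior kind: {self.kind!r}")
        if not self.lo < self.hi:
            raise ValueError("uniform prior requires lo < hi")
        if self.lo < 0:
            raise ValueError("rates are nonnegative; lo must be >= 0")
        for r in (self.gamma_mean_range, self.gamma_shape_range):
            if not (0 <= r[0] < r[1]):
                raise ValueError("hyperprior ranges must be positive intervals")

    @classmethod
    def uniform(cls, lo: float = 0.0, hi: float = 100.0) -> "Prior":
        return cls(kind="uniform", lo=lo, hi=hi)

    @classmethod
    def gamma(cls, mean_range=(0.0, 10.0), shape_range=(0.0, 10.0)) -> "Prior":
        return cls(kind="gamma", gamma_mean_range=tuple(mean_range),
                   gamma_shape_range=tuple(shape_range))


@dataclass(frozen=True)
class ChainSettings:
    iterations: int = 100_000
    burnin: int = 1_000
    thin: int = 10
    seed: int = 0
    target_acceptance: float = 0.30
    ratedev: float = 1.0
    tune_interval: int = 50

    def __post_init__(self):
        if not 0 <= self.burnin < self.iterations:
            raise ValueError("burn-in must be < iterations")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")

    @property
    def n_samples(self) -> int:
        return (self.iterations - self.burnin) // self.thin


#: named settings profiles.  "desk" is the default working scale; the two
#: "paper" profiles carry the published cluster-scale run lengths
#: (ancestral reconstruction and pairwise-dependence analyses respectively).
PROFILES = {
    "desk": ChainSettings(iterations=100_000, burnin=1_000, thin=10),
    "paper-ancestral": ChainSettings(iterations=50_050_000, burnin=50_000, thin=1000),
    "paper-discrete": ChainSettings(iterations=500_500_000, burnin=500_000, thin=1000),
}


# ---------------------------------------------------------------------------
# rate models


@dataclass(frozen=True)
class RateModel:
    """A named family of CTMCs parameterized by a vector of free rates."""

    name: str
    rate_names: tuple
    n_states: int
    _builder: callable = field(repr=False)

    @property
    def n_rates(self) -> int:
        return len(self.rate_names)

    def build_Q(self, rates: np.ndarray) -> np.ndarray:
        """Raw generator ndarray from the free-rate vector."""
        return self._builder(rates)


def _binary_Q(r):
    return np.array([[-r[0], r[0]], [r[1], -r[1]]])


def _independent_Q(r):
    return ctmc.build_independent_Q(*r).Q


def _dependent_Q(r):
    return ctmc.build_dependent_Q(*r).Q


MODELS = {
    "binary": RateModel("binary", ctmc.BINARY_RATE_NAMES, 2, _binary_Q),
    "independent": RateModel("independent", ctmc.INDEP_RATE_NAMES, 4, _independent_Q),
    "dependent": RateModel("dependent", ctmc.DEP_RATE_NAMES, 4, _dependent_Q),
}


def get_model(model) -> RateModel:
    if isinstance(model, RateModel):
        return model
    try:
        return MODELS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")


# ---------------------------------------------------------------------------
# posterior samples


@dataclass
class PosteriorSample:
    """Thinned draws from one rj-MCMC run."""

    model: str
    rate_names: tuple
    rates: np.ndarray       # (n_samples, n_rates) realized rate values
    zero: np.ndarray        # (n_samples, n_rates) zero-bin membership
    n_classes: np.ndarray   # (n_samples,) number of rate classes
    loglik: np.ndarray      # (n_samples,)
    tree_index: np.ndarray  # (n_samples,)
    settings: ChainSettings
    prior: Prior
    acceptance_rate: float  # value-move acceptance over the whole run
    final_ratedev: float
    hypers: np.ndarray | None = None  # (n_samples, 2) gamma (shape, mean)

    def __len__(self) -> int:
        return self.rates.shape[0]

    def to_tsv(self, path) -> None:
        """Trace log: iteration, logL, per-rate value and zero flag, tree index."""
        it = self.settings.burnin + (np.arange(len(self)) + 1) * self.settings.thin
        cols = {"iteration": it, "loglik": self.loglik}
        for k, name in enumerate(self.rate_names):
            cols[name] = self.rates[:, k]
        for k, name in enumerate(self.rate_names):
            cols[f"{name}_zero"] = self.zero[:, k].astype(int)
        cols["n_classes"] = self.n_classes
        cols["tree_index"] = self.tree_index
        pd.DataFrame(cols).to_csv(Path(path), sep="\t", index=False,
                                  float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, model="dependent", settings=None, prior=None):
        df = pd.read_csv(Path(path), sep="\t")
        m = get_model(model)
        return cls(
            model=m.name,
            rate_names=m.rate_names,
            rates=df[list(m.rate_names)].to_numpy(),
            zero=df[[f"{n}_zero" for n in m.rate_names]].to_numpy().astype(bool),
            n_classes=df["n_classes"].to_numpy(),
            loglik=df["loglik"].to_numpy(),
            tree_index=df["tree_index"].to_numpy(),
            settings=settings or ChainSettings(),
            prior=prior or Prior(),
            acceptance_rate=float("nan"),
            final_ratedev=float("nan"),
        )


# ---------------------------------------------------------------------------
# the sampler


def autotune_ratedev(ratedev: float, acceptance_history, target: float = 0.30) -> float:
    """Multiplicative proposal-scale update toward a target acceptance rate.

    Applied only during burn-in (the scale is frozen afterwards so the
    post-burn-in kernel satisfies detailed balance).
    """
    hist = np.asarray(list(acceptance_history), dtype=float)
    if hist.size == 0:
        raise ValueError("acceptance history must be nonempty")
    observed = float(hist.mean())
    return float(np.clip(ratedev * math.exp(observed - target), 1e-6, 1e6))


class _ChainState:
    __slots__ = ("assign", "values", "hypers", "loglik", "tree_idx")

    def __init__(self, assign, values, hypers, loglik, tree_idx):
        self.assign = assign      # int array, -1 = zero bin, else class index
        self.values = values      # list[float], one per class
        self.hypers = hypers      # [shape, mean] for the gamma hyperprior
        self.loglik = loglik
        self.tree_idx = tree_idx

    def rate_vector(self) -> np.ndarray:
        vals = np.asarray(self.values + [0.0])
        return vals[self.assign]  # assign == -1 picks the trailing 0.0


def _draw_value(rng, prior: Prior, hypers) -> float:
    if prior.kind == "uniform":
        return float(rng.uniform(prior.lo, prior.hi))
    shape, mean = hypers
    return float(rng.gamma(shape, mean / shape))


def _value_logpdf(v: float, prior: Prior, hypers) -> float:
    if prior.kind == "uniform":
        if prior.lo < v < prior.hi:
            return -math.log(prior.hi - prior.lo)
        return -math.inf
    if v <= 0:
        return -math.inf
    shape, mean = hypers
    scale = mean / shape
    return (shape - 1.0) * math.log(v) - v / scale - shape * math.log(scale) - math.lgamma(shape)


def run_rjmcmc(
    model,
    trees: TreeSample,
    tips,
    prior: Prior,
    settings: ChainSettings,
    *,
    root_prior=None,
    likelihood: bool = True,
    init_value: float = 1.0,
) -> PosteriorSample:
    """Run one reversible-jump chain and return the thinned posterior sample.

    ``likelihood=False`` disables the data term (a constant likelihood), in
    which case the chain samples the prior over models and rate values — the
    basis of the prior-recovery validation.
    """
    model = get_model(model)
    if tips is not None and tips.n_states != model.n_states:
        raise ValueError(
            f"tip data has {tips.n_states} states but model {model.name!r} "
            f"expects {model.n_states}"
        )
    rng = np.random.default_rng(settings.seed)
    K = model.n_rates

    evaluators: list = [None] * len(trees)

    def loglik_fn(tree_idx: int, rates: np.ndarray) -> float:
        if not likelihood:
            return 0.0
        ev = evaluators[tree_idx]
        if ev is None:
            ev = ctmc.TreeLikelihood(trees[tree_idx], tips, root=root_prior)
            evaluators[tree_idx] = ev
        return ev.loglik(model.build_Q(rates))

    # initial state: all rates in one class
    hypers = [1.0, 1.0]
    if prior.kind == "gamma":
        hypers = [
            0.5 * (prior.gamma_shape_range[0] + prior.gamma_shape_range[1]),
            0.5 * (prior.gamma_mean_range[0] + prior.gamma_mean_range[1]),
        ]
    state = _ChainState(
        assign=np.zeros(K, dtype=np.int64),
        values=[float(init_value)],
        hypers=hypers,
        loglik=0.0,
        tree_idx=0,
    )
    state.loglik = loglik_fn(0, state.rate_vector())
    if not np.isfinite(state.loglik):
        raise ArithmeticError(
            "non-finite likelihood at initialization; "
            f"state: values={state.values}, tree=0"
        )

    # fixed move-type probabilities (constants, so they may appear in the
    # split/merge acceptance ratios)
    p_tree = 0.10 if len(trees) > 1 else 0.0
    p_hyper = 0.05 if prior.kind == "gamma" else 0.0
    p_split = p_merge = 0.125
    p_zero = 0.20
    p_value = 1.0 - p_tree - p_hyper - p_split - p_merge - p_zero
    thresholds = np.cumsum([p_value, p_split, p_merge, p_zero, p_tree, p_hyper])

    ratedev = settings.ratedev
    n_samples = settings.n_samples
    out_rates = np.empty((n_samples, K))
    out_zero = np.empty((n_samples, K), dtype=bool)
    out_nclass = np.empty(n_samples, dtype=np.int64)
    out_loglik = np.empty(n_samples)
    out_tree = np.empty(n_samples, dtype=np.int64)
    out_hypers = np.empty((n_samples, 2)) if prior.kind == "gamma" else None

    val_prop = val_acc = 0
    win_prop = win_acc = 0
    sample_i = 0

    for it in range(settings.iterations):
        u = rng.random()
        move = int(np.searchsorted(thresholds, u))

        if move == 0:
            # ---- value update
            k = len(state.values)
            if k > 0:
                c = int(rng.integers(k))
                v = state.values[c]
                v_new = v + (rng.random() - 0.5) * ratedev
                val_prop += 1
                win_prop += 1
                dprior = _value_logpdf(v_new, prior, state.hypers) - _value_logpdf(
                    v, prior, state.hypers
                )
                if np.isfinite(dprior):
                    old = state.values[c]
                    state.values[c] = v_new
                    ll = loglik_fn(state.tree_idx, state.rate_vector())
                    if math.log(rng.random() + 1e-300) < ll - state.loglik + dprior:
                        state.loglik = ll
                        val_acc += 1
                        win_acc += 1
                    else:
                        state.values[c] = old

        elif move == 1:
            # ---- split
            sizes = np.bincount(state.assign[state.assign >= 0],
                                minlength=len(state.values))
            eligible = np.flatnonzero(sizes >= 2)
            if eligible.size:
                c = int(eligible[int(rng.integers(eligible.size))])
                members = np.flatnonzero(state.assign == c)
                m = members.size
                while True:
                    bits = rng.integers(0, 2, m)
                    if 0 < bits.sum() < m:
                        break
                v_new = _draw_value(rng, prior, state.hypers)
                k = len(state.values)
                new_assign = state.assign.copy()
                new_assign[members[bits == 1]] = k
                new_values = state.values + [v_new]
                vals = np.asarray(new_values + [0.0])
                ll = loglik_fn(state.tree_idx, vals[new_assign])
                k1 = k + 1
                log_a = (
                    ll - state.loglik
                    + math.log(p_merge) - math.log(k1 * (k1 - 1))
                    - math.log(p_split) + math.log(eligible.size)
                    + math.log(2.0 ** m - 2.0)
                )
                if math.log(rng.random() + 1e-300) < log_a:
                    state.assign = new_assign
                    state.values = new_values
                    state.loglik = ll

        elif move == 2:
            # ---- merge
            k = len(state.values)
            if k >= 2:
                a = int(rng.integers(k))
                b = int(rng.integers(k - 1))
                if b >= a:
                    b += 1
                new_assign = state.assign.copy()
                new_assign[new_assign == b] = a
                new_assign[new_assign > b] -= 1
                a_after = a if a < b else a - 1
                new_values = [v for i, v in enumerate(state.values) if i != b]
                vals = np.asarray(new_values + [0.0])
                ll = loglik_fn(state.tree_idx, vals[new_assign])
                sizes_after = np.bincount(new_assign[new_assign >= 0],
                                          minlength=len(new_values))
                elig_after = int((sizes_after >= 2).sum())
                m_merged = int(sizes_after[a_after])
                log_a = (
                    ll - state.loglik
                    + math.log(p_split) - math.log(elig_after)
                    - math.log(2.0 ** m_merged - 2.0)
                    - math.log(p_merge) + math.log(k * (k - 1))
                )
                if math.log(rng.random() + 1e-300) < log_a:
                    state.assign = new_assign
                    state.values = new_values
                    state.loglik = ll

        elif move == 3:
            # ---- zero-bin move: a rate hops between the zero bin and any
            # class (an existing one or a fresh singleton).  Hastings factors
            # account for the 1/(k+1) destination choice; fresh-value proposal
            # densities cancel against the value prior.
            r = int(rng.integers(K))
            k = len(state.values)
            if state.assign[r] == -1:
                j = int(rng.integers(k + 1))
                new_assign = state.assign.copy()
                if j < k:  # join existing class j
                    new_assign[r] = j
                    new_values = state.values
                else:  # fresh singleton
                    v_new = _draw_value(rng, prior, state.hypers)
                    new_assign[r] = k
                    new_values = state.values + [v_new]
                log_h = math.log(k + 1.0)
                vals = np.asarray(list(new_values) + [0.0])
                ll = loglik_fn(state.tree_idx, vals[new_assign])
                if math.log(rng.random() + 1e-300) < ll - state.loglik + log_h:
                    state.assign = new_assign
                    state.values = list(new_values)
                    state.loglik = ll
            else:
                c = int(state.assign[r])
                members = int(np.sum(state.assign == c))
                new_assign = state.assign.copy()
                new_assign[r] = -1
                if members == 1:  # class disappears; reverse re-creates it
                    new_assign[new_assign > c] -= 1
                    new_values = [v for i, v in enumerate(state.values) if i != c]
                    log_h = -math.log(float(k))
                else:  # class survives; reverse rejoins it among k+1 choices
                    new_values = state.values
                    log_h = -math.log(k + 1.0)
                vals = np.asarray(list(new_values) + [0.0])
                ll = loglik_fn(state.tree_idx, vals[new_assign])
                if math.log(rng.random() + 1e-300) < ll - state.loglik + log_h:
                    state.assign = new_assign
                    state.values = list(new_values)
                    state.loglik = ll

        elif move == 4:
            # ---- tree move
            j = int(rng.integers(len(trees)))
            if j != state.tree_idx:
                ll = loglik_fn(j, state.rate_vector())
                if math.log(rng.random() + 1e-300) < ll - state.loglik:
                    state.tree_idx = j
                    state.loglik = ll

        else:
            # ---- gamma hyperparameter move
            which = int(rng.integers(2))  # 0: shape, 1: mean
            lo, hi = (prior.gamma_shape_range if which == 0
                      else prior.gamma_mean_range)
            cur = state.hypers[which]
            newh = cur + rng.normal(0.0, 0.1 * (hi - lo))
            if max(lo, 1e-6) < newh < hi:
                trial = list(state.hypers)
                trial[which] = newh
                dl = sum(
                    _value_logpdf(v, prior, trial) - _value_logpdf(v, prior, state.hypers)
                    for v in state.values
                )
                if math.log(rng.random() + 1e-300) < dl:
                    state.hypers = trial

        # ---- proposal-scale tuning during burn-in only
        if it < settings.burnin and win_prop >= settings.tune_interval:
            ratedev = autotune_ratedev(
                ratedev, [win_acc / win_prop], settings.target_acceptance
            )
            win_prop = win_acc = 0

        # ---- record
        if it >= settings.burnin and (it - settings.burnin + 1) % settings.thin == 0:
            if sample_i < n_samples:
                out_rates[sample_i] = state.rate_vector()
                out_zero[sample_i] = state.assign == -1
                out_nclass[sample_i] = len(state.values)
                out_loglik[sample_i] = state.loglik
                out_tree[sample_i] = state.tree_idx
                if out_hypers is not None:
                    out_hypers[sample_i] = state.hypers
                sample_i += 1

    return PosteriorSample(
        model=model.name,
        rate_names=model.rate_names,
        rates=out_rates[:sample_i],
        zero=out_zero[:sample_i],
        n_classes=out_nclass[:sample_i],
        loglik=out_loglik[:sample_i],
        tree_index=out_tree[:sample_i],
        settings=settings,
        prior=prior,
        acceptance_rate=val_acc / val_prop if val_prop else float("nan"),
        final_ratedev=ratedev,
        hypers=out_hypers[:sample_i] if out_hypers is not None else None,
    )


# ---------------------------------------------------------------------------
# marginal likelihood and diagnostics


def harmonic_mean_logL(sample) -> float:
    """Log of the harmonic mean of sampled likelihoods (log-space stable).

    log HM = log n - logsumexp(-logL_i).  Converges on the log marginal
    likelihood for long chains, though with high variance — callers should
    aggregate over independent runs.
    """
    logL = np.asarray(getattr(sample, "loglik", sample), dtype=float)
    if logL.size == 0:
        raise ValueError("empty sample")
    if logL.size < 2:
        raise ValueError("harmonic mean requires at least 2 samples")
    return float(np.log(logL.size) - logsumexp(-logL))


def effective_sample_size(x) -> float:
    """ESS by the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return float(n)
    var = x.var()
    if var == 0:
        return float(n)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1]
        if pair < 0:
            break
        s += pair
    ess = n / (1.0 + 2.0 * s)
    return float(min(max(ess, 1.0), n))


def chain_diagnostics(sample: PosteriorSample) -> dict:
    """Stationarity flag and per-parameter ESS; flags, never hard failures.

    Stationarity is a Geweke-style comparison of the first 10% and last 50%
    of the log-likelihood trace, with variances scaled by segment ESS.
    """
    logL = np.asarray(sample.loglik, dtype=float)
    n = logL.size
    if n < 10:
        raise ValueError("diagnostics require at least 10 samples")
    notes = []
    a = logL[: max(2, n // 10)]
    b = logL[n // 2:]
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        z = 0.0
        notes.append("zero-variance log-likelihood trace")
    else:
        ea, eb = effective_sample_size(a), effective_sample_size(b)
        z = (a.mean() - b.mean()) / math.sqrt(va / ea + vb / eb + 1e-300)
    ess = {"loglik": effective_sample_size(logL)}
    if ess["loglik"] == n and va == 0 and vb == 0:
        notes.append("loglik constant; ESS reported as sample size")
    for k, name in enumerate(sample.rate_names):
        col = sample.rates[:, k]
        ess[name] = effective_sample_size(col)
        if col.var() == 0:
            notes.append(f"{name} constant; ESS reported as sample size")
    return {
        "geweke_z": float(z),
        "stationary": bool(abs(z) < 2.0),
        "ess": ess,
        "notes": notes,
    }
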