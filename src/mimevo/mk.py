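"""Mk-model machinery for discrete colour-pattern evolution.

The k-state Mk model is a continuous-time Markov chain on a phylogeny: a
rate matrix Q (rows summing to zero) governs transitions among pattern
states along branches, and a root prior closes the likelihood. This module
provides

* transition probabilities (closed form for the equal-rates model, matrix
  exponential otherwise);
* trait simulation along a tree, optionally with the full change history;
* the pruning (post-order) log-likelihood with numerical scaling;
* maximum-likelihood rate estimation with a likelihood-ratio interval;
* marginal ancestral reconstruction (per-node posterior state vectors);
* a Bayesian variant — MCMC over the rate with per-sample joint
  ancestral-state draws;
* origin events: nodes whose most-probable state differs from the parent's,
  dated in relative time units, with reversals flagged.

States are 1-based (1..k) at the API surface, matching the six-state
colour-pattern coding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq, minimize_scalar

from .trees import Phylogeny, TreeIndex

__all__ = [
    "MkModel",
    "AncestralReconstruction",
    "OriginEvent",
    "RateFit",
    "transition_matrix",
    "simulate_trait",
    "simulate_history",
    "log_likelihood",
    "estimate_rate",
    "rate_interval",
    "marginal_ancestral",
    "bayesian_ancestral",
    "origin_events",
]


@dataclass(frozen=True)
class MkModel:
    """k-state Mk model: rate matrix + root prior."""

    k: int
    Q: np.ndarray
    structure: str = "equal_rates"
    root_prior: np.ndarray = None

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        if Q.shape != (self.k, self.k):
            raise ValueError("Q must be k x k")
        off = Q[~np.eye(self.k, dtype=bool)]
        if (off < -1e-12).any():
            raise ValueError("off-diagonal rates must be non-negative")
        if np.abs(Q.sum(axis=1)).max() > 1e-10:
            raise ValueError("Q rows must sum to zero")
        prior = self.root_prior
        if prior is None:
            prior = np.full(self.k, 1.0 / self.k)
        prior = np.asarray(prior, dtype=float)
        if abs(prior.sum() - 1.0) > 1e-9:
            raise ValueError("root prior must sum to 1")
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "root_prior", prior)

    @classmethod
    def equal_rates(cls, k: int, rate: float, root_prior=None) -> "MkModel":
        """ER model: every off-diagonal rate equals ``rate``."""
        if rate < 0:
            raise ValueError("rate must be non-negative")
        Q = np.full((k, k), rate)
        np.fill_diagonal(Q, -(k - 1) * rate)
        return cls(k=k, Q=Q, structure="equal_rates", root_prior=root_prior)

    @property
    def er_rate(self) -> float:
        if self.structure != "equal_rates":
            raise ValueError("not an equal-rates model")
        return float(self.Q[0, 1]) if self.k > 1 else 0.0


def transition_matrix(model: MkModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1.

    The equal-rates case uses the closed form
    P_ii = 1/k + (k-1)/k · e^{-k·mu·t}, P_ij = 1/k − 1/k · e^{-k·mu·t}.
    """
    if t < 0:
        raise ValueError("elapsed time must be non-negative")
    k = model.k
    if model.structure == "equal_rates":
        mu = model.er_rate
        e = math.exp(-k * mu * t)
        P = np.full((k, k), (1.0 - e) / k)
        np.fill_diagonal(P, (1.0 + (k - 1) * e) / k)
        return P
    return expm(model.Q * t)


def _branch_transition_matrices(model: MkModel, lengths: np.ndarray) -> np.ndarray:
    """Stack of P(t) for every branch length (vectorised for ER)."""
    k = model.k
    if model.structure == "equal_rates":
        mu = model.er_rate
        e = np.exp(-k * mu * np.asarray(lengths))
        P = np.empty((len(lengths), k, k))
        P[:] = ((1.0 - e) / k)[:, None, None]
        idx = np.arange(k)
        P[:, idx, idx] = ((1.0 + (k - 1) * e) / k)[:, None]
        return P
    return np.stack([expm(model.Q * t) for t in lengths])


# ---------------------------------------------------------------------------
# Simulation


def simulate_trait(tree: Phylogeny, model: MkModel, seed) -> Dict[str, int]:
    """Simulate tip states (1-based) under the Mk model; seed-reproducible."""
    traits, _, _ = simulate_history(tree, model, seed, record_changes=False)
    return traits


def simulate_history(
    tree: Phylogeny,
    model: MkModel,
    seed,
    record_changes: bool = True,
):
    """Simulate a trait and (optionally) its full change history.

    Returns ``(tip_states, changes, root_state)`` where changes is a list of
    ``(child_node_index, time_along_branch, from_state, to_state)`` recording
    every substitution event on the branch above the given node (times
    measured from the branch's rootward end). Uses the exact Gillespie walk
    along each branch, so the recorded history replays to the tip states.
    """
    rng = np.random.default_rng(seed)
    idx = tree.index()
    k = model.k
    Q = model.Q
    states = np.zeros(idx.n_nodes, dtype=int)
    states[idx.root] = rng.choice(k, p=model.root_prior)
    changes: List[Tuple[int, float, int, int]] = []
    # walk root -> leaves
    stack = [idx.root]
    while stack:
        node = stack.pop()
        for child in idx.children[node]:
            s = states[node]
            t_total = idx.lengths[child]
            t = 0.0
            while True:
                out_rate = -Q[s, s]
                if out_rate <= 0:
                    break
                t += rng.exponential(1.0 / out_rate)
                if t >= t_total:
                    break
                probs = Q[s].copy()
                probs[s] = 0.0
                probs = probs / probs.sum()
                new_s = rng.choice(k, p=probs)
                if record_changes:
                    changes.append((int(child), float(t), int(s + 1), int(new_s + 1)))
                s = new_s
            states[child] = s
            stack.append(child)
    tips = {lab: int(states[i]) + 1 for i, lab in enumerate(idx.tip_labels)}
    return tips, changes, int(states[idx.root]) + 1


# ---------------------------------------------------------------------------
# Likelihood


def _tip_likelihoods(idx: TreeIndex, k: int, traits: Dict[str, int]) -> np.ndarray:
    unknown = set(traits) - set(idx.tip_labels)
    if unknown:
        raise ValueError(f"traits reference unknown tips: {sorted(unknown)[:5]}")
    L = np.ones((idx.n_nodes, k))
    for lab, i in idx.tip_index.items():
        s = traits.get(lab)
        if s is None:
            continue  # missing data: vector of ones
        if not (1 <= int(s) <= k):
            raise ValueError(f"state {s} for tip {lab!r} outside 1..{k}")
        L[i, :] = 0.0
        L[i, int(s) - 1] = 1.0
    return L


def _pruning(
    idx: TreeIndex, model: MkModel, traits: Dict[str, int]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Post-order partial likelihoods with per-node log scaling.

    Returns (partials, log_scale, P) where partials[i] are the scaled
    conditional likelihoods at node i, log_scale[i] the accumulated log
    scaling below i, and P the per-branch transition matrices.
    """
    k = model.k
    P = _branch_transition_matrices(model, idx.lengths)
    partial = _tip_likelihoods(idx, k, traits)
    log_scale = np.zeros(idx.n_nodes)
    for node in idx.postorder:
        vec = np.ones(k)
        ls = 0.0
        for child in idx.children[node]:
            vec = vec * (P[child] @ partial[child])
            ls += log_scale[child]
        m = vec.max()
        if m <= 0:
            # impossible configuration under this model
            partial[node] = vec
            log_scale[node] = -np.inf
            continue
        partial[node] = vec / m
        log_scale[node] = ls + math.log(m)
    return partial, log_scale, P


def log_likelihood(tree: Phylogeny, model: MkModel, traits: Dict[str, int]) -> float:
    """Felsenstein pruning log-likelihood of tip states under the model."""
    idx = tree.index() if isinstance(tree, Phylogeny) else tree
    partial, log_scale, _ = _pruning(idx, model, traits)
    root = idx.root
    lik = float(model.root_prior @ partial[root])
    if lik <= 0 or not np.isfinite(log_scale[root]):
        return -np.inf
    return math.log(lik) + float(log_scale[root])


@dataclass
class RateFit:
    """ML equal-rates fit: point estimate, log-likelihood, model, flags."""

    model: MkModel
    rate: float
    log_lik: float
    boundary: bool = False
    interval: Optional[Tuple[float, float]] = None


def estimate_rate(
    tree: Phylogeny,
    traits: Dict[str, int],
    k: Optional[int] = None,
    structure: str = "equal_rates",
    rate_max: float = 100.0,
    tol: float = 1e-8,
) -> RateFit:
    """Maximise the ER likelihood over the single transition rate.

    A constant (single observed state) trait sits at the mu = 0 boundary and
    is reported as such with a warning. ``k`` defaults to the number of
    observed states (use 6 for the colour-pattern coding).
    """
    if structure != "equal_rates":
        raise NotImplementedError("only equal_rates estimation is implemented")
    observed = {int(s) for s in traits.values() if s is not None}
    if k is None:
        k = max(observed) if observed else 2
    idx = tree.index() if isinstance(tree, Phylogeny) else tree
    if len(observed) < 2:
        warnings.warn("constant trait: ML rate is at the 0 boundary")
        model = MkModel.equal_rates(k, 0.0)
        return RateFit(model=model, rate=0.0,
                       log_lik=log_likelihood(tree, model, traits), boundary=True)

    def nll(log_mu):
        model = MkModel.equal_rates(k, math.exp(log_mu))
        return -log_likelihood(idx, model, traits)

    res = minimize_scalar(
        nll, bounds=(math.log(1e-8), math.log(rate_max)), method="bounded",
        options={"xatol": tol},
    )
    mu = math.exp(res.x)
    model = MkModel.equal_rates(k, mu)
    boundary = mu <= 2e-8 or mu >= rate_max * 0.99
    return RateFit(model=model, rate=mu, log_lik=-res.fun, boundary=boundary)


def rate_interval(
    tree: Phylogeny,
    traits: Dict[str, int],
    fit: RateFit,
    level: float = 0.95,
) -> Tuple[float, float]:
    """Likelihood-ratio confidence interval for the ER rate.

    The bounds solve logL(mu) = logL(mu_hat) − chi2_{1,level}/2 on either
    side of the estimate (profile likelihood for the 1-parameter model).
    """
    from scipy.stats import chi2

    idx = tree.index() if isinstance(tree, Phylogeny) else tree
    drop = chi2.ppf(level, df=1) / 2.0
    target = fit.log_lik - drop
    k = fit.model.k

    def f(mu):
        return log_likelihood(idx, MkModel.equal_rates(k, mu), traits) - target

    mu_hat = max(fit.rate, 1e-10)
    lo = 0.0
    if f(1e-10) < 0:
        lo = brentq(f, 1e-10, mu_hat, xtol=1e-10)
    hi_bracket = mu_hat * 2 if mu_hat > 0 else 1.0
    while f(hi_bracket) > 0 and hi_bracket < 1e6:
        hi_bracket *= 4
    hi = hi_bracket if hi_bracket >= 1e6 else brentq(f, mu_hat, hi_bracket, xtol=1e-10)
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Ancestral reconstruction


@dataclass
class AncestralReconstruction:
    """Per-internal-node state probabilities and MAP calls.

    ``node_probs`` is (n_nodes, k); tip rows hold their observed indicator
    (or the flat vector for missing tips). ``map_state`` holds 1-based MAP
    states for every node, ties broken toward the lower state index and
    recorded in ``ties``.
    """

    tree_index: TreeIndex
    node_probs: np.ndarray
    map_state: np.ndarray
    method: str
    ties: List[int] = field(default_factory=list)
    rate_samples: Optional[np.ndarray] = None
    ess: Optional[float] = None

    def prob(self, node: int) -> np.ndarray:
        return self.node_probs[node]


def _map_states(probs: np.ndarray) -> Tuple[np.ndarray, List[int]]:
    map_state = probs.argmax(axis=1) + 1  # argmax takes the lowest index on ties
    ties = [
        int(i)
        for i in range(len(probs))
        if (np.isclose(probs[i], probs[i].max(), rtol=0, atol=1e-12)).sum() > 1
    ]
    return map_state.astype(int), ties


def marginal_ancestral(
    tree: Phylogeny,
    model: MkModel,
    traits: Dict[str, int],
) -> AncestralReconstruction:
    """Marginal (empirical-Bayes) ancestral state probabilities.

    Standard inside/outside passes: the post-order pass gives conditional
    likelihoods below each node, a pre-order pass propagates the likelihood
    of everything outside, and the normalised product is the marginal
    posterior P(state at node | all tips).
    """
    idx = tree.index() if isinstance(tree, Phylogeny) else tree
    k = model.k
    partial, log_scale, P = _pruning(idx, model, traits)
    outside = np.zeros((idx.n_nodes, k))
    outside[idx.root] = model.root_prior
    # pre-order: root first
    for node in reversed(idx.postorder):
        for child in idx.children[node]:
            sib = np.ones(k)
            for other in idx.children[node]:
                if other != child:
                    sib = sib * (P[other] @ partial[other])
            msg = outside[node] * sib
            out = msg @ P[child]  # sum_i msg_i P_ij
            s = out.sum()
            outside[child] = out / s if s > 0 else out
    probs = outside * partial
    sums = probs.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    probs = probs / sums
    map_state, ties = _map_states(probs)
    return AncestralReconstruction(
        tree_index=idx, node_probs=probs, map_state=map_state,
        method="marginal_ML", ties=ties,
    )


def _sample_joint_history(
    idx: TreeIndex, model: MkModel, partial: np.ndarray, P: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one joint ancestral-state assignment (backward sampling)."""
    k = model.k
    states = np.zeros(idx.n_nodes, dtype=int)
    root = idx.root
    p = model.root_prior * partial[root]
    p = p / p.sum()
    states[root] = rng.choice(k, p=p)
    for node in reversed(idx.postorder):
        for child in idx.children[node]:
            p = P[child][states[node], :] * partial[child]
            p = p / p.sum()
            states[child] = rng.choice(k, p=p)
    return states


def _ess(x: np.ndarray) -> float:
    """Initial-positive-sequence effective sample size of a scalar chain."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for lag in range(1, n // 2):
        if acf[lag] <= 0:
            break
        s += acf[lag]
    return float(n / (1.0 + 2.0 * s))


def bayesian_ancestral(
    tree: Phylogeny,
    traits: Dict[str, int],
    k: Optional[int] = None,
    generations: int = 1_000_000,
    sample_every: int = 1_000,
    burnin_fraction: float = 0.25,
    seed: int = 0,
    proposal_sd: float = 0.6,
) -> AncestralReconstruction:
    """Bayesian ancestral reconstruction under the ER Mk model.

    A Metropolis chain samples the transition rate (exponential prior with
    mean at the ML estimate; log-scale random-walk proposals); every
    ``sample_every`` generations one joint ancestral-state draw is taken.
    After discarding ``burnin_fraction`` of the samples, per-node posterior
    state frequencies and MAP calls are reported, with the rate-chain ESS.
    A poorly mixing chain (ESS < 100) triggers a warning, not a failure.
    """
    if generations < 10 * sample_every:
        raise ValueError("need at least 10 retained samples (generations too small)")
    rng = np.random.default_rng(seed)
    idx = tree.index() if isinstance(tree, Phylogeny) else tree
    observed = {int(s) for s in traits.values() if s is not None}
    if k is None:
        k = max(observed) if observed else 2
    fit = estimate_rate(tree, traits, k=k)
    prior_mean = max(fit.rate, 1e-3)

    def log_post(mu):
        if mu <= 0:
            return -np.inf
        ll = log_likelihood(idx, MkModel.equal_rates(k, mu), traits)
        return ll - mu / prior_mean  # exponential prior (log-density up to const)

    mu = prior_mean
    lp = log_post(mu)
    n_samples = generations // sample_every
    rates = np.zeros(n_samples)
    draws = np.zeros((n_samples, idx.n_nodes), dtype=int)
    for s in range(n_samples):
        for _ in range(sample_every):
            prop = mu * math.exp(proposal_sd * rng.normal())
            lp_prop = log_post(prop)
            # log-scale proposal Jacobian: q(mu->prop)/q(prop->mu) = prop/mu
            if math.log(rng.uniform()) < lp_prop - lp + math.log(prop / mu):
                mu, lp = prop, lp_prop
        rates[s] = mu
        model = MkModel.equal_rates(k, mu)
        partial, _, P = _pruning(idx, model, traits)
        draws[s] = _sample_joint_history(idx, model, partial, P, rng)
    burn = int(burnin_fraction * n_samples)
    kept = draws[burn:]
    kept_rates = rates[burn:]
    probs = np.zeros((idx.n_nodes, k))
    for state in range(k):
        probs[:, state] = (kept == state).mean(axis=0)
    map_state, ties = _map_states(probs)
    ess = _ess(kept_rates)
    if ess < 100:
        warnings.warn(f"rate chain mixing is poor (ESS = {ess:.1f} < 100)")
    return AncestralReconstruction(
        tree_index=idx, node_probs=probs, map_state=map_state,
        method="bayesian_mcmc", ties=ties, rate_samples=kept_rates, ess=ess,
    )


# ---------------------------------------------------------------------------
# Origin events


@dataclass(frozen=True)
class OriginEvent:
    """A state origin: a node whose MAP state differs from its parent's."""

    state: int
    node: int
    rtu_age: float
    parent_state: int
    is_reversal: bool


def origin_events(
    rtu_tree: Phylogeny,
    rec: AncestralReconstruction,
) -> List[OriginEvent]:
    """Date state origins on a relative-time tree from a reconstruction.

    An event is recorded at every node whose MAP state differs from its
    parent's; its age is the RTU age of the child node of the transition
    branch (the conservative, latest-possible origin). An event is a
    reversal when its state equals the MAP state of some strict ancestor
    above the parent (a return to an ancestral pattern). Events are sorted
    oldest-first; the per-state independent-origin count is the number of
    events for that state.
    """
    idx = rec.tree_index
    fresh = rtu_tree.index()
    if fresh.tip_labels != idx.tip_labels or fresh.n_nodes != idx.n_nodes:
        raise ValueError("reconstruction does not match the supplied tree")
    ages_by_node = rtu_tree.node_ages()
    # map dendropy nodes to index positions via a fresh index traversal
    order = _node_order(rtu_tree)
    ages = np.zeros(idx.n_nodes)
    for node, i in order.items():
        ages[i] = ages_by_node[node]
    events = []
    for node in range(idx.n_nodes):
        parent = idx.parent[node]
        if parent < 0:
            continue
        s, ps = int(rec.map_state[node]), int(rec.map_state[parent])
        if s == ps:
            continue
        # ancestral MAP states strictly above the parent
        anc_states = set()
        a = idx.parent[parent]
        while a >= 0:
            anc_states.add(int(rec.map_state[a]))
            a = idx.parent[a]
        events.append(
            OriginEvent(
                state=s, node=int(node), rtu_age=float(ages[node]),
                parent_state=ps, is_reversal=s in anc_states,
            )
        )
    events.sort(key=lambda e: (-e.rtu_age, e.node))
    return events


def _node_order(tree: Phylogeny):
    """Node -> index mapping consistent with Phylogeny.index()."""
    tips = list(tree._tree.leaf_node_iter())
    order = {node: i for i, node in enumerate(tips)}
    internal = [n for n in tree._tree.postorder_node_iter() if not n.is_leaf()]
    for j, node in enumerate(internal):
        order[node] = len(tips) + j
    return order


def origin_counts(events: Sequence[OriginEvent]) -> Dict[int, int]:
    """Independent-origin count per state (reversals included as events)."""
    counts: Dict[int, int] = {}
    for e in events:
        counts[e.state] = counts.get(e.state, 0) + 1
    return counts
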