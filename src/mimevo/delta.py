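"""δ-statistic phylogenetic signal for categorical traits.

δ measures how strongly a categorical trait is structured by a phylogeny.
The computation follows the published entropy-based Bayesian recipe:

1. an MCMC over the equal-rates Mk transition rate yields, at each retained
   rate sample, marginal ancestral state probabilities at every internal
   node; averaging across samples gives posterior node probability vectors;
2. the Shannon entropy of each node vector, normalised by log k, measures
   the uncertainty of that ancestral state;
3. the node entropies are modelled as Beta(α, β) draws; a Metropolis chain
   with exponential priors samples (α, β), and δ = mean(β)/mean(α).

Low node uncertainties (trait tracks the tree) push the Beta mass toward 0,
inflating β relative to α — so larger δ means stronger phylogenetic signal.
Significance comes from a tip-label shuffle null: the trait is permuted
across tips, δ recomputed, and p = (1 + #{null ≥ observed}) / (1 + n).

A clade must carry at least 20 tips and at least two observed states; the
computation is refused (never silently run) otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .mk import MkModel, estimate_rate, log_likelihood, marginal_ancestral
from .trees import Phylogeny

__all__ = [
    "DeltaSettings",
    "DeltaResult",
    "split_clades",
    "compute_delta",
    "shuffle_null",
    "MIN_CLADE_SIZE",
]

MIN_CLADE_SIZE = 20


@dataclass(frozen=True)
class DeltaSettings:
    """MCMC settings for δ.

    ``sim``/``thin``/``burn`` govern the Beta-parameter chain: ``sim``
    Metropolis iterations thinned every ``thin``, with the first ``burn``
    retained samples discarded. Defaults carry the original analysis
    settings (sim=1e6, thin=100, burn=2500); desk-scale work can shrink
    them. ``rate_samples``/``rate_steps`` govern the ancestral-probability
    MCMC over the Mk rate; ``lambda0`` is the exponential-prior rate and
    ``se`` the proposal s.d. of the Beta chain, at the reference method's
    defaults.
    """

    sim: int = 1_000_000
    thin: int = 100
    burn: int = 2_500
    lambda0: float = 0.1
    se: float = 0.5
    rate_samples: int = 20
    rate_steps: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.sim < self.thin:
            raise ValueError("sim must be >= thin")
        if self.burn >= self.sim // self.thin:
            raise ValueError("burn must leave retained samples (burn < sim/thin)")


@dataclass
class DeltaResult:
    """δ for one clade, with the shuffle null when computed."""

    delta: float
    clade: str
    n_tips: int
    settings: DeltaSettings
    entropies: np.ndarray
    null_deltas: List[float] = field(default_factory=list)
    p_value: Optional[float] = None


def split_clades(
    tree: Phylogeny,
    clade_map: Dict[str, str],
    min_size: int = MIN_CLADE_SIZE,
) -> Tuple[Dict[str, Phylogeny], Dict[str, str]]:
    """Split a tree into named clades of at least ``min_size`` tips.

    ``clade_map`` assigns each tip to a named group (e.g. a subfamily); the
    induced subtree of each sufficiently large group is returned, and
    undersized groups are reported in the skipped map with the reason.
    """
    tips = set(tree.tip_labels)
    by_clade: Dict[str, List[str]] = {}
    for tip, clade in clade_map.items():
        if tip in tips:
            by_clade.setdefault(clade, []).append(tip)
    retained: Dict[str, Phylogeny] = {}
    skipped: Dict[str, str] = {}
    for clade, members in sorted(by_clade.items()):
        if len(members) < min_size:
            skipped[clade] = (
                f"below threshold: {len(members)} tips < {min_size}"
            )
        else:
            retained[clade] = tree.prune_to(members)
    return retained, skipped


def _posterior_node_entropies(
    tree: Phylogeny,
    traits: Dict[str, int],
    k: int,
    settings: DeltaSettings,
    rng: np.random.Generator,
) -> np.ndarray:
    """Posterior ancestral probabilities → normalised node entropies.

    A short Metropolis chain over the ER rate (exponential prior centred on
    the ML estimate, log-scale proposals) is thinned to ``rate_samples``
    draws; marginal ancestral vectors are averaged across draws.
    """
    idx = tree.index()
    fit = estimate_rate(idx, traits, k=k)
    prior_mean = max(fit.rate, 1e-3)

    def log_post(mu):
        if mu <= 0:
            return -np.inf
        return log_likelihood(idx, MkModel.equal_rates(k, mu), traits) - mu / prior_mean

    mu = prior_mean
    lp = log_post(mu)
    n_internal = idx.n_nodes - idx.n_tips
    acc = np.zeros((n_internal, k))
    for _ in range(settings.rate_samples):
        for _ in range(settings.rate_steps):
            prop = mu * math.exp(0.5 * rng.normal())
            lpp = log_post(prop)
            if math.log(rng.uniform()) < lpp - lp + math.log(prop / mu):
                mu, lp = prop, lpp
        rec = marginal_ancestral(idx, MkModel.equal_rates(k, mu), traits)
        acc += rec.node_probs[idx.n_tips :, :]
    probs = acc / settings.rate_samples
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log(probs), 0.0)
    ent = -plogp.sum(axis=1) / math.log(k)
    return ent


def _beta_mcmc(
    x: np.ndarray, settings: DeltaSettings, rng: np.random.Generator
) -> np.ndarray:
    """Metropolis chain over Beta(α, β) fitted to the entropies.

    The Beta log-likelihood reduces to sufficient statistics
    (Σ log x, Σ log(1−x)), so each iteration is scalar arithmetic.
    """
    n = len(x)
    slx = float(np.log(x).sum())
    sl1x = float(np.log1p(-x).sum())
    lam = settings.lambda0
    lgamma = math.lgamma

    def log_post(a: float, b: float) -> float:
        if a <= 0 or b <= 0:
            return -math.inf
        return (
            (a - 1.0) * slx
            + (b - 1.0) * sl1x
            - n * (lgamma(a) + lgamma(b) - lgamma(a + b))
            - lam * (a + b)  # independent exponential priors
        )

    a = float(rng.exponential(1.0)) + 0.1
    b = float(rng.exponential(1.0)) + 0.1
    lp = log_post(a, b)
    n_keep = settings.sim // settings.thin
    out = np.zeros((n_keep, 2))
    se = settings.se
    i_keep = 0
    normals = rng.normal(0.0, se, size=settings.sim)
    unifs = rng.uniform(1e-300, 1.0, size=settings.sim)
    for it in range(settings.sim):
        if it % 2 == 0:
            prop = abs(a + normals[it])
            lpp = log_post(prop, b)
            if math.log(unifs[it]) < lpp - lp:
                a, lp = prop, lpp
        else:
            prop = abs(b + normals[it])
            lpp = log_post(a, prop)
            if math.log(unifs[it]) < lpp - lp:
                b, lp = prop, lpp
        if (it + 1) % settings.thin == 0:
            out[i_keep] = (a, b)
            i_keep += 1
    return out[settings.burn :]


def compute_delta(
    tree: Phylogeny,
    traits: Dict[str, int],
    settings: Optional[DeltaSettings] = None,
    clade: str = "",
    k: Optional[int] = None,
) -> DeltaResult:
    """δ phylogenetic signal of a categorical trait on one clade.

    Deterministic given the settings seed; larger δ means the trait tracks
    the phylogeny more closely. Raises for clades under 20 tips and for
    constant traits (zero-entropy degeneracy).
    """
    settings = settings or DeltaSettings()
    n_tips = tree.n_tips
    if n_tips < MIN_CLADE_SIZE:
        raise ValueError(
            f"delta requires at least {MIN_CLADE_SIZE} taxa, got {n_tips}"
        )
    observed = sorted({int(s) for t, s in traits.items() if s is not None
                       and t in set(tree.tip_labels)})
    if len(observed) < 2:
        raise ValueError("degenerate trait: fewer than two observed states")
    if k is None:
        k = max(observed)
    rng = np.random.default_rng(settings.seed)
    ent = _posterior_node_entropies(tree, traits, k, settings, rng)
    # keep entropies strictly inside (0, 1) for the Beta model
    eps = 1e-6
    x = np.clip(ent, eps, 1.0 - eps)
    samples = _beta_mcmc(x, settings, rng)
    delta = float(samples[:, 1].mean() / samples[:, 0].mean())
    return DeltaResult(
        delta=delta, clade=clade, n_tips=n_tips, settings=settings, entropies=ent,
    )


def shuffle_null(
    tree: Phylogeny,
    traits: Dict[str, int],
    settings: Optional[DeltaSettings] = None,
    n_shuffles: int = 100,
    clade: str = "",
    k: Optional[int] = None,
) -> DeltaResult:
    """δ with a tip-label permutation null and an add-one p-value.

    The observed δ is compared against δ recomputed on ``n_shuffles``
    independent permutations of the trait across tips;
    p = (1 + #{null ≥ observed}) / (1 + n_shuffles). A permutation that
    happens to reproduce the original labelling still counts.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle for a null distribution")
    settings = settings or DeltaSettings()
    result = compute_delta(tree, traits, settings, clade=clade, k=k)
    rng = np.random.default_rng(np.random.SeedSequence([settings.seed, 0xD3]))
    labels = [t for t in tree.tip_labels if t in traits]
    values = [traits[t] for t in labels]
    nulls = []
    for i in range(n_shuffles):
        perm = rng.permutation(len(values))
        shuffled = {labels[j]: values[perm[j]] for j in range(len(values))}
        sub_settings = replace(settings, seed=int(rng.integers(2**31 - 1)))
        nulls.append(
            compute_delta(tree, shuffled, sub_settings, clade=clade, k=k).delta
        )
    result.null_deltas = nulls
    result.p_value = (1 + sum(d >= result.delta for d in nulls)) / (1 + n_shuffles)
    return result
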