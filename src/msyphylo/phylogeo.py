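"""Discrete ancestral-region inference over six geographic macroregions.

Each tip of the mutation tree is assigned one (or a set of) region(s);
ancestral nodes are inferred under two models:

* **Fitch parsimony** — two-pass minimum-change state sets, the quick
  deterministic baseline;
* a **Bayesian single-rate CTMC** — regions evolve along branches under a
  symmetric (equal-exchangeability) continuous-time Markov chain; the
  migration rate gets a diffuse prior and is integrated out by MCMC.
  Each posterior draw assigns exactly one region to every ancestral node
  (sampled jointly from the conditional distribution given the tips), and
  per-node marginal posteriors are the tallies of those draws.

The symmetric model is a deliberate stand-in for unpublished
"Bayesian binary MCMC"-style machinery: it targets the same per-node
marginal posterior summaries from the same inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .tree import MutationTree

REGIONS: tuple[str, ...] = (
    "Central-Western Africa",
    "Southern Africa",
    "Eastern Africa",
    "Northern Africa",
    "Europe",
    "Rest-of-world",
)

TipRegions = Mapping[str, Union[str, Sequence[str], frozenset]]


def _tip_vector(value, alphabet: Sequence[str]) -> np.ndarray:
    states = [value] if isinstance(value, str) else list(value)
    vec = np.zeros(len(alphabet))
    for s in states:
        if s not in alphabet:
            raise KeyError(f"unknown region {s!r}")
        vec[alphabet.index(s)] = 1.0
    if vec.sum() == 0:
        raise ValueError("tip assigned no region")
    return vec


# ----------------------------------------------------------------------
# Fitch parsimony
# ----------------------------------------------------------------------
@dataclass
class FitchResult:
    state_sets: dict[str, frozenset[str]]
    n_changes: int


def fitch_state_sets(
    tree: MutationTree,
    tips: TipRegions,
    alphabet: Sequence[str] = REGIONS,
) -> FitchResult:
    """Two-pass minimum-change parsimony state sets.

    Implemented as unit-cost dynamic programming (down-pass) plus an
    outside pass, which on binary trees reproduces classic Fitch sets and
    stays exact on polytomies.  A node's reported set contains exactly
    the states it takes in at least one minimum-change labelling;
    multi-region tips enter with all their allowed states at cost zero.
    """
    k = len(alphabet)
    idx = {s: i for i, s in enumerate(alphabet)}
    INF = float("inf")
    down: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            if node.label not in tips:
                raise KeyError(f"tip {node.label!r} has no region assignment")
            value = tips[node.label]
            states = [value] if isinstance(value, str) else list(value)
            unknown = set(states) - set(alphabet)
            if unknown:
                raise KeyError(f"unknown region(s) {sorted(unknown)}")
            cost = np.full(k, INF)
            for s in states:
                cost[idx[s]] = 0.0
            down[id(node)] = cost
        else:
            cost = np.zeros(k)
            for child in node.children:
                c = down[id(child)]
                best = c.min()
                # staying costs c[s]; switching costs best+1
                cost += np.minimum(c, best + 1.0)
            down[id(node)] = cost

    up: dict[int, np.ndarray] = {id(tree.root): np.zeros(k)}
    for node in tree.preorder():
        base = up[id(node)]
        for child in node.children:
            # cost above the child if the parent takes state s
            sib_cost = base.copy()
            for sib in node.children:
                if sib is not child:
                    c = down[id(sib)]
                    sib_cost += np.minimum(c, c.min() + 1.0)
            c_up = np.minimum(sib_cost, sib_cost.min() + 1.0)
            up[id(child)] = c_up

    n_changes = int(down[id(tree.root)].min())
    labelled: dict[str, frozenset[str]] = {}
    for i, node in enumerate(tree.preorder()):
        key = node.label if node.label is not None else f"_node{i}"
        total = down[id(node)] + up[id(node)]
        labelled[key] = frozenset(
            alphabet[j] for j in range(k) if total[j] == n_changes
        )
    return FitchResult(state_sets=labelled, n_changes=n_changes)


# ----------------------------------------------------------------------
# CTMC machinery
# ----------------------------------------------------------------------
def transition_matrix(rate: float, duration: float, k: int) -> np.ndarray:
    """Symmetric k-state CTMC transition probabilities.

    Total leaving rate ``rate``; all destinations equally likely.  Closed
    form from the single non-unit eigenvalue exp(-k/(k-1) * rate * t).
    """
    decay = math.exp(-k / (k - 1) * rate * duration)
    p_same = 1.0 / k + (1.0 - 1.0 / k) * decay
    p_diff = (1.0 - decay) / k
    mat = np.full((k, k), p_diff)
    np.fill_diagonal(mat, p_same)
    return mat


def _branch_durations(tree: MutationTree, unit_lengths: bool) -> dict[int, float]:
    durations: dict[int, float] = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        if unit_lengths or node.age is None or node.parent.age is None:
            durations[id(node)] = 1.0
        else:
            durations[id(node)] = max(node.parent.age - node.age, 0.0)
    return durations


def _partials(
    tree: MutationTree,
    tips: TipRegions,
    rate: float,
    durations: Mapping[int, float],
    alphabet: Sequence[str],
) -> dict[int, np.ndarray]:
    """Felsenstein pruning: P(tip data below v | state of v)."""
    k = len(alphabet)
    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            partial[id(node)] = _tip_vector(tips[node.label], alphabet)
        else:
            vec = np.ones(k)
            for child in node.children:
                pmat = transition_matrix(rate, durations[id(child)], k)
                vec *= pmat @ partial[id(child)]
            partial[id(node)] = vec
    return partial


def log_likelihood(
    tree: MutationTree,
    tips: TipRegions,
    rate: float,
    unit_lengths: bool = False,
    alphabet: Sequence[str] = REGIONS,
) -> float:
    """Log P(tip regions | tree, rate) with a uniform root prior."""
    durations = _branch_durations(tree, unit_lengths)
    partial = _partials(tree, tips, rate, durations, alphabet)
    root = partial[id(tree.root)]
    return float(np.log(root.mean()))


def exact_node_posteriors(
    tree: MutationTree,
    tips: TipRegions,
    rate: float,
    unit_lengths: bool = False,
    alphabet: Sequence[str] = REGIONS,
) -> dict[str, np.ndarray]:
    """Exact per-node marginal posteriors at a fixed rate (inside-outside
    message passing with a uniform root prior)."""
    k = len(alphabet)
    durations = _branch_durations(tree, unit_lengths)
    partial = _partials(tree, tips, rate, durations, alphabet)

    outside: dict[int, np.ndarray] = {id(tree.root): np.full(k, 1.0 / k)}
    for node in tree.preorder():
        for child in node.children:
            # message to child: outside(node) x product of sibling messages
            vec = outside[id(node)].copy()
            for sib in node.children:
                if sib is child:
                    continue
                pmat = transition_matrix(rate, durations[id(sib)], k)
                vec *= pmat @ partial[id(sib)]
            pmat = transition_matrix(rate, durations[id(child)], k)
            outside[id(child)] = vec @ pmat
    out: dict[str, np.ndarray] = {}
    for i, node in enumerate(tree.preorder()):
        key = node.label if node.label is not None else f"_node{i}"
        post = outside[id(node)] * partial[id(node)]
        out[key] = post / post.sum()
    return out


def _sample_joint_states(
    tree: MutationTree,
    partial: Mapping[int, np.ndarray],
    rate: float,
    durations: Mapping[int, float],
    k: int,
    rng: np.random.Generator,
) -> dict[int, int]:
    """Draw one joint ancestral labelling from the conditional posterior.

    Degenerate zero-probability partials (conflicting tips on zero-length
    branches) fall back to the uniform prior, so the posterior stays
    defined rather than erroring.
    """
    states: dict[int, int] = {}
    root_post = _normalize_or_uniform(partial[id(tree.root)])
    states[id(tree.root)] = int(rng.choice(k, p=root_post))
    for node in tree.preorder():
        for child in node.children:
            pmat = transition_matrix(rate, durations[id(child)], k)
            weights = _normalize_or_uniform(
                pmat[states[id(node)]] * partial[id(child)]
            )
            states[id(child)] = int(rng.choice(k, p=weights))
    return states


def _normalize_or_uniform(vec: np.ndarray) -> np.ndarray:
    total = vec.sum()
    if total <= 0 or not np.isfinite(total):
        return np.full(len(vec), 1.0 / len(vec))
    return vec / total


@dataclass
class PhylogeoConfig:
    n_samples: int = 20_000
    burnin: int = 2_000
    seed: int = 5222
    rate_prior_mean: Optional[float] = None  # default: 5 / total tree length
    fixed_rate: Optional[float] = None
    unit_lengths: bool = False


@dataclass
class NodeRegionPosterior:
    alphabet: tuple[str, ...]
    probabilities: dict[str, np.ndarray]
    rate_samples: np.ndarray = field(default_factory=lambda: np.empty(0))

    def vector(self, node: str) -> np.ndarray:
        return self.probabilities[node]


def bayes_regions(
    tree: MutationTree,
    tips: TipRegions,
    config: Optional[PhylogeoConfig] = None,
    alphabet: Sequence[str] = REGIONS,
) -> NodeRegionPosterior:
    """Posterior region probabilities for every node of the tree.

    The migration rate is either fixed (``config.fixed_rate``) or sampled
    by Metropolis random walk under an exponential prior whose mean puts a
    handful of expected migrations on the whole tree.  For each retained
    iteration one joint single-region labelling of the ancestral nodes is
    drawn; marginals are the tallies.  Deterministic under the seed.
    """
    config = config or PhylogeoConfig()
    rng = np.random.default_rng(config.seed)
    k = len(alphabet)
    durations = _branch_durations(tree, config.unit_lengths)
    total_len = sum(durations.values())
    # diffuse default: about five expected migrations over the whole tree
    prior_mean = config.rate_prior_mean or 5.0 / max(total_len, 1e-12)

    nodes = list(tree.preorder())
    keys = [
        nd.label if nd.label is not None else f"_node{i}"
        for i, nd in enumerate(nodes)
    ]
    tallies = {key: np.zeros(k) for key in keys}

    def loglik(rate: float) -> tuple[float, dict[int, np.ndarray]]:
        part = _partials(tree, tips, rate, durations, alphabet)
        root = part[id(tree.root)]
        return float(np.log(max(root.mean(), 1e-300))), part

    if config.fixed_rate is not None:
        rate = config.fixed_rate
        _, part = loglik(rate)
        rate_draws = np.full(config.n_samples, rate)
        # vectorized joint draws: sample every iteration's root state at
        # once, then each child conditioned on its parent's states
        n_draws = config.n_samples
        root_post = _normalize_or_uniform(part[id(tree.root)])
        draws: dict[int, np.ndarray] = {
            id(tree.root): rng.choice(k, size=n_draws, p=root_post)
        }
        for node in tree.preorder():
            for child in node.children:
                pmat = transition_matrix(rate, durations[id(child)], k)
                cond = pmat * part[id(child)][None, :]
                sums = cond.sum(axis=1, keepdims=True)
                cond = np.where(
                    sums > 0, cond / np.where(sums > 0, sums, 1.0), 1.0 / k
                )
                cum = np.cumsum(cond, axis=1)
                u = rng.random(n_draws)
                parent_states = draws[id(node)]
                draws[id(child)] = (
                    u[:, None] > cum[parent_states]
                ).sum(axis=1)
        for nd, key in zip(nodes, keys):
            tallies[key] = np.bincount(draws[id(nd)], minlength=k).astype(float)
    else:
        rate = prior_mean
        ll, part = loglik(rate)
        lp = ll - rate / prior_mean
        rate_list: list[float] = []
        total_iters = config.burnin + config.n_samples
        for it in range(total_iters):
            cand = rate * math.exp(0.3 * rng.normal())
            ll_c, part_c = loglik(cand)
            lp_c = ll_c - cand / prior_mean
            if math.log(rng.random() + 1e-300) < lp_c - lp + math.log(
                cand / rate
            ):
                rate, lp, part = cand, lp_c, part_c
            if it >= config.burnin:
                rate_list.append(rate)
                states = _sample_joint_states(
                    tree, part, rate, durations, k, rng
                )
                for nd, key in zip(nodes, keys):
                    tallies[key][states[id(nd)]] += 1
        rate_draws = np.array(rate_list)

    probabilities = {
        key: tally / tally.sum() for key, tally in tallies.items()
    }
    return NodeRegionPosterior(
        alphabet=tuple(alphabet),
        probabilities=probabilities,
        rate_samples=rate_draws,
    )


def summarize_origin(
    posterior: NodeRegionPosterior, node: str
) -> tuple[str, float, bool]:
    """(best region, posterior probability, tie flag) for a node.

    Ties (within 1e-9) are broken by alphabet order and flagged.
    """
    vec = posterior.vector(node)
    best = int(np.argmax(vec))
    tie = bool(np.sum(np.abs(vec - vec[best]) < 1e-9) > 1)
    return posterior.alphabet[best], float(vec[best]), tie
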