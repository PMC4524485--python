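"""Node-age estimation from per-branch mutation counts.

Two estimators are provided, mirroring common practice in Y-chromosome
SNP dating:

* the **rho statistic** — the mean number of mutations separating a
  node's descendant tips from the node itself.  Under a strict molecular
  clock E[rho] = mu * t, so dividing by the calibrated per-lineage
  mutation rate converts rho directly to years.  The associated standard
  error uses the Saillard estimator, sigma^2 = (1/n^2) * sum_b n_b^2 m_b,
  summing over branches below the node (n_b descendant tips through
  branch b carrying m_b mutations).

* a **Bayesian strict-clock sampler** — MCMC over internal-node ages with
  a Poisson likelihood on per-branch mutation counts (on a perfect
  phylogeny the sequence likelihood factorizes to exactly these counts)
  and a coalescent prior with an exponential-expansion population
  trajectory.  This is a deliberately simplified stand-in for full
  sequence-level Bayesian dating; it targets the same node-age posteriors
  from the same sufficient statistics.

All ages are stored in years; the customary reporting unit is ka.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .tree import MutationTree, TreeNode


@dataclass(frozen=True)
class CalibratedClock:
    """Per-site substitution rate and target length.

    Defaults are the fossil-calibrated rate 0.716e-9 /site/year and the
    1,495,512-bp MSY target it was calibrated for.
    """

    rate_per_site_year: float = 0.716e-9
    target_length_bp: int = 1_495_512

    def __post_init__(self) -> None:
        if self.rate_per_site_year <= 0 or self.target_length_bp <= 0:
            raise ValueError("clock rate and target length must be positive")

    @property
    def per_lineage_rate_year(self) -> float:
        """Expected mutations per lineage per year over the target."""
        return self.rate_per_site_year * self.target_length_bp

    def mutations_to_years(self, mutations: float) -> float:
        return mutations / self.per_lineage_rate_year

    def years_to_mutations(self, years: float) -> float:
        return years * self.per_lineage_rate_year


PAPER_CLOCK = CalibratedClock()


@dataclass
class NodeAgeEstimate:
    node: str
    rho: float
    sigma: float
    age_years: float
    ci_low_years: float
    ci_high_years: float

    @property
    def age_ka(self) -> float:
        return self.age_years / 1000.0


def _tip_counts_and_distances(
    node: TreeNode,
) -> tuple[int, float, list[tuple[int, int]]]:
    """(n_tips, sum of node-to-tip mutation distances, [(n_b, m_b)...])."""
    branches: list[tuple[int, int]] = []

    def recurse(nd: TreeNode, depth: int) -> tuple[int, float]:
        if nd.is_tip:
            n_below, dist_sum = 1, float(depth)
        else:
            n_below, dist_sum = 0, 0.0
            for child in nd.children:
                nc, dc = recurse(child, depth + len(child.mutations))
                n_below += nc
                dist_sum += dc
        return n_below, dist_sum

    n_total = 0
    total = 0.0
    for child in node.children:
        nc, dc = recurse(child, len(child.mutations))
        n_total += nc
        total += dc

    # second pass for per-branch tip counts
    def count(nd: TreeNode) -> int:
        if nd.is_tip:
            n = 1
        else:
            n = sum(count(c) for c in nd.children)
        branches.append((n, len(nd.mutations)))
        return n

    for child in node.children:
        count(child)
    if node.is_tip:
        n_total, total = 1, 0.0
    return n_total, total, branches


def rho_statistic(tree: MutationTree, node: str) -> float:
    """Mean mutation-count distance from ``node`` to its descendant tips."""
    nd = tree.find(node)
    n, total, _ = _tip_counts_and_distances(nd)
    if n == 0:
        raise ValueError(f"node {node!r} has no descendant tips")
    return total / n


def rho_sigma(tree: MutationTree, node: str) -> float:
    """Saillard standard error of rho at ``node``."""
    nd = tree.find(node)
    n, _, branches = _tip_counts_and_distances(nd)
    if n == 0:
        raise ValueError(f"node {node!r} has no descendant tips")
    if nd.is_tip:
        # a single lineage: Poisson, variance = mutation count on its branch
        return math.sqrt(len(nd.mutations))
    var = sum(nb * nb * mb for nb, mb in branches) / (n * n)
    return math.sqrt(var)


def age_from_rho(
    rho: float, sigma: float, clock: CalibratedClock, node: str = ""
) -> NodeAgeEstimate:
    """Convert a rho value and its standard error to years.

    The 95% interval is the normal approximation rho +/- 1.96 sigma,
    floored at zero.
    """
    if rho < 0:
        raise ValueError("rho must be non-negative")
    lam = clock.per_lineage_rate_year
    return NodeAgeEstimate(
        node=node,
        rho=rho,
        sigma=sigma,
        age_years=rho / lam,
        ci_low_years=max(0.0, (rho - 1.96 * sigma) / lam),
        ci_high_years=max(0.0, (rho + 1.96 * sigma) / lam),
    )


def date_node(
    tree: MutationTree, node: str, clock: CalibratedClock = PAPER_CLOCK
) -> NodeAgeEstimate:
    """rho-date one internal node of a mutation tree."""
    rho = rho_statistic(tree, node)
    sigma = rho_sigma(tree, node)
    return age_from_rho(rho, sigma, clock, node=node)


def date_all_nodes(
    tree: MutationTree, clock: CalibratedClock = PAPER_CLOCK
) -> dict[str, NodeAgeEstimate]:
    return {
        nd.label: date_node(tree, nd.label, clock)
        for nd in tree.internal_nodes()
        if nd.label is not None
    }


# ----------------------------------------------------------------------
# Bayesian strict-clock dating
# ----------------------------------------------------------------------
@dataclass
class PriorSpec:
    """Hyperpriors for the expansion-coalescent tree prior.

    current_size: lognormal(log-mean, log-sd) on the present male
    effective population size (in units of years, i.e. Ne x generation
    time); ratio: exponential(mean) on the ancestral/current size ratio;
    growth: uniform[0, hi] on the per-year growth rate of the recent
    expansion phase.
    """

    current_size_logmean: float = 10.0
    current_size_logsd: float = 3.0
    ratio_mean: float = 0.2
    growth_hi: float = 0.00133


@dataclass
class BayesDatingConfig:
    chain_steps: int = 200_000
    sample_every: int = 200
    burnin_fraction: float = 0.2
    priors: PriorSpec = field(default_factory=PriorSpec)
    seed: int = 1515
    ess_warn_threshold: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 < self.burnin_fraction < 1.0:
            raise ValueError("burnin_fraction must be in (0, 1)")
        if self.chain_steps < 10 * self.sample_every:
            raise ValueError("chain_steps must be >= 10 * sample_every")


@dataclass
class PosteriorSummary:
    node: str
    mean_years: float
    hpd_low_years: float
    hpd_high_years: float
    ess: float

    @property
    def mean_ka(self) -> float:
        return self.mean_years / 1000.0


def _hpd(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    x = np.sort(samples)
    n = len(x)
    k = max(1, int(math.ceil(mass * n)))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def _ess(x: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS estimate."""
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.var(x) * n)
    tau = 1.0
    for lag in range(1, n // 2):
        if acf[lag] < 0.05:
            break
        tau += 2.0 * acf[lag]
    return float(n / tau)


class _ExpansionCoalescent:
    """Log-density of coalescent node times under an expansion trajectory.

    Backwards in time the population shrinks from N0 at rate g until it
    reaches the ancestral size r*N0, constant earlier.  Sizes are in
    "coalescent years" (Ne x generation time), so the pairwise
    coalescence rate at time t is 1/N(t).
    """

    @staticmethod
    def log_density(
        coal_times: np.ndarray, n_tips: int, n0: float, ratio: float, g: float
    ) -> float:
        if np.any(coal_times <= 0):
            return -np.inf
        t_star = math.log(1.0 / ratio) / g if g > 0 and ratio < 1 else 0.0
        n_anc = ratio * n0

        def inv_n(t: float) -> float:
            if g <= 0 or ratio >= 1:
                return 1.0 / n0
            return 1.0 / (n0 * math.exp(-g * t)) if t < t_star else 1.0 / n_anc

        def cum_inv_n(t: float) -> float:
            # integral of 1/N(u) du from 0 to t
            if g <= 0 or ratio >= 1:
                return t / n0
            if t <= t_star:
                return (math.exp(g * t) - 1.0) / (n0 * g)
            head = (math.exp(g * t_star) - 1.0) / (n0 * g)
            return head + (t - t_star) / n_anc

        times = np.sort(coal_times)
        logp = 0.0
        t_prev = 0.0
        k = n_tips
        for t in times:
            pairs = k * (k - 1) / 2.0
            logp -= pairs * (cum_inv_n(float(t)) - cum_inv_n(t_prev))
            logp += math.log(inv_n(float(t)))
            t_prev = float(t)
            k -= 1
        return logp


def bayes_node_ages(
    tree: MutationTree,
    clock: CalibratedClock = PAPER_CLOCK,
    config: BayesDatingConfig | None = None,
) -> dict[str, PosteriorSummary]:
    """MCMC posterior over internal-node ages.

    Node ages are constrained to parent >= child; each branch contributes
    Poisson(per-lineage-rate x duration) on its observed mutation count;
    the node times get an expansion-coalescent prior whose three
    hyperparameters (current size, ancestral/current ratio, growth rate)
    are sampled under the configured hyperpriors.  Deterministic under a
    fixed seed.
    """
    config = config or BayesDatingConfig()
    rng = np.random.default_rng(config.seed)
    lam = clock.per_lineage_rate_year

    nodes = list(tree.preorder())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.array(
        [index[id(nd.parent)] if nd.parent is not None else -1 for nd in nodes]
    )
    counts = np.array([len(nd.mutations) for nd in nodes], dtype=float)
    is_tip = np.array([nd.is_tip for nd in nodes])
    internal = np.where(~is_tip)[0]
    n_tips = int(is_tip.sum())
    children: dict[int, list[int]] = {i: [] for i in range(len(nodes))}
    for i, p in enumerate(parent):
        if p >= 0:
            children[p].append(i)

    # initial ages from rho-like path averages (counts / lam), jittered
    ages = np.zeros(len(nodes))
    for i in reversed(range(len(nodes))):  # postorder-ish: children first
        nd = nodes[i]
        if not nd.is_tip:
            kid_ages = [ages[c] + (counts[c] + 0.5) / lam for c in children[i]]
            ages[i] = max(kid_ages)
    # fix ordering: ensure strictly increasing rootwards
    for i in range(len(nodes)):
        p = parent[i]
        if p >= 0 and ages[p] <= ages[i] and not is_tip[i]:
            ages[p] = ages[i] * 1.01 + 1.0

    n0 = math.exp(config.priors.current_size_logmean)
    ratio = config.priors.ratio_mean
    growth = 0.5 * config.priors.growth_hi
    prior = config.priors

    def log_likelihood(a: np.ndarray) -> float:
        dur = a[parent[1:]] - a[1:]
        if np.any(dur < 0):
            return -np.inf
        mu = lam * dur
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = counts[1:] * np.log(np.where(mu > 0, mu, 1.0)) - mu
        if np.any((mu == 0) & (counts[1:] > 0)):
            return -np.inf
        return float(terms.sum())

    def log_prior(a: np.ndarray, n0_: float, r_: float, g_: float) -> float:
        if n0_ <= 0 or r_ <= 0:
            return -np.inf
        if not 0.0 <= g_ <= prior.growth_hi:
            return -np.inf
        lp = (
            -((math.log(n0_) - prior.current_size_logmean) ** 2)
            / (2 * prior.current_size_logsd**2)
            - math.log(n0_)
            - r_ / prior.ratio_mean
        )
        coal = _ExpansionCoalescent.log_density(
            a[internal], n_tips, n0_, r_, g_
        )
        return lp + coal

    def log_post(a: np.ndarray, n0_: float, r_: float, g_: float) -> float:
        ll = log_likelihood(a)
        if not np.isfinite(ll):
            return -np.inf
        return ll + log_prior(a, n0_, r_, g_)

    current = log_post(ages, n0, ratio, growth)
    if not np.isfinite(current):
        raise RuntimeError("could not initialize the dating chain")

    n_int = len(internal)
    kept: list[np.ndarray] = []
    keep_from = int(config.burnin_fraction * config.chain_steps)

    for step in range(config.chain_steps):
        kind = step % (n_int + 3)
        if kind < n_int:
            i = internal[rng.integers(n_int)]
            lo = max((ages[c] for c in children[i]), default=0.0)
            hi = ages[parent[i]] if parent[i] >= 0 else math.inf
            old = ages[i]
            if math.isinf(hi):
                newv = old * math.exp(0.2 * rng.normal())
            else:
                width = 0.25 * (hi - lo) + 1.0
                newv = old + width * (rng.random() - 0.5)
                if newv < lo or newv > hi:
                    newv = old  # reject out-of-bounds directly
            ages[i] = newv
            prop = log_post(ages, n0, ratio, growth)
            log_hastings = (
                math.log(newv / old)
                if math.isinf(hi) and old > 0 and newv > 0
                else 0.0
            )
            if math.log(rng.random() + 1e-300) < prop - current + log_hastings:
                current = prop
            else:
                ages[i] = old
        else:
            which = kind - n_int
            old3 = (n0, ratio, growth)
            if which == 0:
                n0_p = n0 * math.exp(0.3 * rng.normal())
                cand = (n0_p, ratio, growth)
                lh = math.log(n0_p / n0)
            elif which == 1:
                r_p = ratio * math.exp(0.3 * rng.normal())
                cand = (n0, r_p, growth)
                lh = math.log(r_p / ratio)
            else:
                g_p = growth + 0.1 * prior.growth_hi * rng.normal()
                cand = (n0, ratio, g_p)
                lh = 0.0
            prop = log_post(ages, *cand)
            if math.log(rng.random() + 1e-300) < prop - current + lh:
                n0, ratio, growth = cand
                current = prop
            else:
                n0, ratio, growth = old3
        if step >= keep_from and step % config.sample_every == 0:
            kept.append(ages[internal].copy())

    draws = np.array(kept)  # (n_kept, n_internal)
    out: dict[str, PosteriorSummary] = {}
    for col, i in enumerate(internal):
        label = nodes[i].label or f"_node{i}"
        x = draws[:, col]
        lo, hi = _hpd(x)
        ess = _ess(x)
        if ess < config.ess_warn_threshold:
            warnings.warn(
                f"node {label!r}: effective sample size {ess:.0f} below "
                f"{config.ess_warn_threshold:.0f}; consider a longer chain",
                stacklevel=2,
            )
        out[label] = PosteriorSummary(
            node=label,
            mean_years=float(x.mean()),
            hpd_low_years=lo,
            hpd_high_years=hi,
            ess=ess,
        )
    return out
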