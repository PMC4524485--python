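"""Synthetic Y-chromosome data with the structure the pipeline assumes.

The generator produces, from one seed:

* a haploid genealogy under an expansion coalescent (recent exponential
  growth on top of a constant ancestral size), node times in years;
* Poisson mutations dropped on every branch at the calibrated
  per-lineage rate, under infinite sites (every mutation is a fresh,
  uniquely named biallelic site), yielding a variant matrix;
* tip macroregions evolved down the tree under a symmetric low-rate CTMC;
* staged genotype panels consistent with a lineage assignment through the
  marker hierarchy, plus a matching population table.

Every stage records its ground truth so downstream modules can be tested
by round trip.  Genealogy simulation is delegated to msprime; mutation
dropping, region evolution and panel emission are done here because the
per-branch bookkeeping is exactly what the tests need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import msprime
import numpy as np

from .classify import (
    ANCESTRAL,
    DERIVED,
    GenotypeRecord,
    MarkerHierarchy,
    MarkerNode,
    next_markers,
)
from .dating import PAPER_CLOCK, CalibratedClock
from .io import VariantMatrix
from .phylogeo import REGIONS, transition_matrix
from .tree import MutationTree, TreeNode


@dataclass
class SimConfig:
    """Study-scale defaults: 33 sampled chromosomes on the calibrated
    1.5-Mb clock, with a male effective population expanding from a
    constant ancestral size (ratio 0.2) at the midpoint of the growth
    prior, generation time 30 years — giving root ages near 60 ka."""

    n_tips: int = 33
    clock: CalibratedClock = field(default_factory=lambda: PAPER_CLOCK)
    current_size: float = 5000.0  # male effective size, individuals
    ancestral_ratio: float = 0.2
    growth_rate_per_year: float = 6.65e-4
    generation_time_years: float = 30.0
    region_rate_per_year: float = 5e-6
    root_region: str = "Eastern Africa"
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("need at least two tips")
        if min(
            self.current_size,
            self.ancestral_ratio,
            self.generation_time_years,
        ) <= 0:
            raise ValueError("demographic parameters must be positive")
        if self.growth_rate_per_year < 0 or self.region_rate_per_year < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class SimTruth:
    """Ground truth of one simulated data set."""

    tree: MutationTree  # node.age in years; branch mutations once dropped
    config: SimConfig
    node_regions: dict[str, str] = field(default_factory=dict)
    tip_lineages: dict[str, str] = field(default_factory=dict)

    def tip_labels(self) -> list[str]:
        return self.tree.tip_labels()

    def node_ages(self) -> dict[str, float]:
        return {
            n.label: n.age
            for n in self.tree.preorder()
            if n.label is not None and n.age is not None
        }

    def branch_mutation_lists(self) -> dict[str, list[str]]:
        return {
            n.label: sorted(n.mutations)
            for n in self.tree.preorder()
            if n.label is not None
        }


def _demography(config: SimConfig) -> msprime.Demography:
    gen = config.generation_time_years
    dem = msprime.Demography()
    # msprime works in generations; sizes in individuals
    g_per_gen = config.growth_rate_per_year * gen
    dem.add_population(
        name="pop",
        initial_size=config.current_size,
        growth_rate=g_per_gen,
    )
    if config.growth_rate_per_year > 0 and config.ancestral_ratio < 1:
        t_star_years = (
            math.log(1.0 / config.ancestral_ratio)
            / config.growth_rate_per_year
        )
        dem.add_population_parameters_change(
            time=t_star_years / gen,
            population="pop",
            initial_size=config.current_size * config.ancestral_ratio,
            growth_rate=0.0,
        )
    return dem


def simulate_genealogy(config: SimConfig) -> SimTruth:
    """Coalescent genealogy with node times in years, deterministic under
    the config seed."""
    ts = msprime.sim_ancestry(
        samples=config.n_tips,
        ploidy=1,
        demography=_demography(config),
        random_seed=config.seed % (2**31 - 1) + 1,
    )
    t = ts.first()
    gen = config.generation_time_years
    width = max(2, len(str(config.n_tips)))

    internal_counter = 0

    def convert(u: int) -> TreeNode:
        nonlocal internal_counter
        kids = list(t.children(u))
        age = t.time(u) * gen
        if not kids:
            label = f"S{u + 1:0{width}d}"
            return TreeNode(label=label, age=age)
        internal_counter += 1
        node = TreeNode(label=None, age=age)
        for v in kids:
            node.add_child(convert(v))
        return node

    root = convert(t.root)
    tree = MutationTree(root).canonicalize()
    # stable internal labels after canonicalization
    i = 0
    for node in tree.preorder():
        if not node.is_tip:
            node.label = "root" if node.parent is None else f"node{i}"
            i += 1
    return SimTruth(tree=tree, config=config)


def drop_mutations(
    truth: SimTruth, clock: Optional[CalibratedClock] = None
) -> VariantMatrix:
    """Poisson mutations on every branch; returns the variant matrix.

    Each branch receives Poisson(per-lineage-rate x duration) brand-new
    sites (infinite sites); the derived carriers of a site are exactly
    the tips below its branch.  Mutation names are recorded on the tree's
    branches for round-trip checks.
    """
    clock = clock or truth.config.clock
    rng = np.random.default_rng((truth.config.seed, 0xC0A1E5CE))
    lam = clock.per_lineage_rate_year
    tree = truth.tree
    tips = tree.tip_labels()
    tip_index = {s: j for j, s in enumerate(tips)}

    site_names: list[str] = []
    positions: list[int] = []
    rows: list[np.ndarray] = []
    counter = 0
    for node in tree.preorder():
        if node.parent is None:
            continue
        duration = node.parent.age - node.age
        count = rng.poisson(lam * duration)
        below = tree.tips_below(node)
        node.mutations = set()
        for _ in range(count):
            counter += 1
            name = f"X{counter:05d}"
            node.mutations.add(name)
            site_names.append(name)
            positions.append(counter)
            row = np.zeros(len(tips), dtype=np.int8)
            for s in below:
                row[tip_index[s]] = 1
            rows.append(row)
    calls = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.zeros((0, len(tips)), dtype=np.int8)
    )
    return VariantMatrix(
        site_names, positions, tips, calls, clock.target_length_bp
    )


def evolve_regions(
    truth: SimTruth,
    alphabet: Sequence[str] = REGIONS,
    rate: Optional[float] = None,
    root_region: Optional[str] = None,
) -> SimTruth:
    """Evolve regions down the tree under the symmetric CTMC.

    Transitions are drawn from the exact endpoint distribution on each
    branch.  Node regions (including tips) are stored on the truth.
    """
    rate = truth.config.region_rate_per_year if rate is None else rate
    root_region = root_region or truth.config.root_region
    if root_region not in alphabet:
        raise KeyError(f"unknown root region {root_region!r}")
    rng = np.random.default_rng((truth.config.seed, 0x9E010))
    k = len(alphabet)
    tree = truth.tree
    states: dict[int, int] = {id(tree.root): alphabet.index(root_region)}
    for node in tree.preorder():
        for child in node.children:
            duration = node.age - child.age
            pmat = transition_matrix(rate, duration, k)
            probs = pmat[states[id(node)]]
            states[id(child)] = int(rng.choice(k, p=probs))
    truth.node_regions = {
        node.label: alphabet[states[id(node)]]
        for node in tree.preorder()
        if node.label is not None
    }
    return truth


def tip_regions(truth: SimTruth) -> dict[str, str]:
    return {
        tip: truth.node_regions[tip]
        for tip in truth.tip_labels()
    }


def _random_lineage(
    hierarchy: MarkerHierarchy, rng: np.random.Generator, stop_prob: float
) -> MarkerNode:
    node = hierarchy.root
    while node.children and rng.random() > stop_prob:
        node = node.children[rng.integers(len(node.children))]
    return node


def emit_genotype_panel(
    truth: SimTruth,
    hierarchy: MarkerHierarchy,
    stop_prob: float = 0.25,
    not_in_clade_prob: float = 0.0,
) -> tuple[list[GenotypeRecord], dict[str, str]]:
    """Staged genotype records for every tip, plus a population mapping.

    Each tip is assigned a lineage (a node of the marker hierarchy, or
    outside the clade with probability ``not_in_clade_prob``); its record
    is then filled by repeatedly asking the staged planner for the next
    markers and answering truthfully (derived iff the marker's branch
    lies on the root-to-lineage path).  The resulting record contains
    derived calls exactly along the path and ancestral calls for the
    tested off-path markers.  Population labels come from tip regions
    when present, else a single default population.
    """
    rng = np.random.default_rng((truth.config.seed, 0x6E407))
    records: list[GenotypeRecord] = []
    populations: dict[str, str] = {}
    for tip in truth.tip_labels():
        record = GenotypeRecord(sample=tip)
        if rng.random() < not_in_clade_prob:
            lineage: Optional[MarkerNode] = None
            truth.tip_lineages[tip] = f"not-{hierarchy.root.label}"
        else:
            lineage = _random_lineage(hierarchy, rng, stop_prob)
            truth.tip_lineages[tip] = lineage.label
        on_path = (
            {n.label for n in hierarchy.path_to_root(lineage)}
            if lineage is not None
            else set()
        )
        # stage the screening exactly as a genotyping lab would
        markers = next_markers(record, hierarchy)
        while markers:
            for m in markers:
                node = hierarchy.node_for_mutation(m)
                state = DERIVED if node.label in on_path else ANCESTRAL
                record.set(m, state)
            markers = next_markers(record, hierarchy)
        records.append(record)
        populations[tip] = truth.node_regions.get(tip, "panel")
    return records, populations
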