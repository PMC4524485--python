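"""Hierarchical marker-tree haplogroup classification.

Y-chromosome haplogroups are defined by derived alleles at biallelic
markers arranged in a known rooted hierarchy.  Genotyping is staged: a
sample is first typed at the top-level markers, and only markers below a
derived node are tested next, so each chromosome is resolved with a small
fraction of the panel.  A chromosome derived at a node but ancestral at
all of that node's tested children belongs to the node's *paragroup*,
written e.g. ``E-M35*`` when every child was excluded.

The module plans the next markers to type, calls the most-derived
haplogroup, validates calls against the hierarchy, and tabulates
population x haplogroup counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
import yaml

ANCESTRAL, DERIVED, UNTESTED = "ancestral", "derived", "untested"


class GenotypeConflictError(ValueError):
    pass


@dataclass
class MarkerNode:
    """One haplogroup in the hierarchy.

    ``mutations`` lists the phylogenetically equivalent markers defining
    the branch (any one of them identifies the clade).  ``stage`` orders
    sibling testing: children at a later stage are only planned once every
    earlier-stage sibling has been tested ancestral (this encodes screens
    such as "test the common branch first, the rare sister only on the
    remainder").
    """

    label: str
    mutations: list[str]
    children: list["MarkerNode"] = field(default_factory=list)
    stage: int = 0
    parent: Optional["MarkerNode"] = None

    def __post_init__(self) -> None:
        if not self.mutations:
            raise ValueError(f"node {self.label!r} has no defining mutations")


class MarkerHierarchy:
    """Rooted tree of genotyped markers with haplogroup labels."""

    def __init__(self, root: MarkerNode) -> None:
        self.root = root
        self._by_label: dict[str, MarkerNode] = {}
        self._by_mutation: dict[str, MarkerNode] = {}
        for node in self.walk():
            if node.label in self._by_label:
                raise ValueError(f"duplicate haplogroup label {node.label!r}")
            self._by_label[node.label] = node
            for m in node.mutations:
                if m in self._by_mutation:
                    raise ValueError(f"mutation {m!r} defines two branches")
                self._by_mutation[m] = node
            for child in node.children:
                child.parent = node

    def walk(self) -> Iterable[MarkerNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def node(self, label: str) -> MarkerNode:
        return self._by_label[label]

    def node_for_mutation(self, mutation: str) -> Optional[MarkerNode]:
        return self._by_mutation.get(mutation)

    def known_mutations(self) -> set[str]:
        return set(self._by_mutation)

    def path_to_root(self, node: MarkerNode) -> list[MarkerNode]:
        path = []
        cur: Optional[MarkerNode] = node
        while cur is not None:
            path.append(cur)
            cur = cur.parent
        return path[::-1]

    def is_ancestor(self, anc: MarkerNode, desc: MarkerNode) -> bool:
        cur: Optional[MarkerNode] = desc
        while cur is not None:
            if cur is anc:
                return True
            cur = cur.parent
        return False

    def depth_first_labels(self) -> list[str]:
        return [n.label for n in self.walk()]

    @classmethod
    def from_yaml(cls, source: Union[str, Path]) -> "MarkerHierarchy":
        """Load a hierarchy from YAML: nested mappings with ``label``,
        ``mutations`` and optional ``children``/``stage`` keys."""
        text = Path(source).read_text()
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_dict(cls, spec: Mapping) -> "MarkerHierarchy":
        def build(d: Mapping) -> MarkerNode:
            node = MarkerNode(
                label=d["label"],
                mutations=list(d["mutations"]),
                stage=int(d.get("stage", 0)),
            )
            for child in d.get("children", []):
                node.children.append(build(child))
            return node

        return cls(build(spec))


def default_hierarchy() -> MarkerHierarchy:
    """The shipped haplogroup-E marker tree (62 genotyped markers plus the
    basal branches), encoded as package data."""
    ref = resources.files("msyphylo").joinpath("data/e_tree.yaml")
    return MarkerHierarchy.from_dict(yaml.safe_load(ref.read_text()))


# ----------------------------------------------------------------------
# genotype records and calls
# ----------------------------------------------------------------------
@dataclass
class GenotypeRecord:
    sample: str
    calls: dict[str, str] = field(default_factory=dict)

    def state(self, mutation: str) -> str:
        return self.calls.get(mutation, UNTESTED)

    def set(self, mutation: str, state: str) -> None:
        if state not in (ANCESTRAL, DERIVED, UNTESTED):
            raise ValueError(f"bad genotype state {state!r}")
        self.calls[mutation] = state


@dataclass
class HaplogroupCall:
    sample: str
    terminal_label: str
    is_paragroup: bool
    path: list[str]
    untested_children: list[str]
    excluded_children: list[str] = field(default_factory=list)

    @property
    def display_label(self) -> str:
        if self.is_paragroup:
            return self.terminal_label + "*"
        if self.untested_children:
            return self.terminal_label + " (unresolved)"
        return self.terminal_label


@dataclass
class Violation:
    kind: str  # "ancestor-ancestral", "incomparable", "unknown-marker",
    #            "equivalent-disagreement"
    detail: str


def _node_state(record: GenotypeRecord, node: MarkerNode) -> str:
    """Aggregate state of a branch over its equivalent mutations."""
    states = {record.state(m) for m in node.mutations}
    states.discard(UNTESTED)
    if not states:
        return UNTESTED
    if len(states) > 1:
        raise GenotypeConflictError(
            f"equivalent mutations of {node.label!r} disagree: "
            + ", ".join(f"{m}={record.state(m)}" for m in node.mutations)
        )
    return states.pop()


def validate(
    record: GenotypeRecord, hierarchy: MarkerHierarchy
) -> list[Violation]:
    """Tree-consistency screen for a genotype record."""
    violations: list[Violation] = []
    for m in record.calls:
        if hierarchy.node_for_mutation(m) is None:
            violations.append(Violation("unknown-marker", m))

    derived_nodes: list[MarkerNode] = []
    for node in hierarchy.walk():
        try:
            state = _node_state(record, node)
        except GenotypeConflictError as exc:
            violations.append(Violation("equivalent-disagreement", str(exc)))
            continue
        if state == DERIVED:
            derived_nodes.append(node)
            anc = node.parent
            while anc is not None:
                try:
                    if _node_state(record, anc) == ANCESTRAL:
                        violations.append(
                            Violation(
                                "ancestor-ancestral",
                                f"{node.label} derived but ancestor "
                                f"{anc.label} tested ancestral",
                            )
                        )
                except GenotypeConflictError:
                    pass
                anc = anc.parent
    for i, a in enumerate(derived_nodes):
        for b in derived_nodes[i + 1 :]:
            if not (
                hierarchy.is_ancestor(a, b) or hierarchy.is_ancestor(b, a)
            ):
                violations.append(
                    Violation(
                        "incomparable",
                        f"derived at {a.label} and {b.label}, which lie on "
                        f"disjoint lineages",
                    )
                )
    return violations


def next_markers(
    record: GenotypeRecord, hierarchy: MarkerHierarchy
) -> list[str]:
    """Markers to type next under the staged screening plan.

    Finds the deepest node whose defining mutations are derived and
    returns the defining mutations of its untested children, honouring
    sibling stages: a later-stage child is only planned when all children
    of earlier stages have been tested (and found ancestral).  Returns the
    root's markers when nothing has been tested, and an empty list when
    the sample is ancestral at the root or fully resolved.
    """
    bad = validate(record, hierarchy)
    hard = [v for v in bad if v.kind != "unknown-marker"]
    if hard:
        raise GenotypeConflictError("; ".join(v.detail for v in hard))

    deepest = _deepest_derived(record, hierarchy)
    if deepest is None:
        if _node_state(record, hierarchy.root) == ANCESTRAL:
            return []
        return list(hierarchy.root.mutations)  # nothing typed yet

    for stage in sorted({c.stage for c in deepest.children}):
        tier = [c for c in deepest.children if c.stage == stage]
        untested = [c for c in tier if _node_state(record, c) == UNTESTED]
        if untested:
            # one representative marker per branch; equivalents are
            # interchangeable for calling
            return [c.mutations[0] for c in untested]
    return []


def _deepest_derived(
    record: GenotypeRecord, hierarchy: MarkerHierarchy
) -> Optional[MarkerNode]:
    best: Optional[MarkerNode] = None
    best_depth = -1
    for node in hierarchy.walk():
        if _node_state(record, node) == DERIVED:
            depth = len(hierarchy.path_to_root(node))
            if depth > best_depth:
                best, best_depth = node, depth
    return best


def call_haplogroup(
    record: GenotypeRecord, hierarchy: MarkerHierarchy
) -> HaplogroupCall:
    """Call the most-derived haplogroup of a record.

    Paragroup semantics: the call gets a ``*`` only when every child of
    the called node was tested and found ancestral; with untested children
    the same label is flagged unresolved instead, and the untested
    children are listed.
    """
    violations = [
        v
        for v in validate(record, hierarchy)
        if v.kind in ("incomparable", "equivalent-disagreement")
    ]
    if violations:
        raise GenotypeConflictError("; ".join(v.detail for v in violations))

    deepest = _deepest_derived(record, hierarchy)
    if deepest is None:
        root_state = _node_state(record, hierarchy.root)
        label = (
            f"not-{hierarchy.root.label}"
            if root_state == ANCESTRAL
            else "untyped"
        )
        return HaplogroupCall(
            sample=record.sample,
            terminal_label=label,
            is_paragroup=False,
            path=[],
            untested_children=[],
        )

    untested = [
        c.label for c in deepest.children if _node_state(record, c) == UNTESTED
    ]
    excluded = [
        c.label
        for c in deepest.children
        if _node_state(record, c) == ANCESTRAL
    ]
    is_para = bool(deepest.children) and not untested
    return HaplogroupCall(
        sample=record.sample,
        terminal_label=deepest.label,
        is_paragroup=is_para,
        path=[n.label for n in hierarchy.path_to_root(deepest)],
        untested_children=untested,
        excluded_children=excluded,
    )


def genotype_to_call(
    record: GenotypeRecord, hierarchy: MarkerHierarchy
) -> str:
    return call_haplogroup(record, hierarchy).display_label


def tabulate_counts(
    calls: Iterable[HaplogroupCall],
    grouping: Mapping[str, str],
    hierarchy: Optional[MarkerHierarchy] = None,
) -> pd.DataFrame:
    """Population x haplogroup count table.

    Columns are ordered depth-first along the hierarchy when one is given
    (paragroup columns follow their node), otherwise alphabetically.
    """
    calls = list(calls)
    unmapped = [c.sample for c in calls if c.sample not in grouping]
    if unmapped:
        raise KeyError(f"samples not mapped to a population: {unmapped[:10]}")
    rows = [
        {"population": grouping[c.sample], "haplogroup": c.display_label}
        for c in calls
    ]
    table = (
        pd.DataFrame(rows)
        .groupby(["population", "haplogroup"])
        .size()
        .unstack(fill_value=0)
    )
    if hierarchy is not None:
        order: list[str] = []
        for label in hierarchy.depth_first_labels():
            for col in (label, label + "*", label + " (unresolved)"):
                if col in table.columns:
                    order.append(col)
        extras = [c for c in table.columns if c not in order]
        table = table[order + sorted(extras)]
    else:
        table = table[sorted(table.columns)]
    return table


def read_genotype_table(
    path: Union[str, Path]
) -> list[GenotypeRecord]:
    """TSV sample x mutation with symbols 0 (ancestral), 1 (derived),
    . (untested)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    symbol = {"0": ANCESTRAL, "1": DERIVED, ".": UNTESTED}
    records = []
    for sample, row in df.iterrows():
        rec = GenotypeRecord(sample=str(sample))
        for mutation, cell in row.items():
            cell = "." if pd.isna(cell) else str(cell)
            if cell not in symbol:
                raise ValueError(
                    f"{path}: bad genotype symbol {cell!r} for {sample}/{mutation}"
                )
            if symbol[cell] != UNTESTED:
                rec.set(str(mutation), symbol[cell])
        records.append(rec)
    return records
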