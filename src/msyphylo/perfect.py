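"""Perfect-phylogeny construction from binary variant matrices.

On the non-recombining Y chromosome, biallelic mutations with known
ancestral states accumulate along a genealogy, so — absent recurrent or
back mutation — the derived-carrier sets of any two sites must be nested
or disjoint (the three-gamete condition for rooted characters).  When that
holds, the sites define a unique maximum-parsimony tree: each distinct
derived set is a clade, sites sharing a derived set collapse onto one
branch, and nesting of the sets gives the parent/child structure.

This module tests the condition, reports violations with witness samples,
and builds the tree with every mutation assigned to exactly one branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

from .io import DERIVED, MISSING, VariantMatrix
from .tree import MutationTree, TreeNode


@dataclass
class ConflictingPair:
    """Two sites whose derived sets overlap without nesting.

    The three witnesses are a sample derived at both sites, one derived
    only at the first, and one derived only at the second — together they
    certify that no rooted tree can host both mutations once each.
    """

    site_a: str
    site_b: str
    witness_both: str
    witness_only_a: str
    witness_only_b: str


@dataclass
class IncompatibilityReport:
    conflicting_pairs: list[ConflictingPair] = field(default_factory=list)

    @property
    def is_compatible(self) -> bool:
        return not self.conflicting_pairs

    def __bool__(self) -> bool:
        return bool(self.conflicting_pairs)


class IncompatibleMatrixError(ValueError):
    def __init__(self, report: IncompatibilityReport) -> None:
        pairs = ", ".join(
            f"({p.site_a}, {p.site_b})" for p in report.conflicting_pairs[:5]
        )
        more = (
            f" and {len(report.conflicting_pairs) - 5} more"
            if len(report.conflicting_pairs) > 5
            else ""
        )
        super().__init__(f"matrix is not a perfect phylogeny: {pairs}{more}")
        self.report = report


def _derived_bitmasks(matrix: VariantMatrix) -> list[int]:
    """Derived-carrier set of each site as an integer bitmask over samples.

    Missing calls are excluded from the set (the observed derived set)."""
    masks = []
    for i in range(matrix.n_sites):
        mask = 0
        row = matrix.calls[i]
        for j in range(matrix.n_samples):
            if row[j] == DERIVED:
                mask |= 1 << j
        masks.append(mask)
    return masks


def check_compatibility(matrix: VariantMatrix) -> IncompatibilityReport:
    """Pairwise three-gamete test over all site pairs.

    With known ancestral states, sites are compatible iff their derived
    sets are nested or disjoint.  Each violating pair is reported with one
    witness sample per forbidden category.
    """
    masks = _derived_bitmasks(matrix)
    samples = matrix.samples
    report = IncompatibilityReport()
    for i in range(len(masks)):
        a = masks[i]
        if not a:
            continue
        for j in range(i + 1, len(masks)):
            b = masks[j]
            both = a & b
            if not both:
                continue
            only_a = a & ~b
            only_b = b & ~a
            if only_a and only_b:
                report.conflicting_pairs.append(
                    ConflictingPair(
                        site_a=matrix.site_names[i],
                        site_b=matrix.site_names[j],
                        witness_both=samples[_lowest_bit(both)],
                        witness_only_a=samples[_lowest_bit(only_a)],
                        witness_only_b=samples[_lowest_bit(only_b)],
                    )
                )
    return report


def _lowest_bit(mask: int) -> int:
    return (mask & -mask).bit_length() - 1


def build_mp_tree(
    matrix: VariantMatrix,
    outgroup: Union[str, Sequence[str]],
) -> MutationTree:
    """Build the unique perfect phylogeny of a compatible matrix.

    ``outgroup`` names the sample(s) that root the ingroup clade (e.g. the
    haplogroup-D chromosomes when building the DE tree); it must exist in
    the matrix.  Sites derived in every sample are invariant on this sample
    set and are dropped with a warning.  Sites with missing calls are
    placed by their observed derived set; the affected samples are recorded
    in ``tree.unresolved`` (site -> missing samples) rather than imputed.

    The returned tree is canonicalized (children ordered by descendant
    count then smallest tip label), so the result is independent of row
    and column order of the input.
    """
    outgroups = [outgroup] if isinstance(outgroup, str) else list(outgroup)
    for og in outgroups:
        if og not in matrix.samples:
            raise KeyError(f"outgroup sample {og!r} not in matrix")

    report = check_compatibility(matrix)
    if report:
        raise IncompatibleMatrixError(report)

    masks = _derived_bitmasks(matrix)
    n = matrix.n_samples
    full = (1 << n) - 1
    unresolved: dict[str, list[str]] = {}

    # group sites by derived set; drop invariant ones
    by_set: dict[int, list[str]] = {}
    for i, mask in enumerate(masks):
        name = matrix.site_names[i]
        miss = [
            matrix.samples[j]
            for j in range(n)
            if matrix.calls[i, j] == MISSING
        ]
        if miss:
            unresolved[name] = miss
        if mask == 0 or mask == full:
            warnings.warn(
                f"site {name!r} is invariant across all samples; dropped",
                stacklevel=2,
            )
            continue
        by_set.setdefault(mask, []).append(name)

    # nodes: the full sample set (root), every distinct derived set, and a
    # singleton for every sample.  The family is laminar, so each set's
    # parent is its smallest strict superset.
    node_sets: set[int] = {full}
    node_sets.update(by_set)
    node_sets.update(1 << j for j in range(n))
    ordered = sorted(node_sets, key=lambda m: (-bin(m).count("1"), m))

    nodes: dict[int, TreeNode] = {}
    counter = 0
    for mask in ordered:
        popcount = bin(mask).count("1")
        if popcount == 1:
            label = matrix.samples[_lowest_bit(mask)]
        elif mask == full:
            label = "root"
        else:
            counter += 1
            label = f"node{counter}"
        node = TreeNode(label=label, mutations=set(by_set.get(mask, ())))
        nodes[mask] = node
        if mask != full:
            parent_mask = min(
                (m for m in node_sets if m != mask and mask & m == mask),
                key=lambda m: bin(m).count("1"),
            )
            nodes[parent_mask].add_child(node)

    tree = MutationTree(nodes[full]).canonicalize()
    tree.unresolved = unresolved  # type: ignore[attr-defined]
    tree.outgroup = outgroups  # type: ignore[attr-defined]

    # suppress unlabelled pass-through: every internal node here has >= 2
    # children or carries mutations by construction except possibly the
    # root when the ingroup is a clade; keep the root as-is (it is the
    # designated ancestor above the outgroup split).
    return tree


def branch_mutation_counts(tree: MutationTree) -> dict[str, int]:
    """Mutations on the branch above each node, keyed by node label."""
    return tree.branch_mutation_counts()
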