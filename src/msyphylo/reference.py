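"""Synthetic stand-ins for the published haplogroup-E data sets.

The original study's supplementary files (the 729 x 33 variant matrix and
the 5,222-sample survey table) are not redistributable here.  This module
reconstructs *synthetic* data sets with the same shape from the values
printed in the study's text, so the full pipeline can be exercised
end-to-end at the published scale:

* :func:`synthetic_sequencing_matrix` builds a 33-chromosome variant
  matrix whose perfect phylogeny reproduces the published tree's key
  clades, with per-branch mutation counts derived from the published node
  ages under the calibrated clock (13 mutations on the haplogroup-E stem,
  3 on the branch below it);
* :func:`synthetic_survey_panel` builds staged genotype records for 5,222
  samples whose haplogroup totals match the published ones (1,147
  E-M215 chromosomes of which 1,141 E-M35, plus 3 E-V44).

Everything here is synthetic: the real data would differ site by site and
sample by sample, but the clade structure, branch counts and totals match
what the study reports, which is what the pipeline's numbers depend on.
"""

from __future__ import annotations

import numpy as np

from .classify import (
    ANCESTRAL,
    DERIVED,
    GenotypeRecord,
    MarkerHierarchy,
    default_hierarchy,
    next_markers,
)
from .dating import PAPER_CLOCK
from .io import VariantMatrix
from .tree import MutationTree, TreeNode

# Published point ages (ka) of the dated nodes, used as the synthetic
# tree's true node times.
NODE_AGES_KA: dict[str, float] = {
    "E": 57.4,
    "E-P147": 54.4,  # the M33 | P2 split
    "E-P2": 47.5,  # the V38 | M215 split
    "E-V38": 45.6,  # M2 | M329
    "E-M215": 38.6,  # M35 | V16
    "E-M35": 25.0,
    "E-V68": 20.3,
    "E-M78": 14.8,
    "E-V13": 8.1,
    "E-V1515": 12.0,
    "E-V1486": 3.5,
}

# Clade structure of the sequenced sample: (label, age_ka, children) or
# (tip_label, None, tip_count).  Ages of undated structural nodes are
# interpolated between their dated neighbours.
# The sequencing set over-sampled divergent E-M35 lineages (the former
# E-M35* chromosomes from the Horn of Africa that resolved into the
# tripartite E-V1515 clade), alongside Complete Genomics haplogroup-DE
# genomes; the tip counts below mirror that design.
_TREE_SPEC = (
    "DE",
    69.54,
    [
        ("D", 2),
        (
            "E",
            57.4,
            [
                ("E-M75x", 1),
                (
                    "E-P147",
                    54.4,
                    [
                        ("E-M33x", 1),
                        (
                            "E-P2",
                            47.5,
                            [
                                (
                                    "E-V38",
                                    45.6,
                                    [("E-M2x", 6), ("E-M329x", 1)],
                                ),
                                (
                                    "E-M215",
                                    38.6,
                                    [
                                        ("E-V16x", 1),
                                        (
                                            "E-M35",
                                            25.0,
                                            [
                                                (
                                                    "E-Z827",
                                                    21.0,
                                                    [
                                                        ("E-M81x", 2),
                                                        ("E-M123x", 1),
                                                        (
                                                            "E-V1515",
                                                            12.0,
                                                            [
                                                                ("E-V1515x", 1),
                                                                (
                                                                    "E-V1486",
                                                                    3.5,
                                                                    [
                                                                        ("E-M293x", 2),
                                                                        ("E-V92x", 1),
                                                                        ("E-V2881x", 1),
                                                                    ],
                                                                ),
                                                                (
                                                                    "E-V1700",
                                                                    9.0,
                                                                    [
                                                                        ("E-V42x", 2),
                                                                        (
                                                                            "E-V1785",
                                                                            6.0,
                                                                            [
                                                                                ("E-V6x", 1),
                                                                                ("E-V1785x", 2),
                                                                            ],
                                                                        ),
                                                                    ],
                                                                ),
                                                            ],
                                                        ),
                                                    ],
                                                ),
                                                (
                                                    "E-V68",
                                                    20.3,
                                                    [
                                                        ("E-V2009x", 1),
                                                        (
                                                            "E-M78",
                                                            14.8,
                                                            [
                                                                (
                                                                    "E-V13",
                                                                    8.1,
                                                                    [("E-V13x", 4)],
                                                                ),
                                                                ("E-V22x", 1),
                                                                ("E-V12x", 1),
                                                                ("E-V65x", 1),
                                                            ],
                                                        ),
                                                    ],
                                                ),
                                            ],
                                        ),
                                    ],
                                ),
                            ],
                        ),
                    ],
                ),
            ],
        ),
    ],
)


def synthetic_reference_tree() -> MutationTree:
    """Build the synthetic 33-tip tree with true node ages in years.

    The DE root age is set so that the haplogroup-E stem spans exactly 13
    expected mutations on the calibrated clock (13 / (mu x L) ~ 12.14 ky
    above the 57.4-ka E node).  Branch mutation counts are not attached
    here; :func:`synthetic_sequencing_matrix` derives them.
    """
    tip_counter = {"n": 0}

    def build(spec) -> TreeNode:
        label, second, third = spec[0], spec[1], spec[2] if len(spec) > 2 else None
        node = TreeNode(label=label, age=second * 1000.0)
        for child in third:
            if len(child) == 2 and isinstance(child[1], int):
                clade, count = child
                for i in range(count):
                    tip_counter["n"] += 1
                    node.add_child(
                        TreeNode(
                            label=f"{clade}_{i + 1:02d}" if count > 1 else clade,
                            age=0.0,
                        )
                    )
            else:
                node.add_child(build(child))
        return node

    tree = MutationTree(build(_TREE_SPEC))
    assert len(tree.tips()) == 33
    return tree


def synthetic_sequencing_matrix(
    seed: int | None = None,
) -> tuple[VariantMatrix, MutationTree]:
    """Synthetic stand-in for the 33-chromosome sequencing matrix.

    Branch mutation counts are the expected counts under the calibrated
    clock, ``round(duration x mu x L)`` (deterministic by default;
    ``seed`` switches to Poisson draws).  Site names are synthetic
    (``B<branch>_<i>``); the haplogroup-E stem gets exactly 13 sites and
    the branch below it (the deep-dichotomy branch) exactly 3.
    Returns the matrix and the generating tree (with mutations attached).
    """
    tree = synthetic_reference_tree()
    lam = PAPER_CLOCK.per_lineage_rate_year
    rng = np.random.default_rng(seed) if seed is not None else None

    tips = tree.tip_labels()
    tip_index = {s: j for j, s in enumerate(tips)}
    site_names: list[str] = []
    positions: list[int] = []
    rows: list[np.ndarray] = []
    pos = 0
    for node in tree.preorder():
        if node.parent is None:
            continue
        duration = node.parent.age - node.age
        expected = lam * duration
        count = (
            int(round(expected)) if rng is None else int(rng.poisson(expected))
        )
        below = tree.tips_below(node)
        branch_id = node.label or "anon"
        node.mutations = set()
        for i in range(count):
            pos += 1
            name = f"{branch_id}.{i + 1:02d}"
            node.mutations.add(name)
            site_names.append(name)
            positions.append(pos)
            row = np.zeros(len(tips), dtype=np.int8)
            for s in below:
                row[tip_index[s]] = 1
            rows.append(row)
    matrix = VariantMatrix(
        site_names,
        positions,
        tips,
        np.array(rows, dtype=np.int8),
        PAPER_CLOCK.target_length_bp,
    )
    return matrix, tree


# ----------------------------------------------------------------------
# survey panel
# ----------------------------------------------------------------------
# Published totals: 5,222 samples screened; 1,147 derived at M215; 1,141
# of those derived at M35; 3 samples on the new deep E-V44 branch.  The
# distribution of the 1,141 E-M35 chromosomes across terminal clades is
# NOT published at this granularity; the split below is a synthetic
# allocation that respects the clade totals the text does state
# (e.g. 12 E-V1785*, 6 E-V2009, 1 E-V1477, 3 V2580 cluster members).
SURVEY_COMPOSITION: dict[str, int] = {
    "E-M35*": 0,
    "E-Z827": 10,  # resolved no further in the synthetic panel
    "E-M81": 180,
    "E-M123": 120,
    "E-V257": 8,
    "E-V1515": 5,
    "E-V1486": 30,
    "E-M293": 60,
    "E-V92": 25,
    "E-V2881": 40,
    "E-V1700": 9,
    "E-V42": 15,
    "E-V1785": 12,
    "E-V6": 35,
    "E-V68": 4,
    "E-V2009": 6,
    "E-M78": 10,
    "E-V1083": 7,
    "E-V13": 250,
    "E-V22": 150,
    "E-V12": 90,
    "E-V264": 2,
    "E-V65": 45,
    "E-V259": 3,
    "E-V1477": 1,
    "E-M34-like-residue": 0,
}
_M35_TOTAL = 1141
_M215_TOTAL = 1147
_V44_TOTAL = 3
_PANEL_TOTAL = 5222


def synthetic_survey_panel(
    hierarchy: MarkerHierarchy | None = None,
    seed: int = 0,
) -> tuple[list[GenotypeRecord], dict[str, str]]:
    """Synthetic stand-in for the genotyping survey.

    Builds staged genotype records (filled by the planner, exactly as the
    screening cascade would) for 5,222 samples: 1,141 E-M35 chromosomes
    allocated across the hierarchy per ``SURVEY_COMPOSITION``, 6
    E-M215*(xM35) chromosomes resolved to E-V16, 3 E-V44, and the
    remainder ancestral at the root markers.  Returns records and a
    sample -> population mapping (a single synthetic population per
    macro-lineage).
    """
    hierarchy = hierarchy or default_hierarchy()
    alloc: list[tuple[str, int]] = []
    allotted = 0
    for label, count in SURVEY_COMPOSITION.items():
        if count <= 0:
            continue
        target = label[:-1] if label.endswith("*") else label
        if target not in {n.label for n in hierarchy.walk()}:
            continue
        alloc.append((target, count))
        allotted += count
    spill = _M35_TOTAL - allotted
    if spill != 0:
        alloc.append(("E-M35", spill))  # unallocated stay at the M35 node

    records: list[GenotypeRecord] = []
    grouping: dict[str, str] = {}
    counter = 0

    def emit(lineage_label: str | None, n: int, population: str) -> None:
        nonlocal counter
        target = (
            {m.label for m in hierarchy.path_to_root(hierarchy.node(lineage_label))}
            if lineage_label is not None
            else set()
        )
        for _ in range(n):
            counter += 1
            rec = GenotypeRecord(sample=f"P{counter:04d}")
            markers = next_markers(rec, hierarchy)
            while markers:
                for m in markers:
                    node = hierarchy.node_for_mutation(m)
                    rec.set(
                        m, DERIVED if node.label in target else ANCESTRAL
                    )
                markers = next_markers(rec, hierarchy)
            records.append(rec)
            grouping[rec.sample] = population

    for label, count in alloc:
        emit(label, count, "survey-" + label)
    emit("E-V16", _M215_TOTAL - _M35_TOTAL, "survey-E-V16")
    emit("E-V44", _V44_TOTAL, "survey-E-V44")
    emit(None, _PANEL_TOTAL - _M215_TOTAL - _V44_TOTAL, "survey-other")
    assert len(records) == _PANEL_TOTAL
    return records, grouping


def synthetic_tip_regions(tree: MutationTree) -> dict[str, object]:
    """Region assignment for each tip of the synthetic reference tree.

    Leaves are assigned to the macroregion(s) where their clade is
    observed (several clades span more than one region, and multi-region
    leaves enter the phylogeographic model as state sets), following the
    distributions the study and the wider literature describe.
    """
    CW, S, E, N, EU, ROW = (
        "Central-Western Africa",
        "Southern Africa",
        "Eastern Africa",
        "Northern Africa",
        "Europe",
        "Rest-of-world",
    )
    by_clade: dict[str, object] = {
        "D": ROW,
        "E-M75x": [CW, E],
        "E-M33x": CW,
        "E-M2x": CW,
        "E-M329x": E,
        "E-V16x": E,
        "E-M81x": N,
        "E-M123x": [N, E, ROW],
        "E-V1515x": E,
        "E-M293x": [S, E],
        "E-V92x": E,
        "E-V2881x": E,
        "E-V42x": E,
        "E-V6x": E,
        "E-V1785x": E,
        "E-V2009x": [EU, N],
        "E-V13x": EU,
        "E-V22x": [E, N],
        "E-V12x": [N, E],
        "E-V65x": N,
    }
    out: dict[str, object] = {}
    for tip in tree.tip_labels():
        clade = tip.rsplit("_", 1)[0]
        out[tip] = by_clade.get(clade, by_clade.get(tip, E))
    return out
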