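"""Perfect-phylogeny construction against independent oracles."""

import itertools

import numpy as np
import pytest

from msyphylo import (
    IncompatibleMatrixError,
    VariantMatrix,
    branch_mutation_counts,
    build_mp_tree,
    check_compatibility,
)

from conftest import random_binary_matrix


def matrix_from_rows(rows, samples=None):
    rows = np.array(rows, dtype=np.int8)
    samples = samples or [f"s{i}" for i in range(rows.shape[1])]
    names = [f"m{i}" for i in range(rows.shape[0])]
    return VariantMatrix(names, list(range(1, len(names) + 1)), samples, rows)


def brute_force_clades(matrix):
    """Independent construction: the clade family of a perfect phylogeny
    is exactly {derived sets} + root + singletons, found by recursive set
    partitioning rather than the builder's superset indexing."""
    derived = {}
    for i, name in enumerate(matrix.site_names):
        ds = frozenset(
            s for s, c in zip(matrix.samples, matrix.calls[i]) if c == 1
        )
        if 0 < len(ds) < matrix.n_samples:
            derived.setdefault(ds, set()).add(name)

    def partition(sample_set, available):
        clades = {sample_set}
        maximal = []
        for ds in sorted(available, key=len, reverse=True):
            if ds < sample_set and not any(ds <= m for m in maximal):
                maximal.append(ds)
        for ds in maximal:
            clades |= partition(ds, [a for a in available if a < ds])
        return clades

    full = frozenset(matrix.samples)
    clades = partition(full, list(derived))
    clades |= {frozenset([s]) for s in matrix.samples}
    return clades, derived


def three_gamete_conflicts(matrix):
    """Brute-force pairwise test over explicit sample sets."""
    conflicts = set()
    sets = {}
    for i, name in enumerate(matrix.site_names):
        sets[name] = frozenset(
            s for s, c in zip(matrix.samples, matrix.calls[i]) if c == 1
        )
    for a, b in itertools.combinations(matrix.site_names, 2):
        A, B = sets[a], sets[b]
        if (A & B) and (A - B) and (B - A):
            conflicts.add(frozenset((a, b)))
    return conflicts


class TestCompatibility:
    def test_single_site_cannot_conflict(self):
        m = matrix_from_rows([[1, 0, 1]])
        assert check_compatibility(m).is_compatible

    def test_overlapping_sets_reported_with_witnesses(self):
        # derived sets {s0,s1} and {s1,s2}: classic three-gamete failure
        m = matrix_from_rows([[1, 1, 0], [0, 1, 1]])
        report = check_compatibility(m)
        assert len(report.conflicting_pairs) == 1
        pair = report.conflicting_pairs[0]
        assert {pair.site_a, pair.site_b} == {"m0", "m1"}
        assert pair.witness_both == "s1"
        assert {pair.witness_only_a, pair.witness_only_b} == {"s0", "s2"}

    def test_agrees_with_brute_force_on_random_matrices(self, rng):
        for _ in range(100):
            n, k = int(rng.integers(3, 8)), int(rng.integers(2, 12))
            calls = rng.integers(0, 2, size=(k, n)).astype(np.int8)
            m = matrix_from_rows(calls)
            got = {
                frozenset((p.site_a, p.site_b))
                for p in check_compatibility(m).conflicting_pairs
            }
            assert got == three_gamete_conflicts(m)


class TestBuilder:
    def test_two_private_sites_make_a_root_bifurcation(self):
        m = matrix_from_rows([[1, 0], [0, 1]], samples=["a", "b"])
        tree = build_mp_tree(m, "a")
        assert {c.label for c in tree.root.children} == {"a", "b"}
        assert tree.find("a").mutations == {"m0"}
        assert tree.find("b").mutations == {"m1"}

    def test_shared_sites_collapse_onto_one_branch(self):
        # 13 sites with the same derived set land on a single stem branch
        rows = [[1, 1, 1, 0]] * 13 + [[1, 0, 0, 0]]
        m = matrix_from_rows(rows)
        tree = build_mp_tree(m, "s3")
        clade = frozenset(["s0", "s1", "s2"])
        stem = next(
            n for n in tree.internal_nodes() if tree.tips_below(n) == clade
        )
        assert len(stem.mutations) == 13

    def test_identical_genotypes_become_sister_tips(self):
        m = matrix_from_rows([[1, 1, 0]])
        tree = build_mp_tree(m, "s2")
        cherry = next(
            n
            for n in tree.internal_nodes()
            if tree.tips_below(n) == frozenset(["s0", "s1"])
        )
        assert {c.label for c in cherry.children} == {"s0", "s1"}
        assert all(not c.mutations for c in cherry.children)

    def test_matches_brute_force_construction(self, rng):
        for _ in range(200):
            n, k = int(rng.integers(3, 9)), int(rng.integers(1, 13))
            m = random_binary_matrix(rng, n, k)
            tree = build_mp_tree(m, m.samples[0])
            clades = {tree.tips_below(nd) for nd in tree.preorder()}
            expected_clades, derived = brute_force_clades(m)
            assert clades == expected_clades
            for nd in tree.preorder():
                if nd.mutations:
                    assert derived[tree.tips_below(nd)] == nd.mutations

    def test_conservation_and_exactness(self, rng):
        m = random_binary_matrix(rng, 10, 40)
        tree = build_mp_tree(m, m.samples[0])
        assert tree.total_mutations() == m.n_sites  # no site lost or doubled
        for nd in tree.preorder():
            for site in nd.mutations:
                assert tree.tips_below(nd) == m.derived_samples(site)

    def test_deterministic_under_row_and_column_permutation(self, rng):
        from msyphylo.io import write_annotated_newick

        m = random_binary_matrix(rng, 7, 15)
        perm_sites = rng.permutation(m.n_sites)
        perm_samples = rng.permutation(m.n_samples)
        m2 = VariantMatrix(
            [m.site_names[i] for i in perm_sites],
            [m.positions[i] for i in perm_sites],
            [m.samples[j] for j in perm_samples],
            m.calls[np.ix_(perm_sites, perm_samples)],
        )
        import io as _io
        from msyphylo.io import _emit

        def render(tree):
            buf = _io.StringIO()
            _emit(tree.root, buf)
            return buf.getvalue()

        t1 = build_mp_tree(m, m.samples[0])
        t2 = build_mp_tree(m2, m.samples[0])
        assert render(t1) == render(t2)

    def test_incompatible_matrix_raises_with_report(self):
        m = matrix_from_rows([[1, 1, 0], [0, 1, 1]])
        with pytest.raises(IncompatibleMatrixError) as err:
            build_mp_tree(m, "s0")
        assert err.value.report.conflicting_pairs

    def test_unknown_outgroup_rejected(self):
        m = matrix_from_rows([[1, 0]])
        with pytest.raises(KeyError):
            build_mp_tree(m, "nope")

    def test_invariant_sites_dropped_with_warning(self):
        m = matrix_from_rows([[1, 1], [1, 0]])
        with pytest.warns(UserWarning, match="invariant"):
            tree = build_mp_tree(m, "s1")
        assert tree.total_mutations() == 1

    def test_missing_calls_placed_by_observed_set_and_reported(self):
        m = matrix_from_rows([[1, 1, 0, 0], [1, -1, 0, 0]])
        tree = build_mp_tree(m, "s3")
        assert tree.unresolved == {"m1": ["s1"]}
        # m1's observed derived set {s0} puts it on the s0 tip branch
        assert "m1" in tree.find("s0").mutations

    def test_subset_consistency(self, rng):
        # the tree restricted to a sample subset equals the tree built
        # from the submatrix
        m = random_binary_matrix(rng, 8, 20)
        keep = m.samples[:5]
        idx = [m.samples.index(s) for s in keep]
        calls = m.calls[:, idx]
        variable = [
            i for i in range(m.n_sites) if 0 < calls[i].sum() < len(keep)
        ]
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            sub = build_mp_tree(
                VariantMatrix(
                    [m.site_names[i] for i in variable],
                    [m.positions[i] for i in variable],
                    keep,
                    calls[variable],
                ),
                keep[0],
            )
        full = build_mp_tree(m, m.samples[0])
        full_clades = {
            frozenset(t for t in full.tips_below(nd) if t in keep)
            for nd in full.preorder()
        }
        sub_clades = {sub.tips_below(nd) for nd in sub.preorder()}
        assert sub_clades <= full_clades | {frozenset()}


class TestBranchCounts:
    def test_counts_sum_to_variable_sites(self, rng):
        m = random_binary_matrix(rng, 9, 30)
        tree = build_mp_tree(m, m.samples[0])
        counts = branch_mutation_counts(tree)
        assert sum(counts.values()) == m.n_sites

    def test_zero_mutation_tree(self):
        m = matrix_from_rows([[1, 1, 0]])  # only one informative site
        tree = build_mp_tree(m, "s2")
        counts = branch_mutation_counts(tree)
        assert all(v == 0 for k, v in counts.items() if k in ("s0", "s1"))
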