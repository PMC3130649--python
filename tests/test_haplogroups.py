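"""Compatibility checking, assignment, single-false-positive resolution.

The brute-force oracle enumerates every root-to-node path by explicit
parent chasing and tests set equality of the derived markers against the
path's called markers — independent of the caller's candidate scoring.
"""
import itertools

import pytest
from hypothesis import given, settings, strategies as st

from yplex import (
    AssignmentStatus,
    assign,
    assign_cohort,
    check_compatibility,
    decode_redundant,
    resolve_single_false_positive,
)
from yplex.errors import YplexError
from yplex.profile import ANCESTRAL, DERIVED, NO_CALL, GenotypeProfile

from conftest import toy_tree


def profile_from_derived(panel, derived, rest=ANCESTRAL, sample_id="s"):
    """All listed markers derived; every other active marker gets ``rest``."""
    calls = {m.name: (DERIVED if m.name in derived else rest) for m in panel.active_markers}
    return GenotypeProfile(sample_id, calls)


def sparse_profile(derived, sample_id="s"):
    return GenotypeProfile(sample_id, {m: DERIVED for m in derived})


def brute_force_compatible(profile, tree):
    for label in tree.nodes:
        path_markers, node = set(), tree[label]
        while True:
            path_markers |= node.defining_markers
            if node.parent is None:
                break
            node = tree[node.parent]
        called_on_path = {m for m in path_markers if profile[m] != NO_CALL}
        if called_on_path == profile.derived_markers:
            return True
    return False


class TestDecodeRedundant:
    def test_concordant_branch_control(self, panel):
        p = sparse_profile({"M145", "M203"})
        consolidated, reports = decode_redundant(p, panel)
        de = next(r for r in reports if r.group == "DE_ctrl")
        assert de.concordant and de.consolidated == DERIVED
        assert consolidated["M145"] == consolidated["M203"] == DERIVED

    def test_discordant_dye_swap_pair_downgrades_to_N(self, panel):
        p = GenotypeProfile("s", {"M9a": DERIVED, "M9b": ANCESTRAL})
        consolidated, reports = decode_redundant(p, panel)
        m9 = next(r for r in reports if r.group == "M9_ctrl")
        assert not m9.concordant
        assert consolidated["M9a"] == consolidated["M9b"] == NO_CALL

    def test_single_called_member_partially_supported(self, panel):
        p = GenotypeProfile("s", {"M145": DERIVED, "M203": NO_CALL})
        consolidated, reports = decode_redundant(p, panel)
        de = next(r for r in reports if r.group == "DE_ctrl")
        assert de.partially_supported and consolidated["M203"] == DERIVED

    def test_error_free_cohort_fully_concordant(self, panel, tree):
        from yplex import SimConfig, simulate_profiles

        profiles, _ = simulate_profiles(SimConfig(n_samples=40, seed=9), tree, panel)
        for p in profiles:
            _, reports = decode_redundant(p, panel)
            assert all(r.concordant for r in reports)


class TestCheckCompatibility:
    def test_full_lineage_is_compatible(self, panel, tree):
        p = profile_from_derived(panel, {"M168", "M89", "M201"})
        assert check_compatibility(p, tree).compatible

    def test_two_branches_is_incompatible(self, panel, tree):
        p = sparse_profile({"M168", "M89", "M201", "M170"})
        summary = check_compatibility(p, tree)
        assert not summary.compatible
        assert summary.conflicts  # at least one off-path derived marker flagged

    def test_missing_on_path_marker_is_uninformative(self, panel, tree):
        p = profile_from_derived(panel, {"M168", "M201"})
        p = p.with_calls({"M89": NO_CALL})
        assert check_compatibility(p, tree).compatible

    def test_skipping_an_on_path_marker_is_incompatible(self, panel, tree):
        # derived below an explicitly ancestral on-path marker
        p = profile_from_derived(panel, {"M168", "M201"})  # M89 ancestral
        summary = check_compatibility(p, tree)
        assert not summary.compatible
        assert "M89" in summary.ancestral_on_path

    @pytest.mark.parametrize(
        "markers",
        [
            {"m_a": "A", "m_a1": "A1", "m_b": "B"},
            {"m_a": "A", "m_a1": "A1", "m_a2": "A2", "m_b": "B", "m_b1": "B1"},
            {f"m{i}": l for i, l in enumerate(["A", "A1", "A11", "A12", "B", "C", "C1"])},
        ],
    )
    def test_exhaustive_agreement_with_brute_force(self, markers):
        t = toy_tree(markers)
        names = list(markers)
        for states in itertools.product((ANCESTRAL, DERIVED, NO_CALL), repeat=len(names)):
            p = GenotypeProfile("s", dict(zip(names, states)))
            assert check_compatibility(p, t).compatible == brute_force_compatible(p, t)


class TestAssign:
    def test_worked_example_assigns_G_paragroup(self, panel, tree):
        p = profile_from_derived(panel, {"M168", "M89", "M201"})
        a = assign(p, tree)
        assert (a.node, a.display_label, a.status) == ("G", "G*", AssignmentStatus.CLEAN)
        assert a.supporting == {"M168", "M89", "M201"}

    def test_all_ancestral_goes_to_root_paragroup(self, panel, tree):
        p = profile_from_derived(panel, set())
        a = assign(p, tree)
        assert (a.node, a.display_label) == ("Y", "Y*")

    def test_terminal_node_has_no_star(self, panel, tree):
        lineage_markers = {
            m for label in tree.lineage("E1b1b1a2") for m in tree[label].defining_markers
        }
        a = assign(profile_from_derived(panel, lineage_markers), tree)
        assert a.display_label == "E1b1b1a2"  # no typed descendants in the panel

    def test_empty_profile_is_status_empty(self, tree):
        a = assign(GenotypeProfile("s", {"M216": NO_CALL}), tree)
        assert a.status is AssignmentStatus.EMPTY and a.node is None

    def test_error_free_cohort_fully_recovered(self, panel, tree):
        from yplex import SimConfig, evaluate_recovery, simulate_profiles

        profiles, records = simulate_profiles(SimConfig(n_samples=500, seed=13), tree, panel)
        assignments = [assign(p, tree) for p in profiles]
        metrics = evaluate_recovery(assignments, records)
        assert metrics.accuracy == 1.0 and metrics.fraction_clean == 1.0

    def test_deterministic(self, panel, tree):
        p = profile_from_derived(panel, {"M168", "M89", "M201"})
        assert assign(p, tree) == assign(p, tree)


class TestMonotonicityAndRobustness:
    def test_adding_consistent_child_call_never_shallows(self, panel, tree):
        p = profile_from_derived(panel, {"M168", "M89", "M201"})
        deeper = p.with_calls({"P287": DERIVED})  # G2 under G
        a, b = assign(p, tree), assign(deeper, tree)
        assert tree.depth(b.node) >= tree.depth(a.node)
        assert b.node == "G2"

    def test_on_path_dropout_keeps_node_while_defining_marker_remains(self, panel, tree):
        base = profile_from_derived(panel, {"M168", "M89", "M201"})
        for dropped in ("M168", "M89"):
            a = assign(base.with_calls({dropped: NO_CALL}), tree)
            assert a.node == "G" and a.status is AssignmentStatus.CLEAN


class TestResolveSingleFalsePositive:
    def test_unique_elimination_resolves(self, tree):
        p = sparse_profile({"M168", "M89", "M170", "M253", "M201"})
        a = assign(p, tree)
        assert a.status is AssignmentStatus.RESOLVED
        assert a.eliminated == "M201"
        assert a.node == "I1"

    def test_ambiguous_elimination_stays_unresolved(self, tree):
        p = sparse_profile({"M168", "M89", "M201", "M170"})
        a = assign(p, tree)
        assert a.status is AssignmentStatus.UNRESOLVED
        assert a.eliminated is None

    def test_compatible_profile_is_a_no_op(self, panel, tree):
        p = profile_from_derived(panel, {"M168", "M89", "M201"})
        a = resolve_single_false_positive(p, tree)
        assert a.status is AssignmentStatus.CLEAN and a.eliminated is None

    def test_terminal_false_positive_is_clean_but_too_deep(self, panel, tree):
        # the documented blind spot: a false positive on a terminal branch
        # below the true node creates no incompatibility
        true_path = {"M168", "M89", "M201"}
        p = profile_from_derived(panel, true_path | {"P287"})  # G2 directly under G
        a = assign(p, tree)
        assert a.status is AssignmentStatus.CLEAN
        assert a.node == "G2"  # wrong but undetectable

    def test_deeper_false_positive_is_caught_by_on_path_ancestral(self, panel, tree):
        # a skipped intermediate marker (P287 ancestral) exposes the error
        p = profile_from_derived(panel, {"M168", "M89", "M201", "M287"})  # G2b, no G2
        a = assign(p, tree)
        assert a.status is AssignmentStatus.RESOLVED
        assert a.eliminated == "M287" and a.node == "G"


class TestAssignCohort:
    def test_status_tally_structure(self, panel, tree):
        from yplex import SimConfig, simulate_profiles

        profiles, _ = simulate_profiles(
            SimConfig(n_samples=30, n_empty_samples=3, seed=4), tree, panel
        )
        table, counts, tally = assign_cohort(profiles, tree, panel)
        assert tally == {"clean": 27, "resolved": 0, "unresolved": 0, "empty": 3}
        assert len(table) == 30

    def test_counts_rows_sum_to_non_empty_samples(self, panel, tree):
        from yplex import SimConfig, simulate_profiles

        profiles, _ = simulate_profiles(
            SimConfig(n_samples=44, n_empty_samples=2, seed=5), tree, panel
        )
        pops = {p.sample_id: ("ES" if i % 2 else "UK") for i, p in enumerate(profiles)}
        _, counts, _ = assign_cohort(profiles, tree, panel, populations=pops)
        assert int(counts.values.sum()) == 42

    def test_duplicate_sample_ids_rejected(self, panel, tree):
        p = profile_from_derived(panel, {"M168"}, sample_id="dup")
        with pytest.raises(YplexError, match="dup"):
            assign_cohort([p, p], tree)

    def test_empty_cohort_yields_empty_table(self, tree):
        table, counts, tally = assign_cohort([], tree)
        assert table.empty and counts.empty
        assert tally == {"clean": 0, "resolved": 0, "unresolved": 0, "empty": 0}


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(0, 3 ** 6 - 1))
def test_assign_matches_oracle_on_random_vectors(code):
    """assign() places every compatible vector at its deepest derived node."""
    markers = {"m0": "A", "m1": "A1", "m2": "A11", "m3": "A2", "m4": "B", "m5": "B1"}
    t = toy_tree(markers)
    names = list(markers)
    states = []
    for _ in names:
        code, r = divmod(code, 3)
        states.append((ANCESTRAL, DERIVED, NO_CALL)[r])
    p = GenotypeProfile("s", dict(zip(names, states)))
    a = assign(p, t)
    if p.is_empty:
        assert a.status is AssignmentStatus.EMPTY
    elif brute_force_compatible(p, t):
        assert a.status is AssignmentStatus.CLEAN
        if p.derived_markers:
            anchors = t.marker_to_node()
            deepest = max((anchors[m] for m in p.derived_markers), key=t.depth)
            assert a.node == deepest
        else:
            assert a.node == t.root
    else:
        assert a.status in (AssignmentStatus.RESOLVED, AssignmentStatus.UNRESOLVED)
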