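"""Haplogroup assignment with phylogenetic compatibility checking.

A hemizygous genotype profile is *compatible* with the tree when its
derived markers are exactly the markers of one root-to-node path,
restricted to markers that were actually called: derived alleles
accumulate along a lineage, so a sample derived for a branch must be
derived for every marker above it and ancestral for every marker on other
branches. Missing calls are treated as uninformative.

Incompatible profiles (derived alleles on mutually exclusive branches)
are handed to a single-false-positive resolver: if removing exactly one
derived call — and only that one — restores compatibility, the profile is
assigned with that marker recorded as eliminated; zero or multiple
candidate removals leave the sample unresolved rather than guessing.

A false positive at a terminal branch directly below the true node is a
known blind spot: it creates no incompatibility and yields a clean but
too-deep call.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import YplexError
from .panel import Panel
from .phylogeny import PhyloTree
from .profile import ANCESTRAL, DERIVED, NO_CALL, GenotypeProfile


class AssignmentStatus(str, enum.Enum):
    CLEAN = "clean"
    RESOLVED = "resolved"
    UNRESOLVED = "unresolved"
    EMPTY = "empty"


@dataclass
class Assignment:
    sample_id: str
    node: Optional[str]
    display_label: Optional[str]
    status: AssignmentStatus
    supporting: set[str] = field(default_factory=set)
    conflicts: set[str] = field(default_factory=set)
    eliminated: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.status is AssignmentStatus.EMPTY) != (self.node is None):
            raise YplexError("status is empty iff no node is assigned")
        if self.status is AssignmentStatus.CLEAN and (self.conflicts or self.eliminated):
            raise YplexError("a clean assignment has no conflicts and no elimination")
        if self.status is AssignmentStatus.RESOLVED and (self.eliminated is None or self.conflicts):
            raise YplexError("a resolved assignment has exactly one eliminated marker")


@dataclass
class CompatibilitySummary:
    compatible: bool
    best_node: Optional[str]
    ancestral_on_path: set[str] = field(default_factory=set)
    derived_off_path: set[str] = field(default_factory=set)

    @property
    def conflicts(self) -> set[str]:
        return self.ancestral_on_path | self.derived_off_path


@dataclass
class RedundantGroupReport:
    group: str
    members: dict[str, str]
    consolidated: str
    concordant: bool
    partially_supported: bool


def decode_redundant(
    profile: GenotypeProfile, panel: Panel
) -> tuple[GenotypeProfile, list[RedundantGroupReport]]:
    """Consolidate redundant internal-control assays into one state each.

    The panel carries two kinds of built-in controls: two assays defining
    the same branch (M145/M203 for DE) and two dye-swapped assays for the
    same variant (M9a/M9b for K). Dye decoding already happened at allele
    calling, so members must agree on the A/D state: agreement gives one
    consolidated state; disagreement downgrades the branch to N and flags
    a discordance; a single called member is used as-is and flagged
    partially supported.
    """
    updates: dict[str, str] = {}
    reports: list[RedundantGroupReport] = []
    for gid, members in sorted(panel.redundancy_groups.items()):
        states = {m.name: profile[m.name] for m in members if m.is_active}
        if not states:
            continue
        called = {s for s in states.values() if s != NO_CALL}
        if len(called) == 1:
            consolidated = called.pop()
            concordant = all(s != NO_CALL for s in states.values())
            partial = not concordant
        elif len(called) == 0:
            consolidated, concordant, partial = NO_CALL, True, False
        else:  # members disagree: at least one is wrong, trust neither
            consolidated, concordant, partial = NO_CALL, False, False
        updates.update({name: consolidated for name in states})
        reports.append(
            RedundantGroupReport(
                group=gid,
                members=states,
                consolidated=consolidated,
                concordant=concordant,
                partially_supported=partial,
            )
        )
    return profile.with_calls(updates), reports


def _candidate_conflicts(
    profile: GenotypeProfile, tree: PhyloTree, node: str
) -> tuple[set[str], set[str]]:
    path = tree.path_markers(node)
    ancestral_on_path = profile.ancestral_markers & path
    derived_off_path = profile.derived_markers - path
    return ancestral_on_path, derived_off_path


def check_compatibility(profile: GenotypeProfile, tree: PhyloTree) -> CompatibilitySummary:
    """Is the derived-marker set one root-to-node path (on called markers)?

    Returns the best candidate node either way; for incompatible profiles
    the violations (ancestral-on-path, derived-off-path) are reported
    relative to that best candidate.
    """
    best: Optional[tuple] = None
    best_node: Optional[str] = None
    for label in sorted(tree.nodes):
        anc_on, der_off = _candidate_conflicts(profile, tree, label)
        path_support = len(profile.derived_markers) - len(der_off)
        # prefer full support, then fewest conflicts, then depth for a
        # deterministic representative path
        key = (-path_support, len(anc_on) + len(der_off), -tree.depth(label), label)
        if best is None or key < best:
            best, best_node = key, label
            if not anc_on and not der_off:
                break  # any compatible path contains all derived markers
    anc_on, der_off = _candidate_conflicts(profile, tree, best_node)
    return CompatibilitySummary(
        compatible=not (anc_on or der_off),
        best_node=best_node,
        ancestral_on_path=anc_on,
        derived_off_path=der_off,
    )


def deepest_derived_node(profile: GenotypeProfile, tree: PhyloTree, below: str) -> Optional[str]:
    """Deepest node on the lineage of ``below`` with a derived defining marker."""
    for label in reversed(tree.lineage(below)):
        if tree.nodes[label].defining_markers & profile.derived_markers:
            return label
    return None


def assign(profile: GenotypeProfile, tree: PhyloTree) -> Assignment:
    """Assign one profile to its haplogroup.

    Compatible profiles go to the deepest node whose defining marker is
    derived (the root paragroup when everything called is ancestral);
    incompatible profiles go through single-false-positive resolution.
    Profiles with no calls at all are marked empty.
    """
    if profile.is_empty:
        return Assignment(profile.sample_id, None, None, AssignmentStatus.EMPTY)
    summary = check_compatibility(profile, tree)
    if not summary.compatible:
        return resolve_single_false_positive(profile, tree)
    node = deepest_derived_node(profile, tree, summary.best_node) or tree.root
    return Assignment(
        sample_id=profile.sample_id,
        node=node,
        display_label=tree.display_label(node),
        status=AssignmentStatus.CLEAN,
        supporting=profile.derived_markers & tree.path_markers(node),
    )


def resolve_single_false_positive(profile: GenotypeProfile, tree: PhyloTree) -> Assignment:
    """Try to explain an incompatibility as one false-positive derived call.

    Each derived call is reverted to ancestral in turn; if exactly one
    reversion restores compatibility the sample is assigned on the
    corrected profile with that marker recorded as eliminated. Zero or
    several workable reversions leave the sample unresolved — no guessing
    and never more than one elimination.
    """
    summary = check_compatibility(profile, tree)
    if summary.compatible:
        return assign(profile, tree)
    successes: list[tuple[str, GenotypeProfile]] = []
    for marker in sorted(profile.derived_markers):
        fixed = profile.with_calls({marker: ANCESTRAL})
        if check_compatibility(fixed, tree).compatible:
            successes.append((marker, fixed))
    if len(successes) != 1:
        return Assignment(
            sample_id=profile.sample_id,
            node=summary.best_node,
            display_label=tree.display_label(summary.best_node),
            status=AssignmentStatus.UNRESOLVED,
            supporting=profile.derived_markers & tree.path_markers(summary.best_node),
            conflicts=summary.conflicts,
        )
    marker, fixed = successes[0]
    clean = assign(fixed, tree)
    return Assignment(
        sample_id=profile.sample_id,
        node=clean.node,
        display_label=clean.display_label,
        status=AssignmentStatus.RESOLVED,
        supporting=clean.supporting,
        eliminated=marker,
    )


def assign_cohort(
    profiles: Iterable[GenotypeProfile],
    tree: PhyloTree,
    panel: Optional[Panel] = None,
    populations: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Assign every sample; tabulate haplogroup x population counts.

    When a panel is given, redundant control assays are consolidated
    first. Returns (per-sample assignment table, counts matrix, status
    tally). Duplicate sample ids are an error.
    """
    profiles = list(profiles)
    ids = [p.sample_id for p in profiles]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise YplexError(f"duplicate sample ids in cohort: {sorted(dupes)}")

    rows = []
    for profile in profiles:
        if panel is not None:
            profile, _ = decode_redundant(profile, panel)
        a = assign(profile, tree)
        rows.append(
            {
                "sample_id": a.sample_id,
                "haplogroup": a.node or "",
                "display_label": a.display_label or "",
                "status": a.status.value,
                "eliminated_marker": a.eliminated or "",
                "supporting_markers": ",".join(sorted(a.supporting)),
                "conflict_markers": ",".join(sorted(a.conflicts)),
                "population": (populations or {}).get(a.sample_id, "all"),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "haplogroup",
            "display_label",
            "status",
            "eliminated_marker",
            "supporting_markers",
            "conflict_markers",
            "population",
        ],
    )
    assigned = table[table["status"] != AssignmentStatus.EMPTY.value]
    counts = (
        assigned.groupby(["display_label", "population"]).size().unstack(fill_value=0)
        if len(assigned)
        else pd.DataFrame()
    )
    tally = {s.value: int((table["status"] == s.value).sum()) for s in AssignmentStatus}
    return table, counts, tally
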