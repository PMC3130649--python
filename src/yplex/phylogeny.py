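"""Haplogroup tree construction from YCC-style labels plus a join table.

YCC nomenclature nests subhaplogroups by extending the parent's label
(E1b1b1a2 under E1b1b1a), so most parent links can be recovered by
longest-prefix matching, tolerating gaps where an intermediate label was
not typed (I1b1 under I1 when no I1b assay exists). Joins that prefixes
cannot express — compound haplogroups such as DE under CT or IJ under F,
and multi-digit siblings such as J2a13 under J2a — come from an explicit
child->parent skeleton table, which always overrides the prefix rule.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Optional

import dendropy
import pandas as pd

from .errors import TreeError
from .panel import Panel

ROOT_LABEL = "Y"

#: marker names with a ``.N`` variant designation mutate recurrently on the
#: phylogeny; the panel types a single placement of each.
_RECURRENT_RE = re.compile(r"\.\d+$")


@dataclass
class HaplogroupNode:
    label: str
    parent: Optional[str]
    defining_markers: set[str] = field(default_factory=set)
    recurrent: bool = False


@dataclass
class PhyloTree:
    """Rooted haplogroup tree with markers anchored to branches."""

    nodes: dict[str, HaplogroupNode]
    root: str = ROOT_LABEL

    def __post_init__(self) -> None:
        roots = [n.label for n in self.nodes.values() if n.parent is None]
        if roots != [self.root]:
            raise TreeError(f"expected exactly one root {self.root!r}, found {roots}")
        for node in self.nodes.values():
            if node.parent is not None and node.parent not in self.nodes:
                raise TreeError(f"node {node.label}: parent {node.parent} does not exist")
        # cycle check by walking every parent chain to the root
        for label in self.nodes:
            self.lineage(label)

    def __contains__(self, label: str) -> bool:
        return label in self.nodes

    def __getitem__(self, label: str) -> HaplogroupNode:
        try:
            return self.nodes[label]
        except KeyError:
            raise TreeError(f"unknown haplogroup label {label!r}") from None

    @cached_property
    def children(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {label: [] for label in self.nodes}
        for node in self.nodes.values():
            if node.parent is not None:
                out[node.parent].append(node.label)
        for kids in out.values():
            kids.sort()
        return out

    def lineage(self, label: str) -> list[str]:
        """Root-to-node path of labels, inclusive at both ends."""
        node = self[label]
        path = [label]
        seen = {label}
        while node.parent is not None:
            if node.parent in seen:
                raise TreeError(f"cycle detected through {node.parent!r}: {path}")
            path.append(node.parent)
            seen.add(node.parent)
            node = self[node.parent]
        return path[::-1]

    def depth(self, label: str) -> int:
        return len(self.lineage(label)) - 1

    def path_markers(self, label: str) -> set[str]:
        """All defining markers on the root-to-node path."""
        out: set[str] = set()
        for anc in self.lineage(label):
            out |= self.nodes[anc].defining_markers
        return out

    def descendants(self, label: str) -> list[str]:
        out, stack = [], list(self.children[label])
        while stack:
            x = stack.pop()
            out.append(x)
            stack.extend(self.children[x])
        return out

    def marker_defined_labels(self) -> list[str]:
        return sorted(l for l, n in self.nodes.items() if n.defining_markers)

    def has_typed_descendant(self, label: str) -> bool:
        return any(self.nodes[d].defining_markers for d in self.descendants(label))

    def display_label(self, label: str) -> str:
        """Paragroup rendering: a star when typed descendants exist."""
        return f"{label}*" if self.has_typed_descendant(label) or label == self.root else label

    def marker_to_node(self) -> dict[str, str]:
        return {m: n.label for n in self.nodes.values() for m in n.defining_markers}

    def to_parent_table(self) -> pd.DataFrame:
        rows = [
            {
                "label": n.label,
                "parent": n.parent if n.parent is not None else "",
                "defining_markers": ",".join(sorted(n.defining_markers)),
            }
            for n in sorted(self.nodes.values(), key=lambda x: (self.depth(x.label), x.label))
        ]
        return pd.DataFrame(rows)

    def to_newick(self) -> str:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = {self.root: dtree.seed_node}
        dtree.seed_node.label = self.root
        for label in sorted(self.nodes, key=self.depth):
            for child in self.children[label]:
                node = dnodes[label].new_child()
                node.label = child
                dnodes[child] = node
        for label, node in dnodes.items():
            if not node.child_nodes():  # leaves serialize via taxa
                node.taxon = taxa.new_taxon(label=label)
        return dtree.as_string(schema="newick", suppress_rooting=True).strip()


def load_skeleton(path) -> dict[str, str]:
    """Read a child->parent join table (TSV with child_label/parent_label)."""
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for col in ("child_label", "parent_label"):
        if col not in table.columns:
            raise TreeError(f"skeleton table {path}: missing column {col!r}")
    joins = dict(zip(table["child_label"], table["parent_label"]))
    if len(joins) != len(table):
        raise TreeError(f"skeleton table {path}: duplicate child labels")
    return joins


def _prefix_parent(label: str, candidates: set[str]) -> Optional[str]:
    for k in range(len(label) - 1, 0, -1):
        if label[:k] in candidates:
            return label[:k]
    return None


def build_tree(
    panel: Panel,
    skeleton: Optional[dict[str, str]] = None,
    include_failed: bool = False,
    root: str = ROOT_LABEL,
) -> PhyloTree:
    """Anchor the panel's haplogroup labels on a rooted tree.

    Parent of a label = skeleton entry if present, else the longest proper
    prefix found among panel or skeleton labels (gap-tolerant). Labels with
    neither raise :class:`TreeError` listing every orphan.
    """
    skeleton = dict(skeleton or {})
    markers = panel.markers if include_failed else panel.active_markers

    by_label: dict[str, set[str]] = {}
    for m in markers:
        by_label.setdefault(m.haplogroup, set()).add(m.name)

    labels = set(by_label) | set(skeleton) | set(skeleton.values()) | {root}
    candidates = set(labels)

    nodes: dict[str, HaplogroupNode] = {}
    orphans: list[str] = []
    for label in sorted(labels):
        if label == root:
            parent = None
        elif label in skeleton:
            parent = skeleton[label]
            by_prefix = _prefix_parent(label, candidates - {label})
            if by_prefix is not None and by_prefix != parent:
                warnings.warn(
                    f"label {label}: skeleton parent {parent} overrides prefix parent {by_prefix}"
                )
        else:
            parent = _prefix_parent(label, candidates - {label})
            if parent is None:
                if label.isalpha():
                    parent = root  # a major haplogroup letter hangs off the root
                else:
                    orphans.append(label)
                    continue
        defining = by_label.get(label, set())
        nodes[label] = HaplogroupNode(
            label=label,
            parent=parent,
            defining_markers=defining,
            recurrent=any(_RECURRENT_RE.search(m) for m in defining),
        )
    if orphans:
        raise TreeError(f"labels with no resolvable parent and no skeleton entry: {orphans}")
    return PhyloTree(nodes=nodes, root=root)


def lineage(tree: PhyloTree, label: str) -> list[str]:
    """Convenience wrapper over :meth:`PhyloTree.lineage`."""
    return tree.lineage(label)


def distinguishable_classes(tree: PhyloTree, include_root: bool = True) -> tuple[set[str], int]:
    """Genotype-resolvable classes under the one-class-per-typed-node convention.

    Each marker-defined node contributes one class: its paragroup (starred)
    when typed descendants remain, the node itself when it is terminal in
    the panel. The all-ancestral root paragroup is one further class when
    ``include_root``. Returns (descriptors, count).
    """
    classes = {tree.display_label(l) for l in tree.marker_defined_labels()}
    if include_root:
        classes.add(f"{tree.root}*")
    return classes, len(classes)


def build_packaged_tree(panel: Optional[Panel] = None) -> PhyloTree:
    """The tree of the packaged 121-assay panel with its join table."""
    from .panel import load_packaged_panel, packaged_skeleton_path

    panel = panel or load_packaged_panel()
    return build_tree(panel, load_skeleton(packaged_skeleton_path()))
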