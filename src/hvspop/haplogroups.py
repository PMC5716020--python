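"""Rule-tree haplogroup assignment for mtDNA motifs and Y-SNP panels.

mtDNA haplogroups are called from an East-Asian classification rule tree
whose nodes carry the diagnostics actually typed in the study panel:
coding-region positions (presence/absence semantics, matching APLP typing,
with explicit alleles only where printed, e.g. 15487T), auxiliary HVS-I
positions, and special length markers (the 9-bp deletion for haplogroup B).
The call is the deepest node whose ancestral path is supported; paraphyletic
"star" nodes (D*, N*) are emitted when the parent is supported and no typed
child diagnostic is present.  Unknown private HVS-I variants never veto a
call; support for mutually exclusive branches at equal depth yields an
explicit ambiguous result, never a silent pick.

Y-chromosome haplogroups are called by walking an ISOGG-style marker panel:
the deepest node whose defining marker is derived wins, an ancestral call at
a node blocks everything below it, and untyped markers do not block but cap
the depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

from .core import PopulationDataset, VariantMotif

__all__ = [
    "HaplogroupTree",
    "YSnpPanel",
    "CallResult",
    "load_mt_tree",
    "load_y_panel",
    "call_mt_haplogroup",
    "call_y_haplogroup",
    "call_dataset",
]

ROOT = "root"


@dataclass(frozen=True)
class TreeNode:
    label: str
    parent: str
    coding: frozenset[int] = frozenset()          # positions, presence semantics
    coding_alleles: frozenset[tuple[int, str]] = frozenset()  # printed alleles
    negative_coding: frozenset[int] = frozenset()  # absence supports the node
    hvs1: frozenset[int] = frozenset()             # auxiliary HVS-I positions
    special: frozenset[str] = frozenset()
    star: bool = False
    motif_led: bool = False

    @property
    def has_positive_definition(self) -> bool:
        return bool(self.coding or self.special or (self.motif_led and self.hvs1))


@dataclass
class HaplogroupTree:
    """Rooted rule tree mapping diagnostic variants to haplogroup labels."""

    nodes: dict[str, TreeNode]

    def __post_init__(self) -> None:
        for node in self.nodes.values():
            if node.parent != ROOT and node.parent not in self.nodes:
                raise ValueError(f"node {node.label}: unknown parent {node.parent}")
        # acyclicity: every node must reach the root
        for label in self.nodes:
            self.path_to_root(label)

    def path_to_root(self, label: str) -> list[str]:
        """Labels from root (exclusive) down to ``label`` (inclusive)."""
        path: list[str] = []
        seen: set[str] = set()
        cur = label
        while cur != ROOT:
            if cur in seen:
                raise ValueError(f"cycle detected at {cur}")
            seen.add(cur)
            path.append(cur)
            cur = self.nodes[cur].parent
        return list(reversed(path))

    def children(self, label: str) -> list[TreeNode]:
        return [n for n in self.nodes.values() if n.parent == label]

    def depth(self, label: str) -> int:
        return len(self.path_to_root(label))


@dataclass(frozen=True)
class YMarker:
    name: str
    node: str
    ancestral: str
    derived: str


@dataclass
class YSnpPanel:
    """Ordered Y-SNP marker panel over an ISOGG-style rule tree."""

    markers: list[YMarker]
    tree: HaplogroupTree

    def __post_init__(self) -> None:
        nodes_with_marker = [m.node for m in self.markers]
        if len(nodes_with_marker) != len(set(nodes_with_marker)):
            raise ValueError("each marker must map to exactly one tree node")
        for m in self.markers:
            if m.node not in self.tree.nodes:
                raise ValueError(f"marker {m.name}: unknown node {m.node}")

    def marker_for(self, node: str) -> YMarker | None:
        for m in self.markers:
            if m.node == node:
                return m
        return None


@dataclass
class CallResult:
    """Outcome of a haplogroup call."""

    label: str
    path: list[str] = field(default_factory=list)
    evidence: dict[str, list[str]] = field(default_factory=dict)
    conflicts: list[str] = field(default_factory=list)
    ambiguous: bool = False
    candidates: list[list[str]] = field(default_factory=list)
    low_confidence: bool = False

    @property
    def clean(self) -> bool:
        return not self.conflicts and not self.ambiguous


# ---------------------------------------------------------------------------
# tree file parsing


def _parse_tree_text(text: str) -> HaplogroupTree:
    nodes: dict[str, TreeNode] = {}
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        parts = (line.split("\t") + [""] * 6)[:6]
        label, parent, coding_s, hvs_s, special_s, flags_s = parts
        coding: set[int] = set()
        alleles: set[tuple[int, str]] = set()
        negative: set[int] = set()
        for tok in filter(None, (t.strip() for t in coding_s.split(","))):
            if tok.startswith("!"):
                negative.add(int(tok[1:]))
            elif tok[-1] in "ACGT":
                alleles.add((int(tok[:-1]), tok[-1]))
                coding.add(int(tok[:-1]))
            else:
                coding.add(int(tok))
        hvs1 = frozenset(
            int(t) for t in filter(None, (t.strip() for t in hvs_s.split(",")))
        )
        special = frozenset(filter(None, (t.strip() for t in special_s.split(","))))
        flags = set(filter(None, (t.strip() for t in flags_s.split(","))))
        nodes[label] = TreeNode(
            label=label,
            parent=parent,
            coding=frozenset(coding),
            coding_alleles=frozenset(alleles),
            negative_coding=frozenset(negative),
            hvs1=hvs1,
            special=special,
            star="star" in flags,
            motif_led="motif_led" in flags,
        )
    return HaplogroupTree(nodes)


def load_mt_tree(path: str | None = None) -> HaplogroupTree:
    """Load the packaged East-Asian mtDNA rule tree (or a user file)."""
    if path is None:
        text = resources.files("hvspop.data").joinpath(
            "mt_tree_east_asian.txt"
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return _parse_tree_text(text)


def load_y_panel(path: str | None = None) -> YSnpPanel:
    """Load the packaged Y-SNP panel (or a user file in the same format)."""
    if path is None:
        text = resources.files("hvspop.data").joinpath("y_panel.txt").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    nodes: dict[str, TreeNode] = {}
    markers: list[YMarker] = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        node, parent, name, anc, der = (line.split("\t") + [""] * 5)[:5]
        nodes[node] = TreeNode(label=node, parent=parent)
        markers.append(YMarker(name=name, node=node, ancestral=anc, derived=der))
    return YSnpPanel(markers=markers, tree=HaplogroupTree(nodes))


# ---------------------------------------------------------------------------
# mtDNA calling


def _node_supported(node: TreeNode, motif: VariantMotif) -> list[str]:
    """Evidence strings if the node's positive diagnostics match, else []."""
    evidence = []
    coding_positions = motif.coding_positions
    for pos in sorted(node.coding):
        if pos in coding_positions:
            evidence.append(str(pos))
    for marker in sorted(node.special):
        if marker in motif.special_markers:
            evidence.append(marker)
    if node.motif_led and node.hvs1:
        transitions = frozenset(
            v.position for v in motif.hvs1_variants if v.kind == "transition"
        )
        if transitions == node.hvs1:
            evidence.append("motif:" + ",".join(map(str, sorted(node.hvs1))))
    return evidence


def call_mt_haplogroup(motif: VariantMotif, tree: HaplogroupTree) -> CallResult:
    """Assign an mtDNA haplogroup from a variant motif.

    The deepest node with direct positive support and a supported ancestral
    path wins; deeper support dominates shallower support on another branch
    (recorded as a conflict), while equal-depth support on divergent
    branches is returned as an ambiguous call.  Star nodes add a trailing
    ``*`` when no typed child is supported.
    """
    if motif.is_empty():
        return CallResult(label="unassigned")

    support: dict[str, list[str]] = {}
    for label, node in tree.nodes.items():
        ev = _node_supported(node, motif)
        if ev:
            support[label] = ev
    # negative diagnostics (the basal M/N dichotomy): supported by absence
    negative_support: set[str] = set()
    for label, node in tree.nodes.items():
        if node.negative_coding and not (
            node.negative_coding & motif.coding_positions
        ):
            negative_support.add(label)

    def path_ok(label: str) -> bool:
        node = tree.nodes[label]
        if node.motif_led:
            return True  # ancestor evidence waived, flagged low-confidence
        for anc in tree.path_to_root(label)[:-1]:
            anc_node = tree.nodes[anc]
            if anc_node.has_positive_definition and anc not in support:
                return False
        return True

    candidates = [lab for lab in support if path_ok(lab)]
    if not candidates:
        # fall back to negatively-defined basal nodes (e.g. N with no child)
        basal = sorted(negative_support, key=tree.depth)
        if basal:
            label = basal[-1]
            node = tree.nodes[label]
            out = node.label + "*" if node.star else node.label
            return CallResult(
                label=out,
                path=tree.path_to_root(label),
                evidence={label: [f"absence of {sorted(node.negative_coding)}"]},
            )
        return CallResult(label="unassigned")

    max_depth = max(tree.depth(lab) for lab in candidates)
    deepest = sorted(lab for lab in candidates if tree.depth(lab) == max_depth)
    if len(deepest) > 1:
        paths = [tree.path_to_root(lab) for lab in deepest]
        return CallResult(
            label="ambiguous",
            ambiguous=True,
            candidates=paths,
            conflicts=[f"equal-depth support for {', '.join(deepest)}"],
            evidence={lab: support[lab] for lab in deepest},
        )
    best = deepest[0]
    path = tree.path_to_root(best)
    node = tree.nodes[best]

    conflicts = [
        f"supported off-path node {lab}"
        for lab in sorted(support)
        if lab not in path and not set(tree.path_to_root(lab)) <= set(path)
    ]
    # negative-diagnostic ancestors contradicted by the coding set
    for anc in path:
        anc_node = tree.nodes[anc]
        if anc_node.negative_coding & motif.coding_positions:
            conflicts.append(
                f"{anc} requires absence of "
                f"{sorted(anc_node.negative_coding & motif.coding_positions)}"
            )

    label = best
    if node.star:
        child_supported = any(c.label in support for c in tree.children(best))
        if not child_supported:
            label = best + "*"
    return CallResult(
        label=label,
        path=path,
        evidence={lab: support[lab] for lab in path if lab in support},
        conflicts=conflicts,
        low_confidence=node.motif_led,
    )


# ---------------------------------------------------------------------------
# Y calling

_STATE_TOKENS = {"der": "derived", "anc": "ancestral"}


def _y_state(genotype: str, marker: YMarker) -> str:
    g = genotype.strip().replace(" ", "").replace("−", "-")
    if not g or g in ("?", "."):
        return "missing"
    low = g.lower()
    if low in _STATE_TOKENS:
        return _STATE_TOKENS[low]
    if g.upper() == marker.derived.upper():
        return "derived"
    if g.upper() == marker.ancestral.upper():
        return "ancestral"
    return "missing"


def call_y_haplogroup(
    genotypes: Mapping[str, str], panel: YSnpPanel
) -> CallResult:
    """Assign a Y haplogroup from a marker->allele genotype map.

    Deepest node with a derived marker and derived-where-typed ancestors;
    an ancestral state blocks all deeper nodes on that branch; missing
    markers do not block but cap the call depth.
    """
    by_name = {m.name: m for m in panel.markers}
    states: dict[str, str] = {}  # node -> state
    for name, genotype in genotypes.items():
        marker = by_name.get(name)
        if marker is None:
            continue
        states[marker.node] = _y_state(str(genotype), marker)

    tree = panel.tree
    best: str | None = None
    conflicts: list[str] = []
    for label in tree.nodes:
        if states.get(label) != "derived":
            continue
        path = tree.path_to_root(label)
        blocked = any(states.get(anc) == "ancestral" for anc in path[:-1])
        if blocked:
            conflicts.append(
                f"{label} derived below an ancestral-typed parent"
            )
            continue
        if best is None or tree.depth(label) > tree.depth(best):
            best = label
    if best is None:
        return CallResult(label="unassigned", conflicts=conflicts)
    path = tree.path_to_root(best)
    evidence = {
        lab: [panel.marker_for(lab).name]  # type: ignore[union-attr]
        for lab in path
        if states.get(lab) == "derived"
    }
    return CallResult(label=best, path=path, evidence=evidence, conflicts=conflicts)


# ---------------------------------------------------------------------------
# dataset-level calling


def call_dataset(
    dataset: PopulationDataset,
    tree: HaplogroupTree | None = None,
    overwrite: bool = True,
) -> dict[str, int]:
    """Annotate every sample in place; return call counts per label."""
    if tree is None:
        tree = load_mt_tree()
    counts: dict[str, int] = {}
    for sample in dataset.samples:
        result = call_mt_haplogroup(sample.motif, tree)
        if overwrite or sample.haplogroup is None:
            sample.haplogroup = result.label
        counts[result.label] = counts.get(result.label, 0) + 1
    return counts


def macro_label(label: str, collapse: Mapping[str, str] | None = None) -> str:
    """Fold sublineage labels into macro-haplogroups (default: D*, D4, D5 -> D)."""
    if collapse is None:
        collapse = {"D*": "D", "D4": "D", "D5": "D"}
    return collapse.get(label, label)
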