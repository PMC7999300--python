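"""Perfect-phylogeny reconstruction from a binary presence matrix.

Characters (SNS or CNA ids) are first merged into groups carried by
identical sample sets.  Two groups are compatible iff their sample sets are
nested or disjoint; a maximal compatible family is chosen greedily by
descending group support (number of characters), and the tree is the Hasse
diagram of the surviving laminar family ordered by set inclusion.  Excluded
groups are reported with their conflicting partners — the analogue of
setting aside characters that cannot be placed on any branch.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .clonality import PresenceMatrix


@dataclass(frozen=True)
class CharacterGroup:
    """Characters sharing one carrier sample set."""

    samples: frozenset[str]
    characters: tuple[str, ...]

    @property
    def support(self) -> int:
        return len(self.characters)


@dataclass
class Conflict:
    excluded: CharacterGroup
    partners: list[CharacterGroup]


def group_characters(char_sets: dict[str, frozenset[str]]) -> list[CharacterGroup]:
    """Merge characters with identical carrier sets; empty sets are dropped."""
    by_set: dict[frozenset[str], list[str]] = {}
    for char, samples in char_sets.items():
        if samples:
            by_set.setdefault(frozenset(samples), []).append(char)
    return [
        CharacterGroup(samples=s, characters=tuple(sorted(chars)))
        for s, chars in by_set.items()
    ]


def matrix_character_sets(
    matrix: PresenceMatrix, include_roles: tuple[str, ...] = ("organoid", "metastasis")
) -> dict[str, frozenset[str]]:
    """Carrier sets of every variant over the selected sample roles."""
    samples = [s for s in matrix.sample_ids if matrix.roles[s] in include_roles]
    present = matrix.present().loc[samples]
    return {
        vid: frozenset(present.index[present[vid]])
        for vid in matrix.variant_ids
    }


def _compatible(a: frozenset, b: frozenset) -> bool:
    return a <= b or b <= a or not (a & b)


def check_compatibility(
    groups: list[CharacterGroup],
) -> tuple[list[CharacterGroup], list[Conflict]]:
    """Greedy maximal compatible family.

    Groups are taken in order of descending support (character count), ties
    broken by the lexicographically smallest sorted sample set; a group is
    excluded if it overlaps an accepted group without nesting.
    """
    ordered = sorted(groups, key=lambda g: (-g.support, sorted(g.samples)))
    accepted: list[CharacterGroup] = []
    conflicts: list[Conflict] = []
    for group in ordered:
        partners = [a for a in accepted if not _compatible(group.samples, a.samples)]
        if partners:
            conflicts.append(Conflict(excluded=group, partners=partners))
        else:
            accepted.append(group)
    return accepted, conflicts


# ---------------------------------------------------------------------------
# tree construction


@dataclass
class PhyloNode:
    node_id: str
    samples: frozenset[str]
    characters: tuple[str, ...] = ()
    parent: str | None = None
    children: list[str] = field(default_factory=list)
    leaf_samples: list[str] = field(default_factory=list)


class PhyloTree:
    """Inferred clone tree: internal nodes are ancestral clones, each edge
    carries the character group that defines its clade."""

    def __init__(self) -> None:
        self.nodes: dict[str, PhyloNode] = {}
        self.root: str | None = None

    def add(self, node: PhyloNode) -> None:
        self.nodes[node.node_id] = node
        if node.parent is None:
            self.root = node.node_id
        else:
            self.nodes[node.parent].children.append(node.node_id)

    @property
    def root_out_degree(self) -> int:
        root = self.nodes[self.root]
        return len(root.children) + len(root.leaf_samples)

    def leaf_names(self) -> list[str]:
        out = []
        for node in self.nodes.values():
            out.extend(node.leaf_samples)
        return sorted(out)

    def edge_characters(self) -> dict[str, tuple[str, ...]]:
        """Characters on the edge entering each node (trunk = root's)."""
        return {nid: n.characters for nid, n in self.nodes.items()}

    def clade_samples(self, node_id: str) -> frozenset[str]:
        return self.nodes[node_id].samples


def build_tree(groups: list[CharacterGroup], samples: list[str]) -> PhyloTree:
    """Hasse diagram of a laminar family, rooted at the all-samples set.

    Each group's characters attach to the edge entering its node; samples
    hang as leaves under their minimal containing set.  Identical-profile
    samples become sibling leaves under one node.  Non-laminar input is
    rejected — run :func:`check_compatibility` first.
    """
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            if not _compatible(a.samples, b.samples):
                raise ValueError(
                    f"groups are not laminar: {sorted(a.samples)} vs {sorted(b.samples)}"
                )
    all_samples = frozenset(samples)
    by_set: dict[frozenset[str], list[str]] = {}
    for g in groups:
        by_set.setdefault(g.samples, []).extend(g.characters)
    if all_samples not in by_set:
        by_set[all_samples] = []

    sets = sorted(by_set, key=lambda s: (-len(s), sorted(s)))
    tree = PhyloTree()
    ids: dict[frozenset[str], str] = {}
    for k, s in enumerate(sets):
        parent_set = None
        for cand in sets:
            if s < cand and (parent_set is None or cand < parent_set):
                parent_set = cand
        node = PhyloNode(
            node_id=f"c{k:03d}",
            samples=s,
            characters=tuple(sorted(by_set[s])),
            parent=ids[parent_set] if parent_set is not None else None,
        )
        ids[s] = node.node_id
        tree.add(node)

    for sample in sorted(samples):
        best = None
        for s in sets:
            if sample in s and (best is None or s < best):
                best = s
        tree.nodes[ids[best]].leaf_samples.append(sample)
    return tree


# ---------------------------------------------------------------------------
# Newick I/O with bracketed edge comments
#
# Hand-rolled because the edge annotations ([&chars=a|b]) carry the character
# groups, which standard newick readers do not round-trip faithfully.


def _escape(name: str) -> str:
    if re.search(r"[\s(),:;\[\]']", name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: PhyloTree) -> str:
    def comment(chars: tuple[str, ...]) -> str:
        if not chars:
            return ""
        return "[&chars=" + "|".join(chars) + "]"

    def render(node_id: str) -> str:
        node = tree.nodes[node_id]
        parts = [_escape(s) for s in sorted(node.leaf_samples)]
        parts += [render(c) for c in node.children]
        if len(parts) == 1 and not node.children and node.node_id != tree.root:
            # single-leaf clade: keep the internal node explicit
            pass
        inner = ",".join(parts)
        return f"({inner}){comment(node.characters)}"

    return render(tree.root) + ";"


class _Parser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.pos = 0
        self.tree = PhyloTree()
        self.counter = 0

    def error(self, msg: str) -> Exception:
        return ValueError(f"newick parse error at position {self.pos}: {msg}")

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def parse(self) -> PhyloTree:
        root_id = self._node(parent=None)
        if self.peek() != ";":
            raise self.error("expected ';'")
        self._finalize_samples(root_id)
        return self.tree

    def _new_id(self) -> str:
        nid = f"c{self.counter:03d}"
        self.counter += 1
        return nid

    def _node(self, parent: str | None) -> str:
        if self.peek() != "(":
            raise self.error("expected '('")
        self.pos += 1
        node = PhyloNode(node_id=self._new_id(), samples=frozenset(), parent=parent)
        self.tree.add(node)
        while True:
            if self.peek() == "(":
                self._node(parent=node.node_id)
            else:
                node.leaf_samples.append(self._name())
            if self.peek() == ",":
                self.pos += 1
                continue
            if self.peek() == ")":
                self.pos += 1
                break
            raise self.error("expected ',' or ')'")
        node.characters = self._comment()
        return node.node_id

    def _name(self) -> str:
        if self.peek() == "'":
            self.pos += 1
            out = []
            while True:
                ch = self.peek()
                if not ch:
                    raise self.error("unterminated quoted name")
                self.pos += 1
                if ch == "'":
                    if self.peek() == "'":
                        out.append("'")
                        self.pos += 1
                    else:
                        break
                else:
                    out.append(ch)
            return "".join(out)
        m = re.match(r"[^\s(),:;\[\]]+", self.text[self.pos :])
        if not m:
            raise self.error("expected a leaf name")
        self.pos += m.end()
        return m.group(0)

    def _comment(self) -> tuple[str, ...]:
        if self.peek() != "[":
            return ()
        end = self.text.find("]", self.pos)
        if end < 0:
            raise self.error("unterminated comment")
        body = self.text[self.pos + 1 : end]
        self.pos = end + 1
        if not body.startswith("&chars="):
            return ()
        payload = body[len("&chars=") :]
        return tuple(payload.split("|")) if payload else ()

    def _finalize_samples(self, node_id: str) -> frozenset[str]:
        node = self.tree.nodes[node_id]
        samples = set(node.leaf_samples)
        for child in node.children:
            samples |= self._finalize_samples(child)
        node.samples = frozenset(samples)
        return node.samples


def read_newick(text: str) -> PhyloTree:
    return _Parser(text.strip()).parse()


def conflict_report(conflicts: list[Conflict]) -> str:
    """TSV: character, sample set, conflicting partners."""
    lines = ["character\tsamples\tconflicts_with"]
    for c in conflicts:
        partner_chars = ";".join(
            ",".join(p.characters) for p in c.partners
        )
        for char in c.excluded.characters:
            lines.append(
                f"{char}\t{','.join(sorted(c.excluded.samples))}\t{partner_chars}"
            )
    return "\n".join(lines) + "\n"
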