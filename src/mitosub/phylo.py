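"""Phylogeny ingest: branch tables, ancestral-sequence propagation, event extraction.

The ingest format is a branch table TSV with columns ``parent_id``,
``child_id``, ``is_tip`` and ``substitutions``, the last a
semicolon-separated list of tokens in mtDNA-phylogeny notation: ancestral
base, 1-based site, derived base, e.g. ``A16182c`` or ``C16519T``
(case-insensitive; a trailing ``!`` marks a back mutation and is accepted
as an ordinary substitution).  Tokens denoting indels (``d`` deletions,
``.1`` insertions) are skipped with a warning.

Given a root sequence, sequences are propagated to every node by applying
each branch's substitutions in preorder, verifying that every token's
ancestral base matches the parent sequence.  Classified
:class:`SubstitutionEvent` records are then extracted against the genome
annotation, dropping events at excluded hot-spot sites.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import dendropy

from .genetic_code import classify_change, translate_codon
from .genome import AnnotatedGenome, State, site_state

_SUB_RE = re.compile(r"^([ACGTacgt])(\d+)([ACGTacgt])!*$")
_INDEL_RE = re.compile(r"^[ACGTacgt]?\d+(\.\d+)?([ACGTacgt]*d|d|[ACGTacgt]+)?$")


class BranchTableError(ValueError):
    pass


class SequenceConsistencyError(ValueError):
    pass


@dataclass
class Substitution:
    """One substitution token on a branch: ``from_base`` at ``site`` became ``to_base``."""

    site: int
    from_base: str
    to_base: str


@dataclass
class Node:
    id: str
    parent: str | None = None
    children: list[str] = field(default_factory=list)
    is_tip: bool = False
    substitutions: list[Substitution] = field(default_factory=list)
    sequence: str | None = None
    time: float | None = None


@dataclass(frozen=True)
class SubstitutionEvent:
    """A classified substitution with the parent-node state it occurred in."""

    branch_child: str
    site: int
    from_base: str
    to_base: str
    change_class: str  # "ts" | "tv"
    synonymy: str  # "syn" | "nonsyn" | "n/a"
    parent_state: State


class PhyloTree:
    """Rooted tree with per-branch substitution lists.

    A branch is identified by its child node; the branch into ``child``
    carries the substitutions separating it from its parent.
    """

    def __init__(self, nodes: dict[str, Node], root: str) -> None:
        self.nodes = nodes
        self.root = root

    def __len__(self) -> int:
        return len(self.nodes)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = self.nodes[stack.pop()]
            yield node
            stack.extend(reversed(node.children))

    def branches(self) -> Iterator[tuple[Node, Node]]:
        """Yield (parent, child) pairs in preorder."""
        for node in self.preorder():
            for child_id in node.children:
                yield node, self.nodes[child_id]

    def tips(self) -> list[Node]:
        return [n for n in self.nodes.values() if n.is_tip]

    def n_branches(self) -> int:
        return len(self.nodes) - 1

    def validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise BranchTableError(
                f"tree must have exactly one root, found {len(roots)}: "
                f"{sorted(n.id for n in roots)[:5]}"
            )
        seen = sum(1 for _ in self.preorder())
        if seen != len(self.nodes):
            raise BranchTableError(
                "tree is not a single connected acyclic component "
                f"({seen} of {len(self.nodes)} nodes reachable from the root)"
            )


def parse_token(token: str) -> Substitution | None:
    """Parse one substitution token; ``None`` for a skippable indel token."""
    token = token.strip()
    m = _SUB_RE.match(token)
    if m:
        return Substitution(
            site=int(m.group(2)),
            from_base=m.group(1).upper(),
            to_base=m.group(3).upper(),
        )
    if token.endswith(("d", "D")) or "." in token:
        warnings.warn(f"skipping indel token {token!r}", stacklevel=3)
        return None
    raise BranchTableError(f"malformed substitution token {token!r}")


def read_branch_table(source: str | Path | IO[str]) -> PhyloTree:
    """Read a branch table TSV into a :class:`PhyloTree` (topology + tokens)."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    if not lines:
        raise BranchTableError("empty branch table")
    header = lines[0].rstrip("\n").split("\t")
    required = ["parent_id", "child_id", "is_tip", "substitutions"]
    if header[: len(required)] != required:
        raise BranchTableError(
            f"branch table header must start with {required}, got {header}"
        )
    nodes: dict[str, Node] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise BranchTableError(f"line {lineno}: expected 4 columns")
        parent_id, child_id, is_tip = parts[0], parts[1], parts[2]
        subs_field = parts[3] if len(parts) > 3 else ""
        if child_id in nodes and nodes[child_id].parent is not None:
            raise BranchTableError(f"line {lineno}: node {child_id} has two parents")
        parent = nodes.setdefault(parent_id, Node(parent_id))
        child = nodes.setdefault(child_id, Node(child_id))
        child.parent = parent_id
        child.is_tip = is_tip.strip().lower() in ("1", "true", "yes")
        parent.children.append(child_id)
        try:
            for token in filter(None, (t.strip() for t in subs_field.split(";"))):
                sub = parse_token(token)
                if sub is not None:
                    child.substitutions.append(sub)
        except BranchTableError as exc:
            raise BranchTableError(f"line {lineno}: {exc}") from None
    roots = [n for n in nodes.values() if n.parent is None]
    if len(roots) != 1:
        raise BranchTableError(
            f"expected one root, found {len(roots)}"
            + (": " + ", ".join(sorted(n.id for n in roots)[:5]) if roots else "")
        )
    tree = PhyloTree(nodes, roots[0].id)
    tree.validate()
    return tree


def write_branch_table(tree: PhyloTree, target: str | Path | IO[str]) -> None:
    lines = ["parent_id\tchild_id\tis_tip\tsubstitutions"]
    for parent, child in tree.branches():
        tokens = ";".join(
            f"{s.from_base}{s.site}{s.to_base}" for s in child.substitutions
        )
        lines.append(f"{parent.id}\t{child.id}\t{int(child.is_tip)}\t{tokens}")
    text = "\n".join(lines) + "\n"
    if hasattr(target, "write"):
        target.write(text)
    else:
        Path(target).write_text(text)


def propagate_sequences(tree: PhyloTree, root_sequence: str) -> PhyloTree:
    """Fill every node's full sequence by applying branch substitutions in preorder.

    Each token's ancestral base must match the running sequence at its site;
    multiple substitutions at one site on one branch are applied in listed
    order.
    """
    root_sequence = root_sequence.upper()
    tree.nodes[tree.root].sequence = root_sequence
    n = len(root_sequence)
    for parent, child in tree.branches():
        seq = list(parent.sequence)  # type: ignore[arg-type]
        for sub in child.substitutions:
            if not 1 <= sub.site <= n:
                raise SequenceConsistencyError(
                    f"branch {parent.id}->{child.id}: site {sub.site} outside 1..{n}"
                )
            if seq[sub.site - 1] != sub.from_base:
                raise SequenceConsistencyError(
                    f"branch {parent.id}->{child.id}, site {sub.site}: "
                    f"token says {sub.from_base} but parent sequence has "
                    f"{seq[sub.site - 1]}"
                )
            seq[sub.site - 1] = sub.to_base
        child.sequence = "".join(seq)
    return tree


def extract_events(
    tree: PhyloTree,
    genome: AnnotatedGenome,
    clusters: dict[str, str] | None = None,
) -> list[SubstitutionEvent]:
    """Extract one classified event per substitution token at non-excluded sites.

    Each event is classified in the sequence context in effect immediately
    before it: the parent-node sequence with this branch's earlier tokens
    already applied.  Synonymy is ``n/a`` outside protein-coding codons.
    """
    events: list[SubstitutionEvent] = []
    for parent, child in tree.branches():
        if parent.sequence is None:
            raise ValueError("sequences not propagated; call propagate_sequences first")
        seq = parent.sequence
        for sub in child.substitutions:
            if sub.site in genome.excluded_sites:
                seq = seq[: sub.site - 1] + sub.to_base + seq[sub.site :]
                continue
            state = site_state(sub.site, seq, genome, clusters)
            if state.codon is not None:
                pos = state.codon_position
                new_codon = (
                    state.codon[: pos - 1] + sub.to_base + state.codon[pos:]
                )
                synonymy = (
                    "syn"
                    if translate_codon(new_codon) == state.amino_acid
                    else "nonsyn"
                )
            else:
                synonymy = "n/a"
            events.append(
                SubstitutionEvent(
                    branch_child=child.id,
                    site=sub.site,
                    from_base=sub.from_base,
                    to_base=sub.to_base,
                    change_class=classify_change(sub.from_base, sub.to_base),
                    synonymy=synonymy,
                    parent_state=state,
                )
            )
            seq = seq[: sub.site - 1] + sub.to_base + seq[sub.site :]
    return events


def to_newick(tree: PhyloTree) -> str:
    """Export topology with estimated node times as branch lengths (Newick)."""
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    def build(node: Node, dnode: dendropy.Node) -> None:
        for child_id in node.children:
            child = tree.nodes[child_id]
            dchild = dendropy.Node()
            if child.time is not None and node.time is not None:
                dchild.edge.length = node.time - child.time
            if child.is_tip:
                dchild.taxon = taxa.new_taxon(child.id)
            else:
                dchild.label = child.id
            dnode.add_child(dchild)
            build(child, dchild)

    root = tree.nodes[tree.root]
    dtree.seed_node.label = root.id
    build(root, dtree.seed_node)
    return dtree.as_string(schema="newick").strip()
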