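"""NCBI-taxonomy-dump loading, lineage rollup and node-count proximity.

The taxonomy is the backbone for two distinct jobs: collating peptide/spectrum
counts from the directly assigned taxa up to the seven canonical ranks, and
picking the closest pre-aligned organism (in nodes traversed) when seeding a
homology search for a new taxon's marker genes.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

CANONICAL_RANKS: tuple[str, ...] = (
    "species", "genus", "family", "order", "class", "phylum", "superkingdom",
)


class TaxonomyError(Exception):
    """Structural problem in a taxonomy dump (cycle, missing parent, ...)."""


@dataclass(frozen=True)
class TaxNode:
    taxid: int
    parent: int
    rank: str
    name: str


def _iter_dmp_rows(source) -> Iterator[list[str]]:
    """Yield field lists from an NCBI ``.dmp`` source.

    Accepts a filesystem path, a file-like object, an iterable of lines, or a
    string containing the dump text itself.  Both the canonical ``\\t|\\t``
    delimiter and bare ``|`` are handled; fields are whitespace-trimmed and a
    trailing empty field (from the terminal ``|``) is dropped.
    """
    if isinstance(source, (str, os.PathLike)) and (
        not isinstance(source, str) or ("\n" not in source and os.path.exists(source))
    ):
        with open(source) as fh:
            yield from _iter_dmp_rows(fh)
        return
    if isinstance(source, str):
        lines: Iterable[str] = source.splitlines()
    else:
        lines = source
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split("|")]
        if fields and fields[-1] == "":
            fields.pop()
        yield fields


class TaxonomyTree:
    """Rooted taxonomy with per-node parent, rank and scientific name.

    Parameters
    ----------
    nodes : mapping taxid -> TaxNode
    root : int
        The taxid whose parent is itself.
    merged : mapping old-taxid -> new-taxid, optional
        Remapping applied transparently on lookup (merged.dmp).
    """

    def __init__(self, nodes: dict[int, TaxNode], root: int,
                 merged: dict[int, int] | None = None):
        self.nodes = nodes
        self.root = root
        self.merged = dict(merged or {})
        self._validate()
        self._depth: dict[int, int] = {}

    # -- construction ------------------------------------------------------

    def _validate(self) -> None:
        for taxid, node in self.nodes.items():
            if node.parent not in self.nodes:
                raise TaxonomyError(
                    f"node {taxid} references missing parent {node.parent}"
                )
        # walk every node to the root, detecting cycles
        ok: set[int] = {self.root}
        for taxid in self.nodes:
            seen: list[int] = []
            cur = taxid
            while cur not in ok:
                if cur in seen:
                    raise TaxonomyError(f"cycle detected at taxon {cur}")
                seen.append(cur)
                parent = self.nodes[cur].parent
                if parent == cur and cur != self.root:
                    raise TaxonomyError(
                        f"self-parented non-root node {cur} (disconnected root?)"
                    )
                cur = parent
            ok.update(seen)

    # -- lookup ------------------------------------------------------------

    def canonical_id(self, taxid: int) -> int:
        """Apply merged-taxid remapping, if any."""
        return self.merged.get(taxid, taxid)

    def __contains__(self, taxid: int) -> bool:
        return self.canonical_id(taxid) in self.nodes

    def node(self, taxid: int) -> TaxNode:
        tid = self.canonical_id(taxid)
        try:
            return self.nodes[tid]
        except KeyError:
            raise KeyError(f"unknown taxon id {taxid}") from None

    def name(self, taxid: int) -> str:
        return self.node(taxid).name

    def rank(self, taxid: int) -> str:
        return self.node(taxid).rank

    def lineage(self, taxid: int) -> list[int]:
        """Path from taxid up to the root, inclusive, starting at taxid."""
        path = [self.canonical_id(taxid)]
        self.node(taxid)  # raise on unknown
        while path[-1] != self.root:
            path.append(self.nodes[path[-1]].parent)
        return path

    def lineage_at_level(self, taxid: int, level: str) -> int | None:
        """The unique ancestor-or-self of `taxid` carrying rank `level`.

        Returns None when no node of that rank occurs on the lineage (for
        example the root queried at species level).
        """
        if level not in CANONICAL_RANKS:
            raise ValueError(
                f"level must be one of {CANONICAL_RANKS}, got {level!r}"
            )
        for tid in self.lineage(taxid):
            if self.nodes[tid].rank == level:
                return tid
        return None

    def depth(self, taxid: int) -> int:
        tid = self.canonical_id(taxid)
        if tid not in self._depth:
            path = self.lineage(tid)
            for i, node in enumerate(reversed(path)):
                self._depth.setdefault(node, i)
        return self._depth[tid]

    def node_path_distance(self, a: int, b: int) -> int:
        """Number of edges on the a -> LCA -> b path."""
        pa = self.lineage(a)
        ancestors_a = {tid: i for i, tid in enumerate(pa)}
        steps_b = 0
        cur = self.canonical_id(b)
        self.node(b)
        while cur not in ancestors_a:
            cur = self.nodes[cur].parent
            steps_b += 1
        return ancestors_a[cur] + steps_b

    def closest_prealigned_taxon(self, taxid: int, prealigned: set[int]) -> int:
        """Member of `prealigned` minimising node_path_distance to `taxid`.

        Ties break to the smallest taxon id, so the choice is reproducible.
        """
        if not prealigned:
            raise ValueError("prealigned set must be non-empty")
        return min(
            prealigned,
            key=lambda t: (self.node_path_distance(taxid, t), self.canonical_id(t)),
        )


def load_taxonomy(nodes_source, names_source, merged_source=None) -> TaxonomyTree:
    """Build a TaxonomyTree from nodes.dmp / names.dmp (optional merged.dmp).

    The scientific name is preferred among multiple name classes; ids without
    any name get the placeholder ``taxid:<id>``.  Duplicate node lines with
    identical content are silently merged; conflicting duplicates keep the
    last occurrence with a warning.
    """
    raw: dict[int, tuple[int, str]] = {}
    for fields in _iter_dmp_rows(nodes_source):
        if len(fields) < 3:
            raise TaxonomyError(f"malformed nodes line: {fields!r}")
        taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
        if taxid in raw and raw[taxid] != (parent, rank):
            warnings.warn(
                f"conflicting duplicate node lines for taxon {taxid}; "
                "keeping the last one",
                stacklevel=2,
            )
        raw[taxid] = (parent, rank)

    names: dict[int, str] = {}
    fallback: dict[int, str] = {}
    for fields in _iter_dmp_rows(names_source):
        if len(fields) < 2:
            continue
        taxid, name = int(fields[0]), fields[1]
        name_class = fields[3] if len(fields) > 3 else ""
        if name_class == "scientific name":
            names[taxid] = name
        else:
            fallback.setdefault(taxid, name)

    nodes = {
        taxid: TaxNode(
            taxid, parent, rank,
            names.get(taxid) or fallback.get(taxid) or f"taxid:{taxid}",
        )
        for taxid, (parent, rank) in raw.items()
    }
    roots = [t for t, n in nodes.items() if n.parent == t]
    if len(roots) != 1:
        raise TaxonomyError(f"expected exactly one root, found {roots}")

    merged = None
    if merged_source is not None:
        merged = {}
        for fields in _iter_dmp_rows(merged_source):
            if len(fields) >= 2:
                merged[int(fields[0])] = int(fields[1])
    return TaxonomyTree(nodes, roots[0], merged)


# Functional aliases mirroring the operation names used elsewhere.

def lineage_at_level(tree: TaxonomyTree, taxid: int, level: str) -> int | None:
    return tree.lineage_at_level(taxid, level)


def node_path_distance(tree: TaxonomyTree, a: int, b: int) -> int:
    return tree.node_path_distance(a, b)


def closest_prealigned_taxon(tree: TaxonomyTree, taxid: int,
                             prealigned: set[int]) -> int:
    return tree.closest_prealigned_taxon(taxid, prealigned)
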