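"""Alignment and tree I/O plus the tree-set harmonization used before
landscape analysis.

Alignments are FASTA; trees are Newick (branch lengths after ``:``,
internal-node labels read as support values, quoted labels allowed).
Trees are represented as :class:`dendropy.Tree` objects throughout the
package; the helpers here add the label-set / bipartition views the
downstream statistics operate on.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

__all__ = [
    "MultipleAlignment",
    "PhyloTree",
    "TreeCollection",
    "MalformedAlignmentError",
    "DuplicateTaxonError",
    "MissingOutgroupError",
    "read_alignments",
    "read_alignment",
    "write_alignment",
    "read_trees",
    "write_trees",
    "parse_newick",
    "to_newick",
    "harmonize_trees",
    "leaf_labels",
    "bipartitions",
    "rooted_clades",
    "topo_leaf_distances",
    "clone_tree",
]

PhyloTree = dendropy.Tree

#: dataset / method codes used across the pipeline
DATASETS = ("ncCDS", "ncINT", "ncGD", "plCDS")
METHODS = ("Cpa", "Cun", "As", "Abs", "AUFbs")

CLASS_TAGS = ("CDS", "INT", "PL")

# nucleotide byte codes used internally: ACGT -> 0..3, anything missing -> 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
MISSING_CODE = 4


class MalformedAlignmentError(ValueError):
    """Rows of a FASTA alignment have unequal lengths."""


class DuplicateTaxonError(ValueError):
    """An alignment contains the same taxon label twice."""


class MissingOutgroupError(ValueError):
    """The requested root taxon is absent from a tree."""


@dataclass
class MultipleAlignment:
    """One locus: a taxa-by-sites character matrix over ``{A,C,G,T,-,N}``.

    ``matrix`` is a 2-D ``numpy`` array of single-byte characters
    (dtype ``S1``), one row per taxon, uppercase.  Ambiguity codes other
    than ``N`` are collapsed to ``N`` on construction; ``-`` and ``N``
    are both treated as missing by every downstream statistic.
    """

    locus_id: str
    class_tag: str
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2:
            raise MalformedAlignmentError(
                f"{self.locus_id}: matrix must be 2-D (taxa x sites)"
            )
        if len(self.taxa) != self.matrix.shape[0]:
            raise MalformedAlignmentError(
                f"{self.locus_id}: {len(self.taxa)} labels for "
                f"{self.matrix.shape[0]} rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise DuplicateTaxonError(f"{self.locus_id}: duplicate taxon labels")
        if self.matrix.shape[1] < 1:
            raise MalformedAlignmentError(f"{self.locus_id}: empty alignment")
        # normalize: uppercase, ambiguity -> N
        up = np.char.upper(self.matrix)
        keep = np.isin(up, np.array([b"A", b"C", b"G", b"T", b"-", b"N"]))
        up[~keep] = b"N"
        self.matrix = up

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def codes(self) -> np.ndarray:
        """uint8 code matrix: A,C,G,T -> 0..3, gap/N -> 4."""
        return _CODE[self.matrix.view(np.uint8)]

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    def subset(self, taxa: Sequence[str]) -> "MultipleAlignment":
        idx = [self.taxa.index(t) for t in taxa]
        return MultipleAlignment(
            self.locus_id, self.class_tag, list(taxa), self.matrix[idx]
        )


@dataclass
class TreeCollection:
    """The labelled species trees keyed by ``(dataset, method)``."""

    entries: dict[tuple[str, str], PhyloTree] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.items())

    def add(self, dataset: str, method: str, tree: PhyloTree) -> None:
        key = (dataset, method)
        if key in self.entries:
            raise KeyError(f"duplicate tree key {key}")
        self.entries[key] = tree

    def get(self, dataset: str, method: str) -> PhyloTree:
        return self.entries[(dataset, method)]

    def keys(self):
        return self.entries.keys()

    def trees(self) -> list[PhyloTree]:
        return list(self.entries.values())


# ---------------------------------------------------------------------------
# alignment I/O


def read_alignment(path: str | os.PathLike, class_tag: str,
                   locus_id: str | None = None) -> MultipleAlignment:
    """Read one aligned FASTA file into a :class:`MultipleAlignment`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MalformedAlignmentError(f"{path}: no sequences")
    labels = [r.id for r in records]
    if len(set(labels)) != len(labels):
        raise DuplicateTaxonError(f"{path}: duplicate taxon labels")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise MalformedAlignmentError(
            f"{path}: unequal sequence lengths {sorted(lengths)}"
        )
    mat = np.array([list(str(r.seq)) for r in records], dtype="S1")
    if locus_id is None:
        locus_id = os.path.splitext(os.path.basename(str(path)))[0]
    return MultipleAlignment(locus_id, class_tag, labels, mat)


def read_alignments(paths: Iterable[str | os.PathLike],
                    class_tag: str) -> list[MultipleAlignment]:
    """Read several per-locus FASTA alignments sharing one locus class."""
    return [read_alignment(p, class_tag) for p in paths]


def write_alignment(aln: MultipleAlignment, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for label, row in zip(aln.taxa, aln.matrix):
            fh.write(f">{label}\n{row.tobytes().decode('ascii')}\n")


# ---------------------------------------------------------------------------
# tree I/O


def parse_newick(text: str, rooted: bool | None = None) -> PhyloTree:
    """Parse a single Newick string.

    Internal-node labels are kept on ``node.label`` and interpreted as
    support values by downstream reports.
    """
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if rooted is not None:
        tree.is_rooted = rooted
    elif tree.is_rooted is None:
        # two-child seed node reads naturally as a rooted tree
        tree.is_rooted = len(tree.seed_node.child_nodes()) == 2
    return tree


def to_newick(tree: PhyloTree, *, include_lengths: bool = True,
              include_support: bool = True) -> str:
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_edge_lengths=not include_lengths,
        suppress_internal_node_labels=not include_support,
        unquoted_underscores=True,
    ).strip()
    return s


def read_trees(path: str | os.PathLike) -> list[PhyloTree]:
    """Read a multi-Newick file, one tree per line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def write_trees(trees: Iterable[PhyloTree], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(to_newick(t) + "\n")


def clone_tree(tree: PhyloTree) -> PhyloTree:
    return tree.clone(depth=1)


# ---------------------------------------------------------------------------
# structural views


def leaf_labels(tree: PhyloTree) -> frozenset[str]:
    return frozenset(l.taxon.label for l in tree.leaf_node_iter())


def _leafsets_below(tree: PhyloTree) -> dict:
    below = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = frozenset([nd.taxon.label])
        else:
            s = frozenset()
            for c in nd.child_nodes():
                s = s | below[c]
            below[nd] = s
    return below


def bipartitions(tree: PhyloTree) -> set[frozenset[frozenset]]:
    """Non-trivial bipartitions of the tree read as unrooted.

    Each split is a frozenset of the two leaf-label sides, so rooted and
    unrooted encodings of the same topology compare equal.
    """
    below = _leafsets_below(tree)
    all_leaves = below[tree.seed_node]
    splits = set()
    for nd in tree.postorder_node_iter():
        if nd.is_leaf() or nd is tree.seed_node:
            continue
        side = below[nd]
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset([side, other]))
    return splits


def rooted_clades(tree: PhyloTree) -> set[frozenset[str]]:
    """Leaf sets of all internal nodes of a rooted tree (root excluded)."""
    below = _leafsets_below(tree)
    return {
        below[nd]
        for nd in tree.postorder_node_iter()
        if not nd.is_leaf() and nd is not tree.seed_node
    }


def topo_leaf_distances(tree: PhyloTree, taxa: Sequence[str],
                        use_lengths: bool = False) -> np.ndarray:
    """Pairwise leaf-to-leaf path lengths (edge counts or branch lengths).

    Path edge counts form a tree metric with unit edge lengths, which the
    quartet machinery uses to read induced quartet topologies off the
    four-point condition.
    """
    nodes = list(tree.preorder_node_iter())
    index = {nd: i for i, nd in enumerate(nodes)}
    adj: list[list[tuple[int, float]]] = [[] for _ in nodes]
    for nd in nodes:
        p = nd.parent_node
        if p is not None:
            w = (nd.edge.length or 0.0) if use_lengths else 1.0
            adj[index[p]].append((index[nd], w))
            adj[index[nd]].append((index[p], w))
    leaf_idx = {}
    for l in tree.leaf_node_iter():
        leaf_idx[l.taxon.label] = index[l]
    n = len(taxa)
    D = np.zeros((n, n))
    for a, ta in enumerate(taxa):
        start = leaf_idx[ta]
        dist = np.full(len(nodes), np.inf)
        dist[start] = 0.0
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if dist[u] + w < dist[v]:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for b, tb in enumerate(taxa):
            D[a, b] = dist[leaf_idx[tb]]
    return D


# ---------------------------------------------------------------------------
# harmonization


def harmonize_trees(trees: Sequence[PhyloTree], drop: Iterable[str] = (),
                    root_on: str | None = None) -> list[PhyloTree]:
    """Prune a drop list from every tree and root each on one outgroup.

    Mirrors the usual pre-treespace clean-up: drop tips so that all trees
    share one leaf set, then place the root on the outgroup's pendant
    edge.  Degree-2 nodes created by pruning are suppressed with their
    branch lengths summed.
    """
    drop = set(drop)
    out = []
    for t in trees:
        t = clone_tree(t)
        labels = leaf_labels(t)
        if root_on is not None and root_on not in labels:
            raise MissingOutgroupError(f"outgroup {root_on!r} absent from tree")
        if drop >= labels:
            raise ValueError("drop list covers all leaves")
        present = drop & labels
        if present:
            t.prune_taxa_with_labels(sorted(present))
        if root_on is not None:
            t.is_rooted = True
            leaf = next(
                l for l in t.leaf_node_iter() if l.taxon.label == root_on
            )
            if leaf.parent_node is not t.seed_node or \
                    len(t.seed_node.child_nodes()) != 2:
                e = leaf.edge
                half = (e.length / 2.0) if e.length is not None else None
                t.reroot_at_edge(e, length1=half, length2=half,
                                 update_bipartitions=False)
        out.append(t)
    sets = {leaf_labels(t) for t in out}
    if len(sets) != 1:
        raise ValueError(
            "trees do not share a common leaf set after harmonization; "
            "extend the drop list"
        )
    return out
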