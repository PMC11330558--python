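"""Rooted time-scaled phylogenies with fossil (non-contemporaneous) tips.

Trees are stored as flat parent-pointer arrays, which keeps the covariance
and regime-painting machinery simple and fast.  Branch lengths are in Myr;
node ages are in Ma before present.  By default the youngest tip anchors
age 0; an explicit ``root_age_ma`` places the tree on an absolute age axis
(required whenever environmental curves are involved).

Reading and writing of Newick/NEXUS goes through :mod:`dendropy`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TreeSet",
    "RegimeMap",
    "TreeValidationError",
    "read_trees",
    "write_trees",
    "prune_to_taxa",
    "bm_covariance",
]


class TreeValidationError(ValueError):
    """Raised when a tree violates the structural invariants."""


class Phylogeny:
    """A rooted binary-or-multifurcating tree with strictly positive branch lengths.

    Parameters
    ----------
    parent
        Integer array of length ``n_nodes``; ``parent[i]`` is the index of
        node *i*'s parent, ``-1`` for the single root.
    length
        Branch length (Myr) of the edge above each node; ``nan`` for the root.
    labels
        Sequence of tip labels (strings) or ``None`` for internal nodes.
    root_age_ma
        Optional absolute age of the root (Ma).  Defaults to the root-to-
        youngest-tip distance, i.e. the youngest tip sits at age 0.
    """

    def __init__(self, parent, length, labels, root_age_ma: float | None = None):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.labels = list(labels)
        n = self.parent.size
        if self.length.size != n or len(self.labels) != n:
            raise TreeValidationError("parent/length/labels size mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeValidationError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                p = int(self.parent[i])
                if not (0 <= p < n):
                    raise TreeValidationError(f"node {i} has invalid parent {p}")
                self.children[p].append(i)
        bad = [
            i
            for i in range(n)
            if i != self.root and not (np.isfinite(self.length[i]) and self.length[i] > 0)
        ]
        if bad:
            raise TreeValidationError(
                "non-positive or missing branch length on edges above nodes "
                f"{bad[:10]} (lengths {[float(self.length[i]) for i in bad[:10]]})"
            )
        self.tips = [i for i in range(n) if not self.children[i]]
        tip_labels = [self.labels[i] for i in self.tips]
        if any(lb is None for lb in tip_labels):
            raise TreeValidationError("every tip must carry a label")
        if len(set(tip_labels)) != len(tip_labels):
            dup = sorted({lb for lb in tip_labels if tip_labels.count(lb) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dup}")
        # depth = time from the root, in Myr
        self.depth = np.zeros(n)
        for i in self.preorder():
            if i != self.root:
                self.depth[i] = self.depth[self.parent[i]] + self.length[i]
        if root_age_ma is None:
            root_age_ma = float(self.depth[self.tips].max())
        self.root_age_ma = float(root_age_ma)
        self._cache: dict[str, np.ndarray] = {}

    # ------------------------------------------------------------------ basics
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips]

    @property
    def node_age(self) -> np.ndarray:
        """Age (Ma before present) of every node."""
        return self.root_age_ma - self.depth

    @property
    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths, ordered like :attr:`tips`."""
        return self.depth[self.tips]

    def preorder(self) -> list[int]:
        order = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def postorder(self) -> list[int]:
        return self.preorder()[::-1]

    def tip_index(self) -> dict[str, int]:
        """Map tip label -> position in the tip ordering."""
        return {self.labels[t]: k for k, t in enumerate(self.tips)}

    def descendant_tips(self) -> list[list[int]]:
        """Per node, the tip positions (into :attr:`tips`) below it."""
        tip_pos = {t: k for k, t in enumerate(self.tips)}
        desc: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in self.postorder():
            if not self.children[v]:
                desc[v] = [tip_pos[v]]
            else:
                acc: list[int] = []
                for c in self.children[v]:
                    acc.extend(desc[c])
                desc[v] = acc
        return desc

    def mrca_matrix(self) -> np.ndarray:
        """(n_tips, n_tips) matrix of MRCA node indices."""
        if "mrca" not in self._cache:
            n = self.n_tips
            M = np.zeros((n, n), dtype=np.int64)
            desc = self.descendant_tips()
            for v in self.preorder():
                kids = self.children[v]
                if not kids:
                    M[desc[v][0], desc[v][0]] = v
                    continue
                for a in range(len(kids)):
                    ia = np.asarray(desc[kids[a]])
                    for b in range(a + 1, len(kids)):
                        ib = np.asarray(desc[kids[b]])
                        M[np.ix_(ia, ib)] = v
                        M[np.ix_(ib, ia)] = v
            self._cache["mrca"] = M
        return self._cache["mrca"]

    def shared_path_matrix(self) -> np.ndarray:
        """(n_tips, n_tips) matrix of root-to-MRCA path lengths (Myr)."""
        return self.depth[self.mrca_matrix()]

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        d = self.tip_depths
        return float(d.max() - d.min()) <= rel_tol * max(1.0, float(d.max()))

    def total_length(self) -> float:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return float(self.length[mask].sum())

    def branch_age_interval(self, node: int) -> tuple[float, float]:
        """(older age, younger age) in Ma of the edge above ``node``."""
        young = self.root_age_ma - self.depth[node]
        return float(young + self.length[node]), float(young)

    # ------------------------------------------------------------ conversions
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, root_age_ma: float | None = None) -> "Phylogeny":
        nodes = list(dtree.preorder_node_iter())
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        length = np.full(len(nodes), np.nan)
        labels: list[str | None] = [None] * len(nodes)
        for nd in nodes:
            i = idx[id(nd)]
            if nd.parent_node is not None:
                parent[i] = idx[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise TreeValidationError("every non-root edge needs a branch length")
                length[i] = float(nd.edge.length)
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise TreeValidationError("unlabelled tip")
                labels[i] = str(nd.taxon.label)
        return cls(parent, length, labels, root_age_ma=root_age_ma)

    @classmethod
    def from_newick(cls, newick: str, root_age_ma: float | None = None) -> "Phylogeny":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True, rooting="default-rooted"
        )
        return cls.from_dendropy(dtree, root_age_ma=root_age_ma)

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if not self.children[v]:
                s = _quote(self.labels[v])
            else:
                s = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v != self.root:
                s += f":{float(self.length[v])!r}"
            return s

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Phylogeny {self.n_tips} tips, root age {self.root_age_ma:.2f} Ma>"


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class TreeSet:
    """An ordered collection of posterior trees plus an optional MCC tree."""

    trees: list[Phylogeny]
    mcc: Phylogeny | None = None

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> Phylogeny:
        return self.trees[i]


@dataclass
class RegimeMap:
    """A piecewise-constant regime painting along a tree's branches.

    ``segments[i]`` is the ordered (rootward -> tipward) list of
    ``(length_myr, regime)`` pairs for the edge above node *i* (empty for the
    root).  ``node_regime[i]`` is the regime at node *i* itself.
    """

    tree: Phylogeny
    segments: list[list[tuple[float, str]]]
    node_regime: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.node_regime:
            self.node_regime = [""] * self.tree.n_nodes
            for v in self.tree.preorder():
                if v == self.tree.root:
                    # root regime = first segment regime of any child
                    for c in self.tree.children[v]:
                        if self.segments[c]:
                            self.node_regime[v] = self.segments[c][0][1]
                            break
                else:
                    self.node_regime[v] = self.segments[v][-1][1]

    def validate(self, tol: float = 1e-9) -> None:
        t = self.tree
        for i in range(t.n_nodes):
            if i == t.root:
                continue
            total = sum(L for L, _ in self.segments[i])
            if abs(total - t.length[i]) > tol * max(1.0, t.length[i]):
                raise ValueError(
                    f"segments on edge above node {i} sum to {total}, expected {t.length[i]}"
                )

    def regimes(self) -> list[str]:
        out: set[str] = set()
        for segs in self.segments:
            out.update(r for _, r in segs)
        return sorted(out)

    def n_transitions(self) -> int:
        n = 0
        for segs in self.segments:
            n += max(0, len(segs) - 1)
        return n

    def relabel(self, mapping: dict[str, str]) -> "RegimeMap":
        """Relabel regimes, merging adjacent segments that coincide."""
        segs_out: list[list[tuple[float, str]]] = []
        for segs in self.segments:
            merged: list[tuple[float, str]] = []
            for L, r in segs:
                r2 = mapping.get(r, r)
                if merged and merged[-1][1] == r2:
                    merged[-1] = (merged[-1][0] + L, r2)
                else:
                    merged.append((L, r2))
            segs_out.append(merged)
        node = [mapping.get(r, r) for r in self.node_regime]
        return RegimeMap(self.tree, segs_out, node)

    def dwell_times(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for segs in self.segments:
            for L, r in segs:
                out[r] = out.get(r, 0.0) + L
        return out

    def to_table(self):
        """Segment table as a pandas DataFrame (node, index, length, regime)."""
        import pandas as pd

        rows = []
        for i, segs in enumerate(self.segments):
            for k, (L, r) in enumerate(segs):
                rows.append({"node": i, "segment": k, "length_myr": L, "regime": r})
        return pd.DataFrame(rows)

    def to_simmap_newick(self) -> str:
        """Newick with per-branch regime annotations in braces,
        ``{regime,length:...}`` segments listed rootward -> tipward."""
        t = self.tree

        def rec(v: int) -> str:
            if not t.children[v]:
                s = _quote(t.labels[v])
            else:
                s = "(" + ",".join(rec(c) for c in t.children[v]) + ")"
            if v != t.root:
                ann = ":".join(f"{r},{L!r}" for L, r in self.segments[v])
                s += ":{" + ann + "}"
            return s

        return rec(t.root) + ";"


# ---------------------------------------------------------------------- I/O


def read_trees(path, format: str = "newick", root_age_ma: float | None = None) -> TreeSet:
    """Read one or more trees from a Newick or NEXUS file.

    NEXUS translate tables are resolved; branch lengths are kept at full
    precision.  Raises on duplicate tip labels or non-positive branch lengths.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}; use 'newick' or 'nexus'")
    tl = dendropy.TreeList.get(
        path=str(path), schema=format, preserve_underscores=True, rooting="default-rooted"
    )
    if not len(tl):
        raise ValueError(f"no trees found in {path}")
    trees = [Phylogeny.from_dendropy(t, root_age_ma=root_age_ma) for t in tl]
    return TreeSet(trees=trees)


def write_trees(treeset: TreeSet | list[Phylogeny], path) -> None:
    trees = treeset.trees if isinstance(treeset, TreeSet) else list(treeset)
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


# ------------------------------------------------------------------- pruning


def prune_to_taxa(tree: Phylogeny, keep) -> Phylogeny:
    """Prune a tree down to the tips in ``keep``.

    Path lengths between every pair of kept tips are preserved exactly;
    unary internal nodes created by the pruning are suppressed with their
    branch lengths summed.
    """
    keep = set(keep)
    have = set(tree.tip_labels)
    missing = sorted(keep - have)
    if missing:
        raise KeyError(f"taxa not in tree: {missing}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to keep")

    n = tree.n_nodes
    keep_node = np.zeros(n, dtype=bool)
    for t in tree.tips:
        if tree.labels[t] in keep:
            keep_node[t] = True
    for v in tree.postorder():
        if tree.children[v]:
            keep_node[v] = any(keep_node[c] for c in tree.children[v])

    # Rebuild: walk from the retained root, collapsing unary chains.
    def surviving_children(v: int) -> list[int]:
        return [c for c in tree.children[v] if keep_node[c]]

    root = tree.root
    while True:
        sc = surviving_children(root)
        if len(sc) == 1 and tree.children[root]:
            root = sc[0]
        else:
            break

    parent_out: list[int] = []
    length_out: list[float] = []
    labels_out: list[str | None] = []

    def build(v: int, parent_idx: int, acc_len: float) -> None:
        sc = surviving_children(v)
        while len(sc) == 1:
            c = sc[0]
            acc_len += float(tree.length[c])
            v = c
            sc = surviving_children(v)
        idx = len(parent_out)
        parent_out.append(parent_idx)
        length_out.append(acc_len if parent_idx >= 0 else np.nan)
        labels_out.append(tree.labels[v] if not sc else None)
        for c in sc:
            build(c, idx, float(tree.length[c]))

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * n + 100))
    try:
        build(root, -1, 0.0)
    finally:
        sys.setrecursionlimit(old_limit)
    return Phylogeny(parent_out, length_out, labels_out)


def bm_covariance(tree: Phylogeny) -> np.ndarray:
    """Brownian-motion covariance structure: shared root-to-MRCA path lengths.

    Entry (i, j) is the length of history shared by tips i and j (diagonal =
    root-to-tip distances, unequal for fossil tips).  Tips are ordered as in
    ``tree.tip_labels``.
    """
    return tree.shared_path_matrix()
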