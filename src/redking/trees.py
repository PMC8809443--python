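"""Unrooted two-clade trees with a basal trifurcation.

The study design compares a lichenized and a non-lichenized clade joined,
together with an outgroup tip, at a basal trifurcation (the unrooted
representation of the constrained species topology).  ``CladeTree`` stores
the topology in indexed arrays convenient for pruning-algorithm likelihood
code, plus a tip -> clade map.  Newick I/O goes through dendropy; PAML-style
``#k`` branch labels in tip or internal-node labels are recognized and
stripped into the branch-label map.
"""

from __future__ import annotations

import re
from typing import Iterable

import dendropy
import numpy as np

LICHENIZED = "lichenized"
NON_LICHENIZED = "non_lichenized"
OUTGROUP = "outgroup"
CLADES = (LICHENIZED, NON_LICHENIZED, OUTGROUP)


class TreeStructureError(ValueError):
    """Topology violates the two-clade design contract."""


_LABEL_TAG = re.compile(r"(?:\s*#\s*|_HASH_)(\d+)\s*$")
_RAW_TAG = re.compile(r"\s*#\s*(\d+)")


class CladeTree:
    """Indexed unrooted tree rooted for computation at the basal trifurcation.

    Nodes are indexed 0..n_nodes-1 with tips first (0..n_tips-1, in
    ``tip_labels`` order).  ``parent[i]`` is the parent index (-1 for the
    basal node) and ``branch_lengths[i]`` the length of the edge above node
    i (0 for the basal node; every other node carries exactly one edge).
    """

    def __init__(
        self,
        parent: np.ndarray,
        branch_lengths: np.ndarray,
        tip_labels: list[str],
        clade_map: dict[str, str],
        branch_labels: dict[int, int] | None = None,
    ):
        self.parent = np.asarray(parent, dtype=int)
        self.branch_lengths = np.asarray(branch_lengths, dtype=float)
        self.tip_labels = list(tip_labels)
        self.clade_map = dict(clade_map)
        self.branch_labels = dict(branch_labels or {})
        self._validate()

    # -- construction ----------------------------------------------------

    def _validate(self):
        n = len(self.parent)
        if len(self.branch_lengths) != n:
            raise TreeStructureError("parent/branch_lengths length mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeStructureError("exactly one basal node required")
        self.root = int(roots[0])
        if np.any(self.branch_lengths < 0):
            raise TreeStructureError("negative branch length")
        missing = [t for t in self.tip_labels if t not in self.clade_map]
        if missing:
            raise TreeStructureError(f"tips without clade assignment: {missing}")
        bad = {c for c in self.clade_map.values()} - set(CLADES)
        if bad:
            raise TreeStructureError(f"unknown clade labels: {sorted(bad)}")
        children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                children[p].append(i)
        self.children = children
        if len(children[self.root]) < 3:
            raise TreeStructureError("basal node must be a trifurcation (unrooted tree)")
        order = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(children[v])
        self.preorder = order
        self.postorder = order[::-1]
        # descendant tip sets per node
        self._tipsets: list[frozenset[int]] = [frozenset()] * n
        for v in self.postorder:
            if not children[v]:
                self._tipsets[v] = frozenset([v])
            else:
                s: set[int] = set()
                for c in children[v]:
                    s |= self._tipsets[c]
                self._tipsets[v] = frozenset(s)
        for clade in (LICHENIZED, NON_LICHENIZED):
            tips = self.clade_tip_indices(clade)
            if tips and not self._is_monophyletic(tips):
                raise TreeStructureError(f"clade {clade!r} is not monophyletic")

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def edges(self) -> list[int]:
        """Indices of nodes that carry an edge (everything but the root)."""
        return [i for i in range(self.n_nodes) if i != self.root]

    def clade_tip_indices(self, clade: str) -> list[int]:
        return [i for i, t in enumerate(self.tip_labels) if self.clade_map[t] == clade]

    def _is_monophyletic(self, tips: Iterable[int]) -> bool:
        want = frozenset(tips)
        return any(self._tipsets[v] == want for v in range(self.n_nodes))

    def mrca(self, tips: Iterable[int]) -> int:
        """Most recent common ancestor relative to the basal trifurcation."""
        want = frozenset(tips)
        best, best_size = None, None
        for v in range(self.n_nodes):
            s = self._tipsets[v]
            if want <= s and (best_size is None or len(s) < best_size):
                best, best_size = v, len(s)
        assert best is not None
        return best

    def path_to_ancestor(self, tip: int, ancestor: int) -> float:
        """Sum of branch lengths on the path tip -> ancestor."""
        total, v = 0.0, tip
        while v != ancestor:
            if v == self.root:
                raise TreeStructureError("ancestor not on path to basal node")
            total += self.branch_lengths[v]
            v = int(self.parent[v])
        return total

    def clade_edges(self, clade: str, include_stem: bool = True) -> list[int]:
        """Edges whose subtree consists exactly of the clade's tips.

        With ``include_stem`` the edge leading into the clade's attachment
        point is included, so the three clade edge sets partition all edges
        of the two-clade design.
        """
        want = set(self.clade_tip_indices(clade))
        out = []
        for v in self.edges:
            s = self._tipsets[v]
            if s <= want:
                if not include_stem and s == want and len(want) > 1:
                    continue
                out.append(v)
        return out

    def edge_clades(self) -> dict[int, str]:
        """Clade assignment of every edge (subtree membership)."""
        out: dict[int, str] = {}
        for clade in CLADES:
            for e in self.clade_edges(clade, include_stem=True):
                out[e] = clade
        return out

    def with_branch_lengths(self, lengths: np.ndarray) -> "CladeTree":
        t = CladeTree(
            self.parent.copy(), np.asarray(lengths, float),
            self.tip_labels, self.clade_map, self.branch_labels,
        )
        return t

    def copy(self) -> "CladeTree":
        return self.with_branch_lengths(self.branch_lengths.copy())

    # -- Newick I/O -------------------------------------------------------

    def to_newick(self) -> str:
        def render(v: int) -> str:
            if not self.children[v]:
                s = self.tip_labels[v]
            else:
                s = "(" + ",".join(render(c) for c in self.children[v]) + ")"
            if v in self.branch_labels:
                s += f" #{self.branch_labels[v]}"
            if v != self.root:
                s += f":{self.branch_lengths[v]:.10g}"
            return s

        return render(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str, clade_map: dict[str, str]) -> "CladeTree":
        # PAML-style "#k" branch labels are not valid newick tokens; fold
        # them into the node label before parsing
        newick = _RAW_TAG.sub(r"_HASH_\1", newick)
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=False, preserve_underscores=True,
        )
        seed = tree.seed_node
        # index tips first, then internal nodes in preorder
        tips = [lf for lf in tree.leaf_node_iter()]
        labels = []
        branch_labels: dict[int, int] = {}
        for lf in tips:
            raw = lf.taxon.label if lf.taxon else (lf.label or "")
            m = _LABEL_TAG.search(raw)
            if m:
                raw = raw[: m.start()]
            labels.append(raw.strip())
        index = {id(lf): i for i, lf in enumerate(tips)}
        nxt = len(tips)
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            index[id(nd)] = nxt
            nxt += 1
        n = nxt
        parent = np.full(n, -1, dtype=int)
        blens = np.zeros(n)
        for nd in tree.preorder_node_iter():
            i = index[id(nd)]
            label = None
            raw = (nd.taxon.label if nd.taxon else None) or nd.label or ""
            m = _LABEL_TAG.search(raw) if raw else None
            if m:
                branch_labels[i] = int(m.group(1))
            if nd is not seed:
                parent[i] = index[id(nd.parent_node)]
                blens[i] = nd.edge.length if nd.edge.length is not None else 0.0
        return cls(parent, blens, labels, clade_map, branch_labels)
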