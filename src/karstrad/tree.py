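"""Time-calibrated tree container and chronological utilities.

Every analysis in this package runs on an ultrametric, rooted, binary
chronogram with branch lengths in millions of years (My).  :class:`TimeTree`
wraps a :mod:`dendropy` tree, validates those invariants once at
construction, and exposes the quantities the downstream modules consume:
node ages measured backward from the present (tips at age 0), branching
times, lineage counts through time, clade extraction and the phylogenetic
(shared path length) covariance matrix.
"""

from __future__ import annotations

import io
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple
import warnings

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "TimeTree",
    "branching_times",
    "lineages_at_time",
    "extract_clade",
    "validate_clades",
]


class TreeError(ValueError):
    """Raised when a tree violates the chronogram invariants."""


def _resolve_polytomies(tree: dendropy.Tree) -> bool:
    """Resolve polytomies to zero-length binary splits, deterministically.

    Children are combined pairwise in lexicographic order of their smallest
    descendant tip label.  Returns True if any polytomy was resolved.
    """
    resolved = False
    # smallest descendant label per node, for deterministic ordering
    minlab: Dict[int, str] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            minlab[id(nd)] = nd.taxon.label if nd.taxon else ""
        else:
            minlab[id(nd)] = min(minlab[id(c)] for c in nd.child_nodes())
    for nd in list(tree.preorder_node_iter()):
        children = nd.child_nodes()
        while len(children) > 2:
            resolved = True
            children = sorted(children, key=lambda c: minlab[id(c)])
            a, b = children[0], children[1]
            nd.remove_child(a)
            nd.remove_child(b)
            new = dendropy.Node(edge_length=0.0)
            new.add_child(a)
            new.add_child(b)
            nd.add_child(new)
            minlab[id(new)] = min(minlab[id(a)], minlab[id(b)])
            children = nd.child_nodes()
    return resolved


class TimeTree:
    """Rooted, binary, ultrametric chronogram (branch lengths in My).

    Parameters
    ----------
    tree
        A dendropy tree with branch lengths.  It is cloned, polytomies are
        resolved (with a warning) and the invariants are checked.
    ultrametric_tol
        Relative tolerance on tip-age deviation: the maximum deviation of a
        tip from age zero may not exceed ``ultrametric_tol`` times the tree
        height.
    """

    def __init__(self, tree: dendropy.Tree, ultrametric_tol: float = 1e-6):
        tree = tree.clone(depth=1)
        tree.is_rooted = True
        tree.suppress_unifurcations()
        if _resolve_polytomies(tree):
            warnings.warn("polytomies resolved to zero-length binary splits")
        self._tree = tree
        self._index(ultrametric_tol)

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str, **kw) -> "TimeTree":
        return cls(_parse(text, "newick"), **kw)

    @classmethod
    def from_string(cls, text: str, **kw) -> "TimeTree":
        """Parse Newick or Nexus text (auto-detected)."""
        schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
        return cls(_parse(text, schema), **kw)

    @classmethod
    def from_file(cls, path: str, **kw) -> "TimeTree":
        with open(path) as fh:
            return cls.from_string(fh.read(), **kw)

    # ------------------------------------------------------------------
    # indexing & invariants
    # ------------------------------------------------------------------
    def _index(self, tol: float) -> None:
        tree = self._tree
        labels = [lf.taxon.label if lf.taxon else None for lf in tree.leaf_node_iter()]
        if any(l is None for l in labels):
            raise TreeError("unlabelled tip")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        if len(labels) < 2:
            raise TreeError("tree must have at least 2 tips")

        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None and nd.edge_length is None:
                raise TreeError("missing branch length")
            if nd.parent_node is not None and nd.edge_length < 0:
                raise TreeError("negative branch length")

        # depths from root, then ages backward from the present
        depth: Dict[int, float] = {}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                depth[id(nd)] = 0.0
            else:
                depth[id(nd)] = depth[id(nd.parent_node)] + nd.edge_length
        height = max(depth[id(lf)] for lf in tree.leaf_node_iter())
        if height <= 0:
            raise TreeError("tree height must be positive")
        worst = max(abs(height - depth[id(lf)]) for lf in tree.leaf_node_iter())
        if worst > tol * height:
            raise TreeError(
                f"tree is not ultrametric: max tip-age deviation {worst:.3g} "
                f"exceeds {tol:g} x height ({height:.6g})"
            )
        for nd in tree.preorder_node_iter():
            nd.age_my = 0.0 if nd.is_leaf() else height - depth[id(nd)]
        self._height = float(height)
        self._tips = sorted(labels)
        # postorder node list; tips first occurrence order is postorder order
        self._postorder: List[dendropy.Node] = list(tree.postorder_node_iter())
        for i, nd in enumerate(self._postorder):
            nd.index = i

    # ------------------------------------------------------------------
    # basic properties
    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def tip_labels(self) -> List[str]:
        """Tip labels, sorted."""
        return list(self._tips)

    @property
    def crown_age(self) -> float:
        """Age of the root node (tree height), in My."""
        return self._height

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    def nodes(self, order: str = "postorder") -> List[dendropy.Node]:
        if order == "postorder":
            return list(self._postorder)
        if order == "preorder":
            return list(self._tree.preorder_node_iter())
        raise ValueError(order)

    def leaves(self) -> List[dendropy.Node]:
        return [nd for nd in self._postorder if nd.is_leaf()]

    def total_edge_length(self) -> float:
        return float(
            sum(nd.edge_length for nd in self._postorder if nd.parent_node is not None)
        )

    def edges(self) -> List[Tuple[dendropy.Node, float, float]]:
        """All branches as (child node, child age, parent age)."""
        out = []
        for nd in self._postorder:
            if nd.parent_node is not None:
                out.append((nd, nd.age_my, nd.parent_node.age_my))
        return out

    # ------------------------------------------------------------------
    # chronology
    # ------------------------------------------------------------------
    def branching_times(self) -> np.ndarray:
        """Internal node ages (My), sorted descending; first = crown age."""
        ages = np.array(
            [nd.age_my for nd in self._postorder if not nd.is_leaf()], dtype=float
        )
        return np.sort(ages)[::-1]

    def lineages_at_time(self, t: float) -> int:
        """Number of ancestral lineages crossing age ``t``.

        Equals 2 just below the root and ``n_tips`` at the present (t=0).
        """
        if t < 0 or t > self.crown_age:
            raise TreeError(f"age {t} outside [0, crown age {self.crown_age}]")
        if t == self.crown_age:
            return 2
        bt = self.branching_times()
        # lineages after k-th branching event (ages >= t): 1 + number of
        # branching events strictly older than t, counting the root
        return int(1 + np.sum(bt > t))

    # ------------------------------------------------------------------
    # clades
    # ------------------------------------------------------------------
    def mrca(self, tips: Iterable[str]) -> dendropy.Node:
        tips = set(tips)
        missing = tips - set(self._tips)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        node = self._tree.mrca(taxon_labels=sorted(tips))
        return node

    def tipset(self, node: dendropy.Node) -> Set[str]:
        return {lf.taxon.label for lf in node.leaf_iter()}

    def extract_clade(self, tips: Iterable[str]) -> "TimeTree":
        """Subtree rooted at the MRCA of ``tips`` (must be monophyletic)."""
        tips = set(tips)
        node = self.mrca(tips)
        have = self.tipset(node)
        intruders = have - tips
        if intruders:
            raise TreeError(
                f"tip set is not monophyletic; intruding tips: {sorted(intruders)[:10]}"
            )
        sub = dendropy.Tree(seed_node=node.extract_subtree())
        return TimeTree(sub)

    def prune_to(self, tips: Iterable[str]) -> "TimeTree":
        """Tree restricted to ``tips`` (need not be monophyletic)."""
        tips = set(tips)
        missing = tips - set(self._tips)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        if len(tips) < 2:
            raise TreeError("need at least 2 tips")
        t = self._tree.clone(depth=1)
        t.retain_taxa_with_labels(sorted(tips))
        t.suppress_unifurcations()
        return TimeTree(t)

    # ------------------------------------------------------------------
    # covariance
    # ------------------------------------------------------------------
    def vcv(self, labels: Sequence[str] | None = None) -> Tuple[List[str], np.ndarray]:
        """Shared-path-length matrix C (My): C_ij = root-to-MRCA(i,j) path.

        Diagonal equals the crown age for an ultrametric tree.  This is the
        Brownian-motion covariance structure up to the rate factor.
        """
        labels = list(labels) if labels is not None else self.tip_labels
        pos = {l: i for i, l in enumerate(labels)}
        missing = set(labels) - set(self._tips)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        n = len(labels)
        C = np.zeros((n, n))
        below: Dict[int, List[int]] = {}
        for nd in self._postorder:
            if nd.is_leaf():
                lab = nd.taxon.label
                below[id(nd)] = [pos[lab]] if lab in pos else []
                if lab in pos:
                    C[pos[lab], pos[lab]] = self.crown_age
            else:
                kids = [below[id(c)] for c in nd.child_nodes()]
                share = self.crown_age - nd.age_my
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in kids[a]:
                            for j in kids[b]:
                                C[i, j] = C[j, i] = share
                below[id(nd)] = [i for k in kids for i in k]
        return labels, C

    # ------------------------------------------------------------------
    # output
    # ------------------------------------------------------------------
    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip() + ("\n" if not s.endswith("\n") else "")

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())

    def copy(self) -> "TimeTree":
        return TimeTree(self._tree)

    def __repr__(self) -> str:
        return f"<TimeTree n_tips={self.n_tips} crown_age={self.crown_age:.4g} My>"


def _parse(text: str, schema: str) -> dendropy.Tree:
    try:
        t = dendropy.Tree.get(
            data=text,
            schema=schema,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        t.is_rooted = True
        return t
    except Exception as exc:  # dendropy raises many flavours
        raise TreeError(f"could not parse tree: {exc}") from exc


# ----------------------------------------------------------------------
# functional wrappers
# ----------------------------------------------------------------------
def read_tree(source: str, **kw) -> TimeTree:
    """Read a tree from Newick/Nexus text or a file path."""
    if "(" in source or source.lstrip().upper().startswith("#NEXUS"):
        return TimeTree.from_string(source, **kw)
    return TimeTree.from_file(source, **kw)


def branching_times(tree: TimeTree) -> np.ndarray:
    return tree.branching_times()


def lineages_at_time(tree: TimeTree, t: float) -> int:
    return tree.lineages_at_time(t)


def extract_clade(tree: TimeTree, tips: Iterable[str]) -> TimeTree:
    return tree.extract_clade(tips)


def validate_clades(tree: TimeTree, clades: Mapping[str, Iterable[str]]) -> None:
    """Check that named clades are monophyletic and pairwise disjoint."""
    seen: Dict[str, str] = {}
    for name, tips in clades.items():
        tips = set(tips)
        for t in tips:
            if t in seen:
                raise TreeError(f"tip {t!r} in both {seen[t]!r} and {name!r}")
            seen[t] = name
        tree.extract_clade(tips)  # raises if not monophyletic
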