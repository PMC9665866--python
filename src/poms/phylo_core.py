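"""Rooted-phylogeny plumbing for balance-tree analysis.

Wraps a :class:`skbio.TreeNode` and exposes the operations the rest of the
package needs: stable node indexing, left/right tip bipartitions, selection of
"testable" nodes (enough tips on both sides), Brownian-motion trait covariance
for phylogenetic regression, and Faith's phylogenetic diversity for sets of
tips.

Conventions
-----------
* Trees must be rooted and strictly bifurcating.  Multifurcations are rejected
  unless ``resolve_multifurcations=True``, in which case they are resolved to
  arbitrary bifurcations with zero-length internal branches (logged).
* The first child in newick order is the "left" side of every node.  The
  left/right choice only flips the sign of a balance, but fixing it makes runs
  reproducible.
* Faith's PD is root-inclusive: the branches connecting the subset to the root
  are counted, so the PD of a singleton is its root-to-tip path length.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

logger = logging.getLogger("poms")

__all__ = [
    "PhylogenyError",
    "NodePartition",
    "BrownianCovariance",
    "Phylogeny",
    "read_tree",
]


class PhylogenyError(ValueError):
    """Raised for malformed or unsupported input trees."""


@dataclass(frozen=True)
class NodePartition:
    """Bipartition of tip labels induced by one internal node.

    ``lhs_tips`` is the tip set of the first child in newick order.
    """

    node_id: str
    lhs_tips: frozenset
    rhs_tips: frozenset

    def __post_init__(self):
        if not self.lhs_tips or not self.rhs_tips:
            raise PhylogenyError(f"node {self.node_id}: empty partition side")
        if self.lhs_tips & self.rhs_tips:
            raise PhylogenyError(f"node {self.node_id}: overlapping partition sides")

    @property
    def n_lhs(self) -> int:
        return len(self.lhs_tips)

    @property
    def n_rhs(self) -> int:
        return len(self.rhs_tips)


@dataclass(frozen=True)
class BrownianCovariance:
    """Expected trait covariance among tips under Brownian motion.

    ``matrix[i, j]`` is the root-to-MRCA path length of tips ``taxa[i]`` and
    ``taxa[j]`` — the shared evolutionary history during which their trait
    values co-vary.  Diagonal entries are root-to-tip depths.
    """

    taxa: tuple
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("covariance shape does not match taxa")

    def reorder(self, taxa) -> "BrownianCovariance":
        """Return a copy with rows/columns permuted to ``taxa`` order."""
        idx = {t: i for i, t in enumerate(self.taxa)}
        try:
            order = np.array([idx[t] for t in taxa])
        except KeyError as exc:
            raise KeyError(f"taxon not in covariance: {exc.args[0]!r}") from None
        return BrownianCovariance(tuple(taxa), self.matrix[np.ix_(order, order)])


class Phylogeny:
    """A validated, indexed, rooted bifurcating tree.

    Internal nodes receive stable identifiers: their newick name when present,
    otherwise ``"N<k>"`` with ``k`` the preorder position.  Identifiers are
    deterministic given the input text.
    """

    def __init__(self, tree: TreeNode, resolve_multifurcations: bool = False):
        self._tree = tree
        self._validate(resolve_multifurcations)
        self._index()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick_text: str, resolve_multifurcations: bool = False) -> "Phylogeny":
        try:
            tree = TreeNode.read(io.StringIO(newick_text), format="newick")
        except Exception as exc:  # skbio raises several parser error types
            raise PhylogenyError(f"could not parse newick: {exc}") from exc
        return cls(tree, resolve_multifurcations=resolve_multifurcations)

    def _validate(self, resolve: bool) -> None:
        tree = self._tree
        tips = [t for t in tree.tips()]
        if not tips:
            raise PhylogenyError("tree has no tips")
        names = [t.name for t in tips]
        if any(n is None or n == "" for n in names):
            raise PhylogenyError("every tip must have a non-empty label")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PhylogenyError(f"duplicate tip labels: {dupes}")
        multis = [n for n in tree.non_tips(include_self=True) if len(n.children) > 2]
        if multis:
            if not resolve:
                raise PhylogenyError(
                    f"tree contains {len(multis)} multifurcating node(s); "
                    "pass resolve_multifurcations=True to resolve arbitrarily"
                )
            tree.bifurcate()
            for node in tree.non_tips(include_self=True):
                if node.length is None and node.parent is not None:
                    node.length = 0.0
            logger.warning(
                "resolved %d multifurcation(s) to arbitrary bifurcations "
                "with zero-length branches",
                len(multis),
            )
        for node in tree.non_tips(include_self=True):
            if len(node.children) != 2:
                raise PhylogenyError(
                    f"internal node {node.name!r} has {len(node.children)} children; "
                    "a rooted bifurcating tree is required"
                )

    def _index(self) -> None:
        # Preorder gives a stable ordering determined by the newick text.
        self._internal = [n for n in self._tree.preorder() if not n.is_tip()]
        self._node_ids = []
        self._by_id = {}
        used = set(t.name for t in self._tree.tips())
        for k, node in enumerate(self._internal):
            nid = node.name if node.name else f"N{k}"
            if nid in self._by_id or nid in used:
                raise PhylogenyError(f"duplicate node identifier {nid!r}")
            self._node_ids.append(nid)
            self._by_id[nid] = node
        self._tip_names = tuple(t.name for t in self._tree.tips())
        self._tipsets = {}  # id(TreeNode) -> frozenset of tip names
        for node in self._tree.postorder():
            if node.is_tip():
                self._tipsets[id(node)] = frozenset((node.name,))
            else:
                s = frozenset().union(*(self._tipsets[id(c)] for c in node.children))
                self._tipsets[id(node)] = s

    # -- basic accessors --------------------------------------------------

    @property
    def tree(self) -> TreeNode:
        return self._tree

    @property
    def tips(self) -> tuple:
        """Tip labels in tree (newick) order."""
        return self._tip_names

    @property
    def n_tips(self) -> int:
        return len(self._tip_names)

    @property
    def node_ids(self) -> list:
        """Internal-node identifiers in preorder."""
        return list(self._node_ids)

    @property
    def root_id(self) -> str:
        return self._node_ids[0]

    def node(self, node_id: str) -> TreeNode:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise KeyError(f"unknown node id {node_id!r}") from None

    def clade_tips(self, node_id: str) -> frozenset:
        """All tip labels descending from ``node_id``."""
        return self._tipsets[id(self.node(node_id))]

    def partition(self, node_id: str) -> NodePartition:
        node = self.node(node_id)
        lhs = self._tipsets[id(node.children[0])]
        rhs = self._tipsets[id(node.children[1])]
        return NodePartition(node_id, lhs, rhs)

    @property
    def total_branch_length(self) -> float:
        return float(
            sum(n.length or 0.0 for n in self._tree.traverse(include_self=False))
        )

    def to_newick(self) -> str:
        buf = io.StringIO()
        self._tree.write(buf, format="newick")
        return buf.getvalue()

    # -- node selection ---------------------------------------------------

    def testable_nodes(self, min_tips: int = 10) -> list:
        """Internal nodes with at least ``min_tips`` tips on *both* sides.

        Returns :class:`NodePartition` records in preorder.  The root is
        included whenever it qualifies.
        """
        if min_tips < 1:
            raise ValueError("min_tips must be >= 1")
        out = []
        for nid in self._node_ids:
            node = self._by_id[nid]
            nl = len(self._tipsets[id(node.children[0])])
            nr = len(self._tipsets[id(node.children[1])])
            if nl >= min_tips and nr >= min_tips:
                out.append(self.partition(nid))
        return out

    def clade_nodes(self, min_total_tips: int = 5, exclude_root: bool = True) -> list:
        """Internal nodes whose total descendant tip count is large enough.

        Used to enumerate the candidate clades for clade-based perturbation
        simulations.
        """
        if min_total_tips < 1:
            raise ValueError("min_total_tips must be >= 1")
        out = []
        for nid in self._node_ids:
            if exclude_root and nid == self.root_id:
                continue
            if len(self._tipsets[id(self._by_id[nid])]) >= min_total_tips:
                out.append(nid)
        return out

    # -- quantitative operations ------------------------------------------

    def _depths(self) -> dict:
        """Root-to-node path length per node (root branch ignored)."""
        depths = {id(self._tree): 0.0}
        for node in self._tree.preorder(include_self=False):
            if node.length is None:
                raise PhylogenyError(
                    f"branch length missing above node {node.name!r}"
                )
            if node.length < 0:
                raise PhylogenyError("negative branch length")
            depths[id(node)] = depths[id(node.parent)] + node.length
        return depths

    def brownian_covariance(self) -> BrownianCovariance:
        """Shared-path-length matrix C with C[i, j] = depth of MRCA(i, j)."""
        depths = self._depths()
        tip_index = {t: i for i, t in enumerate(self._tip_names)}
        n = len(self._tip_names)
        C = np.zeros((n, n))
        for t in self._tree.tips():
            i = tip_index[t.name]
            C[i, i] = depths[id(t)]
        for node in self._tree.non_tips(include_self=True):
            d = depths[id(node)]
            left = np.array([tip_index[t] for t in self._tipsets[id(node.children[0])]])
            right = np.array([tip_index[t] for t in self._tipsets[id(node.children[1])]])
            # tips split across the two children coalesce exactly here
            C[np.ix_(left, right)] = d
            C[np.ix_(right, left)] = d
        return BrownianCovariance(self._tip_names, C)

    def faith_pd(self, tip_subset) -> float:
        """Faith's phylogenetic diversity of a tip set (root-inclusive).

        Sum of branch lengths over the minimal subtree connecting the subset
        *and the root*.
        """
        subset = frozenset(tip_subset)
        if not subset:
            raise ValueError("tip_subset must be non-empty")
        unknown = subset - set(self._tip_names)
        if unknown:
            raise KeyError(f"unknown tip label(s): {sorted(unknown)}")
        total = 0.0
        for node in self._tree.traverse(include_self=False):
            if self._tipsets[id(node)] & subset:
                if node.length is None:
                    raise PhylogenyError(
                        f"branch length missing above node {node.name!r}"
                    )
                total += node.length
        return float(total)

    def shear(self, tip_subset) -> "Phylogeny":
        """Restrict the tree to ``tip_subset`` (child order preserved)."""
        subset = set(tip_subset)
        unknown = subset - set(self._tip_names)
        if unknown:
            raise KeyError(f"unknown tip label(s): {sorted(unknown)}")
        if len(subset) < 2:
            raise PhylogenyError("cannot shear to fewer than 2 tips")
        sheared = self._tree.shear(subset)
        sheared.prune()
        return Phylogeny(sheared)


def read_tree(newick_text: str, resolve_multifurcations: bool = False) -> Phylogeny:
    """Parse newick text into a validated :class:`Phylogeny`."""
    return Phylogeny.from_newick(newick_text, resolve_multifurcations=resolve_multifurcations)
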