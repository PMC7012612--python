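"""Phylogenetic tree containers, Newick I/O, and branch addressing.

Every downstream quantity in this package (relative evolutionary rates,
phenotype paths, Brownian simulations) is indexed by *branches* of a rooted
species tree. Branches are addressed by the frozen set of tip labels that
descend from the branch's child node, which makes branch identity stable
under pruning of species: a surviving branch's tip-set is simply intersected
with the kept species.

Newick parsing and serialization are delegated to dendropy; trees are then
held in a lightweight node structure that supports the traversals, pruning
with branch-identity tracking, and cached linear operators the rest of the
package needs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "NewickParseError",
    "Node",
    "PhyloTree",
    "GeneTreeSet",
    "read_newick",
    "write_newick",
    "prune",
    "master_tree",
    "robinson_foulds",
    "load_fixture_tree",
    "read_gene_trees",
    "write_gene_trees",
]

#: Species present in the printed mammal tree but excluded from all analyses
#: because no longevity data exist for it.
EXCLUDED_FOR_MISSING_TRAITS = ("Cape_golden_mole",)


class TreeError(ValueError):
    """Invalid tree structure or incompatible tree operation."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class Node:
    """A node of a rooted tree. ``length`` is the branch above the node."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: List["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, {self.length!r}, {len(self.children)} children)"


class PhyloTree:
    """Rooted phylogenetic tree with branch lengths.

    Treated as immutable after construction: traversal orders, tip-sets and
    the linear operators used for ancestral reconstruction and Brownian
    simulation are computed lazily and cached on the instance.
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()
        self._tipsets: Dict[int, frozenset] = {}
        self._cache: Dict[str, object] = {}

    # -- construction / validation ------------------------------------------

    def _validate(self) -> None:
        names = [n.name for n in self.iter_leaves()]
        if not names:
            raise TreeError("tree has no tips")
        if any(not n for n in names):
            raise TreeError("empty tip label")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
        for node in self.iter_nodes():
            if node is self.root:
                continue
            if not math.isfinite(node.length):
                raise TreeError(f"non-finite branch length above {node.name!r}")
            if node.length < 0:
                raise TreeError(
                    f"negative branch length {node.length} above {node.name!r}"
                )

    # -- traversal -----------------------------------------------------------

    def iter_nodes(self) -> Iterator[Node]:
        """Preorder traversal."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def iter_postorder(self) -> Iterator[Node]:
        out: List[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def iter_leaves(self) -> Iterator[Node]:
        for node in self.iter_nodes():
            if node.is_leaf:
                yield node

    @property
    def tips(self) -> List[str]:
        """Tip labels in tree (preorder) order."""
        return [n.name for n in self.iter_leaves()]

    @property
    def tip_set(self) -> frozenset:
        return frozenset(self.tips)

    def __len__(self) -> int:
        return len(self.tips)

    # -- branch addressing ---------------------------------------------------

    def tipset(self, node: Node) -> frozenset:
        """Frozen set of tip labels descending from ``node``."""
        key = id(node)
        got = self._tipsets.get(key)
        if got is None:
            if node.is_leaf:
                got = frozenset((node.name,))
            else:
                got = frozenset().union(*(self.tipset(c) for c in node.children))
            self._tipsets[key] = got
        return got

    def branch_nodes(self) -> List[Node]:
        """Non-root nodes in canonical branch order.

        Order is deterministic: by tip-set size, then by the lexicographically
        smallest member. Within one tree the (size, smallest member) pair is
        unique, because two distinct clades sharing a tip are nested and so
        differ in size.
        """
        cached = self._cache.get("branch_nodes")
        if cached is None:
            nodes = [n for n in self.iter_nodes() if n is not self.root]
            # resolve postorder first so tipsets build bottom-up cheaply
            for n in self.iter_postorder():
                self.tipset(n)
            nodes.sort(key=lambda n: (len(self.tipset(n)), min(self.tipset(n))))
            self._cache["branch_nodes"] = cached = nodes
        return cached  # type: ignore[return-value]

    def branch_ids(self) -> List[frozenset]:
        """Branch identifiers (descendant tip-sets) in canonical order."""
        return [self.tipset(n) for n in self.branch_nodes()]

    def branch_labels(self) -> List[str]:
        """Short, human-readable branch labels, unique within this tree."""
        return [branch_label(ts) for ts in self.branch_ids()]

    def branch_lengths(self) -> Dict[frozenset, float]:
        return {self.tipset(n): n.length for n in self.branch_nodes()}

    def branch_length_array(self) -> np.ndarray:
        return np.array([n.length for n in self.branch_nodes()], dtype=float)

    def depth(self) -> float:
        """Maximum root-to-tip path length."""
        depths = {id(self.root): 0.0}
        best = 0.0
        for node in self.iter_nodes():
            if node is self.root:
                continue
            d = depths[id(node.parent)] + node.length
            depths[id(node)] = d
            if node.is_leaf:
                best = max(best, d)
        return best

    # -- copying / serialization --------------------------------------------

    def copy(self) -> "PhyloTree":
        return PhyloTree(_copy_node(self.root))

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({len(self)} tips)"


def branch_label(tipset: frozenset) -> str:
    """Label a branch by its smallest member and clade size, e.g. ``Human+3``."""
    return f"{min(tipset)}+{len(tipset)}"


def _copy_node(node: Node) -> Node:
    new = Node(node.name, node.length)
    for child in node.children:
        new.add_child(_copy_node(child))
    return new


# -- Newick I/O --------------------------------------------------------------


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Underscores in labels are preserved verbatim. Branches without an explicit
    length are assigned 0.0 with a warning; negative lengths are rejected.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        offset = ""
        col = getattr(exc, "col_num", None)
        line = getattr(exc, "line_num", None)
        if col is not None:
            offset = f" (line {line}, column {col})"
        raise NewickParseError(f"malformed Newick{offset}: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    return PhyloTree(root)


def _from_dendropy(dnode: "dendropy.Node") -> Node:
    if dnode.is_leaf():
        name = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(name=name)
    else:
        node = Node(name=None)
    length = dnode.edge.length
    if dnode.parent_node is not None:
        if length is None:
            warnings.warn("branch without length treated as 0.0", stacklevel=3)
            length = 0.0
        node.length = float(length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def write_newick(tree: PhyloTree) -> str:
    """Serialize to Newick. Branch lengths round-trip at full float precision."""
    return _write_node(tree.root, is_root=True) + ";"


def _write_node(node: Node, is_root: bool = False) -> str:
    if node.is_leaf:
        body = node.name
    else:
        body = "(" + ",".join(_write_node(c) for c in node.children) + ")"
        if node.name:
            body += node.name
    if is_root:
        return body
    return f"{body}:{node.length!r}"


def load_fixture_tree(name: str = "mammal61") -> PhyloTree:
    """Load one of the bundled mammal species trees.

    ``mammal61`` is the 62-tip tree of the UCSC 100-way mammal set (61
    analysis species plus the cape golden mole, which lacks longevity data);
    ``placental34`` is the 34-species placental subtree used for branch-site
    analyses.
    """
    path = Path(__file__).parent / "data" / f"{name}.nwk"
    return read_newick(path.read_text())


# -- pruning -----------------------------------------------------------------


def prune(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Restrict a tree to a subset of species.

    Degree-two nodes arising from tip removal are suppressed and their branch
    lengths summed, so path lengths between kept species are preserved.
    """
    pruned, _ = prune_with_map(tree, keep)
    return pruned


def prune_with_map(
    tree: PhyloTree, keep: Iterable[str]
) -> Tuple[PhyloTree, Dict[frozenset, frozenset]]:
    """Prune and report branch identity across the pruning.

    Returns ``(pruned_tree, mapping)`` where ``mapping`` sends each surviving
    branch id (tip-set in the pruned tree) to the id of the child-most
    original branch on the path it represents. The surviving tip-set always
    equals the original tip-set intersected with ``keep``.
    """
    keep = frozenset(keep)
    missing = keep - tree.tip_set
    if missing:
        raise TreeError(f"species not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise TreeError("cannot prune to fewer than 2 species")

    # copy with original tipsets attached
    orig_of: Dict[int, frozenset] = {}

    def copy_rec(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if node.name not in keep:
                return None
            new = Node(node.name, node.length)
            orig_of[id(new)] = tree.tipset(node)
            return new
        kids = [c2 for c in node.children if (c2 := copy_rec(c)) is not None]
        if not kids:
            return None
        if len(kids) == 1:
            # suppress this node: child absorbs the branch above, child-most
            # original identity wins
            kids[0].length += node.length
            return kids[0]
        new = Node(node.name, node.length)
        for k in kids:
            new.add_child(k)
        orig_of[id(new)] = tree.tipset(node)
        return new

    new_root = copy_rec(tree.root)
    assert new_root is not None
    # a root that ended up on a suppressed chain keeps no branch above it
    new_root.parent = None
    new_root.length = 0.0
    pruned = PhyloTree(new_root)
    mapping = {
        pruned.tipset(n): orig_of[id(n)]
        for n in pruned.iter_nodes()
        if n is not pruned.root
    }
    return pruned, mapping


# -- gene tree sets ----------------------------------------------------------


@dataclass
class GeneTreeSet:
    """A collection of per-gene trees over a common species universe."""

    gene_ids: List[str]
    trees: Dict[str, PhyloTree]
    species_universe: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.species_universe:
            self.species_universe = frozenset().union(
                *(t.tip_set for t in self.trees.values())
            )
        for gid in self.gene_ids:
            extra = self.trees[gid].tip_set - self.species_universe
            if extra:
                raise TreeError(
                    f"gene {gid!r} has tips outside the species universe: "
                    f"{sorted(extra)}"
                )

    @classmethod
    def from_trees(cls, trees: Mapping[str, PhyloTree]) -> "GeneTreeSet":
        ids = sorted(trees)
        return cls(gene_ids=ids, trees=dict(trees))

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __getitem__(self, gene_id: str) -> PhyloTree:
        return self.trees[gene_id]

    def restrict_species(self, keep: Iterable[str]) -> "GeneTreeSet":
        """Prune every gene tree to ``keep``; genes left with <2 species drop out."""
        keep = frozenset(keep)
        trees: Dict[str, PhyloTree] = {}
        for gid in self.gene_ids:
            sub = self.trees[gid].tip_set & keep
            if len(sub) < 2:
                continue
            trees[gid] = prune(self.trees[gid], sub)
        return GeneTreeSet(
            gene_ids=[g for g in self.gene_ids if g in trees],
            trees=trees,
            species_universe=keep & self.species_universe,
        )


def read_gene_trees(path: str | Path) -> GeneTreeSet:
    """Read gene trees from a directory of ``*.nwk`` files or a single
    tab-delimited file with lines ``gene_id<TAB>newick``."""
    path = Path(path)
    trees: Dict[str, PhyloTree] = {}
    if path.is_dir():
        for f in sorted(path.glob("*.nwk")):
            trees[f.stem] = read_newick(f.read_text())
    else:
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            try:
                gid, nwk = line.split("\t", 1)
            except ValueError:
                raise NewickParseError(
                    f"{path}:{lineno}: expected 'gene<TAB>newick'"
                ) from None
            trees[gid.strip()] = read_newick(nwk)
    if not trees:
        raise TreeError(f"no gene trees found at {path}")
    return GeneTreeSet.from_trees(trees)


def write_gene_trees(genes: GeneTreeSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for gid in genes.gene_ids:
            fh.write(f"{gid}\t{genes.trees[gid].to_newick()}\n")


# -- master tree -------------------------------------------------------------


def master_tree(genes: GeneTreeSet) -> PhyloTree:
    """Average gene-tree branch lengths onto the shared species topology.

    The scaffold topology is taken from a gene tree that covers the full
    species universe; every gene tree must equal the scaffold restricted to
    its own tips (fixed-topology assumption). Each master branch length is
    the arithmetic mean of that branch's length over the gene trees that
    contain the branch; a gene branch spanning a path of collapsed master
    branches is attributed to the child-most branch on the path.
    """
    scaffold = None
    for gid in genes.gene_ids:
        if genes.trees[gid].tip_set == genes.species_universe:
            scaffold = genes.trees[gid]
            break
    if scaffold is None:
        raise TreeError(
            "no gene tree spans the full species universe; cannot build a "
            "master topology (supertree construction is not supported)"
        )
    order = scaffold.branch_ids()
    index = {ts: i for i, ts in enumerate(order)}
    sums = np.zeros(len(order))
    counts = np.zeros(len(order), dtype=int)
    for gid in genes.gene_ids:
        gtree = genes.trees[gid]
        if gtree.tip_set == genes.species_universe:
            mapping = {ts: ts for ts in gtree.branch_ids()}
            expected = set(order)
        else:
            _, mapping = prune_with_map(scaffold, gtree.tip_set)
            expected = set(mapping)
        got = set(gtree.branch_ids())
        if got != expected:
            raise TreeError(
                f"gene {gid!r} topology is incongruent with the master topology"
            )
        for node in gtree.branch_nodes():
            i = index[mapping[gtree.tipset(node)]]
            sums[i] += node.length
            counts[i] += 1
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    master = scaffold.copy()
    for node in master.branch_nodes():
        mean = means[index[master.tipset(node)]]
        if np.isfinite(mean):
            node.length = float(mean)
    return master


# -- topology comparison -----------------------------------------------------


def _nontrivial_splits(tree: PhyloTree) -> set:
    """Unrooted, normalized non-trivial bipartitions of a rooted tree."""
    all_tips = tree.tip_set
    ref = min(all_tips)
    n = len(all_tips)
    splits = set()
    for ts in tree.branch_ids():
        if len(ts) < 2 or len(ts) > n - 2:
            continue
        side = all_tips - ts if ref in ts else ts
        splits.add(side)
    return splits


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Robinson-Foulds distance: symmetric difference of non-trivial
    bipartitions between two trees on the same tip set."""
    if a.tip_set != b.tip_set:
        raise TreeError("Robinson-Foulds requires identical tip sets")
    return len(_nontrivial_splits(a) ^ _nontrivial_splits(b))
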