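"""Dated species-tree handling.

A :class:`SpeciesTree` wraps an ultrametric, dated phylogeny (node ages in
millions of years, My) and answers the three questions the transfer pipeline
keeps asking:

* how long ago did two species diverge (:meth:`SpeciesTree.divergence_my`);
* which maximal clades are younger than an age threshold
  (:meth:`SpeciesTree.clades_younger_than`), used both to collapse species
  into young clades within which horizontal transfer is not called, and to
  exclude recently diverged species pairs;
* which two sister clades descend from the most recent common ancestor of a
  species pair (:meth:`SpeciesTree.sister_clade_pair`), the unit for which
  core-gene synonymous-divergence null distributions are built.

Trees are read from Newick with branch lengths in My.  Species labels are
normalized by replacing spaces with underscores; the same normalization must
be applied to the metadata tables the tree is matched against.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "SpeciesTree",
    "CladePartition",
    "CladePair",
    "parse_timetree",
    "normalize_species",
    "count_reciprocal_searches",
]

#: Relative ultrametricity tolerance, as a fraction of tree height.
ULTRAMETRIC_RTOL = 1e-6


def normalize_species(name: str) -> str:
    """Canonical species identifier: spaces become underscores."""
    return name.strip().replace(" ", "_")


@dataclass(frozen=True)
class CladePair:
    """The two sister clades descending from the MRCA of a species pair."""

    mrca_age: float
    clade_a: frozenset[str]
    clade_b: frozenset[str]

    def key(self) -> tuple[frozenset[str], frozenset[str]]:
        """Unordered identity of the pair (for dictionary lookups)."""
        return tuple(sorted((self.clade_a, self.clade_b), key=sorted))  # type: ignore[return-value]


@dataclass(frozen=True)
class CladePartition:
    """Partition of the tips into maximal clades younger than a threshold."""

    age_threshold: float
    assignment: dict[str, int]
    clades: dict[int, frozenset[str]] = field(default_factory=dict)

    def clade_of(self, species: str) -> int:
        return self.assignment[species]

    def members(self, clade_id: int) -> frozenset[str]:
        return self.clades[clade_id]

    def __len__(self) -> int:
        return len(self.clades)


class SpeciesTree:
    """Ultrametric dated species tree with O(1) divergence-time lookups.

    Node ages are computed from branch lengths (My).  Construction validates
    that every tip sits at the same root-to-tip depth up to
    ``ULTRAMETRIC_RTOL`` of the tree height; tip depths are not rescaled.
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        tree.is_rooted = True
        for leaf in tree.leaf_node_iter():
            leaf.taxon.label = normalize_species(leaf.taxon.label)
        self._tree = tree
        self._tips: list[str] = sorted(
            leaf.taxon.label for leaf in tree.leaf_node_iter()
        )
        if len(set(self._tips)) != len(self._tips):
            raise ValueError("duplicate tip labels after normalization")
        self._tip_index = {sp: i for i, sp in enumerate(self._tips)}
        self._compute_ages()
        self._divergence = self._pairwise_mrca_ages()

    # -- construction helpers -------------------------------------------------

    def _compute_ages(self) -> None:
        root = self._tree.seed_node
        depth: dict[dendropy.Node, float] = {root: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            edge = node.edge.length
            if edge is None:
                raise ValueError(f"missing branch length above node {node}")
            depth[node] = depth[node.parent_node] + edge
        tip_depths = {
            leaf.taxon.label: depth[leaf] for leaf in self._tree.leaf_node_iter()
        }
        height = max(tip_depths.values())
        self._height = height
        tol = max(height, 1.0) * ULTRAMETRIC_RTOL
        worst = max(tip_depths, key=lambda sp: abs(tip_depths[sp] - height))
        if abs(tip_depths[worst] - height) > tol:
            raise ValueError(
                "tree is not ultrametric: tip "
                f"{worst!r} at depth {tip_depths[worst]:.6g} vs height {height:.6g}"
            )
        self._age: dict[dendropy.Node, float] = {}
        for node in self._tree.preorder_node_iter():
            age = 0.0 if node.is_leaf() else height - depth[node]
            if age < -tol:
                raise ValueError("negative node age: branch lengths inconsistent")
            self._age[node] = max(age, 0.0)
        for node in self._tree.preorder_node_iter():
            for child in node.child_nodes():
                if not child.is_leaf() and self._age[child] > self._age[node] + tol:
                    raise ValueError("child node older than its parent")

    def _pairwise_mrca_ages(self):
        import numpy as np

        n = len(self._tips)
        div = np.zeros((n, n))
        tipsets: dict[dendropy.Node, list[int]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                tipsets[node] = [self._tip_index[node.taxon.label]]
                continue
            groups = [tipsets.pop(c) for c in node.child_nodes()]
            age = self._age[node]
            for ga, gb in itertools.combinations(groups, 2):
                for i in ga:
                    div[i, np.asarray(gb)] = age
                    div[np.asarray(gb), i] = age
            tipsets[node] = [i for g in groups for i in g]
        return div

    # -- public surface -------------------------------------------------------

    @property
    def tips(self) -> list[str]:
        return list(self._tips)

    @property
    def height(self) -> float:
        """Root age in My."""
        return self._height

    def __contains__(self, species: str) -> bool:
        return normalize_species(species) in self._tip_index

    def _idx(self, species: str) -> int:
        sp = normalize_species(species)
        try:
            return self._tip_index[sp]
        except KeyError:
            raise KeyError(f"species {species!r} is not a tip of the tree") from None

    def divergence_my(self, sp1: str, sp2: str) -> float:
        """Age (My) of the MRCA of two tips; 0 for a species with itself."""
        i, j = self._idx(sp1), self._idx(sp2)
        return float(self._divergence[i, j])

    def clades_younger_than(self, threshold: float) -> CladePartition:
        """Maximal monophyletic groups whose crown age is strictly below
        ``threshold`` (My).  Tips whose smallest non-trivial containing clade
        meets or exceeds the threshold become singleton clades."""
        if threshold <= 0:
            raise ValueError("threshold must be > 0 My")
        assignment: dict[str, int] = {}
        clades: dict[int, frozenset[str]] = {}
        next_id = 0

        def visit(node, parent_blocked: bool) -> None:
            nonlocal next_id
            age = self._age[node]
            if age < threshold and (parent_blocked or node is self._tree.seed_node):
                members = frozenset(
                    leaf.taxon.label for leaf in node.leaf_iter()
                )
                cid = next_id
                next_id += 1
                clades[cid] = members
                for sp in members:
                    assignment[sp] = cid
                return
            for child in node.child_nodes():
                visit(child, parent_blocked=True)

        root = self._tree.seed_node
        if self._age[root] < threshold:
            visit(root, parent_blocked=False)
        else:
            for child in root.child_nodes():
                visit(child, parent_blocked=True)
        return CladePartition(float(threshold), assignment, clades)

    def sister_clade_pair(self, sp1: str, sp2: str) -> CladePair:
        """The two clades descending from MRCA(sp1, sp2) that contain sp1 and
        sp2 respectively.  At a polytomy, each side is the single child
        subtree containing the query species (other children are ignored), so
        the operation is symmetric under argument swap."""
        if normalize_species(sp1) == normalize_species(sp2):
            raise ValueError("sister_clade_pair requires two distinct species")
        self._idx(sp1), self._idx(sp2)  # raise on unknown species
        t1 = self._tree.taxon_namespace.get_taxon(normalize_species(sp1))
        t2 = self._tree.taxon_namespace.get_taxon(normalize_species(sp2))
        mrca = self._tree.mrca(taxa=[t1, t2])
        side_a = side_b = None
        for child in mrca.child_nodes():
            labels = frozenset(leaf.taxon.label for leaf in child.leaf_iter())
            if normalize_species(sp1) in labels:
                side_a = labels
            if normalize_species(sp2) in labels:
                side_b = labels
        assert side_a is not None and side_b is not None
        return CladePair(float(self._age[mrca]), side_a, side_b)

    def crown_age(self, species: frozenset[str] | set[str]) -> float:
        """Age of the MRCA of a set of tips (0 for a single tip)."""
        species = {normalize_species(s) for s in species}
        if len(species) == 1:
            return 0.0
        taxa = [self._tree.taxon_namespace.get_taxon(s) for s in sorted(species)]
        if any(t is None for t in taxa):
            missing = sorted(s for s, t in zip(sorted(species), taxa) if t is None)
            raise KeyError(f"species not on tree: {missing}")
        return float(self._age[self._tree.mrca(taxa=taxa)])

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


def count_reciprocal_searches(tree: SpeciesTree,
                              threshold: float = 40.0) -> int:
    """Number of ordered species pairs whose divergence reaches
    ``threshold`` My — one reciprocal similarity search per ordered pair of
    species belonging to different clades younger than the threshold."""
    partition = tree.clades_younger_than(threshold)
    sizes = [len(partition.members(cid)) for cid in partition.clades]
    n = sum(sizes)
    return n * (n - 1) - sum(s * (s - 1) for s in sizes)


def parse_timetree(newick_text: str) -> SpeciesTree:
    """Parse a Newick string with branch lengths in My into a SpeciesTree.

    Raises ``ValueError`` (with the parser's position information) on
    malformed Newick and on trees that are not ultrametric within tolerance.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    return SpeciesTree(tree)
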