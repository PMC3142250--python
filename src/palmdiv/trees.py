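"""Dated ultrametric trees (chronograms) and their branching times.

A chronogram is a rooted, binary, ultrametric tree whose branch lengths are
in units of absolute time (Ma here).  Node ages are measured backward from
the present, so all extant tips sit at age 0 and the root age equals the
crown age of the clade.  The diversification machinery downstream consumes
only the sorted internal-node ages (:class:`BranchingTimes`), optionally
truncated at a sampling-reliability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import dendropy
import numpy as np

__all__ = [
    "Chronogram",
    "BranchingTimes",
    "UltrametricityError",
    "PolytomyError",
    "parse_newick",
    "read_newick_trees",
    "write_newick_trees",
    "branching_times",
    "stem_age",
    "truncate_at",
]

DEFAULT_ULTRAMETRICITY_TOL = 1e-6


class UltrametricityError(ValueError):
    """Root-to-tip depths differ beyond the allowed tolerance."""


class PolytomyError(ValueError):
    """Tree contains a node with more than two children."""


class Chronogram:
    """A rooted, binary, ultrametric, dated phylogeny.

    Parameters
    ----------
    tree:
        A rooted ``dendropy.Tree`` with branch lengths in Ma.  The tree is
        used in place (not copied).
    tolerance:
        Relative tolerance on the spread of root-to-tip depths.  Dated trees
        exported by Bayesian samplers carry floating-point noise, so exact
        ultrametricity is not required; the spread must satisfy
        ``max_depth - min_depth <= tolerance * max_depth``.
    resolve_polytomies:
        If True, polytomies are resolved at random into zero-length
        bifurcations using ``rng``; otherwise a :class:`PolytomyError` is
        raised.
    rng:
        ``numpy.random.Generator`` used only for polytomy resolution.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        tolerance: float = DEFAULT_ULTRAMETRICITY_TOL,
        resolve_polytomies: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        self._tree = tree
        self.tolerance = float(tolerance)
        self._resolved_polytomies = False
        tree.suppress_unifurcations()
        if any(len(nd.child_nodes()) > 2 for nd in tree.preorder_node_iter()):
            if not resolve_polytomies:
                raise PolytomyError(
                    "tree contains polytomies; pass resolve_polytomies=True "
                    "to break them randomly into zero-length bifurcations"
                )
            self._resolve(rng if rng is not None else np.random.default_rng())
            self._resolved_polytomies = True
        self._compute_ages()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        text: str,
        tolerance: float = DEFAULT_ULTRAMETRICITY_TOL,
        resolve_polytomies: bool = False,
        rng: np.random.Generator | None = None,
    ) -> "Chronogram":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                rooting="force-rooted",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"could not parse newick: {exc}") from exc
        return cls(
            tree,
            tolerance=tolerance,
            resolve_polytomies=resolve_polytomies,
            rng=rng,
        )

    def _resolve(self, rng: np.random.Generator) -> None:
        # Random zero-length resolution: repeatedly detach two random
        # children of each polytomy and reattach them under a new node.
        for node in list(self._tree.preorder_node_iter()):
            while len(node.child_nodes()) > 2:
                children = node.child_nodes()
                i, j = rng.choice(len(children), size=2, replace=False)
                a, b = children[int(i)], children[int(j)]
                node.remove_child(a)
                node.remove_child(b)
                joint = node.new_child(edge_length=0.0)
                joint.add_child(a)
                joint.add_child(b)

    def _compute_ages(self) -> None:
        tree = self._tree
        root = tree.seed_node
        root.depth = 0.0
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            length = node.edge.length if node.edge.length is not None else 0.0
            if length < 0:
                raise ValueError(f"negative branch length {length}")
            node.depth = node.parent_node.depth + length

        tips = list(tree.leaf_node_iter())
        if not tips:
            raise ValueError("tree has no tips")
        depths = np.array([t.depth for t in tips], dtype=float)
        max_depth = float(depths.max())
        if max_depth > 0 and (max_depth - depths.min()) > self.tolerance * max_depth:
            raise UltrametricityError(
                "tree is not ultrametric: root-to-tip depths span "
                f"[{depths.min():.9g}, {max_depth:.9g}] beyond relative "
                f"tolerance {self.tolerance:g}"
            )

        self._labels: list[str] = []
        for tip in tips:
            if tip.taxon is None or not tip.taxon.label:
                raise ValueError("every tip needs a non-empty label")
            self._labels.append(tip.taxon.label)
        if len(set(self._labels)) != len(self._labels):
            raise ValueError("tip labels must be unique")

        for node in tree.preorder_node_iter():
            node.age = 0.0 if node.is_leaf() else max_depth - node.depth
        # Guard against float noise producing an infinitesimally "younger"
        # parent; zero-length edges from polytomy resolution give age ties.
        slack = self.tolerance * max(max_depth, 1.0)
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and node.parent_node.age < node.age - slack:
                raise ValueError("internal node younger than its child")

    # -- basic accessors ---------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    @property
    def tip_labels(self) -> list[str]:
        return list(self._labels)

    @property
    def crown_age(self) -> float:
        return float(self._tree.seed_node.age)

    def node_ages(self) -> dict[int, float]:
        """Ages of all nodes keyed by id (tips included, age 0)."""
        return {id(n): float(n.age) for n in self._tree.preorder_node_iter()}

    def internal_ages(self) -> np.ndarray:
        """Internal-node ages in descending order (root first)."""
        ages = [n.age for n in self._tree.preorder_internal_node_iter()]
        return np.sort(np.asarray(ages, dtype=float))[::-1]

    def postorder(self) -> Iterator[dendropy.Node]:
        return self._tree.postorder_node_iter()

    def preorder(self) -> Iterator[dendropy.Node]:
        return self._tree.preorder_node_iter()

    def find_tip(self, label: str) -> dendropy.Node:
        for tip in self._tree.leaf_node_iter():
            if tip.taxon.label == label:
                return tip
        raise KeyError(f"no tip labelled {label!r}")

    # -- derived quantities ------------------------------------------------

    def branching_times(self) -> "BranchingTimes":
        return branching_times(self)

    def stem_age(self, label: str) -> float:
        return stem_age(self, label)

    def stem_ages(self) -> dict[str, float]:
        """Stem age (parent-node age) for every tip.

        For a tip attached directly to the root this is the root age, the
        oldest point at which the tip lineage demonstrably existed.
        """
        out = {}
        for tip in self._tree.leaf_node_iter():
            out[tip.taxon.label] = float(tip.parent_node.age)
        return out

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".17g",
        )
        return s.strip()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Chronogram n_tips={self.n_tips} crown_age={self.crown_age:.4g}>"


@dataclass(frozen=True)
class BranchingTimes:
    """Descending internal-node ages of a chronogram.

    ``window_end`` marks where the observation window closes: 0 for a
    complete tree observed to the present, or a positive threshold age when
    nodes younger than the threshold have been deleted.  All retained ages
    exceed ``window_end``; the implied number of lineages at the window end
    is ``n_tips = len(ages) + 1``.
    """

    ages: np.ndarray
    window_end: float = 0.0

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        if ages.ndim != 1 or ages.size < 1:
            raise ValueError("need at least one branching time")
        if np.any(np.diff(ages) > 0):
            ages = np.sort(ages)[::-1]
        if self.window_end < 0:
            raise ValueError("window_end must be >= 0")
        if ages[-1] <= self.window_end:
            raise ValueError("all branching times must exceed window_end")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "window_end", float(self.window_end))

    @property
    def n_tips(self) -> int:
        """Lineage count at the end of the observation window."""
        return int(self.ages.size) + 1

    @property
    def crown_age(self) -> float:
        return float(self.ages[0])

    def truncate_at(self, threshold: float) -> "BranchingTimes":
        return truncate_at(self, threshold)


def parse_newick(text: str, **kwargs) -> Chronogram:
    """Parse a single newick string into a :class:`Chronogram`."""
    return Chronogram.from_newick(text, **kwargs)


def read_newick_trees(path, **kwargs) -> list[Chronogram]:
    """Read a multi-tree newick file (one tree per line).

    Used for posterior chronogram samples; blank lines are skipped.
    """
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(Chronogram.from_newick(line, **kwargs))
    if not trees:
        raise ValueError(f"no trees found in {path}")
    return trees


def write_newick_trees(trees: Iterable[Chronogram], path) -> None:
    with open(path, "w") as fh:
        for tr in trees:
            fh.write(tr.to_newick() + "\n")


def branching_times(tree: Chronogram) -> BranchingTimes:
    """Extract descending internal-node ages; requires >= 2 tips."""
    if tree.n_tips < 2:
        raise ValueError("branching times require a tree with >= 2 tips")
    return BranchingTimes(tree.internal_ages(), window_end=0.0)


def stem_age(tree: Chronogram, label: str) -> float:
    """Age of the node where the tip's lineage split from its sister."""
    tip = tree.find_tip(label)
    return float(tip.parent_node.age)


def truncate_at(bt: BranchingTimes, threshold: float) -> BranchingTimes:
    """Delete branching times at or below ``threshold``.

    The observation window then ends at ``threshold`` rather than at the
    present: the youngest retained interval runs from the youngest retained
    node down to the threshold age.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if threshold >= bt.crown_age:
        raise ValueError(
            f"threshold {threshold} >= crown age {bt.crown_age}: no branching "
            "times would remain"
        )
    if threshold <= bt.window_end:
        if threshold == bt.window_end:
            return bt
        raise ValueError("threshold lies inside the already-truncated window")
    kept = bt.ages[bt.ages > threshold]
    return BranchingTimes(kept, window_end=float(threshold))
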