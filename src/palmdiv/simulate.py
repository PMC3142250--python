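"""Synthetic chronograms, richness tables, characters and range histories.

The generators emulate the statistical structure of a genus-level study of
a large tropical plant family: Yule / birth-death / two-rate chronograms of
order 100-200 tips, a right-skewed genus richness distribution (one
representative species sampled per genus out of a family total of roughly
2,400 species across 183 genera), three-state Mk biome characters with
TRF-dominant ancestry, and DEC range histories over seven areas with a
maximum range size of two.

All simulators accept an integer seed or a ``numpy.random.Generator`` and
are exactly reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy

from .biogeography import EpochModel, RangeSpace, build_range_space, \
    cladogenesis_scenarios, dec_generator
from .biome import mk_transition_matrix
from .trees import BranchingTimes, Chronogram

__all__ = [
    "simulate_yule",
    "yule_branching_times",
    "simulate_birth_death",
    "simulate_yule2rate",
    "simulate_richness",
    "simulate_mk_states",
    "simulate_dec_ranges",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _tip_labels(n: int) -> list[str]:
    return [f"t{i + 1}" for i in range(n)]


# ---------------------------------------------------------------------------
# Pure-birth (Yule) simulation
# ---------------------------------------------------------------------------

def yule_branching_times(n_tips: int, birth_rate: float, seed=None) -> BranchingTimes:
    """Branching times of a pure-birth tree conditioned on its tip count.

    The tree grows from the two crown lineages; with j lineages the waiting
    time to the next speciation is Exponential(j * birth_rate), and a final
    Exponential(n * birth_rate) interval separates the last node from the
    present.  This is the fast path used by the Monte Carlo null
    distributions, which need only node ages, not topologies.
    """
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = _as_rng(seed)
    j = np.arange(2, n_tips + 1)
    waits = rng.exponential(1.0 / (j * birth_rate))
    total = waits.sum()
    # Node k (k = 1 .. n-1) sits at forward time sum(waits[:k-1]); k=1 is
    # the crown at forward time 0.
    forward = np.concatenate(([0.0], np.cumsum(waits[:-1])))
    ages = total - forward
    return BranchingTimes(np.sort(ages)[::-1], window_end=0.0)


def _tree_from_ages(ages_desc: np.ndarray, rng: np.random.Generator,
                    labels: list[str] | None = None) -> Chronogram:
    """Random-join (coalescent-style) topology over given node ages.

    Joining two uniformly chosen subtree roots at each node age yields the
    same distribution over labelled topologies as forward uniform splitting
    (the Yule topology distribution).
    """
    n = len(ages_desc) + 1
    if labels is None:
        labels = _tip_labels(n)
    taxa = dendropy.TaxonNamespace(labels)
    active: list[tuple[dendropy.Node, float]] = []
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        active.append((node, 0.0))
    for age in np.sort(ages_desc):  # youngest node first
        i, j = rng.choice(len(active), size=2, replace=False)
        (a, age_a), (b, age_b) = active[int(i)], active[int(j)]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = age - age_a
        b.edge.length = age - age_b
        active = [x for k, x in enumerate(active) if k not in (int(i), int(j))]
        active.append((parent, float(age)))
    root = active[0][0]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    return Chronogram(tree)


def simulate_yule(n_tips: int, birth_rate: float, seed=None) -> Chronogram:
    """Pure-birth chronogram conditioned on its tip count."""
    rng = _as_rng(seed)
    bt = yule_branching_times(n_tips, birth_rate, rng)
    return _tree_from_ages(bt.ages, rng)


# ---------------------------------------------------------------------------
# Birth-death simulation
# ---------------------------------------------------------------------------

def simulate_birth_death(n_tips: int, birth_rate: float, death_rate: float,
                         seed=None, max_retries: int = 1000) -> Chronogram:
    """Reconstructed birth-death chronogram with exactly ``n_tips`` survivors.

    Forward simulation from two crown lineages; the clade is retried when it
    dies out before reaching ``n_tips`` extant lineages.  Extinct lineages
    are pruned, so the returned tree is ultrametric and its crown age is the
    age of the most recent common ancestor of the survivors.  With
    ``death_rate == 0`` the simulation reduces exactly to the pure-birth
    scheme of :func:`simulate_yule`.
    """
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    if not birth_rate > death_rate >= 0:
        raise ValueError("need birth_rate > death_rate >= 0")
    rng = _as_rng(seed)
    total_rate = birth_rate + death_rate
    p_birth = birth_rate / total_rate
    for attempt in range(max_retries):
        taxa = dendropy.TaxonNamespace()
        root = dendropy.Node()
        c1, c2 = dendropy.Node(), dendropy.Node()
        root.add_child(c1)
        root.add_child(c2)
        births = {id(root): 0.0, id(c1): 0.0, id(c2): 0.0}
        alive = [c1, c2]
        t = 0.0
        failed = False
        while len(alive) < n_tips:
            t += rng.exponential(1.0 / (len(alive) * total_rate))
            idx = int(rng.integers(len(alive)))
            node = alive[idx]
            if rng.random() < p_birth:
                a, b = dendropy.Node(), dendropy.Node()
                node.add_child(a)
                node.add_child(b)
                births[id(a)] = births[id(b)] = t
                node.death = t
                alive[idx] = a
                alive.append(b)
            else:
                node.death = t
                node.extinct = True
                del alive[idx]
                if not alive:
                    failed = True
                    break
        if failed:
            continue
        T = t + rng.exponential(1.0 / (n_tips * total_rate))
        for i, node in enumerate(alive):
            node.taxon = taxa.new_taxon(label=f"t{i + 1}")
            node.death = T
        # Set edge lengths, then prune extinct subtrees.
        for node in root.preorder_iter():
            if node is root:
                continue
            end = getattr(node, "death", T)
            node.edge.length = end - births[id(node)]
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.seed_node = root
        tree.is_rooted = True
        _prune_extinct(tree)
        return Chronogram(tree)
    raise RuntimeError(
        f"clade died out in all {max_retries} attempts before reaching "
        f"{n_tips} survivors"
    )


def _prune_extinct(tree: dendropy.Tree) -> None:
    changed = True
    while changed:
        changed = False
        for leaf in list(tree.leaf_node_iter()):
            if leaf.taxon is None:
                leaf.parent_node.remove_child(leaf)
                changed = True
    # Collapse unifurcations, merging branch lengths.
    for node in list(tree.preorder_node_iter()):
        children = node.child_nodes()
        if len(children) == 1 and node.parent_node is not None:
            child = children[0]
            child.edge.length += node.edge.length
            parent = node.parent_node
            parent.remove_child(node)
            parent.add_child(child)
    # The root may have degenerated into a chain; reseed at the basal split.
    seed = tree.seed_node
    while len(seed.child_nodes()) == 1:
        seed = seed.child_nodes()[0]
    seed.parent_node = None
    seed.edge.length = None
    tree.seed_node = seed


# ---------------------------------------------------------------------------
# Two-rate pure-birth simulation
# ---------------------------------------------------------------------------

def simulate_yule2rate(n_tips: int, rate_old: float, rate_young: float,
                       shift_age: float, seed=None) -> Chronogram:
    """Pure-birth chronogram whose speciation rate shifts at a fixed age.

    Lineages speciate at ``rate_old`` while older than ``shift_age`` (ages
    measured back from the present) and at ``rate_young`` afterwards.  Node
    ages are drawn tip-rootward from the piecewise-exponential waiting-time
    distribution implied by the lineage-count-weighted hazard, which matches
    the two-rate likelihood exactly; the topology is a uniform random join.
    """
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    if rate_old <= 0 or rate_young <= 0:
        raise ValueError("rates must be > 0")
    if shift_age <= 0:
        raise ValueError("shift_age must be > 0")
    rng = _as_rng(seed)
    ages = np.empty(n_tips - 1)
    t = 0.0
    for idx, j in enumerate(range(n_tips, 1, -1)):
        target = rng.exponential(1.0)  # integrated hazard to the next node
        if t < shift_age:
            hazard_to_shift = j * rate_young * (shift_age - t)
            if target <= hazard_to_shift:
                t = t + target / (j * rate_young)
            else:
                t = shift_age + (target - hazard_to_shift) / (j * rate_old)
        else:
            t = t + target / (j * rate_old)
        ages[idx] = t
    return _tree_from_ages(np.sort(ages)[::-1], rng)


# ---------------------------------------------------------------------------
# Genus richness
# ---------------------------------------------------------------------------

def simulate_richness(tips, total_target: int, seed=None,
                      sampled_per_genus: int = 1) -> pd.DataFrame:
    """Right-skewed per-genus species totals summing to ``total_target``.

    Totals are geometric draws (heavy right tail, mimicking hyperdiverse
    genera such as *Calamus* alongside many small or monotypic genera)
    adjusted minimally so that the family total is exact.  By default one
    species per genus is sampled, the genus-level design of the study.
    """
    labels = list(tips.tip_labels) if isinstance(tips, Chronogram) else list(tips)
    n = len(labels)
    if total_target < n:
        raise ValueError("total_target must be >= number of genera")
    rng = _as_rng(seed)
    p = min(1.0, n / total_target)
    totals = rng.geometric(p, size=n).astype(int)
    diff = int(total_target - totals.sum())
    while diff != 0:
        i = int(rng.integers(n))
        if diff > 0:
            totals[i] += 1
            diff -= 1
        elif totals[i] > max(1, sampled_per_genus):
            totals[i] -= 1
            diff += 1
    sampled = np.minimum(totals, sampled_per_genus)
    return pd.DataFrame({"genus": labels, "total": totals, "sampled": sampled})


# ---------------------------------------------------------------------------
# Discrete character simulation
# ---------------------------------------------------------------------------

def simulate_mk_states(tree: Chronogram, q: float, k: int = 3, seed=None,
                       root_state: int | None = None) -> dict[str, int]:
    """Evolve an Mk1 character down the tree; returns tip -> state.

    The root state is uniform over the k states unless fixed; each branch
    transition is sampled directly from the closed-form Mk1 probabilities.
    """
    if q < 0 or k < 2:
        raise ValueError("need q >= 0 and k >= 2")
    rng = _as_rng(seed)
    state: dict[int, int] = {}
    tips: dict[str, int] = {}
    for node in tree.preorder():
        if node.parent_node is None:
            s = int(rng.integers(k)) if root_state is None else int(root_state)
        else:
            t = max(0.0, node.parent_node.age - node.age)
            P = mk_transition_matrix(q, t, k)
            s = int(rng.choice(k, p=P[state[id(node.parent_node)]]))
        state[id(node)] = s
        if node.is_leaf():
            tips[node.taxon.label] = s
    return tips


# ---------------------------------------------------------------------------
# DEC range simulation
# ---------------------------------------------------------------------------

def simulate_dec_ranges(tree: Chronogram, d: float, e: float,
                        epochs: EpochModel | None = None,
                        space: RangeSpace | None = None,
                        seed=None, root_range=None,
                        max_retries: int = 100) -> dict[str, frozenset]:
    """Forward DEC simulation; returns tip -> area set.

    Anagenetic dispersal/extirpation events are drawn from the epoch-aware
    generator along each branch; at each node a cladogenetic inheritance
    scenario is sampled uniformly from the allowed set.  A branch whose
    lineage hits the null range is resampled (up to ``max_retries``), since
    the study's tips are all extant and occupy at least one area.
    """
    if space is None:
        space = build_range_space(7, 2)
    if epochs is None:
        epochs = EpochModel.uniform(space.n_areas)
    if epochs.oldest < tree.crown_age:
        raise ValueError("epochs do not cover the crown age")
    rng = _as_rng(seed)
    Qs = [dec_generator(space, d, e, ep.multipliers) for ep in epochs.epochs]

    if root_range is None:
        root_idx = int(rng.integers(1, space.n_states))
    else:
        root_idx = space.index(root_range)
        if root_idx == 0:
            raise ValueError("root range must be non-empty")

    def evolve_branch(start_idx: int, t_old: float, t_young: float) -> int:
        for _ in range(max_retries):
            idx = start_idx
            dead = False
            for epoch_idx, dt in epochs.segments(t_old, t_young):
                Q = Qs[epoch_idx]
                remaining = dt
                while True:
                    rate = -Q[idx, idx]
                    if rate <= 0:
                        break
                    w = rng.exponential(1.0 / rate)
                    if w >= remaining:
                        break
                    remaining -= w
                    probs = Q[idx].copy()
                    probs[idx] = 0.0
                    probs /= probs.sum()
                    idx = int(rng.choice(space.n_states, p=probs))
                    if idx == 0:
                        dead = True
                        break
                if dead:
                    break
            if not dead:
                return idx
        raise RuntimeError(
            f"branch hit the null range in all {max_retries} resamples; "
            "extirpation rate too high relative to branch lengths"
        )

    ranges: dict[int, int] = {}
    tips: dict[str, frozenset] = {}
    for node in tree.preorder():
        if node.parent_node is None:
            ranges[id(node)] = root_idx
        else:
            parent_post = ranges[id(node)]  # set below at the parent's split
            t_old, t_young = node.parent_node.age, node.age
            if t_old > t_young:
                ranges[id(node)] = evolve_branch(parent_post, t_old, t_young)
        if node.is_leaf():
            tips[node.taxon.label] = space.ranges[ranges[id(node)]]
        else:
            scenarios = cladogenesis_scenarios(space.ranges[ranges[id(node)]])
            left, right, _ = scenarios[int(rng.integers(len(scenarios)))]
            ch = node.child_nodes()
            ranges[id(ch[0])] = space.index(left)
            ranges[id(ch[1])] = space.index(right)
    return tips
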