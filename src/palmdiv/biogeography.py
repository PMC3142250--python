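"""Time-stratified dispersal-extinction-cladogenesis (DEC) model.

Geographic ranges are subsets of a fixed set of areas (by default the seven
continental-scale units A-G used for palms, with ranges capped at two areas
because each area is already continent-sized).  Along branches, ranges gain
areas by dispersal at rate ``d`` (modulated by per-epoch dispersal
multipliers between pairs of areas) and lose areas by extirpation at rate
``e``.  At speciation the ancestral range is partitioned between the two
daughters under the standard DEC scenario set: a singleton range is
inherited by both daughters; a widespread range either splits by vicariance
(one area versus the rest) or by subset sympatry (one area versus the full
range).  The null (empty) range is carried as an absorbing state of the
anagenetic process but never participates in cladogenesis and is excluded
from the root summation.

The time-stratified variant replaces the single dispersal-multiplier matrix
with a piecewise-constant sequence of matrices over geological epochs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .trees import Chronogram

__all__ = [
    "RangeSpace",
    "Epoch",
    "EpochModel",
    "DECResult",
    "build_range_space",
    "dec_generator",
    "branch_transition",
    "cladogenesis_scenarios",
    "dec_loglik",
    "fit_dec",
    "read_ranges_csv",
    "example_m1_epochs",
]

DEFAULT_AREAS = ("A", "B", "C", "D", "E", "F", "G")


@dataclass(frozen=True)
class RangeSpace:
    """Canonical enumeration of geographic ranges.

    The state list starts with the null range (index 0) followed by all
    non-empty subsets of the areas up to ``max_size``, ordered by size then
    lexicographically.
    """

    areas: tuple[str, ...]
    max_size: int
    ranges: tuple[frozenset, ...] = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.areas)
        if not (1 <= self.max_size <= n):
            raise ValueError("max_size must lie in [1, n_areas]")
        if len(set(self.areas)) != n:
            raise ValueError("area labels must be unique")
        states: list[frozenset] = [frozenset()]
        for size in range(1, self.max_size + 1):
            for combo in itertools.combinations(self.areas, size):
                states.append(frozenset(combo))
        object.__setattr__(self, "ranges", tuple(states))

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_states(self) -> int:
        return len(self.ranges)

    def index(self, rng: frozenset | set | str) -> int:
        if isinstance(rng, str):
            rng = frozenset(rng)
        rng = frozenset(rng)
        try:
            return self.ranges.index(rng)
        except ValueError:
            raise KeyError(f"range {sorted(rng)} not in state space") from None

    def label(self, idx: int) -> str:
        return "".join(sorted(self.ranges[idx])) or "0"


def build_range_space(n_areas: int = 7, max_size: int = 2,
                      areas: tuple[str, ...] | None = None) -> RangeSpace:
    """Enumerate the null range plus all non-empty ranges of size <= max."""
    if areas is None:
        if n_areas <= 26:
            areas = tuple(chr(ord("A") + i) for i in range(n_areas))
        else:  # pragma: no cover - beyond any realistic analysis
            areas = tuple(f"A{i}" for i in range(n_areas))
    return RangeSpace(areas=tuple(areas), max_size=max_size)


@dataclass(frozen=True)
class Epoch:
    """One time slice with its area-by-area dispersal multiplier matrix.

    ``start`` (older) and ``end`` (younger) are ages in Ma; ``start`` may be
    ``inf`` for the oldest epoch.  Multipliers scale the base dispersal rate
    between ordered pairs of areas and must be positive.
    """

    start: float
    end: float
    multipliers: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.multipliers, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("multiplier matrix must be square")
        if np.any(m <= 0):
            raise ValueError("dispersal multipliers must be positive")
        if not self.start > self.end:
            raise ValueError("epoch start must be older than its end")
        object.__setattr__(self, "multipliers", m)


@dataclass(frozen=True)
class EpochModel:
    """Ordered, contiguous epochs covering [oldest boundary, 0]."""

    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        eps = tuple(self.epochs)
        if not eps:
            raise ValueError("need at least one epoch")
        if eps[-1].end != 0.0:
            raise ValueError("youngest epoch must end at the present (0)")
        for older, younger in zip(eps, eps[1:]):
            if older.end != younger.start:
                raise ValueError("epochs must be contiguous and ordered old to young")
        n = eps[0].multipliers.shape[0]
        if any(e.multipliers.shape[0] != n for e in eps):
            raise ValueError("all epochs must share the same area count")
        object.__setattr__(self, "epochs", eps)

    @property
    def n_areas(self) -> int:
        return self.epochs[0].multipliers.shape[0]

    @property
    def oldest(self) -> float:
        return self.epochs[0].start

    @classmethod
    def uniform(cls, n_areas: int, start: float = np.inf) -> "EpochModel":
        """Single-epoch model with all multipliers 1 (the unconstrained M0)."""
        return cls((Epoch(start, 0.0, np.ones((n_areas, n_areas))),))

    @classmethod
    def from_dict(cls, spec: dict) -> "EpochModel":
        eps = []
        for item in spec["epochs"]:
            start = float(item["start"]) if item["start"] != "inf" else np.inf
            eps.append(Epoch(start, float(item["end"]),
                             np.asarray(item["multipliers"], dtype=float)))
        return cls(tuple(eps))

    def to_dict(self) -> dict:
        return {
            "epochs": [
                {
                    "start": "inf" if np.isinf(e.start) else e.start,
                    "end": e.end,
                    "multipliers": e.multipliers.tolist(),
                }
                for e in self.epochs
            ]
        }

    def segments(self, t_old: float, t_young: float) -> list[tuple[int, float]]:
        """Split a branch interval into (epoch index, duration) pieces, old first."""
        if not t_old > t_young:
            raise ValueError("t_old must exceed t_young")
        if t_old > self.oldest or t_young < 0:
            raise ValueError(
                f"branch [{t_old}, {t_young}] not covered by epochs "
                f"reaching back to {self.oldest}"
            )
        out = []
        for i, ep in enumerate(self.epochs):
            lo = max(t_young, ep.end)
            hi = min(t_old, ep.start)
            if hi > lo:
                out.append((i, hi - lo))
        return out


def example_m1_epochs(areas: tuple[str, ...] = DEFAULT_AREAS) -> EpochModel:
    """An illustrative five-epoch constrained dispersal model (M1).

    The published constrained analysis used five geological time frames
    with pairwise dispersal multipliers drawn from the levels
    {0.01, 0.25, 0.5, 0.75, 1}; the exact matrices are not reproducible
    from the main text, so this config is a documented, synthetic example
    built from the same multiplier levels and a plausible
    Laurasia-centred connectivity history.  It is intended for exercising
    the time-stratified machinery, not as the published model.
    """
    n = len(areas)

    def mat(default: float, pairs: dict[tuple[int, int], float]) -> np.ndarray:
        m = np.full((n, n), default)
        np.fill_diagonal(m, 1.0)
        for (i, j), v in pairs.items():
            m[i, j] = v
            m[j, i] = v
        return m

    # Areas: A South America, B North/Central America, C Africa,
    # D Indian Ocean islands, E India, F Eurasia, G Pacific.
    epochs = (
        # Mid/Late Cretaceous: Laurasian corridor (B-F) open, southern
        # continents separating.
        Epoch(np.inf, 65.0, mat(0.01, {(1, 5): 1.0, (0, 1): 0.5, (0, 2): 0.25,
                                       (2, 4): 0.25, (3, 4): 0.5})),
        # Paleocene-Eocene: boreotropical connection still strong.
        Epoch(65.0, 34.0, mat(0.01, {(1, 5): 0.75, (0, 1): 0.5, (2, 5): 0.5,
                                     (4, 5): 0.75, (3, 4): 0.25})),
        # Oligocene: cooling severs the northern corridor.
        Epoch(34.0, 23.0, mat(0.01, {(1, 5): 0.25, (0, 1): 0.5, (2, 5): 0.25,
                                     (4, 5): 1.0, (5, 6): 0.5})),
        # Miocene: Sunda/Sahul convergence, Indian Ocean stepping stones.
        Epoch(23.0, 5.0, mat(0.01, {(0, 1): 0.75, (2, 3): 0.5, (3, 4): 0.5,
                                    (4, 5): 1.0, (5, 6): 0.75})),
        # Plio-Pleistocene: modern configuration, Panama closed.
        Epoch(5.0, 0.0, mat(0.01, {(0, 1): 1.0, (2, 3): 0.5, (4, 5): 1.0,
                                   (5, 6): 1.0})),
    )
    return EpochModel(epochs)


# ---------------------------------------------------------------------------
# Anagenetic process
# ---------------------------------------------------------------------------

def dec_generator(space: RangeSpace, d: float, e: float,
                  multipliers: np.ndarray | None = None) -> np.ndarray:
    """Instantaneous rate matrix over ranges for one epoch.

    Dispersal adds area ``b`` to range ``R`` at rate ``d * sum_{a in R}
    m[a, b]`` (only while ``|R| < max_size``); extirpation removes each area
    of ``R`` at rate ``e`` (singletons decay to the absorbing null range).
    """
    if d < 0 or e < 0:
        raise ValueError("d and e must be >= 0")
    n = space.n_areas
    if multipliers is None:
        multipliers = np.ones((n, n))
    m = np.asarray(multipliers, dtype=float)
    if m.shape != (n, n):
        raise ValueError(f"multiplier matrix must be {n}x{n}, got {m.shape}")
    area_idx = {a: i for i, a in enumerate(space.areas)}
    S = space.n_states
    Q = np.zeros((S, S))
    for i, rng in enumerate(space.ranges):
        if not rng:
            continue  # null range is absorbing
        if len(rng) < space.max_size:
            for b in space.areas:
                if b in rng:
                    continue
                target = rng | {b}
                rate = d * sum(m[area_idx[a], area_idx[b]] for a in rng)
                if rate > 0:
                    Q[i, space.index(target)] += rate
        for a in rng:
            Q[i, space.index(rng - {a})] += e
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def _propagator(Q: np.ndarray, t: float) -> np.ndarray:
    return scipy.linalg.expm(Q * t)


class _EpochPropagators:
    """Eigendecomposition-backed exp(Q*t) for each epoch's generator.

    One decomposition per epoch per (d, e) evaluation; each branch segment
    then costs two small matrix products.  Falls back to ``expm`` when the
    generator is too close to defective for spectral reconstruction.
    """

    def __init__(self, space: RangeSpace, d: float, e: float, epochs: EpochModel):
        self.Qs = [dec_generator(space, d, e, ep.multipliers) for ep in epochs.epochs]
        self._spectral = []
        for Q in self.Qs:
            try:
                w, U = np.linalg.eig(Q)
                Uinv = np.linalg.inv(U)
                err = np.abs(U @ np.diag(w) @ Uinv - Q).max()
                ok = err < 1e-9 * max(1.0, np.abs(Q).max())
            except np.linalg.LinAlgError:  # pragma: no cover - degenerate
                ok = False
                w = U = Uinv = None
            self._spectral.append((ok, w, U, Uinv))

    def expQt(self, epoch_idx: int, t: float) -> np.ndarray:
        ok, w, U, Uinv = self._spectral[epoch_idx]
        if ok:
            P = (U * np.exp(w * t)) @ Uinv
            P = np.real(P)
        else:  # pragma: no cover - rare fallback
            P = _propagator(self.Qs[epoch_idx], t)
        np.clip(P, 0.0, None, out=P)
        return P


def branch_transition(space: RangeSpace, d: float, e: float, epochs: EpochModel,
                      t_old: float, t_young: float) -> np.ndarray:
    """Transition probability matrix along a branch from ``t_old`` to ``t_young``.

    Ordered product of per-epoch matrix exponentials over the sub-intervals
    the branch crosses (oldest first).
    """
    props = _EpochPropagators(space, d, e, epochs)
    P = np.eye(space.n_states)
    for epoch_idx, dt in epochs.segments(t_old, t_young):
        P = P @ props.expQt(epoch_idx, dt)
    return P


# ---------------------------------------------------------------------------
# Cladogenesis
# ---------------------------------------------------------------------------

def cladogenesis_scenarios(rng: frozenset | set | str) -> list[tuple[frozenset, frozenset, float]]:
    """Allowed (left, right, weight) range-inheritance scenarios at a node.

    Singleton ranges are inherited identically by both daughters.  A
    widespread range splits either by vicariance (one area versus the
    remainder) or by subset sympatry (one area versus the full range), with
    both left/right orders enumerated and uniform weights summing to 1.
    """
    if isinstance(rng, str):
        rng = frozenset(rng)
    rng = frozenset(rng)
    if not rng:
        raise ValueError("the null range cannot speciate")
    if len(rng) == 1:
        return [(rng, rng, 1.0)]
    raw: list[tuple[frozenset, frozenset]] = []
    for a in sorted(rng):
        single = frozenset({a})
        rest = rng - single
        raw.append((single, rest))       # vicariance
        raw.append((rest, single))
        raw.append((single, rng))        # subset sympatry
        raw.append((rng, single))
    # Deduplicate while preserving order (relevant only for 2-area ranges,
    # where vicariance "rest" is itself a singleton).
    seen = set()
    scenarios = []
    for pair in raw:
        if pair not in seen:
            seen.add(pair)
            scenarios.append(pair)
    w = 1.0 / len(scenarios)
    return [(l, r, w) for l, r in scenarios]


def _scenario_tables(space: RangeSpace):
    """Flattened (parent, left, right, weight) index arrays for fast combine."""
    parents, lefts, rights, weights = [], [], [], []
    for i, rng in enumerate(space.ranges):
        if not rng:
            continue
        for l, r, w in cladogenesis_scenarios(rng):
            parents.append(i)
            lefts.append(space.index(l))
            rights.append(space.index(r))
            weights.append(w)
    return (np.array(parents), np.array(lefts), np.array(rights),
            np.array(weights))


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def _validate_tips(space: RangeSpace, tree: Chronogram, tip_ranges: dict) -> dict[str, int]:
    out = {}
    missing = [t for t in tree.tip_labels if t not in tip_ranges]
    if missing:
        raise ValueError(f"tips without range coding: {missing}")
    for label in tree.tip_labels:
        rng = tip_ranges[label]
        if isinstance(rng, str):
            rng = frozenset(rng)
        rng = frozenset(rng)
        if not rng:
            raise ValueError(f"tip {label!r} has an empty range")
        if len(rng) > space.max_size:
            raise ValueError(
                f"tip {label!r} range {sorted(rng)} exceeds the maximum range "
                f"size {space.max_size}; recode it to a putative ancestral "
                "area (as done for widespread genera such as Cocos)"
            )
        out[label] = space.index(rng)
    return out


class _DecEngine:
    """Pruning over range states with cached tree traversal structures."""

    def __init__(self, tree: Chronogram, tip_ranges: dict, space: RangeSpace,
                 epochs: EpochModel):
        if epochs.n_areas != space.n_areas:
            raise ValueError("epoch model and range space disagree on area count")
        if epochs.oldest < tree.crown_age:
            raise ValueError("epochs do not cover the crown age")
        self.space = space
        self.epochs = epochs
        self.tree = tree
        self.tip_idx = _validate_tips(space, tree, tip_ranges)
        self.sc_parent, self.sc_left, self.sc_right, self.sc_w = _scenario_tables(space)
        # Postorder node list with per-node metadata.
        self.nodes = list(tree.postorder())
        self.node_pos = {id(n): i for i, n in enumerate(self.nodes)}
        self.root_pos = self.node_pos[id(tree.tree.seed_node)]
        self.branch_segments = []
        for n in self.nodes:
            if n.parent_node is None:
                self.branch_segments.append(None)
            elif n.parent_node.age <= n.age:
                self.branch_segments.append([])  # zero-length edge
            else:
                self.branch_segments.append(
                    epochs.segments(n.parent_node.age, n.age))

    def _branch_matrices(self, props: _EpochPropagators) -> list[np.ndarray | None]:
        S = self.space.n_states
        eye = np.eye(S)
        out: list[np.ndarray | None] = [None] * len(self.branch_segments)
        # Branches lying within one epoch (all of them under M0) share that
        # epoch's eigendecomposition, so their propagators batch into a
        # single einsum; multi-epoch branches multiply segment propagators.
        groups: dict[int, list[tuple[int, float]]] = {}
        for i, segs in enumerate(self.branch_segments):
            if segs is None:
                continue
            if len(segs) == 0:
                out[i] = eye
            elif len(segs) == 1:
                groups.setdefault(segs[0][0], []).append((i, segs[0][1]))
            else:
                P = eye
                for epoch_idx, dt in segs:
                    P = P @ props.expQt(epoch_idx, dt)
                out[i] = P
        for epoch_idx, items in groups.items():
            ok, w, U, Uinv = props._spectral[epoch_idx]
            if ok:
                ts = np.array([t for _, t in items])
                E = np.exp(np.multiply.outer(ts, w))
                Ps = np.real((U[None, :, :] * E[:, None, :]) @ Uinv)
                np.clip(Ps, 0.0, None, out=Ps)
                for (i, _), P in zip(items, Ps):
                    out[i] = P
            else:  # pragma: no cover - rare fallback
                for i, dt in items:
                    out[i] = props.expQt(epoch_idx, dt)
        return out

    def _combine(self, Dl: np.ndarray, Dr: np.ndarray) -> np.ndarray:
        vals = self.sc_w * Dl[self.sc_left] * Dr[self.sc_right]
        return np.bincount(self.sc_parent, weights=vals,
                           minlength=self.space.n_states)

    def inside(self, d: float, e: float):
        """Per-node conditional likelihoods (scaled) and the log-likelihood.

        Returns (inside vectors, down vectors, branch matrices, log scaling
        per node, total logL under the flat root sum).
        """
        props = _EpochPropagators(self.space, d, e, self.epochs)
        Ps = self._branch_matrices(props)
        S = self.space.n_states
        L = [None] * len(self.nodes)
        down = [None] * len(self.nodes)  # likelihood propagated to branch top
        logscale = np.zeros(len(self.nodes))
        for i, node in enumerate(self.nodes):
            if node.is_leaf():
                vec = np.zeros(S)
                vec[self.tip_idx[node.taxon.label]] = 1.0
            else:
                ch = node.child_nodes()
                cl, cr = self.node_pos[id(ch[0])], self.node_pos[id(ch[1])]
                vec = self._combine(down[cl], down[cr])
                logscale[i] = logscale[cl] + logscale[cr]
            mx = vec.max()
            if mx <= 0:
                return L, down, Ps, logscale, -np.inf
            vec = vec / mx
            logscale[i] += np.log(mx)
            L[i] = vec
            if Ps[i] is not None:
                down[i] = Ps[i] @ vec
            elif node.parent_node is not None:
                down[i] = vec  # zero-length edge
        root_vec = L[self.root_pos].copy()
        root_vec[0] = 0.0  # null range excluded from the root sum
        total = root_vec.sum()
        if total <= 0:
            return L, down, Ps, logscale, -np.inf
        logL = np.log(total) + logscale[self.root_pos]
        return L, down, Ps, logscale, logL

    def loglik(self, d: float, e: float, root_prior: str = "flat_sum") -> float:
        L, _, _, logscale, logL = self.inside(d, e)
        if root_prior == "uniform" and np.isfinite(logL):
            logL -= np.log(self.space.n_states - 1)
        return float(logL)

    def marginals(self, d: float, e: float):
        """Outside-inside marginal range probabilities per node.

        A node's marginal describes its range immediately before its own
        cladogenetic split (for internal nodes) or at the tip (for leaves).
        Also returns per-node ranked cladogenetic scenarios at the root of
        each split.
        """
        L, down, Ps, logscale, logL = self.inside(d, e)
        if not np.isfinite(logL):
            raise ValueError("data have zero likelihood at these rates")
        S = self.space.n_states
        out = [None] * len(self.nodes)
        root = self.nodes[self.root_pos]
        prior = np.ones(S)
        prior[0] = 0.0
        out[self.root_pos] = prior
        for i in reversed(range(len(self.nodes))):
            node = self.nodes[i]
            if node.is_leaf():
                continue
            ch = node.child_nodes()
            cl, cr = self.node_pos[id(ch[0])], self.node_pos[id(ch[1])]
            for child_pos, sib_pos in ((cl, cr), (cr, cl)):
                # Outside at the top of the child's branch: route the
                # parent's outside value through the scenarios whose
                # child-side range matches, weighting by the sibling's
                # propagated inside likelihood.
                side = self.sc_left if child_pos == cl else self.sc_right
                other = self.sc_right if child_pos == cl else self.sc_left
                vals = (out[i][self.sc_parent] * self.sc_w
                        * down[sib_pos][other])
                top = np.bincount(side, weights=vals, minlength=S)
                P = Ps[child_pos]
                out[child_pos] = top if P is None else top @ P
        marg = {}
        for i, node in enumerate(self.nodes):
            v = out[i] * L[i]
            v[0] = 0.0
            s = v.sum()
            marg[i] = v / s if s > 0 else v
        # Ranked split scenarios per internal node.
        splits = {}
        for i, node in enumerate(self.nodes):
            if node.is_leaf():
                continue
            ch = node.child_nodes()
            cl, cr = self.node_pos[id(ch[0])], self.node_pos[id(ch[1])]
            vals = (out[i][self.sc_parent] * self.sc_w
                    * down[cl][self.sc_left] * down[cr][self.sc_right])
            tot = vals.sum()
            if tot > 0:
                vals = vals / tot
            order = np.argsort(vals)[::-1]
            splits[i] = [
                (self.space.label(self.sc_parent[k]),
                 self.space.label(self.sc_left[k]),
                 self.space.label(self.sc_right[k]),
                 float(vals[k]))
                for k in order[:8] if vals[k] > 1e-12
            ]
        return marg, splits, logL


def dec_loglik(tree: Chronogram, tip_ranges: dict, d: float, e: float,
               epochs: EpochModel | None = None,
               space: RangeSpace | None = None,
               root_prior: str = "flat_sum") -> float:
    """DEC log-likelihood of tip ranges on a chronogram.

    ``root_prior`` is either ``"flat_sum"`` (unweighted sum over non-null
    root ranges, the Lagrange convention) or ``"uniform"``.
    """
    if space is None:
        space = build_range_space(7, 2)
    if epochs is None:
        epochs = EpochModel.uniform(space.n_areas)
    engine = _DecEngine(tree, tip_ranges, space, epochs)
    return engine.loglik(d, e, root_prior=root_prior)


@dataclass
class DECResult:
    d: float
    e: float
    loglik: float
    root_prior: str
    converged: bool
    node_marginals: dict  # frozenset(tip labels) -> {range label: prob}
    node_splits: dict     # frozenset(tip labels) -> ranked (parent, l, r, prob)
    space: RangeSpace
    epochs: EpochModel

    def marginal_for_clade(self, tips) -> dict[str, float]:
        return self.node_marginals[frozenset(tips)]

    def most_likely_range(self, tips) -> str:
        m = self.marginal_for_clade(tips)
        return max(m, key=m.get)


def fit_dec(tree: Chronogram, tip_ranges: dict,
            epochs: EpochModel | None = None,
            space: RangeSpace | None = None,
            root_prior: str = "flat_sum",
            starts: tuple[tuple[float, float], ...] = ((0.01, 0.01),
                                                       (0.1, 0.01),
                                                       (0.005, 0.05))) -> DECResult:
    """Maximum-likelihood DEC fit with node marginals at the optimum.

    Rates are optimized on the log scale with a derivative-free simplex from
    several starting points; the best optimum is kept and non-convergence is
    flagged rather than raised.
    """
    from scipy.optimize import minimize

    if space is None:
        space = build_range_space(7, 2)
    if epochs is None:
        epochs = EpochModel.uniform(space.n_areas)
    engine = _DecEngine(tree, tip_ranges, space, epochs)

    bounds = (-14.0, 4.0)

    def neg(params):
        ld, le = params
        if not (bounds[0] <= ld <= bounds[1] and bounds[0] <= le <= bounds[1]):
            return 1e12
        val = engine.loglik(np.exp(ld), np.exp(le), root_prior=root_prior)
        return 1e12 if not np.isfinite(val) else -val

    best = None
    converged = False
    for d0, e0 in starts:
        res = minimize(neg, x0=np.log([d0, e0]), method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    d_hat, e_hat = np.exp(best.x)
    marg, splits, logL = engine.marginals(d_hat, e_hat)
    if root_prior == "uniform":
        logL -= np.log(space.n_states - 1)

    def clade_key(node):
        return frozenset(t.taxon.label for t in node.leaf_iter())

    node_marginals = {}
    node_splits = {}
    for i, node in enumerate(engine.nodes):
        key = clade_key(node)
        node_marginals[key] = {
            space.label(j): float(p) for j, p in enumerate(marg[i]) if p > 1e-12
        }
        if i in splits:
            node_splits[key] = splits[i]
    return DECResult(d=float(d_hat), e=float(e_hat), loglik=float(logL),
                     root_prior=root_prior, converged=converged,
                     node_marginals=node_marginals, node_splits=node_splits,
                     space=space, epochs=epochs)


def read_ranges_csv(path, space: RangeSpace | None = None) -> dict[str, frozenset]:
    """Read a genus,areas CSV where areas is a letter string such as "AB"."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "genus" not in cols or "areas" not in cols:
        raise ValueError("range CSV needs 'genus' and 'areas' columns")
    out = {}
    for _, row in df.iterrows():
        out[str(row["genus"])] = frozenset(str(row["areas"]).strip())
    if space is not None:
        for genus, rng in out.items():
            for a in rng:
                if a not in space.areas:
                    raise ValueError(f"{genus}: unknown area {a!r}")
    return out
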