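"""Mk1 ancestral-state machinery for discrete biome characters.

The biome of each genus is coded as one of three states (0 = tropical rain
forest, 1 = mangrove, 2 = non-TRF), with genera spanning TRF and non-TRF
biomes coded as the ambiguous state set {0, 2}.  Evolution follows the
symmetric k-state Markov model with a single rate parameter q (Mk1): every
off-diagonal transition occurs at rate q, so the transition probabilities
have the closed form

    P_ii(t) = 1/k + (k-1)/k * exp(-k q t)
    P_ij(t) = 1/k * (1 - exp(-k q t))        (i != j)

Likelihoods are computed by Felsenstein pruning with a uniform root prior
(the Mesquite Mk1 convention); ancestral "proportional likelihoods" are the
per-node marginal state probabilities normalized to sum to one.  A
tip-randomization test of phylogenetic signal compares the observed Fitch
parsimony step count against a permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .trees import Chronogram

__all__ = [
    "mk_transition_matrix",
    "mk_loglik",
    "fit_mk",
    "marginal_ancestral_states",
    "fitch_steps",
    "tip_randomization_test",
    "read_states_csv",
    "MkFit",
    "AncestralStateReport",
    "TipRandomizationResult",
    "AMBIGUOUS_TRF_NONTRF",
]

#: Coding used for genera occurring in both TRF and non-TRF biomes: the
#: mangrove state is not an admissible resolution of the ambiguity.
AMBIGUOUS_TRF_NONTRF = frozenset({0, 2})

_Q_BOUNDS = (1e-8, 1e3)


def mk_transition_matrix(q: float, t: float, k: int = 3) -> np.ndarray:
    """Closed-form Mk1 transition probability matrix for one branch."""
    if q < 0 or t < 0:
        raise ValueError("q and t must be >= 0")
    if k < 2:
        raise ValueError("need k >= 2 states")
    decay = np.exp(-k * q * t)
    off = (1.0 - decay) / k
    P = np.full((k, k), off)
    np.fill_diagonal(P, 1.0 / k + (k - 1) / k * decay)
    return P


def _normalize_states(tree: Chronogram, states: dict, k: int) -> dict[str, frozenset]:
    out = {}
    missing = [t for t in tree.tip_labels if t not in states]
    if missing:
        raise ValueError(f"tips without state coding: {missing}")
    for label in tree.tip_labels:
        s = states[label]
        if isinstance(s, (int, np.integer)):
            s = frozenset({int(s)})
        else:
            s = frozenset(int(x) for x in s)
        if not s or not s <= set(range(k)):
            raise ValueError(f"tip {label!r}: state set {sorted(s)} invalid for k={k}")
        out[label] = s
    return out


def _tip_partials(state_set: frozenset, k: int) -> np.ndarray:
    vec = np.zeros(k)
    for s in state_set:
        vec[s] = 1.0
    return vec


def _pruning(tree: Chronogram, states: dict[str, frozenset], q: float, k: int):
    """Postorder conditional likelihoods; returns (vectors, down, log-scalers)."""
    nodes = list(tree.postorder())
    pos = {id(n): i for i, n in enumerate(nodes)}
    L: list[np.ndarray] = [None] * len(nodes)
    down: list[np.ndarray] = [None] * len(nodes)
    logscale = np.zeros(len(nodes))
    for i, node in enumerate(nodes):
        if node.is_leaf():
            vec = _tip_partials(states[node.taxon.label], k)
        else:
            vec = np.ones(k)
            for ch in node.child_nodes():
                vec = vec * down[pos[id(ch)]]
            logscale[i] = sum(logscale[pos[id(ch)]] for ch in node.child_nodes())
        mx = vec.max()
        if mx <= 0:
            return nodes, pos, L, down, logscale, -np.inf
        vec = vec / mx
        logscale[i] += np.log(mx)
        L[i] = vec
        if node.parent_node is not None:
            t = max(0.0, node.parent_node.age - node.age)
            down[i] = mk_transition_matrix(q, t, k) @ vec
    root = pos[id(tree.tree.seed_node)]
    logL = np.log(L[root].mean()) + logscale[root]  # uniform 1/k root prior
    return nodes, pos, L, down, logscale, float(logL)


def mk_loglik(tree: Chronogram, states: dict, q: float, k: int = 3) -> float:
    """Mk1 log-likelihood of the tip states under rate ``q``.

    Ambiguous tips contribute a partial likelihood of 1 for each admissible
    state; the root state is drawn from the uniform distribution over the k
    states.
    """
    st = _normalize_states(tree, states, k)
    return _pruning(tree, st, q, k)[-1]


@dataclass
class MkFit:
    q: float
    loglik: float
    at_bound: str | None  # None, "lower" or "upper"


def fit_mk(tree: Chronogram, states: dict, k: int = 3,
           bounds: tuple[float, float] = _Q_BOUNDS) -> MkFit:
    """One-dimensional bounded ML estimate of the Mk1 rate (log scale)."""
    st = _normalize_states(tree, states, k)

    def neg(logq):
        return -_pruning(tree, st, float(np.exp(logq)), k)[-1]

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    q_hat = float(np.exp(res.x))
    loglik = float(-res.fun)
    # A likelihood flat out to a bound (invariant characters, or saturating
    # data such as a two-tip tree with opposite states) means the MLE sits
    # on that bound, even when the optimizer parks inside the plateau.
    at_bound = None
    if -neg(hi) >= loglik - 1e-6:
        at_bound, q_hat, loglik = "upper", bounds[1], float(-neg(hi))
    elif -neg(lo) >= loglik - 1e-6:
        at_bound, q_hat, loglik = "lower", bounds[0], float(-neg(lo))
    return MkFit(q=q_hat, loglik=loglik, at_bound=at_bound)


@dataclass
class AncestralStateReport:
    """Per-node proportional likelihoods of each ancestral state.

    Nodes are keyed by the frozenset of descendant tip labels.  Each value
    is a length-k probability vector summing to one.
    """

    q: float
    loglik: float
    k: int
    marginals: dict  # frozenset -> np.ndarray

    def for_clade(self, tips) -> np.ndarray:
        return self.marginals[frozenset(tips)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, probs in self.marginals.items():
            row = {"clade": ";".join(sorted(key)), "n_tips": len(key)}
            row.update({f"state_{s}": float(p) for s, p in enumerate(probs)})
            rows.append(row)
        return pd.DataFrame(rows).sort_values("n_tips", ascending=False,
                                              ignore_index=True)


def marginal_ancestral_states(tree: Chronogram, states: dict, q: float,
                              k: int = 3) -> AncestralStateReport:
    """Marginal (outside-inside) ancestral state probabilities at every node."""
    st = _normalize_states(tree, states, k)
    nodes, pos, L, down, logscale, logL = _pruning(tree, st, q, k)
    if not np.isfinite(logL):
        raise ValueError("tip data have zero likelihood under this rate")
    outside: list[np.ndarray] = [None] * len(nodes)
    root = pos[id(tree.tree.seed_node)]
    outside[root] = np.full(k, 1.0 / k)
    for i in reversed(range(len(nodes))):
        node = nodes[i]
        if node.is_leaf():
            continue
        children = node.child_nodes()
        for ch in children:
            ci = pos[id(ch)]
            top = outside[i].copy()
            for sib in children:
                if sib is not ch:
                    top = top * down[pos[id(sib)]]
            t = max(0.0, node.age - ch.age)
            outside[ci] = top @ mk_transition_matrix(q, t, k)
    marginals = {}
    for i, node in enumerate(nodes):
        v = outside[i] * L[i]
        s = v.sum()
        key = frozenset(t.taxon.label for t in node.leaf_iter())
        marginals[key] = v / s
    return AncestralStateReport(q=float(q), loglik=logL, k=k, marginals=marginals)


def fitch_steps(tree: Chronogram, states: dict, k: int = 3) -> int:
    """Minimum number of state changes (Fitch parsimony with state sets)."""
    st = _normalize_states(tree, states, k)
    steps = 0
    sets: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf():
            sets[id(node)] = st[node.taxon.label]
        else:
            ch = node.child_nodes()
            acc = sets[id(ch[0])]
            for other in ch[1:]:
                inter = acc & sets[id(other)]
                if inter:
                    acc = inter
                else:
                    acc = acc | sets[id(other)]
                    steps += 1
            sets[id(node)] = acc
    return steps


@dataclass
class TipRandomizationResult:
    observed_steps: int
    null_steps: np.ndarray
    p_value: float
    interval_99: tuple[float, float]
    significant: bool
    reps: int
    seed: int | None


def tip_randomization_test(tree: Chronogram, states: dict, reps: int = 1000,
                           seed: int | None = None, k: int = 3) -> TipRandomizationResult:
    """Permutation test of phylogenetic signal in a discrete character.

    The tip-to-state assignment is shuffled uniformly ``reps`` times; the
    parsimony step count of each permutation forms the null.  Signal is
    declared when the observed step count falls below the null's 0.5th
    percentile (outside the 99% interval).  The p-value uses the add-one
    estimator on the lower tail (fewer steps = stronger clustering).
    """
    if reps < 100:
        raise ValueError("use at least 100 randomizations")
    st = _normalize_states(tree, states, k)
    observed = fitch_steps(tree, st, k)
    rng = np.random.default_rng(seed)
    labels = tree.tip_labels
    values = [st[t] for t in labels]
    null = np.empty(reps)
    for r in range(reps):
        perm = rng.permutation(len(labels))
        shuffled = {labels[i]: values[perm[i]] for i in range(len(labels))}
        null[r] = fitch_steps(tree, shuffled, k)
    p = (np.sum(null <= observed) + 1.0) / (reps + 1.0)
    lo, hi = np.percentile(null, [0.5, 99.5])
    return TipRandomizationResult(
        observed_steps=observed, null_steps=null, p_value=float(p),
        interval_99=(float(lo), float(hi)), significant=bool(observed < lo),
        reps=reps, seed=seed,
    )


def read_states_csv(path, k: int = 3) -> dict[str, frozenset]:
    """Read a genus,state CSV; ambiguity is encoded as "0&2" (or "?")."""
    df = pd.read_csv(path)
    df.columns = [c.lower() for c in df.columns]
    if "genus" not in df.columns or "state" not in df.columns:
        raise ValueError("state CSV needs 'genus' and 'state' columns")
    out = {}
    for _, row in df.iterrows():
        raw = str(row["state"]).strip()
        if raw == "?":
            out[str(row["genus"])] = AMBIGUOUS_TRF_NONTRF
        else:
            out[str(row["genus"])] = frozenset(int(x) for x in raw.split("&"))
    for genus, s in out.items():
        if not s <= set(range(k)):
            raise ValueError(f"{genus}: states {sorted(s)} outside 0..{k - 1}")
    return out
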