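"""Diversification-rate likelihoods, model selection and node-spread tests.

All five models are likelihoods of the branching times ``u_1 > ... >
u_{n-1}`` of a reconstructed chronogram, expressed through the durations
``g_j`` (j = 2..n) during which exactly j lineages exist.  The final
interval ``g_n`` ends at the observation window ``window_end`` (0 for
complete trees, the truncation threshold for threshold-restricted data).
The data-constant combinatorial factor (sum of ln j) is dropped identically
from every model, so it cancels from all AIC comparisons.

Models:

* pure_birth:  one rate, lambda; closed-form MLE (n-2)/S with
  S = sum_j j*g_j.
* birth_death: net rate r = lambda - mu and relative extinction
  a = mu/lambda, conditioned on the crown age with both crown lineages
  surviving (the reconstructed-process likelihood).
* yule2rate:   pure birth whose rate shifts from lambda1 to lambda2 at
  age ts (the shift event itself belongs to the older regime).
* DDX:         exponential density dependence, per-lineage rate
  r1 * j**(-x).
* DDL:         logistic density dependence, per-lineage rate
  r1 * (1 - j/K), requiring K > n.

The rate-constancy statistic is dAIC_RC = (best rate-constant AIC) - (best
rate-variable AIC); negative values favour constancy.  Its significance and
that of the gamma statistic are assessed against pure-birth Monte Carlo
nulls matched to the observed lineage count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .trees import BranchingTimes

__all__ = [
    "ModelFitResult",
    "RateConstancyTest",
    "GammaTest",
    "loglik_pure_birth",
    "loglik_birth_death",
    "loglik_yule2rate",
    "loglik_ddx",
    "loglik_ddl",
    "fit_pure_birth",
    "fit_all_models",
    "delta_aic_rc",
    "rate_constancy_test",
    "gamma_stat",
    "gamma_null_test",
]

RATE_CONSTANT = ("pure_birth", "birth_death")
RATE_VARIABLE = ("yule2rate", "DDX", "DDL")


def lineage_intervals(bt: BranchingTimes, extend_to_present: bool = False):
    """Lineage counts j = 2..n and interval durations ``g_j``.

    The final interval ends at ``bt.window_end`` by default.  With
    ``extend_to_present`` it runs to age 0 instead — the naive convention
    for threshold-truncated data, kept for comparison only.
    """
    end = 0.0 if extend_to_present else bt.window_end
    edges = np.concatenate((bt.ages, [end]))
    g = -np.diff(edges)
    if np.any(g < 0):
        raise ValueError("branching times must be sorted above window_end")
    j = np.arange(2, bt.n_tips + 1)
    return j, g


def _S(bt: BranchingTimes, extend_to_present: bool = False) -> float:
    j, g = lineage_intervals(bt, extend_to_present)
    return float(np.sum(j * g))


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

def loglik_pure_birth(bt: BranchingTimes, birth_rate: float,
                      extend_to_present: bool = False) -> float:
    """Pure-birth (Yule) log-likelihood: (n-2) ln(lambda) - lambda * S."""
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    n = bt.n_tips
    return float((n - 2) * np.log(birth_rate)
                 - birth_rate * _S(bt, extend_to_present))


def fit_pure_birth(bt: BranchingTimes, extend_to_present: bool = False):
    """Closed-form MLE lambda_hat = (n-2)/S and its log-likelihood."""
    n = bt.n_tips
    S = _S(bt, extend_to_present)
    if n < 3:
        raise ValueError("pure-birth MLE needs at least 3 tips (one free event)")
    lam = (n - 2) / S
    return lam, loglik_pure_birth(bt, lam, extend_to_present)


def loglik_birth_death(bt: BranchingTimes, r: float, a: float,
                       extend_to_present: bool = False) -> float:
    """Constant-rate birth-death log-likelihood on branching times.

    Conditioned on the crown age with both crown lineages surviving to the
    end of the observation window; ``r`` is the net diversification rate
    and ``a`` the relative extinction mu/lambda in [0, 1).  For truncated
    data, ages are measured from the window end (where n lineages are
    observed), which reduces to the standard formula when window_end = 0.
    """
    if r <= 0:
        raise ValueError("net rate r must be > 0")
    if not 0 <= a < 1:
        raise ValueError("relative extinction a must lie in [0, 1)")
    shift = 0.0 if extend_to_present else bt.window_end
    u = bt.ages - shift
    n = bt.n_tips
    with np.errstate(over="raise"):
        try:
            terms = np.log(np.expm1(r * u) + (1.0 - a))
        except FloatingPointError:
            return -np.inf
    return float((n - 2) * np.log(r) + r * np.sum(u[1:]) + n * np.log1p(-a)
                 - 2.0 * np.sum(terms))


def loglik_yule2rate(bt: BranchingTimes, rate_old: float, rate_young: float,
                     shift_age: float, extend_to_present: bool = False) -> float:
    """Two-rate pure-birth log-likelihood with a shift at ``shift_age``.

    ``rate_old`` applies to the portion of the tree older than the shift
    age, ``rate_young`` to the younger portion; a speciation event exactly
    at the shift age belongs to the older regime.
    """
    if rate_old <= 0 or rate_young <= 0:
        raise ValueError("rates must be > 0")
    end = 0.0 if extend_to_present else bt.window_end
    if not end < shift_age < bt.crown_age:
        raise ValueError(
            f"shift_age must lie inside the observation window "
            f"({end}, {bt.crown_age})"
        )
    events = bt.ages[1:]  # the n-2 non-crown nodes
    n_old = int(np.sum(events >= shift_age))
    n_young = events.size - n_old
    S_old, S_young = _split_exposure(bt, shift_age, end)
    return float(n_old * np.log(rate_old) + n_young * np.log(rate_young)
                 - rate_old * S_old - rate_young * S_young)


def _split_exposure(bt: BranchingTimes, shift_age: float, end: float):
    """Lineage-time exposure S split at the shift age."""
    edges = np.concatenate((bt.ages, [end]))
    upper, lower = edges[:-1], edges[1:]
    j = np.arange(2, bt.n_tips + 1)
    old = np.clip(upper - np.maximum(lower, shift_age), 0.0, None)
    total = upper - lower
    S_old = float(np.sum(j * old))
    S_young = float(np.sum(j * (total - old)))
    return S_old, S_young


def loglik_ddx(bt: BranchingTimes, r1: float, x: float,
               extend_to_present: bool = False) -> float:
    """Exponential density-dependent (DDX) log-likelihood.

    Per-lineage speciation rate while j lineages exist: r1 * j**(-x).
    """
    if r1 <= 0:
        raise ValueError("r1 must be > 0")
    j, g = lineage_intervals(bt, extend_to_present)
    lam = r1 * j.astype(float) ** (-x)
    return float(np.sum(np.log(lam[:-1])) - np.sum(j * lam * g))


def loglik_ddl(bt: BranchingTimes, r1: float, K: float,
               extend_to_present: bool = False) -> float:
    """Logistic density-dependent (DDL) log-likelihood.

    Per-lineage speciation rate while j lineages exist: r1 * (1 - j/K);
    K must exceed the observed lineage count so every rate is positive.
    """
    if r1 <= 0:
        raise ValueError("r1 must be > 0")
    n = bt.n_tips
    if K <= n:
        raise ValueError(f"carrying capacity K must exceed n = {n}")
    j, g = lineage_intervals(bt, extend_to_present)
    lam = r1 * (1.0 - j / K)
    return float(np.sum(np.log(lam[:-1])) - np.sum(j * lam * g))


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelFitResult:
    model: str
    params: dict
    loglik: float
    n_params: int
    converged: bool = True

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


def _simplex(neg, x0s, bounds):
    """Best of several Nelder-Mead runs with box penalties."""
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def wrapped(x):
        if np.any(x < lo) or np.any(x > hi):
            return 1e12
        v = neg(x)
        return 1e12 if not np.isfinite(v) else v

    best = None
    ok = False
    for x0 in x0s:
        res = minimize(wrapped, x0=np.asarray(x0, dtype=float),
                       method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    return best.x, -best.fun, ok


def fit_all_models(bt: BranchingTimes,
                   extend_to_present: bool = False) -> dict[str, ModelFitResult]:
    """Maximum-likelihood fits of all five diversification models.

    The pure-birth rate has a closed form; the other models use bounded
    derivative-free simplex optimization on log-transformed rates.  The
    two-rate shift age is profiled over the observed branching times and
    interval midpoints (the likelihood is piecewise in the shift age) and
    then refined locally.  Nested models are guaranteed a log-likelihood at
    least that of pure birth by seeding them at the pure-birth optimum.
    """
    n = bt.n_tips
    if n < 4:
        raise ValueError("model comparison needs at least 4 tips")
    ext = extend_to_present
    fits: dict[str, ModelFitResult] = {}

    lam, pb_logL = fit_pure_birth(bt, ext)
    fits["pure_birth"] = ModelFitResult("pure_birth", {"lambda": lam},
                                        pb_logL, 1)

    # Birth-death: optimize (ln r, a); include the pure-birth boundary a=0.
    def neg_bd(x):
        return -loglik_birth_death(bt, np.exp(x[0]), x[1], ext)

    (x_bd, bd_logL, bd_ok) = _simplex(
        neg_bd,
        x0s=[(np.log(lam), 0.0), (np.log(lam * 2), 0.5), (np.log(lam), 0.9)],
        bounds=[(np.log(lam) - 12, np.log(lam) + 8), (0.0, 1.0 - 1e-9)],
    )
    if bd_logL < pb_logL:  # boundary optimum a = 0
        x_bd, bd_logL, bd_ok = np.array([np.log(lam), 0.0]), pb_logL, True
    r_hat, a_hat = float(np.exp(x_bd[0])), float(x_bd[1])
    fits["birth_death"] = ModelFitResult(
        "birth_death",
        {"r": r_hat, "a": a_hat,
         "lambda": r_hat / (1 - a_hat), "mu": a_hat * r_hat / (1 - a_hat)},
        bd_logL, 2, bd_ok)

    # Two-rate pure birth: profile the shift age over candidates.
    end = 0.0 if ext else bt.window_end
    edges = np.concatenate((bt.ages, [end]))
    mids = (edges[:-1] + edges[1:]) / 2.0
    candidates = np.unique(np.concatenate((bt.ages[1:], mids)))
    candidates = candidates[(candidates > end) & (candidates < bt.crown_age)]
    events = bt.ages[1:]
    best = (pb_logL, lam, lam, float(mids[len(mids) // 2]))
    for ts in candidates:
        n_old = int(np.sum(events >= ts))
        n_young = events.size - n_old
        S_old, S_young = _split_exposure(bt, float(ts), end)
        l1 = n_old / S_old if n_old > 0 and S_old > 0 else lam
        l2 = n_young / S_young if n_young > 0 and S_young > 0 else lam
        if l1 <= 0 or l2 <= 0:
            continue
        ll = loglik_yule2rate(bt, l1, l2, float(ts), ext)
        if ll > best[0]:
            best = (ll, l1, l2, float(ts))
    y2_logL, l1, l2, ts = best

    def neg_y2(x):
        return -loglik_yule2rate(bt, np.exp(x[0]), np.exp(x[1]), x[2], ext)

    span = bt.crown_age - end
    (x_y2, ref_logL, y2_ok) = _simplex(
        neg_y2, x0s=[(np.log(l1), np.log(l2), ts)],
        bounds=[(np.log(lam) - 12, np.log(lam) + 8),
                (np.log(lam) - 12, np.log(lam) + 8),
                (end + 1e-9 * span, bt.crown_age - 1e-9 * span)],
    )
    if ref_logL >= y2_logL:
        y2_logL, l1, l2, ts = ref_logL, float(np.exp(x_y2[0])), \
            float(np.exp(x_y2[1])), float(x_y2[2])
    fits["yule2rate"] = ModelFitResult(
        "yule2rate", {"lambda1": l1, "lambda2": l2, "ts": ts}, y2_logL, 3, y2_ok)

    # DDX: optimize (ln r1, x); x = 0 recovers pure birth.
    def neg_ddx(x):
        return -loglik_ddx(bt, np.exp(x[0]), x[1], ext)

    (x_dx, dx_logL, dx_ok) = _simplex(
        neg_ddx, x0s=[(np.log(lam), 0.0), (np.log(lam * 3), 0.5),
                      (np.log(lam), -0.5)],
        bounds=[(np.log(lam) - 12, np.log(lam) + 10), (-10.0, 10.0)],
    )
    if dx_logL < pb_logL:
        x_dx, dx_logL, dx_ok = np.array([np.log(lam), 0.0]), pb_logL, True
    fits["DDX"] = ModelFitResult(
        "DDX", {"r1": float(np.exp(x_dx[0])), "x": float(x_dx[1])},
        dx_logL, 2, dx_ok)

    # DDL: optimize (ln r1, ln(K - n)); K -> inf recovers pure birth.
    def neg_ddl(x):
        return -loglik_ddl(bt, np.exp(x[0]), n + np.exp(x[1]), ext)

    (x_dl, dl_logL, dl_ok) = _simplex(
        neg_ddl, x0s=[(np.log(lam), np.log(n)), (np.log(lam), np.log(9 * n)),
                      (np.log(lam), np.log(0.1 * n))],
        bounds=[(np.log(lam) - 12, np.log(lam) + 10), (-10.0, 25.0)],
    )
    K_hat = n + float(np.exp(x_dl[1]))
    if dl_logL < pb_logL:
        x_dl, dl_logL, dl_ok = np.array([np.log(lam), 25.0]), pb_logL, True
        K_hat = n + float(np.exp(25.0))
    fits["DDL"] = ModelFitResult(
        "DDL", {"r1": float(np.exp(x_dl[0])), "K": K_hat}, dl_logL, 2, dl_ok)
    return fits


def delta_aic_rc(fits: dict[str, ModelFitResult]) -> float:
    """Best rate-constant AIC minus best rate-variable AIC.

    Negative values indicate that a rate-constant model approximates the
    branching times best; large positive values indicate rate variability.
    """
    missing = [m for m in RATE_CONSTANT + RATE_VARIABLE if m not in fits]
    if missing:
        raise ValueError(f"missing model fits: {missing}")
    aic_rc = min(fits[m].aic for m in RATE_CONSTANT)
    aic_rv = min(fits[m].aic for m in RATE_VARIABLE)
    return float(aic_rc - aic_rv)


# ---------------------------------------------------------------------------
# Monte Carlo tests
# ---------------------------------------------------------------------------

@dataclass
class RateConstancyTest:
    observed: float
    null: np.ndarray
    p_value: float
    fits: dict
    reps: int
    seed: int | None
    lambda_null: float

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"RateConstancyTest(dAIC_RC={self.observed:.4g}, "
                f"p={self.p_value:.4g}, reps={self.reps})")


def rate_constancy_test(bt: BranchingTimes, reps: int = 1000, seed=None,
                        extend_to_present: bool = False) -> RateConstancyTest:
    """Parametric-bootstrap test of diversification-rate constancy.

    Pure-birth trees matched to the observed lineage count are simulated at
    the observed pure-birth MLE rate; dAIC_RC is computed for each under
    the same interval convention as the data.  The p-value is the add-one
    upper-tail estimator (large dAIC_RC = evidence for rate variability).
    """
    from .simulate import yule_branching_times

    if reps < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    fits = fit_all_models(bt, extend_to_present)
    observed = delta_aic_rc(fits)
    lam = fits["pure_birth"].params["lambda"]
    rng = np.random.default_rng(seed)
    null = np.empty(reps)
    for r in range(reps):
        sim = yule_branching_times(bt.n_tips, lam, rng)
        null[r] = delta_aic_rc(fit_all_models(sim))
    p = (np.sum(null >= observed) + 1.0) / (reps + 1.0)
    return RateConstancyTest(observed=float(observed), null=null,
                             p_value=float(p), fits=fits, reps=reps,
                             seed=seed, lambda_null=float(lam))


def gamma_stat(bt: BranchingTimes, extend_to_present: bool = False) -> float:
    """Pybus-Harvey gamma: standardized spread of internal nodes.

    Negative when nodes crowd toward the root, positive when they crowd
    toward the tips; approximately standard normal under constant-rate pure
    birth.
    """
    n = bt.n_tips
    if n < 3:
        raise ValueError("gamma needs at least 3 tips")
    j, g = lineage_intervals(bt, extend_to_present)
    T_i = np.cumsum(j * g)  # T_2 .. T_n
    T = T_i[-1]
    mean_T = T_i[:-1].mean()  # average of T_2 .. T_{n-1}
    return float((mean_T - T / 2.0) / (T * np.sqrt(1.0 / (12.0 * (n - 2)))))


@dataclass
class GammaTest:
    observed: float
    null: np.ndarray
    p_two_sided: float
    p_lower: float
    reps: int
    seed: int | None


def gamma_null_test(gamma_obs: float, n_tips: int, reps: int = 1000,
                    seed=None) -> GammaTest:
    """Empirical gamma null from pure-birth trees of the same tip count.

    Reports the two-sided p-value and the lower-tail p-value (the
    museum-versus-cradle contrast is directional: early node crowding gives
    gamma < 0).  Gamma is invariant to the speciation rate, so the null
    uses unit rate.
    """
    from .simulate import yule_branching_times

    if reps < 100:
        raise ValueError("use at least 100 simulated trees")
    rng = np.random.default_rng(seed)
    null = np.empty(reps)
    for r in range(reps):
        null[r] = gamma_stat(yule_branching_times(n_tips, 1.0, rng))
    p_lower = (np.sum(null <= gamma_obs) + 1.0) / (reps + 1.0)
    p_upper = (np.sum(null >= gamma_obs) + 1.0) / (reps + 1.0)
    p_two = min(1.0, 2.0 * min(p_lower, p_upper))
    return GammaTest(observed=float(gamma_obs), null=null,
                     p_two_sided=float(p_two), p_lower=float(p_lower),
                     reps=reps, seed=seed)
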