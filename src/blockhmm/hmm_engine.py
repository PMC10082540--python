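"""Fitting engine for the three-state influence HMM.

The latent chain over sites has states (-1, 0, +1) = (Negative, No, Positive
Influence), initial distribution ``pi`` and transition matrix ``A``.  Fitting
follows a six-step loop: evaluate the master objective (the observed-data log
likelihood), run forward-backward and Viterbi, update parameters by a
generalized EM step, clamp parameters at their identifiability thresholds,
and stop once the objective improves by less than ``epsilon``.  The iteration
with the highest objective supplies the reported state sequence; the driver
repeats the loop from one Default and several Random starting points and keeps
the best run.

M-step details: ``pi`` and ``A`` use the Baum-Welch closed forms, which
exactly maximize the transition part of the expected complete-data log
likelihood.  The four influence strengths are updated by bounded cyclic
coordinate ascent (one variable at a time).  The per-site null distributions
are updated by a minorize-maximize step on the probability simplex, which is
guaranteed not to decrease the objective - all that generalized EM requires.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .core_model import (
    IDX_NEG,
    IDX_NONE,
    IDX_POS,
    GenotypeData,
    InfluenceStrengths,
    STATE_LABELS,
    build_contingency_tables,
    emission_log_prob_matrix,
    log_multinomial_coeff,
    tilt_log_factors,
    validate_null,
)
from .errors import FittingError, InputValidationError

logger = logging.getLogger("blockhmm.hmm_engine")

_STATE_ARRAY = np.array(STATE_LABELS)
# Viterbi tie-break preference: No Influence first, then Negative, then Positive.
_TIE_PREF = np.array([IDX_NONE, IDX_NEG, IDX_POS], dtype=np.int64)


@dataclass(frozen=True)
class MarkovParameters:
    """Initial state distribution ``pi`` and row-stochastic transition matrix ``A``."""

    pi: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        A = np.asarray(self.A, dtype=float)
        if pi.shape != (3,) or A.shape != (3, 3):
            raise InputValidationError("pi must have shape (3,) and A shape (3, 3)")
        if np.any(pi < 0) or np.any(A < 0):
            raise InputValidationError("Markov parameters must be nonnegative")
        if abs(pi.sum() - 1.0) > 1e-9 or np.any(np.abs(A.sum(axis=1) - 1.0) > 1e-9):
            raise InputValidationError("pi and every row of A must sum to 1")
        object.__setattr__(self, "pi", pi / pi.sum())
        object.__setattr__(self, "A", A / A.sum(axis=1, keepdims=True))


@dataclass(frozen=True)
class HmmParameters:
    """Full parameter set: per-site nulls, influence strengths, Markov parameters."""

    nulls: np.ndarray  # (p, 3)
    theta: InfluenceStrengths
    markov: MarkovParameters

    def __post_init__(self) -> None:
        object.__setattr__(self, "nulls", validate_null(np.atleast_2d(self.nulls)))

    @property
    def n_sites(self) -> int:
        return self.nulls.shape[0]


@dataclass(frozen=True)
class ThresholdConfig:
    """Thresholds and numeric settings of the fitting loop.

    ``theta_min`` keeps the influence states distinguishable from No Influence
    (benchmarks use 0.1 / 0.15 / 0.2); ``a_min`` keeps predicted influential
    sites in blocks; ``epsilon`` is the stopping threshold on objective
    improvement.  ``update_nulls=False`` freezes the per-site null
    distributions at their initial estimates (sensitivity analysis only).
    """

    theta_min: float = 0.15
    a_min: float = 0.5
    epsilon: float = 0.01
    max_iterations: int = 500
    posterior_floor: float = float(np.exp(-30))
    seed: int = 0
    theta_max: float = 10.0
    update_nulls: bool = True
    null_mm_iterations: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.a_min < 1):
            raise InputValidationError("a_min must lie in (0, 1)")
        if self.epsilon <= 0:
            raise InputValidationError("epsilon must be > 0")
        if self.theta_min < 0:
            raise InputValidationError("theta_min must be >= 0")


@dataclass
class TrellisVariables:
    """Forward/backward log variables, marginal posteriors, and log likelihood."""

    log_alpha: np.ndarray
    log_beta: np.ndarray
    gamma: np.ndarray
    log_likelihood: float


@dataclass
class FitResult:
    """Output of a fit: decoded states, posteriors and winning parameters.

    ``states`` is the Viterbi path (labels in {-1, 0, +1}) under ``params``,
    both taken from the iteration of the winning run with the highest master
    objective.  ``objective_trace`` holds that run's per-iteration objectives.
    """

    states: np.ndarray
    gamma: np.ndarray
    params: HmmParameters
    objective_trace: np.ndarray
    selected_run: str
    run_objectives: dict = field(default_factory=dict)

    @property
    def objective(self) -> float:
        return float(np.max(self.objective_trace))


# ---------------------------------------------------------------------------
# Trellis recursions (log space)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _forward_kernel(log_pi, logA, log_em):  # pragma: no cover - exercised via wrapper
    p = log_em.shape[0]
    la = np.empty((p, 3))
    for k in range(3):
        la[0, k] = log_pi[k] + log_em[0, k]
    for j in range(1, p):
        for l in range(3):
            mx = -np.inf
            for k in range(3):
                v = la[j - 1, k] + logA[k, l]
                if v > mx:
                    mx = v
            if mx == -np.inf:
                la[j, l] = -np.inf
            else:
                s = 0.0
                for k in range(3):
                    s += np.exp(la[j - 1, k] + logA[k, l] - mx)
                la[j, l] = mx + np.log(s) + log_em[j, l]
    return la


@njit(cache=True)
def _backward_kernel(logA, log_em):  # pragma: no cover - exercised via wrapper
    p = log_em.shape[0]
    lb = np.empty((p, 3))
    for k in range(3):
        lb[p - 1, k] = 0.0
    for j in range(p - 2, -1, -1):
        for k in range(3):
            mx = -np.inf
            for l in range(3):
                v = logA[k, l] + log_em[j + 1, l] + lb[j + 1, l]
                if v > mx:
                    mx = v
            if mx == -np.inf:
                lb[j, k] = -np.inf
            else:
                s = 0.0
                for l in range(3):
                    s += np.exp(logA[k, l] + log_em[j + 1, l] + lb[j + 1, l] - mx)
                lb[j, k] = mx + np.log(s)
    return lb


@njit(cache=True)
def _viterbi_kernel(log_pi, logA, log_em, pref):  # pragma: no cover
    p = log_em.shape[0]
    delta = np.empty((p, 3))
    psi = np.zeros((p, 3), dtype=np.int64)
    for k in range(3):
        delta[0, k] = log_pi[k] + log_em[0, k]
    for j in range(1, p):
        for l in range(3):
            best = -np.inf
            arg = pref[0]
            for t in range(3):
                k = pref[t]
                v = delta[j - 1, k] + logA[k, l]
                if v > best:
                    best = v
                    arg = k
            delta[j, l] = best + log_em[j, l]
            psi[j, l] = arg
    best = -np.inf
    last = pref[0]
    for t in range(3):
        k = pref[t]
        if delta[p - 1, k] > best:
            best = delta[p - 1, k]
            last = k
    path = np.empty(p, dtype=np.int64)
    path[p - 1] = last
    for j in range(p - 2, -1, -1):
        path[j] = psi[j + 1, path[j + 1]]
    return path


def _check_emissions(log_em: np.ndarray) -> np.ndarray:
    log_em = np.asarray(log_em, dtype=float)
    if log_em.ndim != 2 or log_em.shape[1] != 3:
        raise InputValidationError("log_emissions must have shape (p, 3)")
    bad = np.nonzero(np.all(np.isneginf(log_em), axis=1))[0]
    if bad.size:
        raise FittingError(f"zero-likelihood site {int(bad[0])}: all states impossible")
    return log_em


def _log_markov(markov: MarkovParameters):
    with np.errstate(divide="ignore"):
        return np.log(markov.pi), np.log(markov.A)


def forward_backward(log_emissions: np.ndarray, markov: MarkovParameters) -> TrellisVariables:
    """Log-space forward-backward pass; returns trellis variables and posteriors.

    The master objective (observed-data log likelihood) is the log-sum-exp of
    the last forward row; ``gamma[j, k] = alpha_j(k) beta_j(k) / sum_k (...)``.
    """
    log_em = _check_emissions(log_emissions)
    log_pi, logA = _log_markov(markov)
    la = _forward_kernel(log_pi, logA, log_em)
    lb = _backward_kernel(logA, log_em)
    ll = float(logsumexp(la[-1]))
    if not np.isfinite(ll):
        raise FittingError("zero-likelihood sequence: no state path has positive probability")
    joint = la + lb
    gamma = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
    return TrellisVariables(la, lb, gamma, ll)


def viterbi(log_emissions: np.ndarray, markov: MarkovParameters) -> np.ndarray:
    """Most probable state sequence (labels in {-1, 0, +1}).

    Ties are broken deterministically, preferring No Influence, then Negative,
    then Positive Influence.
    """
    log_em = _check_emissions(log_emissions)
    log_pi, logA = _log_markov(markov)
    path = _viterbi_kernel(log_pi, logA, log_em, _TIE_PREF)
    return _STATE_ARRAY[path]


def e_step(
    tables: np.ndarray,
    params: HmmParameters,
    log_coeff: np.ndarray | None = None,
) -> tuple[TrellisVariables, np.ndarray]:
    """Evaluate emissions, run forward-backward and compute transition posteriors.

    Returns the trellis variables and ``xi`` of shape ``(p-1, 3, 3)`` where
    ``xi[j, k, l]`` is the posterior probability of being in state ``k`` at
    site ``j`` and ``l`` at site ``j+1``.
    """
    log_em = emission_log_prob_matrix(tables, params.nulls, params.theta, log_coeff)
    trellis = forward_backward(log_em, params.markov)
    xi = _transition_posteriors(trellis, params.markov, log_em)
    return trellis, xi


def _transition_posteriors(
    trellis: TrellisVariables, markov: MarkovParameters, log_em: np.ndarray
) -> np.ndarray:
    _, logA = _log_markov(markov)
    with np.errstate(invalid="ignore"):
        log_xi = (
            trellis.log_alpha[:-1, :, None]
            + logA[None, :, :]
            + (log_em + trellis.log_beta)[1:, None, :]
            - trellis.log_likelihood
        )
    xi = np.exp(log_xi)
    # normalize per transition to absorb rounding
    xi /= xi.sum(axis=(1, 2), keepdims=True)
    return xi


# ---------------------------------------------------------------------------
# M-step pieces
# ---------------------------------------------------------------------------


def _theta_pair_objective(
    tables: np.ndarray, nulls: np.ndarray, weights: np.ndarray, positive: bool
):
    """Weighted expected log-emission as a function of one strength pair.

    For the Negative Influence pair the tilt is (+t0, 0, -t1); for the
    Positive Influence pair it is (-t0, 0, +t1).  Only the theta-dependent
    part is returned (the control multinomial and coefficients are constant).
    """
    m = tables[:, 1, :].astype(float)
    M = m.sum(axis=1)
    w = np.asarray(weights, dtype=float)
    wm0 = float(np.sum(w * m[:, 0]))
    wm2 = float(np.sum(w * m[:, 2]))
    p0, p1, p2 = nulls[:, 0], nulls[:, 1], nulls[:, 2]
    wM = w * M
    sign = -1.0 if positive else 1.0

    def objective(t0: float, t1: float) -> float:
        z = np.exp(sign * t0) * p0 + p1 + np.exp(-sign * t1) * p2
        return sign * (t0 * wm0 - t1 * wm2) - float(np.sum(wM * np.log(z)))

    return objective


def _maximize_pair(objective, t0: float, t1: float, lo: float, hi: float,
                   cycles: int = 2) -> tuple[float, float]:
    """Bounded cyclic coordinate ascent on a two-argument objective."""
    for _ in range(cycles):
        for coord in (0, 1):
            if coord == 0:
                f = lambda t: -objective(t, t1)
                cur = t0
            else:
                f = lambda t: -objective(t0, t)
                cur = t1
            res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-6})
            cand = float(res.x)
            if -res.fun < -f(cur):  # keep current value unless strictly improved
                cand = cur
            if coord == 0:
                t0 = cand
            else:
                t1 = cand
    return t0, t1


def _update_theta(
    tables: np.ndarray,
    gamma: np.ndarray,
    nulls: np.ndarray,
    theta: InfluenceStrengths,
    config: ThresholdConfig,
) -> InfluenceStrengths:
    lo, hi = config.theta_min, config.theta_max
    obj_neg = _theta_pair_objective(tables, nulls, gamma[:, IDX_NEG], positive=False)
    t0m, t1m = _maximize_pair(
        obj_neg, np.clip(theta.theta0_minus, lo, hi), np.clip(theta.theta1_minus, lo, hi), lo, hi
    )
    obj_pos = _theta_pair_objective(tables, nulls, gamma[:, IDX_POS], positive=True)
    t0p, t1p = _maximize_pair(
        obj_pos, np.clip(theta.theta0_plus, lo, hi), np.clip(theta.theta1_plus, lo, hi), lo, hi
    )
    return InfluenceStrengths(t0m, t1m, t0p, t1p)


def _update_nulls(
    tables: np.ndarray,
    gamma: np.ndarray,
    theta: InfluenceStrengths,
    nulls: np.ndarray,
    n_inner: int = 30,
) -> np.ndarray:
    """Minorize-maximize update of the per-site null distributions.

    The per-site objective sum_k gamma_j(k) log f_k^j reduces (up to
    constants) to sum_i (n_i + m_i) log p_i - M sum_k gamma_j(k) log Z_k(p),
    with Z_k the tilt normalizer.  Linearizing each -log Z_k at the current
    point gives a concave surrogate whose simplex maximizer is
    p_i = (n_i + m_i) / (lambda + d_i); lambda is found by bisection.  Each
    pass cannot decrease the objective; passes repeat until the update is
    stationary or ``n_inner`` is reached.
    """
    E = np.exp(tilt_log_factors(theta))  # (3 states, 3 genotypes)
    counts = tables.sum(axis=1).astype(float)  # (p, 3)
    M = tables[:, 1, :].sum(axis=1).astype(float)  # (p,)
    S = counts.sum(axis=1)
    active = S > 0
    p_cur = np.array(nulls, dtype=float)
    pos = counts > 0
    for _ in range(n_inner):
        Z = p_cur @ E.T  # (p, 3 states)
        d = M[:, None] * ((gamma / Z) @ E)  # (p, 3 genotypes)
        d_masked = np.where(pos, d, np.inf)
        d_min = d_masked.min(axis=1)
        d_masked_max = np.where(pos, d, -np.inf)
        d_max = d_masked_max.max(axis=1)
        lo = np.maximum(S - d_max, -d_min + 1e-10 * (1.0 + np.abs(d_min)))
        hi = S - d_min
        hi = np.maximum(hi, lo + 1e-12)
        for _b in range(64):
            mid = 0.5 * (lo + hi)
            with np.errstate(divide="ignore", invalid="ignore"):
                h = np.where(pos, counts / (mid[:, None] + d), 0.0).sum(axis=1) - 1.0
            above = h > 0
            lo = np.where(above, mid, lo)
            hi = np.where(above, hi, mid)
        lam = 0.5 * (lo + hi)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_new = np.where(pos, counts / (lam[:, None] + d), 0.0)
        p_new = np.clip(p_new, 1e-12, None)
        p_new /= p_new.sum(axis=1, keepdims=True)
        p_new = np.where(active[:, None], p_new, p_cur)
        if np.max(np.abs(p_new - p_cur)) < 1e-10:
            p_cur = p_new
            break
        p_cur = p_new
    return p_cur


def m_step(
    tables: np.ndarray,
    gamma: np.ndarray,
    xi: np.ndarray,
    params: HmmParameters,
    config: ThresholdConfig,
) -> HmmParameters:
    """Generalized-EM parameter update.

    ``pi`` and ``A`` use the Baum-Welch closed forms; the strengths use
    bounded cyclic coordinate ascent; the nulls use the MM pass (skipped if
    ``config.update_nulls`` is false).  Every piece is non-decreasing in the
    expected complete-data objective.
    """
    pi_new = gamma[0] / gamma[0].sum()
    denom = gamma[:-1].sum(axis=0)
    A_old = params.markov.A
    with np.errstate(divide="ignore", invalid="ignore"):
        A_new = xi.sum(axis=0) / denom[:, None]
    # states with no posterior mass before the last site keep their old row
    A_new = np.where(denom[:, None] > 1e-300, A_new, A_old)
    A_new = A_new / A_new.sum(axis=1, keepdims=True)

    theta_new = _update_theta(tables, gamma, params.nulls, params.theta, config)

    if config.update_nulls:
        try:
            nulls_new = _update_nulls(
                tables, gamma, theta_new, params.nulls, config.null_mm_iterations
            )
        except FloatingPointError:  # pragma: no cover - defensive
            warnings.warn("null-distribution update failed; keeping previous values")
            nulls_new = params.nulls
    else:
        nulls_new = params.nulls

    return HmmParameters(nulls_new, theta_new, MarkovParameters(pi_new, A_new))


def enforce_thresholds(params: HmmParameters, config: ThresholdConfig) -> HmmParameters:
    """Clamp strengths at ``theta_min`` and diagonal transitions at ``a_min``.

    When a diagonal entry is raised, the row's off-diagonal mass is rescaled
    proportionally so the row still sums to 1.  Idempotent.
    """
    theta = params.theta.clipped(config.theta_min)
    A = np.array(params.markov.A, dtype=float)
    for k in range(3):
        if A[k, k] < config.a_min:
            off = 1.0 - A[k, k]
            scale = (1.0 - config.a_min) / off if off > 0 else 0.0
            for l in range(3):
                if l != k:
                    A[k, l] *= scale
            A[k, k] = config.a_min
        A[k] /= A[k].sum()
    return HmmParameters(params.nulls, theta, MarkovParameters(params.markov.pi, A))


# ---------------------------------------------------------------------------
# Initial parameter estimates
# ---------------------------------------------------------------------------


def _golden_max_vec(f, lo, hi, n_iter: int = 60) -> np.ndarray:
    """Elementwise golden-section maximization of a vectorized unimodal function."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.array(lo, dtype=float)
    b = np.array(hi, dtype=float)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(n_iter):
        go_right = fc < fd
        a = np.where(go_right, c, a)
        b = np.where(go_right, b, d)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = f(c), f(d)
    return 0.5 * (a + b)


def _per_site_strengths(
    tables: np.ndarray, nulls: np.ndarray, positive: bool, theta_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site maximizers of the state-specific log emission over (t0, t1).

    Bounded cyclic coordinate ascent (two cycles of elementwise golden-section
    search), initialized at 0.5, run for every site simultaneously.
    """
    m = tables[:, 1, :].astype(float)
    M = m.sum(axis=1)
    p0, p1, p2 = nulls[:, 0], nulls[:, 1], nulls[:, 2]
    sign = -1.0 if positive else 1.0

    def obj(t0, t1):
        z = np.exp(sign * t0) * p0 + p1 + np.exp(-sign * t1) * p2
        return sign * (t0 * m[:, 0] - t1 * m[:, 2]) - M * np.log(z)

    p = tables.shape[0]
    t0 = np.full(p, 0.5)
    t1 = np.full(p, 0.5)
    zeros = np.zeros(p)
    caps = np.full(p, theta_max)
    for _ in range(2):
        t0 = _golden_max_vec(lambda t: obj(t, t1), zeros, caps)
        t1 = _golden_max_vec(lambda t: obj(t0, t), zeros, caps)
    return t0, t1


def _median_above(values: np.ndarray, theta_min: float) -> float:
    kept = values[values > theta_min]
    return float(np.median(kept)) if kept.size else float(theta_min)


def default_initials(tables: np.ndarray, config: ThresholdConfig) -> HmmParameters:
    """Deterministic starting estimates built from the observed tables.

    Nulls come from control-row frequencies (pseudocount 0.5 for empty cells,
    then renormalized).  Global strengths are medians of per-site maximizers
    exceeding ``theta_min``.  Site-independent posterior proxies ``b`` (the
    Bayes posterior under a uniform prior, floored at ``posterior_floor``)
    supply ``pi`` and the expected-transition estimate of ``A``.
    """
    tables = np.asarray(tables)
    if tables.shape[0] == 0:
        raise InputValidationError("cannot build initials from an empty table sequence")
    n_row = tables[:, 0, :].astype(float)
    N = n_row.sum(axis=1, keepdims=True)
    pseudo = np.where(n_row == 0, 0.5, n_row)
    nulls = pseudo / np.where(N > 0, N, 1.0)
    nulls /= nulls.sum(axis=1, keepdims=True)

    t0m, t1m = _per_site_strengths(tables, nulls, positive=False, theta_max=config.theta_max)
    t0p, t1p = _per_site_strengths(tables, nulls, positive=True, theta_max=config.theta_max)
    theta = InfluenceStrengths(
        _median_above(t0m, config.theta_min),
        _median_above(t1m, config.theta_min),
        _median_above(t0p, config.theta_min),
        _median_above(t1p, config.theta_min),
    )

    log_f = emission_log_prob_matrix(tables, nulls, theta)
    b = np.exp(log_f - logsumexp(log_f, axis=1, keepdims=True))
    b = np.maximum(b, config.posterior_floor)
    b /= b.sum(axis=1, keepdims=True)

    pi = b[0] / b[0].sum()
    if tables.shape[0] > 1:
        counts = b[:-1].T @ b[1:]
        A = counts / b[:-1].sum(axis=0)[:, None]
        A /= A.sum(axis=1, keepdims=True)
    else:
        A = np.full((3, 3), 1.0 / 3.0)
    return HmmParameters(nulls, theta, MarkovParameters(pi, A))


def random_triple(rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Normalized, descending-sorted triple(s) of U(0,1) draws."""
    shape = (3,) if size is None else (size, 3)
    u = rng.random(shape)
    t = u / u.sum(axis=-1, keepdims=True)
    return np.sort(t, axis=-1)[..., ::-1].copy()


def random_pi(rng: np.random.Generator) -> np.ndarray:
    """Random initial-state vector: largest mass on No Influence, coin for the rest."""
    t = random_triple(rng)
    pi = np.empty(3)
    pi[IDX_NONE] = t[0]
    if rng.random() < 0.5:
        pi[IDX_NEG], pi[IDX_POS] = t[1], t[2]
    else:
        pi[IDX_NEG], pi[IDX_POS] = t[2], t[1]
    return pi


def random_transition_matrix(
    rng: np.random.Generator, diag_low: float = 0.5, diag_high: float = 1.0
) -> np.ndarray:
    """Random row-stochastic matrix with U(diag_low, diag_high) diagonals.

    Each row's off-diagonal mass is split t : (1 - t) between the two
    remaining entries (in column order), t ~ U(0, 1).
    """
    A = np.zeros((3, 3))
    for k in range(3):
        diag = rng.uniform(diag_low, diag_high)
        t = rng.random()
        others = [l for l in range(3) if l != k]
        A[k, k] = diag
        A[k, others[0]] = t * (1.0 - diag)
        A[k, others[1]] = (1.0 - t) * (1.0 - diag)
    return A


def random_initials(rng: np.random.Generator, n_sites: int) -> HmmParameters:
    """Random starting estimates: sorted-triple nulls, U(0,1) strengths,
    random ``pi`` and a transition matrix with U(0.5, 1) diagonals."""
    nulls = random_triple(rng, n_sites)
    theta = InfluenceStrengths(*rng.random(4))
    pi = random_pi(rng)
    A = random_transition_matrix(rng)
    return HmmParameters(nulls, theta, MarkovParameters(pi, A))


# ---------------------------------------------------------------------------
# Fitting driver
# ---------------------------------------------------------------------------


@dataclass
class _RunRecord:
    name: str
    trace: list
    best_objective: float
    best_states: np.ndarray
    best_gamma: np.ndarray
    best_params: HmmParameters


def _run_em(
    tables: np.ndarray,
    params: HmmParameters,
    config: ThresholdConfig,
    name: str,
    log_coeff: np.ndarray,
) -> _RunRecord:
    trace: list = []
    best = None
    prev_obj = -np.inf
    for _it in range(config.max_iterations):
        log_em = emission_log_prob_matrix(tables, params.nulls, params.theta, log_coeff)
        trellis = forward_backward(log_em, params.markov)
        obj = trellis.log_likelihood
        states = viterbi(log_em, params.markov)
        trace.append(obj)
        logger.info(
            "run=%s iter=%d objective=%.6f theta_clamped=%d diag_clamped=%d",
            name, _it, obj,
            int(np.sum(params.theta.as_array() <= config.theta_min)),
            int(np.sum(np.diag(params.markov.A) <= config.a_min)),
        )
        if best is None or obj > best[0]:
            best = (obj, states, trellis.gamma, params)
        if len(trace) > 1 and (obj - prev_obj) < config.epsilon:
            break
        prev_obj = obj
        xi = _transition_posteriors(trellis, params.markov, log_em)
        params = m_step(tables, trellis.gamma, xi, params, config)
        params = enforce_thresholds(params, config)
    assert best is not None
    return _RunRecord(name, trace, best[0], best[1], best[2], best[3])


def fit(
    data: GenotypeData | np.ndarray,
    config: ThresholdConfig | None = None,
    n_random_starts: int = 3,
) -> FitResult:
    """Fit the influence HMM with one Default and ``n_random_starts`` Random starts.

    ``data`` may be a :class:`GenotypeData` or a precomputed ``(p, 2, 3)``
    table array.  Each run iterates objective evaluation, E-step/Viterbi,
    M-step and threshold enforcement until the objective improves by less
    than ``epsilon`` (a decrease also stops the loop); the iteration with the
    highest objective supplies that run's output, and the run with the highest
    best objective wins overall.  Random-run sub-seeds are ``config.seed + k``.
    """
    if config is None:
        config = ThresholdConfig()
    if isinstance(data, GenotypeData):
        tables = build_contingency_tables(data)
    else:
        tables = np.asarray(data)
    if tables.ndim != 3 or tables.shape[1:] != (2, 3):
        raise InputValidationError("tables must have shape (p, 2, 3)")
    if tables.shape[0] == 0:
        raise InputValidationError("cannot fit a model with zero variant sites")
    if n_random_starts < 0:
        raise InputValidationError("n_random_starts must be >= 0")
    log_coeff = log_multinomial_coeff(tables).sum(axis=-1)

    records = [_run_em(tables, default_initials(tables, config), config, "default", log_coeff)]
    for k in range(n_random_starts):
        rng = np.random.default_rng(config.seed + k)
        init = random_initials(rng, tables.shape[0])
        records.append(_run_em(tables, init, config, f"random-{k + 1}", log_coeff))

    winner = max(records, key=lambda r: r.best_objective)
    return FitResult(
        states=winner.best_states,
        gamma=winner.best_gamma,
        params=winner.best_params,
        objective_trace=np.array(winner.trace),
        selected_run=winner.name,
        run_objectives={r.name: r.best_objective for r in records},
    )
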