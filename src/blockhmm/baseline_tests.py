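"""Site-by-site baselines: Fisher's exact test on 2x3 tables with
Bonferroni and Benjamini-Hochberg classification.

The exact test is the Freeman-Halton extension of Fisher's test: conditional
on all margins, the p-value sums the probabilities of every table at most as
probable as the observed one.  Enumeration is used while the conditional table
space is small enough; otherwise the p-value is estimated by Monte Carlo
sampling from the multivariate hypergeometric null.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .core_model import SiteContingencyTable
from .errors import InputValidationError

#: Report the exact p-value while the conditional space has at most this many
#: tables; beyond it the p-value is a 10^5-permutation Monte-Carlo estimate.
ENUMERATION_LIMIT = 200_000
#: Largest space for which the MC estimate is drawn from its exact Binomial
#: sampling distribution (the space is still cheap to enumerate); beyond this,
#: tables are permuted explicitly.
_BINOMIAL_SHORTCUT_LIMIT = 20_000_000
#: Monte-Carlo sample size used beyond the enumeration limit.
MC_SAMPLES = 100_000
#: Relative tolerance treating near-equal table probabilities as ties.
_TIE_TOL = 1e-7


def _as_table_array(table) -> np.ndarray:
    if isinstance(table, SiteContingencyTable):
        return table.as_array()
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 3):
        raise InputValidationError(f"expected a 2x3 table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise InputValidationError("table counts must be nonnegative")
    return arr


_lgamma_table = gammaln(np.arange(2049, dtype=float))


def _lgamma_int(n: np.ndarray) -> np.ndarray:
    """gammaln(n) for nonnegative integer arrays via a growing lookup table."""
    global _lgamma_table
    top = int(np.max(n)) if np.size(n) else 0
    if top >= _lgamma_table.size:
        _lgamma_table = gammaln(np.arange(2 * top + 2, dtype=float))
    return _lgamma_table[np.asarray(n, dtype=np.int64)]


def _log_table_prob(m_grid: np.ndarray, cols: np.ndarray, N: int, M: int) -> np.ndarray:
    """Log conditional probability of case rows ``m_grid`` given all margins."""
    c = cols[None, :] if m_grid.ndim == 2 else cols
    log_choose = (
        _lgamma_int(c + 1) - _lgamma_int(m_grid + 1) - _lgamma_int(c - m_grid + 1)
    ).sum(axis=-1)
    denom = (
        _lgamma_int(np.array(N + M + 1))
        - _lgamma_int(np.array(M + 1))
        - _lgamma_int(np.array(N + 1))
    )
    return log_choose - denom


def _enumeration_size(cols: np.ndarray, N: int, M: int) -> int:
    ranges = np.minimum(cols, M) - np.maximum(0, cols - N) + 1
    order = np.argsort(ranges)
    return int(ranges[order[0]] * ranges[order[1]])


@njit(cache=True)
def _enum_pvalue_kernel(c0, c1, c2, N, M, lg, cutoff):  # pragma: no cover
    """Sum conditional probabilities of case rows at most as probable as cutoff.

    Iterates the (m0, m1) grid; ``lg`` is a gammaln lookup table over integers.
    """
    denom = lg[N + M + 1] - lg[M + 1] - lg[N + 1]
    total = 0.0
    lo0 = max(0, c0 - N)
    hi0 = min(c0, M)
    lo1 = max(0, c1 - N)
    hi1 = min(c1, M)
    for m0 in range(lo0, hi0 + 1):
        part0 = lg[c0 + 1] - lg[m0 + 1] - lg[c0 - m0 + 1]
        for m1 in range(lo1, hi1 + 1):
            m2 = M - m0 - m1
            if m2 < 0 or m2 > c2 or m2 < c2 - N:
                continue
            logp = (
                part0
                + lg[c1 + 1] - lg[m1 + 1] - lg[c1 - m1 + 1]
                + lg[c2 + 1] - lg[m2 + 1] - lg[c2 - m2 + 1]
                - denom
            )
            if logp <= cutoff:
                total += np.exp(logp)
    return total


def fisher_exact_2x3(
    table,
    simulations: int = MC_SAMPLES,
    enumeration_limit: int = ENUMERATION_LIMIT,
    mc_seed: int = 1729,
    binomial_shortcut_limit: int = _BINOMIAL_SHORTCUT_LIMIT,
) -> float:
    """Two-sided Freeman-Halton exact p-value for one 2x3 table.

    Conditional on the row margins (N, M) and the column (genotype) margins,
    the p-value is the total probability of tables no more probable than the
    observed one.  When the conditional space exceeds ``enumeration_limit``
    tables the p-value is a Monte-Carlo estimate over ``simulations``
    permutation draws under a fixed sub-seed, i.e. ``(hits + 1) / (B + 1)``
    with hits ~ Binomial(B, p); while the space remains enumerable the hit
    count is drawn directly from that Binomial law (identical distribution,
    no per-draw sampling), and explicit permutation draws are used beyond
    ``binomial_shortcut_limit``.  Degenerate margins (N = 0 or M = 0) admit a
    single table, so p = 1.
    """
    arr = _as_table_array(table)
    n_row, m_row = arr[0], arr[1]
    N, M = int(n_row.sum()), int(m_row.sum())
    if N == 0 or M == 0:
        return 1.0
    cols = (n_row + m_row).astype(np.int64)
    log_obs = float(_log_table_prob(m_row, cols, N, M))
    cutoff = log_obs + _TIE_TOL * max(1.0, abs(log_obs))
    size = _enumeration_size(cols, N, M)

    if size <= max(enumeration_limit, 1):
        return min(1.0, _exact_tail(cols, N, M, cutoff))

    rng = np.random.default_rng(mc_seed)
    if size <= binomial_shortcut_limit:
        p_exact = min(1.0, _exact_tail(cols, N, M, cutoff))
        hits = int(rng.binomial(simulations, p_exact))
    else:
        # multivariate hypergeometric via nested univariate draws (vectorized)
        m0 = rng.hypergeometric(cols[0], cols[1] + cols[2], M, size=simulations)
        m1 = rng.hypergeometric(cols[1], cols[2], M - m0)
        draws = np.stack([m0, m1, M - m0 - m1], axis=1)
        logp = _log_table_prob(draws, cols, N, M)
        hits = int(np.sum(logp <= cutoff))
    # add-one estimator keeps the p-value positive and valid
    return float((hits + 1) / (simulations + 1))


def _exact_tail(cols: np.ndarray, N: int, M: int, cutoff: float) -> float:
    """Total conditional probability of tables with log-probability <= cutoff."""
    # iterate over the two columns with the smallest admissible ranges
    order = np.argsort(np.minimum(cols, M) - np.maximum(0, cols - N))
    c = cols[order]
    _lgamma_int(np.array(N + M + 1))  # ensure the lookup table is large enough
    return float(
        _enum_pvalue_kernel(int(c[0]), int(c[1]), int(c[2]), N, M, _lgamma_table, cutoff)
    )


def fisher_exact_carrier_2x2(table) -> float:
    """Fisher exact test after collapsing genotypes to carrier / non-carrier.

    Sensitivity-analysis alternative to the full 2x3 test: columns 1 and 2
    (one or two minor-allele copies) are merged before a classical two-sided
    2x2 exact test.
    """
    from scipy.stats import fisher_exact

    arr = _as_table_array(table)
    collapsed = np.column_stack([arr[:, 0], arr[:, 1] + arr[:, 2]])
    return float(fisher_exact(collapsed, alternative="two-sided")[1])


def _check_pvals(p_values: np.ndarray) -> np.ndarray:
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        raise InputValidationError("empty p-value vector")
    if np.any((p_values < 0) | (p_values > 1) | ~np.isfinite(p_values)):
        raise InputValidationError("p-values must lie in [0, 1]")
    return p_values


def bonferroni_classify(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Binary calls under Bonferroni: site called iff p < alpha / (number of sites)."""
    p_values = _check_pvals(p_values)
    return (p_values < alpha / p_values.size).astype(np.int64)


def bh_fdr_classify(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Binary calls under the Benjamini-Hochberg step-up FDR procedure."""
    p_values = _check_pvals(p_values)
    reject, *_ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    return reject.astype(np.int64)
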