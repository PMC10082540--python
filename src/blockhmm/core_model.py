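"""Data model and state-dependent multinomial emission distributions.

A dataset is a genotype matrix ``G`` (subjects x sites, minor-allele dosage
0/1/2) and a binary phenotype vector ``y``.  Each site is summarized by its
2x3 phenotype-by-genotype contingency table.  Conditional on a latent
influence state s in {-1, 0, +1}, the control row is multinomial(N, p) under
the site's null genotype distribution p and the case row is multinomial(M, q)
where q is p tilted on the log-odds scale by the influence strengths theta:

* s =  0:  q = p
* s = -1:  q  propto  (exp(theta0m) p0,  p1,  exp(-theta1m) p2)
* s = +1:  q  propto  (exp(-theta0p) p0, p1,  exp(theta1p) p2)

so a Negative Influence site shifts case probability mass toward the
homozygous-major genotype and a Positive Influence site toward the
homozygous-minor genotype.  All probability arithmetic is carried out in
natural-log space; log-factorials use the log-gamma function so that large
sample sizes never overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .errors import InputValidationError

#: Latent state labels in the fixed internal order (index 0, 1, 2).
STATE_LABELS = (-1, 0, 1)
IDX_NEG, IDX_NONE, IDX_POS = 0, 1, 2

_SIMPLEX_TOL = 1e-12


@dataclass(frozen=True)
class InfluenceStrengths:
    """Nonnegative log-odds tilts applied to the case genotype distribution.

    ``theta0_minus``/``theta1_minus`` act in the Negative Influence state
    (mass toward 0 copies / away from 2 copies); ``theta0_plus``/
    ``theta1_plus`` act analogously in the Positive Influence state.
    """

    theta0_minus: float
    theta1_minus: float
    theta0_plus: float
    theta1_plus: float

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not np.isfinite(value) or value < 0:
                raise InputValidationError(
                    f"influence strength {name} must be finite and >= 0, got {value}"
                )

    def as_dict(self) -> dict:
        return {
            "theta0_minus": self.theta0_minus,
            "theta1_minus": self.theta1_minus,
            "theta0_plus": self.theta0_plus,
            "theta1_plus": self.theta1_plus,
        }

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.theta0_minus, self.theta1_minus, self.theta0_plus, self.theta1_plus]
        )

    def clipped(self, minimum: float) -> "InfluenceStrengths":
        return InfluenceStrengths(
            max(self.theta0_minus, minimum),
            max(self.theta1_minus, minimum),
            max(self.theta0_plus, minimum),
            max(self.theta1_plus, minimum),
        )


@dataclass(frozen=True)
class SiteContingencyTable:
    """2x3 genotype-count table at one site: controls (n) over cases (m)."""

    n0: int
    n1: int
    n2: int
    m0: int
    m1: int
    m2: int

    def __post_init__(self) -> None:
        for name in ("n0", "n1", "n2", "m0", "m1", "m2"):
            if getattr(self, name) < 0:
                raise InputValidationError(f"negative count {name}")

    @property
    def N(self) -> int:
        return self.n0 + self.n1 + self.n2

    @property
    def M(self) -> int:
        return self.m0 + self.m1 + self.m2

    def as_array(self) -> np.ndarray:
        return np.array([[self.n0, self.n1, self.n2], [self.m0, self.m1, self.m2]])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "SiteContingencyTable":
        arr = np.asarray(arr)
        if arr.shape != (2, 3):
            raise InputValidationError(f"expected a 2x3 table, got shape {arr.shape}")
        return cls(*(int(v) for v in arr.ravel()))


@dataclass
class GenotypeData:
    """Genotype matrix plus phenotype vector for a case-control sample.

    ``G`` has one row per subject and one column per variant site; entries are
    minor-allele copy counts in {0, 1, 2}.  ``y`` holds the phenotype (0 =
    control, 1 = case) of each subject, aligned with the rows of ``G``.
    """

    G: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G)
        self.y = np.asarray(self.y).ravel()
        if self.G.ndim != 2:
            raise InputValidationError("genotype matrix must be 2-dimensional")
        if self.G.shape[0] != self.y.shape[0]:
            raise InputValidationError(
                f"genotype matrix has {self.G.shape[0]} rows but phenotype vector "
                f"has {self.y.shape[0]} entries"
            )
        bad = np.argwhere(~np.isin(self.G, (0, 1, 2)))
        if bad.size:
            i, j = bad[0]
            raise InputValidationError(
                f"genotype entry at subject {i}, site {j} is {self.G[i, j]!r}; "
                "expected 0, 1 or 2 minor-allele copies"
            )
        bad_y = np.argwhere(~np.isin(self.y, (0, 1)))
        if bad_y.size:
            i = int(bad_y[0][0])
            raise InputValidationError(
                f"phenotype entry for subject {i} is {self.y[i]!r}; expected 0 or 1"
            )
        self.G = self.G.astype(np.int64, copy=False)
        self.y = self.y.astype(np.int64, copy=False)

    @property
    def n_subjects(self) -> int:
        return self.G.shape[0]

    @property
    def n_sites(self) -> int:
        return self.G.shape[1]

    @property
    def N(self) -> int:
        """Number of phenotype-0 (control) subjects."""
        return int(np.sum(self.y == 0))

    @property
    def M(self) -> int:
        """Number of phenotype-1 (case) subjects."""
        return int(np.sum(self.y == 1))


def build_contingency_tables(data: GenotypeData) -> np.ndarray:
    """Tally the per-site 2x3 contingency tables of a dataset.

    Returns an array of shape ``(p, 2, 3)`` where ``tables[j, 0]`` are the
    control counts ``(n0, n1, n2)`` and ``tables[j, 1]`` the case counts
    ``(m0, m1, m2)`` at site ``j``.  Row sums equal N and M at every site.
    """
    p = data.n_sites
    tables = np.zeros((p, 2, 3), dtype=np.int64)
    for pheno in (0, 1):
        sub = data.G[data.y == pheno]
        for g in (0, 1, 2):
            tables[:, pheno, g] = np.sum(sub == g, axis=0)
    return tables


def validate_null(null: np.ndarray) -> np.ndarray:
    """Check that ``null`` rows are strictly positive probability 3-vectors."""
    null = np.asarray(null, dtype=float)
    if null.shape[-1] != 3:
        raise InputValidationError("null distribution must have 3 components")
    if np.any(null <= 0):
        raise InputValidationError("null distribution components must be > 0")
    if np.any(np.abs(null.sum(axis=-1) - 1.0) > 1e-9):
        raise InputValidationError("null distribution must sum to 1")
    return null


def tilt_log_factors(theta: InfluenceStrengths) -> np.ndarray:
    """Per-state additive log tilts, shape (3 states, 3 genotypes).

    Row order follows :data:`STATE_LABELS`: Negative, No, Positive Influence.
    """
    return np.array(
        [
            [theta.theta0_minus, 0.0, -theta.theta1_minus],
            [0.0, 0.0, 0.0],
            [-theta.theta0_plus, 0.0, theta.theta1_plus],
        ]
    )


def case_distribution(
    state: int, null: np.ndarray, theta: InfluenceStrengths
) -> np.ndarray:
    """Case genotype distribution q at one site given the influence state.

    ``null`` may be a single 3-vector or an array of 3-vectors in its last
    axis; the tilt is applied and re-normalized along that axis.
    """
    if state not in STATE_LABELS:
        raise InputValidationError(f"state must be one of {STATE_LABELS}, got {state}")
    null = validate_null(null)
    c = tilt_log_factors(theta)[STATE_LABELS.index(state)]
    unnorm = np.exp(c) * null
    return unnorm / unnorm.sum(axis=-1, keepdims=True)


def case_distributions(nulls: np.ndarray, theta: InfluenceStrengths) -> np.ndarray:
    """All three case distributions per site; shape ``(p, 3 states, 3)``."""
    nulls = np.atleast_2d(np.asarray(nulls, dtype=float))
    tilts = np.exp(tilt_log_factors(theta))  # (3 states, 3 genotypes)
    unnorm = nulls[:, None, :] * tilts[None, :, :]
    return unnorm / unnorm.sum(axis=-1, keepdims=True)


def log_multinomial_coeff(counts: np.ndarray) -> np.ndarray:
    """log of the multinomial coefficient total!/(c0!c1!...) along the last axis."""
    counts = np.asarray(counts, dtype=float)
    return gammaln(counts.sum(axis=-1) + 1.0) - gammaln(counts + 1.0).sum(axis=-1)


def _xlogy_sum(counts: np.ndarray, probs: np.ndarray, axis: int = -1) -> np.ndarray:
    """sum(counts * log(probs)) with the 0*log(0)=0 convention, -inf otherwise."""
    counts = np.asarray(counts, dtype=float)
    probs = np.asarray(probs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(probs)
    terms = np.where(counts == 0, 0.0, terms)
    return terms.sum(axis=axis)


def emission_log_prob(
    table: SiteContingencyTable | np.ndarray, null: np.ndarray, q: np.ndarray
) -> float:
    """Natural-log emission probability of one 2x3 table.

    The emission is the product of two multinomials: the control row under the
    null distribution ``p`` and the case row under the state-specific case
    distribution ``q``.  A zero probability facing a positive count yields
    ``-inf`` rather than an exception.
    """
    if isinstance(table, SiteContingencyTable):
        arr = table.as_array()
    else:
        arr = np.asarray(table)
        if arr.shape != (2, 3):
            raise InputValidationError(f"expected a 2x3 table, got shape {arr.shape}")
    n_row, m_row = arr[0], arr[1]
    value = (
        log_multinomial_coeff(n_row)
        + _xlogy_sum(n_row, null)
        + log_multinomial_coeff(m_row)
        + _xlogy_sum(m_row, q)
    )
    return float(value)


def emission_log_prob_matrix(
    tables: np.ndarray,
    nulls: np.ndarray,
    theta: InfluenceStrengths,
    log_coeff: np.ndarray | None = None,
) -> np.ndarray:
    """Log emission probabilities for all sites and states; shape ``(p, 3)``.

    ``log_coeff`` (the table-dependent multinomial coefficients, as returned
    by ``log_multinomial_coeff(tables).sum(-1)``-style precomputation) may be
    supplied to avoid recomputing it across EM iterations.
    """
    tables = np.asarray(tables)
    nulls = np.asarray(nulls, dtype=float)
    if log_coeff is None:
        log_coeff = log_multinomial_coeff(tables).sum(axis=-1)  # (p,)
    q = case_distributions(nulls, theta)  # (p, 3, 3)
    control_part = _xlogy_sum(tables[:, 0, :], nulls)  # (p,)
    case_part = _xlogy_sum(tables[:, 1, None, :], q, axis=-1)  # (p, 3)
    return log_coeff[:, None] + control_part[:, None] + case_part
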