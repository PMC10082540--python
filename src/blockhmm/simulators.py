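"""Benchmark data generators.

Two engines produce case-control SNP datasets with known per-site truth:

* the **HMM-model simulator** draws a latent state chain and per-site
  genotype distributions from the influence model itself, then samples each
  site's contingency table directly from the two multinomials;
* the **block-model simulator** plants contiguous blocks of influential sites
  in a genome of independent Hardy-Weinberg sites, and generates phenotypes
  through a logistic disease model so that the causal direction (genotype ->
  phenotype) is the reverse of the HMM generative story.

The block engine's number of influential sites is drawn from an empirical
count distribution built once by simulating many HMM-model state chains and
discarding counts above a cap.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core_model import GenotypeData, InfluenceStrengths, case_distributions
from .errors import InputValidationError
from .hmm_engine import HmmParameters, MarkovParameters, random_pi, random_triple

#: Number of variant sites used throughout the benchmarks.
DEFAULT_N_SITES = 1024


@dataclass(frozen=True)
class HmmSimConfig:
    """HMM-model simulation settings (defaults match the benchmark regime)."""

    n_sites: int = DEFAULT_N_SITES
    n_controls: int = 1000
    n_cases: int = 1000

    def __post_init__(self) -> None:
        if min(self.n_sites, self.n_controls, self.n_cases) <= 0:
            raise InputValidationError("all HmmSimConfig sizes must be positive")


@dataclass(frozen=True)
class BlockSimConfig:
    """Block-model simulation settings.

    ``strength_mode`` selects how influential-site effect sizes |beta_j| are
    drawn: ``"maf_dependent"`` uses 0.3*|log10 q| so rarer alleles act more
    strongly, ``"uniform"`` draws U(0.6, 1.2).  ``maf_mode`` is ``"mixed"``
    (q = 0.001 * 500**u, 0.1%-50%) or ``"low"`` (q = 0.001 * 10**u, 0.1%-1%).
    ``impurity`` is the probability an in-block site reverts to No Influence;
    the target influential-site count is scaled by 1/(1-impurity) to
    compensate.
    """

    n_controls: int
    n_cases: int
    n_sites: int = DEFAULT_N_SITES
    strength_mode: str = "uniform"
    maf_mode: str = "mixed"
    noise_terms: bool = False
    impurity: float = 0.0
    count_list: tuple | None = None
    max_subject_attempts: int = 10_000_000

    def __post_init__(self) -> None:
        if min(self.n_controls, self.n_cases, self.n_sites) <= 0:
            raise InputValidationError("sample sizes and n_sites must be positive")
        if not (0 <= self.impurity < 1):
            raise InputValidationError("impurity must lie in [0, 1)")
        if self.strength_mode not in ("maf_dependent", "uniform"):
            raise InputValidationError(f"unknown strength_mode {self.strength_mode!r}")
        if self.maf_mode not in ("mixed", "low"):
            raise InputValidationError(f"unknown maf_mode {self.maf_mode!r}")


@dataclass
class SimulatedDataset:
    """A synthesized dataset with ground truth and full generation record."""

    data: GenotypeData
    truth: np.ndarray
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# HMM-model engine
# ---------------------------------------------------------------------------


def _sample_markov_batch(rng: np.random.Generator, reps: int):
    """Vectorized draw of `reps` (pi, A) pairs from the HMM-simulation priors.

    Diagonals: a00 = 0.5 + 0.5*Beta(99,1); the influence-state diagonals use
    Beta(90,10).  Off-diagonal mass from state 0 splits U(0,1); from the
    influence states a Beta(99,1) share returns to No Influence.
    State order is the internal index (-1, 0, +1) -> (0, 1, 2).
    """
    triples = random_triple(rng, reps)  # descending
    coin = rng.random(reps) < 0.5
    pis = np.empty((reps, 3))
    pis[:, 1] = triples[:, 0]
    pis[:, 0] = np.where(coin, triples[:, 1], triples[:, 2])
    pis[:, 2] = np.where(coin, triples[:, 2], triples[:, 1])

    a00 = 0.5 + 0.5 * rng.beta(99, 1, reps)
    a_nn = 0.5 + 0.5 * rng.beta(90, 10, reps)
    a_pp = 0.5 + 0.5 * rng.beta(90, 10, reps)
    t1 = rng.random(reps)
    t2 = rng.beta(99, 1, reps)
    t3 = rng.beta(99, 1, reps)
    As = np.empty((reps, 3, 3))
    As[:, 1, 1] = a00
    As[:, 1, 0] = t1 * (1 - a00)
    As[:, 1, 2] = (1 - t1) * (1 - a00)
    As[:, 0, 0] = a_nn
    As[:, 0, 1] = t2 * (1 - a_nn)
    As[:, 0, 2] = (1 - t2) * (1 - a_nn)
    As[:, 2, 2] = a_pp
    As[:, 2, 1] = t3 * (1 - a_pp)
    As[:, 2, 0] = (1 - t3) * (1 - a_pp)
    return pis, As


def simulate_hmm_parameters(rng: np.random.Generator, n_sites: int = DEFAULT_N_SITES) -> HmmParameters:
    """Random ground-truth parameters for an HMM-model dataset.

    Nulls are sorted random triples per site; each strength component is
    U(0.05, 1) (the lower bound keeps influences detectable in principle);
    pi and A come from the batch priors above.
    """
    nulls = random_triple(rng, n_sites)
    theta = InfluenceStrengths(*rng.uniform(0.05, 1.0, 4))
    pi, A = _sample_markov_batch(rng, 1)
    return HmmParameters(nulls, theta, MarkovParameters(pi[0], A[0]))


def sample_state_chain(
    markov: MarkovParameters, n_sites: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample a latent chain; returns internal state indices (0, 1, 2)."""
    cum_pi = np.cumsum(markov.pi)
    cum_A = np.cumsum(markov.A, axis=1)
    states = np.empty(n_sites, dtype=np.int64)
    states[0] = int(np.searchsorted(cum_pi, rng.random(), side="right"))
    for j in range(1, n_sites):
        states[j] = int(np.searchsorted(cum_A[states[j - 1]], rng.random(), side="right"))
    return np.minimum(states, 2)


def simulate_hmm_dataset(
    config: HmmSimConfig,
    rng: np.random.Generator,
    params: HmmParameters | None = None,
    states: np.ndarray | None = None,
) -> SimulatedDataset:
    """Generate one dataset from the influence model itself.

    A truth chain is drawn from (pi, A); at each site the control row is
    multinomial(N, p_j) and the case row multinomial(M, q_j) with q_j the
    state-tilted case distribution.  Genotype columns are filled by shuffling
    subjects within each phenotype group to meet the sampled counts exactly,
    so rebuilding the contingency tables recovers the draws.  ``params`` and
    ``states`` may be supplied to fix the generating model (used by
    parameter-recovery checks).
    """
    if params is None:
        params = simulate_hmm_parameters(rng, config.n_sites)
    if params.n_sites != config.n_sites:
        raise InputValidationError("params cover a different number of sites")
    if states is None:
        state_idx = sample_state_chain(params.markov, config.n_sites, rng)
    else:
        states = np.asarray(states)
        if not np.all(np.isin(states, (-1, 0, 1))):
            raise InputValidationError("states must be labels in {-1, 0, 1}")
        state_idx = states + 1
    N, M = config.n_controls, config.n_cases

    q_all = case_distributions(params.nulls, params.theta)  # (p, 3, 3)
    q_sel = q_all[np.arange(config.n_sites), state_idx]
    control_rows = rng.multinomial(N, params.nulls)  # (p, 3)
    case_rows = rng.multinomial(M, q_sel)

    G = np.empty((N + M, config.n_sites), dtype=np.int64)
    genotypes = np.array([0, 1, 2])
    for j in range(config.n_sites):
        G[:N, j] = rng.permutation(np.repeat(genotypes, control_rows[j]))
        G[N:, j] = rng.permutation(np.repeat(genotypes, case_rows[j]))
    y = np.concatenate([np.zeros(N, dtype=np.int64), np.ones(M, dtype=np.int64)])

    truth = state_idx - 1
    provenance = {
        "engine": "hmm",
        "nulls": params.nulls,
        "theta": params.theta.as_dict(),
        "pi": params.markov.pi,
        "A": params.markov.A,
        "control_rows": control_rows,
        "case_rows": case_rows,
    }
    return SimulatedDataset(GenotypeData(G, y), truth, provenance)


def influential_count_distribution(
    rng: np.random.Generator,
    reps: int = 10_000,
    cap: int = 300,
    n_sites: int = DEFAULT_N_SITES,
) -> np.ndarray:
    """Empirical distribution of influential-site counts under the HMM priors.

    Draws ``reps`` (pi, A) pairs and a state chain from each, counts the
    non-zero-state sites, and discards counts above ``cap``.  Only the chains
    are needed, so no genotypes are generated.
    """
    pis, As = _sample_markov_batch(rng, reps)
    cum_pi = np.cumsum(pis, axis=1)
    cum_A = np.cumsum(As, axis=2)
    u = rng.random(reps)
    state = (u[:, None] > cum_pi).sum(axis=1)
    counts = (state != 1).astype(np.int64)
    rows = np.arange(reps)
    for _j in range(1, n_sites):
        u = rng.random(reps)
        state = (u[:, None] > cum_A[rows, state]).sum(axis=1)
        counts += state != 1
    kept = counts[counts <= cap]
    if kept.size == 0:
        raise InputValidationError("count distribution is empty after capping")
    return kept


@functools.lru_cache(maxsize=8)
def default_count_list(
    seed: int, reps: int = 10_000, cap: int = 300, n_sites: int = DEFAULT_N_SITES
) -> tuple:
    """Session-cached influential-site count distribution for block models."""
    rng = np.random.default_rng([seed, 104_729])
    return tuple(influential_count_distribution(rng, reps, cap, n_sites).tolist())


# ---------------------------------------------------------------------------
# Block-model engine
# ---------------------------------------------------------------------------


def simulate_block_truth(
    config: BlockSimConfig, rng: np.random.Generator, count_list=None
):
    """Draw a ground-truth state sequence made of non-overlapping blocks.

    A target influential-site count is sampled from ``count_list`` (scaled by
    1/(1-impurity)); 1-4 blocks with Poisson lengths are placed uniformly at
    random without overlap; each block is Negative or Positive Influence with
    equal probability; in-block sites revert to No Influence independently
    with probability ``impurity``.
    Returns ``(truth, blocks)`` with blocks as (start, length, sign) tuples.
    """
    counts = count_list if count_list is not None else config.count_list
    if counts is None:
        raise InputValidationError("a count_list is required to draw block truth")
    counts = np.asarray(counts)
    target = int(counts[rng.integers(0, counts.size)])
    if config.impurity > 0:
        target = int(round(target / (1.0 - config.impurity)))

    n_blocks = int(rng.integers(1, 5))
    lengths = None
    for _ in range(1000):
        cand = rng.poisson(target / n_blocks, n_blocks)
        cand = np.maximum(cand, 1)
        if cand.sum() <= config.n_sites:
            lengths = cand
            break
    if lengths is None:
        raise InputValidationError(
            f"cannot place {n_blocks} blocks with ~{target} influential sites "
            f"in {config.n_sites} sites"
        )

    starts = None
    for _ in range(10_000):
        cand = np.array([rng.integers(0, config.n_sites - L + 1) for L in lengths])
        order = np.argsort(cand)
        s, l = cand[order], lengths[order]
        if np.all(s[1:] >= s[:-1] + l[:-1]):
            starts, lengths = s, l
            break
    if starts is None:
        raise InputValidationError("failed to place non-overlapping blocks")

    truth = np.zeros(config.n_sites, dtype=np.int64)
    blocks = []
    for start, length in zip(starts, lengths):
        sign = -1 if rng.random() < 0.5 else 1
        states = np.full(length, sign, dtype=np.int64)
        if config.impurity > 0:
            states[rng.random(length) < config.impurity] = 0
        truth[start : start + length] = states
        blocks.append((int(start), int(length), int(sign)))
    return truth, blocks


def _draw_mafs(config: BlockSimConfig, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(config.n_sites)
    base = 500.0 if config.maf_mode == "mixed" else 10.0
    return 0.001 * base**u


def simulate_block_dataset(
    config: BlockSimConfig,
    rng: np.random.Generator,
    count_list=None,
    truth: np.ndarray | None = None,
) -> SimulatedDataset:
    """Generate one dataset under the logistic block disease model.

    Genotypes are independent Hardy-Weinberg draws per site; the phenotype is
    Bernoulli with logit P(Y=1) = beta0 + sum_j beta_j G_j (+ optional noise
    0.5*X1 + 0.5*X2 with X1 standard normal and X2 a fair coin).  The
    intercept beta0 = -mu + log(b/a) targets the desired case:control ratio,
    with mu estimated as the mean genetic score of 1000 fresh genotypes.
    Subjects are generated one at a time and kept only while their phenotype's
    quota is unfilled.  Sites with no minor-allele carriers are removed from
    both the genotype matrix and the truth vector.  A fixed ``truth`` vector
    may be supplied instead of drawing one (used by calibration checks).
    """
    if truth is None:
        truth, blocks = simulate_block_truth(config, rng, count_list)
    else:
        truth = np.asarray(truth, dtype=np.int64)
        if truth.shape != (config.n_sites,):
            raise InputValidationError("truth must have one state per site")
        blocks = []
    mafs = _draw_mafs(config, rng)

    beta = np.zeros(config.n_sites)
    influential = truth != 0
    n_inf = int(influential.sum())
    if config.strength_mode == "maf_dependent":
        magnitude = 0.3 * np.abs(np.log10(mafs[influential]))
    else:
        magnitude = rng.uniform(0.6, 1.2, n_inf)
    beta[influential] = magnitude * truth[influential]

    ref = rng.binomial(2, mafs, size=(1000, config.n_sites))
    mu = float((ref @ beta).mean())
    a, b = config.n_controls, config.n_cases
    beta0 = -mu + np.log(b / a)

    need = [a, b]
    rows, phenos = [], []
    attempts = 0
    batch = max(256, (a + b) // 4)
    while need[0] > 0 or need[1] > 0:
        if attempts >= config.max_subject_attempts:
            raise InputValidationError(
                f"subject quota not met after {attempts} attempts "
                f"(still need {need[0]} controls, {need[1]} cases)"
            )
        B = min(batch, config.max_subject_attempts - attempts)
        Gb = rng.binomial(2, mafs, size=(B, config.n_sites))
        logits = beta0 + Gb @ beta
        if config.noise_terms:
            logits = logits + 0.5 * rng.standard_normal(B) + 0.5 * rng.integers(0, 2, B)
        yb = (rng.random(B) < expit(logits)).astype(np.int64)
        attempts += B
        # sequential quota fill over the batch
        take0 = np.cumsum(yb == 0) <= need[0]
        take1 = np.cumsum(yb == 1) <= need[1]
        keep = np.where(yb == 0, take0, take1)
        rows.append(Gb[keep])
        phenos.append(yb[keep])
        kept_y = yb[keep]
        need[0] -= int(np.sum(kept_y == 0))
        need[1] -= int(np.sum(kept_y == 1))

    G = np.vstack(rows)
    y = np.concatenate(phenos)

    carriers = G.sum(axis=0) > 0
    provenance = {
        "engine": "block",
        "mafs": mafs,
        "beta": beta,
        "beta0": float(beta0),
        "mu": mu,
        "blocks": blocks,
        "impurity": config.impurity,
        "noise_terms": config.noise_terms,
        "removed_sites": int(np.sum(~carriers)),
        "attempts": attempts,
    }
    return SimulatedDataset(
        GenotypeData(G[:, carriers], y), truth[carriers], provenance
    )


# ---------------------------------------------------------------------------
# Benchmark groups
# ---------------------------------------------------------------------------

#: The nine benchmark configurations: (engine, settings, default trial count).
SIMULATION_GROUPS: dict[int, dict] = {
    1: {"engine": "hmm", "n_controls": 1000, "n_cases": 1000, "trials": 20},
    2: {"engine": "block", "n_controls": 1000, "n_cases": 1000,
        "strength_mode": "maf_dependent", "maf_mode": "mixed",
        "noise_terms": False, "impurity": 0.0, "trials": 20},
    3: {"engine": "block", "n_controls": 1000, "n_cases": 1000,
        "strength_mode": "uniform", "maf_mode": "mixed",
        "noise_terms": True, "impurity": 0.25, "trials": 20},
    4: {"engine": "block", "n_controls": 1000, "n_cases": 1000,
        "strength_mode": "uniform", "maf_mode": "mixed",
        "noise_terms": True, "impurity": 0.5, "trials": 20},
    5: {"engine": "block", "n_controls": 1500, "n_cases": 500,
        "strength_mode": "uniform", "maf_mode": "mixed",
        "noise_terms": False, "impurity": 0.0, "trials": 20},
    6: {"engine": "block", "n_controls": 1500, "n_cases": 500,
        "strength_mode": "uniform", "maf_mode": "mixed",
        "noise_terms": True, "impurity": 0.25, "trials": 20},
    7: {"engine": "block", "n_controls": 150, "n_cases": 150,
        "strength_mode": "uniform", "maf_mode": "mixed",
        "noise_terms": False, "impurity": 0.0, "trials": 40},
    8: {"engine": "block", "n_controls": 200, "n_cases": 100,
        "strength_mode": "uniform", "maf_mode": "mixed",
        "noise_terms": False, "impurity": 0.0, "trials": 40},
    9: {"engine": "block", "n_controls": 2500, "n_cases": 2500,
        "strength_mode": "uniform", "maf_mode": "low",
        "noise_terms": False, "impurity": 0.0, "trials": 20},
}


def group_config(group_id: int, n_sites: int = DEFAULT_N_SITES):
    """The simulation configuration object for one benchmark group."""
    if group_id not in SIMULATION_GROUPS:
        raise InputValidationError(f"unknown simulation group {group_id}; use 1-9")
    spec = SIMULATION_GROUPS[group_id]
    if spec["engine"] == "hmm":
        return HmmSimConfig(n_sites=n_sites, n_controls=spec["n_controls"],
                            n_cases=spec["n_cases"])
    return BlockSimConfig(
        n_controls=spec["n_controls"],
        n_cases=spec["n_cases"],
        n_sites=n_sites,
        strength_mode=spec["strength_mode"],
        maf_mode=spec["maf_mode"],
        noise_terms=spec["noise_terms"],
        impurity=spec["impurity"],
    )


def run_simulation_group(
    group_id: int,
    n_trials: int | None = None,
    seed: int = 0,
    n_sites: int = DEFAULT_N_SITES,
    count_list=None,
) -> list[SimulatedDataset]:
    """Generate the datasets of one benchmark group with per-trial sub-seeds.

    The block-model count distribution is built once per session (from
    ``seed``) and shared across groups unless ``count_list`` is given.
    """
    spec = SIMULATION_GROUPS.get(group_id)
    if spec is None:
        raise InputValidationError(f"unknown simulation group {group_id}; use 1-9")
    if n_trials is None:
        n_trials = spec["trials"]
    config = group_config(group_id, n_sites)
    if spec["engine"] == "block" and count_list is None:
        count_list = default_count_list(seed, n_sites=n_sites)
    datasets = []
    for trial in range(n_trials):
        rng = np.random.default_rng([seed, group_id, trial])
        if spec["engine"] == "hmm":
            ds = simulate_hmm_dataset(config, rng)
        else:
            ds = simulate_block_dataset(config, rng, count_list)
        ds.provenance["group"] = group_id
        ds.provenance["trial"] = trial
        ds.provenance["seed"] = [seed, group_id, trial]
        datasets.append(ds)
    return datasets
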