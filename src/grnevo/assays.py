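"""Network-level assays: mutation accumulation, robustness/epistasis fits,
and the evolvability assay.

Mutation accumulation imposes m = 1..6 simultaneous mutations (each level
replicated 50 times) on randomly chosen non-zero elements and records the
percentage of mutants that remain developmentally viable (W_m) and the mean
Euclidean distance between pre- and post-mutation phenotypes among viable
mutants. Responses are summarized by power laws fitted with log-log OLS:

    viability:  ln(W_m) = -alpha * m^beta + ln(100)
    distance:   W_m = alpha * m^beta

beta is the directional-epistasis exponent (beta > 1 synergistic: each
additional mutation hurts more; beta < 1 antagonistic; beta = 1 independent
effects) and alpha the single-mutation effect size. Viability robustness is
W_1 = 100*exp(-alpha); phenotypic robustness is 1/W_1 = 1/alpha of the
distance fit (the inverse of the fitted single-mutation distance).

The evolvability assay clones a network into a fresh population of 250 and
selects it for four generations toward each of ten random target phenotypes
under the standard engine; the rate of adaptation is the per-generation
decline of ln Euclidean distance to the target (pooled member-level OLS) and
the production of phenotypic variation the SD of member distances averaged
over the four selected generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .config import SimConfig
from .core import RegulatoryNetwork, develop, develop_batch
from .errors import FitDegenerateError, GrnError
from .evolution import Population, log_fitness_batch, make_offspring_pool, _truncate

DEFAULT_M_VALUES = tuple(range(1, 7))
EXPANDED_M_VALUES = tuple(range(1, 51))
DEFAULT_REPLICATES = 50
DISTANCE_FLOOR = 1e-6


@dataclass
class MutationResponse:
    """Per-m viability and phenotypic-distance response of one network."""

    m_values: np.ndarray
    percent_viable: np.ndarray  # W_m, in percent
    mean_distance: np.ndarray  # NaN where no replicate was viable
    replicates: int


@dataclass
class MutationResponseFit:
    """Estimated power-law parameters for one response mode."""

    mode: str  # "viability" or "distance"
    alpha: float
    beta: float
    r2: float
    w1: Optional[float] = None  # viability robustness, percent
    robustness: Optional[float] = None  # phenotypic robustness 1/W_1


@dataclass
class EvolvabilityMeasure:
    """Averaged evolvability of one network over the assay targets."""

    adaptation_rate: float
    phenotypic_variation: float
    n_targets: int
    per_target_rates: np.ndarray = field(default_factory=lambda: np.empty(0))
    per_target_variation: np.ndarray = field(default_factory=lambda: np.empty(0))
    initial_distances: np.ndarray = field(default_factory=lambda: np.empty(0))


def random_target(N: int, rng: np.random.Generator) -> np.ndarray:
    """A random optimal phenotype: elements i.i.d. uniform on [-1, +1]."""
    return rng.uniform(-1.0, 1.0, size=N)


def mutation_accumulation(
    net: RegulatoryNetwork,
    s0: np.ndarray,
    m_values: Sequence[int] = DEFAULT_M_VALUES,
    replicates: int = DEFAULT_REPLICATES,
    rng: Optional[np.random.Generator] = None,
    steps: int = 100,
    a: float = 1.0,
    threshold: float = 1e-4,
    with_replacement: bool = False,
) -> MutationResponse:
    """Impose m simultaneous mutations, replicated, and record the response.

    Each mutant has m distinct non-zero elements (sampled without
    replacement unless ``with_replacement``) replaced by fresh standard-
    normal draws, then develops from the lineage's founding state ``s0``.
    """
    if rng is None:
        rng = np.random.default_rng()
    m_values = np.asarray(list(m_values), dtype=int)
    loci = np.flatnonzero(net.mask.ravel())
    if np.any(m_values < 0):
        raise ValueError("mutation counts must be >= 0")
    if not with_replacement and np.any(m_values > loci.size):
        raise ValueError(
            f"cannot place more than {loci.size} distinct mutations"
        )
    pre = develop(net, s0, steps=steps, a=a, threshold=threshold).phenotype

    pct = np.empty(m_values.size)
    dist = np.full(m_values.size, np.nan)
    N = net.N
    for k, m in enumerate(m_values):
        mutants = np.repeat(net.weights.ravel()[None], replicates, axis=0)
        if m > 0:
            if with_replacement:
                sel = rng.integers(loci.size, size=(replicates, m))
            else:
                keys = rng.random((replicates, loci.size))
                sel = np.argpartition(keys, m - 1, axis=1)[:, :m]
            positions = loci[sel]
            mutants[np.arange(replicates)[:, None], positions] = rng.standard_normal(
                (replicates, m)
            )
        phen, _, viable, _ = develop_batch(
            mutants.reshape(replicates, N, N), s0, steps=steps, a=a, threshold=threshold
        )
        pct[k] = 100.0 * viable.mean()
        if viable.any():
            dist[k] = float(
                np.linalg.norm(phen[viable] - pre[None, :], axis=1).mean()
            )
    return MutationResponse(
        m_values=m_values, percent_viable=pct, mean_distance=dist, replicates=replicates
    )


def _loglog_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS of ln(y) on ln(x); returns (slope, intercept, r2)."""
    res = stats.linregress(np.log(x), np.log(y))
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_viability_powerlaw(
    resp: MutationResponse, clamp: bool = True
) -> MutationResponseFit:
    """Fit ln(W_m) = -alpha*m^beta + ln(100) by log-log regression.

    The transform y_m = ln(100) - ln(W_m) linearizes to
    ln(y_m) = ln(alpha) + beta*ln(m). Boundary observations (0% or 100%
    viable) are undefined under the transform; with ``clamp`` they are pulled
    half an observation inside the scale (0% -> 100/(2R), 100% ->
    100*(1 - 1/(2R)) for R replicates) so they stay usable, otherwise they
    are dropped. Interior observations are never touched.
    """
    m = resp.m_values.astype(float)
    w = resp.percent_viable.astype(float).copy()
    if clamp:
        w[w == 0.0] = 100.0 / (2 * resp.replicates)
        w[w == 100.0] = 100.0 * (1.0 - 1.0 / (2 * resp.replicates))
    usable = (m > 0) & (w > 0) & (w < 100.0)
    if usable.sum() < 2:
        raise FitDegenerateError(
            "fewer than 2 usable mutation levels for the viability fit"
        )
    y = np.log(100.0) - np.log(w[usable])
    beta, intercept, r2 = _loglog_fit(m[usable], y)
    alpha = float(np.exp(intercept))
    return MutationResponseFit(
        mode="viability", alpha=alpha, beta=beta, r2=r2,
        w1=float(100.0 * np.exp(-alpha)),
    )


def fit_distance_powerlaw(resp: MutationResponse) -> MutationResponseFit:
    """Fit W_m = alpha*m^beta to mean phenotypic distance.

    alpha = exp(intercept) is the fitted single-mutation distance W_1;
    phenotypic robustness is its inverse 1/W_1.
    """
    m = resp.m_values.astype(float)
    d = resp.mean_distance.astype(float)
    usable = (m > 0) & np.isfinite(d) & (d > 0)
    if usable.sum() < 2:
        raise FitDegenerateError(
            "fewer than 2 positive mutation levels for the distance fit"
        )
    beta, intercept, r2 = _loglog_fit(m[usable], d[usable])
    alpha = float(np.exp(intercept))
    return MutationResponseFit(
        mode="distance", alpha=alpha, beta=beta, r2=r2, robustness=float(1.0 / alpha)
    )


def evolvability_assay(
    net: RegulatoryNetwork,
    s0: np.ndarray,
    config: Optional[SimConfig] = None,
    rng: Optional[np.random.Generator] = None,
    n_targets: int = 10,
    generations: int = 4,
    distance_floor: float = DISTANCE_FLOOR,
    targets: Optional[Sequence[np.ndarray]] = None,
) -> EvolvabilityMeasure:
    """Directional-selection assay toward random target phenotypes.

    For each target, 250 clones of the network are selected for four
    generations by the standard engine (pool 1000, mu = 0.1, rank
    truncation). The adaptation rate is the negated pooled OLS slope of
    ln(distance) on generation index (generations 0..4, every member;
    distances floored before logging), so larger = faster adaptation.
    Phenotypic variation is the SD of member distances averaged over the
    four post-selection generations. Both are averaged across targets.
    ``targets`` overrides the random targets (e.g. for controls selecting
    toward the network's own phenotype).
    """
    if rng is None:
        rng = np.random.default_rng()
    if config is None:
        config = SimConfig()
    pop0 = Population.from_founder(
        net, s0, config.pop_size, steps=config.dev_steps, a=config.a,
        threshold=config.stability_threshold,
    )
    if targets is not None:
        targets = [np.asarray(t, dtype=float) for t in targets]
        n_targets = len(targets)
    rates = np.empty(n_targets)
    variations = np.empty(n_targets)
    init_dists = np.empty(n_targets)
    gen_idx = np.repeat(np.arange(generations + 1), config.pop_size).astype(float)
    for j in range(n_targets):
        target = targets[j] if targets is not None else random_target(net.N, rng)
        init_dists[j] = float(np.linalg.norm(pop0.phenotypes[0] - target))
        pop = pop0
        dists = np.empty((generations + 1, config.pop_size))
        dists[0] = np.linalg.norm(pop.phenotypes - target[None, :], axis=1)
        for g in range(1, generations + 1):
            pool = make_offspring_pool(pop, config, rng, generation=g)
            logf = log_fitness_batch(pool.phenotypes, target, config.sigma)
            idx = _truncate(logf, config.pop_size, rng)
            pop = Population(
                weights=pool.weights[idx].copy(),
                mask=pop.mask,
                s0=pop.s0,
                phenotypes=pool.phenotypes[idx].copy(),
                generation=g,
            )
            dists[g] = np.linalg.norm(pop.phenotypes - target[None, :], axis=1)
        y = np.log(np.maximum(dists, distance_floor)).ravel()
        slope = _pooled_slope(gen_idx, y)
        rates[j] = -slope
        # per-generation SD of member distances; a clonal generation has
        # exactly zero variation (no rounding residue from the mean)
        sds = dists[1:].std(axis=1, ddof=1)
        sds[np.ptp(dists[1:], axis=1) == 0.0] = 0.0
        variations[j] = float(sds.mean())
    return EvolvabilityMeasure(
        adaptation_rate=float(rates.mean()),
        phenotypic_variation=float(variations.mean()),
        n_targets=n_targets,
        per_target_rates=rates,
        per_target_variation=variations,
        initial_distances=init_dists,
    )


def _pooled_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    denom = np.dot(xc, xc)
    if denom == 0:
        return 0.0
    return float(np.dot(xc, y - y.mean()) / denom)
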