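"""Reproduction, mutation, truncation selection, and the generation loop.

Each generation a pool of exactly ``pool_size`` developmentally viable
offspring is assembled: parents are drawn uniformly at random from the
current population; sexual reproduction copies each of the N matrix rows
whole from one parent or the other with probability 1/2 (cis-regulatory
elements tightly linked to their gene), asexual reproduction clones a single
parent. Every non-zero matrix element of the offspring then mutates
independently with probability mu/(c*N^2), receiving a fresh standard-normal
value; topology never changes. Offspring that fail to develop stably are
discarded and redrawn — developmental instability is lethal before selection
acts. The ``pop_size`` offspring closest to the current optimal phenotype
(highest fitness F = exp(-D/sigma), rank-truncation with random tie-break)
form the next generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimConfig
from .core import (
    RegulatoryNetwork,
    develop,
    develop_batch,
    expression_distance,
)
from .errors import GrnError, MeltdownError
from .noise import (
    NoiseSeries,
    SelectionRegime,
    directional_targets,
    make_red_noise,
    optimum_at,
    whiten,
)
from .seeding import spawn_rngs


@dataclass
class Population:
    """An evolving population sharing one topology and one founding state.

    Stored as a stacked (K, N, N) weight array for batch evaluation;
    ``members`` materializes :class:`RegulatoryNetwork` views on demand.
    """

    weights: np.ndarray  # (K, N, N)
    mask: np.ndarray  # (N, N) shared topology
    s0: np.ndarray  # (N,) lineage founding expression state
    phenotypes: np.ndarray  # (K, N) realized phenotypes under s0
    generation: int = 0

    @property
    def size(self) -> int:
        return self.weights.shape[0]

    @property
    def members(self) -> list[RegulatoryNetwork]:
        return [RegulatoryNetwork(w.copy(), self.mask.copy()) for w in self.weights]

    @classmethod
    def from_founder(
        cls,
        net: RegulatoryNetwork,
        s0: np.ndarray,
        size: int,
        steps: int = 100,
        a: float = 1.0,
        threshold: float = 1e-4,
    ) -> "Population":
        res = develop(net, s0, steps=steps, a=a, threshold=threshold)
        if not res.viable:
            raise GrnError("founder is not developmentally viable under its s0")
        return cls(
            weights=np.repeat(net.weights[None], size, axis=0),
            mask=net.mask.copy(),
            s0=np.asarray(s0, dtype=float).copy(),
            phenotypes=np.repeat(res.phenotype[None], size, axis=0),
            generation=0,
        )


@dataclass
class OffspringPool:
    """A filled pool of viable offspring plus the attempt count."""

    weights: np.ndarray  # (pool_size, N, N)
    phenotypes: np.ndarray  # (pool_size, N)
    stability: np.ndarray  # (pool_size,)
    attempts: int


def recombine(
    parent_a: RegulatoryNetwork,
    parent_b: RegulatoryNetwork,
    rng: np.random.Generator,
) -> RegulatoryNetwork:
    """Row-wise free recombination of two parental matrices."""
    if parent_a.N != parent_b.N or not np.array_equal(parent_a.mask, parent_b.mask):
        raise GrnError("parents must share N and topology mask")
    take_a = rng.random(parent_a.N) < 0.5
    weights = np.where(take_a[:, None], parent_a.weights, parent_b.weights)
    return RegulatoryNetwork(weights.copy(), parent_a.mask.copy())


def mutate(
    net: RegulatoryNetwork, mu: float, rng: np.random.Generator
) -> RegulatoryNetwork:
    """Per-genome-rate mutation: each existing interaction independently hit
    with probability mu/(c*N^2) and redrawn from the standard normal."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    out = net.copy()
    if mu == 0:
        return out
    _mutate_batch_inplace(out.weights[None], net.mask, mu / net.n_links, rng)
    return out


def _mutate_batch_inplace(
    weights: np.ndarray, mask: np.ndarray, per_locus_rate: float, rng: np.random.Generator
) -> None:
    if per_locus_rate <= 0:
        return
    hits = (rng.random(weights.shape) < per_locus_rate) & mask
    n = int(hits.sum())
    if n:
        weights[hits] = rng.standard_normal(n)


def fitness(phenotype: np.ndarray, optimum: np.ndarray, sigma: float = 0.05) -> float:
    """Gaussian-decay fitness F = exp(-D/sigma) on the normalized distance D."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(np.exp(-expression_distance(phenotype, optimum) / sigma))


def log_fitness_batch(
    phenotypes: np.ndarray, optimum: np.ndarray, sigma: float
) -> np.ndarray:
    """log F for a (K, N) phenotype batch; avoids underflow of exp."""
    d = phenotypes - optimum[None, :]
    D = (d * d).sum(axis=1) / (4.0 * phenotypes.shape[1])
    return -D / sigma


def select_survivors(
    pool: OffspringPool,
    optimum: np.ndarray,
    pop_size: int,
    rng: np.random.Generator,
    sigma: float = 0.05,
    mask: Optional[np.ndarray] = None,
    s0: Optional[np.ndarray] = None,
    generation: int = 0,
) -> Population:
    """Rank-truncation: keep the ``pop_size`` fittest offspring.

    Survival depends only on fitness rank, so any strictly decreasing
    function of distance yields the same survivors; ties (e.g. clone-
    dominated pools) are broken uniformly at random.
    """
    if pool.weights.shape[0] < pop_size:
        raise GrnError("pool smaller than the requested population size")
    logf = log_fitness_batch(pool.phenotypes, np.asarray(optimum, float), sigma)
    idx = _truncate(logf, pop_size, rng)
    return Population(
        weights=pool.weights[idx].copy(),
        mask=mask if mask is not None else np.ones(pool.weights.shape[1:], bool),
        s0=s0 if s0 is not None else np.zeros(pool.weights.shape[1]),
        phenotypes=pool.phenotypes[idx].copy(),
        generation=generation,
    )


def _truncate(logf: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of the top-k values; ties broken uniformly at random."""
    perm = rng.permutation(logf.shape[0])
    order = perm[np.argsort(-logf[perm], kind="stable")]
    return order[:k]


def make_offspring_pool(
    pop: Population,
    config: SimConfig,
    rng: np.random.Generator,
    generation: int = 0,
) -> OffspringPool:
    """Fill a pool of exactly ``pool_size`` viable offspring.

    Candidates are produced in batches (vectorized recombination, mutation
    and development); inviable ones are discarded and redrawn. Exceeding
    ``attempt_cap_factor * pool_size`` development attempts raises
    :class:`MeltdownError` — mutation pressure so high that viable offspring
    cannot be assembled.
    """
    if pop.size == 0:
        raise GrnError("population is empty")
    K, N = pop.size, pop.weights.shape[1]
    need = config.pool_size
    cap = config.attempt_cap_factor * config.pool_size
    rate = config.per_locus_rate
    got, attempts = 0, 0
    acc_est = 0.85  # running viability estimate for batch sizing
    w_parts, p_parts, v_parts = [], [], []
    while got < need:
        budget = cap - attempts
        if budget <= 0:
            raise MeltdownError(generation, attempts)
        B = int(min(max(np.ceil((need - got) / acc_est * 1.03), 32), budget))
        if config.reproduction == "sexual":
            pa = rng.integers(K, size=B)
            if K > 1:  # two distinct parents per pair
                pb = rng.integers(K - 1, size=B)
                pb[pb >= pa] += 1
            else:
                pb = pa
            take_a = rng.random((B, N)) < 0.5
            off = np.where(take_a[:, :, None], pop.weights[pa], pop.weights[pb])
        else:
            off = pop.weights[rng.integers(K, size=B)].copy()
        _mutate_batch_inplace(off, pop.mask, rate, rng)
        phen, v, viable, _ = develop_batch(
            off,
            pop.s0,
            steps=config.dev_steps,
            a=config.a,
            threshold=config.stability_threshold,
        )
        attempts += B
        nv = int(viable.sum())
        if nv:
            w_parts.append(off[viable])
            p_parts.append(phen[viable])
            v_parts.append(v[viable])
            got += nv
        acc_est = max(0.5 * acc_est + 0.5 * (nv / B), 0.02)
        if got < need and attempts >= cap:
            raise MeltdownError(generation, attempts)
    weights = np.concatenate(w_parts)[:need]
    phen = np.concatenate(p_parts)[:need]
    stab = np.concatenate(v_parts)[:need]
    return OffspringPool(weights=weights, phenotypes=phen, stability=stab, attempts=attempts)


def build_regime(
    config: SimConfig,
    s_init: np.ndarray,
    rng: np.random.Generator,
) -> SelectionRegime:
    """Construct the optimum schedule for a run.

    Noise regimes synthesize one red series spanning the whole run (white
    regimes additionally permute it); directional regimes pick one of the
    five displaced targets sampled across half a dominant period.
    """
    if config.regime == "stabilizing":
        return SelectionRegime("stabilizing", s_init)
    series = make_red_noise(
        config.period,
        config.gamma,
        config.generations + 1,
        rng,
        normalize=config.normalize_noise,
    )
    if config.regime == "red":
        return SelectionRegime("red", s_init, noise=series)
    if config.regime == "white":
        return SelectionRegime("white", s_init, noise=whiten(series, rng))
    targets = directional_targets(s_init, series)
    return SelectionRegime(
        "directional", s_init, directional_target=targets[config.directional_target - 1]
    )


@dataclass
class SimulationResult:
    """Everything a run produces, sufficient to reproduce it bit-exactly."""

    config: SimConfig
    seed: Optional[int]
    founder: RegulatoryNetwork
    s0: np.ndarray
    s_init: np.ndarray
    mean_log_fitness: np.ndarray  # (generations,) survivor mean log F per generation
    metrics: pd.DataFrame  # tidy: generation, metric, value
    population: Population  # final population
    pool_attempts: int


def _cadence(config: SimConfig) -> list[int]:
    gens = set(range(config.assay_every, config.generations + 1, config.assay_every))
    if config.fine_cadence:
        gens.update(g for g in range(50, 501, 50) if g <= config.generations)
    return sorted(gens)


def run_simulation(
    config: SimConfig,
    founder: Optional[tuple[RegulatoryNetwork, np.ndarray]] = None,
    seed: Optional[int] = None,
) -> SimulationResult:
    """Run one population for ``config.generations`` generations.

    One master seed is split into independent founder/noise/evolution/assay
    streams, so e.g. changing the assay cadence cannot perturb the
    evolutionary trajectory. ``founder`` may supply a pre-generated
    (network, s0) pair; otherwise one is rejection-sampled from the founder
    stream.
    """
    from . import assays as assay_mod
    from . import metrics as popmetrics
    from .core import random_stable_seed

    rngs = spawn_rngs(seed, ["founder", "noise", "evolution", "assay"])
    if founder is None:
        net, s0 = random_stable_seed(
            config.N,
            config.c,
            rngs["founder"],
            max_tries=config.founder_max_tries,
            steps=config.dev_steps,
            a=config.a,
            threshold=config.stability_threshold,
        )
    else:
        net, s0 = founder
        s0 = np.asarray(s0, dtype=float)

    founder_net = net.copy()
    pop = Population.from_founder(
        net, s0, config.pop_size, steps=config.dev_steps, a=config.a,
        threshold=config.stability_threshold,
    )
    s_init = pop.phenotypes[0].copy()
    regime = build_regime(config, s_init, rngs["noise"])

    ev_rng = rngs["evolution"]
    cadence = set(_cadence(config))
    mean_logf = np.empty(config.generations)
    rows: list[dict] = []
    total_attempts = 0

    for t in range(1, config.generations + 1):
        pool = make_offspring_pool(pop, config, ev_rng, generation=t)
        total_attempts += pool.attempts
        opt = optimum_at(regime, t)
        logf = log_fitness_batch(pool.phenotypes, opt, config.sigma)
        idx = _truncate(logf, config.pop_size, ev_rng)
        pop = Population(
            weights=pool.weights[idx].copy(),
            mask=pop.mask,
            s0=pop.s0,
            phenotypes=pool.phenotypes[idx].copy(),
            generation=t,
        )
        mean_logf[t - 1] = float(logf[idx].mean())

        if t in cadence:
            rec = popmetrics.metrics_record(pop, founder_net)
            rec["mean_log_fitness"] = mean_logf[t - 1]
            if config.assay_mutation or config.assay_evolvability:
                rec.update(
                    _assay_battery(pop, config, rngs["assay"], assay_mod)
                )
            for name, value in rec.items():
                rows.append({"generation": t, "metric": name, "value": value})

    metrics_df = pd.DataFrame(rows, columns=["generation", "metric", "value"])
    return SimulationResult(
        config=config,
        seed=seed,
        founder=founder_net,
        s0=s0,
        s_init=s_init,
        mean_log_fitness=mean_logf,
        metrics=metrics_df,
        population=pop,
        pool_attempts=total_attempts,
    )


def _assay_battery(pop, config, rng, assay_mod) -> dict:
    """Optional per-network assays on a random sample of the population."""
    k = min(config.assay_sample, pop.size)
    sample = rng.choice(pop.size, size=k, replace=False)
    out: dict[str, float] = {}
    if config.assay_mutation:
        a_v, b_v, w1_v, a_d, b_d, rob_d = [], [], [], [], [], []
        for i in sample:
            net = RegulatoryNetwork(pop.weights[i].copy(), pop.mask.copy())
            resp = assay_mod.mutation_accumulation(net, pop.s0, rng=rng)
            try:
                fit = assay_mod.fit_viability_powerlaw(resp)
                a_v.append(fit.alpha); b_v.append(fit.beta); w1_v.append(fit.w1)
            except GrnError:
                pass
            try:
                fit = assay_mod.fit_distance_powerlaw(resp)
                a_d.append(fit.alpha); b_d.append(fit.beta); rob_d.append(fit.robustness)
            except GrnError:
                pass
        if a_v:
            out["viability_alpha"] = float(np.mean(a_v))
            out["viability_beta"] = float(np.mean(b_v))
            out["viability_robustness"] = float(np.mean(w1_v))
        if a_d:
            out["distance_alpha"] = float(np.mean(a_d))
            out["distance_beta"] = float(np.mean(b_d))
            out["phenotypic_robustness"] = float(np.mean(rob_d))
    if config.assay_evolvability:
        rates, varis = [], []
        for i in sample:
            net = RegulatoryNetwork(pop.weights[i].copy(), pop.mask.copy())
            ev = assay_mod.evolvability_assay(net, pop.s0, config=config, rng=rng)
            rates.append(ev.adaptation_rate)
            varis.append(ev.phenotypic_variation)
        out["adaptation_rate"] = float(np.mean(rates))
        out["phenotypic_variation"] = float(np.mean(varis))
    return out
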