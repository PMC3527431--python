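"""Population-level response variables recorded along a simulation.

Allelic diversity is the mean number of distinct weight values per non-zero
matrix position across the population (1 for a clonal population, up to the
population size). Phenotypic diversity counts distinct realized phenotype
vectors. Matrix change is the fraction of (member, locus) weights that differ
from the founder's values. The interaction profile multiplies each
off-diagonal interaction a_ij by the member's realized expression s_j of the
regulating gene: the absolute value measures interaction strength and the
sign the realized direction of regulation (activating vs repressing).

Value comparisons are exact by default: weights propagate by copy or fresh
standard-normal draw, so floating equality is meaningful; a tolerance knob
exists for robustness against externally produced data.
"""

from __future__ import annotations

import numpy as np

from .core import RegulatoryNetwork
from .errors import GrnError
from .evolution import Population

METRIC_NAMES = (
    "allelic_diversity",
    "phenotypic_diversity",
    "matrix_change",
    "interaction_strength",
    "prop_positive",
)


def _locus_matrix(pop: Population) -> np.ndarray:
    """(K, L) view of member weights at the L non-zero loci."""
    flat = pop.weights.reshape(pop.size, -1)
    return flat[:, pop.mask.ravel()]


def allelic_diversity(pop: Population, decimals: int | None = None) -> float:
    """Mean number of unique alleles per non-zero locus."""
    if pop.size == 0:
        raise GrnError("population is empty")
    w = _locus_matrix(pop)
    if decimals is not None:
        w = np.round(w, decimals)
    w = np.sort(w, axis=0)
    counts = 1 + (np.diff(w, axis=0) != 0).sum(axis=0)
    return float(counts.mean())


def phenotypic_diversity(pop: Population, decimals: int | None = None) -> int:
    """Number of distinct phenotype vectors in the population."""
    if pop.size == 0:
        raise GrnError("population is empty")
    p = pop.phenotypes
    if decimals is not None:
        p = np.round(p, decimals)
    return int(np.unique(p, axis=0).shape[0])


def matrix_change(pop: Population, founder: RegulatoryNetwork) -> float:
    """Fraction of member weights at non-zero loci that differ from the
    founder's values, averaged over members."""
    if not np.array_equal(pop.mask, founder.mask):
        raise GrnError("population and founder topology masks differ")
    w = _locus_matrix(pop)
    f = founder.weights.ravel()[pop.mask.ravel()]
    return float((w != f[None, :]).mean())


def interaction_profile(pop: Population) -> tuple[float, float]:
    """(mean interaction strength, proportion of positive interactions).

    For every member and every off-diagonal non-zero element a_ij, the signed
    realized effect is a_ij * s_j with s_j the member's own phenotype
    expression of the regulating gene. Strength is the mean absolute effect;
    prop_positive the fraction of effects strictly greater than zero (zero
    effects count as non-positive — a measure-zero event for continuous
    weights).
    """
    off = pop.mask & ~np.eye(pop.mask.shape[0], dtype=bool)
    if not off.any():
        return 0.0, 0.0
    i_idx, j_idx = np.nonzero(off)
    effects = pop.weights[:, i_idx, j_idx] * pop.phenotypes[:, j_idx]
    return float(np.abs(effects).mean()), float((effects > 0).mean())


def time_average(series: np.ndarray, window: int) -> float:
    """Arithmetic mean of the trailing ``window`` entries.

    Applied to per-generation log fitness this is the geometric-mean-fitness
    measure appropriate to fluctuating environments.
    """
    series = np.asarray(series, dtype=float)
    if window < 1 or window > series.shape[0]:
        raise GrnError(
            f"window {window} invalid for series of length {series.shape[0]}"
        )
    return float(series[-window:].mean())


def metrics_record(pop: Population, founder: RegulatoryNetwork) -> dict[str, float]:
    """All standard population metrics as one flat record."""
    strength, prop_pos = interaction_profile(pop)
    return {
        "allelic_diversity": allelic_diversity(pop),
        "phenotypic_diversity": float(phenotypic_diversity(pop)),
        "matrix_change": matrix_change(pop, founder),
        "interaction_strength": strength,
        "prop_positive": prop_pos,
    }
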