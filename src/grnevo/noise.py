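"""Colored environmental noise and optimal-phenotype schedules.

Red (positively autocorrelated) noise is synthesized by summing sine waves:

    E(t) = sum_{f=1..floor(n/2)} f^(-gamma) * sin(2*pi*f*t/n + theta_f)

where ``n`` is the period of the dominant (f=1, largest amplitude) wave,
``theta_f`` are random phases drawn once per series, and ``gamma`` steepens
the amplitude decay with frequency. gamma = 1 gives reddened noise that
approximates a single sine wave; gamma = 0 gives a flat amplitude spectrum.
The series is rescaled by its maximum absolute value so values span [-1, 1].

A white-noise control is an exact random permutation of a red series: the
value distribution (hence the total environmental variation) is identical,
only the temporal autocorrelation is destroyed.

A :class:`SelectionRegime` maps a generation index to the optimal phenotype
S_opt(t): constant at the founding phenotype (stabilizing), the founding
phenotype shifted by the scalar noise value and clipped to expression bounds
(red/white), or a fixed displaced target (directional).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigError


@dataclass
class NoiseSeries:
    """An environmental time series with its color parameters."""

    values: np.ndarray  # (T,) scalar series, or (T, N) per-gene series
    gamma: float
    period: int
    color: str  # "red" or "white"

    def __len__(self) -> int:
        return self.values.shape[0]


def make_red_noise(
    period: int,
    gamma: float,
    length: int,
    rng: np.random.Generator,
    normalize: bool = True,
    n_waves: Optional[int] = None,
    phases: Optional[np.ndarray] = None,
) -> NoiseSeries:
    """Spectral synthesis of a red noise series.

    ``n_waves`` and ``phases`` override the harmonic count (default
    floor(period/2)) and the random phases; they exist for degenerate,
    analytically checkable configurations.
    """
    if period < 2:
        raise ValueError(f"period must be >= 2, got {period}")
    if length < 1:
        raise ValueError("length must be >= 1")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    F = n_waves if n_waves is not None else max(period // 2, 1)
    theta = (
        np.asarray(phases, dtype=float)
        if phases is not None
        else rng.uniform(0.0, 2.0 * np.pi, size=F)
    )
    if theta.shape != (F,):
        raise ValueError("phases must have one entry per component wave")
    f = np.arange(1, F + 1, dtype=float)
    t = np.arange(length, dtype=float)
    # (T, F) phase matrix; amplitudes decay as f^-gamma
    values = (f ** -gamma * np.sin(2.0 * np.pi * np.outer(t, f) / period + theta)).sum(
        axis=1
    )
    if normalize:
        peak = np.abs(values).max()
        if peak > 0:
            values = values / peak
    return NoiseSeries(values=values, gamma=gamma, period=period, color="red")


def whiten(red: NoiseSeries, rng: np.random.Generator) -> NoiseSeries:
    """Random permutation of a red series; identical value multiset."""
    if red.color != "red":
        raise ValueError("whiten expects a red noise series")
    perm = rng.permutation(len(red))
    return NoiseSeries(
        values=red.values[perm], gamma=red.gamma, period=red.period, color="white"
    )


def lag1_autocorrelation(values: np.ndarray) -> float:
    """Diagnostic lag-1 autocorrelation of a series."""
    v = np.asarray(values, dtype=float)
    v = v - v.mean()
    denom = np.dot(v, v)
    if denom == 0:
        return 0.0
    return float(np.dot(v[:-1], v[1:]) / denom)


@dataclass
class SelectionRegime:
    """Rule mapping generation t to the optimal phenotype S_opt(t)."""

    regime_type: str  # stabilizing | directional | red | white
    s_init: np.ndarray
    noise: Optional[NoiseSeries] = None
    directional_target: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.regime_type not in ("stabilizing", "directional", "red", "white"):
            raise ConfigError(f"unknown regime type {self.regime_type!r}")
        self.s_init = np.asarray(self.s_init, dtype=float)
        if self.regime_type in ("red", "white") and self.noise is None:
            raise ConfigError(f"{self.regime_type} regime requires a noise series")
        if self.regime_type == "directional":
            if self.directional_target is None:
                raise ConfigError("directional regime requires a target phenotype")
            self.directional_target = np.asarray(self.directional_target, dtype=float)


def optimum_at(regime: SelectionRegime, t: int) -> np.ndarray:
    """Optimal phenotype at generation ``t``, clipped to expression bounds.

    For noise regimes the scalar environmental value at ``t`` is added to
    every gene of the founding phenotype (one shared environmental variable);
    a (T, N) noise series adds per-gene values instead.
    """
    if regime.regime_type == "stabilizing":
        return regime.s_init.copy()
    if regime.regime_type == "directional":
        return regime.directional_target.copy()
    if t >= len(regime.noise) or t < 0:
        raise IndexError(f"generation {t} outside noise series of length {len(regime.noise)}")
    shift = regime.noise.values[t]
    return np.clip(regime.s_init + shift, -1.0, 1.0)


def directional_targets(
    s_init: np.ndarray, red: NoiseSeries, n_targets: int = 5
) -> list[np.ndarray]:
    """Candidate directional-selection optima.

    Samples the red series at even intervals across half the dominant period
    (t_k = k*n/10 for k = 1..5 with n = 50) and shifts the founding phenotype
    by each sampled value, clipping to [-1, +1]. The targets therefore span a
    range of displacement comparable to what fluctuating selection imposes.
    """
    if red.color != "red":
        raise ValueError("directional targets are drawn from a red series")
    half = red.period // 2
    if len(red) <= half:
        raise ValueError("noise series shorter than half a period")
    s_init = np.asarray(s_init, dtype=float)
    indices = [int(round(k * red.period / (2 * n_targets))) for k in range(1, n_targets + 1)]
    return [np.clip(s_init + red.values[i], -1.0, 1.0) for i in indices]
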