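"""Genotypes and developmental dynamics of model gene regulatory networks.

A genotype is an ``N x N`` real matrix ``A`` whose element ``a_ij`` is the
regulatory effect of gene ``j`` on gene ``i``. A fixed boolean mask defines
which interactions exist (the network topology); topology never changes under
mutation or recombination, only interaction strengths and signs evolve.

Development iterates the synchronous map

    s_i(t+1) = f( sum_j a_ij * s_j(t) ),    f(x) = 2 / (1 + exp(-a*x)) - 1,

for a fixed window of 100 steps from a founding expression state ``s0``. Each
expression level lies in (-1, +1): +1 is complete activation, -1 complete
repression. A genotype is developmentally stable (viable) when expression
settles: the mean normalized squared deviation of the last 10 states from
their average (the stability index ``V``) falls below 1e-4. Oscillatory or
chaotic trajectories are lethal.

Batched variants (`develop_batch`) evaluate many genotypes simultaneously and
are the workhorses of the evolution engine and the assay battery; `develop`
is the single-genotype reference API.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GenerationFailureError, GrnError

# Model-wide defaults: 100 developmental steps, stability judged on the last
# 10 of them with threshold 1e-4, sigmoid gain a = 1.
DEV_STEPS = 100
TAIL_WINDOW = 10
STABILITY_THRESHOLD = 1e-4
SIGMOID_GAIN = 1.0


@dataclass
class RegulatoryNetwork:
    """A gene network genotype: weights plus an immutable topology mask."""

    weights: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise GrnError("weights must be a square matrix")
        if self.mask.shape != self.weights.shape:
            raise GrnError("mask shape must match weights")
        if np.any(self.weights[~self.mask] != 0.0):
            raise GrnError("weights must be zero outside the topology mask")

    @property
    def N(self) -> int:
        return self.weights.shape[0]

    @property
    def c(self) -> float:
        """Connectance: fraction of the N*N possible interactions present."""
        return float(self.mask.sum()) / (self.N * self.N)

    @property
    def n_links(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "RegulatoryNetwork":
        return RegulatoryNetwork(self.weights.copy(), self.mask.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return (
            self.weights.shape == other.weights.shape
            and np.array_equal(self.weights, other.weights)
            and np.array_equal(self.mask, other.mask)
        )


@dataclass
class DevelopmentResult:
    """Outcome of one developmental run.

    ``phenotype`` is the expression state at the final step (S_p),
    ``stability_index`` the variability V of the last 10 states, ``viable``
    whether V fell below the stability threshold, and ``tail_states`` the
    (10, N) array of those last states.
    """

    phenotype: np.ndarray
    stability_index: float
    viable: bool
    tail_states: np.ndarray


def sigmoid(x, a: float = SIGMOID_GAIN):
    """Regulatory input-to-expression map with range (-1, +1).

    ``a`` sets the steepness of the transition from repression to activation.
    Odd and strictly increasing; f(0) = 0.
    """
    if a <= 0:
        raise ValueError(f"sigmoid gain must be positive, got {a}")
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow saturates correctly to -1
        out = 2.0 / (1.0 + np.exp(-a * x)) - 1.0
    return out if out.ndim else float(out)


def random_network(N: int, c: float, rng: np.random.Generator) -> RegulatoryNetwork:
    """Draw a random genotype: round(c*N^2) interactions placed uniformly,
    weights i.i.d. standard normal."""
    if not (isinstance(N, (int, np.integer)) and N >= 2):
        raise ValueError(f"N must be an integer >= 2, got {N}")
    if not (0.0 < c <= 1.0):
        raise ValueError(f"connectance must lie in (0, 1], got {c}")
    n_links = int(round(c * N * N))
    flat = rng.choice(N * N, size=n_links, replace=False)
    mask = np.zeros(N * N, dtype=bool)
    mask[flat] = True
    mask = mask.reshape(N, N)
    weights = np.zeros((N, N))
    weights[mask] = rng.standard_normal(n_links)
    return RegulatoryNetwork(weights, mask)


def random_expression_state(N: int, rng: np.random.Generator) -> np.ndarray:
    """Founding expression state: each gene uniform on [-1, +1]."""
    return rng.uniform(-1.0, 1.0, size=N)


def expression_distance(s1: np.ndarray, s2: np.ndarray) -> float:
    """Normalized squared distance D(s1, s2) = sum (s1_i - s2_i)^2 / (4N).

    Normalization by 4N maps the maximal separation (all genes at opposite
    saturation) to 1, so V and the fitness distance live on [0, 1].
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("expression states must have equal length")
    d = s1 - s2
    return float(np.dot(d, d) / (4.0 * s1.shape[-1]))


def euclidean_distance(s1: np.ndarray, s2: np.ndarray) -> float:
    """Plain L2 distance between expression states (no normalization);
    the distance used by the evolvability and phenotypic-distance assays."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("expression states must have equal length")
    return float(np.linalg.norm(s1 - s2))


def stability_index(tail_states: np.ndarray, reduce: str = "mean") -> float:
    """Variability V of a developmental tail.

    V = (1/10) * sum_t D(S(t), S_ave) over the 10 tail states, with S_ave the
    elementwise mean state. ``reduce='sum'`` skips the 1/10 factor (exposed
    because the averaging convention is a model choice; the 1e-4 viability
    threshold is calibrated to the mean).
    """
    tail = np.asarray(tail_states, dtype=float)
    if tail.ndim != 2 or tail.shape[0] != TAIL_WINDOW:
        raise ValueError(f"expected {TAIL_WINDOW} tail states, got shape {tail.shape}")
    if reduce not in ("mean", "sum"):
        raise ValueError("reduce must be 'mean' or 'sum'")
    if np.all(tail == tail[0]):
        return 0.0  # identical states: exactly zero, no rounding residue
    N = tail.shape[1]
    dev = tail - tail.mean(axis=0)
    v = float((dev * dev).sum()) / (4.0 * N)
    return v / TAIL_WINDOW if reduce == "mean" else v


def develop_batch(
    weights: np.ndarray,
    s0: np.ndarray,
    steps: int = DEV_STEPS,
    a: float = SIGMOID_GAIN,
    threshold: float = STABILITY_THRESHOLD,
):
    """Develop a batch of genotypes synchronously.

    Parameters
    ----------
    weights : (B, N, N) array of interaction matrices.
    s0 : (N,) shared founding state or (B, N) per-genotype states.
    steps, a, threshold : developmental window, sigmoid gain, viability cut.

    Returns
    -------
    phenotypes : (B, N) states at the final step.
    v : (B,) stability indices.
    viable : (B,) boolean, v < threshold.
    tail : (TAIL_WINDOW, B, N) the last 10 states.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 3:
        raise ValueError("weights must have shape (B, N, N)")
    B, N = weights.shape[0], weights.shape[1]
    if steps < TAIL_WINDOW:
        raise ValueError(f"steps must be >= {TAIL_WINDOW}")
    s0 = np.asarray(s0, dtype=float)
    if s0.ndim == 1:
        if s0.shape[0] != N:
            raise ValueError("s0 length must equal N")
        s = np.broadcast_to(s0, (B, N)).copy()
    else:
        if s0.shape != (B, N):
            raise ValueError("per-genotype s0 must have shape (B, N)")
        s = s0.copy()

    aw = a * weights  # fold the gain into the matrices once
    for _ in range(steps - TAIL_WINDOW):
        s = 2.0 / (1.0 + np.exp(-np.matmul(aw, s[..., None])[..., 0])) - 1.0
    tail = np.empty((TAIL_WINDOW, B, N))
    for k in range(TAIL_WINDOW):
        s = 2.0 / (1.0 + np.exp(-np.matmul(aw, s[..., None])[..., 0])) - 1.0
        tail[k] = s
    dev = tail - tail.mean(axis=0)
    v = (dev * dev).sum(axis=(0, 2)) / (4.0 * N * TAIL_WINDOW)
    # converged trajectories (all tail states identical) are exactly stable;
    # clear the rounding residue of the mean subtraction
    v[np.all(tail == tail[-1][None], axis=(0, 2))] = 0.0
    return tail[-1].copy(), v, v < threshold, tail


def develop(
    net: RegulatoryNetwork,
    s0: np.ndarray,
    steps: int = DEV_STEPS,
    a: float = SIGMOID_GAIN,
    threshold: float = STABILITY_THRESHOLD,
) -> DevelopmentResult:
    """Develop one genotype from ``s0`` and judge its stability."""
    s0 = np.asarray(s0, dtype=float)
    if s0.shape != (net.N,):
        raise ValueError(f"s0 must have length {net.N}, got shape {s0.shape}")
    phen, v, viable, tail = develop_batch(
        net.weights[None], s0, steps=steps, a=a, threshold=threshold
    )
    return DevelopmentResult(
        phenotype=phen[0],
        stability_index=float(v[0]),
        viable=bool(viable[0]),
        tail_states=tail[:, 0, :],
    )


def random_stable_seed(
    N: int,
    c: float,
    rng: np.random.Generator,
    max_tries: int = 10_000,
    steps: int = DEV_STEPS,
    a: float = SIGMOID_GAIN,
    threshold: float = STABILITY_THRESHOLD,
):
    """Rejection-sample a developmentally stable founder.

    Draws (random network, random founding state) pairs until development is
    viable. Returns ``(net, s0)``; the founding state is the lineage's fixed
    developmental initial condition — every descendant and every assay mutant
    is developed from this same ``s0`` so phenotype differences reflect
    genotype alone.
    """
    if max_tries < 1:
        raise ValueError("max_tries must be >= 1")
    for _ in range(max_tries):
        net = random_network(N, c, rng)
        s0 = random_expression_state(N, rng)
        res = develop(net, s0, steps=steps, a=a, threshold=threshold)
        if res.viable:
            return net, s0
    raise GenerationFailureError(max_tries)
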