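"""Discrete-generation Wright-Fisher simulator over haplotype classes.

Each generation applies, in fixed order:

1. **mutation** -- deterministic expected flux between adjacent classes
   (class ``z`` sends a fraction ``z u10`` of its frequency down and
   ``(L - z) u01`` up; double mutations within a generation are ignored,
   valid because ``L u10 <= 0.1``);
2. **selection** -- reweighting by the Gaussian fitness of each class,
   normalized by mean fitness;
3. **drift** -- one multinomial draw of ``N`` individuals across classes.

Stochasticity therefore enters only through drift; mutation acts on class
frequencies, mirroring the class-frequency bookkeeping the model is built on.
A biallelic neutral marker can be embedded (doubling the state over the
marker's allele), and a sparse multi-type variant handles blocks whose sites
fall into several selection-coefficient classes, with fitness measured on the
performance scale.

Large-``N`` scenarios are made tractable by rescaling: reduce ``N`` and
inflate ``u10``, ``u01`` and ``s`` by the same factor so the products
``N u10``, ``N u01`` and ``N s`` -- which govern the stationary behavior --
are unchanged, subject to ``N >= 1000``, ``s <= 0.1`` and ``L u10 <= 0.1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .model import MAX_L_U10, MAX_S, ModelConfig, SiteTypeScheme, gaussian_fitness

__all__ = [
    "PopulationState",
    "TrajectorySample",
    "Trajectory",
    "RescaledParams",
    "mutation_rate_for_N",
    "rescale_params",
    "rescale_config",
    "mutation_step",
    "selection_step",
    "drift_step",
    "run",
    "run_with_neutral_marker",
    "run_multitype",
]


class TrajectorySample(NamedTuple):
    """One recorded observation of the population."""

    generation: int
    mean_z: float
    var_z: float
    neutral_freq: float  # NaN when the marker is not tracked
    mean_performance: float  # NaN for single-type runs


@dataclass(frozen=True)
class PopulationState:
    """Counts over the ``L + 1`` haplotype classes at one generation."""

    counts: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if np.any(c < 0):
            raise ValueError("class counts must be >= 0")
        object.__setattr__(self, "counts", c)

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.N


class Trajectory:
    """Recorded samples of a run, stored columnwise; behaves as a sequence of
    :class:`TrajectorySample` and converts to a :class:`pandas.DataFrame`."""

    def __init__(
        self,
        generation: np.ndarray,
        mean_z: np.ndarray,
        var_z: np.ndarray,
        neutral_freq: np.ndarray | None = None,
        mean_performance: np.ndarray | None = None,
    ) -> None:
        n = len(generation)
        nan = np.full(n, np.nan)
        self.generation = np.asarray(generation)
        self.mean_z = np.asarray(mean_z, dtype=float)
        self.var_z = np.asarray(var_z, dtype=float)
        self.neutral_freq = nan if neutral_freq is None else np.asarray(neutral_freq)
        self.mean_performance = (
            nan if mean_performance is None else np.asarray(mean_performance)
        )

    def __len__(self) -> int:
        return len(self.generation)

    def __getitem__(self, i: int) -> TrajectorySample:
        return TrajectorySample(
            int(self.generation[i]),
            float(self.mean_z[i]),
            float(self.var_z[i]),
            float(self.neutral_freq[i]),
            float(self.mean_performance[i]),
        )

    def __iter__(self) -> Iterator[TrajectorySample]:
        for i in range(len(self)):
            yield self[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generation,
                "mean_z": self.mean_z,
                "var_z": self.var_z,
                "neutral_freq": self.neutral_freq,
                "mean_performance": self.mean_performance,
            }
        )


# ---------------------------------------------------------------------------
# parameter scaling


def mutation_rate_for_N(N: float, c: float = 0.0011, gamma: float = 0.76) -> float:
    """Per-site + -> - mutation rate implied by the empirical scaling of
    mutation rate with (coalescent) population size: ``u10 = c N^-gamma``.

    With the defaults, ``N u10`` rises from about 0.01 at ``N = 1e4`` to
    about 0.1 at ``N = 2e8``, matching the weak scaling of population-level
    silent-site diversity across organisms.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if c <= 0 or gamma < 0:
        raise ValueError("require c > 0 and gamma >= 0")
    return c * N ** (-gamma)


@dataclass(frozen=True)
class RescaledParams:
    """Parameters after speed rescaling; products N u10, N u01, N s preserved."""

    N_prime: int
    u10_prime: float
    u01_prime: float
    s_prime: float
    scale_factor: float


def rescale_params(config: ModelConfig, N_floor: int = 1000) -> RescaledParams:
    """Largest admissible reduction of ``N`` holding ``N u10``, ``N u01`` and
    ``N s`` constant, subject to ``N' >= N_floor``, ``s' <= 0.1`` and
    ``L u10' <= 0.1``.  Returns the identity when no reduction is possible.
    """
    if config.s > MAX_S or config.L * config.u10 > MAX_L_U10:
        raise ValueError("configuration violates the scaling constraints even at f=1")
    f_max = config.N / N_floor
    if config.s > 0:
        f_max = min(f_max, MAX_S / config.s)
    if config.u10 > 0:
        f_max = min(f_max, MAX_L_U10 / (config.L * config.u10))
    if f_max <= 1:
        return RescaledParams(config.N, config.u10, config.u01, config.s, 1.0)
    N_prime = math.ceil(config.N / f_max)
    f = config.N / N_prime
    return RescaledParams(N_prime, config.u10 * f, config.u01 * f, config.s * f, f)


def rescale_config(config: ModelConfig, N_floor: int = 1000) -> ModelConfig:
    """Apply :func:`rescale_params` and return the equivalent, faster config.

    Explicit burn-in / sampling settings are kept as given (they are already
    in generations of the rescaled process); ``None`` defaults re-derive from
    the reduced ``N``.
    """
    rp = rescale_params(config, N_floor)
    return config.with_(N=rp.N_prime, u10=rp.u10_prime, s=rp.s_prime)


# ---------------------------------------------------------------------------
# the three per-generation steps


def mutation_step(freqs: np.ndarray, L: int, u01: float, u10: float) -> np.ndarray:
    """Deterministic expected mutation flux between adjacent classes.

    First order in the mutation rates: class ``z`` keeps
    ``1 - z u10 - (L - z) u01`` of its frequency, sending ``z u10`` to
    ``z - 1`` and ``(L - z) u01`` to ``z + 1``.  Conserves total frequency.
    """
    f = np.asarray(freqs, dtype=float)
    z = np.arange(L + 1)
    down = z * u10
    up = (L - z) * u01
    if np.any(down + up > 1.0):
        raise ValueError(
            "per-class mutation exit probability exceeds 1; rates are "
            "incompatible with the one-step scheme"
        )
    return _flux(f, down, up)


def _flux(f: np.ndarray, down: np.ndarray, up: np.ndarray) -> np.ndarray:
    fd = f * down
    fu = f * up
    out = f - fd - fu
    out[:-1] += fd[1:]
    out[1:] += fu[:-1]
    return out


def selection_step(freqs: np.ndarray, fitness: np.ndarray) -> np.ndarray:
    """Reweight class frequencies by fitness, normalized by mean fitness."""
    f = np.asarray(freqs, dtype=float) * np.asarray(fitness, dtype=float)
    total = f.sum()
    if total <= 0:
        raise FloatingPointError("mean fitness is zero; degenerate state")
    return f / total


def drift_step(freqs: np.ndarray, N: int, rng: np.random.Generator) -> np.ndarray:
    """One multinomial draw of ``N`` individuals across classes."""
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    f = np.asarray(freqs, dtype=float)
    return rng.multinomial(N, f / f.sum())


# ---------------------------------------------------------------------------
# run drivers


def _initial_class(config: ModelConfig) -> int:
    if config.init_state == "all_minus":
        return 0
    if config.init_state == "all_plus":
        return config.L
    return int(round(config.theta_N))


def _check_exit_prob(L: int, u01: float, u10: float, extra: float = 0.0) -> None:
    worst = max(L * u10, L * u01) + extra
    if worst > 1.0:
        raise ValueError("mutation rates incompatible with the one-step scheme")


def run(config: ModelConfig) -> Trajectory:
    """Simulate the mutation -> selection -> drift cycle and record samples.

    Discards ``config.burn_in`` generations, then records ``n_samples``
    observations every ``sample_interval`` generations.  Fully reproducible
    from ``config.seed``.
    """
    if config.track_neutral:
        return run_with_neutral_marker(config)
    L, N = config.L, config.N
    _check_exit_prob(L, config.u01, config.u10)
    rng = np.random.default_rng(config.seed)
    z = np.arange(L + 1, dtype=float)
    z2 = z * z
    log_w = -config.s * (z - config.theta_S) ** 2
    W = np.exp(log_w)
    down = z * config.u10
    up = (L - z) * config.u01

    f = np.zeros(L + 1)
    f[_initial_class(config)] = 1.0

    interval = config.sample_interval
    n_samples = config.n_samples
    inv_N = 1.0 / N

    if log_w.min() > -600.0:

        def advance(f: np.ndarray, gens: int) -> np.ndarray:
            for _ in range(gens):
                f = _flux(f, down, up)
                f *= W
                f /= f.sum()
                f = rng.multinomial(N, f) * inv_N
            return f

    else:
        # sharp optimum: W underflows far from theta_S, so selection must be
        # computed relative to the fittest occupied class each generation
        def advance(f: np.ndarray, gens: int) -> np.ndarray:
            for _ in range(gens):
                f = _flux(f, down, up)
                # clip at 0: classes fitter than the best occupied one carry
                # zero frequency, so their (shifted) weight is irrelevant
                f = f * np.exp(np.minimum(log_w - log_w[f > 0.0].max(), 0.0))
                f /= f.sum()
                f = rng.multinomial(N, f) * inv_N
            return f

    f = advance(f, config.burn_in)

    gen = np.empty(n_samples, dtype=np.int64)
    mean = np.empty(n_samples)
    var = np.empty(n_samples)
    g = config.burn_in
    for k in range(n_samples):
        f = advance(f, interval)
        g += interval
        m = float(np.dot(z, f))
        gen[k] = g
        mean[k] = m
        var[k] = float(np.dot(z2, f)) - m * m
    return Trajectory(gen, mean, np.maximum(var, 0.0))


def run_with_neutral_marker(
    config: ModelConfig, marker_init_freq: float = 0.5
) -> Trajectory:
    """Simulate with a biallelic neutral marker embedded in the haplotypes.

    The class state is doubled over the marker allele ``a`` in {0, 1}; the
    marker mutates symmetrically at rate ``config.neutral_rate``, has no
    fitness effect, and experiences the same joint multinomial drift as the
    selected background, so its diversity reflects linked interference.
    The marker starts at frequency ``marker_init_freq`` (default 1/2, mass
    split between the two marker states); burn-in must exceed the drift
    timescale ``~N`` for the starting choice to wash out.
    """
    if not (0.0 <= marker_init_freq <= 1.0):
        raise ValueError("marker_init_freq must be in [0, 1]")
    L, N = config.L, config.N
    mu = config.neutral_rate
    _check_exit_prob(L, config.u01, config.u10, extra=mu)
    rng = np.random.default_rng(config.seed)
    z = np.arange(L + 1, dtype=float)
    z2 = z * z
    log_w = -config.s * (z - config.theta_S) ** 2
    if log_w.min() <= -600.0:
        raise ValueError(
            "fitness range too sharp for the marker-tracking loop; start the "
            "population nearer the optimum or reduce s"
        )
    W = np.exp(log_w)
    down = z * config.u10
    up = (L - z) * config.u01

    g2 = np.zeros((2, L + 1))
    g2[0, _initial_class(config)] = 1.0 - marker_init_freq
    g2[1, _initial_class(config)] = marker_init_freq

    interval = config.sample_interval
    n_samples = config.n_samples
    inv_N = 1.0 / N

    def advance(g2: np.ndarray, gens: int) -> np.ndarray:
        for _ in range(gens):
            fd = g2 * down
            fu = g2 * up
            g2 = g2 - fd - fu
            g2[:, :-1] += fd[:, 1:]
            g2[:, 1:] += fu[:, :-1]
            if mu > 0.0:
                g2 = g2 * (1.0 - mu) + g2[::-1] * mu
            g2 = g2 * W
            g2 /= g2.sum()
            g2 = rng.multinomial(N, g2.ravel()).reshape(2, L + 1) * inv_N
        return g2

    g2 = advance(g2, config.burn_in)

    gen = np.empty(n_samples, dtype=np.int64)
    mean = np.empty(n_samples)
    var = np.empty(n_samples)
    pneu = np.empty(n_samples)
    g = config.burn_in
    for k in range(n_samples):
        g2 = advance(g2, interval)
        g += interval
        f = g2.sum(axis=0)
        m = float(np.dot(z, f))
        gen[k] = g
        mean[k] = m
        var[k] = float(np.dot(z2, f)) - m * m
        pneu[k] = float(g2[1].sum())
    return Trajectory(gen, mean, np.maximum(var, 0.0), neutral_freq=pneu)


# ---------------------------------------------------------------------------
# multi-type (heterogeneous site effects), sparse over class tuples


def run_multitype(
    config: ModelConfig,
    scheme: SiteTypeScheme,
    max_states: int = 100_000,
) -> Trajectory:
    """Simulate a block whose sites fall into several selection classes.

    The state is a sparse map from per-type + counts ``(n_1, ..., n_K)`` to
    individual counts.  Mutation moves one site of one type per event (first
    order), selection acts on the performance score through
    ``W = exp(-s_1 (P - theta_P)^2)`` so that a one-unit performance deficit
    costs about ``s_1`` near the optimum, and drift is a joint multinomial.
    ``config.s`` and ``config.theta_S`` are ignored; the scheme supplies the
    fitness scale.  A single-class scheme delegates to :func:`run` (identical
    trajectory for the same seed).
    """
    if scheme.n_types == 1:
        L1, s1 = scheme.classes[0]
        single = config.with_(L=L1, s=s1, theta_S=scheme.theta_P)
        traj = run(single)
        return Trajectory(
            traj.generation, traj.mean_z, traj.var_z,
            mean_performance=traj.mean_z.copy(),
        )

    K = scheme.n_types
    counts_by_type = scheme.site_counts
    weights = scheme.weights
    s1, theta_P = scheme.s1, scheme.theta_P
    u10, u01 = config.u10, config.u01
    _check_exit_prob(int(counts_by_type.sum()), u01, u10)
    N = config.N
    rng = np.random.default_rng(config.seed)

    if config.init_state == "all_minus":
        start = tuple(0 for _ in range(K))
    elif config.init_state == "all_plus":
        start = tuple(int(Lx) for Lx in counts_by_type)
    else:
        frac = config.beta / (1.0 + config.beta)
        start = tuple(int(round(Lx * frac)) for Lx in counts_by_type)
    state: dict[tuple, int] = {start: N}

    fitness_cache: dict[tuple, float] = {}

    def fitness(n: tuple) -> float:
        w = fitness_cache.get(n)
        if w is None:
            P = float(np.dot(n, weights))
            w = math.exp(-s1 * (P - theta_P) ** 2)
            fitness_cache[n] = w
        return w

    def step(state: dict[tuple, int]) -> dict[tuple, int]:
        # mutation: expected flux on frequencies, one type per event
        freq: dict[tuple, float] = {}
        for n, c in state.items():
            f = c / N
            stay = f
            for x in range(K):
                nx = n[x]
                if nx > 0:
                    amt = nx * u10 * f
                    stay -= amt
                    m = list(n)
                    m[x] = nx - 1
                    key = tuple(m)
                    freq[key] = freq.get(key, 0.0) + amt
                room = counts_by_type[x] - nx
                if room > 0 and u01 > 0.0:
                    amt = room * u01 * f
                    stay -= amt
                    m = list(n)
                    m[x] = nx + 1
                    key = tuple(m)
                    freq[key] = freq.get(key, 0.0) + amt
            freq[n] = freq.get(n, 0.0) + stay
        if len(freq) > max_states:
            raise RuntimeError(
                f"sparse state exceeded the configured cap ({max_states} classes)"
            )
        # selection + drift
        keys = list(freq.keys())
        p = np.array([freq[k] * fitness(k) for k in keys])
        p /= p.sum()
        drawn = rng.multinomial(N, p)
        return {k: int(c) for k, c in zip(keys, drawn) if c > 0}

    interval = config.sample_interval
    n_samples = config.n_samples

    for _ in range(config.burn_in):
        state = step(state)

    gen = np.empty(n_samples, dtype=np.int64)
    mean = np.empty(n_samples)
    var = np.empty(n_samples)
    perf = np.empty(n_samples)
    g = config.burn_in
    for k in range(n_samples):
        for _ in range(interval):
            state = step(state)
        g += interval
        tot_z = tot_z2 = tot_P = 0.0
        for n, c in state.items():
            zv = float(sum(n))
            tot_z += c * zv
            tot_z2 += c * zv * zv
            tot_P += c * float(np.dot(n, weights))
        m = tot_z / N
        gen[k] = g
        mean[k] = m
        var[k] = max(tot_z2 / N - m * m, 0.0)
        perf[k] = tot_P / N
    return Trajectory(gen, mean, var, mean_performance=perf)
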