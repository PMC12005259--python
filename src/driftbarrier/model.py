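"""Domain types for a fully linked, biallelic, additive trait under Gaussian selection.

The model: a haploid asexual population of ``N`` individuals carries a single
non-recombining block of ``L`` biallelic sites.  Each site contributes 0 (the
"-" allele) or 1 (the "+" allele) to the genotypic value ``z``, so ``z`` equals
the number of + alleles and ranges over ``0..L``.  Fitness is Gaussian
(stabilizing) around an optimum ``theta_S``:  ``W(z) = exp(-s (z - theta_S)^2)``,
where ``s`` measures the strength of selection (equivalently ``1/(2 Vs)`` in the
usual quantitative-genetic notation).  Mutation is reversible with per-site
rates ``u10`` (+ -> -) and ``u01 = beta * u10`` (- -> +); the bias
``beta <= 1`` pushes the neutral expectation of the trait,
``theta_N = L beta / (1 + beta)``, below ``L/2``.

Because the block never recombines and all sites within a class have equal
effects, the population state reduces to counts over the ``L + 1`` haplotype
classes.  Heterogeneous allelic effects enter only through
:class:`SiteTypeScheme`, which groups sites into classes of equal selection
coefficient and measures adaptation on a "performance" scale in units of the
largest-effect sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ModelConfig",
    "SiteTypeScheme",
    "genotypic_value",
    "gaussian_fitness",
    "performance",
    "neutral_mean",
]

#: hard constraints carried over from the simulation design: selection and the
#: per-block mutation input must stay weak enough for the one-step mutation
#: scheme and the rescaling trick to be valid.
MAX_S = 0.1
MAX_L_U10 = 0.1

_INIT_STATES = ("neutral_mean", "all_minus", "all_plus")


@dataclass(frozen=True)
class ModelConfig:
    """Full parameterization of one simulation / theory scenario.

    Parameters
    ----------
    N
        Haploid population size (individuals).  Diploid results follow by
        substituting ``2N``.
    L
        Number of fully linked biallelic sites in the block.
    s
        Selection strength per squared phenotypic unit (``= 1/(2 Vs)``).
    theta_S
        Optimal genotypic value, in phenotypic units; any real value in
        ``[0, L]``.  ``theta_S = L`` gives the half-Gaussian (purely
        directional) regime.
    u10
        Per-site, per-generation mutation rate from + to -.
    beta
        Mutation bias ``u01 / u10`` in ``(0, 1]``.
    burn_in_generations
        Generations discarded before sampling.  ``None`` means the
        conservative default ``1000 * N``.
    sample_interval_generations
        Generations between recorded samples.  ``None`` means
        ``max(1, N // 10)``.
    n_samples
        Number of recorded trajectory samples after burn-in.
    seed
        64-bit seed for the run's random generator.
    track_neutral
        Whether to embed a biallelic neutral marker in the haplotypes.
    neutral_mu
        Symmetric per-generation mutation rate of the neutral marker;
        ``None`` defaults to ``u10``.
    init_state
        Starting configuration: ``"neutral_mean"`` (monomorphic at the class
        nearest ``theta_N``; default, minimizes burn-in transients),
        ``"all_minus"`` or ``"all_plus"``.
    """

    N: int
    L: int
    s: float
    theta_S: float
    u10: float
    beta: float = 1.0
    burn_in_generations: int | None = None
    sample_interval_generations: int | None = None
    n_samples: int = 10_000
    seed: int = 0
    track_neutral: bool = False
    neutral_mu: float | None = None
    init_state: str = "neutral_mean"

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise ValueError(f"N must be an integer >= 1, got {self.N!r}")
        if not (isinstance(self.L, (int, np.integer)) and self.L >= 1):
            raise ValueError(f"L must be an integer >= 1, got {self.L!r}")
        if self.s < 0:
            raise ValueError(f"selection strength s must be >= 0, got {self.s}")
        if self.s > MAX_S:
            raise ValueError(
                f"s = {self.s} exceeds the supported maximum {MAX_S}; "
                "rescale the scenario (see rescale_params)"
            )
        if not (0 < self.beta <= 1):
            raise ValueError(f"mutation bias beta must be in (0, 1], got {self.beta}")
        if self.u10 < 0:
            raise ValueError(f"u10 must be >= 0, got {self.u10}")
        if self.L * self.u10 > MAX_L_U10:
            raise ValueError(
                f"L*u10 = {self.L * self.u10:.3g} exceeds the supported maximum "
                f"{MAX_L_U10}; rescale the scenario (see rescale_params)"
            )
        if not (0 <= self.theta_S <= self.L):
            raise ValueError(
                f"theta_S must lie in [0, L] = [0, {self.L}], got {self.theta_S}"
            )
        if self.theta_S == self.L / 2 and self.L % 2 != 0:
            # An exactly intermediate optimum is only attainable for even L.
            raise ValueError(
                f"theta_S = L/2 requires an even L (got L = {self.L}); "
                "choose an attainable optimum explicitly"
            )
        if self.burn_in_generations is not None and self.burn_in_generations < 0:
            raise ValueError("burn_in_generations must be >= 0")
        if (
            self.sample_interval_generations is not None
            and self.sample_interval_generations < 1
        ):
            raise ValueError("sample_interval_generations must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.neutral_mu is not None and self.neutral_mu < 0:
            raise ValueError("neutral_mu must be >= 0")
        if self.init_state not in _INIT_STATES:
            raise ValueError(
                f"init_state must be one of {_INIT_STATES}, got {self.init_state!r}"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def u01(self) -> float:
        """Per-site - -> + mutation rate, ``beta * u10``."""
        return self.beta * self.u10

    @property
    def theta_N(self) -> float:
        """Neutral expectation of the mean phenotype, ``L beta / (1 + beta)``."""
        return neutral_mean(self.L, self.beta)

    @property
    def burn_in(self) -> int:
        return (
            1000 * self.N
            if self.burn_in_generations is None
            else self.burn_in_generations
        )

    @property
    def sample_interval(self) -> int:
        if self.sample_interval_generations is None:
            return max(1, self.N // 10)
        return self.sample_interval_generations

    @property
    def neutral_rate(self) -> float:
        return self.u10 if self.neutral_mu is None else self.neutral_mu

    def with_(self, **changes) -> "ModelConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class SiteTypeScheme:
    """Site classes of heterogeneous effect, with a performance-scale optimum.

    ``classes`` is an ordered list of ``(L_x, s_x)`` pairs, by decreasing
    selection coefficient; the first entry defines the scale.  Performance is
    ``P = sum_x n_x * (s_x / s_1)`` where ``n_x`` counts + alleles of type x,
    so one largest-effect site contributes one performance unit.
    """

    classes: tuple[tuple[int, float], ...]
    theta_P: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        cls = tuple((int(Lx), float(sx)) for Lx, sx in self.classes)
        object.__setattr__(self, "classes", cls)
        if not cls:
            raise ValueError("SiteTypeScheme requires at least one site class")
        for Lx, sx in cls:
            if Lx < 1:
                raise ValueError(f"every site count L_x must be >= 1, got {Lx}")
            if sx <= 0:
                raise ValueError(f"every selection coefficient s_x must be > 0, got {sx}")
        svals = [sx for _, sx in cls]
        if any(a < b for a, b in zip(svals, svals[1:])):
            raise ValueError("site classes must be ordered by decreasing s_x")
        if math.isnan(self.theta_P):
            object.__setattr__(self, "theta_P", self.max_performance)
        if not (0 <= self.theta_P <= self.max_performance):
            raise ValueError(
                f"theta_P must lie in [0, {self.max_performance:.6g}], "
                f"got {self.theta_P}"
            )

    @property
    def n_types(self) -> int:
        return len(self.classes)

    @property
    def s1(self) -> float:
        """Selection coefficient of the largest-effect class (sets the scale)."""
        return self.classes[0][1]

    @property
    def weights(self) -> np.ndarray:
        """Per-class performance weights ``s_x / s_1``."""
        return np.array([sx / self.s1 for _, sx in self.classes])

    @property
    def site_counts(self) -> np.ndarray:
        return np.array([Lx for Lx, _ in self.classes])

    @property
    def max_performance(self) -> float:
        """Performance with every site occupied by a + allele."""
        return float(np.dot(self.site_counts, self.weights))


# ---------------------------------------------------------------------------
# elementary maps


def genotypic_value(n_plus: int, L: int) -> float:
    """Genotypic value of a haplotype carrying ``n_plus`` + alleles.

    With allelic effects scaled to 0/1, ``z = n_plus = L - n_minus``.
    """
    if not 0 <= n_plus <= L:
        raise ValueError(f"n_plus must lie in [0, L] = [0, {L}], got {n_plus}")
    return float(n_plus)


def gaussian_fitness(z, theta_S: float, s: float):
    """Gaussian fitness ``W(z) = exp(-s (z - theta_S)^2)``.

    Maximal (``= 1``) at ``z = theta_S`` and symmetric about it; for small s
    the fitness deficit of a one-unit deviation is approximately ``s``.
    Accepts scalars or arrays.
    """
    if s < 0:
        raise ValueError(f"selection strength s must be >= 0, got {s}")
    z = np.asarray(z, dtype=float)
    w = np.exp(-s * (z - theta_S) ** 2)
    return float(w) if w.ndim == 0 else w


def performance(n_by_type: Sequence[int], scheme: SiteTypeScheme) -> float:
    """Performance score ``sum_x n_x (s_x / s_1)`` of a multi-type genome.

    Measured in units of the largest-effect sites; monotone nondecreasing in
    every ``n_x`` and maximal when all sites carry + alleles.
    """
    n = np.asarray(n_by_type)
    if n.shape != (scheme.n_types,):
        raise ValueError(
            f"expected {scheme.n_types} per-type counts, got shape {n.shape}"
        )
    counts = scheme.site_counts
    if np.any(n < 0) or np.any(n > counts):
        raise ValueError(f"per-type + counts {n.tolist()} outside [0, L_x]")
    return float(np.dot(n, scheme.weights))


def neutral_mean(L: int, beta: float) -> float:
    """Expected mean phenotype under mutation and drift alone.

    ``theta_N = L beta / (1 + beta)``: the balance point of the reversible
    per-site mutation process.
    """
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    return L * beta / (1.0 + beta)
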