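"""Analytical approximations for the steady-state distribution of mean phenotypes.

This module collects the closed-form machinery that accompanies the
class-based Wright-Fisher simulator:

* the exact diffusion stationary distribution of (quasi-)fixed trait values,
  ``Phi_s(z) = C * Phi_n(z) * W(z)^(2 Ne)``, a multistate generalization of
  the Li-Bulmer two-allele steady state, together with its mean;
* Gaussian approximations to the distribution of population means, built on
  the variance ratio ``kappa = sigma_N^2 / sigma_S^2`` that weighs the
  selective optimum ``theta_S`` against the neutral expectation ``theta_N``;
* mean-absolute-deviation (MAD) predictors for the drift-dominated regime,
  the mutation-selection-balance regime, and a blend covering both;
* the half-Gaussian (optimum at the edge of genotypic space) and general
  interior-optimum deviations, a free-recombination benchmark, and the
  folded-normal MAD used when the distribution of means overlaps the optimum;
* inference of ``phi = Ne / N`` by inverting the predictors against observed
  deviations, the operational definition of the drift effective size here;
* composition rules for blocks containing several site-effect classes.

Two conventions for ``kappa`` coexist in the source literature: the unbiased
narrative value ``2 N L s`` and the value ``4 Ne s L beta / (1+beta)^2``
implied by the printed biased-mutation deviations (which is ``Ne L s`` at
``beta = 1``, a factor-2 tension).  Both are implemented and named; each
downstream formula uses the convention under which it was printed.  See
``docs/methods.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .model import ModelConfig, SiteTypeScheme, neutral_mean

__all__ = [
    "TheoryPrediction",
    "PhiEstimate",
    "neutral_distribution",
    "stationary_distribution",
    "expected_mean_exact",
    "sigma_N_sq",
    "sigma_S_sq",
    "kappa",
    "gaussian_mean_approx",
    "gaussian_var_approx",
    "mad_weak_selection",
    "mad_segregating",
    "mad_blend",
    "free_recombination_delta",
    "halfgauss_mean_deviation",
    "general_optimum_deviation",
    "halfgauss_mad_blend",
    "folded_normal_mad",
    "mad_from_gaussian",
    "estimate_phi",
    "multitype_halfgauss_mads",
    "interference_bias_parameter",
    "interference_bias_argmax",
    "interference_equivalent_sites",
    "multitype_mad",
    "predict",
]


# ---------------------------------------------------------------------------
# exact stationary distribution (fixed-state / weak-mutation limit)


def neutral_distribution(L: int, beta: float) -> np.ndarray:
    """Distribution of quasi-fixed trait values under mutation and drift alone.

    Binomial over ``z = 0..L`` with per-site success probability
    ``beta / (1 + beta)``; its mean is ``theta_N``.
    """
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    z = np.arange(L + 1)
    return stats.binom.pmf(z, L, beta / (1.0 + beta))


def stationary_distribution(
    L: int, beta: float, Ne: float, s: float, theta_S: float
) -> np.ndarray:
    """Stationary distribution of quasi-fixed trait values under selection.

    ``Phi_s(z) proportional to Phi_n(z) * W(z)^(2 Ne)`` with Gaussian
    ``W``; the exponent is kept at ``2 Ne`` exactly as in the haploid
    diffusion weighting.  Computed in the log domain so that large
    ``2 Ne s`` does not underflow.
    """
    if Ne <= 0:
        raise ValueError(f"Ne must be > 0, got {Ne}")
    if s < 0:
        raise ValueError(f"s must be >= 0, got {s}")
    z = np.arange(L + 1)
    log_neutral = stats.binom.logpmf(z, L, beta / (1.0 + beta))
    log_w = log_neutral - 2.0 * Ne * s * (z - theta_S) ** 2
    log_w -= log_w.max()
    w = np.exp(log_w)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError(
            "stationary distribution numerically infeasible for these parameters"
        )
    return w / total


def expected_mean_exact(stationary: np.ndarray) -> float:
    """Expected mean phenotype ``sum_z z Phi_s(z)`` of a fixed-state distribution."""
    p = np.asarray(stationary, dtype=float)
    return float(np.dot(np.arange(p.size), p))


# ---------------------------------------------------------------------------
# Gaussian approximation building blocks


def sigma_N_sq(L: int, beta: float) -> float:
    """Variance of the distribution of means under mutation pressure alone,
    ``L beta / (1 + beta)^2`` (the binomial variance of the neutral
    fixed-state distribution)."""
    return L * beta / (1.0 + beta) ** 2


def sigma_S_sq(Ne: float, s: float) -> float:
    """Variance of the distribution of means when selection prevails,
    ``1 / (4 Ne s)``."""
    if Ne <= 0 or s <= 0:
        raise ValueError("sigma_S_sq requires Ne > 0 and s > 0")
    return 1.0 / (4.0 * Ne * s)


def kappa(Ne: float, L: int, s: float, beta: float = 1.0,
          convention: str = "biased") -> float:
    """Variance ratio ``kappa = sigma_N^2 / sigma_S^2`` weighing selection
    against mutation in the Gaussian approximation.

    ``convention="unbiased"`` returns ``2 Ne L s``, the value quoted for the
    no-bias narrative and used on the weak-selection MAD pathway.
    ``convention="biased"`` returns ``4 Ne s L beta / (1 + beta)^2``, the
    value under which the Gaussian mean/variance approximations reproduce the
    printed half-Gaussian and general-optimum deviations exactly.  At
    ``beta = 1`` the two differ by a factor of 2 -- a documented tension in
    the source formulas, surfaced here rather than reconciled.
    """
    if Ne < 0 or s < 0:
        raise ValueError("kappa requires Ne >= 0 and s >= 0")
    if convention == "unbiased":
        return 2.0 * Ne * L * s
    if convention == "biased":
        return sigma_N_sq(L, beta) / (1.0 / (4.0 * Ne * s)) if s > 0 else 0.0
    raise ValueError(f"unknown kappa convention {convention!r}")


def gaussian_mean_approx(kappa_value: float, theta_S: float, theta_N: float) -> float:
    """Expected mean phenotype ``(kappa theta_S + theta_N) / (kappa + 1)``."""
    if kappa_value < 0:
        raise ValueError("kappa must be >= 0")
    return (kappa_value * theta_S + theta_N) / (kappa_value + 1.0)


def gaussian_var_approx(kappa_value: float, sigma_N2: float) -> float:
    """Variance of the distribution of means, ``sigma_N^2 / (kappa + 1)``."""
    if kappa_value < 0:
        raise ValueError("kappa must be >= 0")
    return sigma_N2 / (kappa_value + 1.0)


# ---------------------------------------------------------------------------
# mean-absolute-deviation predictors (intermediate optimum, beta = 1)


def mad_weak_selection(N: float, L: int, s: float) -> float:
    """MAD of means from an intermediate optimum in the drift-dominated regime.

    ``sqrt(L / (pi (2 N L s + 1)))``; applies for ``beta = 1``,
    ``theta_S = L/2``.  For ``N L s >> 1`` it reduces to ``(2 pi N s)^-0.5``.
    """
    if N < 0 or s < 0:
        raise ValueError("mad_weak_selection requires N >= 0 and s >= 0")
    return math.sqrt(L / (math.pi * (2.0 * N * L * s + 1.0)))


def mad_segregating(u10: float, L: int, s: float, beta: float = 1.0) -> float:
    """MAD contribution of segregating mutation-selection-balance polymorphism.

    ``L u10 (1 + beta) / s``, the general-bias form; at ``beta = 1`` this is
    the no-bias value ``2 u10 L / s``.  Valid in the near-deterministic
    ``N s >> 1`` regime.
    """
    if s <= 0:
        raise ValueError("mad_segregating requires s > 0 (deterministic regime)")
    if u10 < 0:
        raise ValueError("u10 must be >= 0")
    return L * u10 * (1.0 + beta) / s


def mad_blend(mad1: float, mad2: float, N: float, s: float, L: int) -> float:
    """Blend of the drift-dominated and segregating MADs across regimes:
    ``mad2 + (mad1 - mad2) exp(-2 N s / L)``."""
    if mad1 < 0 or mad2 < 0:
        raise ValueError("MAD inputs must be >= 0")
    return mad2 + (mad1 - mad2) * math.exp(-2.0 * N * s / L)


def free_recombination_delta(N: float, s: float, beta: float) -> float:
    """Benchmark deviation of the grand mean from the optimum under free
    recombination and ``N L s >> 1``:  ``(1 - ln beta) / (4 N s)``."""
    if not (0 < beta <= 1):
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    if N * s <= 0:
        raise ValueError("free_recombination_delta requires N s > 0")
    return (1.0 - math.log(beta)) / (4.0 * N * s)


# ---------------------------------------------------------------------------
# half-Gaussian and general-optimum deviations (biased kappa convention)


def halfgauss_mean_deviation(
    Ne: float, L: int, s: float, beta: float, asymptotic: bool = False
) -> float:
    """Deviation ``theta_S - mu(zbar)`` for the half-Gaussian optimum
    ``theta_S = L``:  ``L (1 + beta) / (4 Ne s L beta + (1 + beta)^2)``.

    With ``asymptotic=True`` returns the ``Ne s L beta >> 1`` limit
    ``(1 + beta) / (4 Ne s beta)``, which is ``1 / (2 Ne s)`` at ``beta = 1``
    and approaches ``1 / (4 Ne s beta)`` for ``beta << 1``.
    """
    if Ne <= 0 or s <= 0 or beta <= 0:
        raise ValueError("halfgauss_mean_deviation requires positive Ne, s, beta")
    if asymptotic:
        return (1.0 + beta) / (4.0 * Ne * s * beta)
    return L * (1.0 + beta) / (4.0 * Ne * s * L * beta + (1.0 + beta) ** 2)


def general_optimum_deviation(
    Ne: float, L: int, s: float, beta: float, x: float
) -> tuple[float, float]:
    """Deviation and spread of means for an optimum at ``theta_S = x L``.

    Returns ``(theta_S - mu(zbar), SD(zbar))`` with

    * deviation ``L (1+beta) [x (1+beta) - beta] / (4 Ne s L beta + (1+beta)^2)``
    * SD ``sqrt(L beta / (4 Ne s L beta + (1+beta)^2))``.

    ``x = 1`` recovers the half-Gaussian deviation exactly; the deviation
    vanishes when the optimum sits at the neutral mean ``x = beta/(1+beta)``.
    """
    if not (0 <= x <= 1):
        raise ValueError(f"x must be in [0, 1], got {x}")
    if Ne <= 0 or s <= 0 or beta <= 0:
        raise ValueError("general_optimum_deviation requires positive Ne, s, beta")
    denom = 4.0 * Ne * s * L * beta + (1.0 + beta) ** 2
    dev = L * (1.0 + beta) * (x * (1.0 + beta) - beta) / denom
    sd = math.sqrt(L * beta / denom)
    return dev, sd


def halfgauss_mad_blend(
    mu_mean: float, L: int, u10: float, s: float, N: float
) -> float:
    """Overall half-Gaussian MAD blending fixation and segregating components:
    ``(L u10 / s) + [L - mu(zbar) - (L u10 / s)] exp(-2 N s)``.

    ``mu_mean`` should come from the half-Gaussian deviation evaluated with
    ``Ne = phi N``; ``L u10 / s`` approximates the number of segregating
    deleterious mutations per genome in large populations.
    """
    if s <= 0:
        raise ValueError("halfgauss_mad_blend requires s > 0")
    seg = L * u10 / s
    return seg + (L - mu_mean - seg) * math.exp(-2.0 * N * s)


def folded_normal_mad(mu_mean: float, sd_mean: float, theta_S: float) -> float:
    """Mean absolute deviation ``E|X - theta_S|`` for
    ``X ~ Normal(mu_mean, sd_mean^2)``.

    Used when the distribution of means overlaps the optimum (closer than
    about two standard deviations), where the signed mean deviation
    understates the absolute one.  This folded-normal expectation is the
    natural formalization of evaluating the deviations conditional on
    residing above and below the optimum; it is an interpretation, adopted
    here as the package's own choice.
    """
    if sd_mean <= 0:
        raise ValueError("folded_normal_mad requires sd_mean > 0")
    m = mu_mean - theta_S
    r = m / sd_mean
    return sd_mean * math.sqrt(2.0 / math.pi) * math.exp(-0.5 * r * r) + m * (
        1.0 - 2.0 * stats.norm.cdf(-r)
    )


def mad_from_gaussian(
    mu_mean: float,
    sd_mean: float,
    theta_S: float,
    overlap_threshold: float = 2.0,
) -> float:
    """MAD of means from the optimum given a Gaussian distribution of means.

    When the mean sits more than ``overlap_threshold`` standard deviations
    from the optimum the signed deviation ``|mu - theta_S|`` is already the
    absolute one; closer in, the distribution straddles the optimum and the
    folded-normal expectation must be used.  The default threshold of two
    standard deviations is the conventional switch point.
    """
    if sd_mean <= 0:
        raise ValueError("mad_from_gaussian requires sd_mean > 0")
    if abs(mu_mean - theta_S) > overlap_threshold * sd_mean:
        return abs(mu_mean - theta_S)
    return folded_normal_mad(mu_mean, sd_mean, theta_S)


# ---------------------------------------------------------------------------
# phi = Ne / N inference by inversion


@dataclass(frozen=True)
class PhiEstimate:
    """Result of inverting a deviation predictor for the drift effective size."""

    phi: float
    Ne: float
    method: str
    observed_deviation: float
    N: int


def _invert_mean(obs: float, config: ModelConfig) -> float:
    """Closed-form Ne from the general-optimum signed deviation."""
    L, s, beta = config.L, config.s, config.beta
    x = config.theta_S / L
    A = L * (1.0 + beta) * (x * (1.0 + beta) - beta)
    if A <= 0:
        raise ValueError(
            "mean-deviation inversion requires theta_S above the neutral mean"
        )
    ceiling = A / (1.0 + beta) ** 2  # deviation as Ne -> 0 (neutral limit)
    if not (0 < obs < ceiling):
        raise ValueError(
            f"observed deviation {obs:.6g} outside the predictor's attainable "
            f"range (0, {ceiling:.6g})"
        )
    return (A / obs - (1.0 + beta) ** 2) / (4.0 * s * L * beta)


def _invert_mad(obs: float, config: ModelConfig) -> float:
    """Closed-form Ne from the blended MAD, Ne substituted only inside the
    weak-selection term (the kappa pathway); census N elsewhere."""
    N, L, s = config.N, config.L, config.s
    mad2 = mad_segregating(config.u10, L, s, beta=1.0)
    damp = math.exp(-2.0 * N * s / L)
    target_mad1 = mad2 + (obs - mad2) / damp
    ceiling = math.sqrt(L / math.pi)  # weak-selection term at Ne = 0
    if not (0 < target_mad1 < ceiling):
        raise ValueError(
            f"observed MAD {obs:.6g} outside the predictor's attainable range"
        )
    return (L / (math.pi * target_mad1**2) - 1.0) / (2.0 * L * s)


def estimate_phi(
    observed_deviation: float, config: ModelConfig, method: str = "mean"
) -> PhiEstimate:
    """Infer ``phi = Ne / N`` by matching a predictor to an observed deviation.

    ``Ne`` is operationally defined as the population size at which the
    Gaussian-approximation theory reproduces the simulated deviation of means
    from the optimum; interference among linked segregating mutations drives
    ``phi`` below 1.

    Parameters
    ----------
    observed_deviation
        ``method="mean"``: the signed deviation ``theta_S - mean(zbar)``.
        ``method="mad"``: the mean absolute deviation ``mean|zbar - theta_S|``
        (no-bias, intermediate-optimum pathway).
    config
        Scenario supplying ``N, L, s, beta, theta_S, u10``.
    method
        ``"mean"`` inverts the general-optimum Gaussian mean formula
        (closed form, valid whenever the optimum exceeds the neutral mean,
        including the half-Gaussian).  ``"mad"`` inverts the blended MAD
        predictor with ``Ne`` substituted inside the variance-ratio term,
        for ``beta = 1`` with an intermediate optimum.
    """
    if method == "mean":
        Ne = _invert_mean(observed_deviation, config)
    elif method == "mad":
        Ne = _invert_mad(observed_deviation, config)
    else:
        raise ValueError(f"unknown phi-estimation method {method!r}")
    if Ne <= 0:
        raise ValueError("inversion produced a nonpositive Ne")
    return PhiEstimate(
        phi=Ne / config.N,
        Ne=Ne,
        method=method,
        observed_deviation=observed_deviation,
        N=config.N,
    )


# ---------------------------------------------------------------------------
# composite bias parameter and multi-type composition


def interference_bias_parameter(beta: float) -> float:
    """Composite bias parameter ``beta (1 - beta) / (1 + beta)^2`` controlling
    the nonmonotonic effect of mutation bias on interference."""
    if not (0 < beta <= 1):
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    return beta * (1.0 - beta) / (1.0 + beta) ** 2


def interference_bias_argmax(grid_step: float = 0.005) -> float:
    """Bias value maximizing the composite parameter (i.e. minimizing the
    predicted ``phi``), located by grid search plus bounded refinement."""
    grid = np.arange(grid_step, 1.0, grid_step)
    vals = grid * (1.0 - grid) / (1.0 + grid) ** 2
    b0 = grid[int(np.argmax(vals))]
    res = optimize.minimize_scalar(
        lambda b: -(b * (1.0 - b) / (1.0 + b) ** 2),
        bounds=(max(b0 - 2 * grid_step, 1e-9), min(b0 + 2 * grid_step, 1.0)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def interference_equivalent_sites(n_y: float, s_x: float, s_y: float) -> float:
    """Number of type-x sites imposing the same interference as ``n_y``
    smaller-effect type-y sites: ``n_y (s_y / s_x)^2``.

    Rule of thumb: ``(s_x / s_y)^2`` small-effect sites interfere about as
    much as one additional large-effect site, so type-y interference on
    type-x sites is safely ignored when this equivalent count is small
    relative to ``n_x``.
    """
    if not (s_x >= s_y > 0):
        raise ValueError("requires s_x >= s_y > 0")
    return n_y * (s_y / s_x) ** 2


def multitype_mad(
    per_type_mads,
    scheme: SiteTypeScheme,
    optimum_kind: str = "intermediate",
) -> float:
    """Combine per-type MADs into a total deviation on the performance scale.

    ``optimum_kind="intermediate"``: each type fluctuates around its own
    interior optimum, and the total MAD is the performance-weighted sum
    ``sum_x mad_x (s_x / s_1)``.

    ``optimum_kind="extreme"``: the optimum sits at the top of the
    performance range; the total deviation is
    ``theta_P - sum_x (s_x / s_1) (L_x - mad_x)`` where each ``mad_x`` is the
    total per-type deviation from the all-plus state.
    """
    mads = np.asarray(per_type_mads, dtype=float)
    if mads.shape != (scheme.n_types,):
        raise ValueError(
            f"expected {scheme.n_types} per-type MADs, got shape {mads.shape}"
        )
    if np.any(mads < 0):
        raise ValueError("per-type MADs must be >= 0")
    w = scheme.weights
    if optimum_kind == "intermediate":
        return float(np.dot(mads, w))
    if optimum_kind == "extreme":
        return float(scheme.theta_P - np.dot(w, scheme.site_counts - mads))
    raise ValueError(f"unknown optimum_kind {optimum_kind!r}")


def multitype_halfgauss_mads(
    scheme: SiteTypeScheme,
    N: float,
    u10: float,
    beta: float,
    phi_by_type=None,
    reduced_intensity: bool = False,
) -> list[float]:
    """Per-type total deviations for an extreme (all-plus) optimum.

    Each class is treated with the single-type half-Gaussian machinery at
    its own ``(L_x, s_x)``: the fixation deficit from the half-Gaussian mean
    deviation at ``Ne = phi_x N`` blended with the segregating load.  With
    ``reduced_intensity`` the selection intensity entering each class is
    ``s_x / 10``, reflecting that when several classes contribute to one
    performance scale, the effective strength of selection per site is
    diluted as smaller-effect classes open up; the switch is off by default
    and intended for extreme-optimum composition only.  Feed the result to
    :func:`multitype_mad` with ``optimum_kind="extreme"``.
    """
    if phi_by_type is None:
        phi_by_type = [1.0] * scheme.n_types
    if len(phi_by_type) != scheme.n_types:
        raise ValueError("phi_by_type length must match the number of classes")
    mads = []
    for (Lx, sx), phi in zip(scheme.classes, phi_by_type):
        s_eff = sx / 10.0 if reduced_intensity else sx
        dev = halfgauss_mean_deviation(phi * N, Lx, s_eff, beta)
        mads.append(halfgauss_mad_blend(Lx - dev, Lx, u10, s_eff, N))
    return mads


# ---------------------------------------------------------------------------
# bundled prediction


@dataclass(frozen=True)
class TheoryPrediction:
    """All analytic quantities for one scenario (at a caller-chosen Ne)."""

    theta_N: float
    kappa_biased: float
    kappa_unbiased: float
    mu_mean: float
    var_mean: float
    sd_mean: float
    mad1: float
    mad2: float
    mad: float
    delta_free_recomb: float
    stationary: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.stationary.sum() - 1.0) > 1e-9:
            raise ValueError("stationary distribution must sum to 1")


def predict(config: ModelConfig, phi: float = 1.0) -> TheoryPrediction:
    """Evaluate the full bundle of analytic predictions for ``config``.

    ``phi`` rescales the effective size used on the Gaussian-approximation
    pathway (``Ne = phi N``); the MAD blend keeps census ``N`` outside the
    variance-ratio term, and the free-recombination benchmark always uses
    census ``N``.
    """
    N, L, s, beta = config.N, config.L, config.s, config.beta
    Ne = phi * N
    theta_N = neutral_mean(L, beta)
    kb = kappa(Ne, L, s, beta, "biased")
    ku = kappa(Ne, L, s, beta, "unbiased")
    mu = gaussian_mean_approx(kb, config.theta_S, theta_N)
    var = gaussian_var_approx(kb, sigma_N_sq(L, beta))
    m1 = mad_weak_selection(Ne, L, s)
    m2 = mad_segregating(config.u10, L, s, beta) if s > 0 else 0.0
    blend = mad_blend(m1, m2, N, s, L)
    dfr = free_recombination_delta(N, s, beta) if N * s > 0 else math.nan
    return TheoryPrediction(
        theta_N=theta_N,
        kappa_biased=kb,
        kappa_unbiased=ku,
        mu_mean=mu,
        var_mean=var,
        sd_mean=math.sqrt(var),
        mad1=m1,
        mad2=m2,
        mad=blend,
        delta_free_recomb=dfr,
        stationary=stationary_distribution(L, beta, Ne, s, config.theta_S),
    )
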