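"""Pre-packaged simulation studies reproducing the model's headline analyses.

Each study builds its scenarios from the preset machinery (desk scale:
``N`` rescaled to 1000 holding ``N u10``, ``N u01`` and ``N s`` fixed),
runs the simulator, and reduces the trajectories to the quantity of
interest together with a Monte-Carlo uncertainty.  They are the engine
behind both the acceptance script and the heavier end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .config import scenario
from .engine import run, run_with_neutral_marker
from .model import ModelConfig
from .summaries import summarize
from .theory import estimate_phi, stationary_distribution

__all__ = [
    "PhiCell",
    "no_bias_phi_sweep",
    "min_phi",
    "DepressionResult",
    "neutral_marker_depression",
    "interference_phi",
    "interference_phi_sweep",
    "ConcordanceResult",
    "stationary_concordance",
]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# phi = Ne/N from the no-bias intermediate-optimum sweep


@dataclass(frozen=True)
class PhiCell:
    L: int
    Ns: float
    mad: float
    mad_se: float
    phi: float
    phi_se: float
    n_samples: int = 0


def _phi_with_se(mad: float, mad_se: float, config: ModelConfig) -> tuple[float, float]:
    """Invert the MAD predictor; propagate the MAD's MC error by finite
    differences (one-sided where the perturbed value leaves the invertible
    range).

    An observed MAD below the predictor's large-Ne floor means the cell
    shows *less* deviation than the theory allows at any effective size --
    no interference signal at all -- and is reported as ``phi = inf``.
    """
    try:
        phi = estimate_phi(mad, config, method="mad").phi
    except ValueError:
        return np.inf, np.nan
    deltas = []
    for obs in (mad - mad_se, mad + mad_se):
        try:
            deltas.append(abs(estimate_phi(obs, config, method="mad").phi - phi))
        except ValueError:
            pass
    return phi, max(deltas) if deltas else np.nan


def min_phi(cells: list["PhiCell"], max_rel_se: float = 0.5) -> float:
    """Smallest well-determined phi across sweep cells.

    Cells whose inversion is uninformative -- non-invertible observations
    (``phi = inf``) or relative Monte-Carlo error above ``max_rel_se``,
    which happens where the MAD is dominated by the Ne-independent
    segregating load (Ns well beyond L/20) -- carry no evidence about Ne
    and are excluded.  Raises if no cell is informative.
    """
    good = [
        c.phi
        for c in cells
        if np.isfinite(c.phi)
        and (not np.isfinite(c.phi_se) or c.phi_se <= max_rel_se * c.phi)
    ]
    if not good:
        raise ValueError("no sweep cell yielded an informative phi estimate")
    return float(min(good))


def _cell_generations(L: int, Ns: float, u10_desk: float = 1e-5) -> int:
    """Sampling-phase length for one sweep cell.

    The trait mean mixes on the class-substitution timescale, roughly
    ``1 / (L u10)`` generations when drift matters (Ns ~ 1) and on the much
    faster mutation-selection-balance timescale ``~1/s`` when selection is
    near-deterministic (Ns >> 1).  Budgets target a few hundred to a few
    thousand effective (independent) observations per cell.
    """
    if Ns >= 10:
        return 2_000_000
    mixing = 1.0 / (L * u10_desk)
    return int(min(max(300 * mixing, 2_000_000), 10_000_000))


def no_bias_phi_sweep(
    seed: int,
    Ls: tuple[int, ...] = (10, 100),
    Ns_values: tuple[float, ...] = (1.0, 10.0),
    length_factor: float = 1.0,
) -> list[PhiCell]:
    """Estimate phi per (L, Ns) cell with beta = 1 and theta_S = L/2.

    Each cell simulates at desk scale, measures the mean absolute deviation
    of sampled means from the optimum, and solves the blended MAD predictor
    for the effective size that reproduces it.  With no mutation bias and an
    interior optimum, interference is weak and phi should stay near (or
    above) 1.  ``length_factor`` scales the per-cell generation budgets
    (use < 1 only for quick exploratory passes).
    """
    cells = []
    seeds = iter(_spawn_seeds(seed, len(Ls) * len(Ns_values)))
    for L in Ls:
        for Ns in Ns_values:
            config = scenario(L=L, Ns=Ns, beta=1.0, x=0.5, scale="desk",
                              seed=next(seeds), n_samples=2)
            gens = int(_cell_generations(L, Ns, config.u10) * length_factor)
            config = config.with_(
                n_samples=max(gens // config.sample_interval, 100)
            )
            # block length spans ~3 mixing times so the bootstrap SE is honest
            mixing = 1.0 / (L * config.u10)
            blk = max(50, int(3 * mixing / config.sample_interval))
            stats = summarize(run(config), config.theta_S, block_len=blk)
            phi, phi_se = _phi_with_se(stats.mad, stats.mc_se_mad, config)
            cells.append(PhiCell(L, Ns, stats.mad, stats.mc_se_mad, phi, phi_se,
                                 config.n_samples))
    return cells


# ---------------------------------------------------------------------------
# linked neutral-marker heterozygosity depression


@dataclass(frozen=True)
class DepressionResult:
    depression_pct: float
    se_pct: float
    het_selected: float
    het_control: float
    replicates: int
    samples_per_run: int = 0


def neutral_marker_depression(
    seed: int,
    L: int = 100,
    Ns: float = 10.0,
    n_samples: int = 100_000,
    replicates: int = 10,
) -> DepressionResult:
    """Percent depression of linked neutral heterozygosity under selection.

    Runs seed-paired selected (beta = 1, theta_S = L/2) and s = 0 control
    populations, each carrying a symmetric neutral marker mutating at the
    selected-site rate, and compares pooled time-averaged 2p(1-p).

    The marker's heterozygosity is dominated by rare, long-lived drift
    excursions (the marker is monomorphic most of the time at 2 N mu ~ 0.02),
    so single-run averages are very noisy; the study therefore pools several
    seed-paired replicates and quotes the across-replicate standard error of
    the pooled ratio (delta method over replicate means).
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2 for an honest standard error")
    hs_all, hc_all = [], []
    for rep_seed in _spawn_seeds(seed, replicates):
        sel_cfg = scenario(L=L, Ns=Ns, beta=1.0, x=0.5, scale="desk",
                           seed=rep_seed, track_neutral=True, n_samples=n_samples)
        ctl_cfg = scenario(L=L, Ns=Ns, beta=1.0, x=0.5, scale="desk",
                           seed=rep_seed, track_neutral=True, n_samples=n_samples,
                           s_zero=True)
        sel = run_with_neutral_marker(sel_cfg)
        ctl = run_with_neutral_marker(ctl_cfg)
        hs_all.append(float(np.mean(2.0 * sel.neutral_freq * (1.0 - sel.neutral_freq))))
        hc_all.append(float(np.mean(2.0 * ctl.neutral_freq * (1.0 - ctl.neutral_freq))))
    hs = np.array(hs_all)
    hc = np.array(hc_all)
    ratio = hs.mean() / hc.mean()
    # delta-method SE of the pooled ratio from across-replicate scatter,
    # keeping the within-pair covariance (seed pairing) in the estimate
    R = replicates
    var_s = hs.var(ddof=1) / R
    var_c = hc.var(ddof=1) / R
    cov = np.cov(hs, hc, ddof=1)[0, 1] / R
    rel_var = (
        var_s / hs.mean() ** 2 + var_c / hc.mean() ** 2
        - 2 * cov / (hs.mean() * hc.mean())
    )
    return DepressionResult(
        depression_pct=float(100.0 * (1.0 - ratio)),
        se_pct=float(100.0 * ratio * np.sqrt(max(rel_var, 0.0))),
        het_selected=float(hs.mean()),
        het_control=float(hc.mean()),
        replicates=replicates,
        samples_per_run=n_samples,
    )


# ---------------------------------------------------------------------------
# large-block interference


def interference_phi(
    seed: int,
    L: int = 1000,
    Ns: float = 10.0,
    beta: float = 0.33,
    x: float = 0.5,
    n_samples: int = 100_000,
    N_census: int = 10_000,
):
    """phi for one large-block biased-mutation cell, by inverting the
    Gaussian-approximation mean formula against the simulated signed
    deviation of the grand mean from the optimum.

    ``N_census`` is the pre-rescaling population size; it sets the mutation
    input ``N u10`` through the empirical rate scaling before the run is
    rescaled down to N = 1000.  Returns the
    :class:`~driftbarrier.theory.PhiEstimate` and the
    :class:`~driftbarrier.summaries.SummaryStats` it was derived from.
    """
    config = scenario(L=L, Ns=Ns, beta=beta, x=x, scale="desk",
                      seed=seed, n_samples=n_samples, N=N_census)
    stats = summarize(run(config), config.theta_S, block_len=1000)
    est = estimate_phi(stats.mean_dev, config, method="mean")
    return est, stats


def interference_phi_sweep(
    seed: int,
    L: int = 1000,
    beta: float = 0.33,
    Ns_values: tuple[float, ...] = (10.0, 30.0),
    N_census_values: tuple[int, ...] = (10**6, 10**8),
    n_samples: int = 100_000,
) -> list[tuple[float, int, float]]:
    """Minimum-phi sweep over the strong-interference region.

    Selective interference grows with both the selection-drift ratio Ns
    (within 1 < Ns < 100) and the population-level mutation input L N u10,
    which under the empirical rate scaling rises with the census size.  The
    sweep therefore covers cells across both axes (each rescaled to
    N = 1000) and returns one ``(Ns, N_census, phi)`` tuple per cell;
    the minimum over cells is the headline interference measure.
    """
    out = []
    seeds = iter(_spawn_seeds(seed, len(Ns_values) * len(N_census_values)))
    for Ns in Ns_values:
        for N_census in N_census_values:
            est, _ = interference_phi(
                next(seeds), L=L, Ns=Ns, beta=beta,
                n_samples=n_samples, N_census=N_census,
            )
            out.append((Ns, N_census, est.phi))
    return out


# ---------------------------------------------------------------------------
# simulator vs exact stationary distribution


@dataclass(frozen=True)
class ConcordanceResult:
    chi2: float
    dof: int
    p_value: float
    n_thinned: int
    observed_freqs: np.ndarray
    expected_probs: np.ndarray


def stationary_concordance(
    seed: int,
    N: int = 100,
    L: int = 4,
    s: float = 0.005,
    theta_S: float = 2.0,
    beta: float = 1.0,
    u10: float = 2.5e-4,
    n_samples: int = 200_000,
    thin: int = 500,
    min_expected: float = 5.0,
) -> ConcordanceResult:
    """Chi-square concordance of simulated means with the exact stationary law.

    At weak per-block mutation the population is monomorphic most of the
    time, so sampled means rounded to the nearest class follow the
    fixed-state stationary distribution (neutral binomial times fitness to
    the ``2N``) with ``Ne = N``.  Consecutive samples are strongly
    autocorrelated (the class substitution time is hundreds of generations
    here), so the goodness-of-fit statistic is computed on a thinned,
    approximately independent subset; classes with expected count below
    ``min_expected`` are merged into their neighbor toward the mode.
    """
    config = ModelConfig(
        N=N, L=L, s=s, theta_S=theta_S, u10=u10, beta=beta, seed=seed,
        burn_in_generations=200 * N,
        sample_interval_generations=max(1, N // 10),
        n_samples=n_samples,
    )
    traj = run(config)
    expected = stationary_distribution(L, beta, N, s, theta_S)
    zbar = traj.mean_z[::thin]
    classes = np.clip(np.rint(zbar).astype(int), 0, L)
    observed = np.bincount(classes, minlength=L + 1).astype(float)

    # merge low-expectation bins inward so the chi-square is well-posed
    mode = int(np.argmax(expected))
    exp_counts = expected * len(classes)
    obs_m, exp_m = [], []
    acc_o = acc_e = 0.0
    for z in range(L + 1):
        toward_mode = (z < mode and exp_counts[: z + 1].sum() < min_expected) or (
            z >= mode and exp_counts[z:].sum() < min_expected
        )
        acc_o += observed[z]
        acc_e += exp_counts[z]
        if acc_e >= min_expected and not toward_mode:
            obs_m.append(acc_o)
            exp_m.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        obs_m[-1] += acc_o
        exp_m[-1] += acc_e
    obs_m, exp_m = np.array(obs_m), np.array(exp_m)
    exp_m *= obs_m.sum() / exp_m.sum()
    chi2, p = sps.chisquare(obs_m, exp_m)
    return ConcordanceResult(
        chi2=float(chi2),
        dof=len(obs_m) - 1,
        p_value=float(p),
        n_thinned=len(classes),
        observed_freqs=observed / observed.sum(),
        expected_probs=expected,
    )
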