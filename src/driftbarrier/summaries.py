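"""Summary statistics of sampled trajectories of population mean phenotypes.

The central quantity is the long-run mean absolute deviation of the
population mean from the optimum, ``mad = mean(|zbar - theta_S|)``, together
with its decomposition into the deviations conditional on residing above and
below the optimum (needed whenever the distribution of means overlaps
``theta_S``).  Because consecutive samples of a Wright-Fisher trajectory are
strongly autocorrelated, Monte-Carlo standard errors come from a block
bootstrap over contiguous blocks of samples rather than from the naive
i.i.d. formula, and a first-half/second-half comparison serves as a
stationarity (burn-in adequacy) diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SummaryStats",
    "StationarityDiagnostic",
    "summarize",
    "heterozygosity_depression",
    "stationarity_check",
    "block_bootstrap_se",
]


@dataclass(frozen=True)
class SummaryStats:
    grand_mean: float
    mad: float
    mean_dev: float  # mean of (theta_S - zbar), signed
    sd_means: float
    frac_above: float
    cond_dev_above: float  # mean |zbar - theta_S| given zbar > theta_S
    cond_dev_below: float  # mean |zbar - theta_S| given zbar <= theta_S
    het_mean: float  # average 2 p (1 - p) of the neutral marker (NaN if untracked)
    n_samples: int
    mc_se_mad: float


@dataclass(frozen=True)
class StationarityDiagnostic:
    passed: bool
    first_half_mean: float
    second_half_mean: float
    combined_se: float


def _mean_z(samples) -> np.ndarray:
    if hasattr(samples, "mean_z"):
        return np.asarray(samples.mean_z, dtype=float)
    return np.asarray([s.mean_z for s in samples], dtype=float)


def _neutral_freq(samples) -> np.ndarray:
    if hasattr(samples, "neutral_freq"):
        return np.asarray(samples.neutral_freq, dtype=float)
    return np.asarray([s.neutral_freq for s in samples], dtype=float)


def block_bootstrap_se(
    x: np.ndarray,
    block_len: int = 50,
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    """Standard error of ``mean(x)`` by bootstrap over contiguous blocks.

    The series is cut into non-overlapping blocks of ``block_len`` samples;
    block means are resampled with replacement.  Robust to autocorrelation
    up to roughly the block length.
    """
    x = np.asarray(x, dtype=float)
    n_blocks = max(len(x) // block_len, 1)
    blocks = x[: n_blocks * block_len].reshape(n_blocks, -1).mean(axis=1)
    if n_blocks == 1:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_blocks, size=(n_boot, n_blocks))
    return float(blocks[idx].mean(axis=1).std(ddof=1))


def summarize(samples, theta_S: float, block_len: int = 50) -> SummaryStats:
    """Compute all summary statistics of a trajectory.

    Ties (samples exactly at the optimum) count toward the "below" side of
    the conditional decomposition; the choice is stated for determinism and
    is measure-zero for real-valued means.
    """
    z = _mean_z(samples)
    if len(z) < 2:
        raise ValueError("summarize requires at least 2 samples")
    dev = theta_S - z
    absdev = np.abs(dev)
    above = z > theta_S
    frac_above = float(above.mean())
    p = _neutral_freq(samples)
    het = 2.0 * p * (1.0 - p)
    return SummaryStats(
        grand_mean=float(z.mean()),
        mad=float(absdev.mean()),
        mean_dev=float(dev.mean()),
        sd_means=float(z.std(ddof=1)),
        frac_above=frac_above,
        cond_dev_above=float(absdev[above].mean()) if above.any() else 0.0,
        cond_dev_below=float(absdev[~above].mean()) if (~above).any() else 0.0,
        het_mean=float(np.nanmean(het)) if np.isfinite(p).any() else np.nan,
        n_samples=len(z),
        mc_se_mad=block_bootstrap_se(absdev, block_len=block_len),
    )


def heterozygosity_depression(selected: SummaryStats, control: SummaryStats) -> float:
    """Percent depression of linked neutral heterozygosity relative to a
    matched neutral control: ``100 (1 - H_sel / H_ctrl)``."""
    if not np.isfinite(control.het_mean) or control.het_mean <= 0:
        raise ValueError("control run has no usable heterozygosity")
    return 100.0 * (1.0 - selected.het_mean / control.het_mean)


def stationarity_check(
    samples, block_len: int = 50, n_sigma: float = 3.0
) -> StationarityDiagnostic:
    """Burn-in adequacy check: the first- and second-half grand means must
    agree within ``n_sigma`` combined block-bootstrap standard errors."""
    z = _mean_z(samples)
    if len(z) < 100:
        raise ValueError("stationarity_check requires at least 100 samples")
    half = len(z) // 2
    a, b = z[:half], z[half:]
    se = np.hypot(
        block_bootstrap_se(a, block_len=block_len),
        block_bootstrap_se(b, block_len=block_len),
    )
    return StationarityDiagnostic(
        passed=bool(abs(a.mean() - b.mean()) <= n_sigma * se),
        first_half_mean=float(a.mean()),
        second_half_mean=float(b.mean()),
        combined_se=float(se),
    )
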