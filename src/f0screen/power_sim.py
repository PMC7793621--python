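"""Bootstrap simulation of screen sensitivity versus injection success rate.

An F0 screen only detects a phenotype if enough of the injected animals are
true biallelic knockouts.  The simulation fits normal distributions to a
control (scrambled-injected) and a knockout phenotype, then builds mixed
"F0" groups in which a fraction ``s`` of the ``n`` animals (default 100)
are drawn from the knockout distribution and the rest from the control
distribution, for every success rate s = 0, 1, ..., 100%.  Each mixture is
summarised by Cohen's d against a fresh control sample, converted into the
minimum per-group sample size achieving 0.8 power at alpha = 0.05 for a
two-sided two-sample t-test (noncentral-t iteration), and the whole sweep
is repeated (default 10 iterations) to produce error bars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeDistribution",
    "SweepResult",
    "UNDETECTABLE",
    "cohens_d",
    "simulate_mixture",
    "two_sample_t_power",
    "min_sample_size",
    "sweep",
    "summarise_mustard_response",
    "fit_phenotype_distribution",
]

#: Sentinel for effect sizes too small to detect below the sample-size ceiling.
UNDETECTABLE = math.inf


@dataclass(frozen=True)
class PhenotypeDistribution:
    """Normal phenotype model for one group (units of the assay)."""

    mean: float
    sd: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")


def fit_phenotype_distribution(
    values: np.ndarray, label: str = "", trim_outliers: tuple[float, float] | None = None
) -> PhenotypeDistribution:
    """Fit an idealised normal distribution to real phenotype values.

    ``trim_outliers=(lo, hi)`` drops values outside the closed interval
    before fitting (used to exclude e.g. non-responding animals on real
    data; synthetic draws are never trimmed).
    """
    values = np.asarray(values, dtype=float)
    if trim_outliers is not None:
        lo, hi = trim_outliers
        values = values[(values >= lo) & (values <= hi)]
    if values.size < 2:
        raise ValueError("need at least two values to fit a distribution")
    return PhenotypeDistribution(float(values.mean()), float(values.std(ddof=1)), label)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with pooled standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("need at least two values per group")
    pooled = math.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    if pooled == 0:
        return 0.0
    return float((x.mean() - y.mean()) / pooled)


def simulate_mixture(
    success_rate: float,
    control: PhenotypeDistribution,
    knockout: PhenotypeDistribution,
    n: int = 100,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one simulated experiment at the given injection success rate.

    The F0 group mixes ``round(n * success_rate)`` knockout draws with
    control draws for the remainder; the control group is ``n`` fresh
    control draws.  Reproducible for a fixed generator/seed.
    """
    if not 0.0 <= success_rate <= 1.0:
        raise ValueError("success_rate must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    n_ko = int(round(n * success_rate))
    f0 = np.concatenate(
        [
            rng.normal(knockout.mean, knockout.sd, n_ko),
            rng.normal(control.mean, control.sd, n - n_ko),
        ]
    )
    ctrl = rng.normal(control.mean, control.sd, n)
    return f0, ctrl


def two_sample_t_power(n: int, d: float, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t-test, n per group, via noncentral t."""
    if n < 2:
        return 0.0
    df = 2 * n - 2
    nc = abs(d) * math.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def min_sample_size(
    d: float, alpha: float = 0.05, power: float = 0.8, ceiling: int = 1000
) -> float:
    """Smallest integer n per group achieving the target power, or UNDETECTABLE.

    Solved by iterating n upward with the noncentral-t power function; a
    zero effect size, or any effect needing more than ``ceiling`` animals
    per group, returns the UNDETECTABLE sentinel (infinity).
    """
    if d == 0:
        return UNDETECTABLE
    for n in range(2, ceiling + 1):
        if two_sample_t_power(n, d, alpha) >= power:
            return float(n)
    return UNDETECTABLE


@dataclass
class SweepResult:
    """Aggregated sweep over success rates.

    ``summary`` has one row per success rate (percent), with the mean and SD
    of the minimum sample size over iterations (computed over detectable
    iterations), the mean Cohen's d, and the count of undetectable
    iterations; ``raw`` keeps every iteration.
    """

    summary: pd.DataFrame
    raw: pd.DataFrame


def sweep(
    control: PhenotypeDistribution,
    knockout: PhenotypeDistribution,
    n: int = 100,
    iterations: int = 10,
    alpha: float = 0.05,
    power: float = 0.8,
    ceiling: int = 1000,
    seed: int | None = None,
) -> SweepResult:
    """Full sensitivity sweep: success rates 0..100% x iterations."""
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(iterations):
        for pct in range(0, 101):
            f0, ctrl = simulate_mixture(pct / 100.0, control, knockout, n=n, rng=rng)
            d = cohens_d(f0, ctrl)
            rows.append(
                {
                    "iteration": it,
                    "success_rate_pct": pct,
                    "cohens_d": d,
                    "min_n": min_sample_size(d, alpha=alpha, power=power, ceiling=ceiling),
                }
            )
    raw = pd.DataFrame(rows)
    finite = raw.replace(UNDETECTABLE, np.nan)
    grouped = finite.groupby("success_rate_pct")
    summary = pd.DataFrame(
        {
            "min_n_mean": grouped["min_n"].mean(),
            "min_n_sd": grouped["min_n"].std(ddof=1),
            "cohens_d_mean": grouped["cohens_d"].mean(),
            "n_undetectable": raw.groupby("success_rate_pct")["min_n"].apply(
                lambda s: int(np.isinf(s).sum())
            ),
        }
    ).reset_index()
    return SweepResult(summary=summary, raw=raw)


def summarise_mustard_response(
    trace: np.ndarray,
    frame_rate: float,
    transfer_frame: int,
    window_seconds: float = 180.0,
) -> float:
    """Delta total activity around a stimulus (e.g. transfer into mustard oil).

    Returns the total activity (sum of delta-pixels/frame) during the first
    ``window_seconds`` after ``transfer_frame`` minus the total activity
    during the ``window_seconds`` immediately before it.  Incomplete
    windows are rejected.
    """
    trace = np.asarray(trace, dtype=float)
    w = int(round(window_seconds * frame_rate))
    if transfer_frame - w < 0 or transfer_frame + w > trace.size:
        raise ValueError("trace does not cover both windows")
    post = trace[transfer_frame : transfer_frame + w].sum()
    pre = trace[transfer_frame - w : transfer_frame].sum()
    return float(post - pre)
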