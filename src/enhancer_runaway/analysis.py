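"""Summaries of escalation runs: mean trajectories, slopes, doubling times.

Mean log strength increases linearly with time during the runaway, so the
escalation rate is summarized by the OLS slope ``a`` of the replicate-mean
trajectory and reported as the doubling time ``T2 = ln(2) / a`` — the
expected number of generations for mean enhancer strength to double on the
geometric scale (strengths start at ``e0 = 1``, ``z = 0``).  A flat or
decreasing trajectory has no doubling time (reported as NaN).

Group comparisons between parameter settings are made on per-replicate
slopes (not per-replicate doubling times, whose ``1/a`` transform blows up
the variance of near-flat replicates) with one-sided permutation tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_model import InvalidParameterError
from .wf_simulator import EscalationResult

__all__ = [
    "TrajectorySummary",
    "mean_log_strength",
    "doubling_time",
    "summarize",
    "replicate_slopes",
    "compare_slopes",
]


@dataclass(frozen=True)
class TrajectorySummary:
    generations: np.ndarray
    z_bar: np.ndarray
    slope: float
    slope_stderr: float
    doubling_time: float  # NaN when slope <= 0
    r_squared: float


def mean_log_strength(trajectories) -> np.ndarray:
    """Average replicate trajectories into one z-bar(t) series.

    Accepts an :class:`EscalationResult` or a (n_iter, T) array of
    per-replicate population means; replicate order is irrelevant.
    """
    if isinstance(trajectories, EscalationResult):
        arr = trajectories.mean_z
    else:
        arr = np.asarray(trajectories, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise InvalidParameterError("trajectories must be a 2-D (replicate, time) array")
    return arr.mean(axis=0)


def doubling_time(generations, z_bar) -> TrajectorySummary:
    """OLS fit of z-bar on time; doubling time ``ln(2)/slope``.

    All sampled points enter the regression, including generation 0.
    """
    t = np.asarray(generations, dtype=float)
    z = np.asarray(z_bar, dtype=float)
    if t.shape != z.shape or t.ndim != 1:
        raise InvalidParameterError("generations and z_bar must be 1-D of equal length")
    if t.size < 3:
        raise InvalidParameterError("need at least 3 time points")
    if np.ptp(t) == 0.0:
        raise InvalidParameterError("time points have zero variance")
    fit = stats.linregress(t, z)
    a = float(fit.slope)
    t2 = np.log(2.0) / a if a > 0.0 else float("nan")
    return TrajectorySummary(
        generations=t,
        z_bar=z,
        slope=a,
        slope_stderr=float(fit.stderr),
        doubling_time=t2,
        r_squared=float(fit.rvalue) ** 2,
    )


def summarize(result: EscalationResult) -> TrajectorySummary:
    """Doubling-time summary of an escalation result's replicate mean."""
    return doubling_time(result.generations, mean_log_strength(result))


def replicate_slopes(result: EscalationResult) -> np.ndarray:
    """Per-replicate OLS slopes of mean z on time."""
    t = result.generations.astype(float)
    tc = t - t.mean()
    denom = float(tc @ tc)
    z = result.mean_z - result.mean_z.mean(axis=1, keepdims=True)
    return (z @ tc) / denom


def compare_slopes(
    slower: np.ndarray,
    faster: np.ndarray,
    n_resamples: int = 9999,
    seed: int = 0,
) -> float:
    """One-sided permutation p-value for mean(slower) < mean(faster).

    Used to assert escalation-rate orderings, e.g. that stronger stabilizing
    selection, TF-mediated regulation or selfing slows the runaway: the
    setting claimed to escalate more slowly goes first.
    """
    slower = np.asarray(slower, float)
    faster = np.asarray(faster, float)
    res = stats.permutation_test(
        (faster, slower),
        lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
        alternative="greater",
        n_resamples=n_resamples,
        rng=np.random.default_rng(seed),
        vectorized=True,
    )
    return float(res.pvalue)
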