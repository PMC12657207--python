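"""Per-panel test-retest coefficients and their Monte Carlo distribution.

The TRC for one simulated sample is the Pearson correlation of the two
observed-score vectors.  Repeating the draw gives the coefficient's sampling
distribution; its mean measures accuracy (against the closed-form expected
TRC) and its standard deviation measures coefficient stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .generator import SeedLike, generate_fixed_tau, generate_scores
from .model import ConditionSpec, InvalidParameterError

__all__ = [
    "EmptyDistributionError",
    "TRCDistribution",
    "pearson_r",
    "replicate_condition",
    "sd_asymptotic",
    "child_seeds",
]


class EmptyDistributionError(RuntimeError):
    """Every replicate produced an undefined correlation."""


@dataclass(frozen=True)
class TRCDistribution:
    """Replicate-level TRC values with their Monte Carlo summary.

    ``mean_trc`` / ``sd_trc`` are the mean and sample standard deviation
    (n-1 denominator) of ``values``; replicates whose correlation was
    undefined (zero-variance draw) are dropped and counted.
    """

    values: np.ndarray
    mean_trc: float
    sd_trc: float
    n: int
    reps_requested: int
    reps_used: int
    dropped: int


def pearson_r(x1, x2) -> float:
    """Product-moment correlation of two equal-length vectors.

    Returns ``nan`` (the undefined-correlation signal) when either vector
    has zero sample variance; raises for mismatched or too-short inputs.
    The result is clipped into [-1, 1] to absorb last-ulp rounding.
    """
    x = np.asarray(x1, dtype=np.float64)
    y = np.asarray(x2, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("inputs must be equal-length 1-d vectors")
    if x.shape[0] < 2:
        raise InvalidParameterError("correlation needs at least 2 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        return float("nan")
    r = float(dx @ dy) / float(np.sqrt(sxx * syy))
    return min(1.0, max(-1.0, r))


def child_seeds(seed: SeedLike, count: int) -> list[np.random.SeedSequence]:
    """Deterministic independent child streams for ``count`` replicates."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    elif isinstance(seed, np.random.Generator):
        raise InvalidParameterError("pass an integer or SeedSequence, not a Generator")
    else:
        ss = np.random.SeedSequence(seed)
    return ss.spawn(count)


def replicate_condition(
    spec: ConditionSpec,
    n: int,
    reps: int,
    seed: SeedLike,
    fixed_tau: bool = False,
) -> TRCDistribution:
    """Simulate one condition ``reps`` times and summarize the TRC draws.

    Each replicate uses an independent child stream spawned from ``seed``, so
    results are reproducible and independent of evaluation order.  The
    fixed-true-score path is taken when ``fixed_tau`` is set or when the spec
    encodes perfect stability.  Observed scores are centered at their known
    population means before correlating -- a translation that leaves Pearson r
    unchanged but lets the generator's scale-invariance contract carry through
    to the correlation bit-for-bit.

    Replicates with undefined correlation (possible only for degenerate
    variances) are dropped and counted in ``dropped``.
    """
    if reps < 2:
        raise InvalidParameterError(f"reps must be >= 2, got {reps}")
    if n < 2:
        raise InvalidParameterError(f"n must be >= 2, got {n}")
    if n == 2:
        warnings.warn(
            "n = 2 gives r = +/-1 almost surely; summaries are degenerate",
            stacklevel=2,
        )
    use_fixed = fixed_tau or spec.tau_stability == 1.0
    draw = generate_fixed_tau if use_fixed else generate_scores
    center1 = spec.true_mean + spec.error_mean
    values = np.empty(reps)
    used = 0
    for child in child_seeds(seed, reps):
        panel = draw(spec, n, child)
        r = pearson_r(panel.x1 - center1, panel.x2 - center1)
        if np.isnan(r):
            continue
        values[used] = r
        used += 1
    if used == 0:
        raise EmptyDistributionError("all replicates had undefined correlations")
    values = values[:used].copy()
    dropped = reps - used
    if dropped:
        warnings.warn(f"dropped {dropped} replicate(s) with undefined r", stacklevel=2)
    sd = float(np.std(values, ddof=1)) if used > 1 else float("nan")
    return TRCDistribution(
        values=values,
        mean_trc=float(values.mean()),
        sd_trc=sd,
        n=n,
        reps_requested=reps,
        reps_used=used,
        dropped=dropped,
    )


def sd_asymptotic(rho: float, n: int) -> float:
    """Large-sample standard deviation of Pearson r: ``(1 - rho^2)/sqrt(n-1)``.

    Serves as the analytic oracle for coefficient-stability checks; accurate
    to a few percent for moderate n and |rho| below ~.95.
    """
    if not (-1.0 <= rho <= 1.0):
        raise InvalidParameterError(f"rho must be in [-1, 1], got {rho}")
    if n < 2:
        raise InvalidParameterError(f"n must be >= 2, got {n}")
    return (1.0 - rho * rho) / np.sqrt(n - 1.0)
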