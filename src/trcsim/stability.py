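"""Coefficient-stability classification, minimum-n search, and bias tables.

Coefficient stability is the tightness of the TRC's sampling distribution
across replicate samples, summarized by its standard deviation: SD <= .05 is
"good", SD <= .025 is "excellent".  The minimum-n search locates the
smallest sample size on a grid from which a criterion holds at that point
and every larger evaluated point (the sustained-crossing rule), mirroring
how sample-size recommendations are read off simulation sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimator import replicate_condition
from .generator import SeedLike
from .model import (
    ConditionSpec,
    InvalidParameterError,
    expected_trc_dependent,
    reliability_from_variances,
    trc_bias,
)

__all__ = [
    "StabilityCriterion",
    "GOOD",
    "EXCELLENT",
    "DEFAULT_N_GRID",
    "MinNResult",
    "classify_stability",
    "min_sample_size",
    "bias_table",
]


@dataclass(frozen=True)
class StabilityCriterion:
    """Named SD threshold for coefficient stability."""

    label: str
    sd_threshold: float


GOOD = StabilityCriterion("good", 0.05)
EXCELLENT = StabilityCriterion("excellent", 0.025)

#: Default candidate sample sizes: dense where thresholds for reliable
#: instruments fall, then hundreds up to the 1000-participant ceiling.
DEFAULT_N_GRID: tuple[int, ...] = (
    2, 3, 5, 8, 10, 15, 20, 25, 30, 40, 50, 75, 100, 150, 200,
    300, 400, 500, 600, 700, 800, 900, 1000,
)

#: Largest sample size the search will evaluate by default.
DEFAULT_CEILING = 1000


@dataclass(frozen=True)
class MinNResult:
    """Outcome of a sustained-crossing minimum-n search.

    ``min_n`` is ``None`` when the criterion is never sustained up to the
    grid ceiling; :attr:`sentinel` renders that as ``">ceiling"`` in tables.
    """

    spec: ConditionSpec
    criterion: StabilityCriterion
    min_n: int | None
    grid: tuple[int, ...]
    sd_profile: np.ndarray

    @property
    def reached(self) -> bool:
        return self.min_n is not None

    @property
    def sentinel(self) -> str:
        return str(self.min_n) if self.reached else f">{max(self.grid)}"

    def profile_frame(self) -> pd.DataFrame:
        """Per-grid-point SDs with the criterion verdict, for CSV export."""
        sds = np.asarray(self.sd_profile)
        return pd.DataFrame(
            {
                "n": list(self.grid),
                "sd_trc": sds,
                "meets_criterion": sds <= self.criterion.sd_threshold,
            }
        )


def classify_stability(sd_trc: float) -> str:
    """Label an SD of replicate TRCs: excellent (<=.025), good (<=.05), else unstable."""
    if sd_trc < 0:
        raise InvalidParameterError(f"sd_trc must be >= 0, got {sd_trc}")
    if sd_trc <= EXCELLENT.sd_threshold:
        return "excellent"
    if sd_trc <= GOOD.sd_threshold:
        return "good"
    return "unstable"


def min_sample_size(
    spec: ConditionSpec,
    criterion: StabilityCriterion,
    grid: tuple[int, ...] = DEFAULT_N_GRID,
    reps: int = 1000,
    seed: SeedLike = 0,
    ceiling: int = DEFAULT_CEILING,
    fixed_tau: bool = False,
) -> MinNResult:
    """Smallest grid n from which the stability criterion holds sustainedly.

    Evaluates ``sd_trc`` at every grid point (each with its own child stream
    spawned from ``seed`` keyed by n, so profiles are reproducible and
    order-independent) and returns the first n at which the SD is at or
    below the threshold *and stays there* for all larger grid points.  A
    single lucky dip below the threshold therefore does not count.
    """
    grid = tuple(grid)
    if len(grid) == 0:
        raise InvalidParameterError("sample-size grid must be non-empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise InvalidParameterError("sample-size grid must be strictly increasing")
    if max(grid) > ceiling:
        raise InvalidParameterError(
            f"grid exceeds the configured ceiling ({max(grid)} > {ceiling})"
        )
    if isinstance(seed, np.random.SeedSequence):
        root = seed
    else:
        root = np.random.SeedSequence(seed)
    sds = np.empty(len(grid))
    for i, n in enumerate(grid):
        point_seed = np.random.SeedSequence(
            entropy=root.entropy, spawn_key=root.spawn_key + (n,)
        )
        dist = replicate_condition(spec, n, reps, point_seed, fixed_tau=fixed_tau)
        sds[i] = dist.sd_trc
    meets = sds <= criterion.sd_threshold
    failing = np.flatnonzero(~meets)
    if failing.size == 0:
        min_n: int | None = grid[0]
    elif failing[-1] == len(grid) - 1:
        min_n = None
    else:
        min_n = grid[failing[-1] + 1]
    return MinNResult(
        spec=spec, criterion=criterion, min_n=min_n, grid=grid, sd_profile=sds
    )


def bias_table(
    specs: list[ConditionSpec],
    n: int = 1000,
    reps: int = 1000,
    seed: SeedLike = 0,
) -> pd.DataFrame:
    """Simulated and closed-form TRC bias for a list of conditions.

    One row per condition: variance coordinates, reliability, expected TRC,
    the Monte Carlo mean/SD, the simulated bias (reliability minus mean TRC),
    and the closed-form bias.  Simulated and closed-form bias agree within
    Monte Carlo error whenever the generator and the algebra are consistent.
    """
    if not specs:
        raise InvalidParameterError("specs must be non-empty")
    if isinstance(seed, np.random.SeedSequence):
        root = seed
    else:
        root = np.random.SeedSequence(seed)
    rows = []
    for i, spec in enumerate(specs):
        child = np.random.SeedSequence(
            entropy=root.entropy, spawn_key=root.spawn_key + (i,)
        )
        dist = replicate_condition(spec, n, reps, child)
        rel = reliability_from_variances(spec.variances)
        rows.append(
            {
                "true_var": spec.variances.true_var,
                "error_var": spec.variances.error_var,
                "tau_stability": spec.tau_stability,
                "error_dependence": spec.error_dependence,
                "reliability": rel,
                "expected_trc": expected_trc_dependent(spec),
                "mean_trc": dist.mean_trc,
                "sd_trc": dist.sd_trc,
                "bias": rel - dist.mean_trc,
                "expected_bias": trc_bias(spec),
                "n": n,
                "reps_used": dist.reps_used,
                "dropped": dist.dropped,
            }
        )
    return pd.DataFrame(rows)
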