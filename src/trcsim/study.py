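"""Orchestration of the two simulation studies over their condition grids.

Study 1 sweeps sample size, true-to-error variance ratio, and true-score
stability with independent errors; Study 2 fixes the variance scale, sweeps
reliability directly, and adds error-score dependence.  Both emit one tidy
row per condition x sample size with the Monte Carlo mean/SD of the TRC,
the closed-form expected TRC, and the bias relative to reliability.

Replicate streams are keyed by (root seed, stability level index,
error-dependence level index, n, replicate) -- deliberately *not* by the
variance cell.  Conditions that differ only in variance scale therefore
share common random numbers, which turns the scale-invariance property of
the generator into bit-identical result rows, and reduces Monte Carlo noise
in comparisons across variance ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .estimator import replicate_condition
from .model import (
    ConditionSpec,
    InvalidParameterError,
    expected_trc_dependent,
    reliability_from_variances,
)
from .stability import DEFAULT_N_GRID

__all__ = [
    "StudyConfig",
    "ConfigError",
    "study1_config",
    "study2_config",
    "run_study1",
    "run_study2",
    "run_study",
    "write_table",
    "write_manifest",
    "RESULT_COLUMNS",
]


class ConfigError(InvalidParameterError):
    """A study configuration field is invalid."""


#: Fixed column order of study result tables.
RESULT_COLUMNS: tuple[str, ...] = (
    "study",
    "n",
    "true_var",
    "error_var",
    "reliability",
    "tau_stability",
    "error_dependence",
    "expected_trc",
    "mean_trc",
    "sd_trc",
    "bias",
    "reps_used",
    "dropped",
)

#: Stability levels of Study 1 (1.0 runs through the fixed-true-score path).
STUDY1_TAU_LEVELS: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)
#: Stability levels of Study 2.
STUDY2_TAU_LEVELS: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6)
#: Error-dependence levels of Study 2, with 0 kept as the independent baseline.
STUDY2_EPS_LEVELS: tuple[float, ...] = (0.0, 0.1, 0.3, 0.5)

_FULL_VARIANCE_GRID: tuple[tuple[float, float], ...] = tuple(
    (float(t), float(e)) for t in range(1, 10) for e in range(1, 10)
)
#: Representative ratio cells for desk-scale Study 1 (reliability .6/.7/.8/.9).
_DESK_VARIANCE_GRID: tuple[tuple[float, float], ...] = (
    (6.0, 4.0),
    (7.0, 3.0),
    (8.0, 2.0),
    (9.0, 1.0),
)
_DESK_N_GRID: tuple[int, ...] = (25, 50, 100, 250, 500, 1000)

_STUDY2_RELIABILITIES: tuple[float, ...] = tuple(
    round(0.60 + 0.05 * k, 2) for k in range(8)
)
#: Total observed-score variance used to realize Study 2 reliabilities.
STUDY2_TOTAL_VAR = 10.0


@dataclass(frozen=True)
class StudyConfig:
    """Full description of one study run (grids, replication, seed, scale)."""

    study: str
    n_grid: tuple[int, ...]
    reps: int
    seed: int
    tau_stability_levels: tuple[float, ...]
    error_dependence_levels: tuple[float, ...]
    variance_grid: tuple[tuple[float, float], ...] = ()
    reliability_grid: tuple[float, ...] = ()
    total_var: float = STUDY2_TOTAL_VAR
    true_mean: float = 10.0
    scale: str = "desk"

    def __post_init__(self) -> None:
        if self.study not in ("study1", "study2"):
            raise ConfigError(f"study must be 'study1' or 'study2', got {self.study!r}")
        if self.reps < 2:
            raise ConfigError(f"reps must be >= 2, got {self.reps}")
        if not self.n_grid or any(n < 2 for n in self.n_grid):
            raise ConfigError("n_grid must be non-empty with every n >= 2")
        if not self.tau_stability_levels:
            raise ConfigError("tau_stability_levels must be non-empty")
        if self.study == "study1":
            if tuple(self.error_dependence_levels) != (0.0,):
                raise ConfigError(
                    "study1 assumes independent errors: error_dependence_levels"
                    " must be (0.0,)"
                )
            if not self.variance_grid:
                raise ConfigError("study1 needs a variance_grid")
        else:
            if not self.reliability_grid:
                raise ConfigError("study2 needs a reliability_grid")
            if not self.total_var > 0:
                raise ConfigError("total_var must be positive")


def study1_config(scale: str = "desk", seed: int = 0, **overrides) -> StudyConfig:
    """Default Study 1 configuration at desk or full scale.

    Desk scale: 4 representative variance ratios, a coarse n grid, and 200
    replicates -- minutes on one CPU.  Full scale: the 9x9 variance grid,
    the default stability n grid, and 1000 replicates.
    """
    if scale not in ("desk", "full"):
        raise ConfigError(f"scale must be 'desk' or 'full', got {scale!r}")
    base = StudyConfig(
        study="study1",
        n_grid=_DESK_N_GRID if scale == "desk" else DEFAULT_N_GRID,
        reps=200 if scale == "desk" else 1000,
        seed=seed,
        tau_stability_levels=STUDY1_TAU_LEVELS,
        error_dependence_levels=(0.0,),
        variance_grid=_DESK_VARIANCE_GRID if scale == "desk" else _FULL_VARIANCE_GRID,
        scale=scale,
    )
    return replace(base, **overrides) if overrides else base


def study2_config(scale: str = "desk", seed: int = 0, **overrides) -> StudyConfig:
    """Default Study 2 configuration at desk or full scale."""
    if scale not in ("desk", "full"):
        raise ConfigError(f"scale must be 'desk' or 'full', got {scale!r}")
    base = StudyConfig(
        study="study2",
        n_grid=(100, 250, 1000) if scale == "desk" else DEFAULT_N_GRID,
        reps=200 if scale == "desk" else 1000,
        seed=seed,
        tau_stability_levels=STUDY2_TAU_LEVELS,
        error_dependence_levels=STUDY2_EPS_LEVELS,
        reliability_grid=_STUDY2_RELIABILITIES,
        scale=scale,
    )
    return replace(base, **overrides) if overrides else base


def _condition_seed(
    config: StudyConfig, tau_idx: int, eps_idx: int, n: int
) -> np.random.SeedSequence:
    # Keyed by correlation structure + n only: variance cells share streams.
    return np.random.SeedSequence(
        entropy=config.seed, spawn_key=(tau_idx, eps_idx, n)
    )


def _run_cell(
    config: StudyConfig,
    spec: ConditionSpec,
    n: int,
    tau_idx: int,
    eps_idx: int,
) -> dict:
    seed = _condition_seed(config, tau_idx, eps_idx, n)
    dist = replicate_condition(
        spec, n, config.reps, seed, fixed_tau=spec.tau_stability == 1.0
    )
    rel = reliability_from_variances(spec.variances)
    return {
        "study": config.study,
        "n": n,
        "true_var": spec.variances.true_var,
        "error_var": spec.variances.error_var,
        "reliability": rel,
        "tau_stability": spec.tau_stability,
        "error_dependence": spec.error_dependence,
        "expected_trc": expected_trc_dependent(spec),
        "mean_trc": dist.mean_trc,
        "sd_trc": dist.sd_trc,
        "bias": rel - dist.mean_trc,
        "reps_used": dist.reps_used,
        "dropped": dist.dropped,
    }


def run_study1(config: StudyConfig, progress=None) -> pd.DataFrame:
    """Sweep Study 1: stability x variance cell x sample size, independent errors.

    Perfect stability (1.0) runs through the fixed-true-score copy path.
    ``progress`` may be a callable taking a status string.
    """
    if config.study != "study1":
        raise ConfigError("run_study1 requires a study1 config")
    rows = []
    for tau_idx, tau in enumerate(config.tau_stability_levels):
        if progress is not None:
            progress(f"study1: tau_stability={tau}")
        for true_var, error_var in config.variance_grid:
            spec = ConditionSpec.of(
                true_var, error_var, tau, 0.0, true_mean=config.true_mean
            )
            for n in config.n_grid:
                rows.append(_run_cell(config, spec, n, tau_idx, 0))
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def run_study2(config: StudyConfig, progress=None) -> pd.DataFrame:
    """Sweep Study 2: reliability x stability x error dependence x sample size.

    Reliability levels are realized as ``true_var = total_var * reliability``
    with the total fixed; scale invariance makes the absolute total
    immaterial, so only the ratio matters.
    """
    if config.study != "study2":
        raise ConfigError("run_study2 requires a study2 config")
    rows = []
    for tau_idx, tau in enumerate(config.tau_stability_levels):
        for eps_idx, eps in enumerate(config.error_dependence_levels):
            if progress is not None:
                progress(f"study2: tau_stability={tau} error_dependence={eps}")
            for rel in config.reliability_grid:
                true_var = config.total_var * rel
                error_var = config.total_var - true_var
                spec = ConditionSpec.of(
                    true_var, error_var, tau, eps, true_mean=config.true_mean
                )
                for n in config.n_grid:
                    rows.append(_run_cell(config, spec, n, tau_idx, eps_idx))
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def run_study(config: StudyConfig, progress=None) -> pd.DataFrame:
    """Dispatch to the configured study."""
    if config.study == "study1":
        return run_study1(config, progress=progress)
    return run_study2(config, progress=progress)


def write_table(table: pd.DataFrame, path) -> None:
    """Write a result table as CSV with the fixed column order."""
    table.to_csv(path, index=False)


def write_manifest(path, config: StudyConfig) -> None:
    """Plain-text provenance record: package version, seed, and grids."""
    lines = [
        f"trcsim_version: {__version__}",
        f"study: {config.study}",
        f"scale: {config.scale}",
        f"seed: {config.seed}",
        f"reps: {config.reps}",
        f"n_grid: {','.join(str(n) for n in config.n_grid)}",
        f"tau_stability_levels: {','.join(str(t) for t in config.tau_stability_levels)}",
        "error_dependence_levels: "
        + ",".join(str(e) for e in config.error_dependence_levels),
    ]
    if config.study == "study1":
        lines.append(
            "variance_grid: "
            + ";".join(f"{t}:{e}" for t, e in config.variance_grid)
        )
    else:
        lines.append(
            "reliability_grid: " + ",".join(str(r) for r in config.reliability_grid)
        )
        lines.append(f"total_var: {config.total_var}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
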