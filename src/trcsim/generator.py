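"""Joint-normal score generation for two-occasion test-retest designs.

Each draw produces paired true scores ``(tau1, tau2)``, paired error scores
``(eps1, eps2)``, and observed scores ``x = tau + eps``.  The four latent
variables are jointly normal with block-diagonal correlation structure: true
scores correlate ``r_tau`` across occasions, errors correlate ``r_eps``, and
every true-error covariance is zero.

Sampling contract
-----------------
Standard-normal deviates are drawn first, correlated with the analytic 2x2
Cholesky factor ``[[1, 0], [r, sqrt(1 - r^2)]]`` of each block, scaled by the
standard deviations, quantized to 24-bit significands, and only then shifted
by the means.  Consequences:

* rescaling both variances by ``4^k`` under the same seed scales every
  deviate by exactly ``2^k`` in floating point, and because the quantized
  deviates add exactly to the mean, every downstream correlation is
  bit-identical to the unscaled run (the scale-invariance contract);
* the rank-deficient ``r = 1`` blocks need no factorization fallback -- the
  analytic factor degenerates to an exact copy;
* the quantization perturbs scores by at most one part in ~10^7, orders of
  magnitude below Monte Carlo noise at any simulated sample size.

Degenerate variances (``true_var = 0`` or ``error_var = 0``) are permitted;
the corresponding component is constant and downstream correlation handling
deals with any resulting zero-variance observed scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ConditionSpec, InvalidParameterError

__all__ = [
    "ScorePanel",
    "TargetCovariance",
    "build_covariance",
    "generate_scores",
    "generate_fixed_tau",
    "panel_to_frame",
]

#: Variable order used by :class:`TargetCovariance` rows/columns.
VARIABLE_ORDER: tuple[str, ...] = ("tau1", "tau2", "eps1", "eps2")

SeedLike = int | np.random.SeedSequence | np.random.Generator


@dataclass(frozen=True)
class ScorePanel:
    """Paired true, error, and observed scores for one simulated sample.

    Invariants: all six vectors share length ``n >= 2`` and the observed
    scores satisfy ``x = tau + eps`` elementwise, exactly.
    """

    tau1: np.ndarray
    tau2: np.ndarray
    eps1: np.ndarray
    eps2: np.ndarray
    x1: np.ndarray
    x2: np.ndarray

    def __post_init__(self) -> None:
        n = self.tau1.shape[0]
        for name in ("tau2", "eps1", "eps2", "x1", "x2"):
            if getattr(self, name).shape != (n,):
                raise InvalidParameterError("all score vectors must share one length")
        if n < 2:
            raise InvalidParameterError("a score panel needs at least 2 observations")

    @property
    def n(self) -> int:
        return self.tau1.shape[0]


@dataclass(frozen=True)
class TargetCovariance:
    """Population 4x4 covariance of ``(tau1, tau2, eps1, eps2)``."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape != (4, 4):
            raise InvalidParameterError("target covariance must be 4x4")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(VARIABLE_ORDER), columns=list(VARIABLE_ORDER)
        )


def build_covariance(spec: ConditionSpec) -> TargetCovariance:
    """Population covariance implied by a condition.

    Diagonal ``(s_t^2, s_t^2, s_e^2, s_e^2)``; ``Cov(tau1, tau2) = r_tau *
    s_t^2``; ``Cov(eps1, eps2) = r_eps * s_e^2``; all true-error covariances
    zero.  Symmetric and positive semidefinite for ``|r| <= 1`` (and rank
    deficient when a correlation hits 1).
    """
    tv = spec.variances.true_var
    ev = spec.variances.error_var
    rt = spec.tau_stability
    re = spec.error_dependence
    matrix = np.array(
        [
            [tv, rt * tv, 0.0, 0.0],
            [rt * tv, tv, 0.0, 0.0],
            [0.0, 0.0, ev, re * ev],
            [0.0, 0.0, re * ev, ev],
        ]
    )
    return TargetCovariance(matrix=matrix)


def _as_generator(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _quantize(values: np.ndarray) -> np.ndarray:
    # Round to 24-bit significands: mantissa truncation commutes with
    # power-of-two scaling and makes the subsequent mean shift an exact sum.
    return values.astype(np.float32).astype(np.float64)


def _correlated_pair(
    z_base: np.ndarray, z_orth: np.ndarray, r: float
) -> tuple[np.ndarray, np.ndarray]:
    # Analytic Cholesky of [[1, r], [r, 1]]; exact copy when r == 1.
    return z_base, r * z_base + np.sqrt(max(1.0 - r * r, 0.0)) * z_orth


def _assemble(
    spec: ConditionSpec,
    u_t1: np.ndarray,
    u_t2: np.ndarray,
    u_e1: np.ndarray,
    u_e2: np.ndarray,
    copy_tau: bool,
) -> ScorePanel:
    sd_t = np.sqrt(spec.variances.true_var)
    sd_e = np.sqrt(spec.variances.error_var)
    tau1 = spec.true_mean + _quantize(sd_t * u_t1)
    tau2 = tau1.copy() if copy_tau else spec.true_mean + _quantize(sd_t * u_t2)
    eps1 = _quantize(sd_e * u_e1)
    eps2 = _quantize(sd_e * u_e2)
    return ScorePanel(
        tau1=tau1, tau2=tau2, eps1=eps1, eps2=eps2, x1=tau1 + eps1, x2=tau2 + eps2
    )


def _draw(spec: ConditionSpec, n: int, seed: SeedLike, copy_tau: bool) -> ScorePanel:
    if n < 2:
        raise InvalidParameterError(f"sample size must be >= 2, got {n}")
    rng = _as_generator(seed)
    z = rng.standard_normal((4, n))
    u_t1, u_t2 = _correlated_pair(z[0], z[1], spec.tau_stability)
    u_e1, u_e2 = _correlated_pair(z[2], z[3], spec.error_dependence)
    return _assemble(spec, u_t1, u_t2, u_e1, u_e2, copy_tau)


def generate_scores(spec: ConditionSpec, n: int, seed: SeedLike) -> ScorePanel:
    """Draw ``n`` joint-normal score quadruples and their observed sums.

    True scores have mean ``spec.true_mean``, errors mean zero, and the
    covariance of ``(tau1, tau2, eps1, eps2)`` targets
    :func:`build_covariance`.  Reproducible: identical ``(spec, n, seed)``
    yields identical panels.
    """
    return _draw(spec, n, seed, copy_tau=False)


def generate_fixed_tau(spec: ConditionSpec, n: int, seed: SeedLike) -> ScorePanel:
    """Draw a panel in which the occasion-2 true scores are an exact copy of
    occasion 1 (the perfectly-stable-trait condition).

    Consumes the same deviate layout as :func:`generate_scores`, so with
    ``tau_stability = 1`` the two paths return bit-identical panels under a
    shared seed; with other stability values the copy simply overrides the
    correlated draw.  Errors are drawn independently unless the spec requests
    error dependence.
    """
    return _draw(spec, n, seed, copy_tau=True)


def panel_to_frame(panel: ScorePanel) -> pd.DataFrame:
    """Tidy per-subject view of a panel (columns: id, tau1..x2)."""
    return pd.DataFrame(
        {
            "id": np.arange(1, panel.n + 1),
            "tau1": panel.tau1,
            "tau2": panel.tau2,
            "eps1": panel.eps1,
            "eps2": panel.eps2,
            "x1": panel.x1,
            "x2": panel.x2,
        }
    )
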