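"""Closed-form classical-test-theory (CTT) algebra for the test-retest coefficient.

CTT decomposes an observed score into a true score plus a random error,
``x = tau + eps``, with ``E[eps] = 0`` and ``Cov(tau, eps) = 0``.  Reliability
is the share of observed-score variance carried by true scores,

    rho_xx = sigma_tau^2 / (sigma_tau^2 + sigma_eps^2).

The test-retest coefficient (TRC) -- the Pearson correlation between two
administrations of the same instrument -- equals reliability only when true
scores are perfectly stable between occasions and the two occasions' errors
are independent.  Relaxing those assumptions gives the closed forms housed
here:

* imperfect stability ``r_tau`` attenuates the TRC to the product
  ``r_tau * rho_xx``;
* dependent errors ``r_eps`` turn the TRC into the variance-weighted mixture
  ``r_tau * rho_xx + r_eps * (1 - rho_xx)``.

Everything in this module is pure, deterministic arithmetic; no random number
generation enters here.  The simulation modules treat these expressions as
the analytic oracle to which Monte Carlo output must converge.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidParameterError",
    "VarianceComponents",
    "ConditionSpec",
    "ReliabilityCategory",
    "RELIABILITY_CATEGORIES",
    "EquivalenceSet",
    "reliability_from_variances",
    "expected_trc",
    "expected_trc_dependent",
    "trc_bias",
    "classify_reliability",
    "equivalent_conditions",
]


class InvalidParameterError(ValueError):
    """A parameter violates its domain constraints."""


@dataclass(frozen=True)
class VarianceComponents:
    """True-score and error-score variances of one instrument.

    Parameters
    ----------
    true_var
        Variance of true scores, ``sigma_tau^2`` (score units squared).
    error_var
        Variance of error scores, ``sigma_eps^2`` (score units squared).

    Both must be nonnegative and their sum (the observed-score variance)
    strictly positive.
    """

    true_var: float
    error_var: float

    def __post_init__(self) -> None:
        if not (self.true_var >= 0.0):
            raise InvalidParameterError(f"true_var must be >= 0, got {self.true_var}")
        if not (self.error_var >= 0.0):
            raise InvalidParameterError(f"error_var must be >= 0, got {self.error_var}")
        if not (self.true_var + self.error_var > 0.0):
            raise InvalidParameterError("total variance must be positive")

    @property
    def total_var(self) -> float:
        """Observed-score variance ``sigma_x^2 = sigma_tau^2 + sigma_eps^2``."""
        return self.true_var + self.error_var

    @property
    def reliability(self) -> float:
        """Reliability as the true-to-total variance ratio."""
        return reliability_from_variances(self)

    def scaled(self, factor: float) -> "VarianceComponents":
        """Both variances multiplied by ``factor`` (> 0); reliability unchanged."""
        if not factor > 0:
            raise InvalidParameterError("scale factor must be positive")
        return VarianceComponents(self.true_var * factor, self.error_var * factor)


@dataclass(frozen=True)
class ConditionSpec:
    """One simulation condition: variance components plus the two cross-time
    correlations that the classical model assumes away.

    Parameters
    ----------
    variances
        True- and error-score variances shared by both occasions.
    tau_stability
        Correlation of true scores across occasions, ``r_tau`` in [0, 1].
        1 encodes the fixed-true-score condition.
    error_dependence
        Correlation of error scores across occasions, ``r_eps`` in [0, 1).
    true_mean
        Location of the true-score distribution (default 10, chosen to keep
        true scores visibly apart from the mean-zero errors).
    error_mean
        Fixed at 0: CTT defines the expected error score to be zero.
    """

    variances: VarianceComponents
    tau_stability: float
    error_dependence: float = 0.0
    true_mean: float = 10.0
    error_mean: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau_stability <= 1.0):
            raise InvalidParameterError(
                f"tau_stability must be in [0, 1], got {self.tau_stability}"
            )
        if not (0.0 <= self.error_dependence < 1.0):
            raise InvalidParameterError(
                f"error_dependence must be in [0, 1), got {self.error_dependence}"
            )
        if self.error_mean != 0.0:
            raise InvalidParameterError("error_mean is fixed at 0 by the model")

    @classmethod
    def of(
        cls,
        true_var: float,
        error_var: float,
        tau_stability: float,
        error_dependence: float = 0.0,
        true_mean: float = 10.0,
    ) -> "ConditionSpec":
        """Convenience constructor from raw variances."""
        return cls(
            variances=VarianceComponents(true_var, error_var),
            tau_stability=tau_stability,
            error_dependence=error_dependence,
            true_mean=true_mean,
        )

    @property
    def reliability(self) -> float:
        return self.variances.reliability


@dataclass(frozen=True)
class ReliabilityCategory:
    """A conventional reliability band with its inclusive lower bound."""

    label: str
    lower_bound: float


#: Conventional interpretation bands: below .70 is unacceptable, .70 acceptable,
#: .80 good, .90 excellent.  Lower bounds are inclusive so classification is total.
RELIABILITY_CATEGORIES: tuple[ReliabilityCategory, ...] = (
    ReliabilityCategory("excellent", 0.90),
    ReliabilityCategory("good", 0.80),
    ReliabilityCategory("acceptable", 0.70),
    ReliabilityCategory("unacceptable", -1.0),
)


@dataclass(frozen=True)
class EquivalenceSet:
    """Parameter triples whose expected TRC matches a target within tolerance.

    ``members`` holds ``(tau_stability, reliability, error_dependence)``
    triples.  The set demonstrates the identifiability problem: distinct
    mixtures of trait stability, reliability, and systematic error can
    produce the same observed test-retest correlation, so the components
    cannot be recovered from two measurement occasions alone.
    """

    target_trc: float
    tolerance: float
    members: tuple[tuple[float, float, float], ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.members)


def reliability_from_variances(v: VarianceComponents) -> float:
    """Reliability as the true-to-total variance ratio.

    ``rho_xx = sigma_tau^2 / (sigma_tau^2 + sigma_eps^2)``; invariant to a
    common rescaling of both variances.
    """
    return v.true_var / (v.true_var + v.error_var)


def _check_unit_interval(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise InvalidParameterError(f"{name} must be in [0, 1], got {value}")


def expected_trc(tau_stability: float, reliability: float) -> float:
    """Expected test-retest correlation under independent errors.

    With imperfect trait stability the TRC attenuates to the product of
    stability and reliability::

        E[r_x1x2] = r_tau * rho_xx

    Both factors live in [0, 1], so the TRC never exceeds either one.
    """
    _check_unit_interval("tau_stability", tau_stability)
    _check_unit_interval("reliability", reliability)
    return tau_stability * reliability


def expected_trc_dependent(spec: ConditionSpec) -> float:
    """Expected test-retest correlation allowing dependent error scores.

    The TRC becomes a variance-weighted mixture of trait stability and error
    dependence::

        E[r_x1x2] = r_tau * rho_xx + r_eps * (1 - rho_xx)

    a convex combination, so the result always lies between
    ``min(r_tau, r_eps)`` and ``max(r_tau, r_eps)``.  With ``r_eps = 0`` this
    reduces exactly to :func:`expected_trc`.
    """
    rel = reliability_from_variances(spec.variances)
    return spec.tau_stability * rel + spec.error_dependence * (1.0 - rel)


def trc_bias(spec: ConditionSpec) -> float:
    """Signed deviation of reliability from the expected TRC.

    ``bias = rho_xx - E[r_x1x2]``.  Positive values mean the TRC
    underestimates reliability (attenuation by unstable true scores);
    negative values mean dependent errors have inflated the TRC above
    reliability.
    """
    return reliability_from_variances(spec.variances) - expected_trc_dependent(spec)


def classify_reliability(trc_value: float) -> ReliabilityCategory:
    """Map a TRC value onto the conventional interpretation bands.

    Returns the highest category whose (inclusive) lower bound does not
    exceed ``trc_value``; anything below .70 is unacceptable.
    """
    if not (-1.0 <= trc_value <= 1.0):
        raise InvalidParameterError(f"a correlation must lie in [-1, 1], got {trc_value}")
    for category in RELIABILITY_CATEGORIES:
        if trc_value >= category.lower_bound:
            return category
    raise AssertionError("unreachable: categories cover [-1, 1]")  # pragma: no cover


def _unit_grid(resolution: float) -> np.ndarray:
    if not resolution > 0:
        raise InvalidParameterError("grid_resolution must be positive")
    steps = int(np.floor(1.0 / resolution + 1e-9))
    if steps < 1:
        raise InvalidParameterError("grid_resolution produces an empty grid")
    grid = np.round(np.arange(steps + 1) * resolution, 12)
    grid = grid[grid <= 1.0 + 1e-12]
    grid[-1] = min(grid[-1], 1.0)
    return grid


def equivalent_conditions(
    target_trc: float,
    grid_resolution: float = 0.05,
    tolerance: float = 0.005,
) -> EquivalenceSet:
    """Enumerate parameter triples whose expected TRC matches a target.

    Sweeps ``(r_tau, rho_xx, r_eps)`` over a uniform grid on [0, 1]^3 (with
    ``r_eps < 1``) and collects every triple whose mixture-form expected TRC
    lies within ``tolerance`` of ``target_trc``.  The resulting set is the
    observational equivalence class of the target: every member is
    indistinguishable from the others on the basis of a single observed
    test-retest correlation.
    """
    _check_unit_interval("target_trc", target_trc)
    if tolerance < 0:
        raise InvalidParameterError("tolerance must be >= 0")
    grid = _unit_grid(grid_resolution)
    eps_grid = grid[grid < 1.0]
    members = []
    for r_tau, rel, r_eps in itertools.product(grid, grid, eps_grid):
        value = r_tau * rel + r_eps * (1.0 - rel)
        if abs(value - target_trc) <= tolerance:
            members.append((float(r_tau), float(rel), float(r_eps)))
    return EquivalenceSet(
        target_trc=target_trc, tolerance=tolerance, members=tuple(members)
    )
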