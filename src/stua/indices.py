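"""Spatio-temporal uncertainty propagation indices.

Given a per-spatial-unit uncertainty measure ``U`` evaluated at two model
times ``t1`` and ``t2`` (for instance a total-effects sensitivity index in
[-1, 1]), two indices summarise how the uncertainty propagates between the
two snapshots:

* the **irrelevance index** ``I = alpha * s - beta**(-s)`` with
  ``s = |U_t1| + |U_t2|`` screens out cells whose uncertainty is
  insignificant at both times (``I <= 0`` excludes the cell); and
* the **relevance index** ``R = eta * U_t2**3 + rho * (U_t2 * |U_t1|)**3``
  ranks the remaining cells, with the sign of ``R`` following the sign of
  the time-2 measure.

The four tuning factors (``alpha``, ``beta``, ``eta``, ``rho``) map onto
interpretable thresholds: ``solve_irrelevance_threshold`` returns the
combined-magnitude cutoff ``lambda_I`` implied by ``(alpha, beta)``, and
``solve_lambda_u`` / ``solve_eta`` convert between ``eta`` and the
time-2 magnitude ``lambda_U`` that reaches a given relevance level
``lambda_R``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.optimize import bisect

__all__ = [
    "IndexFactors",
    "UncertaintyField",
    "PropagationMaps",
    "ThresholdQuery",
    "RelevanceCategory",
    "irrelevance_index",
    "relevance_index",
    "solve_irrelevance_threshold",
    "solve_lambda_u",
    "solve_eta",
    "rho_emphasis_bound",
    "classify_relevance",
    "propagation_maps",
]

#: Missing-value sentinel used throughout for unoccupied / undefined cells.
MISSING = np.nan


class RelevanceCategory(IntEnum):
    """Per-cell classification of the propagation analysis."""

    EXCLUDED = 0          # I <= 0 or cell unoccupied
    RELEVANT_NEGATIVE = 1  # R < -tol: time-2 measure significantly negative
    RELEVANT_POSITIVE = 2  # R > +tol: time-2 measure significantly positive
    NEAR_ZERO = 3          # |R| <= tol: relevant at t1 but not at t2


@dataclass(frozen=True)
class IndexFactors:
    """The four tuning factors of the propagation indices.

    ``alpha`` (> 0) and ``beta`` (>= 1) set the irrelevance screening
    threshold; ``eta`` (> 0) and ``rho`` (>= 0) set the steepness of the
    relevance index in the time-2 measure and in joint-high edge cases
    respectively.  ``beta >= 1`` guarantees the screen never marks
    high-uncertainty cells irrelevant.
    """

    alpha: float
    beta: float
    eta: float
    rho: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "eta", "rho"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"factor {name!r} must be finite, got {v!r}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.beta < 1:
            raise ValueError(f"beta must be >= 1, got {self.beta}")
        if self.eta <= 0:
            raise ValueError(f"eta must be > 0, got {self.eta}")
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")


@dataclass
class UncertaintyField:
    """A per-spatial-unit uncertainty measure at one labelled time step."""

    values: np.ndarray
    time_label: str = ""
    measure_name: str = ""
    occupied: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.occupied is None:
            self.occupied = np.isfinite(self.values)
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if self.occupied.shape != self.values.shape:
            raise ValueError(
                f"occupied shape {self.occupied.shape} != values shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values[self.occupied])):
            raise ValueError("occupied cells must carry finite values")
        # unoccupied cells carry the missing sentinel
        self.values = np.where(self.occupied, self.values, MISSING)


@dataclass
class PropagationMaps:
    """Irrelevance / relevance grids with per-cell categories."""

    irrelevance: np.ndarray
    relevance: np.ndarray
    category: np.ndarray        # integer grid of RelevanceCategory codes
    lambda_I_used: float
    factors: IndexFactors | None = None
    near_zero_tol: float = 0.05


@dataclass(frozen=True)
class ThresholdQuery:
    """Threshold triple used when picking index factors."""

    lambda_I: float
    lambda_R: float
    lambda_U: float

    def __post_init__(self) -> None:
        for name in ("lambda_I", "lambda_R", "lambda_U"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")


def _check_finite(name: str, x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return arr


def irrelevance_index(u1, u2, factors: IndexFactors):
    """Irrelevance index ``I = alpha*s - beta**(-s)`` with ``s = |u1|+|u2|``.

    Strictly increasing in ``s`` for ``beta >= 1``; cells with ``I <= 0``
    are insignificant at both times and are excluded from further analysis.
    Accepts scalars or arrays (broadcast).
    """
    a1 = _check_finite("u1", u1)
    a2 = _check_finite("u2", u2)
    s = np.abs(a1) + np.abs(a2)
    out = factors.alpha * s - factors.beta ** (-s)
    return float(out) if out.ndim == 0 else out


def relevance_index(u1, u2, factors: IndexFactors):
    """Relevance index ``R = eta*u2**3 + rho*(u2*|u1|)**3``.

    The sign of ``R`` equals the sign of ``u2`` (both terms carry ``u2**3``
    and ``eta, rho >= 0``); its magnitude is non-decreasing in ``eta``,
    ``rho``, ``|u1|`` and ``|u2|``.
    """
    a1 = _check_finite("u1", u1)
    a2 = _check_finite("u2", u2)
    out = factors.eta * a2**3 + factors.rho * (a2 * np.abs(a1)) ** 3
    return float(out) if out.ndim == 0 else out


def solve_irrelevance_threshold(alpha: float, beta: float) -> float:
    """Combined-magnitude screening threshold ``lambda_I`` for (alpha, beta).

    Returns the unique root ``s*`` of ``alpha*s = beta**(-s)`` on ``s > 0``:
    the left side rises strictly from 0 while the right side is
    non-increasing from 1, so a single crossing exists in
    ``(0, max(1, 1/alpha)]``.  Solved by bisection to 1e-10.  A cell is
    screened in exactly when ``|u1| + |u2| > lambda_I``.
    """
    if not (np.isfinite(alpha) and alpha > 0):
        raise ValueError(f"alpha must be > 0, got {alpha!r}")
    if not (np.isfinite(beta) and beta >= 1):
        raise ValueError(f"beta must be >= 1, got {beta!r}")
    f = lambda s: alpha * s - beta ** (-s)
    hi = max(1.0, 1.0 / alpha)
    # at beta = 1 the root sits exactly at 1/alpha, i.e. on the bracket end
    if f(hi) == 0.0:
        return float(hi)
    while f(hi) < 0:  # floating-point graze at the bracket end
        hi *= 2.0
    return float(bisect(f, 0.0, hi, xtol=1e-10))


def solve_lambda_u(eta: float, lambda_R: float) -> float:
    """Time-2 magnitude ``lambda_U = (lambda_R/eta)**(1/3)``.

    This is the ``|U_t2|`` value at which the eta-only term of the relevance
    index reaches the visual-emphasis level ``lambda_R``.
    """
    if not (np.isfinite(eta) and eta > 0):
        raise ValueError(f"eta must be > 0, got {eta!r}")
    if not (np.isfinite(lambda_R) and lambda_R > 0):
        raise ValueError(f"lambda_R must be > 0, got {lambda_R!r}")
    return float((lambda_R / eta) ** (1.0 / 3.0))


def solve_eta(lambda_U: float, lambda_R: float) -> float:
    """Inverse of :func:`solve_lambda_u`: ``eta = lambda_R / lambda_U**3``."""
    if not (np.isfinite(lambda_U) and lambda_U > 0):
        raise ValueError(f"lambda_U must be > 0, got {lambda_U!r}")
    if not (np.isfinite(lambda_R) and lambda_R > 0):
        raise ValueError(f"lambda_R must be > 0, got {lambda_R!r}")
    return float(lambda_R / lambda_U**3)


def rho_emphasis_bound(u1: float, u2: float, kappa: float = 3) -> float:
    """Lower bound on ``rho`` for emphasising a joint-high edge case.

    Returns ``(1/|u1*u2|)**kappa``: choosing ``rho`` above this bound makes
    the rho-term dominate at the edge case ``(u1, u2)``.  The cubic
    convention (``kappa=3``) follows the relevance index's cubic term; the
    linear convention (``kappa=1``) expresses the bound directly on the
    product scale (at ``u1 = u2 = 0.5`` it gives the minimal ``rho = 4``).
    """
    prod = u1 * u2
    if prod == 0 or not np.isfinite(prod):
        raise ValueError(f"u1*u2 must be non-zero and finite, got {prod!r}")
    return float((1.0 / abs(prod)) ** kappa)


def classify_relevance(r_value: float, u2_value: float, tol: float) -> RelevanceCategory:
    """Classify a relevance value against the near-zero tolerance.

    ``|R| <= tol`` is near-zero (significant at t1 only); otherwise the sign
    of ``R`` — which must agree with the sign of the time-2 measure —
    decides between the positive and negative relevant categories.
    """
    if tol < 0:
        raise ValueError(f"tol must be >= 0, got {tol}")
    if abs(r_value) <= tol:
        return RelevanceCategory.NEAR_ZERO
    cat = (
        RelevanceCategory.RELEVANT_NEGATIVE
        if r_value < 0
        else RelevanceCategory.RELEVANT_POSITIVE
    )
    if u2_value != 0 and np.sign(r_value) != np.sign(u2_value):
        raise ValueError(
            f"relevance sign {np.sign(r_value)} contradicts time-2 measure sign "
            f"{np.sign(u2_value)}; R must inherit the sign of U_t2"
        )
    return cat


def propagation_maps(
    field_t1: UncertaintyField,
    field_t2: UncertaintyField,
    factors: IndexFactors,
    near_zero_tol: float = 0.05,
) -> PropagationMaps:
    """Full screening + classification between two uncertainty snapshots.

    Per occupied cell: compute ``I``; cells with ``I <= 0`` are excluded
    (the boundary is excluded), the rest receive ``R`` and one of the three
    relevant categories.  Unoccupied cells carry the missing sentinel in
    both grids and the excluded category.
    """
    if field_t1.values.shape != field_t2.values.shape:
        raise ValueError(
            f"field shapes differ: {field_t1.values.shape} vs {field_t2.values.shape}"
        )
    if not np.array_equal(field_t1.occupied, field_t2.occupied):
        raise ValueError("fields must share the same occupancy mask")

    occ = field_t1.occupied
    u1 = np.where(occ, field_t1.values, 0.0)
    u2 = np.where(occ, field_t2.values, 0.0)

    irr = np.asarray(irrelevance_index(u1, u2, factors))
    rel = np.asarray(relevance_index(u1, u2, factors))

    included = occ & (irr > 0)
    category = np.full(occ.shape, int(RelevanceCategory.EXCLUDED), dtype=np.int8)
    category[included & (rel < -near_zero_tol)] = int(RelevanceCategory.RELEVANT_NEGATIVE)
    category[included & (rel > near_zero_tol)] = int(RelevanceCategory.RELEVANT_POSITIVE)
    category[included & (np.abs(rel) <= near_zero_tol)] = int(RelevanceCategory.NEAR_ZERO)

    irr = np.where(occ, irr, MISSING)
    rel = np.where(included, rel, MISSING)

    return PropagationMaps(
        irrelevance=irr,
        relevance=rel,
        category=category,
        lambda_I_used=solve_irrelevance_threshold(factors.alpha, factors.beta),
        factors=factors,
        near_zero_tol=near_zero_tol,
    )
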