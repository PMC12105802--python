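"""Per-spatial-unit variance maps and total-effects sensitivity fields.

The estimator follows the paired-matrix Monte Carlo construction: a base
input matrix ``A`` (one row per run, one named column block per input
variable) and a companion ``A*_j`` identical to ``A`` except that the focus
column ``j`` is independently redrawn from the same distribution.  Running
the model over both sets with common random numbers gives two output
ensembles ``B`` and ``B*_j``; per spatial unit,

* ``V``  = population variance of the ``B`` outputs (all inputs varied),
* ``VC`` = population variance of the ``B*_j`` outputs, and
* ``S``  = ``(V - VC) / V`` is the total-effects sensitivity field:
  positive where the output is more sensitive to ``j`` than to the
  remaining inputs, negative in the opposite case, and exactly zero when
  the model ignores ``j`` (common random numbers make ``B*_j`` equal ``B``
  bitwise in that case).

Because the redraw leaves the marginal of ``j`` unchanged, ``E[V] = E[VC]``
and ``S`` scatters around zero with a spread that grows with the true
sensitivity to ``j``.  The classical Jansen total-order estimator over the
same paired ensembles is provided as an independent cross-check
(:func:`jansen_total_effects`).

Sampling is column-wise quasi-random: a scrambled Sobol' sequence mapped
through each column's inverse CDF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import norm, qmc

from .indices import MISSING

__all__ = [
    "ColumnSpec",
    "InputMatrix",
    "ResultEnsemble",
    "SensitivityField",
    "build_sample_matrices",
    "run_ensemble",
    "variance_map",
    "complement_variance_map",
    "total_effects_field",
    "jansen_total_effects",
]


@dataclass(frozen=True)
class ColumnSpec:
    """Distribution of one named input column (a block of ``width`` values).

    ``mean`` / ``sd`` are scalars or length-``width`` arrays, supporting
    spatially stratified inputs (e.g. a different SD per agent region).
    Only the normal family is needed here; draws are produced by pushing
    quasi-random uniforms through the inverse CDF.
    """

    name: str
    mean: float | np.ndarray
    sd: float | np.ndarray
    width: int = 1
    dist: str = "normal"

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.dist != "normal":
            raise ValueError(f"unsupported distribution {self.dist!r}")
        mean = np.broadcast_to(np.asarray(self.mean, dtype=float), (self.width,))
        sd = np.broadcast_to(np.asarray(self.sd, dtype=float), (self.width,))
        if np.any(sd < 0):
            raise ValueError("sd must be >= 0")
        return mean + sd * norm.ppf(u)


@dataclass
class InputMatrix:
    """Monte Carlo sample rows, stored as named (m, width) column blocks."""

    columns: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ms = {name: arr.shape[0] for name, arr in self.columns.items()}
        if len(set(ms.values())) > 1:
            raise ValueError(f"inconsistent row counts across columns: {ms}")
        if self.m < 2:
            raise ValueError(f"need m >= 2 sample rows, got {self.m}")

    @property
    def m(self) -> int:
        return next(iter(self.columns.values())).shape[0]

    def row(self, k: int) -> dict[str, np.ndarray]:
        return {name: arr[k] for name, arr in self.columns.items()}


@dataclass
class ResultEnsemble:
    """Per-run output grids at each recorded time step.

    ``outputs`` has shape (m, n_times, H, W); ``time_labels`` names the
    second axis.  Cells outside ``occupied`` carry the missing sentinel.
    """

    outputs: np.ndarray
    time_labels: list
    occupied: np.ndarray

    def __post_init__(self) -> None:
        self.outputs = np.asarray(self.outputs, dtype=float)
        if self.outputs.ndim != 4:
            raise ValueError("outputs must have shape (m, n_times, H, W)")
        if self.outputs.shape[1] != len(self.time_labels):
            raise ValueError("time_labels length must match outputs axis 1")
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if self.occupied.shape != self.outputs.shape[2:]:
            raise ValueError("occupancy grid shape mismatch")

    @property
    def m(self) -> int:
        return self.outputs.shape[0]

    def at_time(self, time_label) -> np.ndarray:
        try:
            idx = self.time_labels.index(time_label)
        except ValueError:
            raise ValueError(
                f"time {time_label!r} not recorded; have {self.time_labels}"
            ) from None
        return self.outputs[:, idx]


@dataclass
class SensitivityField:
    """V, VC and S grids for one focus input at one time step.

    ``S = (V - VC)/V`` exactly where ``V > 0``; the missing sentinel where
    ``V = 0`` (no output variation: unoccupied or purchase-free cells).
    """

    V: np.ndarray
    VC: np.ndarray
    S: np.ndarray
    input_name: str = ""
    time_label: str = ""


def build_sample_matrices(
    dist_spec: Sequence[ColumnSpec],
    m: int,
    focus_column: str,
    seed: int,
) -> tuple[InputMatrix, InputMatrix]:
    """Build the paired matrices A and A*_focus.

    Every column of ``A`` is drawn from a scrambled Sobol' stream pushed
    through the column's inverse CDF.  ``A*_focus`` shares every column of
    ``A`` (the same arrays) except the focus column, which is an
    independent redraw from the same distribution.  Deterministic under a
    fixed seed.
    """
    if m < 2:
        raise ValueError(f"need m >= 2, got {m}")
    names = [c.name for c in dist_spec]
    if focus_column not in names:
        raise ValueError(f"unknown focus column {focus_column!r}; have {names}")
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate column names in spec: {names}")

    widths = [c.width for c in dist_spec]
    focus = next(c for c in dist_spec if c.name == focus_column)

    # One joint quasi-random stream: the base matrix uses the first
    # sum(widths) dimensions and the focus redraw the extra focus.width
    # dimensions (the radial construction).  Drawing the redraw from a
    # separately scrambled stream would leave it point-wise correlated
    # with the base column.
    qmc_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    with warnings.catch_warnings():
        # Sobol' balance warning for m not a power of two is expected here.
        warnings.simplefilter("ignore", UserWarning)
        u = qmc.Sobol(d=sum(widths) + focus.width, scramble=True, seed=qmc_seed).random(m)
    u_a, u_star = u[:, : sum(widths)], u[:, sum(widths) :]

    cols_a: dict[str, np.ndarray] = {}
    offset = 0
    for c in dist_spec:
        cols_a[c.name] = c.ppf(u_a[:, offset : offset + c.width])
        offset += c.width

    cols_star = dict(cols_a)
    cols_star[focus_column] = focus.ppf(u_star)

    prov = {"seed": seed, "m": m, "focus_column": focus_column}
    A = InputMatrix(cols_a, provenance={**prov, "set": "V"})
    A_star = InputMatrix(cols_star, provenance={**prov, "set": "VC"})
    return A, A_star


def run_seeds_for(master_seed: int, m: int) -> np.ndarray:
    """Per-run seeds derived reproducibly from a master seed.

    Paired ensembles must be run with the same array so that all
    non-focus stochasticity is common across the pair.
    """
    return np.array(
        [int(np.random.SeedSequence([master_seed, k]).generate_state(1)[0] % (2**31))
         for k in range(m)],
        dtype=np.int64,
    )


def run_ensemble(
    model_runner: Callable[[Mapping[str, np.ndarray], int], np.ndarray],
    A: InputMatrix,
    record_times: Sequence,
    master_seed: int = 0,
    occupied: np.ndarray | None = None,
) -> ResultEnsemble:
    """Run a model over every sample row of ``A``.

    ``model_runner(row, run_seed)`` must return an array of shape
    (n_times, H, W) with one output grid per entry of ``record_times`` and
    be deterministic given its arguments.  Run seeds are derived from
    ``master_seed`` and the row index, so a paired ensemble evaluated with
    the same ``master_seed`` sees identical non-focus randomness.
    """
    seeds = run_seeds_for(master_seed, A.m)
    grids = []
    for k in range(A.m):
        try:
            out = np.asarray(model_runner(A.row(k), int(seeds[k])), dtype=float)
        except Exception as exc:
            raise RuntimeError(f"model runner failed on sample row {k}: {exc}") from exc
        if out.ndim == 2:
            out = out[None, ...]
        if out.shape[0] != len(record_times):
            raise ValueError(
                f"runner returned {out.shape[0]} grids for row {k}, "
                f"expected {len(record_times)}"
            )
        grids.append(out)
    outputs = np.stack(grids, axis=0)
    if occupied is None:
        occupied = np.all(np.isfinite(outputs), axis=(0, 1))
    return ResultEnsemble(outputs=outputs, time_labels=list(record_times), occupied=occupied)


def _population_variance(stack: np.ndarray) -> np.ndarray:
    # divide-by-m variance across the run axis, two-pass for stability
    mean = np.nanmean(stack, axis=0)
    return np.nanmean((stack - mean) ** 2, axis=0)


def variance_map(ensemble: ResultEnsemble, time_label) -> np.ndarray:
    """Per-cell population variance of the ensemble outputs at one time.

    Unoccupied cells carry the missing sentinel.  Population (divide-by-m)
    variance is used; adding a constant to every run leaves it unchanged.
    """
    if ensemble.m < 2:
        raise ValueError("need at least two runs to form a variance map")
    stack = ensemble.at_time(time_label)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        v = _population_variance(stack)
    return np.where(ensemble.occupied, v, MISSING)


def complement_variance_map(ensemble_star: ResultEnsemble, time_label) -> np.ndarray:
    """VC: the variance map of the focus-redrawn ensemble ``B*_j``."""
    return variance_map(ensemble_star, time_label)


def total_effects_field(
    V: np.ndarray,
    VC: np.ndarray,
    input_name: str = "",
    time_label: str = "",
) -> SensitivityField:
    """Total-effects sensitivity field ``S = (V - VC)/V``.

    A positive value marks cells where the output is more sensitive to the
    focus input than to the remaining inputs; a negative value the
    opposite.  Cells with ``V = 0`` (or missing V) are undefined.
    """
    V = np.asarray(V, dtype=float)
    VC = np.asarray(VC, dtype=float)
    if V.shape != VC.shape:
        raise ValueError(f"V shape {V.shape} != VC shape {VC.shape}")
    defined = np.isfinite(V) & np.isfinite(VC) & (V > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(defined, (V - VC) / np.where(defined, V, 1.0), MISSING)
    return SensitivityField(V=V, VC=VC, S=S, input_name=input_name, time_label=time_label)


def jansen_total_effects(
    B_A: ResultEnsemble,
    B_Aj: ResultEnsemble,
    time_label,
    clip: bool = True,
) -> np.ndarray:
    """Jansen total-order estimate ``sum((f_A - f_A*)^2) / (2 m V)`` per cell.

    Standard paired cross-check estimator; in [0, 1] up to Monte Carlo
    noise for additive models (values are clipped to [0, 1 + 1e-6] unless
    ``clip=False``).  Cells with ``V = 0`` are undefined.
    """
    if B_A.m != B_Aj.m:
        raise ValueError(f"unpaired ensembles: m={B_A.m} vs m={B_Aj.m}")
    fa = B_A.at_time(time_label)
    fb = B_Aj.at_time(time_label)
    V = _population_variance(fa)
    defined = np.isfinite(V) & (V > 0) & B_A.occupied
    with np.errstate(divide="ignore", invalid="ignore"):
        est = np.mean((fa - fb) ** 2, axis=0) / (2.0 * np.where(defined, V, 1.0))
    est = np.where(defined, est, MISSING)
    if clip:
        est = np.where(defined, np.clip(est, 0.0, 1.0 + 1e-6), est)
    return est
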