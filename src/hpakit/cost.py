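"""Spline-interpolated, mean-normalised cost functions.

An adaptive integrator does not place mesh points at the data sampling times,
so simulated hormone curves are first interpolated with a cubic spline over
the solver mesh and then evaluated exactly at the data time points.  Both the
evaluated spline values and the data are normalised to a mean concentration
before residuals are formed, which makes cost values dimensionless and
comparable across models that operate on different concentration scales.

Three costs are provided:

* :func:`sse_cost` — the primary cost: mean of squared normalised residuals
  over time points and hormones;
* :func:`max_max_cost` — worst absolute normalised residual over both
  hormones;
* :func:`mean_max_cost` — per-hormone worst residual, averaged over hormones.

Two conventions are switchable and recorded on every result:

* ``normalize``: ``"data"`` divides both simulation and data by the *data*
  mean (the default); ``"shape"`` divides the simulation by its own sampled
  mean instead, comparing pure shapes independently of simulated scale.
* ``average``: ``"mean"`` divides the summed squared residuals by
  N_points x N_hormones (the default); ``"sum_half"`` divides the per-point
  hormone sums by the number of hormones only, leaving the sum over time
  points unreduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .datasets import SubjectRecord
from .desolver import Solution
from .models import ModelSpec

__all__ = [
    "Interpolant",
    "CostConvention",
    "CostBreakdown",
    "CostError",
    "fit_spline",
    "sse_cost",
    "max_max_cost",
    "mean_max_cost",
]


class CostError(ValueError):
    """Cost undefined for these inputs (e.g. non-positive normalisation mean)."""


@dataclass(frozen=True)
class Interpolant:
    """Cubic interpolating spline with not-a-knot end conditions.

    Exact at its knots; defined on [first knot, last knot] only.
    """

    knot_times: np.ndarray
    knot_values: np.ndarray
    _spline: CubicSpline = field(repr=False, compare=False, default=None)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        lo, hi = self.knot_times[0], self.knot_times[-1]
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError(
                f"evaluation outside spline domain [{lo:g}, {hi:g}]"
            )
        out = self._spline(t)
        # exactness at knots is part of the contract; the polynomial
        # evaluation can be a few ulp off, so snap exact time matches
        idx = np.searchsorted(self.knot_times, t)
        idx = np.clip(idx, 0, self.knot_times.size - 1)
        hit = self.knot_times[idx] == t
        if out.ndim == 0:
            return self.knot_values[idx] if hit else out
        out[hit] = self.knot_values[idx[hit]]
        return out


def fit_spline(times: Sequence[float], values: Sequence[float]) -> Interpolant:
    """Fit a not-a-knot cubic spline through ``(times, values)``.

    Requires at least 2 strictly increasing knots.  (With 2 or 3 knots the
    interpolant degenerates to the unique line/parabola.)
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least 2 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knot times must be strictly increasing")
    spline = CubicSpline(t, v, bc_type="not-a-knot")
    return Interpolant(knot_times=t, knot_values=v, _spline=spline)


@dataclass(frozen=True)
class CostConvention:
    normalize: str = "data"  # "data" | "shape"
    average: str = "mean"    # "mean" | "sum_half"

    def __post_init__(self):
        if self.normalize not in ("data", "shape"):
            raise ValueError(f"unknown normalize convention {self.normalize!r}")
        if self.average not in ("mean", "sum_half"):
            raise ValueError(f"unknown average convention {self.average!r}")

    @property
    def label(self) -> str:
        return f"normalize={self.normalize},average={self.average}"


DEFAULT_CONVENTION = CostConvention()


@dataclass(frozen=True)
class CostBreakdown:
    """Full decomposition of one cost evaluation.

    ``per_hormone`` maps hormone label to ``(normalisation mean, vector of
    normalised residuals d_i/mu - s_i/nu)``; ``total`` is recomputable from
    the stored residuals under the stated convention.
    """

    per_hormone: dict[str, tuple[float, np.ndarray]]
    n_points: int
    total: float
    convention: str

    def recompute_total(self) -> float:
        return _reduce(
            {h: r for h, (_, r) in self.per_hormone.items()},
            self.n_points,
            self.convention,
        )


def _reduce(residuals: dict[str, np.ndarray], n_points: int, label: str) -> float:
    n_h = len(residuals)
    if n_h == 0 or n_points == 0:  # failed evaluation placeholder
        return float("inf")
    ss = sum(float(np.sum(r**2)) for r in residuals.values())
    if "average=mean" in label:
        return ss / (n_points * n_h)
    return ss / n_h  # sum over points, divided by hormone count


def _normalized_residuals(
    solution: Solution,
    model: ModelSpec,
    subject: SubjectRecord,
    convention: CostConvention,
) -> tuple[dict[str, tuple[float, np.ndarray]], int]:
    residuals: dict[str, tuple[float, np.ndarray]] = {}
    n_points = None
    for label, series in subject.hormones().items():
        if label not in model.output_map:
            raise CostError(
                f"model {model.name!r} output_map lacks hormone {label!r}"
            )
        idx, scale = model.output_map[label]
        sim_mesh = solution.states[:, idx] * scale
        spline = fit_spline(solution.mesh_times, sim_mesh)
        s = spline(series.times)
        d = series.values
        d_mean = float(np.mean(d))
        if d_mean <= 0:
            raise CostError(
                f"data mean for {label!r} is {d_mean:g}; normalisation undefined"
            )
        if convention.normalize == "data":
            norm_mean = d_mean
            r = d / d_mean - s / d_mean
        else:  # shape: simulation normalised to its own sampled mean
            s_mean = float(np.mean(s))
            if s_mean <= 0:
                raise CostError(
                    f"simulated mean for {label!r} is {s_mean:g}; shape "
                    "normalisation undefined"
                )
            norm_mean = s_mean
            r = d / d_mean - s / s_mean
        residuals[label] = (norm_mean, r)
        n_points = len(d)
    if not residuals:
        raise CostError("subject carries no hormone series")
    return residuals, n_points


def sse_cost(
    solution: Solution,
    model: ModelSpec,
    subject: SubjectRecord,
    convention: CostConvention = DEFAULT_CONVENTION,
) -> CostBreakdown:
    """Mean-normalised sum-of-squared-errors cost.

    For each hormone the simulated state is splined over the solver mesh,
    evaluated at the subject's sampling times, normalised per ``convention``,
    and squared residuals are accumulated.  Zero iff the sampled simulation
    matches the data exactly.
    """
    residuals, n_points = _normalized_residuals(solution, model, subject, convention)
    total = _reduce(
        {h: r for h, (_, r) in residuals.items()}, n_points, convention.label
    )
    return CostBreakdown(
        per_hormone=residuals,
        n_points=n_points,
        total=total,
        convention=convention.label,
    )


def max_max_cost(
    solution: Solution,
    model: ModelSpec,
    subject: SubjectRecord,
    convention: CostConvention = DEFAULT_CONVENTION,
) -> float:
    """Maximum over hormones of the maximum absolute normalised residual."""
    residuals, _ = _normalized_residuals(solution, model, subject, convention)
    return max(float(np.max(np.abs(r))) for _, r in residuals.values())


def mean_max_cost(
    solution: Solution,
    model: ModelSpec,
    subject: SubjectRecord,
    convention: CostConvention = DEFAULT_CONVENTION,
) -> float:
    """Mean over hormones of the per-hormone maximum absolute residual."""
    residuals, _ = _normalized_residuals(solution, model, subject, convention)
    return float(
        np.mean([np.max(np.abs(r)) for _, r in residuals.values()])
    )
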