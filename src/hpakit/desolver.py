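"""Adaptive ODE/DDE integration with continuous dense output.

A single explicit embedded Runge-Kutta pair — Dormand-Prince 5(4), the same
pair behind most general-purpose non-stiff solvers — drives both ordinary and
delay differential equations here:

* **ODE**: standard adaptive stepping with the mixed error test
  ``atol + rtol * |y|`` and a quartic dense-output interpolant per accepted
  step, so the solution can be evaluated at arbitrary times (the downstream
  cost function samples it exactly at the data time points).
* **DDE (method of steps)**: delayed states are read from the user-supplied
  history function for lookup times at or before the start of integration and
  from the continuously extended dense output afterwards.  The step size is
  capped at the smallest positive lag, which guarantees that every delayed
  lookup lands in already-accepted history (a lookup during a trial step at
  stage time ``t + c*h`` with lag ``tau >= h`` reaches back to at most ``t``).

Forced mesh points (e.g. the on/off switching times of a stress episode) are
honoured exactly by integrating between consecutive breakpoints and
re-evaluating the right-hand side at each, so driver discontinuities never
sit inside a step.

Integration is fully deterministic: identical inputs give bitwise-identical
results.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .models import Drivers, ModelSpec

__all__ = [
    "Solution",
    "History",
    "Diagnostics",
    "IntegrationError",
    "StepSizeUnderflow",
    "DelayLookupError",
    "integrate",
    "integrate_rhs",
    "dense_eval",
    "sample",
]

# Dormand-Prince 5(4) tableau (FSAL: the 7th stage is the first stage of the
# next step).  B gives the 5th-order solution, E the embedded error weights,
# P the dense-output polynomial coefficients (order-4 interpolant).
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = [
    np.array([]),
    np.array([1 / 5]),
    np.array([3 / 40, 9 / 40]),
    np.array([44 / 45, -56 / 15, 32 / 9]),
    np.array([19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729]),
    np.array([9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656]),
]
_B = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84])
_E = np.array(
    [71 / 57600, 0.0, -71 / 16695, 71 / 1920, -17253 / 339200, 22 / 525, -1 / 40]
)
_P = np.array(
    [
        [1, -8048581381 / 2820520608, 8663915743 / 2820520608, -12715105075 / 11282082432],
        [0, 0, 0, 0],
        [0, 131558114200 / 32700410799, -68118460800 / 10900136933, 87487479700 / 32700410799],
        [0, -1754552775 / 470086768, 14199869525 / 1410260304, -10690763975 / 1880347072],
        [0, 127303824393 / 49829197408, -318862633887 / 49829197408, 701980252875 / 199316789632],
        [0, -282668133 / 205662961, 2019193451 / 616988883, -1453857185 / 822651844],
        [0, 40617522 / 29380423, -110615467 / 29380423, 69997945 / 29380423],
    ]
)

_SAFETY = 0.9
_MIN_FACTOR = 0.2
_MAX_FACTOR = 10.0
_ORDER_EXP = -1.0 / 5.0


class IntegrationError(RuntimeError):
    pass


class StepSizeUnderflow(IntegrationError):
    """Step size collapsed below machine resolution (stiffness or blow-up)."""

    def __init__(self, t: float):
        self.t = t
        super().__init__(
            f"step size underflow at t = {t:.6g}; the problem may be stiff "
            "or the solution diverging"
        )


class DelayLookupError(IntegrationError):
    pass


@dataclass(frozen=True)
class Diagnostics:
    n_accepted: int
    n_rejected: int
    n_rhs: int


@dataclass(frozen=True)
class _Segment:
    """Dense output for one accepted step on [t_old, t_new]."""

    t_old: float
    t_new: float
    y_old: np.ndarray
    Q: np.ndarray  # (n_states, 4)

    def __call__(self, t: float) -> np.ndarray:
        h = self.t_new - self.t_old
        x = (t - self.t_old) / h
        powers = np.array([x, x**2, x**3, x**4])
        return self.y_old + h * (self.Q @ powers)


class History:
    """Pre-integration state history for DDE problems.

    Wraps a callable ``t -> state vector`` defined for ``t <= t0``.  The
    default (and the common physiological choice when starting from
    equilibrium) is a constant history equal to the initial state.
    """

    def __init__(self, fn: Callable[[float], np.ndarray]):
        self._fn = fn

    def __call__(self, t: float) -> np.ndarray:
        return np.asarray(self._fn(t), dtype=float)

    @classmethod
    def constant(cls, y0: np.ndarray) -> "History":
        y0 = np.asarray(y0, dtype=float).copy()
        return cls(lambda t: y0)


@dataclass
class Solution:
    """Integrator output: accepted mesh, states, and a dense evaluator."""

    mesh_times: np.ndarray
    states: np.ndarray
    t0: float
    t1: float
    diagnostics: Diagnostics
    segments: list[_Segment] = field(repr=False, default_factory=list)
    # starts[i] == segments[i].t_old, for binary search
    _starts: list[float] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        self._starts = [s.t_old for s in self.segments]

    def __call__(self, t: float) -> np.ndarray:
        return dense_eval(self, t)


def dense_eval(solution: Solution, t: float) -> np.ndarray:
    """Evaluate the continuous interpolant at ``t`` within the span.

    Exact (bitwise) at mesh nodes; raises outside the integrated span —
    extrapolation is never silently performed.
    """
    if t < solution.t0 or t > solution.t1:
        raise IntegrationError(
            f"t = {t:g} outside integrated span [{solution.t0:g}, {solution.t1:g}]"
        )
    # snap to stored mesh states for exactness at the nodes
    k = bisect.bisect_left(solution.mesh_times, t)
    if k < len(solution.mesh_times) and solution.mesh_times[k] == t:
        return solution.states[k].copy()
    i = bisect.bisect_right(solution._starts, t) - 1
    i = max(0, min(i, len(solution.segments) - 1))
    return solution.segments[i](t)


def sample(solution: Solution, times: Sequence[float]) -> np.ndarray:
    """Dense-evaluate the solution at each requested time (rows in order)."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.empty((0, solution.states.shape[1]))
    return np.array([dense_eval(solution, t) for t in times])


def _error_norm(err: np.ndarray, y0: np.ndarray, y1: np.ndarray,
                rtol: float, atol: float) -> float:
    scale = atol + rtol * np.maximum(np.abs(y0), np.abs(y1))
    return float(np.sqrt(np.mean((err / scale) ** 2)))


def integrate_rhs(
    f: Callable[[float, np.ndarray], np.ndarray],
    span: tuple[float, float],
    y0: Sequence[float],
    rtol: float = 1e-6,
    atol: float = 1e-9,
    forced_points: Sequence[float] = (),
    max_step: float = np.inf,
    first_step: float | None = None,
    on_accept: Callable[[_Segment], None] | None = None,
) -> Solution:
    """Integrate ``y' = f(t, y)`` over ``span`` with DP 5(4) adaptive steps.

    ``forced_points`` inside the span become exact mesh points and the RHS is
    re-evaluated there (no FSAL reuse across a breakpoint), so piecewise
    drivers switch cleanly.  ``on_accept`` is an internal hook used by the
    DDE driver to expose each accepted dense segment immediately.
    """
    t0, t1 = float(span[0]), float(span[1])
    if not t1 > t0:
        raise ValueError(f"require t1 > t0, got span ({t0}, {t1})")
    y = np.asarray(y0, dtype=float).copy()
    n = y.size

    inner = sorted({float(p) for p in forced_points if t0 < p < t1})
    breakpoints = [t0] + inner + [t1]

    mesh_t = [t0]
    mesh_y = [y.copy()]
    segments: list[_Segment] = []
    n_acc = n_rej = n_rhs = 0

    h_abs = first_step if first_step is not None else min(
        (t1 - t0) / 100.0, 1.0, max_step
    )
    h_abs = min(h_abs, max_step, t1 - t0)

    for left, right in zip(breakpoints, breakpoints[1:]):
        t = left
        fk = f(t, y)  # fresh evaluation at each breakpoint
        n_rhs += 1
        if np.asarray(fk).size != n:
            raise IntegrationError(
                f"rhs returned {np.asarray(fk).size} components for {n} states"
            )
        while t < right:
            h = min(h_abs, right - t, max_step)
            if h < 1e-12 * max(1.0, abs(t)):
                raise StepSizeUnderflow(t)
            K = np.empty((7, n))
            K[0] = fk
            for s in range(1, 6):
                ts = t + _C[s] * h
                ys = y + h * (_A[s] @ K[:s])
                K[s] = f(ts, ys)
            y_new = y + h * (_B @ K[:6])
            t_new = t + h
            K[6] = f(t_new, y_new)
            n_rhs += 6
            err = h * (_E @ K)

            bad = not (np.all(np.isfinite(y_new)) and np.all(np.isfinite(err)))
            if bad:
                norm = np.inf
            else:
                norm = _error_norm(err, y, y_new, rtol, atol)

            if norm <= 1.0:
                seg = _Segment(t, t_new, y.copy(), K.T @ _P)
                segments.append(seg)
                if on_accept is not None:
                    on_accept(seg)
                mesh_t.append(t_new)
                mesh_y.append(y_new.copy())
                fk = K[6]
                t, y = t_new, y_new
                n_acc += 1
                if norm == 0.0:
                    factor = _MAX_FACTOR
                else:
                    factor = min(_MAX_FACTOR, _SAFETY * norm**_ORDER_EXP)
                h_abs = min(h * factor, max_step)
            else:
                n_rej += 1
                if not np.isfinite(norm):
                    factor = _MIN_FACTOR
                else:
                    factor = max(_MIN_FACTOR, _SAFETY * norm**_ORDER_EXP)
                h_abs = h * factor

    return Solution(
        mesh_times=np.array(mesh_t),
        states=np.array(mesh_y),
        t0=t0,
        t1=t1,
        diagnostics=Diagnostics(n_acc, n_rej, n_rhs),
        segments=segments,
    )


def integrate(
    model: ModelSpec,
    params: Mapping[str, float] | None = None,
    span: tuple[float, float] = (0.0, 1440.0),
    initial: Sequence[float] | None = None,
    history: History | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    forced_points: Sequence[float] = (),
    drivers: Drivers | None = None,
) -> Solution:
    """Integrate a registered model over ``span`` (minutes).

    For DDE models (``model.delays`` non-empty with positive lags) the method
    of steps is used: ``history`` must be defined on ``[t0 - max lag, t0]``
    and defaults to a constant equal to the initial state.  Lookups for a lag
    name not declared in the model raise :class:`DelayLookupError`.
    """
    p = dict(model.params.defaults())
    if params is not None:
        p.update(params)
    drv = drivers or model.default_drivers
    if initial is None:
        if model.initial_state is None:
            raise ValueError("no initial state given and model declares none")
        initial = model.initial_state
    y_init = np.asarray(initial, dtype=float)
    if y_init.size != model.n_states:
        raise ValueError(
            f"initial state has {y_init.size} components, model has "
            f"{model.n_states} states"
        )
    t0 = float(span[0])
    forced = list(forced_points) + drv.stress.boundaries

    if not model.has_delays:
        return integrate_rhs(
            lambda t, y: model.rhs(t, y, p, drv),
            span, y_init, rtol=rtol, atol=atol, forced_points=forced,
        )

    lag_map = model.lag_map
    positive_lags = [v for v in lag_map.values() if v > 0]
    max_step = min(positive_lags) if positive_lags else np.inf
    hist = history or History.constant(y_init)
    h0 = hist(t0)
    if h0.size != y_init.size or not np.allclose(h0, y_init, rtol=0, atol=1e-12):
        raise ValueError("history(t0) must equal the initial state")

    # accepted dense segments, appended as integration proceeds
    live_segments: list[_Segment] = []
    seg_starts: list[float] = []

    def lookup_state(tq: float) -> np.ndarray:
        if tq <= t0:
            return hist(tq)
        if not live_segments or tq > live_segments[-1].t_new + 1e-12:
            raise DelayLookupError(
                f"delayed lookup at t = {tq:g} beyond accepted history"
            )
        i = bisect.bisect_right(seg_starts, tq) - 1
        i = max(0, min(i, len(live_segments) - 1))
        return live_segments[i](min(tq, live_segments[i].t_new))

    def f(t: float, y: np.ndarray) -> np.ndarray:
        def lagged(name: str) -> np.ndarray:
            try:
                lag = lag_map[name]
            except KeyError:
                raise DelayLookupError(
                    f"lookup for undeclared delay {name!r}; declared: "
                    f"{sorted(lag_map)}"
                ) from None
            if lag == 0.0:
                return y
            return lookup_state(t - lag)

        return model.rhs(t, y, lagged, p, drv)

    def on_accept(seg: _Segment) -> None:
        live_segments.append(seg)
        seg_starts.append(seg.t_old)

    return integrate_rhs(
        f, span, y_init, rtol=rtol, atol=atol, forced_points=forced,
        max_step=max_step, on_accept=on_accept,
    )
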