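"""Model plugin contract and demonstration HPA-axis models.

The hypothalamic-pituitary-adrenal (HPA) axis is the neuroendocrine cascade
CRH -> ACTH -> cortisol.  A stressor drives CRH release from the hypothalamus,
CRH drives pituitary ACTH secretion, ACTH drives adrenal cortisol production,
and cortisol (via glucocorticoid-receptor binding) represses CRH and ACTH
synthesis, closing a negative-feedback loop.  Superimposed on the feedback
dynamics are a circadian drive from the suprachiasmatic nucleus (peak ~8 AM)
and, in laboratory protocols, an acute stress episode (e.g. a 20-min Trier
Social Stress Test).

This module defines:

* the declarative :class:`ModelSpec` contract through which any ODE or DDE
  model of the axis can be registered (states, parameter table with bounds,
  delays, drivers, output mapping to measurable hormones);
* the driver primitives :class:`StressProtocol` (piecewise-constant acute
  stress input) and :class:`CircadianDrive` (cosinor SCN drive);
* three fully specified demonstration models that exercise the structural
  features found across the published model family: Hill-type cortisol
  feedback (:func:`minimal_model`), bound-receptor feedback with a positive
  receptor loop (:func:`receptor_model`), and distributed action delays
  (:func:`delayed_model`);
* :func:`steady_state`, the flat-driver equilibrium used to initialise
  simulations before a stress protocol.

All internal times are minutes.  Concentration scales are arbitrary: the
downstream cost function normalises every hormone series to its mean, so only
the *shape* of a simulated response matters when matching data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.optimize

__all__ = [
    "ParameterEntry",
    "ParameterTable",
    "StressProtocol",
    "CircadianDrive",
    "Drivers",
    "Delay",
    "ModelSpec",
    "SteadyStateError",
    "minimal_hpa_rhs",
    "receptor_hpa_rhs",
    "delayed_hpa_rhs",
    "minimal_model",
    "receptor_model",
    "delayed_model",
    "canonical_tsst_protocol",
    "steady_state",
    "MODEL_REGISTRY",
    "get_model",
]


# ---------------------------------------------------------------------------
# parameter table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterEntry:
    """One named parameter with its default value and optimisation bounds."""

    name: str
    default: float
    lower: float
    upper: float
    optimize: bool = True

    def __post_init__(self) -> None:
        if not (self.lower <= self.default <= self.upper):
            raise ValueError(
                f"parameter {self.name!r}: require lower <= default <= upper, "
                f"got {self.lower} <= {self.default} <= {self.upper}"
            )
        if self.optimize and not (
            np.isfinite(self.lower) and np.isfinite(self.upper)
        ):
            raise ValueError(
                f"parameter {self.name!r}: bounds must be finite when flagged "
                "for optimisation"
            )


@dataclass(frozen=True)
class ParameterTable:
    """Ordered collection of :class:`ParameterEntry` with unique names."""

    entries: tuple[ParameterEntry, ...]

    def __post_init__(self) -> None:
        entries = tuple(
            e if isinstance(e, ParameterEntry) else ParameterEntry(*e)
            for e in self.entries
        )
        object.__setattr__(self, "entries", entries)
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def defaults(self) -> dict[str, float]:
        return {e.name: e.default for e in self.entries}

    def optimizable(self) -> list[str]:
        return [e.name for e in self.entries if e.optimize]

    def bounds(self, names: Sequence[str] | None = None) -> list[tuple[float, float]]:
        by_name = {e.name: (e.lower, e.upper) for e in self.entries}
        if names is None:
            names = self.optimizable()
        return [by_name[n] for n in names]

    def __getitem__(self, name: str) -> ParameterEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StressProtocol:
    """Piecewise-constant acute-stress input.

    ``episodes`` is a sequence of ``(start, end, amplitude)`` in minutes with
    amplitude >= 0.  The drive evaluates to ``baseline`` outside all episodes
    and ``baseline + amplitude`` on the half-open interval ``[start, end)``.
    The half-open convention makes the on/off switching deterministic when an
    episode boundary coincides with a mesh point.
    """

    episodes: tuple[tuple[float, float, float], ...] = ()
    baseline: float = 1.0

    def __post_init__(self) -> None:
        eps = tuple(
            (float(s), float(e), float(a)) for (s, e, a) in self.episodes
        )
        eps = tuple(sorted(eps))
        for s, e, a in eps:
            if not s < e:
                raise ValueError(f"episode start {s} must precede end {e}")
            if a < 0:
                raise ValueError("episode amplitude must be >= 0")
        for (s0, e0, _), (s1, _, _) in zip(eps, eps[1:]):
            if s1 < e0:
                raise ValueError("stress episodes must not overlap")
        object.__setattr__(self, "episodes", eps)

    def __call__(self, t: float) -> float:
        for s, e, a in self.episodes:
            if s <= t < e:
                return self.baseline + a
        return self.baseline

    @property
    def boundaries(self) -> list[float]:
        """Every episode on/off time, for use as forced mesh points."""
        out: list[float] = []
        for s, e, _ in self.episodes:
            out.extend((s, e))
        return out


@dataclass(frozen=True)
class CircadianDrive:
    """Cosinor SCN drive ``mesor + amplitude * cos(2*pi*(t - peak_time)/period)``.

    ``peak_time`` is in the same time coordinate as the simulation clock; with
    ``mesor > amplitude >= 0`` the drive is strictly positive.
    """

    mesor: float = 1.0
    amplitude: float = 0.0
    peak_time: float = 0.0
    period: float = 1440.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.mesor <= self.amplitude:
            raise ValueError("require mesor > amplitude for a positive drive")

    def __call__(self, t: float) -> float:
        return self.mesor + self.amplitude * np.cos(
            2.0 * np.pi * (t - self.peak_time) / self.period
        )


def evaluate_stress(protocol: StressProtocol, t: float) -> float:
    """Evaluate a stress protocol at time ``t`` (minutes)."""
    return protocol(t)


def evaluate_circadian(drive: CircadianDrive, t: float) -> float:
    """Evaluate a circadian drive at time ``t`` (minutes)."""
    return drive(t)


@dataclass(frozen=True)
class Drivers:
    """The external inputs a model RHS may consult: circadian and stress."""

    circadian: CircadianDrive = field(default_factory=CircadianDrive)
    stress: StressProtocol = field(default_factory=StressProtocol)

    def circ(self, t: float) -> float:
        return self.circadian(t)

    def acute(self, t: float) -> float:
        return self.stress(t)

    def flattened(self) -> "Drivers":
        """Constant drivers: circadian frozen at its mesor, stress at baseline."""
        flat_circ = CircadianDrive(
            mesor=self.circadian.mesor,
            amplitude=0.0,
            peak_time=self.circadian.peak_time,
            period=self.circadian.period,
        )
        flat_stress = StressProtocol(episodes=(), baseline=self.stress.baseline)
        return Drivers(circadian=flat_circ, stress=flat_stress)


def canonical_tsst_protocol(amplitude: float = 2.0, baseline: float = 1.0) -> StressProtocol:
    """The canonical 20-min laboratory stress episode on ``[0, 20)`` minutes.

    Time zero is the start of the stress test; the default amplitude triples
    the hypothalamic drive during the test (baseline 1 -> 3).
    """
    return StressProtocol(episodes=((0.0, 20.0, amplitude),), baseline=baseline)


# ---------------------------------------------------------------------------
# model spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Delay:
    name: str
    lag: float

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError(f"delay {self.name!r}: lag must be >= 0")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one differential-equation model.

    ``rhs`` has signature ``rhs(t, y, params, drivers)`` for ODE models and
    ``rhs(t, y, lagged, params, drivers)`` for DDE models, where ``lagged``
    is a lookup ``lagged(name) -> state vector at t - lag[name]`` for each
    declared :class:`Delay`.  The derivative vector must have the same length
    as ``state_names``.

    ``output_map`` maps measurable hormone labels (at least ``"cortisol"``)
    to ``(state index, scale factor)`` pairs.

    Models declaring ``time_unit="hours"`` are converted to minutes at
    registration (derivatives scaled by 1/60, lags by 60) so that the whole
    framework runs on one clock.
    """

    name: str
    state_names: tuple[str, ...]
    params: ParameterTable
    rhs: Callable
    output_map: Mapping[str, tuple[int, float]]
    delays: tuple[Delay, ...] = ()
    initial_state: np.ndarray | None = None
    time_unit: str = "minutes"
    default_drivers: Drivers = field(default_factory=Drivers)

    def __post_init__(self) -> None:
        delays = tuple(
            d if isinstance(d, Delay) else Delay(*d) for d in self.delays
        )
        object.__setattr__(self, "delays", delays)
        object.__setattr__(self, "output_map", dict(self.output_map))
        if "cortisol" not in self.output_map:
            raise ValueError("output_map must cover at least cortisol")
        for label, (idx, scale) in self.output_map.items():
            if not 0 <= idx < len(self.state_names):
                raise ValueError(f"output_map[{label!r}]: bad state index {idx}")
        if self.time_unit not in ("minutes", "hours"):
            raise ValueError("time_unit must be 'minutes' or 'hours'")
        if self.time_unit == "hours":
            object.__setattr__(self, "rhs", _scale_rhs(self.rhs, 1.0 / 60.0))
            object.__setattr__(
                self, "delays", tuple(Delay(d.name, d.lag * 60.0) for d in delays)
            )
            object.__setattr__(self, "time_unit", "minutes")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def has_delays(self) -> bool:
        return len(self.delays) > 0

    @property
    def lag_map(self) -> dict[str, float]:
        return {d.name: d.lag for d in self.delays}

    def with_drivers(self, drivers: Drivers) -> "ModelSpec":
        return replace(self, default_drivers=drivers)


def _scale_rhs(rhs: Callable, factor: float) -> Callable:
    def scaled(*args):
        return factor * np.asarray(rhs(*args), dtype=float)

    return scaled


# ---------------------------------------------------------------------------
# demonstration right-hand sides
# ---------------------------------------------------------------------------

def _check_positive(p: Mapping[str, float], *names: str) -> None:
    for n in names:
        if p[n] <= 0:
            raise ValueError(f"parameter {n!r} must be positive, got {p[n]}")


def minimal_hpa_rhs(t, y, p, drivers):
    """Three-state cascade CRH (C) -> ACTH (A) -> cortisol (F).

    Hill-repression feedback of cortisol on both CRH and ACTH production::

        dC/dt = k_c * circ(t) * stress(t) / (1 + (F/K_i)^n)  - w_c * C
        dA/dt = k_a * C       / (1 + (F/K_i2)^m)             - w_a * A
        dF/dt = k_f * A - w_f * F

    All production terms are positive at y = 0, so the nonnegative orthant is
    forward-invariant.
    """
    _check_positive(p, "K_i", "K_i2")
    C, A, F = y
    feedback_c = 1.0 + (F / p["K_i"]) ** p["n"] if F > 0 else 1.0
    feedback_a = 1.0 + (F / p["K_i2"]) ** p["m"] if F > 0 else 1.0
    dC = p["k_c"] * drivers.circ(t) * drivers.acute(t) / feedback_c - p["w_c"] * C
    dA = p["k_a"] * C / feedback_a - p["w_a"] * A
    dF = p["k_f"] * A - p["w_f"] * F
    return np.array([dC, dA, dF])


def receptor_hpa_rhs(t, y, p, drivers):
    """Four-state model with glucocorticoid-receptor (R) dynamics.

    Negative feedback acts through the bound-receptor proxy F*R rather than
    cortisol alone, and receptor production carries a positive-feedback Hill
    term in (F*R)^2 — the structural motif that lets receptor models produce
    ultradian oscillations without an external pulse generator::

        dC/dt = k_c * circ(t)*stress(t) / (1 + F*R/K_i) - w_c * C
        dA/dt = k_a * C / (1 + F*R/K_i)                 - w_a * A
        dF/dt = k_f * A - w_f * F
        dR/dt = k_r * (F*R)^2 / (K + (F*R)^2) + k_b - w_r * R
    """
    _check_positive(p, "K_i", "K")
    C, A, F, R = y
    bound = F * R
    feedback = 1.0 + bound / p["K_i"]
    dC = p["k_c"] * drivers.circ(t) * drivers.acute(t) / feedback - p["w_c"] * C
    dA = p["k_a"] * C / feedback - p["w_a"] * A
    dF = p["k_f"] * A - p["w_f"] * F
    dR = p["k_r"] * bound**2 / (p["K"] + bound**2) + p["k_b"] - p["w_r"] * R
    return np.array([dC, dA, dF, dR])


def delayed_hpa_rhs(t, y, lagged, p, drivers):
    """Delayed variant of the minimal cascade.

    Delays separate hormone production from action: CRH acts on the pituitary
    after ``tau_c``, ACTH on the adrenal after ``tau_a``, and cortisol
    feedback reaches the hypothalamus/pituitary after ``tau_f``::

        dC/dt = k_c*circ(t)*stress(t)/(1 + (F(t-tau_f)/K_i)^n)  - w_c*C
        dA/dt = k_a*C(t-tau_c)/(1 + (F(t-tau_f)/K_i2)^m)        - w_a*A
        dF/dt = k_f*A(t-tau_a) - w_f*F

    With all lags zero this reduces exactly to :func:`minimal_hpa_rhs`.
    """
    _check_positive(p, "K_i", "K_i2")
    C, A, F = y
    F_lag = lagged("tau_f")[2]
    C_lag = lagged("tau_c")[0]
    A_lag = lagged("tau_a")[1]
    feedback_c = 1.0 + (F_lag / p["K_i"]) ** p["n"] if F_lag > 0 else 1.0
    feedback_a = 1.0 + (F_lag / p["K_i2"]) ** p["m"] if F_lag > 0 else 1.0
    dC = p["k_c"] * drivers.circ(t) * drivers.acute(t) / feedback_c - p["w_c"] * C
    dA = p["k_a"] * C_lag / feedback_a - p["w_a"] * A
    dF = p["k_f"] * A_lag - p["w_f"] * F
    return np.array([dC, dA, dF])


# ---------------------------------------------------------------------------
# demonstration model constructors
# ---------------------------------------------------------------------------

# Default rate constants (per minute) are implementation constants chosen so
# that (a) the flat-driver steady state is strictly positive, (b) cortisol
# feedback is half-maximal at rest (F* ~ K_i), and (c) the canonical 20-min
# stress episode produces a peak-and-return cortisol response that is back
# within a few percent of baseline by four hours.  Decay rates bracket the
# physiological ordering: CRH clears fastest, cortisol slowest.
_MINIMAL_PARAMS = (
    ("k_c", 0.24, 0.024, 2.4, True),     # CRH production drive
    ("w_c", 0.12, 0.012, 1.2, False),    # CRH clearance, tau ~ 8 min
    ("k_a", 3.6, 0.36, 36.0, True),      # ACTH production per unit CRH
    ("w_a", 0.06, 0.006, 0.6, False),    # ACTH clearance, tau ~ 17 min
    ("k_f", 1.0 / 120.0, 1.0 / 1200.0, 1.0 / 12.0, True),  # cortisol production
    ("w_f", 0.025, 0.0025, 0.25, True),  # cortisol clearance, tau ~ 40 min
    ("K_i", 10.0, 1.0, 100.0, True),     # feedback half-repression (on CRH)
    ("K_i2", 10.0, 1.0, 100.0, True),    # feedback half-repression (on ACTH)
    ("n", 2.0, 1.0, 10.0, False),        # Hill exponent, CRH feedback
    ("m", 2.0, 1.0, 10.0, False),        # Hill exponent, ACTH feedback
)

_RECEPTOR_PARAMS = (
    ("k_c", 0.24, 0.024, 2.4, True),
    ("w_c", 0.12, 0.012, 1.2, False),
    ("k_a", 3.6, 0.36, 36.0, True),
    ("w_a", 0.06, 0.006, 0.6, False),
    ("k_f", 1.0 / 120.0, 1.0 / 1200.0, 1.0 / 12.0, True),
    ("w_f", 0.025, 0.0025, 0.25, True),
    ("K_i", 10.0, 1.0, 100.0, True),     # half-repression in bound-GR units
    ("k_r", 0.01, 0.001, 0.1, True),     # receptor positive-feedback gain
    ("K", 100.0, 1.0, 1e4, False),       # Hill constant for (F*R)^2
    ("k_b", 0.005, 5e-4, 0.05, False),   # basal receptor synthesis
    ("w_r", 0.01, 0.001, 0.1, False),    # receptor turnover
)

#: Default circadian drive for the demonstration models.  The simulation clock
#: is minutes relative to the 17:00 stress-test start, so the 8 AM cortisol
#: peak sits at -540 min; amplitude 0.25 on a mesor of 1 keeps the drive
#: positive while producing the familiar morning peak / evening trough.
DEFAULT_CIRCADIAN = CircadianDrive(
    mesor=1.0, amplitude=0.25, peak_time=-540.0, period=1440.0
)


def _default_drivers() -> Drivers:
    return Drivers(circadian=DEFAULT_CIRCADIAN, stress=StressProtocol())


def minimal_model() -> ModelSpec:
    """Three-state demonstration model with Hill cortisol feedback."""
    return ModelSpec(
        name="minimal",
        state_names=("CRH", "ACTH", "cortisol"),
        params=ParameterTable(tuple(ParameterEntry(*p) for p in _MINIMAL_PARAMS)),
        rhs=minimal_hpa_rhs,
        output_map={"acth": (1, 1.0), "cortisol": (2, 1.0)},
        default_drivers=_default_drivers(),
    )


def receptor_model() -> ModelSpec:
    """Four-state demonstration model with bound-GR feedback and a positive
    receptor loop."""
    return ModelSpec(
        name="receptor",
        state_names=("CRH", "ACTH", "cortisol", "GR"),
        params=ParameterTable(tuple(ParameterEntry(*p) for p in _RECEPTOR_PARAMS)),
        rhs=receptor_hpa_rhs,
        output_map={"acth": (1, 1.0), "cortisol": (2, 1.0)},
        default_drivers=_default_drivers(),
    )


def delayed_model(
    tau_c: float = 5.0, tau_a: float = 10.0, tau_f: float = 15.0
) -> ModelSpec:
    """Delayed demonstration model (method-of-steps DDE).

    Default lags: CRH->pituitary 5 min, ACTH->adrenal 10 min, cortisol
    feedback 15 min.
    """
    return ModelSpec(
        name="delayed",
        state_names=("CRH", "ACTH", "cortisol"),
        params=ParameterTable(tuple(ParameterEntry(*p) for p in _MINIMAL_PARAMS)),
        rhs=delayed_hpa_rhs,
        output_map={"acth": (1, 1.0), "cortisol": (2, 1.0)},
        delays=(Delay("tau_c", tau_c), Delay("tau_a", tau_a), Delay("tau_f", tau_f)),
        default_drivers=_default_drivers(),
    )


MODEL_REGISTRY: dict[str, Callable[[], ModelSpec]] = {
    "minimal": minimal_model,
    "receptor": receptor_model,
    "delayed": delayed_model,
}


def get_model(name: str) -> ModelSpec:
    """Instantiate a registered demonstration model by name."""
    try:
        return MODEL_REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered: {sorted(MODEL_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

class SteadyStateError(RuntimeError):
    """No nonnegative equilibrium found within the iteration budget."""


def steady_state(
    model: ModelSpec,
    params: Mapping[str, float] | None = None,
    drivers: Drivers | None = None,
    tol: float = 1e-10,
) -> np.ndarray:
    """Flat-driver equilibrium of ``model``.

    Drivers are flattened (circadian frozen at its mesor, stress at baseline)
    and the algebraic system rhs(y) = 0 is solved with a Powell-hybrid root
    finder from several deterministic starting points.  For DDE models the
    delayed lookup returns the current state, which is exact at equilibrium.

    Returns the first root with all components >= 0 and max-norm residual
    below ``tol``; raises :class:`SteadyStateError` otherwise.
    """
    p = dict(model.params.defaults())
    if params is not None:
        p.update(params)
    drv = (drivers or model.default_drivers).flattened()

    if model.has_delays:
        def fun(y):
            return model.rhs(0.0, y, lambda name: y, p, drv)
    else:
        def fun(y):
            return model.rhs(0.0, y, p, drv)

    guesses = [np.full(model.n_states, g) for g in (1.0, 0.1, 10.0, 100.0)]
    if model.initial_state is not None:
        guesses.insert(0, np.asarray(model.initial_state, dtype=float))
    # feedback-free cascade guess for the demonstration family
    if set(model.state_names[:3]) >= {"CRH", "ACTH", "cortisol"} and all(
        k in p for k in ("k_c", "w_c", "k_a", "w_a", "k_f", "w_f")
    ):
        circ0 = drv.circ(0.0)
        stress0 = drv.acute(0.0)
        C0 = p["k_c"] * circ0 * stress0 / p["w_c"]
        A0 = p["k_a"] * C0 / p["w_a"]
        F0 = p["k_f"] * A0 / p["w_f"]
        base = [C0, A0, F0]
        base += [1.0] * (model.n_states - 3)
        guesses.insert(0, np.array(base))

    for guess in guesses:
        try:
            sol = scipy.optimize.root(fun, guess, method="hybr", tol=1e-14)
        except (ValueError, FloatingPointError):
            continue
        y = sol.x
        if not np.all(np.isfinite(y)) or np.any(y < 0):
            continue
        resid = np.max(np.abs(fun(y)))
        if resid < tol:
            return y
    raise SteadyStateError(
        f"no nonnegative steady state found for model {model.name!r} "
        f"(residual tolerance {tol:g})"
    )
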