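"""Hormone time-series schemas, I/O and synthetic cohort generators.

Two sampling schemas are supported:

* **TSST schema** — the 11-point blood-draw grid around a 20-min laboratory
  stressor starting at 17:00: samples at -30 and -15 min before the test, at
  the start, 10 and 20 min into the test, then every 15 min for 90 min after
  it ends.  Times are stored relative to the test start.
* **basal schema** — 24-h resting series sampled at 10-min intervals in
  clock minutes, with a circadian envelope peaking near 8 AM modulating
  12-18 discrete ultradian secretory pulses of 60-90 min period.

The synthetic generators stand in for clinical cohorts so the whole
validation pipeline is exercisable without any data download.  They emulate
the documented empirical shape: baseline -> sharp rise during the stressor ->
exponential return to baseline over the following 90 min, with log-normal
inter-subject variability, multiplicative log-normal assay noise, ACTH
peaking before cortisol, and an optional fraction of anomalous responders
whose ACTH declines monotonically while cortisol peaks 30 min *after* the
test ends.

Units are metadata only (defaults pg/mL for ACTH, ug/dL for cortisol); the
cost normalisation makes every downstream number unit-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import CircadianDrive

__all__ = [
    "HormoneSeries",
    "SubjectRecord",
    "Cohort",
    "CohortStats",
    "BasalSeries",
    "GROUPS",
    "TSST_START_CLOCK_MIN",
    "tsst_time_grid",
    "load_cohort",
    "save_cohort",
    "cohort_mean",
    "synth_tsst_cohort",
    "synth_basal_series",
    "save_results",
    "load_results",
]

logger = logging.getLogger(__name__)

GROUPS = ("control", "MDD-melancholic", "MDD-atypical", "MDD-neither")

#: The stress test starts at 5:00 PM = clock minute 1020 (metadata only;
#: TSST grids are stored relative to the test start).
TSST_START_CLOCK_MIN = 1020


def tsst_time_grid() -> np.ndarray:
    """The 11-point TSST sampling grid in minutes relative to test start."""
    return np.array(
        [-30.0, -15.0, 0.0, 10.0, 20.0, 35.0, 50.0, 65.0, 80.0, 95.0, 110.0]
    )


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HormoneSeries:
    """One hormone's sampled concentrations on a time grid."""

    hormone: str
    times: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if np.any(v < 0):
            raise ValueError("hormone concentrations must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject ACTH and cortisol series sharing one time grid."""

    subject_id: str
    group: str
    cortisol: HormoneSeries
    acth: HormoneSeries | None = None

    def __post_init__(self):
        if self.acth is not None and not np.array_equal(
            self.acth.times, self.cortisol.times
        ):
            raise ValueError(
                f"subject {self.subject_id!r}: ACTH and cortisol must share "
                "one time grid"
            )

    @property
    def times(self) -> np.ndarray:
        return self.cortisol.times

    def hormones(self) -> dict[str, HormoneSeries]:
        out = {}
        if self.acth is not None:
            out["acth"] = self.acth
        out["cortisol"] = self.cortisol
        return out


@dataclass(frozen=True)
class Cohort:
    """A set of subjects on a common time grid."""

    subjects: tuple[SubjectRecord, ...]
    reference_event: tuple[float, float] | None = None  # (start, duration) min
    exclusions: tuple[tuple[str, str], ...] = ()  # (subject_id, reason)

    def __post_init__(self):
        subjects = tuple(self.subjects)
        object.__setattr__(self, "subjects", subjects)
        ids = [s.subject_id for s in subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        if subjects:
            grid = subjects[0].times
            for s in subjects[1:]:
                if not np.array_equal(s.times, grid):
                    raise ValueError("all subjects must share one time grid")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def times(self) -> np.ndarray:
        if not self.subjects:
            raise ValueError("empty cohort has no time grid")
        return self.subjects[0].times

    def get(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(f"no subject {subject_id!r} in cohort")


@dataclass(frozen=True)
class CohortStats:
    """Pointwise cohort mean profile with per-point sample SDs."""

    mean: SubjectRecord
    cortisol_sd: np.ndarray
    acth_sd: np.ndarray | None = None


@dataclass(frozen=True)
class BasalSeries:
    """A 24-h basal ACTH/cortisol pair plus the circadian envelope used."""

    acth: HormoneSeries
    cortisol: HormoneSeries
    envelope: CircadianDrive
    pulse_times: np.ndarray


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["subject_id", "group", "time_min", "acth", "cortisol"]


def load_cohort(path, schema: str = "tsst") -> Cohort:
    """Load a delimited-text cohort table.

    Expected columns: ``subject_id, group, time_min, acth, cortisol`` (in the
    basal schema the ``acth`` column may be entirely empty).  Subjects whose
    grid does not match the schema — i.e. with any missing sample — are
    excluded with a logged reason, mirroring the clinical rule of dropping
    subjects with any missing data point; non-numeric cells are a hard parse
    failure reported with the offending row number.
    """
    if schema not in ("tsst", "basal"):
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty cohort file")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    def _numeric(col: str, required: bool) -> np.ndarray:
        # parse with Python float(): correctly rounded, so the CSV format
        # round-trips bit-for-bit (C-parser fast paths can be off by 1 ulp)
        raw = df[col]
        out = np.empty(len(raw))
        for i, cell in enumerate(raw):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or (
                isinstance(cell, str) and cell.strip() == ""
            ):
                if required:
                    raise ValueError(
                        f"{path}: missing value in column {col!r} at file row "
                        f"{i + 2}"
                    )
                out[i] = np.nan
                continue
            try:
                out[i] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} in column {col!r} "
                    f"at file row {i + 2}"
                ) from None
        return out

    time_min = _numeric("time_min", required=True)
    cort = _numeric("cortisol", required=True)
    acth = _numeric("acth", required=False)

    subjects: list[SubjectRecord] = []
    exclusions: list[tuple[str, str]] = []
    expected = tsst_time_grid() if schema == "tsst" else None
    ref_grid = None

    for sid, idx in df.groupby("subject_id", sort=False).groups.items():
        idx = np.asarray(idx)
        order = np.argsort(time_min[idx], kind="stable")
        idx = idx[order]
        t = time_min[idx]
        group = df.loc[idx[0], "group"]
        if schema == "tsst":
            grid = expected
        else:
            if ref_grid is None:
                ref_grid = t
            grid = ref_grid
        if len(t) != len(grid) or not np.array_equal(t, grid):
            reason = (
                f"time grid {t.tolist()} does not match the {schema} schema "
                "(missing or extra sample points)"
            )
            logger.warning("excluding subject %r: %s", sid, reason)
            exclusions.append((str(sid), reason))
            continue
        a_vals = acth[idx]
        acth_series = None
        if np.all(np.isfinite(a_vals)):
            acth_series = HormoneSeries("acth", t, a_vals, units="pg/mL")
        elif np.any(np.isfinite(a_vals)):
            reason = "partially missing ACTH values"
            logger.warning("excluding subject %r: %s", sid, reason)
            exclusions.append((str(sid), reason))
            continue
        try:
            record = SubjectRecord(
                subject_id=str(sid),
                group=str(group),
                cortisol=HormoneSeries("cortisol", t, cort[idx], units="ug/dL"),
                acth=acth_series,
            )
        except ValueError as exc:
            logger.warning("excluding subject %r: %s", sid, exc)
            exclusions.append((str(sid), str(exc)))
            continue
        subjects.append(record)

    if not subjects:
        raise ValueError(f"{path}: no valid subjects after exclusions")
    event = (0.0, 20.0) if schema == "tsst" else None
    return Cohort(
        subjects=tuple(subjects),
        reference_event=event,
        exclusions=tuple(exclusions),
    )


def save_cohort(cohort: Cohort, path) -> Path:
    """Write a cohort back to the delimited format read by :func:`load_cohort`."""
    rows = []
    for s in cohort.subjects:
        for i, t in enumerate(s.times):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "time_min": t,
                    "acth": s.acth.values[i] if s.acth is not None else "",
                    "cortisol": s.cortisol.values[i],
                }
            )
    path = Path(path)
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)
    return path


def cohort_mean(cohort: Cohort) -> CohortStats:
    """Pointwise arithmetic mean and sample SD (ddof=1) per hormone.

    With a single subject the mean equals that subject and every SD is 0.
    """
    if len(cohort) == 0:
        raise ValueError("cannot average an empty cohort")
    t = cohort.times
    cort = np.array([s.cortisol.values for s in cohort.subjects])
    have_acth = all(s.acth is not None for s in cohort.subjects)

    def _sd(mat):
        if mat.shape[0] < 2:
            return np.zeros(mat.shape[1])
        return mat.std(axis=0, ddof=1)

    acth_series = None
    acth_sd = None
    if have_acth:
        acth = np.array([s.acth.values for s in cohort.subjects])
        acth_series = HormoneSeries("acth", t, acth.mean(axis=0), units="pg/mL")
        acth_sd = _sd(acth)
    mean_record = SubjectRecord(
        subject_id="mean",
        group="mean",
        cortisol=HormoneSeries("cortisol", t, cort.mean(axis=0), units="ug/dL"),
        acth=acth_series,
    )
    return CohortStats(mean=mean_record, cortisol_sd=_sd(cort), acth_sd=acth_sd)


# ---------------------------------------------------------------------------
# synthetic TSST cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TsstProfile:
    """Population parameters of the synthetic stress-response generator.

    Baselines are log-normal across subjects (medians 20 pg/mL ACTH,
    10 ug/dL cortisol, ~25% inter-subject CV).  The stress response rises as
    a smooth half-sine from test start to a peak drawn in [10, 35] min (ACTH
    peaking 5-10 min before cortisol) and decays exponentially at a rate
    drawn so the 110-min sample is back within ``final_fraction`` of
    baseline.  Assay noise is multiplicative log-normal (default CV 15%).
    """

    baseline_acth: float = 20.0
    baseline_cortisol: float = 10.0
    baseline_log_sd: float = 0.25
    rel_amplitude_acth: float = 1.5
    rel_amplitude_cortisol: float = 1.0
    amplitude_log_sd: float = 0.3
    acth_peak_window: tuple[float, float] = (10.0, 25.0)
    cort_peak_delay: tuple[float, float] = (5.0, 10.0)
    final_fraction: float = 0.15
    noise_cv: float = 0.15


DEFAULT_GROUP_MIX: Mapping[str, float] = {
    # the documented cohort composition: 15/58 controls, 43/58 MDD
    "control": 15 / 58,
    "MDD-melancholic": 15 / 58,
    "MDD-atypical": 14 / 58,
    "MDD-neither": 14 / 58,
}


def _counts_from_mix(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    total = sum(mix.values())
    raw = {g: n * w / total for g, w in mix.items()}
    counts = {g: int(np.floor(v)) for g, v in raw.items()}
    short = n - sum(counts.values())
    # largest-remainder apportionment, ties broken by group name
    order = sorted(raw, key=lambda g: (-(raw[g] - counts[g]), g))
    for g in order[:short]:
        counts[g] += 1
    return counts


def _response_curve(t, baseline, amp, t_peak, rate, t_on=0.0):
    """Baseline -> half-sine rise on [t_on, t_peak] -> exponential decay."""
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, baseline)
    rising = (t >= t_on) & (t <= t_peak)
    out[rising] += amp * np.sin(
        0.5 * np.pi * (t[rising] - t_on) / (t_peak - t_on)
    ) ** 2
    falling = t > t_peak
    out[falling] += amp * np.exp(-rate * (t[falling] - t_peak))
    return out


def synth_tsst_cohort(
    n_subjects: int,
    group_mix: Mapping[str, float] | None = None,
    profile_params: TsstProfile | None = None,
    anomaly_fraction: float = 0.0,
    seed: int | None = None,
) -> Cohort:
    """Generate a synthetic TSST cohort on the canonical 11-point grid.

    ``anomaly_fraction`` of the subjects (rounded, drawn deterministically
    from the seed) are anomalous responders: monotonically decreasing ACTH
    across the whole grid with the cortisol peak at the +50 min grid point,
    i.e. 30 min after the 20-min test ends.  Identical seeds reproduce
    identical cohorts.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0.0 <= anomaly_fraction <= 1.0:
        raise ValueError("anomaly_fraction must be in [0, 1]")
    prof = profile_params or TsstProfile()
    if prof.noise_cv < 0 or prof.final_fraction <= 0:
        raise ValueError("invalid profile parameters")
    rng = np.random.default_rng(seed)
    grid = tsst_time_grid()
    counts = _counts_from_mix(n_subjects, group_mix or DEFAULT_GROUP_MIX)
    labels = [g for g, c in counts.items() for _ in range(c)]

    n_anom = int(round(anomaly_fraction * n_subjects))
    anomalous = np.zeros(n_subjects, dtype=bool)
    anomalous[rng.choice(n_subjects, size=n_anom, replace=False)] = True

    sigma = np.sqrt(np.log1p(prof.noise_cv**2))

    def _noisy(values):
        if prof.noise_cv == 0:
            return values
        return values * np.exp(rng.normal(0.0, sigma, size=values.shape))

    subjects = []
    for i in range(n_subjects):
        b_acth = prof.baseline_acth * np.exp(rng.normal(0, prof.baseline_log_sd))
        b_cort = prof.baseline_cortisol * np.exp(rng.normal(0, prof.baseline_log_sd))
        if anomalous[i]:
            # patient-1 style: ACTH declines across the grid; cortisol peaks
            # 30 min after the test ends (+50 min grid point)
            trend = b_acth * 1.3 * np.exp(
                np.linspace(0.0, np.log(0.5), grid.size)
            )
            a_vals = np.sort(_noisy(trend))[::-1]
            amp = 1.5 * b_cort * np.exp(rng.normal(0, prof.amplitude_log_sd))
            pulse = np.exp(-((grid - 50.0) ** 2) / (2 * 12.0**2))
            pulse[grid < 0] = 0.0
            c_vals = _noisy(b_cort + amp * pulse)
            k50 = int(np.flatnonzero(grid == 50.0)[0])
            if np.argmax(c_vals) != k50:  # generator guarantee, not assay truth
                c_vals[k50] = c_vals.max() * 1.05
        else:
            amp_a = (
                prof.rel_amplitude_acth
                * b_acth
                * np.exp(rng.normal(0, prof.amplitude_log_sd))
            )
            amp_c = (
                prof.rel_amplitude_cortisol
                * b_cort
                * np.exp(rng.normal(0, prof.amplitude_log_sd))
            )
            tp_a = rng.uniform(*prof.acth_peak_window)
            tp_c = min(tp_a + rng.uniform(*prof.cort_peak_delay), 35.0)
            ffrac = rng.uniform(prof.final_fraction / 3, prof.final_fraction)

            def _rate(amp, base, tp):
                target = ffrac * base
                if amp <= target:
                    return 0.01
                return np.log(amp / target) / (110.0 - tp)

            a_vals = _noisy(
                _response_curve(grid, b_acth, amp_a, tp_a, _rate(amp_a, b_acth, tp_a))
            )
            c_vals = _noisy(
                _response_curve(grid, b_cort, amp_c, tp_c, _rate(amp_c, b_cort, tp_c))
            )
        subjects.append(
            SubjectRecord(
                subject_id=str(i + 1),
                group=labels[i],
                acth=HormoneSeries("acth", grid, a_vals, units="pg/mL"),
                cortisol=HormoneSeries("cortisol", grid, c_vals, units="ug/dL"),
            )
        )
    return Cohort(subjects=tuple(subjects), reference_event=(0.0, 20.0))


# ---------------------------------------------------------------------------
# synthetic basal series
# ---------------------------------------------------------------------------

def synth_basal_series(
    duration: float = 1440.0,
    circadian_params: CircadianDrive | None = None,
    n_pulses: int | None = None,
    pulse_period_range: tuple[float, float] = (60.0, 90.0),
    seed: int | None = None,
    sample_interval: float = 10.0,
) -> BasalSeries:
    """Generate one 24-h basal ACTH/cortisol pair in clock minutes.

    A cosinor envelope peaking at 8 AM (clock minute 480) modulates discrete
    secretory pulses.  Candidate pulse times are laid down at inter-pulse
    intervals drawn uniformly from ``pulse_period_range``; if more candidates
    fit the day than ``n_pulses`` (default: drawn uniformly from 12-18), the
    surplus pulses with the lowest envelope value are dropped — emulating the
    overnight quiescent period with little to no secretion between episodes.
    """
    lo, hi = pulse_period_range
    if not 0 < lo <= hi:
        raise ValueError("invalid pulse_period_range")
    rng = np.random.default_rng(seed)
    env = circadian_params or CircadianDrive(
        mesor=1.0, amplitude=0.7, peak_time=480.0, period=1440.0
    )
    if n_pulses is None:
        n_pulses = int(rng.integers(12, 19))
    if n_pulses < 0:
        raise ValueError("n_pulses must be >= 0")

    t = np.arange(0.0, duration + 0.5 * sample_interval, sample_interval)
    envelope = np.array([env(tt) for tt in t])

    pulse_times = []
    tp = rng.uniform(0.0, lo)
    while tp < duration:
        pulse_times.append(tp)
        tp += rng.uniform(lo, hi)
    pulse_times = np.array(pulse_times)
    if len(pulse_times) > n_pulses:
        env_at = np.array([env(tt) for tt in pulse_times])
        keep = np.sort(np.argsort(env_at)[len(pulse_times) - n_pulses:])
        pulse_times = pulse_times[keep]

    def _series(base_level, pulse_gain, width, lead):
        vals = 0.3 * base_level * envelope
        for tk in pulse_times:
            amp = pulse_gain * base_level * env(tk) * np.exp(rng.normal(0, 0.3))
            vals = vals + amp * np.exp(-((t - (tk - lead)) ** 2) / (2 * width**2))
        return np.maximum(vals, 0.0)

    cort = _series(base_level=10.0, pulse_gain=0.8, width=10.0, lead=0.0)
    acth = _series(base_level=20.0, pulse_gain=0.8, width=8.0, lead=8.0)
    return BasalSeries(
        acth=HormoneSeries("acth", t, acth, units="pg/mL"),
        cortisol=HormoneSeries("cortisol", t, cort, units="ug/dL"),
        envelope=env,
        pulse_times=pulse_times,
    )


# ---------------------------------------------------------------------------
# results persistence
# ---------------------------------------------------------------------------

def save_results(runs: Sequence, solutions: Mapping[str, pd.DataFrame], path):
    """Persist optimisation runs and sampled solution arrays.

    Writes a spreadsheet workbook (sheets ``parameters`` and ``solutions``)
    plus plain CSV mirrors next to it.  The CSV mirrors round-trip losslessly
    (Python float repr is shortest-round-trip).  Returns
    ``(workbook_path, parameters_csv, solutions_csv)``.
    """
    if not runs:
        raise ValueError("no runs to save")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    rows = []
    for run in runs:
        row = {
            "run_id": run.run_id,
            "algorithm": run.algorithm,
            "seed": run.seed,
            "popsize": run.popsize,
            "generations": run.generations,
            "best_cost": run.best_cost,
        }
        row.update({f"param:{k}": v for k, v in run.best_params.items()})
        rows.append(row)
    params_df = pd.DataFrame(rows)

    sol_frames = []
    for run_id, frame in solutions.items():
        frame = frame.copy()
        frame.insert(0, "run_id", run_id)
        sol_frames.append(frame)
    sol_df = (
        pd.concat(sol_frames, ignore_index=True) if sol_frames else pd.DataFrame()
    )

    workbook = path.with_suffix(".xlsx")
    with pd.ExcelWriter(workbook, engine="openpyxl") as writer:
        params_df.to_excel(writer, sheet_name="parameters", index=False)
        sol_df.to_excel(writer, sheet_name="solutions", index=False)
    params_csv = path.parent / (path.stem + "_parameters.csv")
    solutions_csv = path.parent / (path.stem + "_solutions.csv")
    params_df.to_csv(params_csv, index=False)
    sol_df.to_csv(solutions_csv, index=False)
    return workbook, params_csv, solutions_csv


def load_results(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the CSV mirrors written by :func:`save_results`."""
    path = Path(path)
    params_csv = path.parent / (path.stem + "_parameters.csv")
    solutions_csv = path.parent / (path.stem + "_solutions.csv")
    params = pd.read_csv(params_csv, float_precision="round_trip")
    try:
        solutions = pd.read_csv(solutions_csv, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        solutions = pd.DataFrame()
    return params, solutions
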