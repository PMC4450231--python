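"""Sampled time-course containers and elementary profile arithmetic.

All dissolution and plasma curves in this package are instances of
:class:`TimeSeriesProfile`: a strictly increasing time grid with one value
per knot, a value unit, a value kind, and an explicit time unit.
Dissolution curves are sampled in minutes and plasma curves in hours;
conversion between the two is always explicit (:meth:`TimeSeriesProfile.in_time_unit`),
never implicit.

Multicompartment dissolution runs (one dissolved-amount/volume/pH trace per
gastrointestinal compartment, plus the collection canister and a withdrawal
ledger) are held in :class:`CompartmentalDissolutionDataset`, from which the
cumulative fraction-dissolved curve used for correlation work is derived by
:func:`cumulative_fraction`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesProfile",
    "CompartmentRecord",
    "SamplingEvent",
    "CompartmentalDissolutionDataset",
    "ProfileRangeError",
    "ProfileParseError",
    "ConfigurationError",
    "resample_linear",
    "auc_trapezoid",
    "cmax_tmax",
    "cumulative_fraction",
    "read_profiles_csv",
    "write_profiles_csv",
]

_KINDS = ("concentration", "amount", "fraction")
_TIME_UNITS = ("min", "h")

#: small assay overshoot tolerated on fraction-kind profiles before a warning
FRACTION_WARN = 1.0001
#: hard upper bound on fraction-kind profiles (flagged overshoot of a
#: deconvolved fraction-absorbed curve is allowed up to here)
FRACTION_LIMIT = 1.05


class ProfileRangeError(ValueError):
    """A requested time lies outside the observed range of a profile."""


class ProfileParseError(ValueError):
    """A profile file violates the CSV dialect contract."""


class ConfigurationError(ValueError):
    """An operation was configured inconsistently with its inputs."""


@dataclass(frozen=True)
class TimeSeriesProfile:
    """A sampled time course.

    Parameters
    ----------
    times
        Strictly increasing, nonnegative sample times (at least two).
    values
        One value per sample time.
    value_unit
        Free-text unit label (``"mg"``, ``"mg/mL"``, ``"ng/mL"``, ...).
    kind
        One of ``"concentration"``, ``"amount"``, ``"fraction"``. Fraction
        profiles must lie in ``[0, 1.05]``; values above 1.0001 trigger a
        warning (tolerated overshoot of a numerically deconvolved curve).
    time_unit
        ``"min"`` (dissolution convention) or ``"h"`` (plasma convention).
    """

    times: np.ndarray
    values: np.ndarray
    value_unit: str = ""
    kind: str = "concentration"
    time_unit: str = "min"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if t.size != v.size:
            raise ValueError(
                f"times ({t.size}) and values ({v.size}) differ in length"
            )
        if t.size < 2:
            raise ValueError("a profile needs at least two samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if t[0] < 0:
            raise ValueError("times must be nonnegative")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("times and values must be finite")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.time_unit not in _TIME_UNITS:
            raise ValueError(
                f"time_unit must be one of {_TIME_UNITS}, got {self.time_unit!r}"
            )
        if self.kind == "fraction":
            if v.min() < -1e-9 or v.max() > FRACTION_LIMIT:
                raise ValueError(
                    "fraction profile values must lie in "
                    f"[0, {FRACTION_LIMIT}]; observed range "
                    f"[{v.min():.6g}, {v.max():.6g}]"
                )
            if v.max() > FRACTION_WARN:
                warnings.warn(
                    f"fraction profile exceeds 1 (max {v.max():.6g}); "
                    "tolerated but flagged",
                    stacklevel=2,
                )

    # -- elementary queries -------------------------------------------------

    def __len__(self) -> int:
        return self.times.size

    @property
    def t_start(self) -> float:
        return float(self.times[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def value_at(self, t) -> np.ndarray | float:
        """Linearly interpolated value(s) at ``t`` (within observed range)."""
        t_arr = np.asarray(t, dtype=float)
        bad = (t_arr < self.times[0] - 1e-12) | (t_arr > self.times[-1] + 1e-12)
        if np.any(bad):
            offender = float(np.atleast_1d(t_arr)[np.atleast_1d(bad)][0])
            raise ProfileRangeError(
                f"time {offender:g} {self.time_unit} outside observed range "
                f"[{self.times[0]:g}, {self.times[-1]:g}] {self.time_unit}"
            )
        out = np.interp(t_arr, self.times, self.values)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def in_time_unit(self, unit: str) -> "TimeSeriesProfile":
        """Return the same curve expressed in ``unit`` (``"min"`` or ``"h"``)."""
        if unit not in _TIME_UNITS:
            raise ValueError(f"unknown time unit {unit!r}")
        if unit == self.time_unit:
            return self
        factor = 1.0 / 60.0 if unit == "h" else 60.0
        return replace(self, times=self.times * factor, time_unit=unit)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {f"time_{self.time_unit}": self.times, "value": self.values}
        )


def resample_linear(profile: TimeSeriesProfile, new_times) -> TimeSeriesProfile:
    """Linearly interpolate ``profile`` onto ``new_times`` (no extrapolation)."""
    new_times = np.asarray(new_times, dtype=float)
    values = profile.value_at(new_times)
    return replace(profile, times=new_times, values=np.asarray(values))


def auc_trapezoid(
    profile: TimeSeriesProfile, t_start: float, t_end: float
) -> float:
    """Trapezoidal area under ``profile`` between ``t_start`` and ``t_end``.

    The window boundaries may fall between knots; boundary values are
    linearly interpolated.
    """
    if not t_start < t_end:
        raise ValueError(f"require t_start < t_end, got [{t_start}, {t_end}]")
    # value_at performs the range check and names the offending time
    v_lo = profile.value_at(t_start)
    v_hi = profile.value_at(t_end)
    inside = (profile.times > t_start) & (profile.times < t_end)
    t = np.concatenate(([t_start], profile.times[inside], [t_end]))
    v = np.concatenate(([v_lo], profile.values[inside], [v_hi]))
    return float(np.trapezoid(v, t))


def cmax_tmax(profile: TimeSeriesProfile) -> tuple[float, float]:
    """Maximum observed value and the earliest time it occurs."""
    idx = int(np.argmax(profile.values))  # argmax returns first occurrence
    return float(profile.values[idx]), float(profile.times[idx])


# ---------------------------------------------------------------------------
# multicompartment dissolution datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamplingEvent:
    """One manual sample withdrawal (medium filtered off, rest returned)."""

    time_min: float
    compartment: str
    withdrawn_mL: float
    #: dissolved drug removed with the filtered volume; if None it is
    #: reconstructed as concentration at the sampling time x withdrawn volume
    withdrawn_dissolved_mg: float | None = None


@dataclass(frozen=True)
class CompartmentRecord:
    """Per-compartment traces on the compartment's sampling grid."""

    dissolved_amount: TimeSeriesProfile  # mg
    volume: TimeSeriesProfile  # mL
    ph: TimeSeriesProfile  # pH units
    #: populated by the transit simulator only; not part of the CSV dialect
    undissolved_amount: TimeSeriesProfile | None = None

    def __post_init__(self) -> None:
        grids = [self.dissolved_amount.times, self.volume.times, self.ph.times]
        if not all(np.array_equal(grids[0], g) for g in grids[1:]):
            raise ValueError("compartment traces must share one sampling grid")
        if self.dissolved_amount.values.min() < -1e-9:
            raise ValueError("dissolved amounts must be nonnegative")
        if self.volume.values.min() < -1e-9:
            raise ValueError("volumes must be nonnegative")


@dataclass(frozen=True)
class CompartmentalDissolutionDataset:
    """All traces of one dynamic dissolution run of one formulation.

    ``compartments`` maps the gut compartment names (stomach, duodenum,
    jejunum, ileum) to their records; the collection canister, which only
    accumulates outflow, is kept separately. ``canister_origin`` is the
    simulator's provenance ledger: dissolved mass in the canister broken
    down by the compartment in which it dissolved, enabling cumulative
    profiles that exclude compartments (the canister share of an imported,
    untagged dataset is attributed to the ileum).
    """

    formulation_id: str
    dose_mg: float
    compartments: dict[str, CompartmentRecord]
    canister: CompartmentRecord | None = None
    sampling_events: tuple[SamplingEvent, ...] = ()
    canister_origin: dict[str, TimeSeriesProfile] | None = None

    def __post_init__(self) -> None:
        if self.dose_mg <= 0:
            raise ValueError("dose_mg must be positive")
        if not self.compartments:
            raise ValueError("dataset needs at least one compartment")
        object.__setattr__(
            self, "sampling_events", tuple(self.sampling_events)
        )


def _withdrawn_mass(
    event: SamplingEvent, record: CompartmentRecord
) -> float:
    if event.withdrawn_dissolved_mg is not None:
        return event.withdrawn_dissolved_mg
    conc = record.dissolved_amount.value_at(event.time_min) / max(
        record.volume.value_at(event.time_min), 1e-12
    )
    return conc * event.withdrawn_mL


def cumulative_fraction(
    dataset: CompartmentalDissolutionDataset,
    include_compartments=None,
    apply_withdrawal_correction: bool = True,
) -> TimeSeriesProfile:
    """Cumulative fraction of the dose dissolved in the included compartments.

    The curve sums, at each sampling time, the dissolved amount residing in
    each included compartment, the dissolved amount accumulated in the
    canister that is attributable to the included compartments, and — when
    the withdrawal correction is on — the dissolved mass removed by earlier
    sample withdrawals from included compartments (1 mL filtered per event;
    the recorded traces are pre-withdrawal, so an event corrects all strictly
    later times).
    """
    if include_compartments is None:
        names = list(dataset.compartments)
    else:
        names = list(include_compartments)
        unknown = [n for n in names if n not in dataset.compartments]
        if unknown:
            raise ConfigurationError(
                f"unknown compartment(s) {unknown}; dataset has "
                f"{sorted(dataset.compartments)}"
            )
    if not names:
        raise ConfigurationError("no compartments included")

    grid = dataset.compartments[names[0]].dissolved_amount.times
    total = np.zeros_like(grid)
    for name in names:
        prof = dataset.compartments[name].dissolved_amount
        if np.array_equal(prof.times, grid):
            total += prof.values
        else:  # staggered imported grids: interpolate on the overlap
            total += np.interp(grid, prof.times, prof.values)

    if dataset.canister is not None:
        if dataset.canister_origin is not None:
            for name in names:
                origin = dataset.canister_origin.get(name)
                if origin is not None:
                    total += np.interp(grid, origin.times, origin.values)
        elif "ileum" in names:
            prof = dataset.canister.dissolved_amount
            total += np.interp(grid, prof.times, prof.values)

    if apply_withdrawal_correction:
        for event in dataset.sampling_events:
            if event.compartment not in names:
                continue
            removed = _withdrawn_mass(
                event, dataset.compartments[event.compartment]
            )
            total[grid > event.time_min + 1e-9] += removed

    return TimeSeriesProfile(
        times=grid,
        values=total / dataset.dose_mg,
        value_unit="fraction of dose",
        kind="fraction",
        time_unit="min",
    )


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

_DISS_COLUMNS = ["time_min", "compartment", "dissolved_mg", "volume_mL", "pH"]
_PLASMA_COLUMNS = ["time_h", "conc_ng_per_mL"]
_EVENT_COLUMNS = ["time_min", "compartment", "withdrawn_mL"]


def write_profiles_csv(obj, path) -> None:
    """Write a dataset or a plasma profile to its CSV dialect.

    Datasets use the dissolution dialect
    (``time_min,compartment,dissolved_mg,volume_mL,pH``; the canister is a
    compartment named ``canister``) with a ``#``-comment metadata line for
    formulation id and dose; sampling events go to a ``.events.csv``
    sidecar. Plasma profiles use ``time_h,conc_ng_per_mL``.
    """
    path = Path(path)
    if isinstance(obj, TimeSeriesProfile):
        prof = obj.in_time_unit("h")
        df = pd.DataFrame(
            {"time_h": prof.times, "conc_ng_per_mL": prof.values}
        )
        df.to_csv(path, index=False)
        return
    if not isinstance(obj, CompartmentalDissolutionDataset):
        raise TypeError(f"cannot serialize {type(obj).__name__}")

    rows = []
    items = list(obj.compartments.items())
    if obj.canister is not None:
        items.append(("canister", obj.canister))
    for name, rec in items:
        for i, t in enumerate(rec.dissolved_amount.times):
            rows.append(
                {
                    "time_min": t,
                    "compartment": name,
                    "dissolved_mg": rec.dissolved_amount.values[i],
                    "volume_mL": rec.volume.values[i],
                    "pH": rec.ph.values[i],
                }
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# formulation_id={obj.formulation_id} dose_mg={obj.dose_mg!r}\n"
        )
        pd.DataFrame(rows, columns=_DISS_COLUMNS).to_csv(fh, index=False)
    if obj.sampling_events:
        ev = pd.DataFrame(
            [
                {
                    "time_min": e.time_min,
                    "compartment": e.compartment,
                    "withdrawn_mL": e.withdrawn_mL,
                }
                for e in obj.sampling_events
            ],
            columns=_EVENT_COLUMNS,
        )
        ev.to_csv(path.with_suffix(".events.csv"), index=False)


def _read_metadata(path: Path) -> dict:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first.lstrip("#").split():
            if "=" in token:
                key, _, val = token.partition("=")
                meta[key] = val
    return meta


def read_profiles_csv(path, formulation_id=None, dose_mg=None):
    """Read a dissolution dataset or a plasma profile from CSV.

    The dialect is detected from the header. Rows of a dissolution file may
    arrive in any order; they are sorted canonically by compartment and
    time. Duplicate times within a compartment, negative volumes, or a
    missing required column raise :class:`ProfileParseError` naming the
    offending row.
    """
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    cols = set(df.columns)

    if set(_PLASMA_COLUMNS) <= cols:
        df = df.sort_values("time_h", kind="stable").reset_index(drop=True)
        return TimeSeriesProfile(
            times=df["time_h"].to_numpy(float),
            values=df["conc_ng_per_mL"].to_numpy(float),
            value_unit="ng/mL",
            kind="concentration",
            time_unit="h",
        )

    missing = [c for c in _DISS_COLUMNS if c not in cols]
    if missing:
        raise ProfileParseError(
            f"{path.name}: missing required column(s) {missing}; "
            f"expected {_DISS_COLUMNS} or {_PLASMA_COLUMNS}"
        )

    neg = df.index[df["volume_mL"].to_numpy(float) < 0]
    if len(neg):
        raise ProfileParseError(
            f"{path.name}: negative volume at row {int(neg[0]) + 2}"
        )

    compartments: dict[str, CompartmentRecord] = {}
    canister = None
    for name, grp in df.groupby("compartment", sort=False):
        grp = grp.sort_values("time_min", kind="stable")
        t = grp["time_min"].to_numpy(float)
        dup = np.flatnonzero(np.diff(t) <= 0)
        if len(dup):
            row = int(grp.index[dup[0] + 1]) + 2
            raise ProfileParseError(
                f"{path.name}: non-monotone/duplicate time for compartment "
                f"{name!r} at row {row}"
            )
        rec = CompartmentRecord(
            dissolved_amount=TimeSeriesProfile(
                t, grp["dissolved_mg"].to_numpy(float), "mg", "amount", "min"
            ),
            volume=TimeSeriesProfile(
                t, grp["volume_mL"].to_numpy(float), "mL", "amount", "min"
            ),
            ph=TimeSeriesProfile(
                t, grp["pH"].to_numpy(float), "pH", "concentration", "min"
            ),
        )
        if name == "canister":
            canister = rec
        else:
            compartments[name] = rec

    events = []
    sidecar = path.with_suffix(".events.csv")
    if sidecar.exists():
        ev = pd.read_csv(sidecar)
        missing = [c for c in _EVENT_COLUMNS if c not in ev.columns]
        if missing:
            raise ProfileParseError(
                f"{sidecar.name}: missing required column(s) {missing}"
            )
        events = [
            SamplingEvent(
                float(r.time_min), str(r.compartment), float(r.withdrawn_mL)
            )
            for r in ev.itertuples()
        ]

    return CompartmentalDissolutionDataset(
        formulation_id=formulation_id
        or meta.get("formulation_id", path.stem),
        dose_mg=float(dose_mg if dose_mg is not None else meta.get("dose_mg", 0) or 0)
        or _require_dose(meta, path),
        compartments=compartments,
        canister=canister,
        sampling_events=tuple(events),
    )


def _require_dose(meta, path) -> float:
    raise ProfileParseError(
        f"{path.name}: dose_mg not found in metadata comment and not "
        "passed to read_profiles_csv"
    )
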