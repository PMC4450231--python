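"""Classical level-A correlation: fraction dissolved -> fraction absorbed.

A level-A model is a point-to-point regression, at matched times, of the
cumulative fraction absorbed in vivo (FABS, from deconvolution) on the
cumulative fraction dissolved in vitro (FDISS):

    FABS = B0 + B1*FDISS + B2*FDISS**2 + E

linear (B2 = 0) or quadratic. Fitted models predict FABS from a new
dissolution curve and, convolved with the unit impulse response, a
predicted plasma profile. Which compartments feed FDISS (e.g. excluding
the stomach, where no absorption occurs) is decided upstream when building
the cumulative curve; the fitter is agnostic to it. Buffered and
nonbuffered formulation designs typically need separate models — keep one
``LevelAModel`` per design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .deconvolution import UIRSpec, convolve
from .profiles import ProfileRangeError, TimeSeriesProfile

__all__ = [
    "LevelAModel",
    "pair_profiles",
    "fit_levelA",
    "predict_fabs",
    "predict_plasma_classical",
]


@dataclass(frozen=True)
class LevelAModel:
    """Fitted regression coefficients with diagnostics."""

    b0: float
    b1: float
    b2: float
    degree: int
    r_squared: float
    residuals: np.ndarray = field(repr=False)
    stderr: tuple[float, ...] = ()
    #: the (time_h, FDISS, FABS) triples the model was fitted on
    time_pairs: np.ndarray = field(default=None, repr=False)
    formulations_used: tuple[str, ...] = ()

    @property
    def linear(self) -> bool:
        return self.b2 == 0.0

    def fabs_of_fdiss(self, fdiss) -> np.ndarray:
        f = np.asarray(fdiss, dtype=float)
        return self.b0 + self.b1 * f + self.b2 * f * f


def pair_profiles(
    fabs: TimeSeriesProfile,
    fdiss: TimeSeriesProfile,
    pairing_times_h=None,
) -> np.ndarray:
    """Time-matched (t, FDISS, FABS) triples on a common hour grid.

    Default pairing times are the dissolution sampling grid converted to
    hours, truncated to the overlap with the absorption profile (dissolution
    is the sparser, bounded signal).
    """
    fabs_h = fabs.in_time_unit("h")
    fdiss_h = fdiss.in_time_unit("h")
    lo = max(fabs_h.t_start, fdiss_h.t_start)
    hi = min(fabs_h.t_end, fdiss_h.t_end)
    if lo >= hi:
        raise ProfileRangeError(
            "absorption and dissolution profiles do not overlap in time "
            f"([{fabs_h.t_start:g}, {fabs_h.t_end:g}] h vs "
            f"[{fdiss_h.t_start:g}, {fdiss_h.t_end:g}] h)"
        )
    if pairing_times_h is None:
        times = fdiss_h.times[(fdiss_h.times >= lo) & (fdiss_h.times <= hi)]
    else:
        times = np.asarray(pairing_times_h, dtype=float)
    times = np.sort(times)
    return np.column_stack(
        [times, fdiss_h.value_at(times), fabs_h.value_at(times)]
    )


def fit_levelA(
    pairs: np.ndarray, degree: int = 1, formulations_used=()
) -> LevelAModel:
    """Ordinary least squares of FABS on FDISS (degree 1 or 2).

    ``pairs`` is either (n, 2) columns (FDISS, FABS) or (n, 3) triples
    (t, FDISS, FABS) as produced by :func:`pair_profiles`; multiple
    formulations can be stacked before fitting.
    """
    pairs = np.asarray(pairs, dtype=float)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 (linear) or 2 (quadratic)")
    if pairs.ndim != 2 or pairs.shape[1] not in (2, 3):
        raise ValueError("pairs must be (n, 2) or (n, 3)")
    if pairs.shape[1] == 3:
        time_pairs = pairs
        fdiss, fabs = pairs[:, 1], pairs[:, 2]
    else:
        time_pairs = None
        fdiss, fabs = pairs[:, 0], pairs[:, 1]
    if pairs.shape[0] < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} pairs for degree {degree}"
        )
    cols = [np.ones_like(fdiss), fdiss]
    if degree == 2:
        cols.append(fdiss * fdiss)
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(
            "rank-deficient design: FDISS values do not identify the "
            f"degree-{degree} regressors (are all FDISS identical?)"
        )
    res = sm.OLS(fabs, x).fit()
    b = res.params
    return LevelAModel(
        b0=float(b[0]),
        b1=float(b[1]),
        b2=float(b[2]) if degree == 2 else 0.0,
        degree=degree,
        r_squared=float(res.rsquared),
        residuals=np.asarray(res.resid),
        stderr=tuple(float(s) for s in res.bse),
        time_pairs=time_pairs,
        formulations_used=tuple(formulations_used),
    )


def predict_fabs(
    model: LevelAModel, fdiss: TimeSeriesProfile, times_h=None
) -> TimeSeriesProfile:
    """Map a dissolution curve through the model to a valid FABS curve.

    Predictions are clipped to [0, 1] and made nondecreasing by running
    maximum (a cumulative absorption profile cannot decrease; the running
    maximum never alters an already-monotone input). A warning is issued
    when clipping touches more than 20% of the points — the model is
    extrapolating badly.
    """
    fdiss_h = fdiss.in_time_unit("h")
    if times_h is None:
        times_h = fdiss_h.times
    times_h = np.asarray(times_h, dtype=float)
    raw = model.fabs_of_fdiss(fdiss_h.value_at(times_h))
    clipped = np.clip(raw, 0.0, 1.0)
    n_clipped = int(np.sum(np.abs(clipped - raw) > 1e-12))
    if n_clipped > 0.2 * raw.size:
        warnings.warn(
            f"level-A prediction clipped at {n_clipped}/{raw.size} points; "
            "the model is extrapolating far outside its fitted range"
        )
    monotone = np.maximum.accumulate(clipped)
    return TimeSeriesProfile(
        times_h, monotone, "fraction of dose", "fraction", "h"
    )


def predict_plasma_classical(
    model: LevelAModel,
    fdiss: TimeSeriesProfile,
    uir: UIRSpec,
    dose_mg: float,
    times_h=None,
    fraction_bioavailable: float = 1.0,
    grid_step_h: float = 0.01,
) -> TimeSeriesProfile:
    """Predicted plasma curve: model-mapped FABS convolved with the UIR."""
    fabs_pred = predict_fabs(model, fdiss)
    return convolve(
        fabs_pred,
        uir,
        dose_mg,
        fraction_bioavailable=fraction_bioavailable,
        times_h=times_h,
        grid_step_h=grid_step_h,
    )
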