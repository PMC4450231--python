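"""Prediction-error metrics, regulatory verdicts, and f1/f2 factors.

Predictability of an in vitro-in vivo correlation model is judged by the
percentage prediction errors of the peak concentration and of the
(partial) area under the plasma curve,

    Cmax_PE[%] = |Cmax,obs - Cmax,pred| / Cmax,obs * 100
    pAUC_PE[%] = |pAUC,obs - pAUC,pred| / pAUC,obs * 100

with the customary regulatory reading: for an external validation both
errors <= 10% support predictability, errors <= 20% are inconclusive
("additional data should be provided"), anything above 20% rejects the
model; for internal validation the average absolute PE must stay <= 10%
with no individual PE above 15%.

The module also provides the standard difference/similarity factors f1/f2
for comparing two dissolution profiles (f2 >= 50 conventionally means
similar).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import TimeSeriesProfile, auc_trapezoid, cmax_tmax, resample_linear

__all__ = [
    "PredictionErrorReport",
    "prediction_error",
    "classify",
    "similarity_factors",
]


@dataclass(frozen=True)
class PredictionErrorReport:
    """Cmax and pAUC prediction errors with the assigned verdict."""

    cmax_pe_percent: float
    pauc_pe_percent: float
    pauc_window: tuple[float, float]
    cmax_observed: float
    cmax_predicted: float
    pauc_observed: float
    pauc_predicted: float
    mode: str = "external"  # "external" | "internal"
    verdict: str = "pass"  # "pass" | "inconclusive" | "fail"

    def to_dict(self) -> dict:
        return {
            "cmax_pe_percent": self.cmax_pe_percent,
            "pauc_pe_percent": self.pauc_pe_percent,
            "pauc_window": list(self.pauc_window),
            "cmax_observed": self.cmax_observed,
            "cmax_predicted": self.cmax_predicted,
            "pauc_observed": self.pauc_observed,
            "pauc_predicted": self.pauc_predicted,
            "mode": self.mode,
            "verdict": self.verdict,
        }


def classify(
    cmax_pe_percent, pauc_pe_percent=None, mode: str = "external"
) -> str:
    """Verdict from the two prediction errors.

    External mode: both PEs <= 10% -> ``pass``; both <= 20% ->
    ``inconclusive``; any > 20% -> ``fail``. Internal mode: average
    absolute PE <= 10% and no individual PE > 15% -> ``pass``, else
    ``fail``. Accepts either the two percentages or a
    :class:`PredictionErrorReport` as first argument.
    """
    if isinstance(cmax_pe_percent, PredictionErrorReport):
        report = cmax_pe_percent
        if pauc_pe_percent is not None:
            mode = pauc_pe_percent
        cmax_pe_percent = report.cmax_pe_percent
        pauc_pe_percent = report.pauc_pe_percent
    if mode not in ("external", "internal"):
        raise ValueError("mode must be 'external' or 'internal'")
    pes = (abs(cmax_pe_percent), abs(pauc_pe_percent))
    if mode == "external":
        if max(pes) <= 10.0:
            return "pass"
        if max(pes) <= 20.0:
            return "inconclusive"
        return "fail"
    if np.mean(pes) <= 10.0 and max(pes) <= 15.0:
        return "pass"
    return "fail"


def prediction_error(
    observed: TimeSeriesProfile,
    predicted: TimeSeriesProfile,
    pauc_window: tuple[float, float] | None = None,
    mode: str = "external",
) -> PredictionErrorReport:
    """Cmax and pAUC prediction errors of a predicted plasma curve.

    The predicted profile is resampled onto the observed time grid (the
    observed grid is the ground truth). The pAUC window defaults to the
    full common observation window; both areas are trapezoidal.
    """
    obs = observed.in_time_unit("h")
    pred = predicted.in_time_unit("h")
    lo = max(obs.t_start, pred.t_start)
    hi = min(obs.t_end, pred.t_end)
    if pauc_window is None:
        pauc_window = (lo, hi)
    t0, t1 = pauc_window
    if not (lo - 1e-9 <= t0 < t1 <= hi + 1e-9):
        raise ValueError(
            f"pAUC window [{t0:g}, {t1:g}] h not covered by both profiles "
            f"(common window [{lo:g}, {hi:g}] h)"
        )

    grid = obs.times[(obs.times >= lo - 1e-12) & (obs.times <= hi + 1e-12)]
    pred_on_obs = resample_linear(pred, grid)
    obs_on_grid = resample_linear(obs, grid)

    cmax_obs, _ = cmax_tmax(obs_on_grid)
    cmax_pred, _ = cmax_tmax(pred_on_obs)
    if cmax_obs <= 0:
        raise ZeroDivisionError(
            "observed Cmax is zero; prediction error undefined"
        )
    pauc_obs = auc_trapezoid(obs_on_grid, t0, t1)
    pauc_pred = auc_trapezoid(pred_on_obs, t0, t1)
    if pauc_obs <= 0:
        raise ZeroDivisionError(
            "observed pAUC is zero; prediction error undefined"
        )

    cmax_pe = abs(cmax_obs - cmax_pred) / cmax_obs * 100.0
    pauc_pe = abs(pauc_obs - pauc_pred) / pauc_obs * 100.0
    return PredictionErrorReport(
        cmax_pe_percent=cmax_pe,
        pauc_pe_percent=pauc_pe,
        pauc_window=(float(t0), float(t1)),
        cmax_observed=cmax_obs,
        cmax_predicted=cmax_pred,
        pauc_observed=pauc_obs,
        pauc_predicted=pauc_pred,
        mode=mode,
        verdict=classify(cmax_pe, pauc_pe, mode),
    )


def similarity_factors(
    reference: TimeSeriesProfile, test: TimeSeriesProfile
) -> tuple[float, float]:
    """Difference factor f1 and similarity factor f2 of two dissolution curves.

    Profiles are compared in percent dissolved on the reference time grid
    restricted to the common range (fraction-kind profiles are converted to
    percent automatically); at least three common points are required.

        f1 = 100 * sum|R - T| / sum R
        f2 = 50 * log10(100 / sqrt(1 + mean((R - T)^2)))
    """
    ref = reference.in_time_unit("min")
    tst = test.in_time_unit("min")
    lo = max(ref.t_start, tst.t_start)
    hi = min(ref.t_end, tst.t_end)
    grid = ref.times[(ref.times >= lo - 1e-12) & (ref.times <= hi + 1e-12)]
    if grid.size < 3:
        raise ValueError(
            f"need at least 3 common time points, found {grid.size}"
        )
    r = np.asarray(ref.value_at(grid), dtype=float)
    t = np.asarray(tst.value_at(grid), dtype=float)
    if reference.kind == "fraction":
        r = r * 100.0
    if test.kind == "fraction":
        t = t * 100.0
    sum_r = float(np.sum(r))
    if sum_r <= 0:
        raise ZeroDivisionError("reference profile sums to zero; f1 undefined")
    f1 = 100.0 * float(np.sum(np.abs(r - t))) / sum_r
    f2 = 50.0 * np.log10(100.0 / np.sqrt(1.0 + float(np.mean((r - t) ** 2))))
    return f1, float(f2)
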