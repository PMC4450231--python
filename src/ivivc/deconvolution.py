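"""Unit-impulse-response convolution and numerical deconvolution.

The classical correlation route treats the plasma curve after an oral dose
as the convolution of the absorption-rate input with the disposition
response to a unit intravenous bolus (the unit impulse response, UIR):

    C(t) = F * D * integral_0^t dFABS/dtau * UIR(t - tau) dtau

Here the UIR is an explicit polyexponential (``sum C_i exp(-lambda_i t)``,
coefficients expressed for a stated basis dose). ``convolve`` discretizes
the cumulative fraction absorbed FABS into per-interval increments on a
uniform grid and sums shifted UIR responses (midpoint placement, second
order accurate). ``deconvolve`` inverts the same lower-triangular system by
nonnegative least squares, optionally with a second-difference smoothing
penalty, so the recovered FABS is nondecreasing by construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .profiles import TimeSeriesProfile, resample_linear

__all__ = [
    "UIRSpec",
    "default_uir",
    "uir_evaluate",
    "convolve",
    "deconvolve",
]


@dataclass(frozen=True)
class UIRSpec:
    """Polyexponential unit-impulse response (disposition after i.v. bolus).

    ``terms`` is a sequence of ``(coefficient, exponent)`` pairs: the
    concentration contribution (ng/mL) and rate constant (per hour) of each
    exponential, expressed for a dose of ``dose_basis_mg``. Scaling to other
    doses is linear.
    """

    terms: tuple[tuple[float, float], ...]
    dose_basis_mg: float = 80.0

    def __post_init__(self) -> None:
        terms = tuple((float(c), float(lam)) for c, lam in self.terms)
        object.__setattr__(self, "terms", terms)
        if not terms:
            raise ValueError("UIR needs at least one exponential term")
        if any(lam <= 0 for _, lam in terms):
            raise ValueError("all UIR exponents must be positive")
        if self.dose_basis_mg <= 0:
            raise ValueError("dose basis must be positive")
        # nonnegativity over the evaluation window (sum of exponentials with
        # possibly negative coefficients can dip below zero)
        probe = np.linspace(0.0, 5.0 / min(lam for _, lam in terms), 512)
        if self.unit_values(probe).min() < -1e-9:
            raise ValueError("UIR must be nonnegative for t >= 0")

    def unit_values(self, times_h) -> np.ndarray:
        """``sum C_i exp(-lambda_i t)`` at ``times_h`` (basis-dose scale)."""
        t = np.asarray(times_h, dtype=float)
        out = np.zeros_like(t)
        for c, lam in self.terms:
            out += c * np.exp(-lam * t)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "dose_basis_mg": self.dose_basis_mg,
                "terms": [{"C": c, "lambda": lam} for c, lam in self.terms],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "UIRSpec":
        obj = json.loads(text)
        return cls(
            terms=tuple((t["C"], t["lambda"]) for t in obj["terms"]),
            dose_basis_mg=obj.get("dose_basis_mg", 80.0),
        )


def uir_from_disposition(
    k10_per_h: float,
    k12_per_h: float,
    k21_per_h: float,
    v_central_L: float,
    dose_basis_mg: float = 80.0,
) -> UIRSpec:
    """Biexponential UIR of a two-compartment disposition after i.v. bolus.

    ``C(t) = (D/V) * [(alpha - k21)/(alpha - beta) * exp(-alpha*t)
    + (k21 - beta)/(alpha - beta) * exp(-beta*t)]`` with alpha/beta the
    roots of ``s^2 + (k10 + k12 + k21)*s + k10*k21``. Concentrations in
    ng/mL for the basis dose in mg and volume in litres.
    """
    a = k10_per_h + k12_per_h + k21_per_h
    disc = a * a - 4.0 * k10_per_h * k21_per_h
    if disc <= 0:
        raise ValueError("degenerate disposition: coincident eigenvalues")
    root = np.sqrt(disc)
    alpha, beta = 0.5 * (a + root), 0.5 * (a - root)
    c0 = 1000.0 * dose_basis_mg / v_central_L  # ng/mL
    return UIRSpec(
        terms=(
            (c0 * (alpha - k21_per_h) / (alpha - beta), alpha),
            (c0 * (k21_per_h - beta) / (alpha - beta), beta),
        ),
        dose_basis_mg=dose_basis_mg,
    )


def default_uir() -> UIRSpec:
    """The default biexponential disposition for an 80 mg basis dose.

    Derived from the same two-compartment disposition the synthetic oral PK
    generator uses by default (k10 = 0.35, k12 = 0.35, k21 = 0.25 per hour,
    Vc = 500 L), so the shipped defaults describe one coherent virtual
    drug; not a reproduction of any published intravenous profile.
    """
    return uir_from_disposition(0.35, 0.35, 0.25, 500.0, 80.0)


def uir_evaluate(uir: UIRSpec, times_h) -> TimeSeriesProfile:
    """Evaluate the UIR on ``times_h`` (concentration at the basis dose)."""
    times_h = np.asarray(times_h, dtype=float)
    if np.any(np.diff(times_h) <= 0) or times_h[0] < 0:
        raise ValueError("times must be increasing and nonnegative")
    return TimeSeriesProfile(
        times_h, uir.unit_values(times_h), "ng/mL", "concentration", "h"
    )


def _check_nondecreasing(values: np.ndarray, tol: float = 1e-6) -> None:
    drops = np.diff(values)
    if drops.size and drops.min() < -tol:
        raise ValueError(
            "cumulative fraction absorbed decreases by "
            f"{-drops.min():.3g} (> tolerance {tol}); not a valid "
            "cumulative absorption profile"
        )


def convolve(
    fabs: TimeSeriesProfile,
    uir: UIRSpec,
    dose_mg: float,
    fraction_bioavailable: float = 1.0,
    times_h=None,
    grid_step_h: float = 0.01,
) -> TimeSeriesProfile:
    """Predict the plasma profile from a cumulative fraction-absorbed curve.

    ``fabs`` must be (near-)nondecreasing; beyond its last knot the terminal
    value is held (absorption finished). The result is evaluated at
    ``times_h`` (default: the fabs grid in hours).
    """
    fabs_h = fabs.in_time_unit("h")
    _check_nondecreasing(fabs_h.values)
    if times_h is None:
        times_h = fabs_h.times
    times_h = np.asarray(times_h, dtype=float)

    h = grid_step_h
    n = max(int(np.ceil(times_h[-1] / h)), 1)
    grid = np.arange(n + 1) * h
    f = np.interp(grid, fabs_h.times, fabs_h.values)
    df = np.diff(f, prepend=0.0)  # df[0] = F(0): mass absorbed before t=0+

    scale = fraction_bioavailable * dose_mg / uir.dose_basis_mg
    u_mid = uir.unit_values(grid + 0.5 * h)
    conc = df[0] * uir.unit_values(grid)
    if n >= 1:
        # contribution at grid index m from increments k>=1: df[k]*U((m-k)h + h/2)
        tail = np.convolve(df[1:], u_mid)[:n]
        conc[1:] += tail
    conc *= scale
    out = np.interp(times_h, grid, conc)
    return TimeSeriesProfile(times_h, out, "ng/mL", "concentration", "h")


def deconvolve(
    plasma: TimeSeriesProfile,
    uir: UIRSpec,
    dose_mg: float,
    grid_step_h: float = 0.05,
    smoothing_lambda: float = 0.0,
    fraction_bioavailable: float = 1.0,
    nonnegative: bool = True,
) -> TimeSeriesProfile:
    """Estimate the cumulative fraction absorbed from a plasma profile.

    Solves the discrete convolution system of :func:`convolve` for the
    per-interval absorption increments on a uniform grid of step
    ``grid_step_h`` — nonnegative least squares by default, so the returned
    cumulative curve is nondecreasing — with an optional second-difference
    penalty weighted by ``smoothing_lambda``. The terminal value is reported
    as estimated, not forced to 1.
    """
    if grid_step_h <= 0:
        raise ValueError("grid step must be positive")
    plasma_h = plasma.in_time_unit("h")
    n = max(int(np.ceil(plasma_h.t_end / grid_step_h)), 1)
    grid = np.arange(n + 1) * grid_step_h
    c_obs = np.interp(grid, plasma_h.times, plasma_h.values)

    scale = fraction_bioavailable * dose_mg / uir.dose_basis_mg
    # lower-triangular response matrix: column 0 is a bolus at t=0, column k
    # an absorption increment during interval k (midpoint response)
    a = np.zeros((n + 1, n + 1))
    a[:, 0] = uir.unit_values(grid)
    u_mid = uir.unit_values(grid + 0.5 * grid_step_h)
    for k in range(1, n + 1):
        a[k:, k] = u_mid[: n + 1 - k]
    a *= scale

    rhs = c_obs
    if smoothing_lambda > 0:
        d2 = np.zeros((n - 1, n + 1))
        for i in range(n - 1):
            d2[i, i : i + 3] = (1.0, -2.0, 1.0)
        a = np.vstack([a, np.sqrt(smoothing_lambda) * d2])
        rhs = np.concatenate([rhs, np.zeros(n - 1)])

    if nonnegative:
        try:
            x, _ = nnls(a, rhs, maxiter=50 * (n + 1))
        except Exception as err:  # pragma: no cover - scipy failure path
            raise RuntimeError(
                "deconvolution system could not be solved; consider "
                "smoothing_lambda > 0"
            ) from err
    else:
        x, *_ = np.linalg.lstsq(a, rhs, rcond=None)
        if x.min() < -1e-9:
            warnings.warn(
                "deconvolved absorption increments contain negative values "
                f"(min {x.min():.3g}); cumulative curve may be non-monotone"
            )

    fabs = np.cumsum(x)
    if fabs.size and fabs[-1] > 1.05:
        warnings.warn(
            f"deconvolved terminal fraction absorbed {fabs[-1]:.3f} exceeds "
            "1.05; check the UIR scale or the bioavailable fraction"
        )
    return TimeSeriesProfile(
        grid,
        np.clip(fabs, 0.0, None),
        "fraction of dose",
        "fraction",
        "h",
    )
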