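"""In-silico four-compartment dynamic dissolution experiment.

The simulator replays a fasted-state gastrointestinal transit protocol:
a stomach dosed with the formulation plus 200 mL of water, followed by
duodenum, jejunum and ileum compartments (33 mL resting volume each) and a
collection canister. Chyme moves downstream on a plug-flow volume schedule —
the stomach empties its mobile volume linearly over its residence time, and
each intestinal compartment re-emits the volume it received one residence
time earlier — while compartment contents stay well mixed, so each
compartment's volume rises, plateaus and returns exactly to its resting
value and the full 200 mL of mobile fluid reaches the canister.

Dissolution follows a cube-root (z-factor) Noyes-Whitney surrogate with a
pH-dependent weak-acid solubility (Henderson-Hasselbalch), optionally capped
by a salting-out ceiling. Buffered formulations raise the gastric pH at
disintegration; nonbuffered ones leave it at the fasted set point, where a
weak acid of ~1 ug/mL intrinsic solubility effectively cannot dissolve.

The module also provides a closed-form two-compartment oral PK generator
used as a synthetic stand-in for mean plasma profiles when exercising the
correlation machinery against known ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .profiles import (
    CompartmentalDissolutionDataset,
    CompartmentRecord,
    ConfigurationError,
    SamplingEvent,
    TimeSeriesProfile,
)

__all__ = [
    "CompartmentSpec",
    "FormulationSpec",
    "MethodSpec",
    "OralPKParams",
    "solubility_at_ph",
    "simulate_transit",
    "generate_synthetic_pk",
]


@dataclass(frozen=True)
class CompartmentSpec:
    """Static description of one compartment of the apparatus.

    ``starting_volume_mL`` is the resting (residual) volume; for the stomach
    the co-administered dosing fluid (``coadministered_volume_mL``, 200 mL of
    water in the fasted protocol) is added on top at t = 0 and emptied
    linearly over the residence time. ``ph_setpoint`` is either a clamped
    value (intestinal compartments, maintained by the pH controller) or
    ``"free"`` (stomach: baseline 2.4, perturbed by a buffered formulation).
    Enzyme and bile levels are descriptive metadata.
    """

    name: str
    starting_volume_mL: float
    residence_time_min: float
    ph_setpoint: float | str = "free"
    coadministered_volume_mL: float = 0.0
    pepsin_mg_per_mL: float = 0.0
    lipase_U_per_mL: float = 0.0
    bile_salts_mM: float = 0.0

    def __post_init__(self) -> None:
        if self.starting_volume_mL <= 0:
            raise ValueError(f"{self.name}: starting volume must be positive")
        if self.residence_time_min <= 0:
            raise ValueError(f"{self.name}: residence time must be positive")
        if isinstance(self.ph_setpoint, str) and self.ph_setpoint != "free":
            raise ValueError("ph_setpoint must be a number or 'free'")
        if not isinstance(self.ph_setpoint, str) and not (
            1.0 <= self.ph_setpoint <= 9.0
        ):
            raise ValueError("ph_setpoint must lie in [1, 9]")


#: fasted-state gastric baseline pH
GASTRIC_BASELINE_PH = 2.4


def default_compartments() -> tuple[CompartmentSpec, ...]:
    """The fasted-state protocol compartments (stomach -> ileum)."""
    return (
        CompartmentSpec(
            "stomach", 30.0, 30.0, "free",
            coadministered_volume_mL=200.0, pepsin_mg_per_mL=1.3,
        ),
        CompartmentSpec(
            "duodenum", 33.0, 10.0, 6.5, lipase_U_per_mL=70, bile_salts_mM=3
        ),
        CompartmentSpec(
            "jejunum", 33.0, 60.0, 6.6, lipase_U_per_mL=70, bile_salts_mM=3
        ),
        CompartmentSpec(
            "ileum", 33.0, 90.0, 7.4, lipase_U_per_mL=70, bile_salts_mM=3
        ),
    )


@dataclass(frozen=True)
class FormulationSpec:
    """Formulation attributes that drive dissolution behavior."""

    formulation_id: str = "formulation"
    dose_mg: float = 80.0
    api_form: str = "amorphous"  # "amorphous" | "crystal"
    buffered: bool = False
    pKa: float = 4.33
    intrinsic_solubility_mg_per_mL: float = 1e-3
    dissolution_rate_coeff_z: float = 0.01  # per (mg^(1/3) min mL^-1)
    disintegration_time_min: float = 3.0
    solubility_ceiling_mg_per_mL: float | None = None
    gastric_ph_after_buffer: float = 7.5

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise ValueError("dose_mg must be nonnegative")
        if self.api_form not in ("amorphous", "crystal"):
            raise ValueError("api_form must be 'amorphous' or 'crystal'")
        if self.intrinsic_solubility_mg_per_mL <= 0:
            raise ValueError("intrinsic solubility must be positive")
        if self.dissolution_rate_coeff_z <= 0:
            raise ValueError("z coefficient must be positive")
        if self.disintegration_time_min < 0:
            raise ValueError("disintegration time must be nonnegative")
        if self.buffered and not (7.0 <= self.gastric_ph_after_buffer <= 8.0):
            raise ValueError(
                "a buffered formulation must raise gastric pH into [7, 8]"
            )


def default_sampling_times(total_duration_min: float) -> tuple[float, ...]:
    """Manual sampling schedule: every 5 min to 43 min, then every 15 min."""
    early = list(np.arange(3.0, min(43.0, total_duration_min) + 1e-9, 5.0))
    late = [t for t in np.arange(58.0, total_duration_min + 1e-9, 15.0)]
    times = early + late
    if not times or times[-1] < total_duration_min - 1e-9:
        times.append(total_duration_min)
    return tuple(times)


@dataclass(frozen=True)
class MethodSpec:
    """The dissolution protocol: compartments, duration, sampling, stepping."""

    compartments: tuple[CompartmentSpec, ...] = field(
        default_factory=default_compartments
    )
    total_duration_min: float = 215.0
    sampling_times_min: tuple[float, ...] | None = None
    withdrawal_mL: float = 1.0
    integration_step_min: float = 0.25

    def __post_init__(self) -> None:
        object.__setattr__(self, "compartments", tuple(self.compartments))
        if self.total_duration_min <= 0:
            raise ValueError("total duration must be positive")
        if self.withdrawal_mL < 0:
            raise ValueError("withdrawal volume must be nonnegative")
        if self.sampling_times_min is None:
            object.__setattr__(
                self,
                "sampling_times_min",
                default_sampling_times(self.total_duration_min),
            )
        st = np.asarray(self.sampling_times_min, dtype=float)
        if st.size == 0 or np.any(np.diff(st) <= 0):
            raise ValueError("sampling times must be a nonempty increasing sequence")
        if st[0] < 0 or st[-1] > self.total_duration_min + 1e-9:
            raise ValueError("sampling times must lie within the run duration")
        object.__setattr__(
            self, "sampling_times_min", tuple(float(x) for x in st)
        )


def solubility_at_ph(
    intrinsic_solubility: float,
    pKa: float,
    ph: float,
    ceiling: float | None = None,
) -> float:
    """Weak-acid saturation solubility at ``ph`` (mg/mL).

    Henderson-Hasselbalch total solubility ``S0 * (1 + 10**(pH - pKa))``,
    optionally capped by a salting-out ceiling (counter-ion effect of a
    carbonate buffer excipient).
    """
    if intrinsic_solubility <= 0:
        raise ValueError("intrinsic solubility must be positive")
    s = intrinsic_solubility * (1.0 + 10.0 ** (ph - pKa))
    if ceiling is not None:
        s = min(s, ceiling)
    return s


def simulate_transit(
    method: MethodSpec,
    formulation: FormulationSpec,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> CompartmentalDissolutionDataset:
    """Run the mass-balance transit/dissolution simulation.

    Fixed-step explicit integration. Per step: (1) dissolution of suspended
    drug at rate ``z * U**(2/3) * (S(pH) - C) * V`` clipped at saturation
    (no dissolution before the disintegration time); (2) plug-flow volume
    transfer carrying dissolved drug at bulk concentration and undissolved
    drug as a homogeneous suspension; (3) pH bookkeeping (intestines clamped,
    stomach free, jumping to the buffered set point at disintegration);
    (4) sample withdrawals at the protocol times, recorded pre-withdrawal
    and logged to the ledger.

    Dissolved mass is provenance-tagged by the compartment in which it
    dissolved so that cumulative profiles can exclude compartments; the
    canister's provenance breakdown is returned on the dataset. Optional
    multiplicative lognormal noise (``noise_sigma``) emulates duplicate
    experimental runs and is applied to observed dissolved amounts only.
    """
    comps = method.compartments
    n = len(comps)
    dt = method.integration_step_min
    if dt <= 0:
        raise ConfigurationError("integration step must be positive")
    min_res = min(c.residence_time_min for c in comps)
    if dt > min_res / 10.0 + 1e-12:
        raise ConfigurationError(
            f"integration step {dt} min exceeds stability guard "
            f"(smallest residence time / 10 = {min_res / 10.0:g} min)"
        )

    n_steps = int(round(method.total_duration_min / dt))
    # sampling times snapped onto the integration grid
    sample_steps = {
        int(round(t / dt)): t for t in method.sampling_times_min
    }

    volume = np.array(
        [c.starting_volume_mL + c.coadministered_volume_mL for c in comps]
    )
    dissolved = np.zeros((n, n))  # [compartment, origin]
    undissolved = np.zeros(n)
    undissolved[0] = formulation.dose_mg
    can_volume = 0.0
    can_dissolved = np.zeros(n)  # by origin
    can_undissolved = 0.0
    ledger: list[SamplingEvent] = []
    withdrawn_dissolved_total = 0.0

    ph = np.empty(n)
    for i, c in enumerate(comps):
        ph[i] = (
            GASTRIC_BASELINE_PH
            if isinstance(c.ph_setpoint, str)
            else c.ph_setpoint
        )

    # plug-flow bookkeeping: inflow received by each compartment per step
    inflow_hist = np.zeros((n, n_steps + 1))
    delay = [max(1, int(round(c.residence_time_min / dt))) for c in comps]
    gastric_rate = comps[0].coadministered_volume_mL / comps[0].residence_time_min
    mobile_remaining = comps[0].coadministered_volume_mL

    disintegrated = formulation.disintegration_time_min <= 0.0
    if disintegrated and formulation.buffered:
        ph[0] = formulation.gastric_ph_after_buffer

    rec_t: list[float] = []
    rec_dissolved: list[np.ndarray] = []
    rec_volume: list[np.ndarray] = []
    rec_ph: list[np.ndarray] = []
    rec_undissolved: list[np.ndarray] = []
    rec_can: list[tuple[float, np.ndarray, float]] = []

    def record(t: float) -> None:
        rec_t.append(t)
        rec_dissolved.append(dissolved.sum(axis=1).copy())
        rec_volume.append(volume.copy())
        rec_ph.append(ph.copy())
        rec_undissolved.append(undissolved.copy())
        rec_can.append((can_volume, can_dissolved.copy(), can_undissolved))

    if 0 in sample_steps:
        record(sample_steps[0])

    for step in range(1, n_steps + 1):
        t0 = (step - 1) * dt

        # disintegration / gastric pH event
        if not disintegrated and t0 >= formulation.disintegration_time_min - 1e-9:
            disintegrated = True
            if formulation.buffered:
                ph[0] = formulation.gastric_ph_after_buffer

        # dissolution (well-mixed suspension; tablet inert pre-disintegration)
        z = formulation.dissolution_rate_coeff_z

        def dissolve(step_min: float) -> None:
            for i in range(n):
                if i == 0 and not disintegrated:
                    continue
                u = undissolved[i]
                if u <= 0 or volume[i] <= 0:
                    continue
                s = solubility_at_ph(
                    formulation.intrinsic_solubility_mg_per_mL,
                    formulation.pKa,
                    ph[i],
                    formulation.solubility_ceiling_mg_per_mL,
                )
                # exponential step: with U frozen, dissolved mass relaxes
                # toward saturation as dM/dt = z*U^(2/3)*(S*V - M)
                headroom = max(s * volume[i] - dissolved[i].sum(), 0.0)
                k_rel = z * u ** (2.0 / 3.0)
                dm = headroom * -np.expm1(-k_rel * step_min)
                dm = min(dm, u)
                dissolved[i, i] += dm
                undissolved[i] -= dm

        # Strang splitting: half-step dissolution around the transfer
        dissolve(0.5 * dt)

        # plug-flow transfers, upstream to downstream, using start-of-phase
        # state for all concentrations
        out_vol = np.zeros(n)
        if mobile_remaining > 1e-12:
            dv = min(gastric_rate * dt, mobile_remaining)
            out_vol[0] = dv
        for i in range(1, n):
            if step > delay[i]:
                out_vol[i] = inflow_hist[i, step - delay[i]]

        moved_dissolved = np.zeros((n, n))
        moved_undissolved = np.zeros(n)
        for i in range(n):
            if out_vol[i] <= 0 or volume[i] <= 0:
                out_vol[i] = max(out_vol[i], 0.0)
                continue
            frac = min(out_vol[i] / volume[i], 1.0)
            moved_dissolved[i] = dissolved[i] * frac
            if i > 0 or disintegrated:
                moved_undissolved[i] = undissolved[i] * frac

        if out_vol[0] > 0:
            mobile_remaining -= out_vol[0]
        for i in range(n):
            if out_vol[i] <= 0:
                continue
            volume[i] -= out_vol[i]
            dissolved[i] -= moved_dissolved[i]
            undissolved[i] -= moved_undissolved[i]
            if i + 1 < n:
                volume[i + 1] += out_vol[i]
                dissolved[i + 1] += moved_dissolved[i]
                undissolved[i + 1] += moved_undissolved[i]
                inflow_hist[i + 1, step] += out_vol[i]
            else:
                can_volume += out_vol[i]
                can_dissolved += moved_dissolved[i]
                can_undissolved += moved_undissolved[i]

        dissolve(0.5 * dt)

        # sampling
        if step in sample_steps:
            t_sample = sample_steps[step]
            record(t_sample)
            w = method.withdrawal_mL
            if w > 0:
                for i, c in enumerate(comps):
                    take = min(w, max(volume[i] - 1e-9, 0.0))
                    if take <= 0:
                        continue
                    frac = take / volume[i]
                    removed = dissolved[i].sum() * frac
                    dissolved[i] *= 1.0 - frac
                    volume[i] -= take
                    withdrawn_dissolved_total += removed
                    ledger.append(
                        SamplingEvent(t_sample, c.name, take, removed)
                    )

    # assemble dataset
    times = np.asarray(rec_t)
    dis = np.vstack(rec_dissolved)  # [sample, compartment]
    vol = np.vstack(rec_volume)
    phs = np.vstack(rec_ph)
    und = np.vstack(rec_undissolved)
    can_vol = np.array([c[0] for c in rec_can])
    can_dis = np.vstack([c[1] for c in rec_can])  # [sample, origin]
    can_und = np.array([c[2] for c in rec_can])

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        dis = dis * rng.lognormal(0.0, noise_sigma, size=dis.shape)
        can_dis = can_dis * rng.lognormal(0.0, noise_sigma, size=can_dis.shape)

    def profile(vals, unit, kind) -> TimeSeriesProfile:
        return TimeSeriesProfile(times, vals, unit, kind, "min")

    compartments = {}
    for i, c in enumerate(comps):
        compartments[c.name] = CompartmentRecord(
            dissolved_amount=profile(dis[:, i], "mg", "amount"),
            volume=profile(vol[:, i], "mL", "amount"),
            ph=profile(phs[:, i], "pH", "concentration"),
            undissolved_amount=profile(und[:, i], "mg", "amount"),
        )
    canister = CompartmentRecord(
        dissolved_amount=profile(can_dis.sum(axis=1), "mg", "amount"),
        volume=profile(can_vol, "mL", "amount"),
        # the canister is unregulated; tag it with the last gut setpoint
        ph=profile(np.full_like(can_vol, phs[-1, -1]), "pH", "concentration"),
        undissolved_amount=profile(can_und, "mg", "amount"),
    )
    canister_origin = {
        c.name: profile(can_dis[:, i], "mg", "amount")
        for i, c in enumerate(comps)
    }
    return CompartmentalDissolutionDataset(
        formulation_id=formulation.formulation_id,
        dose_mg=formulation.dose_mg if formulation.dose_mg > 0 else 1.0,
        compartments=compartments,
        canister=canister,
        sampling_events=tuple(ledger),
        canister_origin=canister_origin,
    )


# ---------------------------------------------------------------------------
# synthetic oral PK ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OralPKParams:
    """Two-compartment first-order-absorption model parameters.

    Rates per hour, central volume in litres; concentrations come out in
    ng/mL for a dose in mg. Defaults give an early peak (Tmax ~ 0.8 h) of
    realistic magnitude for a high-first-pass statin mean profile.
    """

    dose_mg: float = 80.0
    ka_per_h: float = 2.2
    k10_per_h: float = 0.35
    k12_per_h: float = 0.35
    k21_per_h: float = 0.25
    v_central_L: float = 500.0
    tlag_h: float = 0.0
    f_bioavailable: float = 1.0

    def __post_init__(self) -> None:
        if min(self.ka_per_h, self.k10_per_h) <= 0:
            raise ValueError("ka and k10 must be positive")
        if min(self.k12_per_h, self.k21_per_h) < 0:
            raise ValueError("k12 and k21 must be nonnegative")
        if self.v_central_L <= 0:
            raise ValueError("central volume must be positive")


def generate_synthetic_pk(params: OralPKParams, times_h) -> TimeSeriesProfile:
    """Closed-form central-compartment concentration on ``times_h``.

    The triexponential solution of the standard two-compartment model with
    first-order absorption and lag time. Near-coincident eigenvalues are
    perturbed by 1e-9 (with a warning) to keep the partial fractions finite.
    """
    times_h = np.asarray(times_h, dtype=float)
    if np.any(np.diff(times_h) <= 0):
        raise ValueError("times must be strictly increasing")
    ka, k10 = params.ka_per_h, params.k10_per_h
    k12, k21 = params.k12_per_h, params.k21_per_h

    a = k10 + k12 + k21
    disc = a * a - 4.0 * k10 * k21
    alpha = 0.5 * (a + np.sqrt(max(disc, 0.0)))
    beta = 0.5 * (a - np.sqrt(max(disc, 0.0)))
    eps = 1e-9
    if abs(alpha - beta) < eps:
        warnings.warn("coincident disposition eigenvalues; perturbing by 1e-9")
        alpha += eps
    if abs(ka - alpha) < eps or abs(ka - beta) < eps:
        warnings.warn("absorption rate coincides with a disposition "
                      "eigenvalue; perturbing by 1e-9")
        ka += eps

    coef_a = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    coef_b = (k21 - beta) / ((ka - beta) * (alpha - beta))
    coef_c = (k21 - ka) / ((alpha - ka) * (beta - ka))

    tp = np.maximum(times_h - params.tlag_h, 0.0)
    scale = (
        1000.0
        * params.f_bioavailable
        * params.dose_mg
        * ka
        / params.v_central_L
    )  # mg/L -> ng/mL
    conc = scale * (
        coef_a * np.exp(-alpha * tp)
        + coef_b * np.exp(-beta * tp)
        + coef_c * np.exp(-ka * tp)
    )
    conc[times_h <= params.tlag_h] = 0.0
    conc = np.maximum(conc, 0.0)
    return TimeSeriesProfile(times_h, conc, "ng/mL", "concentration", "h")
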