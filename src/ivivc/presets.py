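"""Shipped method and formulation presets, and their YAML round trip.

Two formulation families mirror the two immediate-release design
strategies studied with the apparatus:

* ``buffered_crystal`` — crystalline drug co-formulated with a carbonate
  buffer that raises the gastric pH to 7-8, enabling early gastric
  dissolution but capping solubility through the counter-ion salting-out
  effect;
* ``nonbuffered_amorphous`` — amorphous drug with no buffer: nothing
  dissolves at gastric pH, dissolution starts in the intestinal
  compartments, and the overall dissolved fraction ends higher.

``formulation_family`` derives slow/medium/fast variants (scaled
dissolution-rate coefficient) from either preset, giving the minimum
three-release-rate set a correlation model is built and validated on.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .transit import (
    CompartmentSpec,
    FormulationSpec,
    MethodSpec,
    default_compartments,
)

__all__ = [
    "buffered_crystal",
    "nonbuffered_amorphous",
    "formulation_family",
    "default_method",
    "truncated_method",
    "load_method_yaml",
    "dump_method_yaml",
    "load_formulation_yaml",
    "dump_formulation_yaml",
]


def buffered_crystal(formulation_id: str = "buffered_crystal") -> FormulationSpec:
    """Crystalline, carbonate-buffered 80 mg tablet preset."""
    return FormulationSpec(
        formulation_id=formulation_id,
        dose_mg=80.0,
        api_form="crystal",
        buffered=True,
        intrinsic_solubility_mg_per_mL=4e-4,
        dissolution_rate_coeff_z=0.01,
        solubility_ceiling_mg_per_mL=0.10,
        gastric_ph_after_buffer=7.5,
    )


def nonbuffered_amorphous(
    formulation_id: str = "nonbuffered_amorphous",
) -> FormulationSpec:
    """Amorphous, unbuffered 80 mg tablet preset."""
    return FormulationSpec(
        formulation_id=formulation_id,
        dose_mg=80.0,
        api_form="amorphous",
        buffered=False,
        intrinsic_solubility_mg_per_mL=1e-3,
        dissolution_rate_coeff_z=0.01,
        solubility_ceiling_mg_per_mL=None,
    )


def formulation_family(
    base: FormulationSpec,
    z_multipliers: tuple[float, ...] = (0.5, 1.0, 2.0),
    labels: tuple[str, ...] = ("slow", "medium", "fast"),
) -> list[FormulationSpec]:
    """Slow/medium/fast release-rate variants of a base formulation."""
    if len(z_multipliers) != len(labels):
        raise ValueError("one label per multiplier required")
    return [
        replace(
            base,
            formulation_id=f"{base.formulation_id}_{label}",
            dissolution_rate_coeff_z=base.dissolution_rate_coeff_z * mult,
        )
        for mult, label in zip(z_multipliers, labels)
    ]


def default_method(**overrides) -> MethodSpec:
    """The full-length 215 min fasted-state protocol."""
    return MethodSpec(**overrides)


def truncated_method(**overrides) -> MethodSpec:
    """The shortened protocol terminated after the 43 min sampling point."""
    overrides.setdefault("total_duration_min", 43.0)
    return MethodSpec(**overrides)


# ---------------------------------------------------------------------------
# YAML round trip
# ---------------------------------------------------------------------------


def dump_method_yaml(method: MethodSpec, path) -> None:
    doc = {
        "compartments": [
            {
                "name": c.name,
                "start_volume_mL": c.starting_volume_mL,
                "residence_min": c.residence_time_min,
                "ph": c.ph_setpoint,
                "coadministered_mL": c.coadministered_volume_mL,
                "pepsin_mg_per_mL": c.pepsin_mg_per_mL,
                "lipase_U_per_mL": c.lipase_U_per_mL,
                "bile_salts_mM": c.bile_salts_mM,
            }
            for c in method.compartments
        ],
        "duration_min": method.total_duration_min,
        "sampling_min": list(method.sampling_times_min),
        "withdrawal_mL": method.withdrawal_mL,
        "step_min": method.integration_step_min,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_method_yaml(path) -> MethodSpec:
    doc = yaml.safe_load(Path(path).read_text())
    comps = tuple(
        CompartmentSpec(
            name=c["name"],
            starting_volume_mL=c["start_volume_mL"],
            residence_time_min=c["residence_min"],
            ph_setpoint=c.get("ph", "free"),
            coadministered_volume_mL=c.get("coadministered_mL", 0.0),
            pepsin_mg_per_mL=c.get("pepsin_mg_per_mL", 0.0),
            lipase_U_per_mL=c.get("lipase_U_per_mL", 0.0),
            bile_salts_mM=c.get("bile_salts_mM", 0.0),
        )
        for c in doc.get("compartments", [])
    ) or default_compartments()
    return MethodSpec(
        compartments=comps,
        total_duration_min=doc["duration_min"],
        sampling_times_min=tuple(doc["sampling_min"])
        if doc.get("sampling_min")
        else None,
        withdrawal_mL=doc.get("withdrawal_mL", 1.0),
        integration_step_min=doc.get("step_min", 0.25),
    )


_FORMULATION_KEYS = (
    "formulation_id",
    "dose_mg",
    "api_form",
    "buffered",
    "pKa",
    "intrinsic_solubility_mg_per_mL",
    "dissolution_rate_coeff_z",
    "disintegration_time_min",
    "solubility_ceiling_mg_per_mL",
    "gastric_ph_after_buffer",
)


def dump_formulation_yaml(formulation: FormulationSpec, path) -> None:
    doc = {k: getattr(formulation, k) for k in _FORMULATION_KEYS}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_formulation_yaml(path) -> FormulationSpec:
    doc = yaml.safe_load(Path(path).read_text())
    kwargs = {k: doc[k] for k in _FORMULATION_KEYS if k in doc}
    return FormulationSpec(**kwargs)
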