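"""Tissue property database with age-dependent scaling.

Dielectric and perfusion properties of adult tissues change markedly with
age: a young child's tissues have higher water content, hence higher
relative permittivity and electrical conductivity at a given frequency, and
higher basal perfusion.  This module stores, per tissue, the 3.5-year-old
("child") property values at the 7 T proton frequency together with the
age-conversion ratios (child / adult), from which adult values are derived,
plus the thermal columns the bioheat solver needs (density, heat capacity,
thermal conductivity, metabolic heat rate).

Liquid tissues (blood, CSF, vitreous and aqueous humor, bile, urine,
intestine contents) are age-invariant: all their ratios are 1.  Density,
thermal conductivity and specific heat capacity carry no age dependency.

The packaged fixture ``data/tissue_properties_7t.csv`` holds the child
values and ratios at 297.2 MHz; its thermal columns are representative
defaults that users may override with their own table.  The drive frequency
is stored with the table; solvers take their frequency from configuration
(the package's study default is 297.2 MHz).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TissueProperties",
    "BloodConstants",
    "TissueTable",
    "load_tissue_table",
    "default_tissue_table",
    "scale_properties_to_age",
    "perfusion_to_volumetric",
    "TABLE_FREQUENCY_HZ",
]

#: Frequency (Hz) at which the packaged dielectric table is tabulated.
TABLE_FREQUENCY_HZ = 297.2e6

REQUIRED_COLUMNS = (
    "tissue", "is_liquid", "density_kg_m3", "heat_capacity_J_kg_C",
    "thermal_conductivity_W_m_C", "metabolic_rate_W_kg",
    "permittivity_ratio", "permittivity_child",
    "conductivity_ratio", "conductivity_child_S_m",
    "perfusion_ratio", "perfusion_child_ml_min_kg",
)


@dataclass(frozen=True)
class TissueProperties:
    """Electrical/thermal/physiological properties of one tissue.

    ``permittivity``/``conductivity``/``perfusion`` hold the values for the
    age this instance represents; the ``*_ratio`` fields are the child/adult
    conversion ratios carried along so that :func:`scale_properties_to_age`
    can derive child properties from an adult instance.
    """

    name: str
    permittivity: float          # relative, dimensionless
    conductivity: float          # S/m
    density: float               # kg/m^3
    heat_capacity: float         # J/(kg C)
    thermal_conductivity: float  # W/(m C)
    metabolic_rate: float        # W/kg
    perfusion: float             # ml/(min kg)
    permittivity_ratio: float = 1.0
    conductivity_ratio: float = 1.0
    perfusion_ratio: float = 1.0
    is_liquid: bool = False

    def __post_init__(self) -> None:
        if self.permittivity < 1:
            raise ValueError(f"{self.name}: relative permittivity must be >= 1")
        if self.conductivity < 0:
            raise ValueError(f"{self.name}: conductivity must be >= 0")
        if self.density <= 0 or self.heat_capacity <= 0:
            raise ValueError(f"{self.name}: density and heat capacity must be positive")
        if self.thermal_conductivity < 0 or self.metabolic_rate < 0 or self.perfusion < 0:
            raise ValueError(f"{self.name}: thermal conductivity, metabolic rate and perfusion must be >= 0")
        if self.is_liquid and not (
            self.permittivity_ratio == self.conductivity_ratio == 1.0
        ):
            # liquid dielectric properties carry no age dependency; the
            # perfusion ratio applies to the surrounding perfused space and
            # is allowed to differ (e.g. CSF)
            raise ValueError(
                f"{self.name}: liquid tissues must have dielectric age ratios = 1.0")


@dataclass(frozen=True)
class BloodConstants:
    """Blood parameters of the perfusion heat-sink term."""

    density: float = 1050.0       # kg/m^3
    heat_capacity: float = 3617.0  # J/(kg C)
    temperature: float = 37.0     # C

    def __post_init__(self) -> None:
        if min(self.density, self.heat_capacity, self.temperature) <= 0:
            raise ValueError("blood constants must be positive")
        if not 30.0 <= self.temperature <= 40.0:
            raise ValueError("blood temperature must be physiologic (30-40 C)")


class TissueTable:
    """Validated per-tissue property table (child values + age ratios)."""

    def __init__(self, frame: pd.DataFrame, frequency_hz: float = TABLE_FREQUENCY_HZ):
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"tissue table missing columns: {missing}")
        frame = frame.copy()
        frame["tissue"] = frame["tissue"].astype(str)
        if frame["tissue"].duplicated().any():
            dup = frame.loc[frame["tissue"].duplicated(), "tissue"].tolist()
            raise ValueError(f"duplicate tissue rows: {dup}")
        self.frame = frame.set_index("tissue", drop=False)
        self.frequency_hz = float(frequency_hz)
        for name in self.frame.index:
            self.child(name)  # runs the per-row invariant checks

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, name: str) -> bool:
        return name in self.frame.index

    @property
    def names(self) -> list[str]:
        return list(self.frame.index)

    def _row(self, name: str) -> pd.Series:
        try:
            return self.frame.loc[name]
        except KeyError:
            raise KeyError(f"unknown tissue {name!r}") from None

    def child(self, name: str) -> TissueProperties:
        """Properties at the model age (as tabulated)."""
        r = self._row(name)
        return TissueProperties(
            name=name,
            permittivity=float(r["permittivity_child"]),
            conductivity=float(r["conductivity_child_S_m"]),
            density=float(r["density_kg_m3"]),
            heat_capacity=float(r["heat_capacity_J_kg_C"]),
            thermal_conductivity=float(r["thermal_conductivity_W_m_C"]),
            metabolic_rate=float(r["metabolic_rate_W_kg"]),
            perfusion=float(r["perfusion_child_ml_min_kg"]),
            permittivity_ratio=float(r["permittivity_ratio"]),
            conductivity_ratio=float(r["conductivity_ratio"]),
            perfusion_ratio=float(r["perfusion_ratio"]),
            is_liquid=bool(int(r["is_liquid"])),
        )

    def adult(self, name: str) -> TissueProperties:
        """Adult properties, derived as child value / conversion ratio.

        A zero ratio (tabulated for unperfused structures) maps to an adult
        value of zero.
        """
        c = self.child(name)
        def un(v: float, ratio: float) -> float:
            return v / ratio if ratio > 0 else 0.0
        return replace(
            c,
            permittivity=max(1.0, un(c.permittivity, c.permittivity_ratio)),
            conductivity=un(c.conductivity, c.conductivity_ratio),
            perfusion=un(c.perfusion, c.perfusion_ratio),
        )


def load_tissue_table(path: str | Path, frequency_hz: float = TABLE_FREQUENCY_HZ) -> TissueTable:
    """Load and validate a tissue-property CSV (see ``REQUIRED_COLUMNS``)."""
    return TissueTable(pd.read_csv(path), frequency_hz=frequency_hz)


def default_tissue_table() -> TissueTable:
    """The packaged 297.2 MHz tissue table (69 tissues)."""
    with resources.as_file(
        resources.files("voxdosim.data") / "tissue_properties_7t.csv"
    ) as p:
        return load_tissue_table(p)


def scale_properties_to_age(adult: TissueProperties) -> TissueProperties:
    """Apply the age-conversion ratios to adult properties.

    Child permittivity / conductivity / perfusion are the adult values times
    their respective ratios; density, thermal conductivity and heat capacity
    are unchanged (no age dependency), and liquid tissues are unchanged
    entirely (all ratios 1).
    """
    return replace(
        adult,
        permittivity=adult.permittivity * adult.permittivity_ratio,
        conductivity=adult.conductivity * adult.conductivity_ratio,
        perfusion=adult.perfusion * adult.perfusion_ratio,
    )


def perfusion_to_volumetric(perfusion_ml_min_kg: float | np.ndarray,
                            tissue_density: float | np.ndarray) -> float | np.ndarray:
    """Convert perfusion W [ml min^-1 kg^-1] to the volumetric rate omega [s^-1].

    omega = W * 1e-6 [m^3/ml] / 60 [s/min] * rho_tissue [kg/m^3], i.e. the
    blood volume flow per tissue volume per second, as used in the Pennes
    sink term rho_b * c_b * omega * (T - T_b).
    """
    w = np.asarray(perfusion_ml_min_kg, dtype=float)
    if np.any(w < 0):
        raise ValueError("perfusion must be >= 0")
    out = w * 1e-6 / 60.0 * np.asarray(tissue_density, dtype=float)
    return float(out) if out.ndim == 0 else out
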