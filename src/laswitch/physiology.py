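"""Chemostat growth-parameter calculations from off-gas balances.

At steady state the specific growth rate equals the dilution rate, so
biomass yield, specific gas-consumption rates and the O₂:CH₄ consumption
ratio follow from the inlet/outlet gas percentages, the gas flow and the
standing biomass.  Gas volumes are standard litres converted at
22.414 L mol⁻¹ (0 °C, 1 atm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConditionSpec",
    "GrowthSummary",
    "MOLAR_VOLUME_L",
    "CH4_MOLAR_MASS",
    "gas_molar_consumption",
    "specific_consumption_rate",
    "biomass_productivity",
    "steady_state_summary",
]

MOLAR_VOLUME_L = 22.414   # L mol⁻¹ at standard conditions
CH4_MOLAR_MASS = 16.04    # g mol⁻¹


@dataclass(frozen=True)
class ConditionSpec:
    """Bioreactor condition: gas supply, culture and dilution settings."""

    label: str
    inlet_ch4_pct: float
    inlet_o2_pct: float
    gas_flow: float          # sL h⁻¹
    culture_volume: float    # L
    biomass_conc: float      # g DCW L⁻¹
    dilution_rate: float     # h⁻¹

    def __post_init__(self) -> None:
        for pct in (self.inlet_ch4_pct, self.inlet_o2_pct):
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"{self.label}: inlet percentage {pct} outside [0, 100]")
        for attr in ("gas_flow", "culture_volume", "biomass_conc"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{self.label}: {attr} must be > 0")
        if self.dilution_rate < 0:
            raise ValueError(f"{self.label}: dilution_rate must be >= 0")


@dataclass(frozen=True)
class GrowthSummary:
    """Table of chemostat growth parameters for one condition."""

    label: str
    mu: float                # h⁻¹
    yield_biomass: float     # g DCW per g CH4
    q_ch4: float             # mmol gDCW⁻¹ h⁻¹
    q_o2: float              # mmol gDCW⁻¹ h⁻¹
    ratio_o2_ch4: float
    productivity: float      # mg DCW h⁻¹

    def as_series(self) -> pd.Series:
        return pd.Series({
            "dilution_rate_h": self.mu,
            "biomass_yield_g_per_g": self.yield_biomass,
            "q_ch4_mmol_gdcw_h": self.q_ch4,
            "q_o2_mmol_gdcw_h": self.q_o2,
            "o2_ch4_ratio": self.ratio_o2_ch4,
            "productivity_mg_dcw_h": self.productivity,
        }, name=self.label)


def gas_molar_consumption(inlet_pct: float, outlet_pct: float,
                          gas_flow: float) -> float:
    """Molar consumption (mmol h⁻¹) from an inlet/outlet percentage drop.

    Negative results (production, e.g. CO₂, or a noisy crossing) are
    returned as signed values with a warning.
    """
    if gas_flow <= 0:
        raise ValueError("gas_flow must be > 0")
    consumed_sl = (inlet_pct - outlet_pct) / 100.0 * gas_flow
    mmol = consumed_sl / MOLAR_VOLUME_L * 1000.0
    if mmol < 0:
        warnings.warn(
            f"negative consumption ({mmol:.3g} mmol/h): outlet {outlet_pct}% "
            f"exceeds inlet {inlet_pct}%", stacklevel=2)
    return mmol


def specific_consumption_rate(mu: float, yield_biomass: float,
                              molar_mass: float = CH4_MOLAR_MASS) -> float:
    """Specific substrate consumption q = 1000·μ / (Y · M), mmol gDCW⁻¹ h⁻¹."""
    if yield_biomass <= 0:
        raise ValueError("yield_biomass must be > 0")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return 1000.0 * mu / (yield_biomass * molar_mass)


def biomass_productivity(dilution_rate: float, biomass_conc: float,
                         culture_volume: float) -> float:
    """Biomass production rate D·X·V in mg DCW h⁻¹."""
    if dilution_rate < 0 or biomass_conc <= 0 or culture_volume <= 0:
        raise ValueError("dilution_rate >= 0 and positive biomass/volume required")
    return dilution_rate * biomass_conc * culture_volume * 1000.0


def steady_state_summary(spec: ConditionSpec, offgas: pd.DataFrame,
                         window: tuple[float, float] | None = None
                         ) -> GrowthSummary:
    """Growth parameters from a steady-state off-gas window.

    ``offgas`` needs columns ``time_h``, ``ch4_out_pct``, ``o2_out_pct``;
    ``window`` is an inclusive (start, end) time range in hours (default:
    the whole series).  Outlet percentages are averaged over the window
    before the gas balance, μ is taken as the dilution rate, and yield is
    biomass production over CH₄ consumption in g h⁻¹.
    """
    required = {"time_h", "ch4_out_pct", "o2_out_pct"}
    missing = required - set(offgas.columns)
    if missing:
        raise ValueError(f"off-gas table missing columns {sorted(missing)}")
    if window is not None:
        t = offgas["time_h"]
        offgas = offgas[(t >= window[0]) & (t <= window[1])]
    if offgas.empty:
        raise ValueError("empty steady-state window")

    ch4_out = float(np.mean(offgas["ch4_out_pct"]))
    o2_out = float(np.mean(offgas["o2_out_pct"]))
    ch4_mmol_h = gas_molar_consumption(spec.inlet_ch4_pct, ch4_out, spec.gas_flow)
    o2_mmol_h = gas_molar_consumption(spec.inlet_o2_pct, o2_out, spec.gas_flow)
    if ch4_mmol_h <= 0:
        raise ValueError(
            f"non-positive CH4 consumption ({ch4_mmol_h:.3g} mmol/h) in window")

    biomass_g_h = spec.biomass_conc * spec.dilution_rate * spec.culture_volume
    ch4_g_h = ch4_mmol_h * CH4_MOLAR_MASS / 1000.0
    standing_biomass = spec.biomass_conc * spec.culture_volume
    return GrowthSummary(
        label=spec.label,
        mu=spec.dilution_rate,
        yield_biomass=biomass_g_h / ch4_g_h,
        q_ch4=ch4_mmol_h / standing_biomass,
        q_o2=o2_mmol_h / standing_biomass,
        ratio_o2_ch4=o2_mmol_h / ch4_mmol_h,
        productivity=biomass_productivity(
            spec.dilution_rate, spec.biomass_conc, spec.culture_volume),
    )
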