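"""Headspace equilibration of a sealed, rigid bottle.

A bottle filled at temperature ``T0`` and pressure ``P0`` contains a liquid
water-ethanol mixture, a headspace of air, and - once stored at a different
temperature ``T`` - water and ethanol vapor evaporated from the liquid.
The equilibrium state couples three balances: chemical equilibrium between
liquid and vapor (activity model), thermal expansion of the liquid (density
model), and the ideal-gas law for the gas inventory.  Air is treated as
dry, insoluble and incondensable, so its mole number is fixed at filling.

The solution is a nested iteration: for a trial headspace volume, a fixed
point on the liquid ethanol mole fraction accounts for the vapor inventory;
the headspace volume itself is found by golden-section minimization of the
mismatch between the thermodynamic liquid density and the density implied
by the remaining liquid mass in the remaining volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import thermo
from ._search import golden_section
from .constants import M_ETHANOL, M_WATER, P_ATM, R_GAS, celsius_to_kelvin

__all__ = [
    "FillState",
    "HeadspaceState",
    "initial_inventory",
    "equilibrate",
    "overpressure_report",
]


@dataclass(frozen=True)
class FillState:
    """Inventories of a bottle just after filling and sealing.

    The headspace initially contains only air; all ethanol and water are in
    the liquid.
    """

    v_bottle: float  # m^3, internal volume
    v_head0: float  # m^3, headspace at filling
    t0_c: float  # degC, filling temperature
    p0: float  # Pa, filling pressure
    abv0: float  # initial alcoholic strength
    n_air: float = field(init=False)  # mol
    n_e0: float = field(init=False)  # mol ethanol, total
    n_w0: float = field(init=False)  # mol water, total

    def __post_init__(self):
        if self.v_bottle <= 0 or self.v_head0 <= 0:
            raise ValueError("volumes must be positive")
        if self.v_head0 >= self.v_bottle:
            raise ValueError(
                f"headspace {self.v_head0} m^3 must be smaller than bottle "
                f"{self.v_bottle} m^3"
            )
        if not (0.0 <= self.abv0 <= 1.0):
            raise ValueError(f"abv0 {self.abv0} outside [0, 1]")
        t0_k = celsius_to_kelvin(self.t0_c)
        v_liq = self.v_bottle - self.v_head0
        n_e0 = thermo.RHO_E_20 / M_ETHANOL * v_liq * self.abv0
        rho_mix = thermo.density(self.t0_c, self.abv0)
        n_w0 = (rho_mix * v_liq - n_e0 * M_ETHANOL) / M_WATER
        object.__setattr__(self, "n_air", self.p0 * self.v_head0 / (R_GAS * t0_k))
        object.__setattr__(self, "n_e0", n_e0)
        object.__setattr__(self, "n_w0", n_w0)

    @property
    def v_fill(self) -> float:
        """Liquid volume at filling, m^3."""
        return self.v_bottle - self.v_head0

    @property
    def m_e0(self) -> float:
        """Initial ethanol mass in the liquid, kg."""
        return self.n_e0 * M_ETHANOL

    @property
    def m_w0(self) -> float:
        """Initial water mass in the liquid, kg."""
        return self.n_w0 * M_WATER


def initial_inventory(
    v_bottle: float, v_head0: float, t0_c: float, p0: float, abv0: float
) -> FillState:
    """Compute the mole inventories of air, ethanol and water at filling."""
    return FillState(v_bottle=v_bottle, v_head0=v_head0, t0_c=t0_c, p0=p0, abv0=abv0)


@dataclass(frozen=True)
class HeadspaceState:
    """Converged gas-liquid equilibrium of the sealed bottle."""

    v_head: float  # m^3
    p_head: float  # Pa
    n_w_gas: float  # mol water vapor
    n_e_gas: float  # mol ethanol vapor
    n_air: float  # mol air
    x_e: float  # liquid ethanol mole fraction
    abv: float  # liquid strength (20 degC reference)
    t_c: float  # storage temperature, degC
    residual: float  # kg m^-3, density mismatch at convergence
    fill: FillState

    @property
    def n_gas(self) -> float:
        return self.n_air + self.n_w_gas + self.n_e_gas

    @property
    def overpressure(self) -> float:
        """P_head - P_atm, Pa."""
        return self.p_head - P_ATM


_XE_TOL = 1e-10
_VHEAD_TOL = 1e-12  # m^3


def _vapor_fixed_point(
    fill: FillState, t_c: float, v_head: float, include_volatiles: bool
) -> tuple[float, float, float, float]:
    """Inner fixed point on x_e for a trial headspace volume.

    Returns ``(x_e, abv, n_e_gas, n_w_gas)``.
    """
    t_k = celsius_to_kelvin(t_c)
    if not include_volatiles:
        x_e0 = fill.n_e0 / (fill.n_e0 + fill.n_w0)
        return x_e0, thermo.abv_from_x_e(x_e0), 0.0, 0.0
    p_w_sat = thermo.saturation_pressure("water", t_k)
    p_e_sat = thermo.saturation_pressure("ethanol", t_k)
    gas_factor = v_head / (R_GAS * t_k)
    x_e = fill.n_e0 / (fill.n_e0 + fill.n_w0)
    abv = thermo.abv_from_x_e(x_e)
    n_e_g = n_w_g = 0.0
    for _ in range(200):
        x_e_old = x_e
        gamma_e, gamma_w = thermo._unifac.activity_coefficients(t_c, x_e)
        n_e_g = gamma_e * x_e * p_e_sat * gas_factor
        n_w_g = gamma_w * (1.0 - x_e) * p_w_sat * gas_factor
        denom = fill.n_e0 + fill.n_w0 - n_e_g - n_w_g
        x_e = (fill.n_e0 - n_e_g) / denom
        if abs(x_e - x_e_old) <= _XE_TOL:
            break
    else:
        raise RuntimeError(
            f"vapor fixed point did not converge (|dx_e|={abs(x_e - x_e_old):.2e})"
        )
    abv = thermo.abv_from_x_e(x_e)
    return x_e, abv, n_e_g, n_w_g


def equilibrate(
    fill: FillState,
    t_c: float,
    include_volatiles: bool = True,
    max_iter: int = 200,
) -> HeadspaceState:
    """Equilibrate the sealed bottle at storage temperature ``t_c`` (degC).

    ``include_volatiles=False`` suppresses evaporation (saturation
    pressures forced to zero), leaving only air and liquid expansion; this
    is mainly a diagnostic mode.

    Raises
    ------
    RuntimeError
        If the nested iteration fails to reduce the density residual below
        1e-3 kg m^-3.
    """

    def density_mismatch(v_head: float) -> float:
        x_e, abv, n_e_g, n_w_g = _vapor_fixed_point(
            fill, t_c, v_head, include_volatiles
        )
        m_liq = (fill.n_e0 - n_e_g) * M_ETHANOL + (fill.n_w0 - n_w_g) * M_WATER
        rho_theoretical = m_liq / (fill.v_bottle - v_head)
        rho_thermo = thermo.density(t_c, abv)
        return abs(rho_thermo - rho_theoretical)

    lo = 1e-3 * fill.v_head0
    hi = fill.v_bottle - 1e-9  # leave 1 mm^3 of liquid
    v_head, residual = golden_section(
        density_mismatch, lo, hi, xtol=_VHEAD_TOL, max_iter=max_iter
    )
    if residual > 1e-3:
        raise RuntimeError(
            f"headspace equilibration failed: density residual "
            f"{residual:.3e} kg m^-3 at V_head={v_head * 1e6:.3f} mL"
        )
    x_e, abv, n_e_g, n_w_g = _vapor_fixed_point(fill, t_c, v_head, include_volatiles)
    t_k = celsius_to_kelvin(t_c)
    p_head = (fill.n_air + n_w_g + n_e_g) * R_GAS * t_k / v_head
    return HeadspaceState(
        v_head=v_head,
        p_head=p_head,
        n_w_gas=n_w_g,
        n_e_gas=n_e_g,
        n_air=fill.n_air,
        x_e=x_e,
        abv=abv,
        t_c=t_c,
        residual=residual,
        fill=fill,
    )


def overpressure_report(
    states: list[HeadspaceState],
    p_atm: float = P_ATM,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Tabulate overpressures and collapse risk for equilibrated states.

    The percentage change column compares each state's overpressure with
    the first state's (the reference filling scenario); a collapse flag is
    raised whenever the internal pressure falls below atmospheric.
    """
    if labels is None:
        labels = [f"state{i}" for i in range(len(states))]
    dp = np.array([s.p_head - p_atm for s in states])
    ref = dp[0] if len(dp) else np.nan
    rows = {
        "label": labels,
        "T_degC": [s.t_c for s in states],
        "P_head_Pa": [s.p_head for s in states],
        "V_head_mL": [s.v_head * 1e6 for s in states],
        "overpressure_Pa": dp,
        "pct_change_vs_first": 100.0 * (dp - ref) / ref if len(dp) else [],
        "collapse_risk": [s.p_head < p_atm for s in states],
    }
    return pd.DataFrame(rows)
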