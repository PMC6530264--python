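"""Binary water-ethanol thermodynamics.

Saturation pressures of the pure components, conversions between alcoholic
strength by volume (abv), mass fraction and mole fraction, mixture density,
and activity-based partial pressures.  abv is the EU legal measure of
alcoholic strength: the volume ratio of pure ethanol to total beverage,
both taken at 20 degC; it is represented as a fraction in [0, 1] everywhere
in this package.

The non-ideality of the binary is captured by group-contribution activity
coefficients (see :mod:`bottlesim._unifac`); the partial pressure of each
species above the beverage is ``p_i = x_i * gamma_i * p_sat_i(T)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from . import _oiml, _unifac
from .constants import M_ETHANOL, M_WATER, celsius_to_kelvin

__all__ = [
    "SATURATION_MODEL",
    "BinaryComposition",
    "DensityTable",
    "saturation_pressure",
    "composition_from_abv",
    "abv_from_masses",
    "density",
    "activities",
    "partial_pressures",
    "write_density_table",
]


@dataclass(frozen=True)
class SaturationModel:
    """Constants of the pure-component vapor-pressure correlations.

    Water uses a modified Goff-Gratch correlation referenced to the normal
    boiling point (T in kelvin); ethanol uses an Antoine correlation with T
    in degC, with the leading offset being log10 of the mmHg -> Pa factor.
    """

    # water
    gg_c1: float = -7.90298
    gg_c2: float = 5.02808
    gg_c3: float = -1.3816e-7
    gg_c4: float = 11.344
    gg_c5: float = 8.1328e-3
    gg_c6: float = 3.49149
    t_w_sat: float = 373.15  # K
    p_std: float = 101324.6  # Pa
    water_t_min_k: float = 273.15
    water_t_max_k: float = 373.15
    # ethanol
    antoine_offset: float = 2.12490  # log10(101325/760)
    antoine_a: float = 8.20417
    antoine_b: float = 1642.89
    antoine_c: float = 230.3
    ethanol_t_min_c: float = -57.0
    ethanol_t_max_c: float = 80.0


SATURATION_MODEL = SaturationModel()


def saturation_pressure(species: str, t_k: float) -> float:
    """Pure-component saturation pressure in Pa at absolute temperature ``t_k``.

    Parameters
    ----------
    species : ``"water"`` or ``"ethanol"``.
    t_k : temperature in kelvin.

    Raises
    ------
    ValueError
        If the temperature falls outside the validity range of the
        correlation for the requested species.
    """
    m = SATURATION_MODEL
    if species == "water":
        if not (m.water_t_min_k <= t_k <= m.water_t_max_k):
            raise ValueError(
                f"water saturation correlation valid on "
                f"[{m.water_t_min_k}, {m.water_t_max_k}] K, got {t_k} K"
            )
        tr = m.t_w_sat / t_k
        log10p = (
            m.gg_c1 * (tr - 1.0)
            + m.gg_c2 * np.log10(tr)
            + m.gg_c3 * (10.0 ** (m.gg_c4 * (1.0 - 1.0 / tr)) - 1.0)
            + m.gg_c5 * (10.0 ** (m.gg_c6 * (1.0 - tr)) - 1.0)
            + np.log10(m.p_std)
        )
        return float(10.0**log10p)
    if species == "ethanol":
        t_c = t_k - 273.15
        if not (m.ethanol_t_min_c <= t_c <= m.ethanol_t_max_c):
            raise ValueError(
                f"ethanol Antoine correlation valid on "
                f"[{m.ethanol_t_min_c}, {m.ethanol_t_max_c}] degC, got {t_c} degC"
            )
        log10p = m.antoine_offset + m.antoine_a - m.antoine_b / (m.antoine_c + t_c)
        return float(10.0**log10p)
    raise ValueError(f"unknown species {species!r}; expected 'water' or 'ethanol'")


@dataclass(frozen=True)
class BinaryComposition:
    """Composition of a water-ethanol mixture in all common measures."""

    abv: float  # volume fraction of ethanol at 20 degC
    w_e: float  # ethanol mass fraction
    x_e: float  # ethanol mole fraction

    @property
    def x_w(self) -> float:
        return 1.0 - self.x_e

    @property
    def w_w(self) -> float:
        return 1.0 - self.w_e


#: density of pure ethanol at 20 degC from the alcoholometric polynomial
RHO_E_20 = _oiml.mixture_density_w(20.0, 1.0)
#: density of pure water at 20 degC
RHO_W_20 = _oiml.mixture_density_w(20.0, 0.0)


def _rho20_from_abv(abv: float) -> tuple[float, float]:
    """Return (rho_mix(20 degC, abv), w_e) solved self-consistently.

    The alcoholometric polynomial takes the mass fraction, while abv is a
    volume-based measure: ``w_e = rho_e20 * abv / rho_mix(20, abv)``.  A
    damped fixed point converges to machine precision in a few iterations.
    """
    rho = RHO_W_20 + (RHO_E_20 - RHO_W_20) * abv  # linear first guess
    w = RHO_E_20 * abv / rho
    for _ in range(100):
        rho_new = _oiml.mixture_density_w(20.0, min(w, 1.0))
        w_new = RHO_E_20 * abv / rho_new
        if abs(w_new - w) < 1e-15:
            w = w_new
            rho = rho_new
            break
        w, rho = w_new, rho_new
    return rho, min(max(w, 0.0), 1.0)


def composition_from_abv(abv: float) -> BinaryComposition:
    """Convert alcoholic strength by volume into mass and mole fractions."""
    if not (0.0 <= abv <= 1.0) or not np.isfinite(abv):
        raise ValueError(f"abv {abv} outside [0, 1]")
    _, w_e = _rho20_from_abv(abv)
    x_e = (w_e / M_ETHANOL) / (w_e / M_ETHANOL + (1.0 - w_e) / M_WATER)
    return BinaryComposition(abv=abv, w_e=w_e, x_e=x_e)


def abv_from_masses(m_e: float, m_w: float) -> float:
    """Alcoholic strength by volume of a mixture of ``m_e`` kg ethanol and
    ``m_w`` kg water (both at the 20 degC reference state)."""
    if not (np.isfinite(m_e) and np.isfinite(m_w)) or m_e < 0 or m_w < 0:
        raise ValueError(f"masses must be finite and non-negative, got {m_e}, {m_w}")
    if m_e + m_w <= 0:
        raise ValueError("total mass must be positive")
    w_e = m_e / (m_e + m_w)
    if w_e <= 0.0:
        return 0.0
    if w_e >= 1.0:
        return 1.0

    def resid(abv: float) -> float:
        return composition_from_abv(abv).w_e - w_e

    return float(brentq(resid, 0.0, 1.0, xtol=1e-13, rtol=1e-14))


def abv_from_x_e(x_e: float) -> float:
    """Alcoholic strength from the ethanol liquid mole fraction."""
    if not (0.0 <= x_e <= 1.0):
        raise ValueError(f"x_e {x_e} outside [0, 1]")
    return abv_from_masses(x_e * M_ETHANOL, (1.0 - x_e) * M_WATER)


def density(t_c: float, abv: float) -> float:
    """Density of the water-ethanol mixture, kg m^-3.

    ``t_c`` in degC within [-20, 70], ``abv`` in [0, 1].  Outside the grid a
    range error is raised (no silent extrapolation).
    """
    if not (0.0 <= abv <= 1.0):
        raise ValueError(f"abv {abv} outside [0, 1]")
    _, w_e = _rho20_from_abv(abv)
    return _oiml.mixture_density_w(t_c, w_e)


class DensityTable:
    """Tabulated ``rho(T, abv)`` on a regular grid with bilinear interpolation.

    The table is evaluated from the alcoholometric polynomial; it exists as
    an exportable, versioned artifact (CSV resource) and as a fast
    interpolation surface.  :func:`density` evaluates the polynomial
    directly and is the reference path.
    """

    version = "1.0"

    def __init__(
        self,
        t_grid: np.ndarray | None = None,
        abv_grid: np.ndarray | None = None,
    ):
        self.t_grid = (
            np.asarray(t_grid, float)
            if t_grid is not None
            else np.arange(-20.0, 70.0 + 1e-9, 2.5)
        )
        self.abv_grid = (
            np.asarray(abv_grid, float)
            if abv_grid is not None
            else np.round(np.arange(0.0, 1.0 + 1e-9, 0.02), 10)
        )
        self.rho = np.array(
            [[density(t, a) for a in self.abv_grid] for t in self.t_grid]
        )

    def __call__(self, t_c: float, abv: float) -> float:
        from scipy.interpolate import RegularGridInterpolator

        if not hasattr(self, "_interp"):
            self._interp = RegularGridInterpolator(
                (self.t_grid, self.abv_grid), self.rho, method="linear"
            )
        return float(self._interp((t_c, abv)))

    def to_frame(self):
        import pandas as pd

        tt, aa = np.meshgrid(self.t_grid, self.abv_grid, indexing="ij")
        return pd.DataFrame(
            {
                "T_degC": tt.ravel(),
                "abv": aa.ravel(),
                "rho_kg_m3": self.rho.ravel(),
            }
        )


def write_density_table(path: str | Path) -> Path:
    """Export the density grid as the package's versioned CSV resource."""
    path = Path(path)
    table = DensityTable()
    frame = table.to_frame()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# bottlesim density table v{table.version}\n")
        frame.to_csv(fh, index=False, float_format="%.6g")
    return path


def activities(t_c: float, abv: float) -> tuple[float, float, float, float]:
    """Water and ethanol activities in the beverage.

    Returns ``(a_w, a_e, gamma_w, gamma_e)`` with ``a_i = gamma_i * x_i``.
    """
    comp = composition_from_abv(abv)
    gamma_e, gamma_w = _unifac.activity_coefficients(t_c, comp.x_e)
    return (
        gamma_w * comp.x_w,
        gamma_e * comp.x_e,
        gamma_w,
        gamma_e,
    )


def partial_pressures(t_c: float, abv: float) -> tuple[float, float, float]:
    """Equilibrium partial pressures above the beverage, Pa.

    Returns ``(p_w, p_e, p_total)`` with ``p_i = a_i * p_sat_i(T)``.
    """
    a_w, a_e, _, _ = activities(t_c, abv)
    t_k = celsius_to_kelvin(t_c)
    p_w = a_w * saturation_pressure("water", t_k)
    p_e = a_e * saturation_pressure("ethanol", t_k) if abv > 0.0 else 0.0
    return p_w, p_e, p_w + p_e
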