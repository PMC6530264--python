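"""Deterministic reference bottles and storage scenarios.

The study conditions are a 55 mL injection-blown PET miniature bottle
(0.80 mm body walls, thicker base and neck, about 10.5 g of plastic)
filled with 44 mL of a hydroalcoholic solution at 20 degC and 101.325 kPa,
then stored in climatic-chamber conditions.  This module generates that
miniature as a deterministic axisymmetric profile, the parametric design
used in the shape optimization, and the beverage/storage preset tables
(B1-B4 x S0-S4).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from . import geometry as geo
from .constants import P_ATM

__all__ = [
    "StorageScenario",
    "miniature_bottle",
    "parametric_miniature_spec",
    "generate_fixture_bottle",
    "scenario_presets",
    "BEVERAGES",
    "STORAGE_CONDITIONS",
]

#: beverage code -> alcoholic strength by volume (fraction)
BEVERAGES: dict[str, float] = {"B1": 0.7, "B2": 0.4, "B3": 0.15, "B4": 0.0}

#: storage code -> (T degC, RH %, sleeve?)
STORAGE_CONDITIONS: dict[str, tuple[float, float, bool]] = {
    "S0": (20.0, 50.0, False),
    "S1": (50.0, 10.0, False),
    "S2": (35.0, 75.0, False),
    "S3": (35.0, 20.0, False),
    "S4": (35.0, 20.0, True),
}

#: default filling conditions shared by all presets
FILL_VOLUME = 44e-6  # m^3
FILL_T0_C = 20.0
FILL_P0 = P_ATM

#: sleeve film: 60 um biaxially oriented PET over the bottle body
SLEEVE_THICKNESS = 60e-6
SLEEVE_Z_RANGE = (8e-3, 72e-3)  # the thin cylindrical body


@dataclass(frozen=True)
class StorageScenario:
    """One beverage stored in one climatic condition."""

    storage_code: str
    beverage_code: str
    t_c: float
    rh_pct: float
    abv0: float
    fill_volume: float = FILL_VOLUME
    t0_c: float = FILL_T0_C
    p0: float = FILL_P0
    sleeve: bool = False
    sleeve_thickness: float = SLEEVE_THICKNESS
    sleeve_z_range: tuple[float, float] = SLEEVE_Z_RANGE
    meta: dict = field(default_factory=dict)

    @property
    def code(self) -> str:
        return f"{self.storage_code}/{self.beverage_code}"


def scenario_presets() -> list[StorageScenario]:
    """All beverage x storage combinations as ready-to-run scenarios."""
    out = []
    for s_code, (t_c, rh, sleeve) in STORAGE_CONDITIONS.items():
        for b_code, abv in BEVERAGES.items():
            out.append(
                StorageScenario(
                    storage_code=s_code,
                    beverage_code=b_code,
                    t_c=t_c,
                    rh_pct=rh,
                    abv0=abv,
                    sleeve=sleeve,
                )
            )
    return out


def get_scenario(storage_code: str, beverage_code: str) -> StorageScenario:
    """Look up a single preset by its codes (e.g. ``"S3"``, ``"B1"``)."""
    for s in scenario_presets():
        if s.storage_code == storage_code and s.beverage_code == beverage_code:
            return s
    raise KeyError(f"unknown scenario {storage_code}/{beverage_code}")


# ---------------------------------------------------------------------------
# miniature bottle

# profile knots: (z mm, radius as fraction of body radius or absolute, l mm).
# The body radius is solved so the internal volume is exactly 55 mL; the
# resulting plastic mass is ~10.5 g, consistent with the weighed bottles.
_R_NECK = 9e-3
_MINIATURE_KNOTS = [
    # z_mm, r_kind ('frac' of r_body | 'abs' m), r_value, l_mm
    (0.0, "frac", 0.55, 1.6),
    (3.0, "frac", 0.90, 1.1),
    (6.0, "frac", 1.00, 0.90),
    (8.0, "frac", 1.00, 0.80),
    (72.0, "frac", 1.00, 0.80),
    (78.0, "frac", 0.95, 0.90),
    (84.0, "mix", 0.25, 1.3),  # r_neck + 0.25 (r_body - r_neck)
    (86.0, "abs", _R_NECK, 1.6),
    (96.0, "abs", _R_NECK, 1.6),
]
_MINIATURE_L_BOTTOM = 1.6e-3
_MINIATURE_V_TARGET = 55e-6


def _miniature_profile(r_body: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    z, r, l = [], [], []
    for z_mm, kind, val, l_mm in _MINIATURE_KNOTS:
        z.append(z_mm * 1e-3)
        if kind == "frac":
            r.append(val * r_body)
        elif kind == "abs":
            r.append(val)
        else:  # mix
            r.append(_R_NECK + val * (r_body - _R_NECK))
        l.append(l_mm * 1e-3)
    return np.array(z), np.array(r), np.array(l)


def miniature_bottle(
    thickness_noise_sd: float = 0.0,
    seed: int | None = None,
) -> geo.BottleGeometry:
    """The 55 mL miniature as a deterministic revolution geometry.

    ``thickness_noise_sd`` (m) adds seeded Gaussian noise to the body
    thickness knots, emulating the measured bottle-to-bottle scatter of
    the thickness profile; it requires an explicit ``seed``.
    """

    def volume_of(r_body: float) -> float:
        z, r, l = _miniature_profile(r_body)
        g = geo.geometry_from_profile(z, r, l, l_bottom=_MINIATURE_L_BOTTOM, l_top=0.0)
        return g.v_internal

    r_body = brentq(
        lambda rb: volume_of(rb) - _MINIATURE_V_TARGET, 8e-3, 25e-3, xtol=1e-12
    )
    z, r, l = _miniature_profile(r_body)
    if thickness_noise_sd > 0.0:
        if seed is None:
            raise ValueError("thickness noise requires an explicit seed")
        rng = np.random.default_rng(seed)
        l = np.clip(l + rng.normal(0.0, thickness_noise_sd, l.shape), 0.2e-3, None)
    g = geo.geometry_from_profile(z, r, l, l_bottom=_MINIATURE_L_BOTTOM, l_top=0.0)
    g.meta.update(
        {
            "source": "miniature-fixture",
            "r_body": r_body,
            "noise_sd": thickness_noise_sd,
            "seed": seed,
        }
    )
    return g


def parametric_miniature_spec() -> dict:
    """Parameter block of the 160 mL parametric design (capacity 150 mL)."""
    return {
        "width": 60e-3,
        "depth": 60e-3,
        "neck_diameter": 22e-3,
        "shoulder_height": 25e-3,
        "l_wall": 0.5e-3,
        "l_top": 1.5e-3,
        "l_bottom": 1.0e-3,
        "l_neck": 1.5e-3,
        "corner_exponent": 4.0,
    }


def generate_fixture_bottle(
    kind: str,
    path: str | Path | io.TextIOBase | None = None,
    thickness_noise_sd: float = 0.0,
    seed: int | None = None,
) -> geo.BottleGeometry | dict:
    """Emit a reference bottle.

    ``kind='miniature'`` returns (and optionally writes as a profile CSV)
    the 55 mL axisymmetric miniature; ``kind='parametric'`` returns the
    parametric design parameter block (optionally written as YAML-style
    ``key: value`` lines).
    """
    if kind == "miniature":
        g = miniature_bottle(thickness_noise_sd=thickness_noise_sd, seed=seed)
        if path is not None:
            z, r, l = _miniature_profile(g.meta["r_body"])
            if thickness_noise_sd > 0.0:
                rng = np.random.default_rng(seed)
                l = np.clip(
                    l + rng.normal(0.0, thickness_noise_sd, l.shape), 0.2e-3, None
                )
            geo.write_profile_csv(path, z, r, l)
        return g
    if kind == "parametric":
        spec = parametric_miniature_spec()
        if path is not None:
            lines = "".join(f"{k}: {v}\n" for k, v in spec.items())
            if isinstance(path, io.TextIOBase):
                path.write(lines)
            else:
                Path(path).write_text(lines, encoding="utf-8")
        return spec
    raise ValueError(f"unknown fixture kind {kind!r}")
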