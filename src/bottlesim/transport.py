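"""Coupled water-ethanol sorption, diffusion and permeation through walls.

The wall of the container is decomposed into vertical sections, each a
thin cylindrical shell discretized radially by a conservative finite-volume
scheme.  Inside each shell the two species diffuse independently
(Fickian, concentration-independent D); coupling happens through the
beverage: the internal boundary activity of each species is set by the
liquid composition via the activity model, and the global water/ethanol
mass balance over all sections updates that composition in time.

Sorption equilibrium at both wall surfaces follows the linear isotherm
``C = a * C_sat(T) * rho_PET``, so the solver works in activity units
``u = C / (C_sat rho_PET)``: the flux between layers of different
materials is then continuous in chemical potential, which makes two-layer
walls (shrink sleeves) a plain extension of the radial grid.

A thin-film mass-transfer conductance ``h`` converts the vapor-side
driving force into a flux at both surfaces; with the default value the
wall resistance dominates by several orders of magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from . import thermo
from .constants import M_ETHANOL, M_WATER, R_GAS, RHO_PET, celsius_to_kelvin
from .geometry import BottleGeometry, WallSection, sectionize
from .headspace import FillState

__all__ = [
    "MaterialProps",
    "EvaluatedProps",
    "SolverOptions",
    "SimulationResult",
    "material_props_at",
    "initialize_walls",
    "apply_sleeve",
    "simulate",
    "WallModel",
    "PET",
]


@dataclass(frozen=True)
class MaterialProps:
    """Transport and sorption anchors for a polymer (default: PET).

    Diffusivities interpolate between the measured anchors: water follows
    a two-point Arrhenius law through the 35 and 50 degC values; ethanol
    interpolates log-linearly in composition between the 35 degC anchors
    and scales in temperature with an apparent activation energy.
    Saturation concentrations interpolate linearly in temperature.
    """

    name: str = "PET"
    d_w_35: float = 1.5e-12  # m^2 s^-1
    d_w_50: float = 2.6e-12
    d_e_35_by_abv: tuple[tuple[float, float], ...] = (
        (0.15, 5.5e-16),
        (0.40, 6.3e-16),
        (0.70, 8.9e-16),
    )
    ea_e: float = 54e3  # J mol^-1, apparent, ethanol
    c_w_sat_35: float = 0.0118  # kg per kg dry polymer
    c_w_sat_50: float = 0.0107
    c_e_sat_35: float = 0.0208
    c_e_sat_50: float = 0.0224
    rho: float = RHO_PET
    t_valid_c: tuple[float, float] = (15.0, 60.0)

    @property
    def ea_w_effective(self) -> float:
        """Water activation energy implied by the two anchors, J mol^-1."""
        t1, t2 = celsius_to_kelvin(35.0), celsius_to_kelvin(50.0)
        return R_GAS * np.log(self.d_w_50 / self.d_w_35) / (1.0 / t1 - 1.0 / t2)


PET = MaterialProps()

#: biaxially oriented PET sleeve film; transport anchors taken equal to the
#: bottle-grade PET defaults
BOPET_SLEEVE = replace(PET, name="BOPET-sleeve")


@dataclass(frozen=True)
class EvaluatedProps:
    """Material properties evaluated at one temperature and composition."""

    d_w: float
    d_e: float
    c_w_sat: float  # kg/kg dry polymer
    c_e_sat: float
    rho: float
    extrapolated: bool = False

    @property
    def s_w(self) -> float:
        """Volumetric water solubility coefficient, kg m^-3 per unit activity."""
        return self.c_w_sat * self.rho

    @property
    def s_e(self) -> float:
        return self.c_e_sat * self.rho


def material_props_at(
    t_c: float, abv: float, material: MaterialProps = PET
) -> EvaluatedProps:
    """Evaluate diffusivities and saturation concentrations at (T, abv)."""
    if not (0.0 <= abv <= 1.0):
        raise ValueError(f"abv {abv} outside [0, 1]")
    lo, hi = material.t_valid_c
    extrapolated = not (lo <= t_c <= hi)
    if extrapolated:
        warnings.warn(
            f"temperature {t_c} degC outside material validity [{lo}, {hi}] degC; "
            "properties extrapolated",
            stacklevel=2,
        )
    t_k = celsius_to_kelvin(t_c)
    t35 = celsius_to_kelvin(35.0)
    # water: two-point Arrhenius through the tabulated anchors
    d_w = material.d_w_35 * np.exp(
        -material.ea_w_effective / R_GAS * (1.0 / t_k - 1.0 / t35)
    )
    # ethanol: log-linear in composition at 35 degC, Arrhenius in T
    abvs = np.array([a for a, _ in material.d_e_35_by_abv])
    lnds = np.log([d for _, d in material.d_e_35_by_abv])
    a_cl = float(np.clip(abv, abvs[0], abvs[-1]))
    d_e_35 = np.exp(np.interp(a_cl, abvs, lnds))
    d_e = d_e_35 * np.exp(-material.ea_e / R_GAS * (1.0 / t_k - 1.0 / t35))
    # saturation concentrations: linear in T
    frac = (t_c - 35.0) / 15.0
    c_w = material.c_w_sat_35 + (material.c_w_sat_50 - material.c_w_sat_35) * frac
    c_e = material.c_e_sat_35 + (material.c_e_sat_50 - material.c_e_sat_35) * frac
    return EvaluatedProps(
        d_w=float(d_w),
        d_e=float(d_e),
        c_w_sat=float(c_w),
        c_e_sat=float(c_e),
        rho=material.rho,
        extrapolated=extrapolated,
    )


def initialize_walls(
    sections: list[WallSection],
    rh0_pct: float,
    t0_c: float,
    material: MaterialProps = PET,
) -> list[dict[str, np.ndarray]]:
    """Initial wall concentration fields, kg m^-3 of polymer.

    Walls start in equilibrium with the pre-storage atmosphere: ethanol
    free, water at ``(RH0/100) * C_w_sat(T0)``.  One uniform field per
    section (single value broadcast later onto the radial grid).
    """
    if not (0.0 <= rh0_pct <= 100.0):
        raise ValueError(f"RH0 {rh0_pct} outside [0, 100] %")
    props = material_props_at(t0_c, 0.0, material)
    c_w0 = rh0_pct / 100.0 * props.c_w_sat * material.rho
    return [
        {"C_e": np.array([0.0]), "C_w": np.array([c_w0])} for _ in sections
    ]


def apply_sleeve(
    sections: list[WallSection],
    z_range: tuple[float, float],
    l_sleeve: float,
    material_sleeve: MaterialProps = BOPET_SLEEVE,
) -> list[WallSection]:
    """Cover the sections overlapping ``z_range`` with an external film.

    Partially covered sections are split in proportion to the overlap so
    the sleeved area equals exactly the z-range share of the surface.
    Returns a new section list; input sections must be sleeve-free.
    """
    if l_sleeve <= 0:
        raise ValueError("sleeve thickness must be positive")
    z_lo, z_hi = z_range
    if z_hi <= z_lo:
        raise ValueError(f"invalid sleeve z-range {z_range}")
    if any(s.sleeve_thickness > 0 for s in sections):
        raise ValueError("sections already carry a sleeve (overlapping sleeves)")
    out: list[WallSection] = []
    for s in sections:
        span = s.z_hi - s.z_lo
        overlap = max(0.0, min(s.z_hi, z_hi) - max(s.z_lo, z_lo))
        phi = overlap / span if span > 0 else 0.0
        if phi <= 0.0:
            out.append(s)
        elif phi >= 1.0:
            out.append(replace(s, sleeve_thickness=l_sleeve))
        else:
            out.append(replace(s, area=s.area * (1.0 - phi)))
            out.append(
                replace(s, area=s.area * phi, sleeve_thickness=l_sleeve)
            )
    return out


@dataclass
class SolverOptions:
    """Numerical settings of the wall/beverage integrator.

    ``n_nodes`` is the radial finite-volume count per wall layer;
    ``dabv_per_step`` limits the per-step change of alcoholic strength and
    thereby the coupling (splitting) error; ``h_conductance`` is the
    film-side mass-transfer conductance at both surfaces (m s^-1).
    """

    n_sections: int = 10
    n_nodes: int = 20
    n_nodes_sleeve: int = 6
    h_conductance: float = 1e-2  # m s^-1
    dt_init: float = 30.0  # s
    dt_max: float = 43200.0  # s
    dt_growth: float = 1.25
    dabv_per_step: float = 1e-5
    rh0_walls_pct: float = 50.0
    t0_walls_c: float = 20.0
    stop_after_thresholds: bool = False
    stop_mode: str = "both"  # "both": run until both criteria crossed;
    # "either": stop at the first crossing (feasibility checks)
    threshold_margin: float = 1.15
    mass_loss_threshold: float = 0.015
    dabv_threshold: float = 0.003

    @classmethod
    def coarse(cls) -> "SolverOptions":
        """Preset for optimization inner loops (fewer nodes, larger steps)."""
        return cls(
            n_sections=4,
            n_nodes=10,
            n_nodes_sleeve=4,
            dt_init=300.0,
            dt_max=2.0 * 86400.0,
            dabv_per_step=1e-4,
            stop_after_thresholds=True,
            stop_mode="either",
        )


class _SectionGrid:
    """Radial finite-volume grid of one wall section (1 or 2 layers).

    Works in activity units per species; assembles and solves the
    backward-Euler tridiagonal system for one time step.
    """

    def __init__(
        self,
        section: WallSection,
        n_nodes: int,
        n_nodes_sleeve: int,
        props_wall: EvaluatedProps,
        props_sleeve: EvaluatedProps | None,
    ):
        self.section = section
        r_in = section.radius
        edges = [np.linspace(r_in, r_in + section.thickness, n_nodes + 1)]
        layers = [0] * n_nodes
        if section.sleeve_thickness > 0.0:
            if props_sleeve is None:
                raise ValueError("sleeved section requires sleeve properties")
            r1 = r_in + section.thickness
            edges.append(
                np.linspace(r1, r1 + section.sleeve_thickness, n_nodes_sleeve + 1)[1:]
            )
            layers += [1] * n_nodes_sleeve
        self.r_edges = np.concatenate(edges)
        self.layer = np.array(layers)
        self.n = self.layer.size
        self.dr = np.diff(self.r_edges)
        self.r_out = float(self.r_edges[-1])
        # axial length such that the inner lateral area equals the section area
        self.ell = section.area / (2.0 * np.pi * r_in)
        self.a_in = section.area
        self.a_out = section.area * self.r_out / r_in
        # cell volumes (cylindrical shells)
        self.vol = np.pi * (self.r_edges[1:] ** 2 - self.r_edges[:-1] ** 2) * self.ell
        self.props = (props_wall, props_sleeve)
        # per-species state in activity units
        self.u = {"w": np.zeros(self.n), "e": np.zeros(self.n)}

    def _coeffs(self, species: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell (D*S) and per-cell solubility S for the species."""
        ds = np.empty(self.n)
        ss = np.empty(self.n)
        for lay in (0, 1):
            mask = self.layer == lay
            if not mask.any():
                continue
            p = self.props[lay]
            d = p.d_w if species == "w" else p.d_e
            s = p.s_w if species == "w" else p.s_e
            ds[mask] = d * s
            ss[mask] = s
        return ds, ss

    def set_concentration(self, species: str, c: np.ndarray | float) -> None:
        """Set the field from a concentration (kg m^-3), converting to activity."""
        _, ss = self._coeffs(species)
        self.u[species] = np.broadcast_to(np.atleast_1d(c), (self.n,)) / ss

    def content(self, species: str) -> float:
        """Mass of the species held in this section's wall, kg."""
        _, ss = self._coeffs(species)
        return float((ss * self.vol * self.u[species]).sum())

    def step(
        self,
        species: str,
        dt: float,
        a_in: float,
        a_out: float,
        k_film: float,
    ) -> tuple[float, float]:
        """Advance one backward-Euler step.

        ``a_in``/``a_out`` are the internal (beverage) and external
        activities; ``k_film`` the film conductance in kg m^-2 s^-1 per
        unit activity difference.  Returns ``(flow_in, flow_out)`` in
        kg s^-1, evaluated at the new time level (conservative).
        """
        ds, ss = self._coeffs(species)
        u = self.u[species]
        n = self.n
        # face conductances G (kg/s per unit activity difference)
        r_faces = self.r_edges[1:-1]
        res = 0.5 * self.dr / ds  # half-cell resistances
        g = 2.0 * np.pi * r_faces * self.ell / (res[:-1] + res[1:])
        # boundary conductances (film + half cell)
        k_in = self.a_in / (1.0 / k_film + res[0] * self.a_in /
                            (2.0 * np.pi * self.r_edges[0] * self.ell))
        k_out = self.a_out / (1.0 / k_film + res[-1] * self.a_out /
                              (2.0 * np.pi * self.r_edges[-1] * self.ell))
        cap = ss * self.vol / dt
        diag = cap.copy()
        lower = np.zeros(n)
        upper = np.zeros(n)
        rhs = cap * u
        diag[:-1] += g
        diag[1:] += g
        upper[1:] = -g
        lower[:-1] = -g
        diag[0] += k_in
        rhs[0] += k_in * a_in
        diag[-1] += k_out
        rhs[-1] += k_out * a_out
        ab = np.zeros((3, n))
        ab[0] = upper
        ab[1] = diag
        ab[2] = lower
        u_new = solve_banded((1, 1), ab, rhs)
        self.u[species] = u_new
        flow_in = k_in * (a_in - u_new[0])
        flow_out = k_out * (u_new[-1] - a_out)
        return float(flow_in), float(flow_out)


class WallModel:
    """All wall sections of a bottle with their radial grids.

    Driving the model with prescribed activities (rather than through
    :func:`simulate`) is useful for verification against closed-form
    permeation results.
    """

    def __init__(
        self,
        sections: list[WallSection],
        t_c: float,
        abv_ref: float,
        options: SolverOptions,
        material: MaterialProps = PET,
        material_sleeve: MaterialProps = BOPET_SLEEVE,
    ):
        self.t_c = t_c
        self.options = options
        self.material = material
        props = material_props_at(t_c, abv_ref, material)
        props_sleeve = material_props_at(t_c, abv_ref, material_sleeve)
        self.props = props
        self.grids = [
            _SectionGrid(
                s, options.n_nodes, options.n_nodes_sleeve, props,
                props_sleeve if s.sleeve_thickness > 0 else None,
            )
            for s in sections
        ]
        t_k = celsius_to_kelvin(t_c)
        p_w_sat = thermo.saturation_pressure("water", t_k)
        p_e_sat = thermo.saturation_pressure("ethanol", t_k)
        h = options.h_conductance
        self.k_film = {
            "w": h * p_w_sat * M_WATER / (R_GAS * t_k),
            "e": h * p_e_sat * M_ETHANOL / (R_GAS * t_k),
        }

    def set_initial_concentrations(
        self, fields: list[dict[str, np.ndarray]]
    ) -> None:
        for grid, f in zip(self.grids, fields):
            grid.set_concentration("e", f["C_e"])
            grid.set_concentration("w", f["C_w"])

    def update_ethanol_diffusivity(self, abv: float) -> None:
        """Refresh D_e for the current liquid composition."""
        p = material_props_at(self.t_c, abv, self.material)
        for g in self.grids:
            g.props = (p, g.props[1])

    def content(self, species: str) -> float:
        return sum(g.content(species) for g in self.grids)

    def step(
        self, dt: float, a_liq: dict[str, float], a_ext: dict[str, float]
    ) -> dict[str, tuple[float, float]]:
        """Advance every section; return summed (flow_in, flow_out) per species."""
        flows = {}
        for sp in ("w", "e"):
            fi = fo = 0.0
            for g in self.grids:
                i, o = g.step(sp, dt, a_liq[sp], a_ext[sp], self.k_film[sp])
                fi += i
                fo += o
            flows[sp] = (fi, fo)
        return flows


@dataclass
class SimulationResult:
    """Time series of the coupled beverage/wall simulation.

    Mass loss follows the permeation definition (beverage plus packaging,
    i.e. the cumulative mass permeated to the exterior); the content
    definition (beverage only) is also recorded.  All masses in kg, time
    in seconds.
    """

    t: np.ndarray
    m_e: np.ndarray
    m_w: np.ndarray
    abv: np.ndarray
    sorbed_w: np.ndarray
    sorbed_e: np.ndarray
    permeated_w: np.ndarray
    permeated_e: np.ndarray
    m0_fill: float
    abv0: float
    meta: dict = field(default_factory=dict)
    wall_snapshot: list[dict[str, np.ndarray]] = field(default_factory=list)

    @property
    def t_days(self) -> np.ndarray:
        return self.t / 86400.0

    @property
    def mass_loss_permeation(self) -> np.ndarray:
        return self.permeated_w + self.permeated_e

    @property
    def mass_loss_content(self) -> np.ndarray:
        return (self.m_e[0] + self.m_w[0]) - (self.m_e + self.m_w)

    @property
    def mass_loss_rel(self) -> np.ndarray:
        """Permeation-definition mass loss relative to the filled mass."""
        return self.mass_loss_permeation / self.m0_fill

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_days": self.t_days,
                "mass_loss_pct": 100.0 * self.mass_loss_rel,
                "abv": self.abv,
                "sorbed_w_kg": self.sorbed_w,
                "sorbed_e_kg": self.sorbed_e,
                "permeated_w_kg": self.permeated_w,
                "permeated_e_kg": self.permeated_e,
            }
        )


def _x_e_of_w(w_e: float) -> float:
    return (w_e / M_ETHANOL) / (w_e / M_ETHANOL + (1.0 - w_e) / M_WATER)


def _abv_secant(w_target: float, guess: float) -> float:
    """Invert w_e(abv) locally by a safeguarded secant iteration."""
    if w_target <= 0.0:
        return 0.0
    if w_target >= 1.0:
        return 1.0
    a0 = float(np.clip(guess, 1e-6, 1.0 - 1e-6))
    a1 = float(np.clip(a0 + 1e-4, 1e-6, 1.0 - 1e-6))
    f0 = thermo.composition_from_abv(a0).w_e - w_target
    f1 = thermo.composition_from_abv(a1).w_e - w_target
    for _ in range(50):
        if f1 == f0:
            break
        a2 = a1 - f1 * (a1 - a0) / (f1 - f0)
        a2 = float(np.clip(a2, 0.0, 1.0))
        if abs(a2 - a1) < 1e-12:
            return a2
        a0, f0 = a1, f1
        a1 = a2
        f1 = thermo.composition_from_abv(a1).w_e - w_target
    return a1


def simulate(
    geometry: BottleGeometry,
    fill: FillState,
    t_storage_c: float,
    rh_pct: float,
    duration_days: float,
    material: MaterialProps = PET,
    options: SolverOptions | None = None,
    sleeve: tuple[tuple[float, float], float] | None = None,
    material_sleeve: MaterialProps = BOPET_SLEEVE,
) -> SimulationResult:
    """Simulate storage of a filled bottle.

    Parameters
    ----------
    geometry : the container.
    fill : filling state (defines the beverage inventory and headspace).
    t_storage_c, rh_pct : storage temperature (degC) and relative humidity (%).
    duration_days : simulated horizon.
    sleeve : optional ``((z_lo, z_hi), thickness)`` external film.
    options : numerical settings; defaults to :class:`SolverOptions`.

    Notes
    -----
    The beverage and headspace are treated as a single well-mixed
    reservoir whose composition sets the internal boundary activities;
    walls start in equilibrium with the pre-storage atmosphere.  The time
    step adapts so the per-step change of abv stays below
    ``options.dabv_per_step``.
    """
    opt = options or SolverOptions()
    sections = sectionize(geometry, opt.n_sections)
    if sleeve is not None:
        sections = apply_sleeve(sections, sleeve[0], sleeve[1], material_sleeve)

    abv0 = fill.abv0
    model = WallModel(sections, t_storage_c, abv0, opt, material, material_sleeve)
    fields = initialize_walls(sections, opt.rh0_walls_pct, opt.t0_walls_c, material)
    model.set_initial_concentrations(fields)

    # reservoir = liquid + headspace vapor (well mixed, equilibrated)
    m_e = fill.m_e0
    m_w = fill.m_w0
    m0_fill = m_e + m_w
    a_ext = {"w": rh_pct / 100.0, "e": 0.0}

    t_end = duration_days * 86400.0
    dt = opt.dt_init
    t = 0.0

    rec: dict[str, list[float]] = {k: [] for k in (
        "t", "m_e", "m_w", "abv", "sw", "se", "pw", "pe")}
    perm = {"w": 0.0, "e": 0.0}
    abv = abv0
    w_e_last_gamma = -1.0
    gamma_e = gamma_w = 1.0

    def record() -> None:
        rec["t"].append(t)
        rec["m_e"].append(m_e)
        rec["m_w"].append(m_w)
        rec["abv"].append(abv)
        rec["sw"].append(model.content("w"))
        rec["se"].append(model.content("e"))
        rec["pw"].append(perm["w"])
        rec["pe"].append(perm["e"])

    record()
    margin = opt.threshold_margin
    while t < t_end:
        dt = min(dt, t_end - t)
        w_e = m_e / (m_e + m_w)
        x_e = _x_e_of_w(w_e)
        if abs(w_e - w_e_last_gamma) > 1e-7 or w_e_last_gamma < 0:
            gamma_e, gamma_w = thermo._unifac.activity_coefficients(
                t_storage_c, x_e
            )
            abv = _abv_secant(w_e, abv)
            model.update_ethanol_diffusivity(abv)
            w_e_last_gamma = w_e
        a_liq = {"w": gamma_w * (1.0 - x_e), "e": gamma_e * x_e}
        flows = model.step(dt, a_liq, a_ext)
        dm_w = flows["w"][0] * dt
        dm_e = flows["e"][0] * dt
        if m_w - dm_w < 0 or m_e - dm_e < 0:
            raise RuntimeError("beverage inventory exhausted during simulation")
        m_w -= dm_w
        m_e -= dm_e
        perm["w"] += flows["w"][1] * dt
        perm["e"] += flows["e"][1] * dt
        t += dt
        w_e_new = m_e / (m_e + m_w)
        abv = _abv_secant(w_e_new, abv)
        record()
        # adapt the step on the abv increment
        dabv_step = abs(abv - rec["abv"][-2]) if len(rec["abv"]) > 1 else 0.0
        if dabv_step > 0:
            dt = min(
                dt * opt.dt_growth,
                dt * opt.dabv_per_step / dabv_step,
                opt.dt_max,
            )
        else:
            dt = min(dt * opt.dt_growth, opt.dt_max)
        if opt.stop_after_thresholds:
            loss_rel = (perm["w"] + perm["e"]) / m0_fill
            m_crossed = loss_rel >= opt.mass_loss_threshold * margin
            a_crossed = abs(abv - abv0) >= opt.dabv_threshold * margin
            if opt.stop_mode == "either" and (m_crossed or a_crossed):
                break
            if opt.stop_mode == "both" and m_crossed and (
                a_crossed or abv0 == 0.0
            ):
                break

    snapshot = [
        {"r": g.r_edges.copy(),
         "C_w": g.u["w"] * g._coeffs("w")[1],
         "C_e": g.u["e"] * g._coeffs("e")[1]}
        for g in model.grids
    ]
    return SimulationResult(
        t=np.array(rec["t"]),
        m_e=np.array(rec["m_e"]),
        m_w=np.array(rec["m_w"]),
        abv=np.array(rec["abv"]),
        sorbed_w=np.array(rec["sw"]),
        sorbed_e=np.array(rec["se"]),
        permeated_w=np.array(rec["pw"]),
        permeated_e=np.array(rec["pe"]),
        m0_fill=m0_fill,
        abv0=abv0,
        meta={
            "t_storage_c": t_storage_c,
            "rh_pct": rh_pct,
            "material": material.name,
            "options": opt,
            "n_sections": len(sections),
        },
        wall_snapshot=snapshot,
    )
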