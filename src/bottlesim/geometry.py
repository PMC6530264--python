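"""Bottle geometry: profiles, parametric shapes, volumes, areas, mass.

Two construction routes are supported:

* measured axisymmetric profiles (``z``, inner radius ``r``, wall thickness
  ``l``), the natural description of an existing bottle;
* a parametric design: a rounded-rectangle (superellipse) body of width
  ``W`` and depth ``D`` blending into a circular neck of diameter ``d``
  over a shoulder of height ``h``, with separate thicknesses for the body
  walls, neck, top and bottom.

Both are reduced to a dense vertical sampling of cross-section area,
wetted perimeter and wall thickness, from which internal volume, internal
surface area and plastic mass follow by quadrature.  For mass transfer the
wall is decomposed into vertical sections of similar thickness
(:func:`sectionize`), each treated as a thin cylindrical shell.

Units are SI meters internally; the profile CSV dialect uses mm for z and
r and micrometers for thickness (header ``z_mm,r_mm,l_um``).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import gamma as _gamma_fn

from .constants import RHO_PET

__all__ = [
    "BottleGeometry",
    "WallSection",
    "geometry_from_profile",
    "parametric_geometry",
    "sectionize",
    "read_profile_csv",
    "write_profile_csv",
]

_N_DENSE = 800  # dense vertical sampling for quadrature


@dataclass(frozen=True)
class WallSection:
    """Equivalent transport section: a thin cylindrical shell element.

    ``area`` is the internal (wetted) surface of the section; ``radius``
    the representative inner radius used by the cylindrical diffusion
    operator; ``sleeve_thickness`` a possible extra external layer.
    """

    z_lo: float
    z_hi: float
    radius: float
    thickness: float
    area: float
    sleeve_thickness: float = 0.0

    @property
    def area_over_thickness(self) -> float:
        return self.area / self.thickness


@dataclass(frozen=True)
class BottleGeometry:
    """Vertical sampling of a closed axisymmetric-equivalent container.

    ``z`` ascends from the base (z = 0) to the neck (z = H).  ``area_xs``
    is the internal cross-section area, ``perimeter`` the internal wetted
    perimeter (already including the slant correction for non-vertical
    walls), ``r_eq`` the equal-area circular radius and ``thickness`` the
    local wall thickness.  ``l_top = 0`` denotes an open mouth sealed by
    an impermeable closure (excluded from transport area and mass).
    """

    z: np.ndarray
    area_xs: np.ndarray
    perimeter: np.ndarray
    r_eq: np.ndarray
    thickness: np.ndarray
    l_bottom: float
    l_top: float
    rho_pet: float = RHO_PET
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        z = np.asarray(self.z, float)
        if z.ndim != 1 or z.size < 2:
            raise ValueError("z must be a 1D array with at least 2 samples")
        if np.any(np.diff(z) <= 0):
            raise ValueError("z must be strictly increasing")
        for name in ("area_xs", "perimeter", "r_eq", "thickness"):
            v = np.asarray(getattr(self, name), float)
            if v.shape != z.shape:
                raise ValueError(f"{name} must match z in shape")
            if np.any(v <= 0):
                raise ValueError(f"{name} must be positive everywhere")

    @property
    def height(self) -> float:
        return float(self.z[-1] - self.z[0])

    @property
    def v_internal(self) -> float:
        """Internal volume, m^3 (quadrature of the cross-section areas)."""
        return float(np.trapezoid(self.area_xs, self.z))

    @property
    def a_internal(self) -> float:
        """Internal polymer-wetted surface area, m^2 (lateral + caps)."""
        a = float(np.trapezoid(self.perimeter, self.z)) + float(self.area_xs[0])
        if self.l_top > 0:
            a += float(self.area_xs[-1])
        return a

    @property
    def mass(self) -> float:
        """Plastic mass of the container, kg (thin-shell quadrature)."""
        shell = float(np.trapezoid(self.perimeter * self.thickness, self.z))
        caps = float(self.area_xs[0]) * self.l_bottom
        if self.l_top > 0:
            caps += float(self.area_xs[-1]) * self.l_top
        return self.rho_pet * (shell + caps)


def _slant_perimeter(z: np.ndarray, r: np.ndarray, base_perimeter: np.ndarray):
    """Scale a perimeter profile by the local wall slant sqrt(1 + r'^2)."""
    drdz = np.gradient(r, z)
    return base_perimeter * np.sqrt(1.0 + drdz**2)


def geometry_from_profile(
    z: np.ndarray,
    r: np.ndarray,
    l: np.ndarray,
    rho_pet: float = RHO_PET,
    l_bottom: float | None = None,
    l_top: float | None = None,
    n_dense: int = _N_DENSE,
) -> BottleGeometry:
    """Build a revolution geometry from sampled (z, r, l) profiles.

    Profiles are interpolated linearly onto a dense grid.  Cap thicknesses
    default to the first/last thickness samples; ``l_top = 0`` marks an
    open mouth closed by an impermeable lid.
    """
    z = np.asarray(z, float)
    r = np.asarray(r, float)
    l = np.asarray(l, float)
    if z.ndim != 1 or z.size < 2 or r.shape != z.shape or l.shape != z.shape:
        raise ValueError("z, r, l must be 1D arrays of the same length >= 2")
    if np.any(np.diff(z) <= 0):
        raise ValueError("z must be strictly increasing")
    if np.any(r <= 0) or np.any(l <= 0):
        raise ValueError("radius and thickness must be positive")
    zz = np.linspace(z[0], z[-1], n_dense)
    rr = np.interp(zz, z, r)
    ll = np.interp(zz, z, l)
    perim = _slant_perimeter(zz, rr, 2.0 * np.pi * rr)
    return BottleGeometry(
        z=zz,
        area_xs=np.pi * rr**2,
        perimeter=perim,
        r_eq=rr,
        thickness=ll,
        l_bottom=float(l[0]) if l_bottom is None else float(l_bottom),
        l_top=float(l[-1]) if l_top is None else float(l_top),
        rho_pet=rho_pet,
        meta={"source": "profile"},
    )


def _superellipse_area(a: np.ndarray, b: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Area of |x/a|^p + |y/b|^p <= 1."""
    return 4.0 * a * b * _gamma_fn(1.0 + 1.0 / p) ** 2 / _gamma_fn(1.0 + 2.0 / p)


def _superellipse_perimeter(
    a: np.ndarray, b: np.ndarray, p: np.ndarray, n_quad: int = 192
) -> np.ndarray:
    """Perimeter of the superellipse, midpoint quadrature on a quarter arc."""
    t = (np.arange(n_quad) + 0.5) * (np.pi / 2.0) / n_quad
    ct, st = np.cos(t), np.sin(t)
    a = np.atleast_1d(np.asarray(a, float))[:, None]
    b = np.atleast_1d(np.asarray(b, float))[:, None]
    p = np.atleast_1d(np.asarray(p, float))[:, None]
    e = 2.0 / p
    dx = -a * e * ct ** (e - 1.0) * st
    dy = b * e * st ** (e - 1.0) * ct
    ds = np.sqrt(dx**2 + dy**2)
    return 4.0 * ds.sum(axis=1) * (np.pi / 2.0) / n_quad


def _smoothstep(u: np.ndarray) -> np.ndarray:
    return u * u * (3.0 - 2.0 * u)


def parametric_geometry(
    height: float,
    width: float,
    depth: float,
    neck_diameter: float,
    shoulder_height: float,
    l_wall: float,
    l_top: float,
    l_bottom: float,
    l_neck: float,
    rho_pet: float = RHO_PET,
    corner_exponent: float = 4.0,
    n_dense: int = _N_DENSE,
) -> BottleGeometry:
    """Parametric bottle: superellipse body blending into a circular neck.

    The body cross-section is a superellipse of half-axes W/2 x D/2 with
    exponent ``corner_exponent`` (2 = ellipse/circle, larger = squarer
    corners).  Over the shoulder height ``h`` the half-axes and exponent
    blend with a C1 smoothstep into a circle of diameter ``d``.  Walls use
    ``l_wall`` on the body and ``l_neck`` on the shoulder/neck; the top is
    a disk of thickness ``l_top`` (the cap region of the design).
    """
    for name, v in [
        ("height", height),
        ("width", width),
        ("depth", depth),
        ("neck_diameter", neck_diameter),
        ("shoulder_height", shoulder_height),
        ("l_wall", l_wall),
        ("l_top", l_top),
        ("l_bottom", l_bottom),
        ("l_neck", l_neck),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    if neck_diameter >= min(width, depth):
        raise ValueError(
            f"neck diameter {neck_diameter} must be smaller than both body "
            f"half-widths ({width}, {depth})"
        )
    if shoulder_height >= height:
        raise ValueError("shoulder height must be smaller than total height")
    if corner_exponent < 2.0:
        raise ValueError("corner exponent must be >= 2")

    z = np.linspace(0.0, height, n_dense)
    z_sh = height - shoulder_height
    u = np.clip((z - z_sh) / shoulder_height, 0.0, 1.0)
    s = _smoothstep(u)
    a = width / 2.0 + (neck_diameter / 2.0 - width / 2.0) * s
    b = depth / 2.0 + (neck_diameter / 2.0 - depth / 2.0) * s
    p = corner_exponent + (2.0 - corner_exponent) * s
    area = _superellipse_area(a, b, p)
    perim = _superellipse_perimeter(a, b, p)
    r_eq = np.sqrt(area / np.pi)
    perim = _slant_perimeter(z, r_eq, perim)
    thickness = l_wall + (l_neck - l_wall) * s
    return BottleGeometry(
        z=z,
        area_xs=area,
        perimeter=perim,
        r_eq=r_eq,
        thickness=thickness,
        l_bottom=l_bottom,
        l_top=l_top,
        rho_pet=rho_pet,
        meta={
            "source": "parametric",
            "blend": "superellipse-smoothstep",
            "H": height,
            "W": width,
            "D": depth,
            "d": neck_diameter,
            "h": shoulder_height,
            "l_wall": l_wall,
            "l_top": l_top,
            "l_bottom": l_bottom,
            "l_neck": l_neck,
            "corner_exponent": corner_exponent,
        },
    )


_PLANAR_RADIUS = 1.0  # m, puts cap disks in the planar limit of the solver


def sectionize(
    geometry: BottleGeometry, n: int, separate_caps: bool = True
) -> list[WallSection]:
    """Decompose the wall into ``n`` vertical equivalent sections.

    Sections partition the wetted surface; each carries the area-weighted
    mean thickness and radius of its z-range.  By default the bottom (and,
    if present, top) caps become their own planar sections, since their
    thickness usually differs strongly from the adjacent lateral wall;
    with ``separate_caps=False`` their area is folded into the first/last
    sections by area-weighted mean thickness instead.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    max_n = geometry.z.size - 1
    if n > max_n:
        warnings.warn(
            f"n={n} exceeds profile resolution; capped to {max_n}", stacklevel=2
        )
        n = max_n
    edges = np.linspace(geometry.z[0], geometry.z[-1], n + 1)
    sections: list[WallSection] = []
    for i in range(n):
        z_lo, z_hi = edges[i], edges[i + 1]
        interior = geometry.z[(geometry.z > z_lo) & (geometry.z < z_hi)]
        zz = np.concatenate([[z_lo], interior, [z_hi]])
        pp = np.interp(zz, geometry.z, geometry.perimeter)
        ll = np.interp(zz, geometry.z, geometry.thickness)
        rr = np.interp(zz, geometry.z, geometry.r_eq)
        area = float(np.trapezoid(pp, zz))
        thick = float(np.trapezoid(pp * ll, zz)) / area
        radius = float(np.trapezoid(pp * rr, zz)) / area
        if not separate_caps:
            if i == 0:
                cap = float(geometry.area_xs[0])
                thick = (thick * area + geometry.l_bottom * cap) / (area + cap)
                area += cap
            if i == n - 1 and geometry.l_top > 0:
                cap = float(geometry.area_xs[-1])
                thick = (thick * area + geometry.l_top * cap) / (area + cap)
                area += cap
        sections.append(
            WallSection(
                z_lo=float(z_lo),
                z_hi=float(z_hi),
                radius=radius,
                thickness=thick,
                area=area,
            )
        )
    if separate_caps:
        z0 = float(geometry.z[0])
        sections.insert(
            0,
            WallSection(
                z_lo=z0, z_hi=z0, radius=_PLANAR_RADIUS,
                thickness=geometry.l_bottom,
                area=float(geometry.area_xs[0]),
            ),
        )
        if geometry.l_top > 0:
            z1 = float(geometry.z[-1])
            sections.append(
                WallSection(
                    z_lo=z1, z_hi=z1, radius=_PLANAR_RADIUS,
                    thickness=geometry.l_top,
                    area=float(geometry.area_xs[-1]),
                )
            )
    return sections


# ---------------------------------------------------------------------------
# profile CSV dialect: header "z_mm,r_mm,l_um", comma separated, UTF-8


def write_profile_csv(
    path: str | Path | io.TextIOBase,
    z: np.ndarray,
    r: np.ndarray,
    l: np.ndarray,
) -> None:
    """Write a (z, r, l) profile in the package's CSV dialect (mm, mm, um)."""
    lines = ["z_mm,r_mm,l_um\n"]
    for zi, ri, li in zip(z, r, l):
        lines.append(f"{zi * 1e3:.6g},{ri * 1e3:.6g},{li * 1e6:.6g}\n")
    data = "".join(lines)
    if isinstance(path, io.TextIOBase):
        path.write(data)
    else:
        Path(path).write_text(data, encoding="utf-8")


def read_profile_csv(path: str | Path | io.TextIOBase) -> tuple[np.ndarray, ...]:
    """Read a profile CSV; returns ``(z, r, l)`` in meters."""
    if isinstance(path, io.TextIOBase):
        text = path.read()
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    header = lines[0].split(",")
    if [h.strip() for h in header] != ["z_mm", "r_mm", "l_um"]:
        raise ValueError(
            f"unexpected profile header {lines[0]!r}; expected 'z_mm,r_mm,l_um'"
        )
    rows = np.array([[float(v) for v in ln.split(",")] for ln in lines[1:]])
    return rows[:, 0] * 1e-3, rows[:, 1] * 1e-3, rows[:, 2] * 1e-6
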