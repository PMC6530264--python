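"""Regulatory shelf-life of a stored beverage.

Two EU criteria end the shelf-life of a bottled alcoholic beverage:

* mass: the prepackage may not fall short of its labeled content by more
  than the tolerable negative error, 1.5 % for capacities of 1 L and
  above (the strictest class);
* strength: the declared alcoholic strength by volume must stay within
  +/- 0.3 % vol (0.003 absolute in the fractional representation).

Shelf-life is the first time either criterion is crossed.  For smaller
capacities the tolerable negative error is larger (9 % at 50 mL), so the
mass criterion time scales by the ratio of tolerable errors - 6x between
the >= 1 L class and a 50 mL miniature - while the strength criterion is
capacity-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .transport import SimulationResult

__all__ = [
    "ShelfLifeResult",
    "evaluate",
    "extrapolate_capacity",
    "capacity_factor",
    "MASS_LOSS_THRESHOLD",
    "DABV_THRESHOLD",
]

#: relative mass-loss threshold (tolerable negative error >= 1 L class)
MASS_LOSS_THRESHOLD = 0.015
#: absolute abv drift threshold (+/- 0.3 % vol)
DABV_THRESHOLD = 0.003

# EU tolerable negative errors for prepackaged liquids by nominal capacity.
# Each row: (capacity_min_m3, capacity_max_m3, pct, absolute_m3-equivalent?)
# Expressed as either a percentage of the nominal quantity or an absolute
# volume, whichever the directive states for that class.
_TNE_TABLE = [
    # (lo mL, hi mL, pct or None, absolute mL or None)
    (5.0, 50.0, 9.0, None),
    (50.0, 100.0, None, 4.5),
    (100.0, 200.0, 4.5, None),
    (200.0, 300.0, None, 9.0),
    (300.0, 500.0, 3.0, None),
    (500.0, 1000.0, None, 15.0),
    (1000.0, 10000.0, 1.5, None),
]


def tolerable_negative_error_pct(capacity_m3: float) -> float:
    """Tolerable negative error as a percentage of the nominal capacity."""
    cap_ml = capacity_m3 * 1e6
    for lo, hi, pct, abs_ml in _TNE_TABLE:
        if lo <= cap_ml <= hi:
            return pct if pct is not None else 100.0 * abs_ml / cap_ml
    supported = ", ".join(f"[{lo:g}, {hi:g}] mL" for lo, hi, _, _ in _TNE_TABLE)
    raise ValueError(
        f"capacity {cap_ml:g} mL outside the tolerable-error classes: {supported}"
    )


def capacity_factor(capacity_m3: float) -> float:
    """Scaling factor of the mass criterion relative to the >= 1 L class."""
    return tolerable_negative_error_pct(capacity_m3) / (100.0 * MASS_LOSS_THRESHOLD)


@dataclass(frozen=True)
class ShelfLifeResult:
    """First-crossing times of the two criteria and their combination.

    ``t_m``/``t_a`` in days (``inf`` when never crossed within the
    simulated horizon); ``factor`` is the capacity extrapolation applied
    to ``t_m``; ``shelf_life_days`` is floored to whole days only when a
    capacity extrapolation is requested.
    """

    t_m_days: float
    t_a_days: float
    shelf_life_days: float
    binding: str  # "mass" | "abv" | "censored"
    factor: float = 1.0
    censored: bool = False


def _first_crossing(t_days: np.ndarray, y: np.ndarray, threshold: float) -> float:
    """First time ``y`` reaches ``threshold``, linear between samples."""
    above = np.nonzero(y >= threshold)[0]
    if above.size == 0:
        return math.inf
    i = int(above[0])
    if i == 0:
        return float(t_days[0])
    frac = (threshold - y[i - 1]) / (y[i] - y[i - 1])
    return float(t_days[i - 1] + frac * (t_days[i] - t_days[i - 1]))


def evaluate(result: SimulationResult) -> ShelfLifeResult:
    """Criterion crossing times of a simulation (>= 1 L class, factor 1)."""
    if result.t.size == 0:
        raise ValueError("empty simulation series")
    t_days = result.t_days
    t_m = _first_crossing(t_days, result.mass_loss_rel, MASS_LOSS_THRESHOLD)
    t_a = _first_crossing(
        t_days, np.abs(result.abv - result.abv0), DABV_THRESHOLD
    )
    shelf = min(t_m, t_a)
    censored = math.isinf(shelf)
    binding = (
        "censored" if censored else ("mass" if t_m <= t_a else "abv")
    )
    return ShelfLifeResult(
        t_m_days=t_m,
        t_a_days=t_a,
        shelf_life_days=shelf,
        binding=binding,
        factor=1.0,
        censored=censored,
    )


def extrapolate_capacity(
    t_m_days: float,
    t_a_days: float | None,
    capacity_m3: float,
) -> float:
    """Shelf-life in whole days for a container of the given capacity
    (``inf`` when censored, i.e. neither criterion ever crossed).

    The mass criterion time scales by the ratio of the capacity class's
    tolerable negative error to the 1.5 % reference; the strength
    criterion does not scale.  The combined shelf-life is floored to
    whole days.
    """
    if t_m_days is None or not t_m_days > 0:
        raise ValueError(f"t_m must be positive, got {t_m_days}")
    factor = capacity_factor(capacity_m3)
    candidates = [factor * t_m_days]
    if t_a_days is not None and math.isfinite(t_a_days):
        candidates.append(float(t_a_days))
    best = min(candidates)
    if math.isinf(best):  # censored: neither criterion crossed
        return math.inf
    return int(math.floor(best))
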