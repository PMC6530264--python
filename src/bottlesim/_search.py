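"""Derivative-free 1D minimization by golden-section interval reduction.

The nested equilibration and design loops of this package all reduce to
bounded scalar minimizations; a deterministic golden-section search keeps
them reproducible bit-for-bit.
"""

from __future__ import annotations

from typing import Callable

_INVPHI = 0.6180339887498949  # 1/phi
_INVPHI2 = 0.3819660112501051  # 1/phi^2


def golden_section(
    f: Callable[[float], float],
    lo: float,
    hi: float,
    xtol: float = 1e-12,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Minimize ``f`` on ``[lo, hi]``; return ``(x_min, f(x_min))``.

    Assumes ``f`` is unimodal on the bracket; otherwise converges to a
    local minimum.  ``xtol`` is an absolute tolerance on the bracket width.
    """
    if hi <= lo:
        raise ValueError(f"invalid bracket [{lo}, {hi}]")
    a, b = lo, hi
    h = b - a
    c = a + _INVPHI2 * h
    d = a + _INVPHI * h
    fc = f(c)
    fd = f(d)
    for _ in range(max_iter):
        if h <= xtol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            h = b - a
            c = a + _INVPHI2 * h
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            h = b - a
            d = a + _INVPHI * h
            fd = f(d)
    if fc < fd:
        return c, fc
    return d, fd
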