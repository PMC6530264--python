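"""Alcoholometric density of water-ethanol mixtures.

Implements the international alcoholometric polynomial (OIML R22, revised
coefficients of Bettin & Spieweck) giving the density of a binary
water-ethanol mixture as a function of temperature and ethanol mass
fraction.  The formula is fitted on data from -20 to 40 degC over the full
composition range; above 40 degC this package evaluates the same polynomial
form as a smooth extrapolation (documented in the methods note).
"""

from __future__ import annotations

import numpy as np

# rho(t, w) = sum_k A_k w^(k-1) + sum_k B_k (t-20)^k
#             + sum_i sum_k C_{i,k} w^k (t-20)^i      [kg m^-3, t in degC]
_A = np.array(
    [
        9.982012300e2,
        -1.929769495e2,
        3.891238958e2,
        -1.668103923e3,
        1.352215441e4,
        -8.829278388e4,
        3.062874042e5,
        -6.138381234e5,
        7.470172998e5,
        -5.478461354e5,
        2.234460334e5,
        -3.903285426e4,
    ]
)

_B = np.array(
    [
        -2.0618513e-1,
        -5.2682542e-3,
        3.6130013e-5,
        -3.8957702e-7,
        7.1693540e-9,
        -9.9739231e-11,
    ]
)

# C[i][k-1] multiplies w^k (t-20)^(i+1)
_C = [
    np.array(
        [
            1.693443461530087e-1,
            -1.046914743455169e1,
            7.196353469546523e1,
            -7.047478054272792e2,
            3.924090430035045e3,
            -1.210164659068747e4,
            2.248646550400788e4,
            -2.605562982188164e4,
            1.852373922069467e4,
            -7.420201433430137e3,
            1.285617841998974e3,
        ]
    ),
    np.array(
        [
            -1.193013005057010e-2,
            2.517399633803461e-1,
            -2.170575700536993,
            1.353034988843029e1,
            -5.029988758547014e1,
            1.096355666577570e2,
            -1.422753946421155e2,
            1.080435942856230e2,
            -4.414153236817392e1,
            7.442971530188783,
        ]
    ),
    np.array(
        [
            -6.802995733503803e-4,
            1.876837790289664e-2,
            -2.002561813734156e-1,
            1.022992966719220,
            -2.895696483903638,
            4.810060584300675,
            -4.672147440794683,
            2.458043105903461,
            -5.411227621436812e-1,
        ]
    ),
    np.array(
        [
            4.075376675622027e-6,
            -8.763058573471110e-6,
            6.515031360099368e-6,
            -1.515784836987210e-6,
        ]
    ),
    np.array(
        [
            -2.788074354782409e-8,
            1.345612883493354e-8,
        ]
    ),
]

#: Validity range of the fitted correlation (degC); evaluation is allowed up
#: to T_MAX_EXTRAP with the polynomial continued smoothly.
T_MIN = -20.0
T_MAX_FIT = 40.0
T_MAX_EXTRAP = 70.0


def mixture_density_w(t_c: float, w_e: float) -> float:
    """Density of a water-ethanol mixture, kg m^-3.

    Parameters
    ----------
    t_c : temperature in degC, within [-20, 70].
    w_e : ethanol mass fraction in [0, 1].
    """
    if not (T_MIN <= t_c <= T_MAX_EXTRAP):
        raise ValueError(
            f"temperature {t_c} degC outside density validity range "
            f"[{T_MIN}, {T_MAX_EXTRAP}] degC"
        )
    if not (0.0 <= w_e <= 1.0):
        raise ValueError(f"ethanol mass fraction {w_e} outside [0, 1]")
    dt = t_c - 20.0
    w_pow = w_e ** np.arange(12)
    rho = float(_A @ w_pow)
    dt_pow = dt ** np.arange(1, 7)
    rho += float(_B @ dt_pow)
    for i, c in enumerate(_C):
        wk = w_e ** np.arange(1, len(c) + 1)
        rho += float(c @ wk) * dt ** (i + 1)
    return rho
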