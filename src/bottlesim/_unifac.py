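"""Binary UNIFAC activity coefficients for water-ethanol.

Original UNIFAC (group-contribution) specialized to the single binary this
package needs: ethanol decomposed into CH3 + CH2 + OH, water as the H2O
group.  Group volume/surface parameters and main-group interaction
parameters are the standard published original-UNIFAC values, embedded as
named constants.  The model predicts the positive deviation from Raoult's
law that drives evaporation and sorption of both species.
"""

from __future__ import annotations

import numpy as np

from .constants import celsius_to_kelvin

# groups: 0=CH3, 1=CH2, 2=OH, 3=H2O
_R_K = np.array([0.9011, 0.6744, 1.0000, 0.9200])
_Q_K = np.array([0.8480, 0.5400, 1.2000, 1.4000])

# main groups: CH3/CH2 -> alkane (index 0), OH -> 1, H2O -> 2
_MAIN = np.array([0, 0, 1, 2])

# interaction parameters a_mn (K), original UNIFAC, rows=m, cols=n
_A_MN = np.array(
    [
        [0.0, 986.5, 1318.0],  # CH2 -> {CH2, OH, H2O}
        [156.4, 0.0, 353.5],  # OH
        [300.0, -229.1, 0.0],  # H2O
    ]
)

# molecule group counts: ethanol = CH3 CH2 OH, water = H2O
_NU = np.array(
    [
        [1, 1, 1, 0],  # ethanol
        [0, 0, 0, 1],  # water
    ],
    dtype=float,
)

_R_I = _NU @ _R_K  # [2.5755, 0.92]
_Q_I = _NU @ _Q_K  # [2.588, 1.40]

_Z = 10.0

#: Temperature validity used by callers (degC)
T_MIN_C = 10.0
T_MAX_C = 70.0


def _psi(t_k: float) -> np.ndarray:
    return np.exp(-_A_MN / t_k)


def _ln_gamma_groups(x_groups: np.ndarray, t_k: float) -> np.ndarray:
    """Residual group activity ln(Gamma_k) for a group mole-fraction vector."""
    theta = _Q_K * x_groups
    theta = theta / theta.sum()
    psi = _psi(t_k)
    # map group-level theta onto main groups
    theta_m = np.zeros(3)
    for k, m in enumerate(_MAIN):
        theta_m[m] += theta[k]
    s_m = theta_m @ psi  # sum_m theta_m psi_mn for each n
    ln_g = np.empty(4)
    for k, mk in enumerate(_MAIN):
        ln_g[k] = _Q_K[k] * (
            1.0
            - np.log(s_m[mk])
            - float((theta_m * psi[mk, :] / s_m).sum())
        )
    return ln_g


def activity_coefficients(t_c: float, x_e: float) -> tuple[float, float]:
    """Return (gamma_e, gamma_w) at temperature ``t_c`` (degC) and ethanol
    liquid mole fraction ``x_e``.

    Pure-component limits return exactly 1.0.
    """
    if not (T_MIN_C <= t_c <= T_MAX_C):
        raise ValueError(
            f"temperature {t_c} degC outside activity-model range "
            f"[{T_MIN_C}, {T_MAX_C}] degC"
        )
    if not (0.0 <= x_e <= 1.0):
        raise ValueError(f"mole fraction {x_e} outside [0, 1]")
    t_k = celsius_to_kelvin(t_c)
    x = np.array([x_e, 1.0 - x_e])

    # combinatorial part (Stavermann-Guggenheim)
    # Computed via phi_i/x_i and theta_i/phi_i, well-defined at x_i -> 0.
    rx = x @ _R_I
    qx = x @ _Q_I
    phi_over_x = _R_I / rx
    theta_over_phi = (_Q_I / _R_I) * (rx / qx)
    l_i = (_Z / 2.0) * (_R_I - _Q_I) - (_R_I - 1.0)
    ln_gc = (
        np.log(phi_over_x)
        + (_Z / 2.0) * _Q_I * np.log(theta_over_phi)
        + l_i
        - phi_over_x * (x @ l_i)
    )

    # residual part
    total_nu = _NU.sum(axis=1)
    x_groups_mix = x @ _NU
    x_groups_mix = x_groups_mix / x_groups_mix.sum()
    ln_g_mix = _ln_gamma_groups(x_groups_mix, t_k)
    ln_gr = np.zeros(2)
    for i in range(2):
        x_groups_pure = _NU[i] / total_nu[i]
        ln_g_pure = _ln_gamma_groups(
            np.where(x_groups_pure > 0, x_groups_pure, 1e-300), t_k
        )
        ln_gr[i] = float((_NU[i] * (ln_g_mix - ln_g_pure)).sum())

    gamma = np.exp(ln_gc + ln_gr)
    # enforce the exact Raoult limit at the pure ends
    if x_e == 1.0:
        gamma[0] = 1.0
    if x_e == 0.0:
        gamma[1] = 1.0
    return float(gamma[0]), float(gamma[1])
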