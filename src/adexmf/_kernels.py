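"""Numba kernel for the mean-field drift.

Scalar re-implementation of the moment formulas, transfer function and the
seven-equation right-hand side, compiled per node.  Kept in exact agreement
with the vectorized reference in :mod:`adexmf.meanfield` (the unit tests
pin both against independently transcribed formulas).
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

# indices into the constants vector
_C_FIELDS = (
    "K_e", "K_i", "Q_e", "Q_i", "tau_e", "tau_i", "E_e", "E_i", "g_L", "C_m",
    "E_L_e", "E_L_i", "T", "N_e", "N_i", "b_e", "b_i", "a", "tau_w", "tau_w_i",
    "rate_max",
)


def pack_constants(si) -> np.ndarray:
    return np.array([getattr(si, f) for f in _C_FIELDS], dtype=np.float64)


_RATE_EPS = 1e-3
_H = 1e-4

_DE = np.array([0.0, 1.0, -1.0, 0.0, 0.0, 1.0, 1.0, -1.0, -1.0])
_DI = np.array([0.0, 0.0, 0.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])


@njit(cache=True, fastmath=False)
def _tf_point(fe, fi, W, E_L, P, Q_e, Q_i, tau_e, tau_i, E_e, E_i, g_L, C_m, rate_max):
    if fe < 0.0:
        fe = 0.0
    if fi < 0.0:
        fi = 0.0
    fe += _RATE_EPS
    fi += _RATE_EPS
    mu_Ge = Q_e * tau_e * fe
    mu_Gi = Q_i * tau_i * fi
    mu_G = g_L + mu_Ge + mu_Gi
    mu_V = (mu_Ge * E_e + mu_Gi * E_i + g_L * E_L - W) / mu_G
    tau_m = C_m / mu_G
    U_e = Q_e / mu_G * (E_e - mu_V)
    U_i = Q_i / mu_G * (E_i - mu_V)
    s_e = fe * (U_e * tau_e) ** 2
    s_i = fi * (U_i * tau_i) ** 2
    sigma_V = math.sqrt(
        s_e / (2.0 * (tau_e + tau_m)) + s_i / (2.0 * (tau_i + tau_m))
    )
    tau_V = (s_e + s_i) / (s_e / (tau_e + tau_m) + s_i / (tau_i + tau_m))
    V = (mu_V + 60e-3) / 10e-3
    S = (sigma_V - 4e-3) / 6e-3
    Tn = tau_V * g_L / C_m - 0.5
    v_thr = (
        P[0] + P[1] * V + P[2] * S + P[3] * Tn + P[4] * V * V + P[5] * S * S
        + P[6] * Tn * Tn + P[7] * V * S + P[8] * V * Tn + P[9] * S * Tn
    )
    rate = math.erfc((v_thr - mu_V) / (math.sqrt(2.0) * sigma_V)) / (2.0 * tau_V)
    if rate < 0.0:
        rate = 0.0
    elif rate > rate_max:
        rate = rate_max
    return rate, mu_V


@njit(cache=True, fastmath=False)
def drift(y, ext_e, C, P_e, P_i, de, di, out):
    """Seven-equation drift (SI, per second) for all nodes."""
    (K_e, K_i, Q_e, Q_i, tau_e, tau_i, E_e, E_i, g_L, C_m,
     E_L_e, E_L_i, T, N_e, N_i, b_e, b_i, a, tau_w, tau_w_i,
     rate_max) = (
        C[0], C[1], C[2], C[3], C[4], C[5], C[6], C[7], C[8], C[9],
        C[10], C[11], C[12], C[13], C[14], C[15], C[16], C[17], C[18], C[19],
        C[20],
    )
    n = y.shape[1]
    Fe = np.empty(9)
    Fi = np.empty(9)
    for k in range(n):
        nu_e = y[0, k]
        nu_i = y[1, k]
        c_ee = y[2, k]
        c_ei = y[3, k]
        c_ii = y[4, k]
        W_e = y[5, k]
        W_i = y[6, k]

        base_e = nu_e + ext_e[k]
        if base_e < 0.0:
            base_e = 0.0
        base_i = nu_i
        if base_i < 0.0:
            base_i = 0.0

        mu_V_e0 = 0.0
        for s in range(9):
            fe = (base_e + _H * de[s]) * K_e
            fi = (base_i + _H * di[s]) * K_i
            r_e, mv = _tf_point(fe, fi, W_e, E_L_e, P_e,
                                Q_e, Q_i, tau_e, tau_i, E_e, E_i, g_L, C_m, rate_max)
            r_i, _ = _tf_point(fe, fi, W_i, E_L_i, P_i,
                               Q_e, Q_i, tau_e, tau_i, E_e, E_i, g_L, C_m, rate_max)
            Fe[s] = r_e
            Fi[s] = r_i
            if s == 0:
                mu_V_e0 = mv

        Fe0 = Fe[0]
        Fi0 = Fi[0]
        dFe_de = (Fe[1] - Fe[2]) / (2 * _H)
        dFe_di = (Fe[3] - Fe[4]) / (2 * _H)
        dFi_de = (Fi[1] - Fi[2]) / (2 * _H)
        dFi_di = (Fi[3] - Fi[4]) / (2 * _H)
        h2 = _H * _H
        d2Fe_ee = (Fe[1] + Fe[2] - 2 * Fe0) / h2
        d2Fe_ii = (Fe[3] + Fe[4] - 2 * Fe0) / h2
        d2Fe_ei = (Fe[5] - Fe[6] - Fe[7] + Fe[8]) / (4 * h2)
        d2Fi_ee = (Fi[1] + Fi[2] - 2 * Fi0) / h2
        d2Fi_ii = (Fi[3] + Fi[4] - 2 * Fi0) / h2
        d2Fi_ei = (Fi[5] - Fi[6] - Fi[7] + Fi[8]) / (4 * h2)

        out[0, k] = (
            Fe0 - nu_e
            + 0.5 * (c_ee * d2Fe_ee + 2 * c_ei * d2Fe_ei + c_ii * d2Fe_ii)
        ) / T
        out[1, k] = (
            Fi0 - nu_i
            + 0.5 * (c_ee * d2Fi_ee + 2 * c_ei * d2Fi_ei + c_ii * d2Fi_ii)
        ) / T
        out[2, k] = (
            Fe0 * (1.0 / T - Fe0) / N_e
            + (Fe0 - nu_e) ** 2
            + 2.0 * (dFe_de * c_ee + dFe_di * c_ei)
            - 2.0 * c_ee
        ) / T
        out[3, k] = (
            (Fe0 - nu_e) * (Fi0 - nu_i)
            + dFe_de * c_ei
            + dFe_di * c_ii
            + dFi_de * c_ee
            + dFi_di * c_ei
            - 2.0 * c_ei
        ) / T
        out[4, k] = (
            Fi0 * (1.0 / T - Fi0) / N_i
            + (Fi0 - nu_i) ** 2
            + 2.0 * (dFi_de * c_ei + dFi_di * c_ii)
            - 2.0 * c_ii
        ) / T
        out[5, k] = (
            -W_e + b_e * tau_w * nu_e + a * (mu_V_e0 - E_L_e)
        ) / tau_w
        out[6, k] = (-W_i + b_i * tau_w_i * nu_i) / tau_w_i
    return out
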