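"""Second-order mean-field dynamics of one excitatory/inhibitory region.

The model tracks seven variables per region: the two population rates, three
rate covariances and two adaptation currents.  The population transfer
function follows the first-passage form: membrane-potential moments are
computed from the presynaptic rates via shot-noise conductance formulas, an
effective firing threshold is read off a fitted second-order polynomial in
the normalized moments, and the output rate is

    rate = erfc((V_thr_eff - mu_V) / (sqrt(2) * sigma_V)) / (2 * tau_V)

clipped to the refractory-limited maximum.

The local recurrent drive is implicit: a population's own excitatory rate
always feeds its synapses with in-degree ``K_e``; the *external* excitatory
input (long-range coupling, noise drive, afferent input) adds to it on the
same footing.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import erfc

from .params import ModelParams, TransferFunctionParams, default_transfer_functions

__all__ = [
    "NodeState",
    "NumericsError",
    "membrane_moments",
    "transfer_function",
    "meanfield_derivatives",
    "find_fixed_points",
]

#: floor (Hz) added to total presynaptic rates inside the moment formulas,
#: keeping sigma_V and tau_V defined at zero input
_RATE_EPS = 1e-3

#: finite-difference step (Hz) for transfer-function derivatives
_DIFF_STEP = 1e-4

#: normalization constants of the effective-threshold polynomial (SI)
_MUV0, _DMUV0 = -60e-3, 10e-3
_SV0, _DSV0 = 4e-3, 6e-3
_TVN0, _DTVN0 = 0.5, 1.0

# finite-difference stencil offsets (units of the step) used for the
# gradient and Hessian of the transfer function w.r.t. (nu_e, nu_i)
_DE = np.array([0.0, 1.0, -1.0, 0.0, 0.0, 1.0, 1.0, -1.0, -1.0])
_DI = np.array([0.0, 0.0, 0.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])

# display <-> SI conversion for the 7-component state vector
# [nu_e, nu_i, c_ee, c_ei, c_ii, W_e, W_i]  (Hz, Hz^2, pA  <->  Hz, Hz^2, A)
_STATE_TO_SI = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1e-12, 1e-12])
# SI drift (per second) -> display drift (per ms)
_DRIFT_TO_DISPLAY = np.array([1e-3, 1e-3, 1e-3, 1e-3, 1e-3, 1e9, 1e9])


class NumericsError(RuntimeError):
    """Raised when the transfer-function evaluation produces non-finite
    moments."""


@dataclass
class NodeState:
    """State of one region: rates (Hz), rate covariances (Hz^2) and
    adaptation currents (pA)."""

    nu_e: float = 1.0
    nu_i: float = 1.0
    c_ee: float = 0.0
    c_ei: float = 0.0
    c_ii: float = 0.0
    W_e: float = 0.0
    W_i: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.nu_e, self.nu_i, self.c_ee, self.c_ei, self.c_ii, self.W_e, self.W_i]
        )

    @classmethod
    def from_array(cls, arr) -> "NodeState":
        return cls(*(float(x) for x in np.asarray(arr)))


def _moments_si(fe, fi, W, E_L, si):
    """Membrane-potential moments from total presynaptic rates (SI).

    ``fe``/``fi`` are total excitatory/inhibitory presynaptic rates per
    neuron in Hz (in-degree already applied), ``W`` the adaptation current
    in A, ``E_L`` the leak reversal in V.  Returns ``(mu_V, sigma_V,
    tau_V)`` in V, V, s.  Broadcasts over arrays.
    """
    fe = np.maximum(fe, 0.0) + _RATE_EPS
    fi = np.maximum(fi, 0.0) + _RATE_EPS
    mu_Ge = si.Q_e * si.tau_e * fe
    mu_Gi = si.Q_i * si.tau_i * fi
    mu_G = si.g_L + mu_Ge + mu_Gi
    mu_V = (mu_Ge * si.E_e + mu_Gi * si.E_i + si.g_L * E_L - W) / mu_G
    tau_m = si.C_m / mu_G
    U_e = si.Q_e / mu_G * (si.E_e - mu_V)
    U_i = si.Q_i / mu_G * (si.E_i - mu_V)
    s_e = fe * (U_e * si.tau_e) ** 2
    s_i = fi * (U_i * si.tau_i) ** 2
    sigma_V = np.sqrt(s_e / (2.0 * (si.tau_e + tau_m)) + s_i / (2.0 * (si.tau_i + tau_m)))
    tau_V = (s_e + s_i) / (s_e / (si.tau_e + tau_m) + s_i / (si.tau_i + tau_m))
    return mu_V, sigma_V, tau_V


def _effective_threshold(mu_V, sigma_V, tau_V, P, si):
    """Fitted effective threshold (V) as a second-order polynomial in the
    normalized moments."""
    V = (mu_V - _MUV0) / _DMUV0
    S = (sigma_V - _SV0) / _DSV0
    T = (tau_V * si.g_L / si.C_m - _TVN0) / _DTVN0
    return (
        P[0]
        + P[1] * V
        + P[2] * S
        + P[3] * T
        + P[4] * V * V
        + P[5] * S * S
        + P[6] * T * T
        + P[7] * V * S
        + P[8] * V * T
        + P[9] * S * T
    )


def _tf_si(fe, fi, W, E_L, P, si, return_mu_v=False):
    """Population transfer function (Hz) from total presynaptic rates (SI)."""
    mu_V, sigma_V, tau_V = _moments_si(fe, fi, W, E_L, si)
    v_thr = _effective_threshold(mu_V, sigma_V, tau_V, P, si)
    rate = erfc((v_thr - mu_V) / (np.sqrt(2.0) * sigma_V)) / (2.0 * tau_V)
    rate = np.clip(rate, 0.0, si.rate_max)
    if return_mu_v:
        return rate, mu_V
    return rate


def _tf_stencil(nu_e, nu_i, W_e, W_i, ext_e, si, P_e, P_i):
    """Evaluate both transfer functions on the 9-point finite-difference
    stencil around ``(nu_e + ext_e, nu_i)``.

    Returns ``(F_e, F_i, mu_V_e)`` with the stencils of shape ``(9, n)``.
    """
    h = _DIFF_STEP
    n = nu_e.shape[0]
    fe = (np.maximum(nu_e + ext_e, 0.0) + h * _DE[:, None]) * si.K_e
    fi = (np.maximum(nu_i, 0.0) + h * _DI[:, None]) * si.K_i
    # stack the two populations along a leading axis for one batched call
    W = np.empty((2, 1, n))
    W[0, 0] = W_e
    W[1, 0] = W_i
    EL = np.array([si.E_L_e, si.E_L_i]).reshape(2, 1, 1)
    P = np.stack([np.asarray(P_e), np.asarray(P_i)], axis=1).reshape(10, 2, 1, 1)
    F, mu_V = _tf_si(fe[None], fi[None], W, EL, P, si, return_mu_v=True)
    return F[0], F[1], mu_V[0, 0]


def _drift_si(y, ext_e, si, P_e, P_i):
    """Right-hand side of the seven mean-field equations (SI, per second).

    Thin wrapper around the compiled kernel; see :func:`_drift_si_numpy`
    for the vectorized reference implementation kept in exact agreement.
    """
    from . import _kernels

    y = np.asarray(y, dtype=float)
    n = y.shape[1]
    ext = np.ascontiguousarray(np.broadcast_to(np.asarray(ext_e, dtype=float), (n,)))
    out = np.empty_like(y)
    return _kernels.drift(
        np.ascontiguousarray(y),
        ext,
        _kernels.pack_constants(si),
        np.asarray(P_e, dtype=float),
        np.asarray(P_i, dtype=float),
        _kernels._DE,
        _kernels._DI,
        out,
    )


def _drift_si_numpy(y, ext_e, si, P_e, P_i):
    """Right-hand side of the seven mean-field equations (SI, per second).

    ``y`` has shape (7, n); ``ext_e`` is the external excitatory input rate
    per node (Hz), added to each node's own excitatory rate before the
    in-degree is applied.  The rate equations carry the second-order
    covariance correction through a finite-difference Hessian of the
    transfer function; the covariance equations carry the finite-size source
    term and the gradient coupling terms.
    """
    nu_e, nu_i, c_ee, c_ei, c_ii, W_e, W_i = y
    h = _DIFF_STEP

    F_e, F_i, mu_V_e0 = _tf_stencil(nu_e, nu_i, W_e, W_i, ext_e, si, P_e, P_i)

    Fe0, Fi0 = F_e[0], F_i[0]
    dFe_de = (F_e[1] - F_e[2]) / (2 * h)
    dFe_di = (F_e[3] - F_e[4]) / (2 * h)
    dFi_de = (F_i[1] - F_i[2]) / (2 * h)
    dFi_di = (F_i[3] - F_i[4]) / (2 * h)
    h2 = h * h
    d2Fe_ee = (F_e[1] + F_e[2] - 2 * Fe0) / h2
    d2Fe_ii = (F_e[3] + F_e[4] - 2 * Fe0) / h2
    d2Fe_ei = (F_e[5] - F_e[6] - F_e[7] + F_e[8]) / (4 * h2)
    d2Fi_ee = (F_i[1] + F_i[2] - 2 * Fi0) / h2
    d2Fi_ii = (F_i[3] + F_i[4] - 2 * Fi0) / h2
    d2Fi_ei = (F_i[5] - F_i[6] - F_i[7] + F_i[8]) / (4 * h2)

    T = si.T
    dnu_e = (
        Fe0 - nu_e + 0.5 * (c_ee * d2Fe_ee + 2 * c_ei * d2Fe_ei + c_ii * d2Fe_ii)
    ) / T
    dnu_i = (
        Fi0 - nu_i + 0.5 * (c_ee * d2Fi_ee + 2 * c_ei * d2Fi_ei + c_ii * d2Fi_ii)
    ) / T

    dc_ee = (
        Fe0 * (1.0 / T - Fe0) / si.N_e
        + (Fe0 - nu_e) ** 2
        + 2.0 * (dFe_de * c_ee + dFe_di * c_ei)
        - 2.0 * c_ee
    ) / T
    dc_ei = (
        (Fe0 - nu_e) * (Fi0 - nu_i)
        + dFe_de * c_ei
        + dFe_di * c_ii
        + dFi_de * c_ee
        + dFi_di * c_ei
        - 2.0 * c_ei
    ) / T
    dc_ii = (
        Fi0 * (1.0 / T - Fi0) / si.N_i
        + (Fi0 - nu_i) ** 2
        + 2.0 * (dFi_de * c_ei + dFi_di * c_ii)
        - 2.0 * c_ii
    ) / T

    dW_e = (
        -W_e + si.b_e * si.tau_w * nu_e + si.a * (mu_V_e0 - si.E_L_e)
    ) / si.tau_w
    dW_i = (-W_i + si.b_i * si.tau_w_i * nu_i) / si.tau_w_i

    return np.stack([dnu_e, dnu_i, dc_ee, dc_ei, dc_ii, dW_e, dW_i])


def _drift_display(y_disp, ext_e, si, P_e, P_i):
    """Drift in display units: state (Hz, Hz^2, pA) -> derivative per ms."""
    y_si = y_disp * _STATE_TO_SI[:, None]
    return _drift_si(y_si, ext_e, si, P_e, P_i) * _DRIFT_TO_DISPLAY[:, None]


def _check_rates(*rates) -> None:
    for r in rates:
        if np.any(np.asarray(r) < 0):
            raise ValueError(f"rates must be nonnegative, got {r}")


def membrane_moments(nu_e_tot, nu_i, W, p: ModelParams, population: str = "e"):
    """Membrane-potential moments of one population.

    Parameters
    ----------
    nu_e_tot : float
        Total excitatory input rate (Hz): the population's own excitatory
        rate plus any external input, before the in-degree is applied.
    nu_i : float
        Inhibitory population rate (Hz).
    W : float
        Adaptation current (pA).
    p : ModelParams
    population : {"e", "i"}
        Selects the leak reversal potential used in the formulas.

    Returns
    -------
    (mu_V, sigma_V, tau_V) : mV, mV, ms
    """
    _check_rates(nu_e_tot, nu_i)
    si = p.si()
    E_L = si.E_L_e if population == "e" else si.E_L_i
    mu_V, sigma_V, tau_V = _moments_si(
        np.asarray(nu_e_tot, dtype=float) * si.K_e,
        np.asarray(nu_i, dtype=float) * si.K_i,
        np.asarray(W, dtype=float) * 1e-12,
        E_L,
        si,
    )
    return mu_V * 1e3, sigma_V * 1e3, tau_V * 1e3


def transfer_function(
    nu_e_tot, nu_i, W, p: ModelParams, tf: TransferFunctionParams
):
    """Output rate (Hz) of one population given its inputs.

    Raises :class:`NumericsError` when the inputs make the membrane moments
    non-finite.
    """
    _check_rates(nu_e_tot, nu_i)
    si = p.si()
    E_L = si.E_L_e if tf.population == "e" else si.E_L_i
    rate = _tf_si(
        np.asarray(nu_e_tot, dtype=float) * si.K_e,
        np.asarray(nu_i, dtype=float) * si.K_i,
        np.asarray(W, dtype=float) * 1e-12,
        E_L,
        tf.coeffs,
        si,
    )
    if not np.all(np.isfinite(rate)):
        raise NumericsError(
            f"non-finite transfer function output for inputs "
            f"nu_e_tot={nu_e_tot}, nu_i={nu_i}, W={W}"
        )
    return rate if np.ndim(rate) else float(rate)


def meanfield_derivatives(
    s: NodeState,
    nu_e_ext: float,
    p: ModelParams,
    tf_e: TransferFunctionParams | None = None,
    tf_i: TransferFunctionParams | None = None,
) -> NodeState:
    """Time derivative (per ms) of one region's seven state variables.

    ``nu_e_ext`` is the external excitatory input rate (Hz) on top of the
    region's own excitatory rate.
    """
    if tf_e is None or tf_i is None:
        tf_e, tf_i = default_transfer_functions()
    _check_rates(s.nu_e, s.nu_i)
    si = p.si()
    dy = _drift_display(
        s.as_array()[:, None], np.array([float(nu_e_ext)]), si, tf_e.coeffs, tf_i.coeffs
    )
    return NodeState.from_array(dy[:, 0])


#: rates closer than this (Hz) are considered the same fixed point
_DEDUP_TOL = 1e-3

#: largest drift magnitude accepted for a converged fixed point; above the
#: finite-difference noise floor of the Hessian term at large covariances
_RESIDUAL_TOL = 1e-5


def _damped_newton(fun, z0, tol=1e-9, max_iter=60, max_backtrack=25):
    """Newton iteration with central-difference Jacobian and step halving.

    Returns the final iterate when the max-residual drops below ``tol`` or
    once progress stalls (the caller re-checks the residual); ``None`` when
    the Jacobian is singular before any progress."""
    z = np.asarray(z0, dtype=float).copy()
    f = fun(z)
    n = z.size
    for _ in range(max_iter):
        if np.abs(f).max() < tol:
            break
        J = np.empty((n, n))
        for j in range(n):
            step = 1e-4 * max(1.0, abs(z[j]))
            zp, zm = z.copy(), z.copy()
            zp[j] += step
            zm[j] -= step
            J[:, j] = (fun(zp) - fun(zm)) / (2 * step)
        try:
            dz = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return None
        lam = 1.0
        for _ in range(max_backtrack):
            zn = z + lam * dz
            fn = fun(zn)
            if np.abs(fn).max() < np.abs(f).max():
                break
            lam *= 0.5
        else:
            break  # stalled; caller decides from the residual
        z, f = zn, fn
    return z


def _jacobian(fun, y, rel_step=1e-6):
    n = y.size
    J = np.empty((n, n))
    for j in range(n):
        step = rel_step * max(1.0, abs(y[j]))
        yp, ym = y.copy(), y.copy()
        yp[j] += step
        ym[j] -= step
        J[:, j] = (fun(yp) - fun(ym)) / (2 * step)
    return J


def _stationary_covariances(nu_e, nu_i, W_e, W_i, ext, si, P_e, P_i):
    """Covariances solving their (linear) stationarity conditions at the
    given rates and adaptation currents.  Scalar inputs; returns
    ``(c_ee, c_ei, c_ii)``."""
    n1 = np.atleast_1d
    F_e, F_i, _ = _tf_stencil(
        n1(float(nu_e)), n1(float(nu_i)), n1(float(W_e)), n1(float(W_i)),
        float(ext), si, P_e, P_i,
    )
    h = _DIFF_STEP
    Fe0, Fi0 = F_e[0, 0], F_i[0, 0]
    a_e = (F_e[1, 0] - F_e[2, 0]) / (2 * h)  # dF_e/dnu_e
    a_i = (F_e[3, 0] - F_e[4, 0]) / (2 * h)  # dF_e/dnu_i
    b_e = (F_i[1, 0] - F_i[2, 0]) / (2 * h)  # dF_i/dnu_e
    b_i = (F_i[3, 0] - F_i[4, 0]) / (2 * h)  # dF_i/dnu_i
    T = si.T
    src = np.array(
        [
            Fe0 * (1.0 / T - Fe0) / si.N_e + (Fe0 - nu_e) ** 2,
            (Fe0 - nu_e) * (Fi0 - nu_i),
            Fi0 * (1.0 / T - Fi0) / si.N_i + (Fi0 - nu_i) ** 2,
        ]
    )
    M = np.array(
        [
            [2 * a_e - 2.0, 2 * a_i, 0.0],
            [b_e, a_e + b_i - 2.0, a_i],
            [0.0, 2 * b_e, 2 * b_i - 2.0],
        ]
    )
    return np.linalg.solve(M, -src)


def _nu_i_equilibrium(nu_e_tot, p, si, P_i, n_iter=80):
    """Inhibitory rate solving ``F_i(nu_e_tot, nu_i) = nu_i`` (vectorized
    bisection; the residual is strictly decreasing in ``nu_i``)."""
    nu_e_tot = np.asarray(nu_e_tot, dtype=float)
    lo = np.zeros_like(nu_e_tot)
    hi = np.full_like(nu_e_tot, si.rate_max)
    fe = nu_e_tot * si.K_e
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        g = _tf_si(fe, mid * si.K_i, 0.0, si.E_L_i, P_i, si) - mid
        lo = np.where(g > 0, mid, lo)
        hi = np.where(g > 0, hi, mid)
    return 0.5 * (lo + hi)


def find_fixed_points(
    nu_e_ext: float,
    p: ModelParams,
    tfs: tuple | None = None,
) -> list:
    """Locate fixed points of the noiseless single-region dynamics.

    A dense grid of excitatory-rate guesses spanning [0, 1/T_refrac] Hz is
    scanned through the rate-balance map (with the inhibitory rate and the
    adaptation current at their conditional equilibria); each bracketed
    balance point seeds a root solve of the full seven-equation drift.
    Converged roots are deduplicated and classified by the sign of the
    leading Jacobian eigenvalue.

    Returns a list of ``(NodeState, stable)`` pairs sorted by ``nu_e``; an
    empty list (with a warning) if nothing converges.
    """
    if tfs is None:
        tfs = default_transfer_functions()
    tf_e, tf_i = tfs
    P_e, P_i = tf_e.coeffs, tf_i.coeffs
    si = p.si()
    ext = float(nu_e_ext)
    extv = np.array([ext])

    def drift(y_disp):
        return _drift_display(y_disp[:, None], extv, si, P_e, P_i)[:, 0]

    def balance(nu_e):
        """F_e - nu_e with nu_i and W_e at conditional equilibrium."""
        nu_e = np.asarray(nu_e, dtype=float)
        nu_i = _nu_i_equilibrium(nu_e + ext, p, si, P_i)
        w = si.b_e * si.tau_w * nu_e  # a-term dropped: subthreshold adaptation
        if si.a != 0.0:  # solve W implicitly by short relaxation
            for _ in range(50):
                mu_v, _, _ = _moments_si(
                    (nu_e + ext) * si.K_e, nu_i * si.K_i, w, si.E_L_e, si
                )
                w = si.b_e * si.tau_w * nu_e + si.a * (mu_v - si.E_L_e)
        return (
            _tf_si((nu_e + ext) * si.K_e, nu_i * si.K_i, w, si.E_L_e, P_e, si) - nu_e,
            nu_i,
            w,
        )

    grid = np.concatenate(
        [np.linspace(0.0, 1.0, 41), np.linspace(1.05, 20.0, 80), np.linspace(20.5, si.rate_max, 180)]
    )
    G, nu_i_grid, w_grid = balance(grid)

    seeds = []
    sign = np.sign(G)
    for i in np.nonzero(sign[:-1] * sign[1:] <= 0)[0]:
        a, b = grid[i], grid[i + 1]
        if sign[i] == 0 and sign[i + 1] == 0:
            continue
        for _ in range(60):  # bisection on the balance map
            m = 0.5 * (a + b)
            gm = balance(m)[0]
            if np.sign(gm) == sign[i]:
                a = m
            else:
                b = m
        ne = 0.5 * (a + b)
        _, ni, w = balance(ne)
        seeds.append(np.array([ne, float(np.asarray(ni).reshape(-1)[0]),
                               float(np.asarray(w).reshape(-1)[0]) * 1e12]))

    def embed(z):
        """Full display state from (nu_e, nu_i, W_e) with covariances at
        their exact linear stationary values."""
        nu_e, nu_i, W_e = max(z[0], 0.0), max(z[1], 0.0), z[2]
        c = _stationary_covariances(
            nu_e, nu_i, W_e * 1e-12, 0.0, ext, si, P_e, P_i
        )
        return np.array([nu_e, nu_i, c[0], c[1], c[2], W_e, 0.0])

    def reduced(z):
        d = drift(embed(z))
        return d[[0, 1, 5]]

    roots = []
    for z0 in seeds:
        z = _damped_newton(reduced, z0)
        if z is None or z[0] < -1e-6 or z[1] < -1e-6:
            continue
        y = embed(z)
        if np.abs(drift(y)).max() > _RESIDUAL_TOL:
            continue
        if any(
            abs(y[0] - r[0]) < _DEDUP_TOL and abs(y[1] - r[1]) < _DEDUP_TOL
            for r in roots
        ):
            continue
        roots.append(y)

    if not roots:
        warnings.warn("fixed-point search did not converge from any seed")
        return []

    out = []
    for y in sorted(roots, key=lambda r: r[0]):
        eigs = np.linalg.eigvals(_jacobian(drift, y))
        out.append((NodeState.from_array(y), bool(eigs.real.max() < 0)))
    return out
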