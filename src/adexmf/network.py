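"""Coupled network simulation: delayed excitatory interactions between
mean-field regions, Ornstein–Uhlenbeck drive, stochastic Heun integration.

Each region receives, on top of its own recurrent excitatory rate, an
external excitatory input

    nu_e_ext^k(t) = nu_aff + max(0, nu_drive + sigma * xi_k(t))
                    + S * sum_j C_jk * nu_e^j(t - d_jk / v_c)

where ``xi_k`` is a per-node Ornstein–Uhlenbeck process of unit Wiener
amplitude and the delays are tract length over axonal speed, rounded to the
nearest integration step.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .connectome import Connectome
from .meanfield import NodeState, _drift_si
from .params import ModelParams, default_transfer_functions

__all__ = [
    "SimulationConfig",
    "RateTimeSeries",
    "DelayBuffer",
    "IntegrationBlowupError",
    "HeunNetworkIntegrator",
    "ou_step",
    "heun_update",
    "delayed_coupling",
    "simulate",
]


class IntegrationBlowupError(RuntimeError):
    """Raised when the state stops being finite during integration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Network simulation settings (times in ms, rates in Hz).

    ``nu_drive`` and ``sigma`` set the baseline and amplitude of the
    Ornstein–Uhlenbeck excitatory drive; ``tau_OU`` its time constant.
    ``S`` scales long-range coupling and ``v_c`` is the axonal conduction
    speed in mm/ms.

    ``cov_max`` bounds the rate covariances (Hz^2): the second-order
    correction is only valid for small fluctuations, and far from
    equilibrium its source term grows explosively, so diagonal covariances
    are clamped to ``[0, cov_max]`` and the cross covariance to the
    Cauchy-Schwarz envelope after every step.  Rates are clamped to the
    refractory-limited range ``[0, 1/T_refrac]``.
    """

    dt: float = 0.1
    duration: float = 5000.0
    transient: float = 2000.0
    S: float = 0.3
    v_c: float = 3.0
    nu_aff: float = 0.0
    nu_drive: float = 0.315
    sigma: float = 0.04
    tau_OU: float = 5.0
    cov_max: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.transient < self.duration:
            raise ValueError("transient must be smaller than duration")
        if self.S < 0:
            raise ValueError("S must be nonnegative")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.tau_OU <= 0:
            raise ValueError("tau_OU must be positive")
        if self.v_c <= 0:
            raise ValueError("v_c must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def n_transient_steps(self) -> int:
        return int(round(self.transient / self.dt))

    @property
    def n_samples(self) -> int:
        return self.n_steps - self.n_transient_steps

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "dt": self.dt, "duration": self.duration, "transient": self.transient,
            "S": self.S, "v_c": self.v_c, "nu_aff": self.nu_aff,
            "nu_drive": self.nu_drive, "sigma": self.sigma,
            "tau_OU": self.tau_OU, "seed": self.seed,
        }


@dataclass
class RateTimeSeries:
    """Post-transient trajectories of all seven state variables per node.

    Arrays have shape ``(n_samples, n_nodes)``; ``times`` is in ms, rates in
    Hz, covariances in Hz^2, adaptation currents in pA.
    """

    times: np.ndarray
    nu_e: np.ndarray
    nu_i: np.ndarray
    c_ee: np.ndarray
    c_ei: np.ndarray
    c_ii: np.ndarray
    W_e: np.ndarray
    W_i: np.ndarray
    dt: float
    config: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.nu_e.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.nu_e.shape[1]


def ou_step(xi, dt: float, tau_OU: float, noise_increment):
    """One Euler–Maruyama update of ``d xi = -xi dt / tau_OU + dW``.

    ``noise_increment`` is a Wiener sample of variance ``dt``; pass 0 for
    the deterministic relaxation.
    """
    if tau_OU <= 0:
        raise ValueError("tau_OU must be positive")
    return xi - xi * (dt / tau_OU) + noise_increment


def heun_update(y, drift_fn, dt: float, noise=0.0):
    """Stochastic Heun update for additive noise.

    Euler predictor carrying the noise increment, trapezoidal corrector
    averaging the drift at the current and predicted states, the same noise
    increment in both stages.  Deterministic (``noise=0``) behaviour is the
    classical second-order Heun scheme.
    """
    y_pred = y + drift_fn(y) * dt + noise
    return y + 0.5 * (drift_fn(y) + drift_fn(y_pred)) * dt + noise


class DelayBuffer:
    """Ring buffer of past per-node excitatory rates.

    Row ``t % depth`` holds the rates at step ``t``.  The buffer must be at
    least one step deeper than the largest delay; it is initialized by
    replicating the initial rates across the whole delay horizon.
    """

    def __init__(self, delay_steps: np.ndarray, init_rates: np.ndarray):
        self.delay_steps = np.asarray(delay_steps, dtype=int)
        n = self.delay_steps.shape[0]
        self.depth = int(self.delay_steps.max()) + 1
        self.buf = np.tile(np.asarray(init_rates, dtype=float), (self.depth, 1))
        self._rows = np.arange(n)

    def check_depth(self) -> None:
        if self.depth <= self.delay_steps.max():
            raise ValueError(
                f"history depth {self.depth} shorter than the maximum delay "
                f"{int(self.delay_steps.max())} steps"
            )

    def push(self, t_index: int, rates: np.ndarray) -> None:
        self.buf[t_index % self.depth] = rates

    def rate_at(self, node: int, t_index: int) -> float:
        return float(self.buf[t_index % self.depth, node])

    def delayed_matrix(self, t_index: int) -> np.ndarray:
        """Matrix ``V[j, k] = nu_e^j(t - d_jk)`` at step ``t_index``."""
        idx = (t_index - self.delay_steps) % self.depth
        return self.buf[idx, self._rows[:, None]]


def delay_steps_matrix(c: Connectome, cfg: SimulationConfig) -> np.ndarray:
    """Inter-node delays in integration steps (nearest-step rounding)."""
    return np.rint(c.tract_lengths / cfg.v_c / cfg.dt).astype(int)


def delayed_coupling(
    history: DelayBuffer,
    c: Connectome,
    k: int,
    t: float,
    cfg: SimulationConfig,
    drive: float = 0.0,
) -> float:
    """Total external excitatory input to node ``k`` at time ``t`` (ms).

    Returns ``nu_aff + drive + S * sum_j C_jk nu_e^j(t - d_jk / v_c)`` with
    delays rounded to the nearest step; the ``j = k`` term has unit weight
    and zero delay.  ``drive`` is the current value of the node's noise
    drive (already floored at zero by the caller).
    """
    history.check_depth()
    t_index = int(round(t / cfg.dt))
    d = history.delay_steps[:, k]
    total = 0.0
    for j in range(c.n_regions):
        total += c.weights[j, k] * history.rate_at(j, t_index - d[j])
    return cfg.nu_aff + drive + cfg.S * total


def stationary_initial_state(
    c: Connectome,
    cfg: SimulationConfig,
    p: ModelParams,
    tfs: tuple | None = None,
) -> NodeState:
    """Self-consistent quasi-stationary state used as the default initial
    condition.

    Iterates the single-region fixed-point problem with the mean-field
    coupling input ``S * m * nu`` (``m`` the mean total in-strength of the
    connectome), keeping the stable fixed point of moderate rate (< 50 Hz)
    when one exists and the near-silent state otherwise.  Starting on a
    stationary branch keeps the strongly nonlinear onset transient — which
    the covariance equations amplify — out of the integration.
    """
    from .meanfield import find_fixed_points

    m = float(c.weights.sum(axis=0).mean())
    drive = cfg.nu_drive + cfg.nu_aff
    nu = 3.0
    best = None
    for _ in range(8):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fps = find_fixed_points(drive + cfg.S * m * nu, p, tfs)
        stable = [s for s, ok in fps if ok and s.nu_e < 50.0]
        if not stable:
            best = None
            break
        best = max(stable, key=lambda s: s.nu_e)
        if abs(best.nu_e - nu) < 1e-3:
            break
        nu = best.nu_e
    if best is None:
        return NodeState(0.01, 0.01, 0.0, 0.0, 0.0, 0.0, 0.0)
    return best


class HeunNetworkIntegrator:
    """Stochastic Heun integrator of the coupled mean-field network.

    Holds the per-node seven-variable state (SI units internally), the
    delay ring buffer and the per-node Ornstein–Uhlenbeck drive processes.
    Noise streams are spawned per node from the master seed, so adding
    nodes does not perturb existing streams.
    """

    def __init__(
        self,
        c: Connectome,
        cfg: SimulationConfig,
        p: ModelParams,
        tfs: tuple | None = None,
        initial_state: NodeState | None = None,
    ):
        if tfs is None:
            tfs = default_transfer_functions()
        self.connectome = c
        self.cfg = cfg
        self.params = p
        self.si = p.si()
        self.P_e, self.P_i = tfs[0].coeffs, tfs[1].coeffs
        n = c.n_regions

        auto_init = initial_state is None
        if auto_init:
            initial_state = stationary_initial_state(c, cfg, p, tfs)
        y0 = initial_state.as_array() * np.array([1, 1, 1, 1, 1, 1e-12, 1e-12])
        self.y = np.tile(y0[:, None], (1, n))
        if auto_init:
            # small deterministic per-node spread to break the all-identical
            # symmetry (synchronized onset transients are pathological)
            init_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xA11)))
            self.y[:2] *= init_rng.uniform(0.9, 1.1, size=(2, n))

        self.delay_steps = delay_steps_matrix(c, cfg)
        self.buffer = DelayBuffer(self.delay_steps, self.y[0])
        self.buffer.check_depth()
        self.t_index = 0

        self.xi = np.zeros(n)
        self._rngs = [
            np.random.Generator(np.random.Philox(np.random.SeedSequence((cfg.seed, node))))
            for node in range(n)
        ]
        self._noise_chunk = np.empty((0, n))
        self._noise_pos = 0

        self._dt_s = cfg.dt * 1e-3
        self._sqrt_dt = np.sqrt(cfg.dt)
        self._weights = c.weights

    def _next_noise(self) -> np.ndarray:
        if self._noise_pos >= self._noise_chunk.shape[0]:
            chunk = 4096
            self._noise_chunk = np.column_stack(
                [rng.standard_normal(chunk) for rng in self._rngs]
            )
            self._noise_pos = 0
        row = self._noise_chunk[self._noise_pos]
        self._noise_pos += 1
        return row

    def _coupling(self) -> np.ndarray:
        """S * sum_j C_jk nu_e^j(t - d_jk) for all k (Hz)."""
        V = self.buffer.delayed_matrix(self.t_index)
        return self.cfg.S * np.einsum("jk,jk->k", self._weights, V)

    def _drive(self, xi: np.ndarray) -> np.ndarray:
        return np.maximum(self.cfg.nu_drive + self.cfg.sigma * xi, 0.0)

    def heun_step(self) -> None:
        """Advance the joint (network state, OU drive) system by one step."""
        cfg = self.cfg
        dW = self._next_noise() * self._sqrt_dt if cfg.sigma > 0 else 0.0
        coup = self._coupling()

        ext0 = cfg.nu_aff + self._drive(self.xi) + coup
        d0 = _drift_si(self.y, ext0, self.si, self.P_e, self.P_i)
        y_pred = self.y + d0 * self._dt_s
        xi_pred = ou_step(self.xi, cfg.dt, cfg.tau_OU, dW)

        ext1 = cfg.nu_aff + self._drive(xi_pred) + coup
        d1 = _drift_si(y_pred, ext1, self.si, self.P_e, self.P_i)
        self.y = self.y + 0.5 * (d0 + d1) * self._dt_s
        self.xi = self.xi + 0.5 * (-self.xi - xi_pred) * (cfg.dt / cfg.tau_OU) + dW

        rm = self.si.rate_max
        np.clip(self.y[0], 0.0, rm, out=self.y[0])
        np.clip(self.y[1], 0.0, rm, out=self.y[1])
        np.clip(self.y[2], 0.0, cfg.cov_max, out=self.y[2])
        np.clip(self.y[4], 0.0, cfg.cov_max, out=self.y[4])
        env = np.sqrt(self.y[2] * self.y[4])
        np.clip(self.y[3], -env, env, out=self.y[3])

        self.t_index += 1
        self.buffer.push(self.t_index, self.y[0])

        if not np.all(np.isfinite(self.y)):
            bad = np.nonzero(~np.isfinite(self.y).all(axis=0))[0]
            raise IntegrationBlowupError(
                f"non-finite state at t = {self.t_index * cfg.dt:.1f} ms "
                f"in node(s) {bad.tolist()}"
            )

    @property
    def state_display(self) -> np.ndarray:
        """Current state in display units (Hz, Hz^2, pA), shape (7, n)."""
        return self.y * np.array([1, 1, 1, 1, 1, 1e12, 1e12])[:, None]


def simulate(
    c: Connectome,
    cfg: SimulationConfig,
    p: ModelParams,
    tfs: tuple | None = None,
    initial_state: NodeState | None = None,
) -> RateTimeSeries:
    """Integrate the coupled network and return the post-transient series.

    Runs ``round(duration / dt)`` Heun steps and keeps the samples after the
    ``transient`` cut, so the returned series holds
    ``round((duration - transient) / dt)`` samples per node.  A paroxysmal
    run is data, not an error; only a numerical blow-up raises.
    """
    integ = HeunNetworkIntegrator(c, cfg, p, tfs, initial_state)
    n = c.n_regions
    n_steps, n_trans = cfg.n_steps, cfg.n_transient_steps
    n_samples = n_steps - n_trans

    out = np.empty((7, n_samples, n), dtype=float)
    times = (np.arange(n_trans + 1, n_steps + 1) * cfg.dt)

    for step in range(1, n_steps + 1):
        integ.heun_step()
        if step > n_trans:
            out[:, step - n_trans - 1, :] = integ.y

    out[5] *= 1e12  # W_e -> pA
    out[6] *= 1e12
    return RateTimeSeries(
        times=times,
        nu_e=out[0], nu_i=out[1],
        c_ee=out[2], c_ei=out[3], c_ii=out[4],
        W_e=out[5], W_i=out[6],
        dt=cfg.dt,
        config=cfg.to_dict(),
    )
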