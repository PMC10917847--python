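"""Parameter containers for the mean-field model.

Public interfaces use the conventional display units of the field: rates in
Hz, times in ms, potentials in mV, currents in pA, conductances in nS and
capacitances in pF.  Numerical kernels convert once to SI via
:meth:`ModelParams.si`.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from types import SimpleNamespace

import yaml

__all__ = [
    "ModelParams",
    "TransferFunctionParams",
    "default_transfer_functions",
    "load_transfer_functions",
]


@dataclass(frozen=True)
class ModelParams:
    """Node-level constants of the two-population mean-field model.

    Parameters
    ----------
    T : float
        Mean-field relaxation timescale (ms).
    b_e : float
        Spike-triggered adaptation increment of excitatory cells (pA).
    a : float
        Subthreshold adaptation conductance of excitatory cells (nS).
    E_L_e, E_L_i : float
        Leak reversal potentials of the excitatory / inhibitory populations
        (mV).
    tau_w : float
        Adaptation time constant of the excitatory population (ms).
    b_i, tau_w_i : float
        Mirrored adaptation constants for the inhibitory population; the
        inhibitory adaptation increment is zero by convention, so the
        inhibitory adaptation current relaxes to zero.
    N_tot : int
        Total size of the underlying spiking network per region.
    inh_fraction : float
        Fraction of inhibitory neurons (0.2 -> 8000 excitatory / 2000
        inhibitory at the default ``N_tot``).
    conn_prob : float
        Recurrent connection probability; sets the synaptic in-degrees
        ``K_e = conn_prob * N_e`` and ``K_i = conn_prob * N_i``.
    C_m, g_L : float
        Membrane capacitance (pF) and leak conductance (nS).
    Q_e, Q_i : float
        Excitatory / inhibitory synaptic quantal conductances (nS).
    tau_syn_e, tau_syn_i : float
        Synaptic decay time constants (ms).
    E_exc, E_inh : float
        Synaptic reversal potentials (mV).
    T_refrac : float
        Absolute refractory period (ms); caps population rates at
        ``1 / T_refrac``.
    """

    T: float = 19.0
    b_e: float = 60.0
    a: float = 0.0
    E_L_e: float = -64.0
    E_L_i: float = -65.0
    tau_w: float = 500.0
    b_i: float = 0.0
    tau_w_i: float = 1.0
    N_tot: int = 10000
    inh_fraction: float = 0.2
    conn_prob: float = 0.05
    C_m: float = 200.0
    g_L: float = 10.0
    Q_e: float = 1.5
    Q_i: float = 5.0
    tau_syn_e: float = 5.0
    tau_syn_i: float = 5.0
    E_exc: float = 0.0
    E_inh: float = -80.0
    T_refrac: float = 5.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"T must be positive, got {self.T}")
        if self.tau_w <= 0 or self.tau_w_i <= 0:
            raise ValueError("adaptation time constants must be positive")
        if self.N_tot <= 0:
            raise ValueError("N_tot must be positive")
        if not 0.0 < self.inh_fraction < 1.0:
            raise ValueError("inh_fraction must lie in (0, 1)")
        if self.T_refrac <= 0:
            raise ValueError("T_refrac must be positive")

    @property
    def N_e(self) -> int:
        return int(round(self.N_tot * (1.0 - self.inh_fraction)))

    @property
    def N_i(self) -> int:
        return self.N_tot - self.N_e

    @property
    def K_e(self) -> float:
        """Excitatory synaptic in-degree per neuron."""
        return self.conn_prob * self.N_e

    @property
    def K_i(self) -> float:
        """Inhibitory synaptic in-degree per neuron."""
        return self.conn_prob * self.N_i

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def si(self) -> SimpleNamespace:
        """Return all constants converted to SI units (V, s, S, F, A, Hz)."""
        return SimpleNamespace(
            T=self.T * 1e-3,
            b_e=self.b_e * 1e-12,
            b_i=self.b_i * 1e-12,
            a=self.a * 1e-9,
            E_L_e=self.E_L_e * 1e-3,
            E_L_i=self.E_L_i * 1e-3,
            tau_w=self.tau_w * 1e-3,
            tau_w_i=self.tau_w_i * 1e-3,
            N_e=self.N_e,
            N_i=self.N_i,
            K_e=self.K_e,
            K_i=self.K_i,
            C_m=self.C_m * 1e-12,
            g_L=self.g_L * 1e-9,
            Q_e=self.Q_e * 1e-9,
            Q_i=self.Q_i * 1e-9,
            tau_e=self.tau_syn_e * 1e-3,
            tau_i=self.tau_syn_i * 1e-3,
            E_e=self.E_exc * 1e-3,
            E_i=self.E_inh * 1e-3,
            rate_max=1.0 / (self.T_refrac * 1e-3),
        )


@dataclass(frozen=True)
class TransferFunctionParams:
    """Fitted effective-threshold polynomial of one population.

    ``coeffs`` are the ten second-order polynomial coefficients (in volts)
    applied to the normalized membrane moments; ``population`` selects which
    leak potential and adaptation current feed the moment formulas.
    """

    population: str
    coeffs: tuple

    def __post_init__(self) -> None:
        if self.population not in ("e", "i"):
            raise ValueError("population must be 'e' or 'i'")
        if len(self.coeffs) != 10:
            raise ValueError("expected 10 threshold coefficients")
        if not all(abs(float(c)) < 1.0 for c in self.coeffs):
            raise ValueError("threshold coefficients must be finite volts < 1")


def load_transfer_functions(path) -> tuple:
    """Load an (excitatory, inhibitory) coefficient pair from a YAML file."""
    with open(path) as fh:
        table = yaml.safe_load(fh)
    return (
        TransferFunctionParams("e", tuple(float(x) for x in table["excitatory"])),
        TransferFunctionParams("i", tuple(float(x) for x in table["inhibitory"])),
    )


def default_transfer_functions() -> tuple:
    """The packaged default coefficient pair."""
    ref = resources.files("adexmf").joinpath("data/tf_coefficients.yaml")
    table = yaml.safe_load(ref.read_text())
    return (
        TransferFunctionParams("e", tuple(float(x) for x in table["excitatory"])),
        TransferFunctionParams("i", tuple(float(x) for x in table["inhibitory"])),
    )
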