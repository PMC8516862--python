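"""Model parameter set for the theta-neuron ASSR microcircuit.

All times are in milliseconds; synaptic strengths and applied currents are
dimensionless, as usual for the theta (Ermentrout-Kopell canonical) model.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter table of the microcircuit plus integration settings.

    The defaults describe the control network: 20 excitatory pyramidal cells
    and 10 inhibitory (PV+ basket) cells, all-to-all coupled, driven by a
    single pacemaker spike source and per-cell Poissonian background noise.

    Attributes
    ----------
    n_E, n_I:
        Population sizes (excitatory / inhibitory).
    tau_R:
        Synaptic rise time constant (ms), shared by all synapse classes.
    tau_exc, tau_inh:
        Decay time constants (ms) of excitatory and inhibitory gating.
    g_ee, g_ei, g_ie, g_ii:
        Synaptic strengths between populations (pre -> post ordering,
        e.g. ``g_ei`` is E onto I).
    g_de, g_di:
        Strength of the pacemaker drive onto E and I cells.
    I_factor:
        Input-strength multiplier applied to both drive strengths.
    b:
        Applied current, identical for all cells in the control network.
        The default -0.01 keeps every cell just below the excitable
        threshold; drive and recurrent excitation lift cells over it.
    b_inh_delta:
        Additional decrement of the applied current of inhibitory cells
        (NMDAR-hypofunction variants only; 0 in control).
    Ag_max:
        Amplitude scale of the noise EPSP kernel.
    eta:
        Gating activation scale: the activation term is
        ``exp(-eta * (1 + cos(theta_pre)))``, sharply peaked at the
        presynaptic spike phase ``theta = pi``.
    noise_rate:
        Rate of the per-cell Poisson background process, events/ms.
    duration, n_steps:
        Trial length (ms) and number of time points; the forward-Euler
        step is ``duration / n_steps``.
    n_trials:
        Trials averaged (in time, before the Fourier transform) per
        condition.
    seed:
        Base random seed for trial-level noise and initial phases.
    """

    n_E: int = 20
    n_I: int = 10
    tau_R: float = 0.1
    tau_exc: float = 2.0
    tau_inh: float = 8.0
    g_ee: float = 0.015
    g_ei: float = 0.025
    g_ie: float = 0.015
    g_ii: float = 0.02
    g_de: float = 0.3
    g_di: float = 0.08
    I_factor: float = 1.0
    b: float = -0.01
    b_inh_delta: float = 0.0
    Ag_max: float = 0.6
    eta: float = 5.0
    noise_rate: float = 1.0 / 40.0
    duration: float = 500.0
    n_steps: int = 8192
    n_trials: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_E < 0 or self.n_I < 0 or self.n_E + self.n_I == 0:
            raise ValueError("need at least one cell")
        for name in ("g_ee", "g_ei", "g_ie", "g_ii", "g_de", "g_di"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tau_R", "tau_exc", "tau_inh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tau_exc == self.tau_R:
            raise ValueError("tau_exc must differ from tau_R (noise kernel degenerate)")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be >= 0")
        if self.I_factor <= 0:
            raise ValueError("I_factor must be > 0")

    @property
    def n_cells(self) -> int:
        return self.n_E + self.n_I

    @property
    def dt(self) -> float:
        """Forward-Euler time step in ms (500/8192 ~ 0.061 ms at defaults)."""
        return self.duration / self.n_steps

    def with_(self, **overrides) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)

    def to_dict(self) -> dict:
        return asdict(self)
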