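"""Small deterministic networks and noise-free stimuli for testing.

These helpers build desk-scale instances of the model (few cells, short
trials, no background noise) with which individual operations can be
checked against closed-form oracles.
"""
from __future__ import annotations

import numpy as np

from .network_builder import NetworkModel
from .parameters import ModelParameters
from .stimulation import StimulusProgram, make_click_train


def tiny_params(**overrides) -> ModelParameters:
    """A 2E+1I network over a short, finely resolved trial, no noise."""
    base = dict(
        n_E=2,
        n_I=1,
        noise_rate=0.0,
        duration=200.0,
        n_steps=4096,
        n_trials=2,
    )
    base.update(overrides)
    return ModelParameters(**base)


def single_cell_params(b: float, duration: float = 500.0, dt: float = 0.01,
                       **overrides) -> ModelParameters:
    """One isolated excitatory theta cell under constant applied current.

    With all synaptic strengths zero and no noise the cell reduces to the
    scalar theta model, whose firing period under constant input ``I0 > 0``
    is ``pi / sqrt(I0)`` ms.
    """
    base = dict(
        n_E=1,
        n_I=0,
        g_ee=0.0,
        g_ei=0.0,
        g_ie=0.0,
        g_ii=0.0,
        g_de=0.0,
        g_di=0.0,
        b=b,
        noise_rate=0.0,
        duration=duration,
        n_steps=int(round(duration / dt)),
        n_trials=1,
    )
    base.update(overrides)
    return ModelParameters(**base)


def silent_stimulus(params: ModelParameters, drive_freq: float = 40.0) -> StimulusProgram:
    """A stimulus program with drive clicks but no background noise."""
    return StimulusProgram(
        drive_freq=drive_freq,
        drive_spike_times=make_click_train(drive_freq, params.duration),
        noise_spike_times=[np.empty(0) for _ in range(params.n_cells)],
        duration=params.duration,
    )


def undriven_stimulus(params: ModelParameters, noise_spike_times=None) -> StimulusProgram:
    """No drive clicks; optionally supply explicit noise spike lists."""
    if noise_spike_times is None:
        noise_spike_times = [np.empty(0) for _ in range(params.n_cells)]
    return StimulusProgram(
        drive_freq=40.0,
        drive_spike_times=np.empty(0),
        noise_spike_times=noise_spike_times,
        duration=params.duration,
    )


def two_cell_toy(s_value: float = 0.5) -> tuple[NetworkModel, np.ndarray]:
    """A frozen two-E-cell structure plus a constant gating matrix.

    Used to check summation identities (e.g. the MEG of a single E->E
    synapse held at ``s`` is ``s`` itself).
    """
    params = ModelParameters(n_E=2, n_I=0, noise_rate=0.0)
    n = params.n_cells
    from .network_builder import build_network

    net = build_network("control", params)
    s = np.zeros((n + 1, n))
    s[0, 1] = s_value
    return net, s
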