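"""Numerics of the theta-neuron network.

Each cell k is a theta neuron,

    dtheta_k/dt = 1 - cos(theta_k) + (b + S_k + N(t)) (1 + cos(theta_k)),

where ``b`` is the applied current, ``S_k`` the total synaptic input and
``N(t)`` the summed noise EPSPs. A spike is the phase crossing pi from
below. Synaptic gating variables follow

    ds_jk/dt = -s_jk / tau_j + exp(-eta (1 + cos(theta_j))) (1 - s_jk) / tau_R,

with the activation term sharply peaked around the presynaptic spike. The
whole coupled system is advanced jointly with forward Euler at a fixed step
``dt = duration / n_steps``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .parameters import ModelParameters

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# elementary update rules (pure functions; the trial loop below repeats the
# same arithmetic in compiled form)
# ---------------------------------------------------------------------------

def theta_drift(theta, total_input):
    """Right-hand side of the theta-neuron equation.

    ``total_input`` is the full current-like term ``b + S_k + N(t)``.
    At ``theta = pi`` the input term vanishes and the drift is exactly 2;
    under constant suprathreshold input I0 > 0 the model fires periodically
    with period ``pi / sqrt(I0)`` ms.
    """
    th = np.asarray(theta, dtype=float)
    inp = np.asarray(total_input, dtype=float)
    if not (np.all(np.isfinite(th)) and np.all(np.isfinite(inp))):
        raise FloatingPointError(
            "non-finite phase or input: numerical blow-up (time step too large?)"
        )
    c = np.cos(th)
    out = 1.0 - c + inp * (1.0 + c)
    return out.item() if np.isscalar(theta) and np.isscalar(total_input) else out


def total_synaptic_input(s, weights, signs):
    """Signed weighted sum ``S_k = sum_j alpha_j g_jk s_jk`` onto one cell.

    ``signs`` is +1 for excitatory presynaptic cells (and the pacemaker),
    -1 for inhibitory ones.
    """
    s = np.asarray(s, dtype=float)
    weights = np.asarray(weights, dtype=float)
    signs = np.asarray(signs, dtype=float)
    if not (s.shape == weights.shape == signs.shape):
        raise ValueError("s, weights and signs must have matching shapes")
    return float(np.sum(signs * weights * s))


def gating_step(s, theta_pre, tau_decay, tau_R, eta, dt):
    """One forward-Euler update of the synaptic gating ODE.

    For valid time constants and a sufficiently small ``dt`` the update maps
    [0, 1] into itself; leaving the interval is treated as an error (the
    step is too large), never silently clamped. With the presynaptic phase
    held at pi the fixed point is ``tau_decay / (tau_decay + tau_R)``.
    """
    if tau_decay <= 0 or tau_R <= 0 or dt <= 0:
        raise ValueError("tau_decay, tau_R and dt must be > 0")
    s = np.asarray(s, dtype=float)
    act = np.exp(-eta * (1.0 + np.cos(np.asarray(theta_pre, dtype=float))))
    new = s + dt * (-s / tau_decay + act * (1.0 - s) / tau_R)
    if np.any(new < 0.0) or np.any(new > 1.0):
        raise ValueError(
            f"gating left [0, 1] (dt={dt} too large for tau_R={tau_R})"
        )
    return new.item() if new.ndim == 0 else new


def noise_epsp(t, t_n, Ag_max, tau_exc, tau_R):
    """Noise EPSP kernel for a single background spike at ``t_n``.

    ``H(t - t_n) * Ag_max * (exp(-(t-t_n)/tau_exc) - exp(-(t-t_n)/tau_R))
    / (tau_exc - tau_R)``; zero before (and exactly at) the spike time.
    Contributions of multiple noise spikes sum linearly.
    """
    if tau_exc == tau_R:
        raise ValueError("tau_exc == tau_R: degenerate kernel")
    t = np.asarray(t, dtype=float)
    dt_ = t - t_n
    out = np.zeros_like(dt_)
    mask = dt_ >= 0
    d = dt_[mask]
    out[mask] = Ag_max * (np.exp(-d / tau_exc) - np.exp(-d / tau_R)) / (tau_exc - tau_R)
    return out.item() if out.ndim == 0 else out


def noise_currents(noise_spike_times, t_grid, Ag_max, tau_exc, tau_R):
    """Summed noise EPSP time course per cell on the sampling grid."""
    n_cells = len(noise_spike_times)
    out = np.zeros((n_cells, len(t_grid)))
    for c, spikes in enumerate(noise_spike_times):
        for t_n in np.asarray(spikes, dtype=float):
            j0 = int(np.searchsorted(t_grid, t_n, side="left"))
            if j0 >= len(t_grid):
                continue
            d = t_grid[j0:] - t_n
            out[c, j0:] += (
                Ag_max * (np.exp(-d / tau_exc) - np.exp(-d / tau_R)) / (tau_exc - tau_R)
            )
    return out


def pacemaker_phase(t_grid, drive_spike_times, period):
    """Deterministic phase trajectory of the pacemaker spike source.

    Between consecutive drive spikes the phase follows the closed-form
    constant-input theta-neuron solution whose period equals the click
    interval (input ``(pi/period)**2``), so the pacemaker crosses pi exactly
    at the listed spike times. Before the first spike the phase rests at 0,
    where the gating activation is negligible.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    spikes = np.asarray(drive_spike_times, dtype=float)
    phase = np.zeros_like(t_grid)
    if spikes.size == 0:
        return phase
    sq = np.pi / period
    idx = np.searchsorted(spikes, t_grid, side="right") - 1
    active = idx >= 0
    d = t_grid[active] - spikes[np.clip(idx[active], 0, spikes.size - 1)]
    u = sq * np.tan(sq * d - 0.5 * np.pi)
    phase[active] = np.mod(2.0 * np.arctan(u), TWO_PI)
    return phase


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

@dataclass
class NeuronState:
    """Joint network state: per-cell phase and per-synapse gating.

    ``s`` is indexed (presynaptic, postsynaptic); the last presynaptic row
    is the pacemaker. Phases are wrapped to [0, 2*pi); the dynamics use
    cos(theta) only, so wrapping is free.
    """

    theta: np.ndarray
    s: np.ndarray


@dataclass
class TrialRecording:
    """Everything recorded from one simulated trial."""

    time: np.ndarray
    theta_trace: np.ndarray
    meg: np.ndarray
    spikes: list[np.ndarray]
    seed_used: int
    s_ee_sum: np.ndarray
    s_drive_sum: np.ndarray


@njit(cache=False)
def _euler_loop(theta, s, weights, alpha, tau_mat, b_cell, noise, act_drive,
                eta, tau_R, dt, n_E):  # pragma: no cover - exercised via simulate_trial
    n = theta.shape[0]
    n_steps = noise.shape[1]
    theta_trace = np.empty((n, n_steps))
    see = np.empty(n_steps)
    sde = np.empty(n_steps)
    s_min = 1.0
    s_max = 0.0
    bad_step = -1

    for k in range(n):
        theta_trace[k, 0] = theta[k]
    tot_ee = 0.0
    tot_de = 0.0
    for j in range(n_E):
        for k in range(n_E):
            tot_ee += s[j, k]
    for k in range(n_E):
        tot_de += s[n, k]
    see[0] = tot_ee
    sde[0] = tot_de

    S = np.empty(n)
    for i in range(1, n_steps):
        # synaptic drive from the current gating state
        for k in range(n):
            acc = 0.0
            for j in range(n + 1):
                acc += alpha[j] * weights[j, k] * s[j, k]
            S[k] = acc
        # gating update (uses current presynaptic phases)
        for j in range(n + 1):
            if j < n:
                act = np.exp(-eta * (1.0 + np.cos(theta[j])))
            else:
                act = act_drive[i - 1]
            for k in range(n):
                sv = s[j, k]
                sv = sv + dt * (-sv / tau_mat[j, k] + act * (1.0 - sv) / tau_R)
                s[j, k] = sv
                if sv < s_min:
                    s_min = sv
                if sv > s_max:
                    s_max = sv
        # phase update
        for k in range(n):
            th = theta[k]
            c = np.cos(th)
            th_new = th + dt * (1.0 - c + (b_cell[k] + S[k] + noise[k, i - 1]) * (1.0 + c))
            if not np.isfinite(th_new):
                bad_step = i
                break
            if th_new >= TWO_PI:
                th_new -= TWO_PI
            elif th_new < 0.0:
                th_new += TWO_PI
            theta[k] = th_new
            theta_trace[k, i] = th_new
        if bad_step >= 0:
            break
        tot_ee = 0.0
        tot_de = 0.0
        for j in range(n_E):
            for k in range(n_E):
                tot_ee += s[j, k]
        for k in range(n_E):
            tot_de += s[n, k]
        see[i] = tot_ee
        sde[i] = tot_de

    return theta_trace, see, sde, s_min, s_max, bad_step


def detect_spikes(theta_trace, time):
    """Per-cell spike times: upward crossings of pi in the wrapped phase.

    Crossing times are linearly interpolated between samples. Wrap-around
    jumps (2*pi -> 0 and 0 -> 2*pi) are excluded by requiring the forward
    difference to stay below pi.
    """
    theta_trace = np.atleast_2d(np.asarray(theta_trace, dtype=float))
    time = np.asarray(time, dtype=float)
    prev = theta_trace[:, :-1]
    cur = theta_trace[:, 1:]
    crossing = (prev < np.pi) & (cur >= np.pi) & ((cur - prev) < np.pi)
    out = []
    for k in range(theta_trace.shape[0]):
        idx = np.nonzero(crossing[k])[0]
        frac = (np.pi - prev[k, idx]) / (cur[k, idx] - prev[k, idx])
        out.append(time[idx] + frac * (time[idx + 1] - time[idx]))
    return out


def simulate_trial(network, stimulus, params: ModelParameters, seed: int,
                   theta0=None) -> TrialRecording:
    """Simulate one trial of the full network with forward Euler.

    The pacemaker drive enters every cell as an excitatory synapse of
    strength ``I_factor * g_de`` (E cells) or ``I_factor * g_di`` (I cells),
    already resolved into ``network.weights``; noise spikes enter as summed
    EPSP currents. Initial phases are drawn uniformly from [0, 2*pi) from
    ``seed`` unless ``theta0`` is given; all gating starts at 0. The result
    is deterministic given (network, stimulus, seed).
    """
    n = network.n_cells
    if stimulus.n_cells != n:
        raise ValueError("stimulus has a noise train count different from the network size")
    n_steps = params.n_steps
    dt = params.dt
    t_grid = dt * np.arange(n_steps)

    noise = noise_currents(
        stimulus.noise_spike_times, t_grid, params.Ag_max, params.tau_exc, params.tau_R
    )
    period = 1000.0 / stimulus.drive_freq
    act_drive = np.exp(
        -params.eta * (1.0 + np.cos(pacemaker_phase(t_grid, stimulus.drive_spike_times, period)))
    )

    if theta0 is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 1]))
        theta = rng.uniform(0.0, TWO_PI, size=n)
    else:
        theta = np.array(theta0, dtype=float)
        if theta.shape != (n,):
            raise ValueError("theta0 must have one phase per cell")
    s0 = np.zeros((n + 1, n))

    theta_trace, see, sde, s_min, s_max, bad_step = _euler_loop(
        theta.copy(), s0, network.weights, network.alpha, network.tau_mat,
        network.b_per_cell, noise, act_drive, params.eta, params.tau_R, dt,
        network.n_E,
    )
    if bad_step >= 0:
        raise FloatingPointError(f"non-finite phase at step {bad_step}: numerical blow-up")
    if s_min < 0.0 or s_max > 1.0:
        raise ValueError(
            f"gating left [0, 1] during the trial (min={s_min}, max={s_max}); "
            "time step too large for tau_R"
        )

    spikes = detect_spikes(theta_trace, t_grid)
    return TrialRecording(
        time=t_grid,
        theta_trace=theta_trace,
        meg=see.copy(),
        spikes=spikes,
        seed_used=int(seed),
        s_ee_sum=see,
        s_drive_sum=sde,
    )
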