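"""Click-train drive and Poissonian background noise programs.

A stimulus program bundles, for one trial, the deterministic periodic drive
spike times (the "click train" relayed by the pacemaker) and one Poisson
noise spike train per network cell.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ModelParameters


@dataclass
class StimulusProgram:
    """Drive and noise event times for a single trial.

    ``drive_spike_times`` are strictly periodic with interval
    ``1000 / drive_freq`` ms; ``noise_spike_times`` holds one sorted array of
    event times (ms) per network cell. All times lie in ``[0, duration)``.
    """

    drive_freq: float
    drive_spike_times: np.ndarray
    noise_spike_times: list[np.ndarray]
    duration: float

    @property
    def n_cells(self) -> int:
        return len(self.noise_spike_times)

    def to_event_table(self) -> list[tuple[int, float]]:
        """Flatten to (cell id, time ms) rows; drive events use cell id -1."""
        rows = [(-1, float(t)) for t in self.drive_spike_times]
        for c, times in enumerate(self.noise_spike_times):
            rows.extend((c, float(t)) for t in times)
        rows.sort(key=lambda r: (r[1], r[0]))
        return rows


def make_click_train(freq: float, duration: float, t0: float = 0.0) -> np.ndarray:
    """Periodic drive spike times ``t0, t0+T, ...`` below ``duration``.

    ``T = 1000/freq`` ms, so a 40 Hz train over 500 ms yields 20 events
    spaced 25 ms apart.
    """
    if freq <= 0:
        raise ValueError("freq must be > 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    period = 1000.0 / freq
    n = int(np.ceil((duration - t0) / period))
    times = t0 + period * np.arange(max(n, 0))
    return times[times < duration]


def make_poisson_noise(
    rate: float, duration: float, n_cells: int, seed
) -> list[np.ndarray]:
    """Independent homogeneous Poisson spike trains, one per cell.

    ``seed`` may be an int or a sequence of ints; per-cell streams are
    spawned deterministically from it, so any single cell's train is
    reproducible in isolation.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_cells)
    trains: list[np.ndarray] = []
    for child in children:
        if rate == 0:
            trains.append(np.empty(0))
            continue
        rng = np.random.default_rng(child)
        # draw exponential gaps in blocks until the trial is covered
        times: list[np.ndarray] = []
        total = 0.0
        block = max(16, int(rate * duration * 1.5) + 1)
        while total < duration:
            gaps = rng.exponential(1.0 / rate, size=block)
            cum = total + np.cumsum(gaps)
            times.append(cum)
            total = cum[-1]
        t = np.concatenate(times)
        trains.append(t[t < duration])
    return trains


def make_trial_stimulus(
    drive_freq: float,
    params: ModelParameters,
    seed,
    t0: float = 0.0,
) -> StimulusProgram:
    """Assemble the full stimulus program for one trial."""
    return StimulusProgram(
        drive_freq=drive_freq,
        drive_spike_times=make_click_train(drive_freq, params.duration, t0=t0),
        noise_spike_times=make_poisson_noise(
            params.noise_rate, params.duration, params.n_cells, seed
        ),
        duration=params.duration,
    )
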