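"""End-to-end experiment pipelines: replication, input sweeps, combinations.

Every condition (variant x drive frequency x input factor x alteration
levels) is simulated for ``n_trials`` noise realisations; the simulated MEG
signals are averaged point-wise in time and the spectrum of the average
yields the 40 Hz and 20 Hz band powers. The beat-skipping index is computed
per trial from the pooled excitatory spike times and averaged over trials
(the skipped-cycle parity varies from trial to trial, so pooling counts
across trials would cancel the very effect being measured).

Seed bookkeeping: a base seed plus a CRC-32 hash of the condition fields
gives a per-condition key, and (base seed, condition key, trial index)
seeds each trial, so any single condition or trial can be re-run in
isolation and parallel execution is byte-identical to serial.
"""
from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .model_core import simulate_trial
from .network_builder import alteration_grid, build_network, scale_input
from .observables import average_trials, beat_skipping_index, compute_meg, power_spectrum
from .parameters import ModelParameters
from .stimulation import make_trial_stimulus

#: the input-strength factors of the sweep experiments (0.1 .. 1.5, step 0.1)
DEFAULT_FACTORS = tuple(round(0.1 * i, 1) for i in range(1, 16))

SWEEP_COLUMNS = [
    "variant",
    "drive_freq",
    "I_factor",
    "gGABA_level",
    "bInh_decrement",
    "p40",
    "p20",
    "p_drive",
    "beat_index",
    "n_trials",
    "base_seed",
]


def condition_key(variant: str, drive_freq: float, I_factor: float,
                  gGABA_level: float, bInh_level: float) -> int:
    """Deterministic 31-bit key identifying a condition."""
    text = f"{variant}|{drive_freq:.6g}|{I_factor:.6g}|{gGABA_level:.6g}|{bInh_level:.6g}"
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def trial_seed(base_seed: int, cond_key: int, trial: int) -> int:
    """Deterministic 31-bit per-trial seed."""
    return zlib.crc32(f"{base_seed}:{cond_key}:{trial}".encode()) & 0x7FFFFFFF


def run_condition(
    variant: str,
    drive_freq: float,
    I_factor: float,
    params: ModelParameters,
    base_seed: int,
    gGABA_level: float = 1.0,
    bInh_level: float = 0.0,
    include_drive_in_meg: bool = False,
    onset_skip: float = 100.0,
    return_spectrum: bool = False,
    **build_kwargs,
):
    """Simulate one condition: n_trials trials, average, spectrum, beat index.

    Returns ``(p40, p20, beat_index)``; ``beat_index`` is the mean of the
    per-trial indices (None if undefined in every trial). With
    ``return_spectrum=True`` the full :class:`PowerResult` of the
    trial-averaged MEG is appended to the tuple.
    """
    network = build_network(
        variant, params, gGABA_level=gGABA_level, bInh_level=bInh_level, **build_kwargs
    )
    network = scale_input(network, I_factor)
    key = condition_key(variant, drive_freq, I_factor, gGABA_level, bInh_level)

    megs = []
    beat_indices = []
    for trial in range(params.n_trials):
        seed = trial_seed(base_seed, key, trial)
        stim = make_trial_stimulus(drive_freq, params, seed)
        try:
            rec = simulate_trial(network, stim, params, seed)
        except (FloatingPointError, ValueError) as err:
            raise RuntimeError(
                f"simulation failed for condition {variant} f={drive_freq} "
                f"I={I_factor} g={gGABA_level} b={bInh_level} trial={trial}: {err}"
            ) from err
        megs.append(compute_meg(rec, network, include_drive=include_drive_in_meg))
        pooled = np.concatenate(rec.spikes[: network.n_E]) if network.n_E else np.empty(0)
        bi = beat_skipping_index(pooled, stim, onset_skip=onset_skip)
        if bi is not None:
            beat_indices.append(bi)

    avg = average_trials(megs)
    spec = power_spectrum(avg, params.dt, n_trials_averaged=params.n_trials)
    beat = float(np.mean(beat_indices)) if beat_indices else None
    if return_spectrum:
        return spec.p40, spec.p20, beat, spec
    return spec.p40, spec.p20, beat


def band_power_at(spec, freq: float) -> float:
    """Power at the spectrum bin nearest ``freq`` Hz."""
    return float(spec.psd[int(np.argmin(np.abs(spec.freqs - freq)))])


def _row(variant, freq, I_factor, g, b, p40, p20, p_drive, beat, params, base_seed):
    return {
        "variant": variant,
        "drive_freq": freq,
        "I_factor": I_factor,
        "gGABA_level": g,
        "bInh_decrement": b,
        "p40": p40,
        "p20": p20,
        "p_drive": p_drive,
        "beat_index": np.nan if beat is None else beat,
        "n_trials": params.n_trials,
        "base_seed": base_seed,
    }


def run_replication(params: ModelParameters | None = None, base_seed: int = 0,
                    **kwargs) -> pd.DataFrame:
    """Control and IPSC variants at 20, 30 and 40 Hz drive, default input."""
    if params is None:
        params = ModelParameters()
    rows = []
    for variant in ("control", "IPSC"):
        for freq in (20.0, 30.0, 40.0):
            p40, p20, beat, spec = run_condition(
                variant, freq, params.I_factor, params, base_seed,
                return_spectrum=True, **kwargs
            )
            rows.append(_row(variant, freq, params.I_factor, 1.0, 0.0,
                             p40, p20, band_power_at(spec, freq), beat,
                             params, base_seed))
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def run_input_sweep(
    variant: str,
    drive_freq: float,
    factors=DEFAULT_FACTORS,
    params: ModelParameters | None = None,
    base_seed: int = 0,
    gGABA_level: float = 1.0,
    bInh_level: float = 0.0,
    **kwargs,
) -> pd.DataFrame:
    """Band powers as a function of the input-strength factor."""
    if params is None:
        params = ModelParameters()
    factors = list(factors)
    if not factors or any(f <= 0 for f in factors):
        raise ValueError("factors must be non-empty and positive")
    rows = []
    for f in factors:
        p40, p20, beat, spec = run_condition(
            variant, drive_freq, f, params, base_seed,
            gGABA_level=gGABA_level, bInh_level=bInh_level,
            return_spectrum=True, **kwargs
        )
        rows.append(_row(variant, drive_freq, f, gGABA_level, bInh_level,
                         p40, p20, band_power_at(spec, drive_freq), beat,
                         params, base_seed))
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def run_combination_sweep(
    variant_family: str,
    drive_freq: float = 40.0,
    params: ModelParameters | None = None,
    base_seed: int = 0,
    grid=None,
    factors=DEFAULT_FACTORS,
    **kwargs,
) -> pd.DataFrame:
    """Cross the alteration grid of a variant family with the input factors.

    ``drive_freq`` is 40 Hz for the combination experiments and 20 Hz for
    the beta-drive experiment.
    """
    if variant_family not in ("IPSC+gGABA", "IPSC+bInh", "Full"):
        raise ValueError("variant_family must be IPSC+gGABA, IPSC+bInh or Full")
    if params is None:
        params = ModelParameters()
    if grid is None:
        grid = alteration_grid(variant_family)
    frames = []
    for g_level, b_level in grid:
        frames.append(
            run_input_sweep(
                variant_family, drive_freq, factors, params, base_seed,
                gGABA_level=g_level, bInh_level=b_level, **kwargs
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# emergence analysis
# ---------------------------------------------------------------------------

def emergence_threshold(p20s) -> float:
    """Declared criterion for a 'substantial' 20 Hz component.

    The threshold is the midpoint between the sweep's minimum and maximum
    20 Hz power. This is a package convention (the underlying study never
    quantifies 'substantial'); it is configurable wherever it is used and
    recorded in run manifests.
    """
    p = np.asarray(p20s, dtype=float)
    return float((p.min() + p.max()) / 2.0)


def beta_window(factors, p20s, threshold: float | None = None):
    """Lower and upper edge of the beta-emergence window on a factor sweep.

    Returns ``(first, collapse, threshold)`` where ``first`` is the
    smallest factor whose 20 Hz power exceeds the threshold and
    ``collapse`` is the smallest factor above the sweep's p20 maximum at
    which p20 has fallen back below it (None if it never does within the
    sweep).
    """
    factors = np.asarray(list(factors), dtype=float)
    p = np.asarray(list(p20s), dtype=float)
    if factors.shape != p.shape or factors.size == 0:
        raise ValueError("factors and p20s must be equal-length and non-empty")
    order = np.argsort(factors)
    factors, p = factors[order], p[order]
    if threshold is None:
        threshold = emergence_threshold(p)
    above = p > threshold
    if not above.any():
        return None, None, threshold
    first = float(factors[np.argmax(above)])
    imax = int(np.argmax(p))
    collapse = None
    for i in range(imax + 1, len(factors)):
        if not above[i]:
            collapse = float(factors[i])
            break
    return first, collapse, threshold
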