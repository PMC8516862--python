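# Methods

## Model

`assrnet` simulates a minimal auditory-cortex microcircuit: `n_E = 20`
excitatory pyramidal cells and `n_I = 10` inhibitory (PV+ basket) cells,
coupled all-to-all within and between populations (self-synapses
included; a flag excludes them). Each cell *k* is a theta neuron,

    dθ_k/dt = 1 − cos θ_k + (b + S_k + N(t)) (1 + cos θ_k),

with a spike defined as the phase crossing π from below. The theta model
is the canonical phase reduction of a type-I excitable neuron: for
constant input `I0 < 0` the cell has a stable rest phase, for `I0 > 0` it
fires periodically with period `π/√I0` ms. All times are milliseconds;
currents and synaptic strengths are dimensionless.

The synaptic input is `S_k = Σ_j α_j g_jk s_jk` with `α = +1` for
excitatory presynaptic cells (and the pacemaker) and `−1` for inhibitory
ones. Gating variables obey

    ds_jk/dt = −s_jk/τ_j + e^(−η(1+cos θ_j)) (1 − s_jk)/τ_R,

so each presynaptic passage through π produces a sharp activation pulse
(width ≈ 0.3 ms for η = 5, since dθ/dt = 2 exactly at the spike phase)
that pushes `s` toward 1, after which `s` decays with the synapse-class
time constant: `τ_exc = 2` ms for excitatory synapses, `τ_inh = 8` ms for
inhibitory synapses in the control circuit.

Background noise is a per-cell homogeneous Poisson process; each noise
event at `t_n` injects the current kernel

    N(t) = H(t−t_n) · Ag_max (e^(−(t−t_n)/τ_exc) − e^(−(t−t_n)/τ_R)) / (τ_exc − τ_R),

with `Ag_max = 0.6` (peak ≈ 0.26, ≈ 0.3 ms after the event). Multiple
events sum linearly; the summed currents are precomputed per cell on the
sampling grid before integration.

### Pacemaker drive

The periodic drive (the "click train": 25 ms inter-click interval for
40 Hz stimulation) is delivered by a single pacemaker spike source that
synapses onto every cell with strengths `I · g_de = I · 0.3` (E cells) and
`I · g_di = I · 0.08` (I cells), where `I` is the input-strength factor
under study. The pacemaker's phase trajectory is the closed-form
constant-input theta-neuron solution whose period equals the click
interval, so it crosses π exactly at the click times; its gating variable
uses the same gating ODE with excitatory kinetics (`τ_exc`). Before the
first click the pacemaker phase rests at 0, where the activation term is
negligible (`e^(−2η) ≈ 5·10⁻⁵`).

### Parameters without a published value

Two constants required by the equations carry no value in the parameter
table and were fixed as follows:

* `η = 5` — the activation-scale value used throughout the
  theta-neuron ASSR model family this package implements; validated by
  the control network's clean 40 Hz entrainment.
* `noise_rate = 1/40` events/ms (25 Hz per cell) — calibrated so that
  background noise alone does **not** entrain the undriven network: with
  the drive weights silenced, no 20 or 40 Hz spectral peak exceeds 3× the
  median PSD of the 2–100 Hz band (at 1/30 events/ms the recurrent
  circuit begins to synchronize spontaneously in the gamma range, which
  would confound the drive-locked measures).

A third constant required judgement: the printed applied current. The
parameter table lists `b = −0.1`, but with that value the drive cannot
lift a resting cell across the excitability barrier (the saddle sits at
±0.61 rad while one drive pulse advances the phase by ≈ 0.2 rad): E cells
respond only sporadically, interneurons stay silent, and none of the
study's qualitative results occur. With `b = −0.01` — the value used by
the model lineage, and consistent with the excitability sweep treating
−0.01 as the control-like interneuron current — the control network
entrains fully and every reported phenomenon reproduces. The package
therefore defaults to `b = −0.01` and treats the printed −0.1 as a
misprint.

## SCZ-like variants

* `IPSC` — prolonged inhibition (reduced GAT1 reuptake): `τ_inh` raised
  8 → 28 ms on **all** inhibitory synapses. (A flag `ipsc_onto_E_only`
  restricts the change to I→E synapses, an alternative reading of the
  alteration's scope; the single-τ reading is the default because the
  parameter table carries one inhibitory decay constant.)
* `IPSC+gGABA` — additionally, reduced GABA levels: `g_ie` and `g_ii`
  scaled by a fraction (sweep: 100% → 10% in 5% steps).
* `IPSC+bInh` — additionally, NMDAR hypofunction at interneurons: the
  inhibitory applied current set to −level, with levels 0.01…0.10 (step
  0.01) then 0.15…0.60 (step 0.05). The mildest level (−0.01) equals the
  control current exactly; this "absolute" semantics is the default, a
  "decrement" reading (`b − level`) is selectable and recorded in every
  run manifest.
* `Full` — all three. The paired grid uses 10 GABA levels (step 10%)
  matched one-to-one with a 10-point subsample of the excitability grid
  spanning 0.01–0.60 (the two grids have unequal lengths, and the pairing
  is a package choice; it is overridable).

## Numerical integration

The joint system (30 phases + 930 gating variables + pacemaker gating) is
advanced with explicit forward Euler at fixed `dt = duration/n_steps =
500/8192 ≈ 0.061` ms, all derivatives evaluated on the pre-step state.
The inner loop is compiled with numba. Phases are wrapped to [0, 2π)
(the dynamics depend on cos θ only); spike times are interpolated
linearly between samples at upward π crossings. The gating update maps
[0, 1] into itself whenever `dt (1/τ + 1/τ_R) ≤ 1`; a violation raises an
error rather than clamping, as does any non-finite state (with the step
index, the standard symptom of too large a step). Initial phases are
drawn uniformly from [0, 2π) per cell per trial (a fixed `theta0` can be
supplied for deterministic tests); gating starts at 0.

Halving `dt` changes the trial-averaged control band powers by under
0.5% at the frequencies the drive excites (40 Hz under 40 Hz drive;
20 Hz and its 40 Hz harmonic under 20 Hz drive). Band powers at
undriven frequencies are noise residuals orders of magnitude below the
signal bands and are not meaningful convergence measures; likewise,
single-trial beta power in the beat-skipping regime is *inherently*
sensitive to any perturbation, integrator refinement included, because
the skipped-beat parity can flip. The convergence statement is therefore
made for the averaged signal at the driven bands, which are the
quantities the analyses use.

## Observables

The simulated MEG is the sum of the recurrent E→E gating variables (the
excitatory synaptic variables with a pyramidal postsynaptic target). The
pacemaker→E gating is excluded by default (`include_drive` adds it): the
MEG sums *unweighted* gating variables, so an included drive synapse
would superimpose a fixed, input-strength-independent copy of the drive
rhythm — incompatible with the observation that 40 Hz power vanishes as
the input factor approaches 0.1, and with the noise-only negative
control. Noise is a current, not a gating variable, and never enters the
sum.

Per condition, `n_trials = 20` trials with independent noise realisations
are averaged point-wise in time *before* the Fourier transform (this
averaging is part of the method under study: beat-skipping of opposite
parity across trials partially cancels in the average — itself a
candidate explanation for why a beta component can be hard to detect in
trial-averaged recordings). The spectrum uses a bare rectangular-window
FFT; with 500 ms trials the resolution is exactly 2 Hz, so 20 and 40 Hz
fall on bins 10 and 20 and no windowing is needed (on-bin sinusoids are
leak-free to machine precision). The PSD convention is one-sided with
`sum(psd) = mean(x²)` (Parseval); all study comparisons are relative, so
only the constancy of the convention matters.

**Beat-skipping index.** Drive cycles (click to click, skipping the first
100 ms of onset transient) are classified low- or high-response by their
pooled excitatory spike count (threshold: midpoint of the smallest and
largest count), and the index is `1 − mean(low)/mean(high)`: 0 for
uniform responding, 1 for strict every-other-cycle responding. Counts are
classified by magnitude rather than by a global even/odd split because
the skipped-beat parity drifts within trials; a parity-pooled index
underestimates the mechanism whenever a slip occurs. The index is
computed per trial and averaged (pooling counts across trials would
cancel alternation of opposite parity), and is undefined (None) for
trials without spikes in the analysis window. At sparse firing (very weak
drive) count fluctuations inflate the index; it is a within-regime
contrast measure, not an absolute synchrony scale.

**Emergence criterion.** "Substantial 20 Hz component" is operationalised
as 20 Hz power above the midpoint of the sweep's minimum and maximum
20 Hz power. The beta window's lower edge is the first factor above
threshold; the upper edge is the first factor past the p20 maximum that
falls back below it. The threshold convention is the package's own (the
study never quantifies "substantial") and is configurable and logged.

## Seeding

base seed → per-condition key (CRC-32 of the condition fields, masked to
31 bits) → per-trial seed (CRC-32 of base seed, condition key, trial
index). Per-cell noise streams are spawned from the trial seed via
`numpy.random.SeedSequence`. Any condition, trial or single cell's noise
train is reproducible in isolation, and parallel execution of conditions
is byte-identical to serial.

## What the synthetic data does and does not emulate

The simulator is the study's own data source — there is no external
data. The click-train drive and Poisson background are idealisations:
no cochlear/thalamic front-end, no amplitude-modulated tones or chirps,
no adaptation, no axonal delays, a single interneuron class, and an MEG
proxy that is a synaptic sum rather than a lead-field projection.
Passing tests therefore show that the *mechanism* (prolonged IPSC decay
→ beat-skipping → subharmonic power, gated by input strength) behaves as
established for this model class — not that real cortex does.

## Problem sizes used by the test suite

Unit tests run desk-scale configurations (2–3 cells, 250 ms trials, 2–3
trials per condition). The acceptance-level tests use the full study
conditions: 30 cells + pacemaker, 8192 steps, 20 trials per condition,
the 15-point factor grid, 5 base seeds for the stochastic window
measurements, and a 10-level (10%-step) GABA grid for the combination
narrowing check.

## Known limitations

* Established results with this model family place the beta window at
  80–120% of the default input strength; under the calibrated noise
  default the measured edges are most often 90% and 110%, within one
  grid step on each side.
* The beat-skipping index saturates upward at very low firing rates (see
  above); comparisons are meaningful within the driven regime.
* Forward Euler at the standard step is adequate (see convergence above)
  but deliberately simple; no adaptive or implicit integration is
  offered.
* The excitability-sweep semantics ("absolute" vs "decrement") and the
  paired grid of the Full model are documented package choices where the
  source material is ambiguous; both are switchable and recorded in run
  manifests.
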