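# assrnet

Theta-neuron microcircuit simulation of gamma-band auditory steady-state
responses (ASSRs) and their beta-band subharmonic.

## The problem

Periodic auditory stimulation ("click trains") entrains cortical
oscillations at the stimulus frequency. In schizophrenia the 40 Hz ASSR
is reliably weakened, and some — but not all — studies additionally
report *increased* 20 Hz power during 40 Hz stimulation. `assrnet`
implements a minimal excitatory/inhibitory circuit model with which the
conditions for that 20 Hz (beta) component can be studied systematically:
which microcircuit alteration produces it, and over which range of
stimulus input strengths it exists.

The circuit couples 20 excitatory pyramidal cells and 10 inhibitory PV+
basket cells, all-to-all, each a theta neuron

dθ_k/dt = 1 − cos θ_k + (b + S_k + N(t))(1 + cos θ_k),

with synaptic gating s_jk driven by presynaptic spikes (activation
e^{−η(1+cos θ_j)}) and decaying with τ_exc = 2 ms (AMPA-like) or
τ_inh = 8 ms (GABA_A-like), a periodic pacemaker drive (the click train),
and per-cell Poisson background noise. A simulated MEG signal — the
summed recurrent excitatory gating onto pyramidal cells — is averaged
over 20 noise-realisation trials in time and Fourier-transformed; the
40 Hz and 20 Hz bin powers are the entrainment measures.

Three schizophrenia-associated alterations are available, alone or
combined: prolonged inhibitory decay (τ_inh 8 → 28 ms; reduced GAT1),
reduced inhibitory weights (reduced GABA levels), and reduced interneuron
excitability (NMDAR hypofunction). With prolonged inhibition, drive in a
narrow input-strength window makes the pyramidal population respond only
to every other click — "beat-skipping" — moving power from 40 Hz to the
20 Hz subharmonic. See `docs/methods.md` for the full model description
and all conventions.

## Worked example

```python
import assrnet as an

params = an.ModelParameters()          # control circuit, 500 ms trials, 20 trials
for variant in ("control", "IPSC"):
    p40, p20, beat = an.run_condition(variant, drive_freq=40.0, I_factor=1.0,
                                      params=params, base_seed=1)
    print(f"{variant:8s} p40={p40:8.1f}  p20={p20:6.1f}  beat={beat:.2f}")

sweep = an.run_input_sweep("IPSC", 40.0, params=params, base_seed=1)
first, collapse, thr = an.beta_window(sweep.I_factor, sweep.p20)
print(f"beta window: emerges at {first:.1f}, collapsed by {collapse:.1f} "
      f"(threshold {thr:.1f})")
```

prints

```
control  p40=  2281.8  p20=   1.1  beat=0.13
IPSC     p40=   836.8  p20= 248.1  beat=0.60
beta window: emerges at 0.9, collapsed by 1.1 (threshold 124.0)
```

The prolonged-inhibition (IPSC) variant loses most of its 40 Hz power
and gains a prominent 20 Hz component at default input strength; its
beat-skipping index (0 = every cycle answered uniformly, 1 = strict
every-other-cycle responding) rises accordingly. The input-strength
sweep (factors 0.1–1.5 of the default drive strength) shows the 20 Hz
component existing only in a narrow window around the default input:
weaker drive cannot synchronize the circuit at all, stronger drive
overrides the prolonged inhibition and restores a pure 40 Hz rhythm.

A command-line interface mirrors the experiment families:

```sh
assrnet replicate   --seed 1 --out results/replication.csv
assrnet input-sweep --seed 1 --variant IPSC --out results/sweep.csv
assrnet combo-sweep --seed 1 --family IPSC+gGABA --out results/combo.csv
assrnet beta-drive  --seed 1 --family Full --out results/beta20.csv
```

Each run writes a CSV results table and a JSON manifest with the fully
resolved configuration.

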