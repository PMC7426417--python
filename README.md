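# synieg

Simulation and quantification of **synthetic immediate-early genes (SynIEGs)**
— transgenes that combine a serum/light-responsive *FOS* promoter with
interchangeable 3′UTRs, degrons and fluorescent reporters to dissect how
mammalian cells decode the *dynamics* (transient vs. sustained Erk) and
*combinations* (growth factor AND DNA damage) of upstream signals.

The package is aimed at quantitative biologists who build or analyze
live-cell reporter circuits. It provides, end to end:

1. **`synieg.circuit_model`** — a kinetic ODE model of multi-step SynIEG
   regulation under programmable stimuli (serum, optogenetic light windows,
   doxorubicin, cycloheximide, MEK inhibitor);
2. **`synieg.movie_synth`** — a renderer that turns simulated trajectories
   into realistic 3-channel, 7-slice time-lapse stacks (nuclear marker,
   MCP-labelled transcription foci, diffuse reporter) with attached ground
   truth;
3. **`synieg.burst_quant`** — the transcription-site quantification chain:
   z-max projection, LoG focus detection, stationary-site tracking, and
   axis-aligned 2D-Gaussian fits whose integrated area
   `I = 2π·A·σx·σy` is the burst intensity;
4. **`synieg.trace_analysis`** — nuclear trace extraction and the summary
   statistics `AUC = Σ_t (intensity(t) − initial)` (baseline = mean of the
   first two timepoints), endpoint fold-change, time-to-peak and adaptation
   time;
5. **`synieg.decoding_stats`** — duration-filter and AND-gate scoring with
   two-sided Student t-tests.

## Model

Normalized pathway inputs `E(t)` (Erk), `D(t)` (DNA damage) and `S(t)`
(protein synthesis) drive, per cell:

    dZ/dt  = k_z·E·S − δ_z·Z                       (Zfp36-like adaptation repressor)
    T_i(t) = k_tx·(k_leak + E·K_z^h/(K_z^h + Z^h)) (per-site transcription rate)
    dM/dt  = Σ_i T_i − δ_m(Z)·M                    (pooled mRNA)
    dP/dt  = k_tl·ε(D)·M − δ_p(E)·P                (reporter protein)

The circuit's parts list switches the regulatory arms on and off: the *FOS*
3′UTR makes `δ_m` increase with Z (Erk-induced mRNA destabilization), the
*BTG2* 3′UTR puts translation efficiency `ε` under miR-21 control (relieved
by DNA damage; a sponge de-represses, overexpression pins repression on),
and the Fra1 degron destabilizes the protein except while Erk is active.
Reported fluorescence is `P` plus a constitutive per-channel
autofluorescence offset. Time is in minutes; intensities in arbitrary
units. Shipped rate constants were calibrated once against the circuit
behaviors listed in `docs/methods.md` and are recorded in
`src/synieg/data/default_params.yaml`.

## Worked example

Simulate the default *fos-btg2* reporter line under 10% serum, render a
movie, and quantify the transcription bursts back out:

```python
import dataclasses
import numpy as np
from synieg import (KineticParams, get_circuit_preset, get_stimulus_preset,
                    make_stimulus, simulate_circuit, CellGeometry, OpticsNoise,
                    render_movie, detect_and_track, burst_traces,
                    mean_burst_trace, IntensityTrace, kinetic_metrics)

params = KineticParams()
program = dataclasses.replace(get_stimulus_preset("serum10"),
                              drug_addition_time_min=10.0, duration_min=190.0)
traj = simulate_circuit(get_circuit_preset("fos-btg2"), params,
                        make_stimulus(program, params.k_damage))

geom = CellGeometry.random(n_sites=8, seed=11)
movie = render_movie(traj, geom, OpticsNoise(), seed=5)

tracks = burst_traces(movie, detect_and_track(movie))
trace = IntensityTrace(times=traj.time_grid, values=mean_burst_trace(tracks))
noise_sd = float(np.nanstd(trace.values[trace.times < 10.0]))
print(len(tracks), kinetic_metrics(trace, noise_sd, t_stimulus=10.0))
```

prints

```
8 {'time_to_peak_min': 28.0, 'adaptation_time_min': 56.0}
```

— all 8 genomic integration sites are recovered as tracks, the mean burst
intensity peaks 28 min after serum addition (within one frame of the
underlying 30-min transcriptional maximum) and has adapted back to within
one noise SD of baseline by 56 min, inside the ~90-min window expected for
an immediate-early response.

At the protein level, the same model reproduces the decoding behaviors of
the named circuits:

```python
from synieg import fold_change
traj = simulate_circuit(get_circuit_preset("fos-tubulin"), params,
                        make_stimulus(get_stimulus_preset("sustained"),
                                      params.k_damage))
print(fold_change(IntensityTrace(times=traj.time_grid, values=traj.protein)))
```

```
(1.4000116585513687, 40.00116585513687)
```

i.e. a 40% increase in reporter fluorescence over 3 h of sustained light
for the unregulated *fos-tubulin* circuit (the *fos*-Fra1deg-*fos* dynamic
filter gives 20%, and the *fos* promoter × *BTG2* 3′UTR AND gate gives a
fourfold dGFP increase only under serum + doxorubicin).

There is also a CLI: `synieg pipeline --circuit fos-btg2 --stimulus serum10`
runs simulate → render → quantify → analyze into one output directory, and
`synieg fixtures` regenerates the canonical demo movie set.

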