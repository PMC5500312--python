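# dendrospt

Single-particle-tracking (SPT) analysis of receptor lateral diffusion on
dendrites — from per-frame quantum-dot localizations to inter-synaptic
transition statistics and first-passage-time modelling.

Neurotransmitter receptors are not fixed at synapses: they diffuse
laterally in the membrane, dwell transiently in synaptic compartments and
occasionally travel from one synapse to the next. Quantifying that motion
from 20 Hz quantum-dot recordings raises a chain of inference problems —
relinking detections across quantum-dot dark periods, estimating diffusion
coefficients from short noisy tracks, classifying localizations into
synaptic compartments, and asking whether an observed synapse-to-synapse
transit time is compatible with free diffusion along the dendrite. This
package implements that chain as a tested, scriptable pipeline for
experimentalists and modellers, with a synthetic-data generator that
produces ground-truthed recordings (anisotropic diffusion, synaptic
trapping, blinking, localization noise) so every estimator can be
validated end to end.

## The quantities it computes

* **Track linking** — a detection at frame *f* extends a track ending at
  frame *f′* iff the displacement is ≤ 4 pixels (0.64 μm at 160 nm/px) and
  the dark period *f − f′ − 1* is ≤ 25 frames (1.25 s at 20 Hz); greedy
  nearest-neighbour, deterministic tie-breaks.
* **MSD and instantaneous D** — MSD(n·dt) averaged over all localization
  pairs n frames apart; D = slope/4 of a least-squares line through the
  first four MSD points (intercept absorbs the ~4σ² localization-noise
  offset).
* **Compartment statistics** — synaptic compartment = punctum dilated by
  2 pixels; dwell episodes (maximal synaptic runs, duration = run length ×
  dt) and inter-synaptic transitions A→B (no third synapse in between,
  time from last frame in A to first frame in B).
* **Anisotropic estimation** — steps decomposed along the dendrite's
  longitudinal/transversal axes; Gaussian fit of single-frame
  displacements gives drift μ = m/dt and D = σ²/(2·dt) per axis.
* **First-passage-time model** — 1D Brownian Monte Carlo (default 5000
  replicates, dt = 50 ms) from a source synapse to an absorbing boundary
  at distance L, censored at the chance time; reports the f-FTP (mean of
  the first percentile of passage times) and locates observed transition
  times on the simulated cumulative curve (percentile intercept). The
  drift-free simulator is validated against the closed form
  F(t) = erfc(L/(2√(Dt))).

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Run the packaged demo — a 12 μm dendrite with three inhibitory synapses
2–4 μm apart, 20 receptors recorded for 1200 frames at 20 Hz with
trapping, blinking and 40 nm localization noise:

```
$ dendrospt run --config configs/demo.yaml --out results/demo
summary written to results/demo/summary.json
D (MSD fit): median 0.047983 um2/s (IQR 0.042604-0.050952, n=26)
```

`results/demo/summary.json` then contains, among others:

| quantity | value | reading |
|---|---|---|
| `D_msd_um2s` | median 0.048, IQR 0.043–0.051 (n = 26) | planar MSD-fit D; the generator's axis-average D is (0.08 + 0.02)/2 = 0.05 μm²s⁻¹, and synaptic trapping drags the estimate slightly below it |
| `transition_time_s` | median 7.2 s (n = 7) | inter-synaptic transit times, last frame in the source synapse to first frame in the target |
| `dwell_time_s` | median 0.15 s (n = 303) | uninterrupted synaptic visits; heavily right-skewed by trapped episodes |
| `D_long_um2s` / `D_trans_um2s` | 0.107 / 0.050 μm²s⁻¹ | per-axis Gaussian-fit D; each is the true value (0.08 / 0.02) plus the uncorrected localization-noise term σ²/dt = 0.032 (see methods note) |
| `intersynaptic_fraction_of_synaptic` | 0.235 (n = 17) | fraction of synapse-visiting tracks that reached a second synapse within the recording |

The linked trajectories, per-track metrics, transition/dwell tables,
per-axis estimates and FPT intercepts are written alongside as CSVs.

Asking whether a 3 μm transit is reachable by free diffusion at the
median mobility:

```
$ dendrospt fpt --d 0.066 --l 3.0 --n 5000 --chance-time 60 --seed 1
1445/5000 passages within 60.0 s (3555 censored)
f-FTP = 7.157 s
```

i.e. at D = 0.066 μm²s⁻¹ about 29% of walkers cover 3 μm within a minute,
and the fastest percentile of them needs ~7 s — sub-second transits
require the higher longitudinal mobility that the anisotropic estimator
measures.

Every subcommand (`simulate`, `link`, `analyze`, `anisotropy`, `fpt`,
`match`, `run`) is a thin wrapper over the library; the same operations
are importable from `dendrospt`.

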