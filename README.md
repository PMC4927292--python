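# smfretkit

Simulation and analysis of surface-tethered single-molecule FRET (smFRET)
experiments: the kind of assay in which donor/acceptor dye pairs on a
tethered protein complex — for example complexin-1 bound to the neuronal
SNARE complex — report conformational states through per-molecule energy
transfer efficiencies, and binding partners in solution produce bursts of
acceptor fluorescence whose dwell times yield association and dissociation
kinetics.

The package covers the full chain from raw two-channel intensities (or
rendered TIRF image stacks) to population and kinetic summaries, and pairs
every analysis stage with a synthetic-data generator built as the exact
inverse of the correction model, so each stage can be validated against
known ground truth.

## What it computes

**FRET efficiency and corrections.** The Förster relation
`E = 1 / (1 + (r/R0)^6)` (R0 = 5.1 nm for Alexa 555/647) links efficiency
to dye separation. From observed channel intensities the estimators are,
in increasing order of correction:

```
E  = I_A / (I_A + I_D)                        (proximity ratio)
D_c = I_D − α·I_A ;  A_c = I_A − β·D_c
E  = A_c / (A_c + D_c)                        (leakage-corrected)
E  = A_c / (A_c + γ·D_c)                      (γ-corrected)
```

with α the acceptor→donor leakage (default 0.165), β the donor→acceptor
leakage (default 0.017), and γ = ΔI_A/ΔI_D the per-molecule detection/
quantum-yield factor estimated from the intensity steps across single-step
acceptor photobleaching.

**Populations.** Per-molecule efficiencies (mean of the first 50 frames at
10 Hz) are histogrammed (bin 0.02 over [−0.2, 1.2]) and decomposed into a
low- and a high-FRET Gaussian; population percentages are area ratios with
split-half SDs.

**Kinetics.** Binding-burst traces are idealized with a two-state
Gaussian-emission HMM; interior dwell times give single-exponential rates,
`k_on = (unbound rate)/[ligand]`, and `K_D = k_off/k_on`.

**Structure-based prediction.** Sterically allowed dye positions are
sampled around labelled residues of a PDB structure; the Förster equation
at the mean-position distance predicts the expected efficiency.

## Worked example

Simulate a two-conformation cohort (40 % low-FRET at E = 0.19, 60 %
high-FRET at E = 0.83, γ = 1.66, realistic noise), select single-pair
molecules, and decompose the efficiency histogram:

```python
import numpy as np
from smfretkit import (TraceSimConfig, CorrectionSet, simulate_cohort,
                       select_single_pair_molecules, per_molecule_efficiency,
                       fit_two_gaussians, population_fraction, detect_bleach_events)

base = dict(transition_rates=[[0.0]], noise_sd=60.0, gamma=1.66,
            acceptor_bleach_rate=0.005, donor_bleach_rate=0.001,
            n_frames=600, efficiency_jitter_sd=0.12)
cohort = simulate_cohort(
    {"trans": TraceSimConfig(state_efficiencies=[0.19], **base),
     "cis": TraceSimConfig(state_efficiencies=[0.83], **base)},
    weights={"trans": 0.4, "cis": 0.6}, n_traces=400, seed=7)

cs = CorrectionSet(alpha=0.165, beta=0.017, gamma=1.66)
kept, dropped = select_single_pair_molecules(cohort, cs)
samples = []
for tr in kept:
    ev = detect_bleach_events(tr)
    first = min([f for f in (ev.acceptor_bleach_frame, ev.donor_bleach_frame)
                 if f is not None], default=None)
    try:
        samples.append(per_molecule_efficiency(tr, cs, mode="gamma",
                                               bleach_frame=first))
    except Exception:
        pass
fit = fit_two_gaussians(samples)
print(f"low  component: mean={fit.low.mean:.3f}  sd={fit.low.sd:.3f}")
print(f"high component: mean={fit.high.mean:.3f}  sd={fit.high.sd:.3f}")
print(f"% cis conformation = {population_fraction(fit, 'high').percent:.1f}")
```

prints

```
low  component: mean=0.204  sd=0.109
high component: mean=0.829  sd=0.109
% cis conformation = 63.8
```

The recovered component means (0.204 / 0.829) sit on the generating state
efficiencies (0.19 / 0.83), and the high-FRET ("cis") percentage matches
the 60 % simulated weight within the fit uncertainty at n ≈ 385 molecules.

The same analyses are scriptable from the shell (`smfret --help`):
`simulate-traces`, `simulate-binding`, `simulate-movie`, `extract-traces`,
`correct`, `fit-populations`, `idealize`, `kinetics`, `predict-fret`, and
the end-to-end `run-conformation` / `run-binding` pipelines, which also
write a provenance manifest with content hashes of every output.

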