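# gbcsim

Structure-to-function modelling of **globular bushy cells** (GBCs) of the
ventral cochlear nucleus — the neurons that sharpen auditory-nerve timing
for binaural hearing.  GBCs receive 5–12 large auditory-nerve terminals
(endbulbs of Held) on their cell body; whether a cell behaves as a
coincidence detector (all endbulbs subthreshold) or in a mixed mode (one
or two suprathreshold inputs) depends on the distribution of contact
areas, the dendritic membrane load, and the axon initial segment.

`gbcsim` implements the full in-silico pipeline connecting those
anatomical quantities to spike timing:

- **morphology** — tagged extended-SWC cell trees (soma, hillock, AIS,
  myelinated axon, proximal dendrite, hubs, shafts, swellings), frustum
  surface areas, diameter inflation to mesh areas, pruning, standard-axon
  substitution, axon-branch conduction delays;
- **membrane / cable** — Hodgkin–Huxley bushy-cell kinetics (Na, KHT,
  KLT, IH) with three dendritic decoration schemes (passive /
  half-active / active), d-λ discretization, and an implicit branched
  cable integrator with current-clamp and series-resistance voltage-clamp
  protocols;
- **endbulb** — stochastic multisite release: `n_sites = 0.7686 × ASA`,
  independent Bernoulli release per site (fixed *Pr*), biexponential
  conductance kernels with polyamine rectification and optional NMDA;
- **an_surrogate** — tone/SAM/click stimulus synthesis and a
  phenomenological auditory-nerve spike generator (envelope-driven
  inhomogeneous Poisson with dead time, calibrated to 200 Hz driven
  rate);
- **calibration** — simulated voltage-clamp measurement of gKLT
  (Boltzmann fit, Rs correction, leak subtraction) with iterative density
  scaling to the 80 nS target, capacitance from charging transients, and
  rheobase by bisection to 1 pA;
- **metrics** — spike detection, vector strength (VS) with grouped SD,
  rate modulation transfer functions, entrainment, shuffled
  autocorrelograms (SAC/CI), cross-correlograms, per-input efficacy /
  participation, and logistic efficacy-vs-ASA fits;
- **asa_voxel** — apposed surface area (ASA) between segmented objects in
  anisotropic voxel volumes (dilation → overlap → marching cubes →
  area/2), with NRRD/TIFF I/O;
- **synthetic / experiments** — seeded generators for toy cells, endbulb
  profiles, voxel phantoms and control spike trains, plus the experiment
  protocols (input-configuration, dendrite pruning, AIS-length sweep).

The central statistic throughout is the vector strength
`VS = |Σ exp(i·2π·f·t_k)| / N` of spike times on the envelope-modulation
cycle, together with the SAC correlation index (Poisson ⇒ 1) and the
entrainment index (ISIs in `[0.5/f, 1.5/f]` per modulation cycle).

## Worked example

```python
import numpy as np
from gbcsim import synthetic as syn, experiments as X, calibration as cal
from gbcsim import an_surrogate as ans, metrics as mt

# a toy GBC with the population-mean geometry (soma 1352 um^2,
# dendrite/soma ratio 2.76, AIS 16.8 um), half-active dendrites
cell = syn.make_toy_cell(syn.CellTemplate(), seed=2)
model = X.build_gbc(cell, mode="half_active")

thr, iters = cal.rheobase(model)
print(f"rheobase: {thr*1e3:.0f} pA ({iters} bisections)")

# six convergent endbulbs, largest suprathreshold (mixed mode),
# driven by a 200 Hz SAM tone at 30 dB SPL
profile = syn.make_endbulb_profile("mixed", n_inputs=6, seed=7)
print("endbulb ASAs (um^2):", np.round(profile.asas, 1))
spec = ans.StimulusSpec(kind="SAM", f_mod_hz=200.0, level_db_spl=30.0,
                        duration_ms=500.0)
resp = X.simulate_sound_response(model, profile, spec, n_trials=10, seed=1)
vs = mt.vector_strength(resp.post_trains, 200.0, window_s=(0.25, 0.5))
fibers = [tr for k in range(profile.n_inputs) for tr in resp.pre_trains[k]]
vs_anf = mt.vector_strength(fibers, 200.0, window_s=(0.25, 0.5))
rate = mt.rmtf({200.0: resp.post_trains}, stim_dur_s=0.5)[200.0]
print(f"driven rate: {rate:.0f} Hz")
print(f"vector strength at 200 Hz: GBC {vs.vs:.3f} vs ANF {vs_anf.vs:.3f}")
```

prints

```
rheobase: 539 pA (11 bisections)
endbulb ASAs (um^2): [199.4  94.3  80.1  68.8  62.3  49. ]
driven rate: 189 Hz
vector strength at 200 Hz: GBC 0.868 vs ANF 0.711
```

The cell fires once per modulation cycle (driven rate ≈ the 200 Hz
modulation frequency) and phase-locks *better* than its auditory-nerve
inputs (VS 0.87 vs 0.71) — the coincidence-detection enhancement that
motivates the convergence architecture.  A rheobase near 0.5 nA and 11
bisections to 1 pA resolution are typical for this geometry.

A thin CLI wraps the same functions:

```sh
gbcsim simulate --out trace.csv --amp-na 2        # current-clamp step
gbcsim fixtures --out fixtures/ --seed 4          # toy cell + endbulb CSV
gbcsim asa --vol-a term.nrrd --vol-b soma.nrrd    # voxel contact area
gbcsim calibrate --mode half_active               # gKLT calibration report
gbcsim experiment --out results/ --f-mod 200      # small SAM experiment
```

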