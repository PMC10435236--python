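# Methods

`gbcsim` models the structure-to-function pipeline for globular bushy
cells (GBCs) of the ventral cochlear nucleus: tagged morphologies are
turned into conductance-based compartmental models, innervated by
ASA-weighted stochastic endbulb synapses driven by a surrogate
auditory-nerve generator, and the resulting spike trains are analysed with
the standard temporal-coding statistics.  This note records the model,
its assumptions, the numerical choices, and what the synthetic test bed
does and does not establish about real data.

## Morphology representation

A cell is a tree of tagged *sections* (soma, axon hillock, AIS, myelinated
axon, proximal dendrite, hub, distal dendrite, swelling); each section is
a polyline of 3-D points with radii whose consecutive points define
conical frustums.  All areas are frustum lateral areas, pi (r1+r2) x
slant.  I/O uses a 7-column extended SWC dialect with a configurable
integer-to-tag map (default in `morphology.DEFAULT_TAG_MAP`); sections
continue through the unique same-tag child point, and every other child
starts a new section attached at that point.  Zero-length frustums are
dropped at parse time.

**Inflation.** Mesh-derived surface areas exceed frustum areas because
meshes resolve membrane crenelations.  `inflate` multiplies all point
radii in a group (soma; all dendritic tags pooled) by a single factor,
iterating until the achieved area is within 0.1% of the target (at most
50 iterations).  Because frustum area is linear in radius at fixed
length, the factor equals the target/current area ratio to 1e-6 and one
iteration suffices; the loop guards degenerate geometries.

**Axon branch delays.** Conduction velocity follows the linear rule
CV = 4.6 x fiber diameter (m/s with diameter in um), with fiber diameter =
axon diameter / g-ratio (default 0.76).  Short internodal branches conduct
slower than the infinite-cable rule predicts; lacking a published closed
form, the slowing is modelled as a multiplicative factor 1 + k (d/L) with
k = 1 by default and exposed as a parameter.  A zero-length (en passant)
branch has zero delay.

## Membrane model

Channel kinetics are the ventral-cochlear-nucleus Hodgkin-Huxley
formulations measured in isolated bushy neurons (fast transient Na+ with
m^3 h; KHT with 0.85 n^2 + 0.15 p; KLT with w^4 z and a steady-state
inactivation floor of 0.5; IH with a single r gate).  Rates are measured
at 22 degC and scaled to the 37 degC simulation temperature with Q10 = 3
(rates); a conductance Q10 of 2 is available but not applied to the base
set, because the base conductances are themselves 37 degC targets fixed
by calibration.  Reversals: ENa +55, EK -70, Eh -43 mV.  Na inter-channel
cooperativity is not modelled (a configuration hook exists but is off).

**Decoration.** Somatic base conductances are gNa 500, gKHT 58, gKLT 80,
gH 30 nS, spread over the capacitance-equivalent reference area of the in
vitro measurement (26 pF at 0.9 uF/cm^2 = 2889 um^2, i.e. 2.769 mS/cm^2
for KLT).  Axonal compartments use fixed ratios of the somatic density
(AIS: Na x100, KHT x2, KLT x1, IH x0.5, leak x1; hillock: Na x5, KHT/KLT
x1, IH 0, leak x1; myelinated: Na 0, KHT/KLT x0.01, IH 0, leak x0.00025).
Dendrites follow one of three bracketing schemes: *passive* (leak only,
0.0693 mS/cm^2), *half-active* (half the somatic densities, leak 0.0693)
and *active* (somatic densities, leak 0.1385).  The tables ship as JSON in
`gbcsim/data/decoration.json`.  Somatic leak density is 0.1385 mS/cm^2
(~1.9 nS on the mean soma), consistent with the active-dendrite scheme
using the somatic leak value.

**Resting potential.** With these densities the standing IH current and
partly activated KLT pin the decorated reference cell near -61 to -62 mV;
the total leak (~4 nS) is too small for its reversal to move rest by more
than ~1 mV.  The default leak reversal is -80 mV (a chloride/pump
dominated leak), which puts the reference cell's rest at -62.3 mV, at the
edge of the intended -65 +/- 3 mV operating range.  This is a documented
compromise: rest cannot be brought to exactly -65 mV through the leak
alone under the mandated decoration tables.  Myelinated sections keep the
same specific capacitance as bare membrane (their leak is 4000x smaller);
myelin capacitance reduction is not modelled.

## Cable integration

The d-lambda rule sets each section's segment count to the smallest odd
integer >= L / (0.1 lambda_f) with lambda_f evaluated at 1 kHz from the
section's length-weighted mean diameter; segment areas partition the
section's frustum area exactly, and axial resistances integrate
Ra ds / (pi r^2) over the actual tapered geometry.  The resulting tree
system is solved exactly each step by Hines elimination (parents indexed
before children; numba-accelerated with a pure-Python fallback).

Stepping is implicit.  Current clamp uses backward Euler at dt = 25 us;
gating variables advance by the exponential (Rush-Larsen) update at the
current voltage.  Voltage clamp uses the trapezoid rule at dt = 5 us with
the pipette node in series through Rs: the clamp charging time constant
(~Rs C ~ 13 us) is under three samples, and a first-order method biases
an exponential fit to the transient by 15-20%, while the trapezoid rule
keeps it within ~2%.  An ideal clamp (Rs = 0) is realised as a very large
series conductance and automatically falls back to the L-stable
first-order method, which damps the otherwise marginally stable stiff
mode.  Every protocol is preceded by a settling run (200 ms by default,
coarse 25 us steps; clamped at the holding potential for voltage-clamp
protocols).  Voltages above 200 mV in magnitude raise an integration
error with diagnostics.  Spike times are reported with parabolic
sub-sample interpolation.

## Endbulb synapses

Release sites per terminal = round(0.7686 sites/um^2 x ASA).  Each
presynaptic spike triggers an independent Bernoulli trial per site with
fixed Pr (default 0.3; the release probability is constant over time, no
depletion or facilitation, and no release-latency jitter), so the release
count per spike is Binomial(n_sites, Pr) and the mean synaptic weight is
linear in ASA.  Each release adds a biexponential conductance transient
(rise 0.1 ms, decay 0.3 ms, peak 0.7 nS per site) — a deliberate
simplification of the kinetic receptor scheme with desensitization; the
acceptance surface here is release statistics and weight scaling, not
receptor microkinetics.  AMPA current rectifies with depolarization
(polyamine block), modelled as a sigmoid scaling with floor 0.2,
half-voltage -20 mV, slope 20 mV.  An optional NMDA component (default
10% of the AMPA peak, rise 2 ms, decay 20 ms) carries a sigmoidal
voltage-dependent Mg2+ block.  Transmitter spillover between sites is
ignored.

## Surrogate auditory nerve

The cochlear transduction model is replaced by a phenomenological
generator.  Stimuli (tones, 100% SAM tones on a 16 kHz carrier, 100 us
click trains) are synthesized at 100 kHz with 2.5 ms cosine-squared
ramps; the steady-portion RMS equals 20 uPa x 10^(level/20).  The
instantaneous firing intensity maps the stimulus envelope through an
expansive power law (exponent `envelope_gain`, default 3) with an
exponential onset-adaptation term (strength 1, tau 10 ms, giving
primary-like PSTHs); spikes are drawn by Poisson thinning with a 0.7 ms
absolute dead time.  For tonal stimuli the spontaneous floor (100 Hz,
high-spontaneous class) is masked while the stimulus gate is open — this
is what lets the surrogate fall silent in SAM troughs and reach
fibre vector strengths of ~0.7-0.8, as real high-SR fibres do near their
best modulation level; for click trains the floor is additive so
spontaneous activity recovers between clicks.  A deterministic bisection
calibrates the drive gain so the steady-state effective rate (accounting
for dead time, r_eff = r/(1 + r tau_d)) equals 200 Hz at the reference
level.  The surrogate locks only to the envelope, never to the carrier;
it has no cochlear filtering, no rate-level saturation structure across
levels, and a single SR class.

## Calibration

gKLT as seen from the soma is measured by simulated voltage clamp in the
calibration configuration (KLT + leak only): 100 ms steps from -80 mV to
+20 mV in 10 mV increments through Rs = 1 MOhm at dt = 5 us; steady-state
currents are the mean of the last 10 ms; leak is subtracted as a line
through the holding current with slope from a -90 mV step; the membrane
voltage is corrected as Vm = Vcmd - I Rs; and a Boltzmann
G = Gmax / (1 + exp(-(V - Vhalf)/k)) is fitted.  Because the KLT z gate
floors at 0.5 at depolarized steady state, the measured Gmax is roughly
half the installed maximal conductance times the dendritic attenuation —
the calibration therefore scales the *measured* conductance to the 80 nS
target, exactly as the experimental protocol it mimics.  Each iteration
rescales all KLT densities by target/measured; convergence (<= 1%) takes
2-3 iterations from the tabulated starting densities, and the cumulative
factor is then applied to Na/KHT/IH, preserving the base ratios
(gNa/gKLT = 500/80).  Input capacitance is measured from a -80 to -90 mV
step as C = tau_fast/Rs with tau_fast from a single-exponential fit to
the clamp-current transient.  Rheobase uses bisection on a 20 ms pulse to
a 1 pA terminal step (11 iterations for a 0-2 nA bracket); the settled
state is computed once and reused across probe currents.

## Spike detection and metrics

Spike detection uses height (peak >= -20 mV), rising slope (>= 20 mV/ms),
falling slope (>= 10 mV/ms), half-width (<= 1 ms) and a 0.7 ms merge
window; parameters are exposed and recorded, since bushy-cell somatic
spikes can be small and EPSPs large.  Vector strength is the resultant
length over spikes in the analysis window, with an SD over 10 groups of
10 consecutive trials (regrouped proportionally and flagged when the
trial count is not 100) and an invalid flag below 50 spikes.  The rMTF
and entrainment windows start 250 ms after stimulus onset and end at the
last whole modulation cycle before offset; entrainment counts ISIs in the
closed interval [0.5/f, 1.5/f] per modulation cycle (the raised lower
bound discounts multiple spikes per cycle at low modulation frequencies).
The SAC histograms all across-trial spike-time differences and normalizes
by N(N-1) r^2 dt D so a homogeneous Poisson process is flat at 1; CI is
the zero-lag value and the half-width interpolates the central peak's
crossings of (1 + CI)/2.  Cross-correlograms show presynaptic rates at
lags <= 0 relative to postsynaptic spikes at 0.1 ms resolution, in Hz.
Efficacy is postsynaptic per presynaptic spikes with one input active;
participation is the fraction of postsynaptic spikes preceded in the
(-2.7, -0.5) ms window by a given input's spike; exclusive attribution
credits a spike to the largest in-window input (rank ties go to the
larger terminal).  Efficacy-vs-ASA curves are fitted with a logistic
Emax / (1 + exp(-(ASA - A50)/k)); degenerate data raise an error rather
than returning silent zeros.

## Voxel ASA

The apposed surface area between a terminal and a cell is computed on the
anisotropic label grid (default 11 x 11 x 60 nm): grids are aligned by
integer voxel offsets, doubly-claimed voxels go to the terminal, the
terminal mask is dilated 3 iterations with an in-plane 4-connected cross
and then 3 iterations with a 6-connected 3-D cross (both radii
configurable), the overlap with the cell is meshed by marching cubes with
spacing-aware coordinates, and the mesh area is halved.  The estimator's
error has two understood components: a rim term proportional to the
contact perimeter times the dilation reach (about 0.6/side for a square
patch of side s um, i.e. ~10% at endbulb scales of 25 um^2 and above, but
~60% for sub-um^2 patches), and a z-staircase inflation on gently curved,
near-horizontal surfaces at the 60 nm section spacing.  The phantom tests
therefore validate accuracy at endbulb-scale flat patches and steep
spherical caps, and use small patches only for topology checks
(zero-contact, translation invariance, monotonicity).  NRRD (raw/gzip)
and multi-page TIFF label volumes are supported.

## Synthetic test bed

Toy cells are built analytically from a template: soma as an equal
length/diameter cylinder (area pi d^2, the same as the equivalent
sphere), a tapered 2.3 um hillock, a thin AIS (14.2-21.4 um range), a
myelinated section, and one proximal dendrite leading to a primary hub
with 2-14 shaft branches interrupted by swellings.  Dendritic membrane is
partitioned as shafts 58%, swellings 28%, hubs 10%, proximal 4% of the
total (the measured compartment shares), and radii are solved so the
per-tag areas match the template exactly.  Population sampling draws soma
area from N(1352, 168.1^2) um^2 and the dendrite/soma ratio from
N(2.76, 0.24^2).  Endbulb profiles draw 5-12 ASAs from a log-normal
(median 80 um^2, sigma 0.55) truncated below 35 um^2 — the terminal-size
threshold at the minimum of the observed size histogram — with the
largest input forced above (mixed mode) or below (coincidence mode)
180 um^2.  Control spike trains (Poisson, periodic, von Mises-jittered,
dead-time Poisson) provide closed-form oracles for the metrics.

What passing tests show: the geometry, integrator, synapse statistics,
calibration loop and metrics implement their contracts to the stated
tolerances on cells with realistic areas and conductances.  What they do
not show: agreement with any real reconstructed cell (toy dendrites are
cylinders, not braided trees; innervation is all-somatic), cochlear
realism of the afferent drive, or receptor-level synaptic dynamics.

## Problem sizes and runtimes

Default test problem sizes are chosen for a laptop-class single core: toy
cells discretize to ~100 segments; calibration runs 11 voltage steps of
100 ms at 5 us per iteration (2-3 iterations per scheme); sound-driven
simulations in the test suite use 300-500 ms stimuli and a handful of
trials; phantom volumes are a few million voxels.  The full experiment
protocols accept the larger sizes (1 s stimuli, 100 trials, seven
modulation frequencies) as parameters.
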