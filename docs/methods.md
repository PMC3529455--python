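# Methods

## Model

The reduced neuron is a persistent-sodium + potassium spiker extended with
the minimal machinery for a functional calcium-gated afterhyperpolarization
(AHP/SK) current: a high-threshold calcium current (gate `p`, midpoint
−40 mV), intracellular calcium with linear influx and first-order
extrusion (`d[Ca]/dt = −0.0005 I_Ca − 0.04 [Ca]`, time constant 25 ms),
and the AHP gate `z` with a fifth-order Hill dependence on calcium
(half-activation 0.003, τ_z = 10 ms). Units are fixed globally as mV, ms,
μS, nA, nF, in which μS·mV = nA and nA/nF = mV/ms; no conversions appear
at call sites. Gating variables and calcium are hard-clamped to their
valid ranges after every step, since forward Euler at dt = 0.02 ms can
overshoot marginally.

Initial conditions: V₀ = E_leak = −80 mV with the gates at their
steady-state values for V₀ and a residual calcium load of 10⁻⁴. Symmetry
between neurons is broken by the stimulus protocol's jittered onsets
(normal draws, SD 200 ms, negative draws clamped to zero), not by noisy
initial states. `z∞(0) := 0` by continuity.

### Two reinterpreted constants

The quoted constant set does not define a working spiking model; the
package deviates from it in exactly two places, each forced and each
verified by simulation (Euler and RK4, several step sizes, many initial
conditions):

1. **Persistent-Na activation slope.** Read as 14.5·ln(5/3) ≈ 7.41 mV.
   Under the alternative reading 14.5/ln(5/3) ≈ 28.4 mV the persistent
   sodium current is 13% activated at −80 mV; the neuron then has no
   resting state, fires at most one spike from any initial condition and
   settles into a globally attracting depolarized equilibrium near
   −27.6 mV at every input level. With 7.41 mV the model rests at
   −79.6 mV and has a rheobase of ≈6.4 nA. A regression test
   (`test_as_printed_slope_reaches_depolarization_block`) documents the
   rejected variant, and the slope is a `ModelParams` field.

2. **Stimulus current scale.** Stimulus amplitudes are quoted on a scale
   100× below the nA of the voltage equation
   (`StimulusProtocol.amplitude_scale = 100`). The μS/nF membrane is
   internally consistent — the calcium-influx factor produces ≈0.003 Ca
   per spike from the several-nA spike calcium current, exactly the AHP
   half-activation, and τ_V ≈ 0.1 ms ≪ τ_n = 3 ms as spike generation
   requires — but it implies a ≈6.4 nA rheobase, which quoted drives of
   0.08–0.1 could never reach. Scaling the conductances down instead
   makes the membrane slower than its gates (only subthreshold
   calcium oscillations remain) and breaks the calcium calibration.
   With the gain of 100 the quoted working drives land precisely in the
   model's narrow tonic-firing window (7.5–11 nA), just above rheobase —
   where a near-threshold pattern generator must sit.

At the working point the single neuron fires at ≈9.3 Hz nearly
independently of drive: the rate is paced by the AHP relaxation clock
(calcium extrusion at 0.04/ms plus τ_z = 10 ms give a ~103 ms cycle),
not by the current.

## Calibration of the coupling axis

With τ_V ≈ 0.1 ms, presynaptic spikes cross gap junctions almost
unattenuated (steady-state transfer ≈ g_gap·degree / g_membrane). At the
quoted g_gap = 0.003 μS a bursting group delivers a collective spikelet
of ~16 mV to the opposite group, recruiting it: the network fully
synchronizes into one group (all seeds). The two-group band of the
reconstruction sits at g_gap ≈ 0.0008–0.0014 μS, about 3× below the
quoted coupling — the expected shift for a membrane that low-passes
spikelets ~3–10× less than a slower intended one. The package therefore
distinguishes:

* the **quoted defaults** (`experiments.DEFAULTS`, g_gap 0.003 μS), used
  wherever the original operating point is stated, and
* the **calibrated two-group point** (`experiments.TWO_GROUP_POINT`,
  I = 0.1, g_gap = 0.0012 μS), used by experiments that need a two-group
  initial state (ramp, topology, connectivity-radius map).

Supporting the calibration, the *measured* average total gap current
(time- and population-average of Σ_j g|V_i − V_j|) at the calibrated
points reproduces the analytic cutoff windows: ≈0.092 nA where three
groups form (window 0.09–0.1 nA) and ≈0.13–0.15 nA where two form
(window 0.1–0.3 nA). Under full synchrony the measurable differentials
collapse, which is why the one-group regime is placed by the nominal
(fixed-dV) current instead.

## Firing-group census

1. Average the voltage traces across neurons; smooth with six passes of a
   centered 4 ms boxcar; keep both the mV signal and a min-subtracted
   [0, 1] normalization.
2. **No-group rule:** 0 groups if the smoothed mV signal swings less than
   3 mV peak-to-trough within the analysis window (out of the ~21 mV a
   fully aligned population can produce; the window minimum serves as the
   signal's own baseline — an absolute or pre-stimulus baseline would be
   crossed by the DC shift of any tonically active but unaligned run).
3. Peaks: local maxima of the normalized signal with height and
   prominence ≥ 0.06 (the "6% of the total signal" filter for spurious
   optima).
4. Period: overlap-normalized autocorrelation, lags 8 ms to a third of
   the window, parabolic refinement; near-ties (0.5%) resolve to the
   shortest lag. Peaks without an autocorrelation maximum ≥ 0.5 mean
   "ungrouped" (rhythmic runs score > 0.9, asynchronous shot noise
   < 0.35).
5. Group count: distinct peak phases per period, clustered with a
   circular gap tolerance of 10% of the period; clusters need ≥ 2 member
   peaks. If folding the period by 2, 3 or 4 merges the clusters into
   sets whose peak heights agree within 0.10 of the normalized range, the
   shorter period wins — this removes spurious period multiples while
   genuinely distinct groups (one always better aligned) survive.
6. Frequency: 1/period is reported as the per-group burst rate (each
   group bursts once per fundamental period); the composite rate is
   n_groups/period.
7. Assignment: spike phases within the period (origin at the deepest
   trough of the smoothed signal, minimizing wrap-around) are clustered
   with a 1-D Gaussian mixture (EM, 10 restarts, seeded; degenerate fits
   retried with growing covariance floors, then a quantile partition).
   A neuron's label is its majority component; a neuron whose majority
   component differs between the early and late half of the window is
   recorded as a switch event.

The analysis window is the final 60% of the run truncated at the mean
stimulus offset, so neither the onset transient nor the silent tail
contaminates baseline or period. Known limitation: a perfectly symmetric
pair of equal-size, equal-amplitude groups is mathematically
indistinguishable in the summed signal from one group at twice the rate;
the emergent groups are reliably asymmetric, and the synthetic generator
mirrors that.

## Synthetic raster generator

`synthetic_raster` emits stylized recordings for testing the census
without the simulator: groups burst at phase offsets k·T/n_groups with
Gaussian spike-timing jitter, spikes are Gaussian voltage bumps (21 mV
peak over a −80 mV baseline, σ = 2.5 ms) so the 3 mV rule is exercised,
group sizes are unequal by default (weights 1 : 0.75 : 0.5 — the
driver/follower asymmetry), `n_groups = 0` draws homogeneous Poisson
trains, and designated "switcher" neurons defect to another group at a
set time. It emulates phase structure, amplitude asymmetry and timing
jitter; it does not emulate subthreshold coupling artifacts, spikelets,
or amplitude drift, so census performance on it bounds only the
phase-analysis stage, not spike detection on real traces.

## Experiments and problem sizes

Desk-scale defaults keep every experiment in seconds on one core: 100
neurons for 1500 ms at dt = 0.02 ms per run (the compiled kernel
integrates one such run in ~1.5 s); ten seeds for the default-point
census; 5–8 seeds per cell in the current-window map; six seeds of the
3500 ms ramp; a 6×6 (C, R) grid at 2–3 seeds for the connectivity-radius
map. The AHP ramp spans 2400 ms so the merged epoch (a ~0.04 μS slice of
the g_AHP axis) lasts a few bursts; merging is therefore detected at
burst resolution — two consecutive network bursts engaging ≥ 75% of the
population — rather than by the sliding-window census, which cannot
resolve it. In the reconstruction the merged rhythm is followed by
depolarization block (the AHP is also what repolarizes the cell between
cycles), so a completed ramp ends silent; both the merge and the silence
occur in the first fifth of the ramp.

## Numerical choices

Forward Euler at dt = 0.02 ms is the production integrator; classical
RK4 serves as the oracle (spike-time discrepancy < 1 ms over 1500 ms at
the working point, and halving dt moves spike times < 0.5 ms). Gap
currents use same-step voltages; for RK4 they are evaluated at each
stage. Spikes are upward crossings of 0 mV with a 2 ms lockout. Traces
are recorded as float32 (30 MB per default run); state integrates in
float64. The compiled (numba) kernel is checked against a plain-numpy
integrator that drives the reference right-hand side. A non-finite
voltage aborts the run naming the neuron and time.

## Theory-map agreement

The analytic (C, R) phase map is reproduced as
`run_connectivity_radius_sweep`, but its cell-by-cell agreement with the
simulated group counts is poor at the corners in this reconstruction, for
two structural reasons. With identical, noiseless neurons, arbitrarily
weak coupling already phase-clusters the population (there is no frequency
dispersion to fight), so the census reports 2–3 groups where the analytic
current is below the ungrouped cutoff; and at high coupling the summed
junction load silences the network outright where the map says one group.
The analytic treatment is validated instead where it makes a measurable
claim: within the intermediate band the *measured* average total gap
current locates the 3-group and 2-group regimes inside the 0.09–0.1 and
0.1–0.3 nA windows (see the current-window tests).

## Known limitations

* The coupling-axis calibration above means quantitative g_gap values are
  not comparable 1:1 with the quoted ones; qualitative structure (more
  coupling → fewer groups; AHP necessity; current-window mapping) is
  preserved and tested.
* The per-group rate at the working point is 9.7 Hz — at, but just
  below, the 10–30 Hz band usually cited for such rhythms; the composite
  two-group rhythm (19.4 Hz) is mid-band.
* Heterogeneous per-edge conductances, gap-junction rectification and
  plasticity, stochastic channels, and the full hypoglossal-motoneuron
  channel set are out of scope; the membrane model is a plug-in point
  (`ModelParams` + the right-hand side) for richer variants.
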