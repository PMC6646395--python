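# Methods

## Model

Two populations of N = 200 conductance-based point neurons each — the
subthalamic nucleus (STN, excitatory) and the external globus pallidus
(GPe, inhibitory) — sit on a 1-D ring with periodic boundaries.  Each cell
carries membrane potential `v`, intracellular calcium `Ca`, gating
variables `n, h, r` and a synaptic output `s`:

    C_m v' = -I_L - I_K - I_Na - I_T - I_Ca - I_AHP - I_syn + I_app + I_stim
    Ca'    = eps (-I_Ca - I_T - k_Ca Ca)
    X'     = phi_X (X_inf(v) - X) / tau_X(v),          X = n, h, r
    s'     = alpha H_inf(v - theta_g)(1 - s) - beta s

with logistic steady states `X_inf` and voltage-dependent time constants
`tau_X`.  The low-threshold calcium current I_T uses the rectified
`b_inf(r)^2` form for STN and `r` directly for GPe; GPe `tau_r` is a
constant.  Each STN cell excites the GPe cell at its lattice position
(weight 0.4 nS/um^2, reversal 0 mV); each GPe cell inhibits the three
neighboring STN cells `{j-1, j, j+1}` (weight 1.38 nS/um^2, reversal
-100 mV).  STN bias currents are Gaussian over cells (mean 10 pA/um^2) and
GPe calcium rates `eps` are Gaussian (mean 0.0055 ms^-1); both vectors are
drawn once per network seed.

The raw LFP is the STN-population mean of `s`.  It is filtered online by a
resonant damped oscillator `u'' + a_d u' + w^2 u = k_f LFP` with
`a_d = k_f = 0.008` and `w = 2*pi/T`; the output `x = u'` has zero phase
shift and unit gain at resonance.  The default resonance period is the
mean period of the stimulation-free LFP; `stngpe calibrate-filter`
re-estimates it from a run (the default network oscillates at 95.7 ms).

## Stimulation

The carrier is a 130 Hz train of asymmetric charge-balanced biphasic
pulses: first phase width PW = 0.2 ms at relative amplitude -10, an
optional interphase gap GW, then a recharging phase of width 10 PW at
amplitude +1.  The gap may not exceed 1000/F - 11 PW = 5.49 ms if charge
balance is to hold; beyond 1000/F - PW = 7.49 ms the pulse is monophasic.
The amplitude factor is frozen at each pulse onset.  Four controllers
modulate that factor: constant K (cDBS), constant K gated on/off (aDBS),
the linear delayed-feedback signal `S(t) = K (x(t - tau) - x(t))` (cpLDF),
and the gated version of the latter (apLDF).  The gate is evaluated only
at local maxima of `x` (online sign change of the discrete derivative):
off -> on above `Th_on`, on -> off below `Th_off`.  The gate is on when
stimulation begins; intensity ramps linearly over `T_ramp` in [0, 2000] ms.
Protocol averages rerun the simulation for evenly spaced ramp intervals
with distinct initial-condition seeds.  Only STN cells receive `I_stim`.

## Observables

Spikes are upward crossings of -10 mV with a 2 ms lockout; burst onsets
are spikes following a gap of more than 25 ms.  Each neuron's phase
increases by 2*pi per inter-onset interval, piecewise linearly; the order
parameter R(t) is the modulus of the population-mean unit phasor, with
neurons excluded at times outside their onset range.  T_on is the gate's
on-fraction over the analysis window, and <|S|> the time average of the
absolute modulation signal (S = K while on for the DBS modes), so that
<|S|> = K*T_on holds exactly for aDBS.  LFP bursts are detected on the
R(t) trace smoothed by a centered 400 ms moving average stepped at 10 ms,
with dual thresholds at the 75th/65th percentiles over the analysis
window (linear-interpolation percentiles); bursts touching a window edge
are discarded.  Burst-length distributions are compared with a two-sided
Mann-Whitney U test (exact permutation enumeration available for small
samples), appropriate for their right-skewed shape.

## Numerics

All 2N cells plus synapses advance with classical fixed-step RK4 at
dt = 0.05 ms; the linear filter uses its exact per-step propagator
(unconditionally stable); the delay is a ring-buffer lookup of
`round(tau/dt)` samples.  The waveform is evaluated analytically at every
RK substage time; a new pulse's frozen amplitude takes effect at the first
grid point at or after its onset (error at most dt).  The default step
resolves the 0.2 ms cathodic phase with 4 substeps; a dt-halving test at
reduced scale bounds the step-size sensitivity of post-transient mean R by
the seed-to-seed spread.  Divergence (any |v| beyond 10^4 mV) aborts with
a diagnostic.  Runs are bitwise reproducible for a fixed pair of seeds
(network heterogeneity seed, initial-condition seed).

## Calibration of unpublished constants

The cell-level constant set of this model family is published only in
supplementary material that is not part of the sources available to this
package; the defaults here therefore follow the published Terman-Rubin
subthalamopallidal constants wherever the lineage fixes them, and the
remaining degrees of freedom were fixed once by calibrating the
stimulation-free coupled network to its documented operating point —
strong in-phase ~10 Hz synchronized bursting with large-amplitude LFP
oscillation — before any stimulated condition was evaluated:

* GPe bias current I_app = -2 pA/um^2: GPe cells are silent without
  subthalamic drive and fire phasically when driven, which closes the
  pacemaker loop (STN burst -> GPe burst -> slow inhibition -> synchronized
  rebound).
* GPe->STN synaptic decay beta = 0.02 ms^-1 (50 ms): slow inhibitory decay
  is what stabilizes the in-phase rhythm; with the fast published decay the
  network settles into fast asynchronous or clustered states (a known
  property of pulse-coupled oscillators — slow inhibition synchronizes).
  This value also sets the collective period, 95.7 ms at the default point.
* Heterogeneity spreads 0.075 pA/um^2 (STN I_app) and 1e-4 ms^-1 (GPe eps):
  five times the nominal sub-percent spreads.  With the nominal spreads the
  synchronized state is a rigid, essentially noiseless lock (R > 0.99) that
  a spatially uniform stimulation current cannot perturb — every cell sits
  at the same phase and receives the same input, so no mode of the
  stimulation can grow a phase difference.  The enlarged (still small,
  0.75%) spread restores the finite phase dispersion that makes the
  baseline fluctuate and renders it desynchronizable, which is a
  precondition for every closed-loop experiment the package exists to run.
* Initial conditions: the default run starts inside the basin of the
  synchronized bursting attractor (common hyperpolarized state, T-current
  deinactivated, small voltage jitter), i.e. with the pathological rhythm
  established, as the stimulation protocols presuppose.  A
  uniformly-random-phase initialization is available (`ic_mode: uniform`);
  from it the network relaxes into an asynchronous state instead — in this
  parameterization the synchronized state is locally, not globally,
  attracting.  At the calibrated heterogeneity the synchronized state is
  moreover metastable: its lifetime is seed-dependent and of the order of
  tens of seconds (some heterogeneity draws hold it beyond 60 s, others
  lose it near 30-40 s), which is why the standard analysis windows end
  within ~30 s of the start.

## What the desk-scale defaults do and do not show

At the calibrated point the package reproduces, from scratch: the
~10 Hz stimulation-free rhythm (95.7 ms period) with strong synchrony and
filtered-LFP maxima near 0.042 (so the clinical thresholds 0.016/0.008
partition the operating range); desynchronization by (adaptive or
continuous) high-frequency DBS above an intensity threshold — with the
standard ramped onset, K = 2 with a 2 ms interphase gap collapses the
rhythm (post-transient R near 0.1) while K = 1.2 is subthreshold; and the
gap-dependence of that threshold (abrupt-onset runs desynchronize at
K = 1.2 with the 2 ms gap but not without it).  Known quantitative
departures from the reference behavior, all traceable to the unavailable
constant set, are: baseline synchrony saturates near R = 0.97 rather than
fluctuating around 0.8; the intensity axis is shifted (the therapeutic
boundary sits ~1.5x higher than reported); the pulsatile delayed-feedback
modes do not desynchronize at any tested gain (up to K = 40 the feedback
signal instead entrains the rhythm), so their operating points are not
reached; and — most consequentially — the asynchronous state is
absorbing, so after the adaptive gate switches off the network does not
resynchronize within the run and the on-off cycling of adaptive
stimulation terminates after its first epoch rather than repeating
(stimulation-time fractions are therefore near 0 or 1, never the
intermediate duty cycles of sustained cycling).  The acceptance suite
reports these honestly rather than tuning toward them.

## Desk-scale problem sizes

Acceptance-style computations use the full 200+200 network with run
lengths of 16-24 s, stimulation onset at 4.5 s, a 3.5 s post-onset
transient skip, and 3 ramp intervals per protocol average (the full
protocol uses 10-20); the delayed-feedback efficiency scan samples gains
{10, 20, 40}.  The test suite uses 20-cell rings for invariant checks and
12-32 s full-size runs for the operating-point checks.
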