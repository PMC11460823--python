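# Methods

## The model

`arousalnet` implements a recurrent network of leaky integrate-and-fire
neurons representing a local auditory-cortical circuit, together with the
statistics used to characterize its metastable dynamics and stimulus coding,
and a mean-field theory of its attractor structure.

Membrane potentials follow

    tau_m dV/dt = -V + tau_m (I_rec + I_bg + I_stim),

with threshold/reset spiking and an absolute refractory period. Recurrent
input arrives through exponential synapses (`tau_syn`): a presynaptic spike
adds `J/tau_syn` to the postsynaptic current, so each spike delivers a total
voltage charge `J`. Background input is an independent Poisson stream per
cell with aggregate rate `C_ext * nu_ext`; sensory stimuli add a
deterministic current with a peak-normalized difference-of-exponentials
timecourse to the targeted excitatory cells.

Two architectures are built from the same in-degree budget: a **uniform**
network (every type-a cell receives exactly `C_ab = p_ab N_b` type-b inputs
of weight `J_ab`) and a **clustered** network in which E and I cells are
grouped into `p` assemblies. Within-cluster weights are potentiated
(`J+_ab`), between-cluster and cluster/background weights depressed to the
unique value `J-_ab` that leaves the total summed synaptic weight equal to
the uniform network's. Per-class in-degree counts are rounded with a
largest-remainder rule so every cell's total in-degree equals `C_ab` exactly;
when the subgroup counts are integral (as in the shipped configs) the weight
sum is conserved to machine precision, otherwise to O(1/C).

**Arousal** enters as a modulation of the background input rates: a uniform
shift (`nu_ext = nu_o (1 + dM)`, "mean" kind) or a quenched Gaussian spread
(`nu_ext = nu_o (1 + z dH)`, truncated at zero, "heterogeneity" kind).
Heterogeneity draws one z per within-cluster cell slot and reuses it across
clusters, so every assembly receives the same realization of the input
distribution; background cells draw independently. z is fixed per network
realization (quenched disorder).

## Integration

The subthreshold dynamics are linear, so each time step advances the
membrane and synaptic state with exact exponential propagators
(unconditionally stable); threshold crossings are detected on the grid and
spike times forced to the grid. The refractory clamp makes double crossings
within a step impossible. Background Poisson input is realized as a per-cell
event stream (the superposition of the independent external synapses is
itself Poisson) injected into the excitatory synaptic variable. Default step
0.05 ms; the sweep workflows use 0.1 ms, at which halving the step changes
population rates by well under 2% (asserted in the test suite). Initial
voltages are drawn uniformly in `[V_r, V_thresh)` per trial.

## Mean-field theory

Each of the `2(p+1)` populations is described by a stationary rate solving
`nu = Phi(mu(nu), sigma(nu))`, where mu and sigma^2 are linear in the rates
with coefficients given by the clustered connectivity, and Phi is the
first-passage rate of an LIF neuron driven by white noise, with integration
bounds shifted by `a*sqrt(tau_s/tau_m)`, `a = -zeta(1/2)/2`, to first order
in the synaptic correlation time. The integrand `exp(x^2) erfc(-x)` is
evaluated in a numerically stable split form (scaled complementary error
function on each half-axis plus an `erfi` antiderivative for the divergent
part), so the solver is robust out to `|q| > 25`, beyond which the rate is
indistinguishable from zero.

Solutions with `nA` active clusters are found by seeding a damped
fixed-point iteration (adaptive step, hybrid-Powell fallback; tolerance
1e-10 on rates) with the first `nA` E and I cluster rates high (50 spikes/s)
and the rest low (2 spikes/s).

Under the heterogeneity modulation the mean input varies across cells within
a population. The quenched theory parameterizes a cell's rate by its
disorder variable z, closes the system on the population mean `nu_bar` and
spatial variance `s^2` of the rates (Gauss-Hermite quadrature, 60 nodes;
40 vs 80 nodes agree to 1e-8), and neglects spatial heterogeneity of the
noise amplitude sigma, as is standard. At `dH = 0` it reduces exactly to the
homogeneous theory.

**Effective 2-cluster theory.** A reduced network (two 80-cell E clusters,
background E and I populations, no inter-cluster depression) is analyzed by
freezing the two cluster rates, adapting the background ("ambient") rates
self-consistently, and reading out the induced cluster rates. Fixed points
of this 2D map are the reduced network's attractors; integrating the flow
along the piecewise-linear path well -> saddle -> well yields a 1D potential
whose barrier height h controls switching. Under `dH > 0` the rate-variance
terms are dropped (they have little effect on the population means). The
path is the straight two-segment polyline rather than the unstable manifold;
this affects h's absolute value, so only h's trend across dH is treated as
comparable across analyses. h is reported relative to the mean of the two
well depths.

## Analysis conventions

* **Cluster rates**: member-averaged, Gaussian-kernel-smoothed (sigma =
  25 ms) rates on a 1 ms grid; a cluster is *active* when its rate is at
  least 15 spikes/s. P(nA), conditioned active/inactive rates, and the mean
  activation-period duration are computed in the window [-0.8, -0.1] s
  before stimulus onset; window-clipped activation periods contribute their
  truncated duration (a bias of order window/timescale, identical across
  conditions).
* **Decoding**: spike counts in 100 ms windows stepped by 20 ms over
  [-0.1, 0.6] s around onset; multiclass LDA (shared covariance, SVD
  solver) with repeated stratified 5-fold cross-validation after balancing
  trials per stimulus; peak accuracy over windows (earliest window on ties).
  Model decoding samples one E cell per cluster plus one background E cell
  (p+1 features) and averages over independent cell samples. The shuffle
  null permutes labels with one stratified 80/20 split per shuffle.
* **Discriminability**: d' per cell, window, and stimulus pair with the
  pooled standard deviation `sqrt((s_a^2+s_b^2)/2)`; the magnitude is used
  (pair order is arbitrary), pairs with zero pooled variance are dropped
  from the pair average; Dsc' is the max over windows of the cell-averaged
  timecourse.
* **Evoked cluster metrics**: cluster signal Cs (targeted minus
  non-targeted mean rate in the peak decoding window) and reliability Cr
  (difference of the fractions of clusters activated >= 1 spike/s above
  their pre-stimulus baseline for at least 25 ms in that window).
* **Spectra**: multitaper point-process spectra on 1 ms-binned trains
  (TW = 5, 9 DPSS tapers, unity weights), mean-subtracted per trial
  (removing the rate line at f = 0), normalized by the trial's mean rate so
  a Poisson process has unit power; low-frequency power is the grid average
  over 1-4 Hz, endpoints inclusive, grid resolution 1/T.
* **Fano factors**: variance/mean of spike counts across trials in 100 ms
  windows (20 ms steps in the model); spontaneous value from the window
  immediately before onset, evoked value at the minimum of the
  population-averaged timecourse within 200 ms after onset.
* **Pupil-side pipeline**: jump artifacts (normalized diameter change
  > 0.08 between consecutive 1 ms samples) masked over [-250, +500] ms;
  moving-average smoothing over 1/30 s; renormalization to % of maximum.
  Unit QC combines a 0.25 spikes/s rate floor with kernel-density peak
  analysis of template amplitudes in 5-minute windows (Scott's-rule
  bandwidth): multimodality (peak-height ratio <= 10, location separation
  >= 40%) in >= 10% of windows, or noise-floor drift (> 10% but not all
  windows near the floor and peak-location range >= 25%), rejects the unit.
  Tone responsiveness uses Mann-Whitney tests of 1 ms-stepped 100 ms evoked
  windows against pooled baseline windows, Bonferroni-corrected, requiring
  >= 5 ms of consecutive significance.

## Default parameters and calibration

The parameter values that define the study conditions (p = 18 clusters,
f = 0.05 of each population per cluster, intracluster E-to-E coupling factor
15.75, activation threshold 15 spikes/s, heterogeneity range dH in
[0, 0.4], five stimuli targeting 50% of clusters / 50% of their E cells,
trial structure and analysis windows) are fixed in the shipped configs.
The remaining magnitudes (weights, external drive) are package choices,
calibrated once with the package's own mean-field theory so that the
unmodulated clustered network is metastable and the heterogeneity
modulation degrades cluster states gradually across the studied range:

* `default.yaml` — full-size network (1600 E + 400 I). The external drive to
  E cells is sparse and strong (80 synapses of weight 5.6/sqrt(N) at 7
  spikes/s) so its mean is moderate relative to threshold — this makes the
  quenched disorder (whose spread is `dH` times the external mean) a graded
  rather than catastrophic perturbation — while I cells receive a dense
  external drive. Within-cluster inhibitory pathways are potentiated
  (factor 5) so each active E cluster recruits its own I cluster, capping
  active-cluster rates near 25-35 spikes/s. The theory gives a ~5 spikes/s
  uniform state coexisting with nA = 1..3 cluster states at the default
  coupling, and a quenched transition to a uniform-only regime inside
  [0, 0.4].
* `reduced.yaml` — half-size sweep network (800 E + 200 I) with p = 9
  clusters of f = 0.1, keeping the full-size cluster size (80 E cells),
  because smaller clusters switch too quickly for any modulation trend to
  be resolved. Weight magnitudes scale by sqrt(2) to preserve the composite
  couplings C*J. The weight-conservation constraint bounds the coupling
  factor below 11 for this geometry; the default is 9.5, at which the
  unmodulated network shows cluster activations of roughly 100 ms that
  shorten and disappear gradually across the dH grid.
* Stimulus amplitude `A_stim = 0.07` (7% of the baseline external drive):
  strong enough that intermediate-heterogeneity networks encode the five
  stimuli well above chance, weak enough not to override the attractor
  dynamics of the unmodulated network.

## What the synthetic sessions emulate

`session.generate_session` produces alternating spontaneous/evoked blocks,
25 ms tones at 775 ms inter-stimulus intervals from five frequencies, a slow
mean-reverting pupil trace (OU process with dilation events at 30 Hz,
upsampled to 1 ms), treadmill-speed bouts, doubly-stochastic Poisson
spiking whose spontaneous and evoked rates depend on pupil through per-unit
gain curves (monotone up/down, inverted-U, flat), per-spike template
amplitudes, and optional injected defects (pupil jump artifacts, bimodal or
drifting amplitudes). It emulates the statistical features the analyses
consume — not waveforms, tonotopy, or realistic tuning-curve shapes — so
passing recovery tests demonstrates that the pipeline extracts the
programmed pupil dependence, not that it would handle every pathology of
real recordings.

## Problem sizes used in the shipped checks

The acceptance workflow sweeps dH over {0, 0.1, 0.2, 0.3, 0.4} with three
network realizations, 15 trials per stimulus (1.7 s trials, onset at 1 s,
0.1 ms step), ten decoding cell-samples with three cross-validation
repeats, and ten 2.5 s spontaneous trials per condition for the spectra;
the transfer-function oracle uses 150 s single-neuron simulations on a 5x5
input grid chosen in the near-threshold noise-driven regime. These sizes
are scaled-down versions of the full study conditions (30 trials, 10-25
realizations, 3.5 s trials); trends are therefore noisier than in the
full-size study and are summarized by rank correlations across the grid.

## Known limitations

* At the reduced sweep sizes (three realizations, 15 trials/stimulus) the
  left edge of the decoding inverted-U — the difference between accuracy at
  zero heterogeneity and at the interior optimum — is comparable to
  realization-to-realization sampling noise, so individual sweep runs can
  show a monotone-decreasing curve; the collapse of accuracy at strong
  heterogeneity is robust in every run. Resolving the left edge reliably
  requires the full-size study conditions (10 realizations, 30 trials).

* The first-order synaptic correction to the transfer function loses
  accuracy deep in the subthreshold regime (relative errors can exceed 10%
  for strongly fluctuation-driven, very-low-rate inputs); the oracle
  comparison grid avoids that corner.
* The reduced sweep network's coupling factor (9.5) is not the full-size
  value (15.75): the conservation constraint makes the two geometries
  non-interchangeable, so absolute rates and timescales are comparable only
  within a configuration.
* The mean-field coupling-matching procedure is implemented and tested, but
  with the package's calibrated parameters the simulated active-cluster
  rate at the default coupling lies below the theory's, so the matched
  coupling lands below (not above) the simulation value; the direction of
  this offset depends on parameter details that are not constrained here.
* Amplitude-QC cut values are tuned to the injected defect families of the
  synthetic sessions; real spike-sorting artifacts are more diverse.
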