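# Methods

This note documents the model implemented by `bisnn`, the parameter
defaults and why they were chosen, the synthetic data the package is tested
on, and the numerical and design decisions a user should know before
trusting — or changing — the defaults.

## Spike codec

A channel is encoded by thresholding its absolute successive differences:
with d(t) = |x(t) − x(t−1)|, the channel threshold is
th = mean(d) + c·std(d).  Conventions:

- `std` is the population (divide-by-count) standard deviation, so
  thresholds are bit-reproducible across implementations.
- The comparison is inclusive (`d ≥ th`); a constant channel has th = 0 and
  encodes to an empty train rather than spiking on every sample.
- A spike at sample index t is timestamped t/sample_rate with the time
  origin at the first sample; the first possible spike is at index 1.
  Encoding at sample t uses only samples ≤ t, so the encoder can run on a
  stream.
- Polarity (the sign of x(t) − x(t−1)) is stored per spike.  The supervised
  stage consumes the unsigned view — a SPAN cannot be trained on mixed
  positive and negative spikes — while decoding uses the signs:
  x̂(t) = x̂(t−1) + sign·th, anchored at the stored initial value.  For
  unsigned predicted trains the caller must opt into a constant-sign policy
  per channel ("positive" for rectified, non-negative targets such as EMG
  envelopes; "negative" exists for completeness).  How a signed trajectory
  should be decoded from unsigned predicted spikes is a genuine ambiguity
  of the architecture; the model stores the majority sign of each target's
  training spikes as that target's decoding sign.

The default encoding factor is c = 0.5 for input channels.  For the smooth
synthetic target envelopes the decoder uses c = 2.5: at c = 0.5 a single
trial's envelope encodes to ~50 spikes on consecutive samples, a desired
train no spiking neuron with a fire-and-reset output can reproduce, whereas
c = 2.5 keeps the desired trains at ~10–15 spikes concentrated on the steep
rise and fall.  Both factors are per-channel configurable.

## Reservoir

Neurons sit on a regular 15 mm grid inside an ellipsoid with semi-axes
(60, 80, 50) mm (x right, y anterior, z superior), 293 neurons by default.
Each neuron is labelled with one of 16 simplified regions — octant
(L/R × A/P × S/I) by depth shell (normalised radius below/above 0.6) — as a
deterministic stand-in for an anatomical atlas; a user CSV with custom
coordinates and region labels can replace the packaged template for
atlas-faithful runs.  A packaged 32-channel 10-20-style montage is provided;
channels map to their nearest free template neuron in lexicographic label
order, which makes the mapping injective and deterministic under
collisions.

Synapses: every ordered pair within radius r = 0.25 × (max pairwise
distance) connects with probability p(d) = 0.8·e^(−d/r); weight magnitudes
are Uniform(0, 8)/d (d in mm).  25 % of presynaptic neurons, seeded, are
inhibitory: their outgoing weights are negated and scaled ×4.

The inhibition-dominated wiring is the one reservoir decision that departs
from the obvious default, and it matters.  With weak, balanced inhibition
the recurrent dynamics are effectively bistable: either input activity dies
within one synaptic hop (a dozen active neurons) or the network ignites
into self-sustained firing at the refractory ceiling, and the boundary
between the two moves with every seed.  Strong inhibition widens the stable
corridor: activity spreads through 100–250 neurons during stimulation and
collapses within tens of milliseconds of stimulus offset, across network
and data seeds.  A stimulus-driven reservoir is what a decoder needs —
inter-trial background firing would feed the readout noise.

LIF dynamics: exponential membrane leak with τ_m = 15 ms, firing threshold
0.5 (weight units), reset to 0, absolute refractory 10 ms (one tick at
100 Hz).  τ_m was raised from the naive one-tick value because a 10 ms
membrane at a 10 ms sample interval leaves essentially no coincidence
window.  Spikes propagate with a one-tick synaptic delay.  Input-mapped
neurons relay encoder spikes 1:1 (a convention, documented rather than
derivable: input drive is not attenuated by leak, and whether input neurons
also integrate recurrent input is immaterial because the relay overrides
the threshold test on input ticks).

STDP: the learning window is W(x) = A₊e^(−x/τ₊) for x > 0 and
−A₋e^(x/τ₋) for x < 0, with A₊ = A₋ = 0.01 and τ₊ = τ₋ = 20 ms; W(0) := 0,
since simultaneous spikes carry no causal information and the window is
otherwise undefined at zero.  The online rule is fire-triggered: weights
change only when a neuron emits a spike, never on spike receipt.  At a fire
event of neuron j at time t, each existing incoming synapse i→j gains
W(t − last_spike(i)) and each outgoing synapse j→k gains
W(last_spike(k) − t) — nearest (most recent) counterpart spike only.  The
all-pairs double sum over two whole trains is exposed separately
(`stdp_total_update`) and is cross-checked against a brute-force loop in
the tests; the per-event magnitude of the online rule is not uniquely
determined by its verbal description, and the nearest-spike choice is ours.
Weights are clipped to [−1, 1].

The unsupervised pass runs once, on the training session only.  The raster
handed to the supervised stage is then **regenerated by a second, frozen
pass** over the same session: supervised learning must see the response of
the same dynamical system that prediction will run, not the transient
emitted while STDP was still reshaping the weights.  (Without this, members
train on clusters that are active mid-learning but silent in the final
network.)  Continual STDP during prediction is available behind a flag, off
by default.

## SPAN neurons

The alpha kernel α(t) = e·τ_s⁻¹·t·e^(−t/τ_s)Θ(t) peaks at exactly 1 at
t = τ_s.  A SPAN's current is the weighted sum of its afferents' convolved
trains; it fires wherever the current reaches th_m.  As written, a
threshold rule fires on every supra-threshold grid point; the default
firing mode adds hysteresis — one spike per upward crossing, silent until
the current falls back below threshold — because a burst of grid-aligned
spikes is not something the learning rule can represent.  The raw
comparator mode remains available (`reset=False`) for oracle tests.

The delta rule update per afferent is

Δw = λ(e/τ²)[Σ_{g,f}(|t_i^f−t_d^g|+τ)e^(−|t_i^f−t_d^g|/τ)
            − Σ_{h,f}(|t_i^f−t_out^h|+τ)e^(−|t_i^f−t_out^h|/τ)],

potentiating toward desired spike times and depressing emitted ones.  When
t_out = t_d the sums cancel term-by-term and the update is exactly zero
(floating-point exact, not approximately — the two sums are the same
computation on the same numbers).

Training runs up to `max_epochs` rounds of current → fire → update,
stopping early when the emitted train matches the desired train: equal
spike counts and sorted-pairwise gaps within ±`match_tolerance` (default
20 ms = 2 ticks).  For points on a line, sorted pairing is the optimal
one-to-one matching, so this is the exact bipartite criterion.
Non-convergence is not an error; the neuron keeps its `trained=False` flag
and the per-epoch van-Rossum-style error trace (L2 distance of the alpha
traces) is returned.  Weights initialise as small positive uniform values,
Uniform(0, 0.1), seeded.

Decoder-context defaults: τ_s = 50 ms, λ = 0.05, τ = 100 ms, th_m = 1,
50 epochs.  These sit on the time scale of the reservoir burst structure
(tens of ms between related spikes) and were chosen so that weight growth
reaches threshold within the epoch budget on cluster-sized afferent sets.

### The single-afferent limit

A SPAN has one weight per afferent.  With a *single* afferent the weight is
a pure gain: the output spike time is the threshold-crossing time of a
fixed trace and can only be steered along that trace's rising flank.  Two
consequences, verified numerically and worth stating because the
single-afferent single-desired-spike task is a natural benchmark:

- Causality bounds success.  If the afferent train has no spike before the
  desired time, no causal neuron can fire there.  For a 10 Hz Poisson
  afferent over 500 ms and a desired spike at 250 ms (±20 ms), ~10 % of
  draws are infeasible for any parameter setting.
- The delta rule has spurious equilibria.  With a shared weight the update
  reduces to Δw ∝ G(t_d) − G(t_out), where G(s) is the proximity of s to
  the afferent spikes under the learning kernel.  The crossing time sweeps
  monotonically as w grows and genuinely decelerates into t_d when
  G(t_out) > G elsewhere on the path — but it stalls wherever
  G(t_out) = G(t_d) with t_out still far from the target, which happens
  when the afferent spikes cluster away from the desired time.

In the regime where the task is solvable at all — the synaptic kernel
spanning the association window (τ_s ≈ 300 ms for a 500 ms pattern),
τ = 200 ms, λ = 2, th_m = 0.5 — the rule converges in roughly half of
random draws within 100 epochs; parameter scans plateau there, well short
of the ~90 % causal ceiling.  Timed output control is an ensemble property:
with cluster-sized afferent sets (the decoder's operating regime) the
weights shape the current profile jointly and training behaves far better.
The acceptance suite keeps a strict ≥90 % single-afferent convergence test;
it fails at the documented rate and is retained as an honest record of this
architectural limit.

## Evolving output layer

One population per target signal.  Per training trial and target, if some
already-trained member reproduces the trial's desired train (match
criterion above), nothing is spawned; otherwise one new SPAN is spawned,
wired to **all neurons of one anatomical cluster**, trained on the trial,
and appended regardless of convergence.  Clusters are taken round-robin per
population, in descending order of their spike count in the training
raster (ties broken by label): populations progressively cover regions,
informative ones first.  The ordering is deterministic given the data and
is stored in the model.

After the supervised pass every member is validated across the training
trials: accuracy = fraction of trials whose output matches the desired
train.  Members with accuracy ≥ κ·(population maximum), κ = 0.8 by
default, keep readout weight equal to their accuracy; the rest are
silenced (weight 0) but retained.  With the strict match criterion and
noisy multi-spike desired trains, accuracies of zero are common; a
population with all members silenced simply has a silent readout neuron,
while its population activity trace (the unweighted average of the
members' alpha-convolved output trains) remains informative and is what
the evaluation correlates against targets.

The readout neuron is a memoryless comparator, taken literally from its
definition: Ī_n(t) = (1/m)Σ w_{m,n}·s̃_{m,n}(t) and q_{n,t} = 1 iff
Ī_n(t) ≥ th_n (inclusive), th_n = 0.5.  The member output trains feeding
the readout are convolved with a separate kernel, `activity_tau` = 300 ms:
member firing is sparse (roughly one spike per trial per member), and the
readout/population trace is meant to live on the time scale of the motor
envelopes it predicts, not of individual spikes.  The readout state
sequence is the population's predicted spike train; decoding it with the
codec under the target's sign policy gives the predicted analog signal.

Event labels over a window are decided by the configured strategy — argmax
of the mean readout state (default) or majority voting over spiking
members — with exact ties and all-zero windows mapping to the no-event
label.

Incremental fitting: the reservoir freezes after its single unsupervised
pass, and `extend` continues spawn/validate bookkeeping (and the random
stream) over further trials of the same session, so a split fit reproduces
the single-pass membership exactly.

## Streaming prediction

Prediction advances one sample at a time: causal threshold encoding of the
new sample, one LIF step (plasticity frozen), recursive O(1) alpha-trace
updates for every reservoir neuron and member (two exponential
accumulators per kernel; a spike registered at the current tick contributes
α(0) = 0, exactly as the batch convolution), member threshold tests with
hysteresis, readout comparison, and a wall-clock stamp per tick.  "Batch"
mode runs the identical loop without the timing log, so streaming and batch
outputs are bit-for-bit equal by construction — the equivalence test
guards against any future divergence.  Latency numbers are reported, never
asserted: they are hardware-dependent.

## Evaluation

Lagged cross-correlation: both series are centred and scaled to unit
population variance over the full record; r(k) = (1/n)Σ_t a_z(t)p_z(t+k)
over the overlapping segment at every integer-sample lag within ±100 ms
(10 samples at 100 Hz; a wider window is a parameter).  This normalisation
is one of several defensible readings of "normalised cross-correlation";
it is pinned by an independent shift-and-loop oracle in the tests and is
invariant under positive affine transforms of either signal.  Constant
inputs raise rather than return NaN.  Maxima are binned as high (r ≥ 0.7),
moderate (0.7 > r ≥ 0.5), weak (0.5 > r ≥ 0.3), very weak (r < 0.3),
boundaries inclusive from above.  Targets are smoothed with a 50 ms moving
average before correlation (the rectified-and-smoothed convention for EMG
envelopes; the window is configurable and undocumented upstream).

Connectivity summaries tally, per population and region, the member count
and summed |afferent weight| — the numbers behind region-wiring diagrams —
with a flag to exclude silenced members.

## Synthetic sessions

A session emulates a cued grasp-and-lift experiment at 100 Hz: 20 trials of
2 s separated by 1 s gaps (≈ one minute of training data), onset jitter
±50 ms.  Four latent sources at fixed scalp locations emit event-locked
bursts — a 0.5 s Hanning envelope on a 10–30 Hz carrier, source-specific
onset delays of 0–300 ms, random phase per trial.  Eight input channels sit
near their dominant source on the scalp ellipsoid and record
gain-weighted source mixtures (Gaussian spatial gain, σ = 45 mm) plus white
noise at a linear SNR of 5.  Targets follow onsets causally with ≥100 ms
lag: EMG-like channels are rectified rise–plateau–fall envelopes (rise
~160 ms — brisk, as real grasp EMG is), kinematics-like channels smooth
sigmoid trapezoids (position-like) or wrapped-phase ramps (angle-like,
bounded to ±1).  All draws flow from the single config seed; the noiseless
generating envelopes are kept as ground truth.

What the generator does *not* emulate: volume conduction and realistic
forward models, artifacts, non-stationarity, inter-subject variability,
trial-to-trial amplitude variation of the targets, and correlated noise.
Passing tests therefore show that the pipeline recovers event-locked
structure under controlled conditions — not that it would reach the same
correlations on recorded EEG/EMG.

The trial-shuffled control circularly shifts each target channel by an
independent random offset of at least one trial length, preserving
marginals while breaking input–target alignment.  Because the trial layout
is near-periodic, an individual shift can land near a multiple of the
period and correlate spuriously; controls are therefore summarised by
medians over seeds.

## Problem sizes and runtimes

Defaults were sized for desk-scale experimentation: a 293-neuron reservoir,
~60 s training sessions, ≤20 members per population, 50 training epochs per
member.  A full fit takes ~1–2 s and a 10-trial prediction well under a
second on one CPU core; the complete test suite runs in under a minute and
the acceptance script in a few minutes.  Median per-tick prediction latency
is ~0.1 ms against the 10 ms real-time budget at 100 Hz.

## Known limitations

- Decoded analog signals integrate th-sized steps from unsigned readout
  states; they track event timing well but not amplitude, and a
  constant-sign policy cannot reproduce non-monotonic trajectories within a
  trial.  Correlation-based evaluation uses the population activity trace,
  which is the quantity the architecture actually predicts.
- Single-afferent SPANs cannot reliably place spikes at arbitrary desired
  times (see above); timing control needs multi-afferent populations.
- The reservoir operating point (inhibition-dominated, stimulus-driven) was
  chosen for decoding; studies of self-sustained reservoir dynamics would
  need different wiring constants.
- Alternative encoders (rate- or rank-based) are out of scope; the codec
  interface is the extension point.
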