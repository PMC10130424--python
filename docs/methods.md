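# Methods

`eibalance` simulates the self-organization of multi-group spiking networks
under a locally altered excitation/inhibition (E/I) balance and quantifies the
resulting group-level activity with multiscale entropy and k-nearest-neighbour
information estimators.  This note records the model, the numerical choices,
the desk-scale study conditions, and what the tests do and do not establish.

## Network model

Each neuron group contains `n_E` regular-spiking (RS) excitatory and `n_I`
fast-spiking (FS) inhibitory Izhikevich neurons

    dv/dt = 0.04 v² + 5v + 140 − u + I_syn,      du/dt = a(bv − u),
    v ≥ 30 mV  ⇒  v ← c,  u ← u + d,

with the canonical constants RS (a, b, c, d) = (0.02, 0.2, −65, 8) and FS
(0.1, 0.2, −65, 2).  Synaptic input is conductance based,

    I_syn = g_AMPA(0 − v) + g_NMDA·s/(1+s)·(0 − v) + g_GABA(−70 − v),
    s = ((v + 80)/60)²,

with each channel a linear two-variable cascade (`dx/dt = −x/τ₂`,
`dg/dt = (Kx − g)/τ₁`; x ← x + w on arrival) using (τ₁, τ₂) = (0.5, 2.4) ms
for AMPA, (4, 40) ms for NMDA and (1, 7) ms for GABA.  K normalizes a
unit-weight impulse to unit peak conductance, so synaptic weights read
directly as peak conductances; the gain is exposed on `ChannelKinetics` for
other conventions.  Excitatory arrivals drive AMPA and NMDA with the same
weight; inhibitory arrivals drive GABA.

Connectivity: every excitatory neuron sends 70 synapses to distinct random
neurons of its own group and 30 to random neurons of adjacent groups (pooled
uniformly over the adjacent groups); every inhibitory neuron sends 100
synapses within its group.  Delays are uniform, 2–4 ms (intra-group
excitatory), 4–10 ms (inter-group excitatory) and 1–3 ms (inhibitory),
rounded to the nearest 0.05 ms step (minimum one step).  Excitatory weights
start U(0, 0.04) and are plastic; inhibitory weights are fixed at W_IE
(onto excitatory cells) and W_II = 0.013 (onto inhibitory cells).  The E/I
balance of the single "imbalanced" group is controlled through
N_I ∈ {100, 150, 200, 250, 300} and W_IE ∈ {0.0125, …, 0.0375}
(baseline 200, 0.025).

## Plasticity

Excitatory synapses follow the triplet STDP rule with two presynaptic traces
(r₁, τ₊ = 16.8 ms; r₂, τ_x = 101 ms) incremented at spike *arrival* times
(spike time + conduction delay) and two postsynaptic traces (o₁,
τ₋ = 33.7 ms; o₂, τ_y = 125 ms):

    arrival:    Δw = −o₁(t)[A₂⁻ + A₃⁻ r₂(t − ε)]
    post spike: Δw = +r₁(t)[A₂⁺ + A₃⁺ o₂(t − ε)]

with A₂⁺ = 5·10⁻¹¹, A₂⁻ = 7·10⁻⁴, A₃⁺ = 6.2·10⁻⁴, A₃⁻ = 2.3·10⁻⁵, ε = 1 ms,
and hard bounds [0, 0.04].  Because A₂⁺ is negligible, potentiation is
essentially rate-gated through the triplet term — sparse firing drifts
weights down, sustained firing drives them up — which is the engine of the
self-organization effects studied here.  (A₂⁺ is orders of magnitude below
the other amplitudes; it is used as stated, and the parameter record is a
plain dataclass so other values can be supplied.)

Conventions the equations leave open, fixed here and mirrored exactly by the
test oracles: the slow traces are read *pre-increment* and decayed to t − ε,
clamped so the lookback never rewinds past the trace's last event; at a
coincident post spike and arrival the post spike is processed first; at an
arrival the depression is applied before the (updated) weight is delivered
to the conductance gate; plasticity applies only inside the scheduled STDP
window while traces always evolve.

## Numerical integration

Time step 0.05 ms throughout.  The channel cascades are linear and
independent of v, so they are advanced with their exact exponential
propagator; the (v, u) pair takes one classical RK4 step per time step with
the channel values evaluated at t, t + dt/2 and t + dt.  The reset is checked
once per full step; a spike detected while integrating step s is stamped at
step s + 1, and its arrivals are delivered at step (s + 1) + delay, so
arrival − spike equals the axonal delay exactly.  Membrane potentials above
1000 mV abort the run as a numerical instability (the reset makes this
unreachable in practice).  Excitatory deliveries travel through a pooled
linked-list ring buffer; inhibitory (static-weight) deliveries through a
dense circular accumulator.  All randomness (network sampling, Poisson
inputs) is drawn outside the compiled loop from seeded generators, so runs
are bit-reproducible.

## Stimulation and schedule

Every neuron receives an independent homogeneous background Poisson train at
0.6 Hz with synaptic weight 0.6, generated as per-step Bernoulli thinning
(drawn exactly via geometric inter-spike counts).  During the external-input
window the excitatory neurons of one stimulated group additionally receive
independent inhomogeneous trains with rate 25 sin²(2πt) Hz (t in seconds —
a 1 Hz envelope peaking at 25 Hz) and weight 0.05; the per-step sum of these
external spikes is the reference signal for mutual information.  Background
input continues during the external window.

The production schedule is 1,520 s: plasticity on [5, 1505) s, the
complexity-analysis window [1510, 1515) s, the external-input window
[1515, 1520) s.  Desk-scale runs compress this to 72 s (2 s warm-up, 60 s
plasticity, 5 s analysis, 5 s input) — see below.

## Analysis chain

**LAP.**  Group activity is the local average potential: the per-step mean
membrane potential of the group's excitatory neurons, with spiking cells
contributing the 30 mV threshold value that step (clamping bounds the
within-step overshoot of the quadratic model; the same clamped signal is
used for complexity and information analysis).

**Multiscale entropy.**  The LAP over the analysis window is block-averaged
to 1 ms (5,000 samples), then sample entropy
SampEn = −ln(C₃/C₂) is computed on coarse-grained copies at scales 1..100
with m = 2 and tolerance r = 0.15 × SD of the scale-1 signal, fixed across
scales.  Template matching uses Chebyshev distance, strict inequality, and
excludes self-matches; C_m counts ordered pairs over all N − m + 1 templates
of length m.  A scale with no matching pair is undefined: it is flagged and
excluded from the complexity index (the sum over scales) rather than
replaced by a surrogate value.  At the 5,000-sample geometry, scale 100
leaves 50 samples; the validity flags make high-scale fragility visible.

**Information.**  MI between each group's LAP and the summed external drive,
and TE from the stimulated group's LAP to each other group's, are estimated
with the KSG algorithm-1 estimator and its conditional (Frenzel–Pompe)
extension, k_nn = 4, natural logs.  A seeded uniform jitter of 10⁻¹⁰ × SD
breaks distance ties and makes estimates reproducible.  The target history
spans 7 ms: k_hist = 140 samples at the native 0.05 ms step, or 7 samples at
the 1 ms resampling the desk-scale pipeline uses (series are block-averaged
to 1 ms; drive counts block-summed).  The full-resolution geometry is
supported but is a production setting: estimator correctness is instead
established on closed-form ground truths (Gaussian MI, linear-AR TE).

## Desk-scale study conditions

Group sizes are scaled by 1/8 (baseline 100 E + 25 I) while per-neuron
out-degrees (70/30/100), dt, kinetics, plasticity constants and weight
bounds keep their full-scale values.  Keeping the out-degrees fixed
preserves each neuron's *expected in-degree* — and hence its synaptic drive
and dynamical regime — exactly, which is why the scaled baseline reproduces
the low-rate (≈1.5 Hz), irregular (ISI CV > 1) excitatory regime of the
full model.  The compressed 72 s schedule gives the plasticity 60 s to act;
this is enough for the weak-inhibition condition to separate clearly from
baseline, though it is partial self-organization compared with the
production 1,500 s.  The replication batches use 10 seeds per condition,
derived from one master seed through counter-based SeedSequence streams.

## What the desk-scale tests show — and do not

With weak local inhibition (H-E/I: N_I scaled from 100, W_IE = 0.0125)
versus baseline, 10 seeds each, one-sided rank tests reproduce: higher mean
excitatory weights, higher excitatory firing rates, lower multiscale-entropy
complexity, and lower mutual information with the external input (all
p < 10⁻³).  The fifth directional effect — lower transfer entropy from the
stimulated group — does **not** reproduce at this scale: desk-scale H
networks saturate into strong synchronous bursting, and the TE between the
two group LAPs is then dominated by intrinsic burst coupling across the
strengthened interconnections rather than by propagation of the external
signal, so TE comes out *higher* than baseline.  The corresponding
acceptance test is kept as specified and fails honestly; reaching the
full-scale regime (8× larger groups, 25× longer plasticity, TE at 0.05 ms
resolution with k_hist = 140) is a cluster-scale computation.

The surrogate generators validate the estimators, not the biology: Gaussian
and AR pairs have no spike structure, and the mini networks share the full
model's physics but not its group size or maturation time.  Passing tests
therefore establish correctness of the machinery and the direction of the
E/I effects in the compressed regime, not quantitative agreement with
full-scale results.

## Known limitations

* Inhibitory synapses are static by design; no homeostatic or intrinsic
  plasticity, so weak inhibition can drive the scaled network into weight
  saturation within the run.
* Only RS/FS cell classes; single-compartment neurons.
* The sample-entropy pair normalization follows the stated definition
  (length-m pairs over N − m + 1 templates, length-(m+1) pairs over N − m);
  implementations that restrict both counts to N − m templates differ by
  O(1/N) at these lengths.
* KSG estimates on short windows can be slightly negative near zero MI;
  values are reported as estimated, without flooring at zero.
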