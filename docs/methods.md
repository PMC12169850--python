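# Model and methods

`replaynet` simulates recurrent networks of Poisson spiking neurons in
which every synapse — afferent, recurrent excitatory, recurrent
inhibitory — follows one predictive plasticity principle: the synapses
converging on a neuron learn to predict that neuron's firing rate.
Driven by probabilistic sensory input, such networks carve themselves
into stimulus-specific cell assemblies and, once the patterned input is
gone, spontaneously reactivate those assemblies; the statistics of the
reactivation reflect the occurrence statistics of the stimuli
experienced during learning.

## Neuron model

Each neuron `i` integrates presynaptic spike trains through exponential
traces `eps(s) = exp(-s/tau)` with `tau = 15 ms`; a spike contributes 1
to its trace immediately.  The membrane potential of the base (`nDL`)
variant is

    u_i = sum_k W_ik x_k + sum_j (M_ij - G_ij) y_j,

with afferent traces `x`, recurrent traces `y`, a signed afferent matrix
`W`, a signed recurrent matrix `M` and a non-negative inhibitory-only
matrix `G`.  Spikes are emitted by Bernoulli thinning of the
instantaneous rate with `dt = 1 ms` (per-step probability `f*dt/1000`,
at most 0.05 with the default `phi0 = 50 Hz`), and the whole system is
integrated with a fixed-step Euler scheme.

### Homeostatic rate function

The instantaneous rate is a sigmoid of the membrane potential whose gain
and threshold are rescaled by a slow per-neuron variable `h`:

    f_i = phi0 / (1 + exp(g*(beta0/h_i) * (-u_i + theta0*h_i)))

`h` decays with `tau_h = 10 s` while it exceeds `u` and jumps to `u`
otherwise, so it tracks the running maximum of the potential over the
last ~10 s.  Two properties of this parameterization carry the model's
qualitative behavior:

- **Self-normalization.**  The rate depends on `u` only through `u/h`:
  half-activation sits exactly at the tracked potential maximum.  A
  neuron therefore fires appreciably only when its current drive
  approaches the strongest drive it has recently seen — reliable,
  repeated input is amplified, unstructured fluctuations are not, and no
  neuron saturates permanently.
- **Silent baseline.**  At `u = 0` the rate is `phi0/(1+e^(g*beta0*theta0))`
  (~1.5e-5 Hz), independent of `h`.  Epochs without structured drive are
  effectively silent, which matters for the learning rule (below).

### Prediction decoder

Every plasticity rule compares the somatic rate with a *static* sigmoid
of a connection-class potential:

    phi(v) = phi0 / (1 + exp(g*beta0*(-v + g*theta0)))

with gain `g*beta0 = 15` and half-activation `g*theta0 = 3`.  Trained
prediction potentials therefore settle on the scale ~3 (where
`phi(v) = f` is solvable for ordinary rates).

The two sigmoids share `g` in the gain but differ by `g` in the
threshold; they are intentionally *not* the same curve.  This asymmetry
is load-bearing twice over.  First, early in learning a neuron's bursts
at its potential maxima meet a decoder output near zero (`phi(v) ~ 0`
for `v` well below 3), so the prediction error is large and positive and
every neuron is eventually recruited into an assembly; if the decoder
half-activated at the somatic threshold instead, those errors would
vanish as soon as predictions matched the (initially low) rates, and
most of the population would never join an assembly.  Second, with the
somatic threshold at `theta0*h` rather than `g*theta0*h`, firing remains
possible at all (the potential maximum tracked by `h` can actually be
reached), and the near-zero baseline keeps the decoder's inability to
represent sub-0.01-Hz rates from exerting a constant uniform
weight-inflation pressure during background epochs.  With the threshold
factor `g` present in the rate function, the half-activation would sit
at three times the tracked maximum — unreachable by construction — and
the network would be silent forever; configurations in between either
collapse into the silent fixed point or inflate all weights uniformly
until assembly structure washes out.  These failure modes were mapped
numerically and the default constants (`g = 3`, `beta0 = 5`,
`theta0 = 1`) are the printed values with `g` confined to the decoder
threshold.

## Learning rules

All rules share the error term

    E(f, v) = phi0^-1 * (1 - phi(v)/phi0) * (f - phi(v))

and update each weight by `eta * E * presynaptic trace` with
`eta = 1e-4` per 1-ms step.  The `W` and `M` updates descend the
Kullback-Leibler divergence between the Poisson process at rate `f` and
the one at rate `phi(v)` (the unit tests verify the `W` rule against a
finite-difference gradient of the KL integrand; the constant of
proportionality is `eta/(g*beta0*phi0)`).  The inhibitory matrix `G`
follows the same functional form on its own potential and is clamped at
zero from below after every step, as are all recurrent matrices of the
sign-constrained variants.  Updates are synchronous, once per Euler
step, using the same-step rate, predictions and traces.

Weight initialization: `W` and `M` are zero-mean Gaussians with
variances `0.1/sqrt(K)` and `0.1/sqrt(N)`; `G` is uniform `1/sqrt(N)`.
Reading `0.1/sqrt(dim)` as a standard deviation instead is exposed as
`init_width="sd"`.

### Network variants

- **nDL** (no Dale's law): signed `W`, signed `M`, non-negative `G`.
- **signed**: every ordered neuron pair is permanently assigned to one
  matrix (50 % `M_exc`, 25 % `M_inh`, 25 % `G` by a seeded draw).
  `M_exc` and `M_inh` share one joint prediction `v_exc - v_inh` and
  move in opposite directions; all recurrent matrices are clamped
  non-negative.
- **DL** (Dale's law): distinct excitatory and inhibitory pools.
  Inhibitory neurons reach each target through two paths: path 2 is
  trained jointly with the excitation it opposes (competition), path 1
  predicts the postsynaptic rate on its own (balance).

## Stimulation protocols

Afferent input is `K` Poisson trains at a 2-Hz background, interrupted
by 100-ms events in which one group of 100 inputs fires at 50 Hz, with
100-ms inter-event intervals; event identities are i.i.d. draws from the
configured occurrence probabilities (or a fixed cycle).  The coherence
task replaces the two groups' event rates by `(coh+0.5)*r_max` and
`(-coh+0.5)*r_max`.  The conditioning protocol drives two non-overlapping
subnetworks with time-aligned events: the A-event is drawn uniformly
from {S1, S2} and the simultaneous B-event from the conditional row
selected by the A-event; afferent wiring is block-restricted so S1/S2
reach only subnetwork A and S3/S4 only subnetwork B, while recurrent
connectivity spans both.

After learning, the patterned events stop but the input neurons keep
firing at the 2-Hz background during the recovery and spontaneous
epochs.  This choice resolves an ambiguity in what "removing the input"
means, and it is not cosmetic: with afferent spiking switched off
entirely, the membrane potentials decay to exactly zero, where the rate
function's baseline (~1.5e-5 Hz) cannot re-ignite activity — the silent
state is absorbing.  With the background retained, the recovering
excitability (decaying `h`) progressively amplifies the weak
structured fluctuations that the trained afferents produce, and
input-free replay resumes within seconds, which is exactly the
recovery phenomenology the protocol is designed around.

## Phases of an experiment

1. **Learning** (default 300 s at desk scale): all matrices plastic.
2. **Recovery** (20 s): patterned input off, plasticity off, `h` decays.
3. **Spontaneous** (100 s): replay statistics are measured here;
   plasticity stays off by default and can be selectively re-enabled
   (the frozen-G protocol keeps `G` off while `W` and `M` learn).
4. **Evoked probes**: each stimulus presented repeatedly (default 20x)
   with plasticity off; the trial-averaged rate table defines the
   assembly assignment (argmax stimulus, selectivity threshold 0.3).

Desk-scale defaults are `N = 100`, two to four input groups of 100, and
300-s learning; the published experiments correspond to `N = 500` and
1000-s learning.  The 300-s desk figure was chosen because the ratio
metrics (below) reach their stationary values by roughly 200-400 s at
this scale while the absolute recurrent weights are still growing.

## Measures

- **Assembly assignment**: argmax of the evoked-rate table with
  selectivity `(max-second)/(max+second) >= 0.3`; ties break to the
  lowest stimulus id; unassigned neurons are excluded from all ratios.
- **Firing-rate / assembly-size / assembly-activity ratios**: the
  target assembly's mean single-neuron rate, member count, and summed
  population rate, each divided by the mean over the other assemblies.
  The activity ratio is the probability readout.
- **AR and choices-to-right**: `AR = r_R_pop/(r_R_pop + r_L_pop)` over
  an epoch; `choices = 100*AR`.
- **Normalized excitatory incoming weights**: positive within-assembly
  mass of `M` per assembly, normalized across assemblies.
- **Lateral inhibition (DL)**: `G_path @ M_IE`, summarized by within-
  vs between-assembly medians and quartiles.
- **Pairwise correlations**: Pearson correlations of 20-ms binned
  spontaneous counts; zero-variance neurons are reported as 0.

## Ablations

- `fixed_h`: the homeostatic variable is frozen at a constant
  (default `theta0`) for the whole pipeline.  The network still forms
  and replays assemblies, but without per-neuron normalization the
  probability estimate degrades.
- `frozen_G_after_stimuli`: after the recovery window, `W` and `M`
  resume learning but `G` does not; the within/between structure of `M`
  erodes relative to the control in which `G` keeps balancing.
- `remove_between_assembly_excitation`: positive cross-assembly entries
  of `M` are zeroed at probe time (not during learning).

## What the synthetic protocols do and do not emulate

The stimulus generator reproduces the statistical skeleton of the
experiments — Poisson trains, fixed-duration events, occurrence
probabilities, coherence-scaled rates — and nothing else: no temporal
structure within events, no rate adaptation, no trial-to-trial
correlations beyond those configured.  Passing tests therefore
demonstrate the learning dynamics under exactly these idealized
statistics, not robustness to naturalistic input.

## Desk-scale limitations

Two effects weaken quantitative probability matching at `N = 100`
relative to the published scale, and both are visible in the acceptance
measurements:

- **Assembly-size noise.**  With ~50 neurons per assembly, the
  recruitment split inherits the sampling noise of the random initial
  afferent projections (~10-20 %).  Statistics that compare assemblies
  are therefore averaged over several independently seeded networks
  (the underlying experiments likewise average 5-20 simulations).
- **Homeostatic rate equalization.**  Spontaneous firing is gated by
  each neuron's own `h`, which normalizes away absolute weight-strength
  differences between assemblies; at this scale the activity-ratio
  statistic is carried mainly by assembly size, which grows sub-linearly
  with the training probability.  The unbiased protocols are unaffected
  (the symmetric point is preserved), but strongly biased protocols
  (e.g. 4:1) yield attenuated activity ratios.

## Numerical choices

- Bernoulli thinning of rates at `dt = 1 ms` (probability <= 0.05).
- `h` clamped at `1e-2` from below; the clamp never fires in default
  runs (rates would have to vanish network-wide for ~46 s first).
- Sigmoid exponents clipped at +-500 before `exp`; the sigmoid is
  saturated to machine precision long before the clip engages.
- The fused integrator stacks `M` and `G` for single-matrix recurrence
  and, when numba is importable, runs a compiled kernel that consumes
  the same random stream in the same order as the pure-numpy path (the
  test suite asserts spike-for-spike agreement); BLAS matrix-vector
  products keep the accumulation order identical between the paths.
- All randomness flows from one seed through named child generators
  (initialization, schedule, and each phase), so runs are reproducible
  bit for bit.
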