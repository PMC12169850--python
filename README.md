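# replaynet

Recurrent spiking-network simulations of how cortex-like circuits can
*learn their own spontaneous activity*: networks in which every synapse
follows a single predictive plasticity rule carve themselves into
stimulus-specific cell assemblies, and after the stimulation ends they
spontaneously reactivate those assemblies with statistics that reflect
how often each stimulus was experienced.  The package is aimed at
computational neuroscientists who want to reproduce, probe or extend
this class of models: the network variants, stimulation protocols,
ablations and replay metrics are all first-class, scriptable objects.

## The model in brief

`N` Poisson neurons with membrane potential

    u_i = Σ_k W_ik x_k + Σ_j (M_ij − G_ij) y_j,

where `x`, `y` are presynaptic traces (`ε(s) = e^(−s/τ)`, τ = 15 ms),
`W` is the afferent matrix, `M` a signed recurrent matrix and `G ≥ 0` an
inhibitory-only matrix.  The instantaneous rate is a sigmoid whose gain
`β0/h` and threshold `θ0·h` are rescaled by a homeostatic variable `h`
that tracks the running maximum of `u` over ~10 s, so half-activation
always sits at the neuron's own recent peak drive.  Every matrix `C`
with prediction potential `v_C` learns by the same rule,

    ΔC_ij = η · φ0⁻¹ (1 − φ(v_C)/φ0)(f − φ(v_C)) · trace_j,

descending the KL divergence between the neuron's firing and the rate
`φ(v_C)` decoded from that connection class alone (`φ` is a static
sigmoid with gain `g·β0` and midpoint `g·θ0`).  Sign-constrained
variants (distinct excitatory/inhibitory synapses; separate E and I
populations with two inhibitory pathways obeying Dale's law) use the
same error term per class.  See `docs/methods.md` for the full model,
the design decisions and the desk-scale limitations.

## Worked example

Train a desk-scale network (N = 100) on two stimuli presented 30 % and
70 % of the time, let it recover, measure its spontaneous replay, and
probe its assemblies:

```bash
replay-sim run --preset fig4 --seed 7 --out runs/biased
```

which prints (exact numbers for this seed):

```
replaynet 0.1.0
protocol=patterns kind=nDL N=100 seed=7
assemblies=[37, 57] unassigned=6
spontaneous pop rates=[4.4, 6.6] Hz
```

Reading this output: the network self-organized two cell assemblies —
37 neurons preferring the rare stimulus and 57 preferring the frequent
one — and during the patterned-input-free epoch the frequent assembly
carries the larger share of the population rate.  The run directory
contains `config.json`, the trained `weights.h5`, the spontaneous spike
raster `raster.csv` and `metrics.json` with the full report, including
the normalized within-assembly excitatory weight mass

```
"normalized_incoming_weights": [0.308, 0.692]
```

— compare the training probabilities 0.3/0.7: the recurrent weight mass
inside each assembly approximates the stimulus occurrence
probabilities.

The same pipeline drives the perceptual-decision experiment: training
with rightward/leftward coherence stimuli at 80 %/20 % biases the
spontaneous activity ratio of the R-encoding assembly, and probing with
intermediate coherences yields the psychometric curve:

```bash
replay-sim decision --preset fig5-biased --seed 3 --out runs/decision
```

Python API equivalents live in `replaynet.experiments`
(`run_experiment`, `run_probability_sweep`, `run_decision_task`,
`run_conditioned_prior`), all driven by a single `ExperimentConfig`
dataclass that serializes to JSON/YAML.

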