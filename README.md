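# effcond

Effective synaptic conductance under somatic voltage clamp: a passive
branched-cable simulator, the static transfer-resistance theory of the
clamp/synapse interaction, and the **intercept method (IM)** estimator that
recovers effective excitatory/inhibitory conductances where the traditional
**slope-and-intercept method (SIM)** fails.

## The problem

To separate the excitatory (E) and inhibitory (I) synaptic input to a
neuron, electrophysiologists clamp the soma at several holding potentials
*V*, record the synaptic current *I*<sub>syn</sub>, fit the linear I-V
relation *I*<sub>syn</sub> = −*k V* + *b* at each time point, and solve

&nbsp;&nbsp;&nbsp;&nbsp;*k* = *g*<sub>E</sub> + *g*<sub>I</sub>,&nbsp;&nbsp;
*b* = *g*<sub>E</sub>ε<sub>E</sub> + *g*<sub>I</sub>ε<sub>I</sub>

for the two conductances (SIM). On a spatial neuron this is wrong: the
clamp controls only the soma (the space-clamp effect), and the clamp
current interacts nonlinearly with dendritic synaptic current. A static
transfer-resistance analysis of the clamped cable shows the true relations
are, to first order in the local conductances,

&nbsp;&nbsp;&nbsp;&nbsp;*k* = (*K*<sub>ES</sub>/*K*<sub>SS</sub>)²*g*<sub>E</sub> + (*K*<sub>IS</sub>/*K*<sub>SS</sub>)²*g*<sub>I</sub>,&nbsp;&nbsp;
*b* = *g*<sub>E</sub><sup>eff</sup>ε<sub>E</sub> + *g*<sub>I</sub><sup>eff</sup>ε<sub>I</sub>,

where *K*<sub>AB</sub> is the transfer resistance between sites A and B,
*K*<sub>SS</sub> the somatic input resistance, and
*g*<sub>q</sub><sup>eff</sup> = (*K*<sub>qS</sub>/*K*<sub>SS</sub>)*g*<sub>q</sub>
is the **effective conductance** the soma actually sees. Because the slope
carries *squared* location-dependent prefactors while the intercept carries
them linearly, no transform can map SIM's output onto the local
conductances, SIM systematically under-estimates both polarities (with
error ratio Δ*g*<sub>E</sub> : Δ*g*<sub>I</sub> = −ε<sub>I</sub> : ε<sub>E</sub>),
and its inhibitory estimate can even go unphysically negative.

The intercept method avoids the contaminated slope entirely: repeat the
protocol at a second inhibitory reversal potential ε<sub>I</sub>′ and solve
the two intercept equations

&nbsp;&nbsp;&nbsp;&nbsp;*b* = *g*<sub>E</sub><sup>eff</sup>ε<sub>E</sub> + *g*<sub>I</sub><sup>eff</sup>ε<sub>I</sub>,&nbsp;&nbsp;
*b*′ = *g*<sub>E</sub><sup>eff</sup>ε<sub>E</sub> + *g*<sub>I</sub><sup>eff</sup>ε<sub>I</sub>′

for the pair of effective conductances.

## What's in the package

| module | contents |
| --- | --- |
| `effcond.morphology` | SWC read/write, ball-and-stick and random-tree builders, zig-zag path distances |
| `effcond.cable` | compartmental discretization, Crank–Nicolson integration, ideal somatic clamp by node substitution, double-exponential synapses, generic gating channels |
| `effcond.transfer` | transfer-resistance matrices, somatic prefactor maps K<sub>XS</sub>/K<sub>SS</sub>, reciprocity checks |
| `effcond.statics` | exact three-port algebra (clamped soma + E + I sites), SIM/IM solvers, closed-form SIM error laws, nonexistence-of-transform witness |
| `effcond.estimators` | per-time-point I-V regression, SIM/IM/per-level conductance traces, reference extractors, waveform fitting, error metrics |
| `effcond.experiments` | input schedules, the full clamp protocol, spatial error scans, reversal-invariance checks |
| `effcond.fixtures` | packaged synthetic neurons and canonical AMPA/GABA<sub>A</sub> kernels (5/7.8 ms and 6/18 ms rise/decay) |
| `effcond.cli` | `effcond` command: `simulate`, `transfer-matrix`, `prefactor-map`, `clamp-protocol`, `estimate`, `error-map`, `static-demo`, `reversal-check`, `make-fixtures` |

All potentials are relative to rest; units are mV / nA / μS / nF / MΩ / ms
throughout.

## Worked example

Deliver a co-located 2.5 nS E / 4 nS I conductance pair 100 μm out on the
packaged long-dendrite neuron, run the five-level clamp protocol at two
inhibitory reversals, and compare both estimators against the
single-polarity references:

```python
from effcond import SynapticEvent
from effcond.fixtures import long_stick_neuron, E_KERNEL, I_KERNEL, EPS_E, EPS_I
from effcond.experiments import InputSchedule, run_protocol

model = long_stick_neuron()
site = model.nearest_compartment(100.0)
events = [SynapticEvent(site, 10.0, E_KERNEL[2], *E_KERNEL[:2], EPS_E, "E"),
          SynapticEvent(site, 10.0, I_KERNEL[2], *I_KERNEL[:2], EPS_I, "I")]
result = run_protocol(model, InputSchedule(events, 1, 1, 0.0, 110.0, seed=0))
for method in ("SIM", "IM"):
    for pol in ("E", "I"):
        s = result.summaries()[method][pol]
        trace = getattr(result, f"{method.lower()}_{pol}")
        print(f"{method:3s} {pol}: peak {trace.peak*1e3:5.2f} nS   "
              f"peak error {100*s.peak_relative_error:5.1f}%   "
              f"negative excursion: {trace.has_negative}")
```

prints

```
SIM E: peak  2.05 nS   peak error   8.3%   negative excursion: True
SIM I: peak  3.19 nS   peak error   9.0%   negative excursion: True
IM  E: peak  2.08 nS   peak error   7.2%   negative excursion: False
IM  I: peak  3.36 nS   peak error   4.3%   negative excursion: False
```

Even 100 μm from the soma SIM already distorts the traces and dips below
zero during the E-dominated phase, while IM tracks the references without
unphysical excursions. The contrast sharpens with distance: run
`effcond error-map` (or `effcond.experiments.spatial_error_map`) to scan
input locations — on the packaged fixture SIM's inhibitory error grows from
~6% to ~90% along the dendrite and its trace swings hard negative
distally, while IM stays within a few percent everywhere.

For the purely algebraic demonstration (a static co-located pair at
prefactor α = 0.2, where SIM returns a negative inhibitory conductance
while IM is exact):

```sh
effcond static-demo --alpha 0.2,1.0
```

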