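# spikeplane

Spiking cortical networks with pair/triplet spike-timing-dependent plasticity
(STDP), graded neuronal damage, and ordinal-pattern information quantifiers —
entropy–complexity–Fisher characterization of network rhythms.

## What it is for

Synaptic depression (LTD) is enhanced when spike *triplets* — pre–post–pre
motifs — contribute on top of the classical pairwise post-before-pre pairing.
`spikeplane` is a simulator-plus-analysis toolbox for asking how that
triplet-enhanced LTD, and progressive silencing of excitatory neurons
("damage"), reshape the collective dynamics of a cortical hypercolumn. It is
aimed at computational neuroscientists studying plasticity, network
oscillations, and information-theoretic signal characterization.

The model network is 1000 Izhikevich neurons (800 intrinsically bursting
excitatory, 200 low-threshold-spiking inhibitory), randomly connected with
Mc = 50 outgoing synapses per neuron (connection probability 0.05) and
integer axonal delays. Membrane dynamics:

    dv/dt = 0.04 v² + 5 v + 140 − u + I
    du/dt = a (b v − u),     v > 30 mV ⇒ v ← c, u ← u + d

Excitatory weights follow trace-based STDP: pair LTP
Δw = +A2⁺ e^(−Δt/τ⁺), and LTD at each presynaptic spike
Δw = −o1(post)·[A2⁻ + A3⁻·r2(pre)], where o1 decays with τ⁻ = 33.7 ms and
the triplet trace r2 with τx = 101 ms (τ⁺ = 16.8 ms). Setting the mode to
`pairwise` zeroes the triplet term; `mixed` keeps it. Damaged neurons hold
their membrane potential at rest and never fire.

The analysis stage converts membrane traces into Bandt–Pompe ordinal PDFs
(embedding dimension D\* = 3, lag τ\* = 1, Lehmer lexicographic pattern
order) per rhythm band (delta … gamma, two HFO bands), builds two global
series per window — the local field potential (per-ms sum of membrane
potentials) and the all-pairs Jensen–Shannon distance series — and summarizes
each by normalized Shannon entropy H, normalized discrete Fisher information
F, and statistical complexity C = QJ·H (QJ the Jensen–Shannon disequilibrium
against the uniform PDF). Results are tidy CSV tables ready for H×F, H×C and
C×H×F plane plots.

## Worked example

The ordinal machinery on a 7-point series with a known closed-form PDF:

```python
from spikeplane import bp_pdf, quantifiers
from spikeplane.infoquant import REFERENCE_SERIES  # (5, 6, 7, 14, 28, 10, 18)

p = bp_pdf(REFERENCE_SERIES, enforce_length=False)
print("ordinal PDF:", p)
q = quantifiers(p)
print(f"H = {q.H:.4f}  F = {q.F:.4f}  C = {q.C:.4f}  QJ = {q.QJ:.4f}")
```

prints

```
ordinal PDF: [0.6 0.  0.  0.2 0.2 0. ]
H = 0.5304  F = 0.5000  C = 0.2802  QJ = 0.5283
```

Three of the five embedded windows are increasing (pattern [012], Lehmer
rank 0), one is [120] and one is [201]: probabilities 3/5, 1/5, 1/5. The
series is moderately ordered (H ≈ 0.53), far from uniform (QJ ≈ 0.53), and
therefore carries non-trivial statistical complexity (C ≈ 0.28).

A miniature experiment — 200 neurons with the full model's in-degree, both
plasticity modes on paired seeds, no damage vs. 60 damaged excitatory cells,
gamma band, LFP source:

```python
from spikeplane.network import NetworkConfig
from spikeplane.pipeline import ExperimentConfig, Seeds, run_experiment

cfg = ExperimentConfig(
    network=NetworkConfig(n_total=200, n_exc=160, n_inh=40, m_out=50),
    modes=("pairwise", "mixed"), damage_levels=(0, 60), bands=("gamma",),
    duration=20_000, n_windows=5, sources=("lfp",), seeds=Seeds(100, 200, 300),
)
table = run_experiment(cfg)
print(table.groupby(["mode", "n_damaged"])[["H", "F", "C"]].median().round(4))
```

```
                         H       F       C
mode     n_damaged
mixed    0          0.6740  0.2143  0.2228
         60         0.6774  0.2136  0.2216
pairwise 0          0.6692  0.2183  0.2252
         60         0.6843  0.2079  0.2186
```

The triplet-LTD (mixed) network runs at higher entropy and lower Fisher
information than the purely pairwise one, and damage pushes entropy up while
Fisher information falls — the orderings the model is designed to expose.
(Single-seed medians; the test suite evaluates these trends over five seeds.
See `docs/methods.md` for what the miniature does and does not reproduce.)

## Command line

```
spikeplane simulate --out runs/a --mode mixed --damage 100 --duration 60000
spikeplane analyze  --record runs/a/membrane --band gamma --out runs/a/results.csv
spikeplane planes   --table runs/a/results.csv --out runs/a/planes --plot
spikeplane run      --config experiment.yaml --out results.csv
spikeplane selftest
```

`simulate` writes a spike raster (`t_ms,neuron_id` CSV), a membrane record
(`.npz` + JSON sidecar) and a weight snapshot; `analyze` turns a membrane
record into quantifier rows; `planes` exports the per-band plane tables;
`selftest` re-derives the closed-form fixtures.

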