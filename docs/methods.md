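# Methods

## Model overview

`spikeplane` simulates a cortical hypercolumn of N quadratic
integrate-and-fire (Izhikevich) neurons and characterizes its collective
dynamics with ordinal-pattern information quantifiers. The two questions the
package is built to probe are (i) how spike-timing-dependent plasticity (STDP)
with *triplet-enhanced long-term depression* changes network dynamics relative
to purely pairwise STDP, and (ii) how graded neuronal damage — excitatory
cells silenced by clamping their membrane potential — moves the network in the
entropy–complexity–Fisher (H, C, F) space, per cortical rhythm band.

## Neuron and network

Each neuron follows

    dv/dt = 0.04 v² + 5 v + 140 − u + I,
    du/dt = a (b v − u),
    if v > 30 mV:  v ← c,  u ← u + d,

with v in mV and t in ms. The excitatory population (80%) uses the
intrinsically bursting preset (a, b, c, d) = (0.02, 0.2, −55, 4); the
inhibitory population (20%) uses low-threshold spiking (0.02, 0.25, −65, 2).
The resting state is the stable (more negative) root of
0.04 v² + (5 − b) v + 140 = 0 with u = b v: −70 mV for b = 0.2, ≈ −64.4 mV
for b = 0.25.

Connectivity: every excitatory neuron projects to Mc = 50 distinct random
targets anywhere in the network (connection probability Mc/N = 0.05 at the
default N = 1000); every inhibitory neuron projects to Mc random excitatory
targets. Excitatory synapses carry uniform-integer conduction delays of
1–10 ms (the delay range is configurable because both 1–10 and 1–20 ms are
defensible; the narrower range is the default), inhibitory delays are 1 ms.
Initial weights are +6 mV (excitatory, plastic, bounded in [0, 10] mV) and
−5 mV (inhibitory, static).

**Integration.** 1 ms outer resolution with two 0.5 ms forward-Euler substeps
for v and one 1 ms step for u — the convention of the classical
polychronization simulator this architecture descends from. Spikes are
detected once per ms; stored traces clamp the peak at 30 mV.

**Drive.** The input current is not part of the model definition; by default
one uniformly random undamaged neuron receives a 20 mV-equivalent pulse each
ms (the same classical convention), switchable to constant or zero drive.

**Damage.** A damaged neuron's membrane potential is held at its resting
value for the whole run: it never fires and transmits nothing. Damage is a
uniformly random subset of the excitatory population of configurable size
(default sweep 0, 100, 200, 300 at N = 1000). Damaged neurons are excluded
from the analysis (LFP sum, per-neuron PDFs, pairwise distances): their
constant traces carry no signal and would only inject a deterministic
degenerate pattern. The exclusion is config-reversible at the analysis entry
points (callers pass the neuron subset).

## Plasticity

Excitatory synapses evolve by trace-based STDP. Each neuron carries three
exponentially decaying traces: r1 (presynaptic pair trace, τ+ = 16.8 ms),
o1 (postsynaptic pair trace, τ− = 33.7 ms), and r2 (presynaptic triplet
trace, τx = 101 ms).

* At a postsynaptic spike, each incoming synapse gains
  Δw = +A2⁺ · r1(pre) — pair LTP: potentiation when the presynaptic neuron
  fired shortly before.
* At a presynaptic spike, each outgoing synapse loses
  Δw = −o1(post) · [A2⁻ + A3⁻ · r2(pre)], where r2 is read *just before* its
  own increment — pair LTD plus a triplet term that deepens depression when
  the presynaptic neuron also fired recently before (pre–post–pre motifs).
* Triplet LTP is disabled (its amplitude is identically zero); potentiation
  is purely pairwise.

`mode="pairwise"` zeroes the effective A3⁻, and reproduces the purely
pairwise rule bit-for-bit on identical spike trains. Traces accumulate
all-to-all by default (+1 per spike); a nearest-spike scheme (reset to 1) is
available. Weight changes are applied immediately at spike events and clipped
to [0, w_max]; simultaneous pre/post events within one ms are processed as a
batch, both updates reading the traces decayed to that instant before either
increment. Inhibitory synapses are static.

**Amplitude defaults.** The amplitudes are not uniquely determined by the
published variants of the triplet rule once triplet LTP is removed, so they
are explicit configuration with the following defaults (mV, additive, for
w_max = 10): A2⁺ = 0.1 (the classical pair-LTP step for mV-scale weights),
A2⁻ = 0.066 and A3⁻ = 0.031, which keep the pair:triplet LTD ratio of the
minimal visual-cortex fit of the triplet-STDP literature after rescaling to
mV weights. With these defaults the triplet term is strong enough to matter:
in a 200-neuron network the pairwise mode undergoes runaway potentiation
(bimodal weights, ~11 Hz excitatory rates) while the mixed mode is stabilized
near unimodal mid-range weights (~3.6 Hz) — the depression channel opened by
triplets acts as the brake. All trend tests in the suite assert orderings and
signs only, never specific values of these amplitudes.

## Spectral stage

The population rhythm is read from the per-ms histogram of network spikes:
its one-sided FFT power spectrum (squared coefficient magnitudes, mean
removed; interior bins doubled so Parseval's identity holds exactly) is
scanned for the band with the highest mean power per Hz among

    delta (0.2–4], theta (4–8], alpha (8–12], beta (12–30],
    gamma (30–100], hfo1 (100–150], hfo2 (150–200] Hz,

half-open intervals, jointly covering (0.2, 200]. The
oscillation-of-interest stopping rule accepts a 1000 ms chunk when its
dominant band matches the configured target. Band isolation of membrane
traces and LFPs uses a 4th-order Butterworth band-pass applied
forward–backward (zero phase, second-order sections), so filtering cannot
distort ordinal patterns through phase shifts.

## Ordinal PDFs and quantifiers

Windows of D* consecutive values (lag τ*; defaults D* = 3, τ* = 1) are mapped
to the permutation of time offsets sorted by decreasing value, ties resolved
in favour of the larger offset (older sample ranks higher), so a constant
window deterministically yields the pattern (D*−1, …, 1, 0). Patterns are
indexed by their Lehmer (factoradic) rank — lexicographic order 012, 021,
102, 120, 201, 210 at D* = 3 — and relative frequencies over the
M − (D*−1)τ* windows form the ordinal PDF. A series must supply at least
10·D*! points (waived only for the 7-point closed-form fixture, whose PDF
(3/5, 0, 0, 1/5, 1/5, 0) is asserted at the start of every analysis run).

On an ordinal PDF P of length N the package computes:

* **H** — Shannon entropy, base 2, divided by log₂N (∈ [0, 1]).
* **Jensen–Shannon divergence** DJS(P, Q) = S[(P+Q)/2] − (S[P]+S[Q])/2 with
  the natural-log entropy functional; its square root is a proper metric.
* **QJ** — disequilibrium Q0·DJS(P, Pe) against the uniform Pe. Q0 is
  computed at run time as the inverse of DJS(point mass, uniform) — the
  maximal divergence — and cross-checked against the closed form
  −2{((N+1)/N)ln(N+1) − 2ln(2N) + ln N}⁻¹ (≈ 2.2031 at N = 6). This is the
  only normalization for which 0 ≤ QJ ≤ 1 with QJ = 1 exactly at a point
  mass.
* **C** = QJ·H — statistical complexity: zero for perfectly ordered (point
  mass) and perfectly random (uniform) PDFs, positive in between.
* **F** — normalized discrete Fisher information in the square-root-amplitude
  form F0·Σ(√p_{i+1} − √p_i)², F0 = 1 when all mass sits on the first or last
  pattern and 1/2 otherwise. The squared-probability-difference variant is
  not used because no constant F0 normalizes it to [0, 1]; the
  square-root form makes the edge-delta condition yield exactly 1. F is
  order-sensitive and always evaluated on the Lehmer-ordered PDF.

## Pipeline

One experiment sweeps mode × damage on a shared topology, with the damage
mask and drive stream drawn per damage level and reused across modes — a
paired design in which any mode difference is attributable to the triplet LTD
term alone. Each 1000 ms window of sustained activity (≥ a configurable
minimum of population spikes; optionally dominant-band-matched) is
band-filtered and reduced to two global series:

* **lfp** — the per-ms sum of all undamaged membrane potentials;
* **js_pair** — the Jensen–Shannon distances between the ordinal PDFs of all
  unordered pairs of undamaged neurons, in lexicographic pair order.

The ordinal PDF of each global series yields one (H, F, C) row per
(mode, damage, band, window, source); CSV floats carry 17 significant digits
so reruns are byte-identical. Plane exports copy (never recompute) the H×F,
H×C and H×F×C columns per band.

Both global-series candidates are always computed because the Fisher stage of
the original construction is ambiguous. Empirically the js_pair series is a
poor Fisher carrier: an unordered sequence of pair distances has a
near-uniform ordinal PDF, so F ≈ 10⁻³ regardless of network state, while the
LFP ordinal PDF produces F in the 0.05–0.3 range and discriminates
conditions. Trend evaluations in the test suite therefore use the lfp source
for all three quantifiers.

## Scaled study conditions

The full-size experiment (N = 1000, hour-scale evolution) is expressed by the
configuration defaults, but the test suite validates the qualitative claims
on a miniature fixed as follows: 200 neurons (160 excitatory, 40 inhibitory)
with the full model's **in-degree preserved** (Mc = 50), 60 s simulated —
45 s of plasticity evolution, then the last 15 windows analyzed
(evolve-then-characterize: mode contrasts accrue through the slowly diverging
weight distributions, so windows taken before the evolution has acted carry
no signal) — damage grid {0, 20, 40, 60}, both plasticity modes on paired
seeds, 5 seeds, beta and gamma bands. Two further scaling choices matter and
were validated explicitly:

* **In-degree, not connection probability, is preserved.** Scaling Mc with N
  (Mc = 10) collapses the collective rhythm into broadband noise and makes
  the two plasticity modes dynamically indistinguishable; keeping Mc = 50
  restores a beta-band population oscillation and a dramatic mode separation.
* **Only bands with periods near the embedding span are analyzed.** With
  τ* = 1 ms and D* = 3 the ordinal embedding spans 2 ms. Band-filtered series
  whose period exceeds that span by two orders of magnitude (delta, theta,
  alpha at 1 kHz sampling) are oversampled: their ordinal PDFs are dominated
  by the smooth local slope, and H, C, F become functions of the band's
  center frequency rather than of the dynamics (measured: indistinguishable
  quantifiers across modes despite threefold firing-rate differences). Beta
  and gamma are both expressive under the embedding and the rhythms the
  scaled network actually produces.

## What the miniature does and does not show

Of the qualitative full-scale claims, the miniature reproduces:

* **Fisher information is higher under pairwise than mixed STDP** (majority
  of seeds, both analyzed bands, LFP source);
* **LFP Shannon entropy rises with damage** (positive Spearman correlation in
  a majority of seeds, both analyzed bands) and is higher under mixed STDP.

It does **not** reproduce the claim that statistical complexity is higher for
mixed STDP. The mechanism
is visible in the numbers: at this scale all LFP entropy values fall in
H ≈ 0.5–0.7, the descending branch of the complexity–entropy curve, where
C ≈ QJ(H)·H is strictly anti-correlated with H; since the mixed mode has the
*higher* entropy (as at full scale), its complexity is mechanically lower.
Recovering C(mixed) > C(pairwise) requires the pairwise network to sit at
much lower entropy (strong global synchrony), which 200 neurons over 60 s do
not reach. The corresponding tests are retained, failing, as an honest record
of the miniature's limits; nothing in the generator or thresholds was
adjusted to mask them.

Other known limitations: the synthetic drive (one random pulse per ms) is
stationary and spatially unstructured, so the model produces no
stimulus-locked or spatially patterned activity; membrane records are stored
densely in float32 (N = 1000 at one hour ≈ 14 GB — long full-scale runs
should record selectively or analyze in segments); simultaneous-spike STDP
updates are batch-ordered rather than sub-ms resolved; delays are ignored in
the plasticity timing (traces are read at soma spike times, the standard
simplification); delivered synaptic currents carry the weight at emission
time.
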