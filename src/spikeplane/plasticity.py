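"""Trace-based STDP: pair LTP, and LTD with pair plus triplet contributions.

Each neuron carries three exponentially decaying spike traces:

* ``r1`` — presynaptic pair trace, time constant ``tau_plus`` (16.8 ms);
* ``o1`` — postsynaptic pair trace, time constant ``tau_minus`` (33.7 ms);
* ``r2`` — presynaptic triplet trace, time constant ``tau_x`` (101 ms).

At a postsynaptic spike every incoming synapse is potentiated by
``A2+ * r1(pre)`` (pair LTP).  At a presynaptic spike every outgoing synapse
is depressed by ``o1(post) * (A2- + A3- * r2(pre))`` where ``r2`` is read
*just before* its own increment (the small-epsilon convention): the triplet
term makes depression stronger when the presynaptic neuron fired recently
before, i.e. pre–post–pre motifs enhance LTD.  The triplet LTP amplitude is
fixed at zero, so potentiation is purely pairwise.

``mode='pairwise'`` zeroes the effective triplet amplitude, reproducing the
purely pairwise rule bit-for-bit on the same spike trains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PlasticityParams",
    "TraceState",
    "decay_traces",
    "on_post_spike",
    "on_pre_spike",
    "run_stdp_on_trains",
    "pairwise_params",
]


@dataclass(frozen=True)
class PlasticityParams:
    """Amplitudes (mV), time constants (ms) and mode of the STDP rule.

    The amplitudes are additive weight changes for weights bounded in
    ``[0, w_max]`` mV.  ``epsilon`` is the conceptual positive offset ensuring
    the triplet trace is evaluated before its own spike's increment; the
    implementation realizes it exactly by ordering the update before the
    increment, so its numeric value is not used in the arithmetic.
    """

    a2_plus: float = 0.1
    a2_minus: float = 0.066
    a3_minus: float = 0.031
    tau_plus: float = 16.8
    tau_minus: float = 33.7
    tau_x: float = 101.0
    epsilon: float = 1e-6
    w_max: float = 10.0
    mode: str = "mixed"  # 'mixed' (pair + triplet LTD) or 'pairwise'
    interaction: str = "all-to-all"  # or 'nearest-spike'

    def __post_init__(self) -> None:
        for name in ("a2_plus", "a2_minus", "a3_minus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("tau_plus", "tau_minus", "tau_x"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be a small positive offset")
        if self.mode not in ("mixed", "pairwise"):
            raise ValueError(f"unknown plasticity mode {self.mode!r}")
        if self.interaction not in ("all-to-all", "nearest-spike"):
            raise ValueError(f"unknown interaction scheme {self.interaction!r}")

    @property
    def effective_a3_minus(self) -> float:
        """Triplet LTD amplitude actually applied (0 in pairwise mode)."""
        return 0.0 if self.mode == "pairwise" else self.a3_minus


@dataclass
class TraceState:
    """Per-neuron spike traces r1 (tau+), o1 (tau-), r2 (tau_x)."""

    r1: np.ndarray
    o1: np.ndarray
    r2: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "TraceState":
        return cls(np.zeros(n), np.zeros(n), np.zeros(n))

    def decay_factors(self, p: PlasticityParams, dt: float) -> tuple[float, float, float]:
        return (
            math.exp(-dt / p.tau_plus),
            math.exp(-dt / p.tau_minus),
            math.exp(-dt / p.tau_x),
        )

    def decay_inplace(self, factors: tuple[float, float, float]) -> None:
        self.r1 *= factors[0]
        self.o1 *= factors[1]
        self.r2 *= factors[2]

    def increment(self, fired: np.ndarray, fired_pre: np.ndarray, interaction: str) -> None:
        """Bump traces at spike time: all-to-all accumulates (+1), nearest-spike
        resets to 1 so only the most recent spike contributes."""
        if interaction == "all-to-all":
            self.o1[fired] += 1.0
            self.r1[fired_pre] += 1.0
            self.r2[fired_pre] += 1.0
        else:
            self.o1[fired] = 1.0
            self.r1[fired_pre] = 1.0
            self.r2[fired_pre] = 1.0


def decay_traces(traces: TraceState, p: PlasticityParams, dt: float) -> TraceState:
    """Return a copy of ``traces`` decayed by ``dt`` ms (each trace by its own tau)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    f = traces.decay_factors(p, dt)
    return TraceState(traces.r1 * f[0], traces.o1 * f[1], traces.r2 * f[2])


def on_post_spike(w: float, r1_pre: float, p: PlasticityParams) -> float:
    """Weight after pair LTP at a postsynaptic spike: w + A2+ * r1(pre), clipped."""
    return float(np.clip(w + p.a2_plus * r1_pre, 0.0, p.w_max))


def on_pre_spike(w: float, o1_post: float, r2_pre_before: float, p: PlasticityParams) -> float:
    """Weight after LTD at a presynaptic spike.

    ``r2_pre_before`` is the presynaptic triplet trace evaluated just before
    this spike's own increment.
    """
    dw = -o1_post * (p.a2_minus + p.effective_a3_minus * r2_pre_before)
    return float(np.clip(w + dw, 0.0, p.w_max))


def run_stdp_on_trains(
    pre_times,
    post_times,
    p: PlasticityParams,
    w0: float = 5.0,
):
    """Replay a single synapse through the STDP rule on given spike trains.

    Offline harness: event-driven with exact exponential decay between events.
    Simultaneous pre and post spikes are processed as one batch — both weight
    updates use the traces decayed to that instant, before either spike's
    increment — matching the network simulator's per-ms semantics.

    Parameters
    ----------
    pre_times, post_times : sorted sequences of spike times (ms).
    w0 : initial weight (mV).

    Returns
    -------
    times : float array of event times.
    w : float array, the weight after each event (clipped to [0, w_max]).
    """
    pre_times = np.asarray(pre_times, dtype=np.float64)
    post_times = np.asarray(post_times, dtype=np.float64)
    for arr, name in ((pre_times, "pre"), (post_times, "post")):
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            raise ValueError(f"{name} spike times must be sorted")
    events = np.unique(np.concatenate([pre_times, post_times]))
    r1 = o1 = r2 = 0.0
    w = float(np.clip(w0, 0.0, p.w_max))
    t_last = events[0] if events.size else 0.0
    out_t, out_w = [], []
    pre_set = set(pre_times.tolist())
    post_set = set(post_times.tolist())
    a3 = p.effective_a3_minus
    for t in events:
        dt = t - t_last
        if dt > 0:
            r1 *= math.exp(-dt / p.tau_plus)
            o1 *= math.exp(-dt / p.tau_minus)
            r2 *= math.exp(-dt / p.tau_x)
        t_last = t
        is_pre = t in pre_set
        is_post = t in post_set
        if is_post:
            w += p.a2_plus * r1
        if is_pre:
            w -= o1 * (p.a2_minus + a3 * r2)
        w = float(np.clip(w, 0.0, p.w_max))
        if is_post:
            o1 = o1 + 1.0 if p.interaction == "all-to-all" else 1.0
        if is_pre:
            if p.interaction == "all-to-all":
                r1, r2 = r1 + 1.0, r2 + 1.0
            else:
                r1, r2 = 1.0, 1.0
        out_t.append(t)
        out_w.append(w)
    return np.asarray(out_t), np.asarray(out_w)


def pairwise_params(p: PlasticityParams) -> PlasticityParams:
    """The purely pairwise counterpart of ``p`` (same amplitudes, mode switched)."""
    return replace(p, mode="pairwise")
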