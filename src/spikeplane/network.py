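"""Random delayed cortical network of Izhikevich neurons, with graded damage.

The network follows the classical polychronization setup: ``N`` quadratic
integrate-and-fire (Izhikevich) neurons, split into an excitatory majority and
an inhibitory minority, each projecting to ``Mc`` random targets through
synapses with integer axonal conduction delays.  Excitatory synapses are
plastic (see :mod:`spikeplane.plasticity`); inhibitory synapses are static.

Neuronal damage is modelled as a clamp: a damaged excitatory neuron keeps its
membrane potential constant at rest, never fires, and injects nothing into the
network — the standard abstraction of a cell that has lost the ability to
propagate action potentials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SPIKE_PEAK_MV",
    "NeuronParams",
    "IB",
    "LTS",
    "NetworkConfig",
    "SynapseTable",
    "DamageMask",
    "MembraneState",
    "SpikeRaster",
    "DriveConfig",
    "SimulationResult",
    "resting_state",
    "build_topology",
    "apply_damage",
    "integrate_step",
    "simulate",
]

#: Action-potential peak: spikes are detected above this value and recorded
#: traces are clamped to it (mV).
SPIKE_PEAK_MV = 30.0


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of the two-variable quadratic (Izhikevich) neuron.

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I,   du/dt = a (b v - u),
    with the reset v <- c, u <- u + d whenever v exceeds the 30 mV peak.

    Parameters
    ----------
    a : recovery time scale (1/ms); small values mean slow recovery.
    b : sensitivity of the recovery variable to subthreshold v (dimensionless).
    c : post-spike reset potential (mV).
    d : post-spike increment of the recovery variable.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"recovery time scale a must be positive, got {self.a}")
        if self.c >= SPIKE_PEAK_MV:
            raise ValueError(
                f"reset potential c={self.c} must lie below the {SPIKE_PEAK_MV} mV spike peak"
            )


#: Intrinsically bursting preset (excitatory population).
IB = NeuronParams(a=0.02, b=0.2, c=-55.0, d=4.0)
#: Low-threshold spiking preset (inhibitory population).
LTS = NeuronParams(a=0.02, b=0.25, c=-65.0, d=2.0)


def resting_state(p: NeuronParams) -> tuple[float, float]:
    """Stable resting fixed point (v_rest, u_rest) of the neuron at I = 0.

    Setting du/dt = 0 gives u = b v; substituting into dv/dt = 0 yields
    0.04 v^2 + (5 - b) v + 140 = 0.  The more negative root is the stable
    node (the other root is the spiking threshold); u_rest = b * v_rest.

    Raises
    ------
    ValueError
        If the quadratic has no real roots, i.e. no resting state exists for
        these parameters.
    """
    qa, qb, qc = 0.04, 5.0 - p.b, 140.0
    disc = qb * qb - 4.0 * qa * qc
    if disc < 0:
        raise ValueError(
            f"no resting state: 0.04 v^2 + {qb} v + 140 has complex roots (b={p.b})"
        )
    v_rest = (-qb - math.sqrt(disc)) / (2.0 * qa)
    return v_rest, p.b * v_rest


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the random delayed network.

    Defaults are the cortical-hypercolumn configuration: 1000 neurons
    (800 excitatory IB, 200 inhibitory LTS), each with ``m_out = 50``
    outgoing synapses so the connection probability is Mc/N = 0.05.
    Excitatory delays are uniform integers in ``delay_range_exc`` (ms);
    inhibitory delays are fixed at ``delay_inh`` (ms).
    """

    n_total: int = 1000
    n_exc: int = 800
    n_inh: int = 200
    m_out: int = 50
    delay_range_exc: tuple[int, int] = (1, 10)
    delay_inh: int = 1
    w_exc_init: float = 6.0
    w_inh_init: float = -5.0
    w_max: float = 10.0
    exc_params: NeuronParams = field(default=IB)
    inh_params: NeuronParams = field(default=LTS)

    def __post_init__(self) -> None:
        if self.n_total != self.n_exc + self.n_inh:
            raise ValueError(
                f"n_total={self.n_total} must equal n_exc+n_inh={self.n_exc + self.n_inh}"
            )
        if self.m_out < 1:
            raise ValueError("m_out must be at least 1")
        lo, hi = self.delay_range_exc
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid excitatory delay range {self.delay_range_exc}")
        if self.delay_inh < 1:
            raise ValueError("inhibitory delay must be >= 1 ms")
        if self.w_exc_init < 0 or self.w_exc_init > self.w_max:
            raise ValueError("initial excitatory weight must lie in [0, w_max]")
        if self.w_inh_init > 0:
            raise ValueError("initial inhibitory weight must be <= 0")

    @property
    def exc_indices(self) -> np.ndarray:
        return np.arange(self.n_exc)

    @property
    def inh_indices(self) -> np.ndarray:
        return np.arange(self.n_exc, self.n_total)

    def param_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-neuron (a, b, c, d) vectors in neuron-index order."""
        out = []
        for name in "abcd":
            e = getattr(self.exc_params, name)
            i = getattr(self.inh_params, name)
            out.append(np.r_[np.full(self.n_exc, e), np.full(self.n_inh, i)])
        return tuple(out)  # type: ignore[return-value]


@dataclass
class SynapseTable:
    """Directed weighted connectome with integer conduction delays.

    Rows are grouped by presynaptic neuron: the outgoing synapses of neuron
    ``j`` occupy rows ``[j*m_out, (j+1)*m_out)``, which :func:`simulate`
    exploits for O(1) outgoing lookup.
    """

    pre: np.ndarray
    post: np.ndarray
    w: np.ndarray
    delay: np.ndarray
    m_out: int

    def __post_init__(self) -> None:
        n = len(self.pre)
        if not (len(self.post) == len(self.w) == len(self.delay) == n):
            raise ValueError("synapse columns must have equal length")

    @property
    def n_synapses(self) -> int:
        return len(self.pre)

    def out_rows(self, neuron: int | np.ndarray) -> np.ndarray:
        """Row indices of the outgoing synapses of one or more neurons."""
        neuron = np.atleast_1d(neuron)
        return (neuron[:, None] * self.m_out + np.arange(self.m_out)).ravel()

    def incoming_index(self, n_total: int, pre_below: int | None = None):
        """CSR-style (indptr, rows) grouping synapse rows by postsynaptic neuron.

        If ``pre_below`` is given only rows whose presynaptic index is below it
        (e.g. excitatory, hence plastic, synapses) are included.
        """
        rows = np.arange(self.n_synapses)
        if pre_below is not None:
            rows = rows[self.pre < pre_below]
        order = np.argsort(self.post[rows], kind="stable")
        rows = rows[order]
        counts = np.bincount(self.post[rows], minlength=n_total)
        indptr = np.concatenate([[0], np.cumsum(counts)])
        return indptr, rows

    def copy(self) -> "SynapseTable":
        return SynapseTable(
            self.pre.copy(), self.post.copy(), self.w.copy(), self.delay.copy(), self.m_out
        )


def build_topology(cfg: NetworkConfig, rng: np.random.Generator) -> SynapseTable:
    """Draw the random delayed connectome.

    Every excitatory neuron projects to ``m_out`` distinct random targets
    anywhere in the network (no self-connections); every inhibitory neuron
    projects to ``m_out`` distinct random *excitatory* targets.  Excitatory
    delays are uniform integers in ``cfg.delay_range_exc``; inhibitory delays
    are ``cfg.delay_inh``.  Initial weights are ``w_exc_init`` / ``w_inh_init``.
    """
    n, mc = cfg.n_total, cfg.m_out
    if mc >= n:
        raise ValueError(f"m_out={mc} must be smaller than n_total={n} to draw distinct targets")
    if cfg.n_inh > 0 and mc > cfg.n_exc:
        raise ValueError(
            f"m_out={mc} exceeds the {cfg.n_exc} excitatory targets available to inhibitory neurons"
        )
    lo, hi = cfg.delay_range_exc
    pre = np.repeat(np.arange(n), mc)
    post = np.empty(n * mc, dtype=np.int64)
    delay = np.empty(n * mc, dtype=np.int64)
    w = np.empty(n * mc, dtype=np.float64)
    for j in range(n):
        sl = slice(j * mc, (j + 1) * mc)
        if j < cfg.n_exc:
            targets = rng.choice(n - 1, size=mc, replace=False)
            targets[targets >= j] += 1  # skip self
            post[sl] = targets
            delay[sl] = rng.integers(lo, hi + 1, size=mc)
            w[sl] = cfg.w_exc_init
        else:
            post[sl] = rng.choice(cfg.n_exc, size=mc, replace=False)
            delay[sl] = cfg.delay_inh
            w[sl] = cfg.w_inh_init
    return SynapseTable(pre=pre, post=post, w=w, delay=delay, m_out=mc)


@dataclass(frozen=True)
class DamageMask:
    """Set of damaged (constant-potential, silent) excitatory neurons."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", np.sort(idx))

    @property
    def n_damaged(self) -> int:
        return len(self.indices)

    def as_bool(self, n_total: int) -> np.ndarray:
        mask = np.zeros(n_total, dtype=bool)
        mask[self.indices] = True
        return mask


def apply_damage(cfg: NetworkConfig, n_damaged: int, rng: np.random.Generator) -> DamageMask:
    """Uniformly random subset of ``n_damaged`` excitatory neurons to clamp."""
    if not 0 <= n_damaged <= cfg.n_exc:
        raise ValueError(f"n_damaged={n_damaged} out of range [0, {cfg.n_exc}]")
    idx = rng.choice(cfg.n_exc, size=n_damaged, replace=False)
    return DamageMask(indices=idx)


@dataclass
class MembraneState:
    """Per-neuron membrane potential v (mV), recovery u, and input current I."""

    v: np.ndarray
    u: np.ndarray
    I: np.ndarray


def integrate_step(
    state: MembraneState,
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    dt: float = 1.0,
    damaged: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the membrane equations by one ``dt`` (ms) step, in place.

    Forward Euler with two dt/2 substeps for v and one dt step for u (the
    numerical scheme conventional for this neuron model at 1 ms resolution).
    Neurons whose v exceeds the 30 mV peak are reported as fired and reset
    (v <- c, u <- u + d); the returned record clamps their value to 30 mV.
    Damaged neurons are skipped entirely: v and u held constant, never fired.

    Returns
    -------
    fired : int array
        Indices of neurons that spiked during this step.
    v_record : float array
        Membrane potentials to store for this ms (spike peak clamped).
    """
    v, u, I = state.v, state.u, state.I
    if damaged is None:
        act = slice(None)
    else:
        act = ~damaged
    va = v[act]
    ua = u[act]
    Ia = I[act]
    half = 0.5 * dt
    for _ in range(2):
        va = va + half * (0.04 * va * va + 5.0 * va + 140.0 - ua + Ia)
    ua = ua + dt * a[act] * (b[act] * va - ua)
    if np.isnan(va).any() or np.isnan(ua).any():
        raise FloatingPointError("membrane integration blew up (non-finite state)")
    v[act] = va
    u[act] = ua
    v_record = np.minimum(v, SPIKE_PEAK_MV)
    above = v > SPIKE_PEAK_MV
    if damaged is not None:
        above &= ~damaged
    fired = np.flatnonzero(above)
    if fired.size:
        v[fired] = c[fired]
        u[fired] += d[fired]
    return fired, v_record


@dataclass
class SpikeRaster:
    """Spike events as parallel (time ms, neuron index) arrays."""

    times: np.ndarray
    neurons: np.ndarray
    duration: int

    def __len__(self) -> int:
        return len(self.times)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"t_ms": self.times, "neuron_id": self.neurons})


@dataclass(frozen=True)
class DriveConfig:
    """External input: 'random_pulse' injects ``amplitude`` mV-equivalent
    current into one uniformly random undamaged neuron each ms; 'constant'
    drives every undamaged neuron each ms; 'none' disables input."""

    kind: str = "random_pulse"
    amplitude: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in ("random_pulse", "constant", "none"):
            raise ValueError(f"unknown drive kind {self.kind!r}")


@dataclass
class SimulationResult:
    raster: SpikeRaster
    v_mv: np.ndarray  # (duration, n_total) float32, spike peak clamped
    synapses: SynapseTable
    damage: DamageMask


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate(
    cfg: NetworkConfig,
    duration: int,
    *,
    plasticity=None,
    damage: DamageMask | None = None,
    drive: DriveConfig = DriveConfig(),
    synapses: SynapseTable | None = None,
    rng_topology=0,
    rng_drive=1,
    v_init: np.ndarray | None = None,
    record: bool = True,
) -> SimulationResult:
    """Run the network for ``duration`` ms at 1 ms resolution.

    Per-ms loop: deliver delayed synaptic currents, add external drive,
    integrate the membrane equations, detect and reset spikes, apply the
    STDP rules of :mod:`spikeplane.plasticity` (if ``plasticity`` is given),
    and schedule the outgoing currents of the neurons that fired.  Membrane
    potentials of every neuron are stored each ms (float32, peak-clamped).

    Randomness flows through two named streams — topology and drive — so
    either can be varied independently; the damage mask is drawn separately
    by :func:`apply_damage`.  Identical configuration and seeds give a
    byte-identical raster and membrane record.
    """
    if duration < 1000:
        raise ValueError("duration must be at least 1000 ms (one analysis window)")
    n = cfg.n_total
    if synapses is None:
        synapses = build_topology(cfg, _as_rng(rng_topology))
    else:
        synapses = synapses.copy()
    if damage is None:
        damage = DamageMask(indices=np.empty(0, dtype=np.int64))
    if damage.n_damaged and damage.indices.max() >= cfg.n_exc:
        raise ValueError("damage mask contains non-excitatory indices")
    dmg_bool = damage.as_bool(n)
    undamaged = np.flatnonzero(~dmg_bool)

    a, b, c, d = cfg.param_arrays()
    v_rest = np.array([resting_state(NeuronParams(a[i], b[i], c[i], d[i]))[0] for i in range(n)])
    v = v_rest.copy() if v_init is None else np.asarray(v_init, dtype=np.float64).copy()
    u = b * v
    state = MembraneState(v=v, u=u, I=np.zeros(n))

    max_delay = int(synapses.delay.max())
    n_slots = max_delay + 1
    buffer = np.zeros((n_slots, n))

    drv = _as_rng(rng_drive)
    mc = synapses.m_out

    if plasticity is not None:
        from .plasticity import TraceState

        traces = TraceState.zeros(n)
        decay = traces.decay_factors(plasticity, 1.0)
        in_indptr, in_rows = synapses.incoming_index(n, pre_below=cfg.n_exc)
    else:
        traces = None

    v_trace = np.empty((duration, n), dtype=np.float32) if record else None
    spike_t: list[np.ndarray] = []
    spike_i: list[np.ndarray] = []

    syn_pre, syn_post, syn_w, syn_delay = (
        synapses.pre,
        synapses.post,
        synapses.w,
        synapses.delay,
    )
    arange_mc = np.arange(mc)

    for t in range(duration):
        slot = t % n_slots
        state.I = buffer[slot].copy()
        buffer[slot] = 0.0
        if drive.kind == "random_pulse":
            j = undamaged[drv.integers(len(undamaged))]
            state.I[j] += drive.amplitude
        elif drive.kind == "constant":
            state.I[undamaged] += drive.amplitude

        if traces is not None:
            traces.decay_inplace(decay)

        fired, v_rec = integrate_step(state, a, b, c, d, dt=1.0, damaged=dmg_bool)
        if record:
            v_trace[t] = v_rec
        if fired.size:
            spike_t.append(np.full(fired.size, t, dtype=np.int64))
            spike_i.append(fired)

            if traces is not None:
                fired_exc = fired[fired < cfg.n_exc]
                # LTP on synapses into every fired neuron (plastic rows only)
                chunks = [in_rows[in_indptr[i] : in_indptr[i + 1]] for i in fired]
                rows_in = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
                if rows_in.size:
                    syn_w[rows_in] += plasticity.a2_plus * traces.r1[syn_pre[rows_in]]
                # LTD on synapses out of every fired excitatory neuron;
                # r2 is read before the increment below (the epsilon offset)
                if fired_exc.size:
                    rows_out = (fired_exc[:, None] * mc + arange_mc).ravel()
                    a3 = plasticity.effective_a3_minus
                    syn_w[rows_out] -= traces.o1[syn_post[rows_out]] * (
                        plasticity.a2_minus + a3 * traces.r2[syn_pre[rows_out]]
                    )
                else:
                    rows_out = np.empty(0, dtype=np.int64)
                touched = rows_in if not rows_out.size else (
                    rows_out if not rows_in.size else np.concatenate([rows_in, rows_out])
                )
                if touched.size:
                    syn_w[touched] = np.clip(syn_w[touched], 0.0, plasticity.w_max)
                traces.increment(fired, fired_exc, plasticity.interaction)

            # schedule delayed currents with the weight at emission time
            rows = (fired[:, None] * mc + arange_mc).ravel()
            np.add.at(buffer, ((t + syn_delay[rows]) % n_slots, syn_post[rows]), syn_w[rows])

    times = np.concatenate(spike_t) if spike_t else np.empty(0, dtype=np.int64)
    ids = np.concatenate(spike_i) if spike_i else np.empty(0, dtype=np.int64)
    raster = SpikeRaster(times=times, neurons=ids, duration=duration)
    return SimulationResult(raster=raster, v_mv=v_trace, synapses=synapses, damage=damage)
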