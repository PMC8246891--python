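"""Simulation front end: stimulation programs, Poisson drive, LIF runs.

A run takes a :class:`~bgsim.network.NetworkInstance`, an optional
:class:`StimulationProgram` describing which extrinsic input neurons deviate
from their baseline Poisson rates, and integration settings.  All randomness
(input spike trains, activated-subset membership) is drawn up front from a
seeded generator, after which the integration kernel is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import params as P
from ._core import run_lif
from .network import NetworkInstance
from .params import ALPHA_HALF_DECAY, tau_from_half_time  # noqa: F401 (re-export)


def alpha_kernel(t, receptor: str, fixed: P.FixedParams | None = None,
                 half_time_mode: str = "peak-to-half"):
    """Alpha-function PSP at one synaptic site, f(t) = s*A*(t/tau)*exp(1-t/tau).

    Positive for the glutamatergic receptors (AMPA, NMDA), negative for
    GABA_A; the peak magnitude is the published amplitude A, reached at
    t = tau.  ``t`` is in ms and may be an array.
    """
    if receptor not in P.RECEPTORS:
        raise ValueError(f"unknown receptor {receptor!r}")
    fixed = fixed or P.FixedParams()
    amp = fixed.psp_amplitude[receptor]
    tau = tau_from_half_time(fixed.psp_half_time[receptor], half_time_mode)
    sign = -1.0 if receptor == "GABAA" else 1.0
    t = np.asarray(t, dtype=float)
    out = sign * amp * (t / tau) * np.exp(1.0 - t / tau)
    return np.where(t >= 0, out, 0.0)


@dataclass
class Activation:
    """A subset of one input population deviating from baseline.

    ``size`` is the number of activated generators (``None`` = whole pool);
    ``schedule`` is either a constant rate in Hz or a list of
    ``(t0_ms, t1_ms, rate_hz)`` segments (baseline outside the segments).
    """

    population: str
    channel: int | None = None   # None for the shared CM/Pf pool
    size: int | None = None
    schedule: float | list = 0.0

    def __post_init__(self):
        if self.population not in P.INPUT_POPULATIONS:
            raise ValueError(f"unknown input population {self.population!r}")
        segs = self.schedule if isinstance(self.schedule, list) else []
        for t0, t1, r in segs:
            if r < 0 or t1 < t0:
                raise ValueError("schedule segments need t1 >= t0 and rate >= 0")
        if isinstance(self.schedule, (int, float)) and self.schedule < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class StimulationProgram:
    """Collection of activations; unlisted generators fire at baseline."""

    activations: list = field(default_factory=list)  # list[Activation]


@dataclass
class SpikeRecord:
    """Per-neuron spike times plus run metadata.

    Spikes emitted during the warm-up window are retained but flagged by
    ``warmup_ms``; analysis helpers exclude them by default.
    """

    ids: np.ndarray
    times: np.ndarray       # ms, from simulation start
    duration_ms: float
    warmup_ms: float
    dt: float
    seed: int
    nucleus_of: np.ndarray
    channel_of: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def window_ms(self) -> float:
        """Length of the analysis window (after warm-up)."""
        return self.duration_ms - self.warmup_ms

    def population_ids(self, nucleus: str, channel: int | None = None) -> np.ndarray:
        code = P.NUCLEI.index(nucleus)
        mask = self.nucleus_of == code
        if channel is not None:
            mask &= self.channel_of == channel
        return np.flatnonzero(mask)

    def spikes_of(self, nucleus: str, channel: int | None = None,
                  include_warmup: bool = False):
        """(ids, times) of the spikes of one population in the analysis window."""
        members = self.population_ids(nucleus, channel)
        mask = np.isin(self.ids, members)
        if not include_warmup:
            mask &= self.times >= self.warmup_ms
        return self.ids[mask], self.times[mask]

    def spike_times(self, neuron_id: int, include_warmup: bool = False) -> np.ndarray:
        mask = self.ids == neuron_id
        if not include_warmup:
            mask &= self.times >= self.warmup_ms
        return self.times[mask]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# duration_ms={self.duration_ms} warmup_ms={self.warmup_ms} "
                     f"dt={self.dt} seed={self.seed}\n")
            fh.write("neuron_id\ttime_ms\n")
            for i, t in zip(self.ids, self.times):
                fh.write(f"{i}\t{t:.4f}\n")


def block_receptors(net: NetworkInstance, nucleus: str, receptors) -> NetworkInstance:
    """Return a view of the network with receptor types silenced in one nucleus.

    Emulates local antagonist injection: the contributions of the named
    receptor types onto neurons of ``nucleus`` are zeroed for the run; the
    rest of the circuit is untouched.
    """
    if nucleus not in P.NUCLEI:
        raise ValueError(f"unknown nucleus {nucleus!r}")
    receptors = tuple(receptors)
    if not receptors:
        raise ValueError("receptor subset must be non-empty")
    for r in receptors:
        if r not in P.RECEPTORS:
            raise ValueError(f"unknown receptor {r!r}")
    view = NetworkInstance(
        param=net.param, seed=net.seed,
        nucleus_of=net.nucleus_of, channel_of=net.channel_of,
        theta=net.theta, tau_m=net.tau_m, t_ref=net.t_ref, v_c=net.v_c,
        inp_population=net.inp_population, inp_channel=net.inp_channel,
        inp_rate=net.inp_rate, groups=net.groups,
        blocks=net.blocks + [(nucleus, receptors)],
        meta=dict(net.meta),
    )
    return view


def _block_matrix(net: NetworkInstance) -> np.ndarray:
    block = np.ones((net.n_neurons, 3))
    for nucleus, receptors in net.blocks:
        members = net.neurons_of(nucleus)
        for r in receptors:
            block[members, P.RECEPTORS.index(r)] = 0.0
    return block


def _csr(pre: np.ndarray, n_sources: int, *cols):
    """Sort synapse arrays by presynaptic id and build an index pointer."""
    order = np.argsort(pre, kind="stable")
    pre_sorted = pre[order]
    indptr = np.searchsorted(pre_sorted, np.arange(n_sources + 1)).astype(np.int64)
    return (indptr,) + tuple(c[order] for c in cols)


def _compile(net: NetworkInstance, dt: float):
    """Flatten synapse groups into CSR arrays for the integration kernel."""
    net_pre, net_post, net_w, net_d, net_k = [], [], [], [], []
    in_pre, in_post, in_w, in_d, in_k = [], [], [], [], []
    for g in net.groups.values():
        n = g.pre.size
        if n == 0:
            continue
        d_steps = max(1, int(round(g.delay / dt)))
        tgt = (in_pre, in_post, in_w, in_d, in_k) if g.from_inputs else \
              (net_pre, net_post, net_w, net_d, net_k)
        tgt[0].append(g.pre)
        tgt[1].append(g.post)
        tgt[2].append(np.full(n, g.weight))
        tgt[3].append(np.full(n, d_steps, dtype=np.int64))
        tgt[4].append(np.full(n, g.kind, dtype=np.int8))

    def cat(parts, dtype):
        return (np.concatenate(parts).astype(dtype) if parts
                else np.empty(0, dtype=dtype))

    s_pre = cat(net_pre, np.int64)
    s_post, s_w, s_d, s_k = (cat(net_post, np.int64), cat(net_w, np.float64),
                             cat(net_d, np.int64), cat(net_k, np.int8))
    i_pre = cat(in_pre, np.int64)
    i_post, i_w, i_d, i_k = (cat(in_post, np.int64), cat(in_w, np.float64),
                             cat(in_d, np.int64), cat(in_k, np.int8))

    syn = _csr(s_pre, net.n_neurons, s_post, s_w, s_d, s_k)
    inp = _csr(i_pre, net.n_inputs, i_post, i_w, i_d, i_k)
    delays = [1]
    if s_d.size:
        delays.append(int(s_d.max()))
    if i_d.size:
        delays.append(int(i_d.max()))
    D = max(delays) + 1
    return syn, inp, D


def _segment_rates(baseline: float, schedule, duration: float):
    """Flatten a schedule into contiguous (t0, t1, rate) segments over the run."""
    if not isinstance(schedule, list):
        return [(0.0, duration, float(schedule))]
    segs = []
    cursor = 0.0
    for t0, t1, rate in sorted(schedule):
        t0, t1 = max(0.0, t0), min(duration, t1)
        if t0 > cursor:
            segs.append((cursor, t0, baseline))
        if t1 > t0:
            segs.append((t0, t1, float(rate)))
        cursor = max(cursor, t1)
    if cursor < duration:
        segs.append((cursor, duration, baseline))
    return segs


def poisson_drive(net: NetworkInstance, program: StimulationProgram | None,
                  duration: float, dt: float, rng: np.random.Generator):
    """Generate one independent Poisson spike train per input generator.

    Returns event arrays (per-step pointer, generator id) for the kernel.
    Activated-subset membership is drawn once per run from ``rng``.
    """
    n_steps = int(round(duration / dt))
    rates = net.inp_rate.copy()
    overrides: dict[int, list] = {}

    for act in (program.activations if program else []):
        pool = net.inputs_of(act.population, act.channel)
        if pool.size == 0:
            raise ValueError(f"no generators for {act.population} channel {act.channel}")
        if act.size is None:
            subset = pool
        else:
            if act.size > pool.size:
                raise ValueError(
                    f"activated subset {act.size} exceeds pool of {pool.size} "
                    f"for {act.population}")
            subset = rng.choice(pool, size=act.size, replace=False)
        if isinstance(act.schedule, list):
            for g in subset:
                overrides[int(g)] = act.schedule
        else:
            rates[subset] = float(act.schedule)

    step_chunks, src_chunks = [], []

    def emit(ids: np.ndarray, t0: float, t1: float, rate: float):
        if rate <= 0 or t1 <= t0 or ids.size == 0:
            return
        lam = rate * (t1 - t0) / 1000.0
        counts = rng.poisson(lam, size=ids.size)
        total = int(counts.sum())
        if total == 0:
            return
        times = rng.uniform(t0, t1, size=total)
        steps = np.minimum((times / dt).astype(np.int64), n_steps - 1)
        step_chunks.append(steps)
        src_chunks.append(np.repeat(ids, counts))

    plain = np.array([g for g in range(net.n_inputs) if g not in overrides],
                     dtype=np.int64)
    # bulk generation for constant-rate generators, grouped by rate
    for rate in np.unique(rates[plain]) if plain.size else []:
        ids = plain[rates[plain] == rate]
        emit(ids, 0.0, duration, float(rate))
    for g, schedule in overrides.items():
        base = float(net.inp_rate[g])
        for t0, t1, rate in _segment_rates(base, schedule, duration):
            emit(np.array([g], dtype=np.int64), t0, t1, rate)

    if step_chunks:
        steps = np.concatenate(step_chunks)
        srcs = np.concatenate(src_chunks)
        order = np.argsort(steps, kind="stable")
        steps, srcs = steps[order], srcs[order]
    else:
        steps = np.empty(0, dtype=np.int64)
        srcs = np.empty(0, dtype=np.int64)
    ev_ptr = np.searchsorted(steps, np.arange(n_steps + 1)).astype(np.int64)
    return ev_ptr, srcs


def events_from_times(times_ms, sources, duration: float, dt: float):
    """Turn explicit (time, generator) pairs into kernel event arrays.

    Useful for driving a network with hand-crafted input spike trains
    instead of Poisson drive.
    """
    n_steps = int(round(duration / dt))
    times = np.asarray(times_ms, dtype=float)
    srcs = np.asarray(sources, dtype=np.int64)
    steps = np.minimum((times / dt).astype(np.int64), n_steps - 1)
    order = np.argsort(steps, kind="stable")
    steps, srcs = steps[order], srcs[order]
    ev_ptr = np.searchsorted(steps, np.arange(n_steps + 1)).astype(np.int64)
    return ev_ptr, srcs


def run(net: NetworkInstance, program: StimulationProgram | None = None,
        duration: float = 2000.0, warmup: float = 1000.0, dt: float = 0.1,
        seed: int = 0, events=None, watch: int | None = None) -> SpikeRecord:
    """Simulate the network and return its spike record.

    ``duration`` and ``warmup`` are in ms; the analysis window is
    ``[warmup, duration]``.  Fully reproducible for a fixed seed.
    ``events`` (from :func:`events_from_times`) replaces the Poisson drive
    with explicit input spikes; ``watch`` records one neuron's membrane
    potential trace into ``record.meta["v_watch"]``.
    """
    if duration <= warmup or warmup < 0:
        raise ValueError("need duration > warmup >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")

    fixed = net.param.fixed
    mode = fixed.half_time_mode
    tau_syn = np.array([tau_from_half_time(fixed.psp_half_time[r], mode)
                        for r in P.RECEPTORS])
    dec = np.exp(-dt / tau_syn)
    lam = dt / tau_syn
    amp = np.array([fixed.psp_amplitude["AMPA"],
                    fixed.psp_amplitude["NMDA"],
                    -fixed.psp_amplitude["GABAA"]]) * math.e

    n_steps = int(round(duration / dt))
    m_decay = np.exp(-dt / net.tau_m)
    ref_steps = np.maximum(1, np.round(net.t_ref / dt)).astype(np.int64)

    syn, inp, D = _compile(net, dt)
    rng = np.random.default_rng(seed)
    if events is None:
        ev_ptr, ev_src = poisson_drive(net, program, duration, dt, rng)
    else:
        ev_ptr, ev_src = events
    block = _block_matrix(net)

    # refractory upper bound on the spike count: overflow-free preallocation
    cap = int(np.sum(n_steps // ref_steps + 1))
    rec_ids = np.empty(cap, dtype=np.int64)
    rec_times = np.empty(cap, dtype=np.float64)

    watch_idx = -1 if watch is None else int(watch)
    v_watch = np.zeros(n_steps if watch_idx >= 0 else 1)

    n_rec = run_lif(n_steps, dt,
                    net.v_c, net.theta, m_decay, ref_steps,
                    syn[0], syn[1], syn[2], syn[3], syn[4],
                    inp[0], inp[1], inp[2], inp[3], inp[4],
                    ev_ptr, ev_src, block, dec, lam, amp, D,
                    rec_ids, rec_times, watch_idx, v_watch)

    meta = {"blocks": list(net.blocks), "build_seed": net.seed}
    if watch_idx >= 0:
        meta["v_watch"] = v_watch

    return SpikeRecord(
        ids=rec_ids[:n_rec].copy(), times=rec_times[:n_rec].copy(),
        duration_ms=float(duration), warmup_ms=float(warmup), dt=float(dt),
        seed=int(seed),
        nucleus_of=net.nucleus_of.copy(), channel_of=net.channel_of.copy(),
        meta=meta,
    )
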