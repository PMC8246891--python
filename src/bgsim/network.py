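"""Stochastic realization of a network instance from a parameterization.

Connectivity follows the anatomical bookkeeping of the source model: the
expected number of synapses a target neuron receives from population Y is

    nu(Y->X) = P(Y->X) * (n_Y / n_X) * alpha(Y->X)

and, with redundancy rho synapses per connected axon, each target neuron is
wired to nu/rho distinct source neurons (the fractional part is realized as a
Bernoulli draw of one extra source).  Focused projections draw sources from
the target's own channel, diffuse ones from all channels.  Each realized
connection carries the weight w = gamma * rho, where gamma is the passive
dendritic attenuation of a synapse placed at fractional position p on a
finite cable of electrotonic length L.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import params as P
from .params import Parameterization, ProjectionSpec, expected_synapse_count

log = logging.getLogger(__name__)

GLUT, GABA = 0, 1

# input-generator population codes
INP_CODES = {"CSN": 0, "PTN": 1, "CMPf": 2, "VIRT": 3}


def synapse_count(fraction: float, n_source: float, n_target: float, alpha: float) -> float:
    """Expected synapses per target neuron, nu = P * (n_Y / n_X) * alpha."""
    if n_target <= 0:
        raise ValueError("target population size must be > 0")
    if fraction < 0 or n_source < 0 or alpha < 0:
        raise ValueError("all inputs must be >= 0")
    return fraction * (n_source / n_target) * alpha


def source_neuron_count(nu: float, rho: float, rng: np.random.Generator) -> int:
    """Number of distinct presynaptic neurons wired to one target neuron.

    Returns floor(nu/rho), plus one more with probability frac(nu/rho), so the
    expectation is exactly nu/rho.
    """
    if nu < 0:
        raise ValueError("nu must be >= 0")
    if rho < 1:
        raise ValueError("redundancy must be >= 1")
    ratio = nu / rho
    base = int(math.floor(ratio))
    frac = ratio - base
    if frac > 0 and rng.random() < frac:
        base += 1
    return base


def electrotonic_length(l_um: float, d_um: float, r_i: float = P.R_I,
                        r_m: float = P.R_M) -> float:
    """Dimensionless electrotonic length L = l * sqrt((4/d) * (Ri/Rm)).

    ``l_um`` and ``d_um`` are in micrometres, ``r_i`` in ohm*cm and ``r_m`` in
    ohm*cm^2; lengths are converted to cm so L is dimensionless.
    """
    if l_um < 0:
        raise ValueError("dendritic length must be >= 0")
    if d_um <= 0 or r_i <= 0 or r_m <= 0:
        raise ValueError("diameter and resistivities must be > 0")
    l_cm = l_um * 1e-4
    d_cm = d_um * 1e-4
    return l_cm * math.sqrt((4.0 / d_cm) * (r_i / r_m))


def attenuation(L: float, p: float) -> float:
    """Dendritic attenuation gamma = cosh(L*(1-p)) / cosh(L).

    p = 0 places the synapse on the soma (gamma = 1); p = 1 on the distal tip
    (gamma = 1/cosh(L)).  gamma decreases monotonically in both p and L.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("synapse location p must be in [0, 1]")
    if L < 0:
        raise ValueError("electrotonic length must be >= 0")
    return math.cosh(L * (1.0 - p)) / math.cosh(L)


@dataclass
class Disruption:
    """A structural circuit manipulation applied at build time.

    kinds:
      - ``poissonify_projection``: replace each realized synapse's presynaptic
        spike source by an independent Poisson generator at ``rate`` Hz
        (same synapse count, weights and delays).
      - ``make_focused`` / ``make_diffuse``: rebuild the named projection's
        topology, leaving the in-degree expectation unchanged.
      - ``block_receptor``: zero the named receptor contributions onto one
        nucleus for the run (resolved at simulation time).
    """

    kind: str
    source: str = ""
    target: str = ""
    rate: float = 0.0
    nucleus: str = ""
    receptors: tuple = ()

    def __post_init__(self):
        kinds = ("poissonify_projection", "make_focused", "make_diffuse", "block_receptor")
        if self.kind not in kinds:
            raise ValueError(f"unknown disruption kind {self.kind!r}")
        if self.kind == "block_receptor":
            if self.nucleus not in P.NUCLEI or not self.receptors:
                raise ValueError("block_receptor needs a nucleus and a receptor subset")
        else:
            if not self.source or not self.target:
                raise ValueError(f"{self.kind} needs a projection (source, target)")
        if self.kind == "poissonify_projection" and self.rate < 0:
            raise ValueError("replacement rate must be >= 0")


@dataclass
class SynapseGroup:
    """All realized synapses of one projection (shared weight/delay/kind)."""

    projection: str
    pre: np.ndarray            # source neuron or input-generator ids
    post: np.ndarray           # target neuron ids (global)
    weight: float              # gamma * rho
    delay: float               # ms
    kind: int                  # GLUT or GABA
    from_inputs: bool          # pre indexes the input-generator table


@dataclass
class NetworkInstance:
    """Realized neurons, input generators and synapse table."""

    param: Parameterization
    seed: int
    nucleus_of: np.ndarray     # per-neuron nucleus code (index into params.NUCLEI)
    channel_of: np.ndarray     # per-neuron channel index
    theta: np.ndarray
    tau_m: np.ndarray
    t_ref: np.ndarray
    v_c: np.ndarray
    inp_population: np.ndarray  # per-generator population code
    inp_channel: np.ndarray     # per-generator channel (-1 = shared pool)
    inp_rate: np.ndarray        # per-generator baseline rate (Hz)
    groups: dict = field(default_factory=dict)   # projection name -> SynapseGroup
    blocks: list = field(default_factory=list)   # (nucleus, receptors) pairs
    meta: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.nucleus_of.size

    @property
    def n_inputs(self) -> int:
        return self.inp_population.size

    def neurons_of(self, nucleus: str, channel: int | None = None) -> np.ndarray:
        """Global ids of the neurons of one nucleus (optionally one channel)."""
        code = P.NUCLEI.index(nucleus)
        mask = self.nucleus_of == code
        if channel is not None:
            mask &= self.channel_of == channel
        return np.flatnonzero(mask)

    def inputs_of(self, population: str, channel: int | None = None) -> np.ndarray:
        code = INP_CODES[population]
        mask = self.inp_population == code
        if channel is not None:
            mask &= self.inp_channel == channel
        return np.flatnonzero(mask)

    def neuron_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "neuron_id": np.arange(self.n_neurons),
            "nucleus": [P.NUCLEI[c] for c in self.nucleus_of],
            "channel": self.channel_of,
        })

    def synapse_table(self) -> pd.DataFrame:
        frames = []
        for g in self.groups.values():
            frames.append(pd.DataFrame({
                "projection": g.projection,
                "pre": g.pre,
                "post": g.post,
                "weight": g.weight,
                "delay_ms": g.delay,
                "transmitter": "glutamate" if g.kind == GLUT else "GABA",
                "pre_is_input": g.from_inputs,
            }))
        return pd.concat(frames, ignore_index=True)

    def export(self, neuron_path, synapse_path) -> None:
        """Write neuron and synapse tables as TSV with the build seed recorded."""
        nt = self.neuron_table()
        st = self.synapse_table()
        for path, table in ((neuron_path, nt), (synapse_path, st)):
            with open(path, "w") as fh:
                fh.write(f"# seed={self.seed}\n")
                table.to_csv(fh, sep="\t", index=False)


def _neuron_arrays(param: Parameterization):
    """Lay out neurons nucleus-major, channel-minor; return id arrays."""
    codes, channels, theta, tau_m, t_ref, v_c = [], [], [], [], [], []
    for code, name in enumerate(P.NUCLEI):
        spec = param.nucleus(name)
        for ch in range(param.n_channels):
            n = spec.n_per_channel
            codes.append(np.full(n, code, dtype=np.int8))
            channels.append(np.full(n, ch, dtype=np.int16))
            theta.append(np.full(n, spec.theta))
            tau_m.append(np.full(n, spec.tau_m))
            t_ref.append(np.full(n, spec.t_ref))
            v_c.append(np.full(n, spec.v_c))
    return (np.concatenate(codes), np.concatenate(channels),
            np.concatenate(theta), np.concatenate(tau_m),
            np.concatenate(t_ref), np.concatenate(v_c))


def _input_arrays(param: Parameterization):
    pool = param.scaled_input_pool
    pops, chans, rates = [], [], []
    for name in ("CSN", "PTN"):
        for ch in range(param.n_channels):
            pops.append(np.full(pool, INP_CODES[name], dtype=np.int8))
            chans.append(np.full(pool, ch, dtype=np.int16))
            rates.append(np.full(pool, param.fixed.input_base_rate[name]))
    pops.append(np.full(pool, INP_CODES["CMPf"], dtype=np.int8))
    chans.append(np.full(pool, -1, dtype=np.int16))
    rates.append(np.full(pool, param.fixed.input_base_rate["CMPf"]))
    return np.concatenate(pops), np.concatenate(chans), np.concatenate(rates)


def _projection_weight(param: Parameterization, proj: ProjectionSpec) -> float:
    spec = param.nucleus(proj.target)
    L = electrotonic_length(spec.dendrite_length, spec.dendrite_diameter,
                            param.fixed.r_i, param.fixed.r_m)
    return attenuation(L, proj.p) * proj.rho


def _draw_sources(pool: np.ndarray, k: int, rng: np.random.Generator,
                  warned: set, projection: str) -> np.ndarray:
    if k <= pool.size:
        return rng.choice(pool, size=k, replace=False)
    if projection not in warned:
        log.warning("projection %s: %d sources requested from pool of %d; "
                    "sampling with replacement", projection, k, pool.size)
        warned.add(projection)
    return rng.choice(pool, size=k, replace=True)


def _realize_projection(param, proj, net, rng, warned) -> SynapseGroup:
    nu = expected_synapse_count(param, proj)
    from_inputs = proj.source in P.INPUT_POPULATIONS
    targets = net.neurons_of(proj.target)
    same_nucleus = (not from_inputs) and proj.source == proj.target

    # per-channel source pools
    if from_inputs:
        pools = {ch: net.inputs_of(proj.source, None if proj.source == "CMPf" else ch)
                 for ch in range(param.n_channels)}
        all_pool = net.inputs_of(proj.source)
    else:
        pools = {ch: net.neurons_of(proj.source, ch) for ch in range(param.n_channels)}
        all_pool = net.neurons_of(proj.source)

    pre_out, post_out = [], []
    for post in targets:
        ch = int(net.channel_of[post])
        pool = pools[ch] if proj.pattern == "focused" else all_pool
        if same_nucleus:
            pool = pool[pool != post]
        k = source_neuron_count(nu, proj.rho, rng)
        if k == 0 or pool.size == 0:
            continue
        src = _draw_sources(pool, k, rng, warned, proj.name)
        pre_out.append(src)
        post_out.append(np.full(src.size, post, dtype=np.int64))

    pre = np.concatenate(pre_out) if pre_out else np.empty(0, dtype=np.int64)
    post = np.concatenate(post_out) if post_out else np.empty(0, dtype=np.int64)
    return SynapseGroup(
        projection=proj.name,
        pre=pre.astype(np.int64),
        post=post,
        weight=_projection_weight(param, proj),
        delay=proj.delay,
        kind=GLUT if proj.transmitter == "glutamate" else GABA,
        from_inputs=from_inputs,
    )


def _poissonify(net: NetworkInstance, group: SynapseGroup, rate: float) -> SynapseGroup:
    """Replace each synapse's spike source by an independent Poisson generator."""
    n_new = group.pre.size
    first = net.n_inputs
    net.inp_population = np.concatenate(
        [net.inp_population, np.full(n_new, INP_CODES["VIRT"], dtype=np.int8)])
    net.inp_channel = np.concatenate(
        [net.inp_channel, np.full(n_new, -1, dtype=np.int16)])
    net.inp_rate = np.concatenate([net.inp_rate, np.full(n_new, float(rate))])
    return SynapseGroup(
        projection=group.projection,
        pre=np.arange(first, first + n_new, dtype=np.int64),
        post=group.post.copy(),
        weight=group.weight,
        delay=group.delay,
        kind=group.kind,
        from_inputs=True,
    )


def build_network(param: Parameterization, disruptions: list | None = None,
                  seed: int = 0) -> NetworkInstance:
    """Realize a network instance; deterministic for a fixed seed.

    Structural disruptions (``make_focused``/``make_diffuse``/``poissonify``)
    are applied during construction; ``block_receptor`` disruptions are
    recorded and resolved when the network is simulated.
    """
    P_mod = param.copy()
    disruptions = list(disruptions or [])
    blocks = []
    poissonify = {}
    for d in disruptions:
        if d.kind == "block_receptor":
            blocks.append((d.nucleus, tuple(d.receptors)))
        elif d.kind in ("make_focused", "make_diffuse"):
            proj = P_mod.projection(d.source, d.target)
            proj.pattern = "focused" if d.kind == "make_focused" else "diffuse"
        else:
            if not P_mod.has_projection(d.source, d.target):
                raise KeyError(f"unknown projection {d.source}->{d.target}")
            poissonify[(d.source, d.target)] = d.rate

    rng = np.random.default_rng(seed)
    codes, channels, theta, tau_m, t_ref, v_c = _neuron_arrays(P_mod)
    inp_pop, inp_ch, inp_rate = _input_arrays(P_mod)

    net = NetworkInstance(
        param=P_mod, seed=int(seed),
        nucleus_of=codes, channel_of=channels,
        theta=theta, tau_m=tau_m, t_ref=t_ref, v_c=v_c,
        inp_population=inp_pop, inp_channel=inp_ch, inp_rate=inp_rate,
        blocks=blocks,
        meta={"disruptions": [d.kind for d in disruptions]},
    )

    warned: set = set()
    for proj in P_mod.projections:
        group = _realize_projection(P_mod, proj, net, rng, warned)
        if (proj.source, proj.target) in poissonify:
            group = _poissonify(net, group, poissonify[(proj.source, proj.target)])
        net.groups[proj.name] = group
    return net


def realized_in_degrees(net: NetworkInstance, source: str, target: str) -> np.ndarray:
    """Distinct-source count per target neuron for one projection."""
    group = net.groups[f"{source}->{target}"]
    targets = net.neurons_of(target)
    counts = np.zeros(targets.size, dtype=np.int64)
    idx = {int(t): i for i, t in enumerate(targets)}
    for post in group.post:
        counts[idx[int(post)]] += 1
    return counts
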