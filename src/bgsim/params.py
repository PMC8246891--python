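"""Model parameterization: fixed constants, optimized ranges, sampling and I/O.

The simulator describes five basal ganglia nuclei (MSN, FSI, STN, GPe, GPi)
receiving three extrinsic excitatory inputs (CSN, PTN, CM/Pf).  A
:class:`Parameterization` bundles everything needed to realize one concrete
network: per-nucleus neuron counts, firing thresholds, tonic inputs, membrane
constants, dendritic cable geometry, and one :class:`ProjectionSpec` per edge
of the wiring diagram (bouton counts, projection fractions, synapse locations,
redundancy, focused/diffuse topology, transmitter, delay).

Anatomical plausibility is a *by construction* property: a parameterization is
plausible when every ranged parameter (bouton count alpha, synapse location p,
firing threshold theta) lies inside its optimized interval.  ``validate_anatomy``
checks exactly that; ``sample_parameterization`` draws a parameterization
uniformly inside the ranges, which by construction always validates.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import brentq

NUCLEI = ("MSN", "FSI", "STN", "GPe", "GPi")
INPUT_POPULATIONS = ("CSN", "PTN", "CMPf")
RECEPTORS = ("AMPA", "NMDA", "GABAA")

#: neurons per channel (1/5000 of the primate totals)
NEURONS_PER_CHANNEL = {"MSN": 10576, "FSI": 212, "STN": 32, "GPe": 100, "GPi": 56}

#: size of each extrinsic input pool (per channel for CSN/PTN, shared for CM/Pf)
INPUT_POOL_SIZE = 12000

#: baseline Poisson rates of the extrinsic inputs (Hz)
INPUT_BASE_RATE = {"CSN": 2.0, "PTN": 15.0, "CMPf": 4.0}

#: maximal rates used in stimulation protocols (Hz)
INPUT_MAX_RATE = {"CSN": 20.0, "PTN": 46.0, "CMPf": 34.0}

#: PSP peak amplitudes (mV) and half-times (ms) per receptor
PSP_AMPLITUDE = {"AMPA": 1.0, "NMDA": 0.025, "GABAA": 0.25}
PSP_HALF_TIME = {"AMPA": 5.0, "NMDA": 100.0, "GABAA": 5.0}

#: membrane resistance (ohm cm^2) and intracellular resistivity (ohm cm)
R_M = 20000.0
R_I = 200.0

#: dendritic extent (um) and mean diameter (um)
DENDRITE_LENGTH = {"MSN": 619.0, "FSI": 961.0, "STN": 750.0, "GPe": 865.0, "GPi": 1132.0}
DENDRITE_DIAMETER = {"MSN": 1.0, "FSI": 1.5, "STN": 1.5, "GPe": 1.7, "GPi": 1.2}

#: membrane time constants (ms) and absolute refractory period (ms)
TAU_M = {"MSN": 13.0, "FSI": 16.0, "STN": 26.0, "GPe": 14.0, "GPi": 14.0}
T_REF = 2.0

#: fraction of source neurons projecting (edges not listed project at 100%)
PROJECTION_FRACTION = {
    ("MSN", "GPi"): 0.82,
    ("STN", "GPe"): 0.83,
    ("STN", "GPi"): 0.72,
    ("STN", "MSN"): 0.17,
    ("STN", "FSI"): 0.17,
    ("GPe", "GPe"): 0.84,
    ("GPe", "GPi"): 0.84,
    ("GPe", "MSN"): 0.16,
    ("GPe", "FSI"): 0.16,
}

#: synapses per connected source axon on one target dendritic tree
REDUNDANCY = 3.0

#: optimized bouton-count intervals alpha_(Y->X)
ALPHA_RANGE = {
    ("MSN", "MSN"): (209.0, 627.0),
    ("FSI", "MSN"): (2172.0, 4928.0),
    ("FSI", "FSI"): (26.0, 140.0),
    ("MSN", "GPe"): (171.0, 203.0),
    ("MSN", "GPi"): (166.0, 288.0),
    ("STN", "GPe"): (291.0, 454.0),
    ("STN", "GPi"): (159.0, 239.0),
    ("STN", "MSN"): (0.0, 109.0),
    ("STN", "FSI"): (0.0, 92.0),
    ("GPe", "GPe"): (37.0, 38.0),
    ("GPe", "GPi"): (16.0, 17.0),
    ("GPe", "STN"): (19.0, 20.0),
    ("CMPf", "MSN"): (5.0, 15.0),
    ("CMPf", "FSI"): (2.0, 4.0),
    ("CMPf", "STN"): (0.0, 1.0),
    ("CMPf", "GPe"): (0.0, 1.0),
    ("CMPf", "GPi"): (0.0, 1.0),
    ("CSN", "MSN"): (248.0, 313.0),
    ("CSN", "FSI"): (4.0, 9.0),
    ("PTN", "MSN"): (4.0, 9.0),
    ("PTN", "FSI"): (0.0, 1.0),
    # no printed interval for the hyperdirect bouton count; the re-scaled
    # afferent band 0-1 (cf. PTN->FSI, CMPf->STN) is adopted as default
    ("PTN", "STN"): (0.0, 1.0),
}

#: optimized synapse-location intervals p_(Y->X), as fractions of dendrite length
P_RANGE = {
    ("CSN", "MSN"): (0.80, 1.00),
    ("PTN", "MSN"): (0.76, 1.00),
    ("CSN", "FSI"): (0.80, 0.96),
    ("PTN", "STN"): (0.63, 1.00),
    ("MSN", "MSN"): (0.64, 0.88),
    ("MSN", "GPe"): (0.48, 0.60),
    ("MSN", "GPi"): (0.30, 0.59),
    ("FSI", "MSN"): (0.00, 0.19),
    ("STN", "GPe"): (0.23, 0.53),
    ("STN", "GPi"): (0.45, 0.59),
    ("GPe", "STN"): (0.28, 0.60),
    ("GPe", "GPe"): (0.00, 0.01),
    ("GPe", "GPi"): (0.00, 0.15),
    ("CMPf", "MSN"): (0.26, 0.59),
    ("CMPf", "FSI"): (0.00, 0.17),
    # locations not printed for the remaining edges: full dendrite by default
    ("FSI", "FSI"): (0.00, 1.00),
    ("STN", "MSN"): (0.00, 1.00),
    ("STN", "FSI"): (0.00, 1.00),
    ("CMPf", "STN"): (0.00, 1.00),
    ("CMPf", "GPe"): (0.00, 1.00),
    ("CMPf", "GPi"): (0.00, 1.00),
    ("PTN", "FSI"): (0.00, 1.00),
}

#: optimized firing-threshold intervals (mV above rest)
THETA_RANGE = {
    "MSN": (28.0, 30.0),
    "FSI": (11.0, 21.0),
    "STN": (24.0, 27.0),
    "GPe": (6.0, 12.0),
    "GPi": (5.0, 7.0),
}

#: target rest rates (Hz) used to initialize tonic inputs when sampling a
#: parameterization: centre of the plausible striatal bands, typical awake
#: primate values for the pallidum and STN
TARGET_REST_RATE = {"MSN": 0.3, "FSI": 10.0, "STN": 20.0, "GPe": 60.0, "GPi": 70.0}

#: half-width (mV) of the uniform jitter applied around the steady-state
#: tonic-input estimate when sampling
VC_JITTER = 0.5

#: fluctuation margin (mV) subtracted from the deterministic mean-drive
#: inversion: synaptic shot noise lifts firing above the constant-drive
#: prediction, most strongly for the near-threshold striatal populations
VC_MARGIN = {"MSN": 4.0, "FSI": 1.0, "STN": 1.5, "GPe": 0.0, "GPi": 0.0}

#: transmitter released by each source population
TRANSMITTER = {
    "MSN": "GABA",
    "FSI": "GABA",
    "GPe": "GABA",
    "STN": "glutamate",
    "CSN": "glutamate",
    "PTN": "glutamate",
    "CMPf": "glutamate",
}

#: default channel topology per source population
_DIFFUSE_SOURCES = {"STN", "CMPf"}

#: the 12 internal edges of the wiring diagram
INTERNAL_EDGES = (
    ("MSN", "MSN"), ("MSN", "GPe"), ("MSN", "GPi"),
    ("FSI", "MSN"), ("FSI", "FSI"),
    ("STN", "MSN"), ("STN", "FSI"), ("STN", "GPe"), ("STN", "GPi"),
    ("GPe", "STN"), ("GPe", "GPe"), ("GPe", "GPi"),
)

#: the 10 afferent edges from the extrinsic input populations
AFFERENT_EDGES = (
    ("CSN", "MSN"), ("CSN", "FSI"),
    ("PTN", "MSN"), ("PTN", "FSI"), ("PTN", "STN"),
    ("CMPf", "MSN"), ("CMPf", "FSI"), ("CMPf", "STN"), ("CMPf", "GPe"), ("CMPf", "GPi"),
)

DEFAULT_EDGES = INTERNAL_EDGES + AFFERENT_EDGES

DEFAULT_DELAY_MS = 1.0


@dataclass
class FixedParams:
    """Constants shared by every parameterization (literature-derived)."""

    neurons_per_channel: dict = field(default_factory=lambda: dict(NEURONS_PER_CHANNEL))
    input_pool_size: int = INPUT_POOL_SIZE
    input_base_rate: dict = field(default_factory=lambda: dict(INPUT_BASE_RATE))
    psp_amplitude: dict = field(default_factory=lambda: dict(PSP_AMPLITUDE))
    psp_half_time: dict = field(default_factory=lambda: dict(PSP_HALF_TIME))
    r_m: float = R_M
    r_i: float = R_I
    dendrite_length: dict = field(default_factory=lambda: dict(DENDRITE_LENGTH))
    dendrite_diameter: dict = field(default_factory=lambda: dict(DENDRITE_DIAMETER))
    tau_m: dict = field(default_factory=lambda: dict(TAU_M))
    t_ref: float = T_REF
    #: reading of the PSP half-time: "peak-to-half" (default) or "log2"
    half_time_mode: str = "peak-to-half"

    def validate(self) -> None:
        for name, n in self.neurons_per_channel.items():
            if n < 1:
                raise ValueError(f"neuron count for {name} must be >= 1")
        if self.input_pool_size < 1:
            raise ValueError("input pool size must be >= 1")
        for pop, r in self.input_base_rate.items():
            if r < 0:
                raise ValueError(f"baseline rate for {pop} must be >= 0")
        for rec in RECEPTORS:
            if self.psp_amplitude[rec] <= 0 or self.psp_half_time[rec] <= 0:
                raise ValueError(f"PSP amplitude/half-time for {rec} must be > 0")
        for name in NUCLEI:
            if self.tau_m[name] <= 0:
                raise ValueError(f"tau_m for {name} must be > 0")


@dataclass
class NucleusSpec:
    """One simulated nucleus: size, excitability and dendritic cable geometry.

    Resting potential is fixed at 0 mV by convention, so ``theta`` and ``v_c``
    are expressed relative to rest.
    """

    name: str
    n_per_channel: int
    theta: float          # firing threshold (mV)
    v_c: float            # tonic input (mV)
    tau_m: float          # membrane time constant (ms)
    t_ref: float = T_REF  # refractory period (ms)
    dendrite_length: float = 0.0    # um
    dendrite_diameter: float = 1.0  # um

    def validate(self) -> None:
        if self.name not in NUCLEI:
            raise ValueError(f"unknown nucleus {self.name!r}")
        if self.n_per_channel < 1:
            raise ValueError(f"{self.name}: n per channel must be >= 1")
        if self.theta <= 0:
            raise ValueError(f"{self.name}: firing threshold must be > 0")
        if self.tau_m <= 0:
            raise ValueError(f"{self.name}: tau_m must be > 0")
        if self.dendrite_length <= 0 or self.dendrite_diameter <= 0:
            raise ValueError(f"{self.name}: dendrite geometry must be > 0")


@dataclass
class ProjectionSpec:
    """One edge of the wiring diagram.

    ``alpha`` is the mean bouton count per source axon in the target nucleus,
    ``fraction`` the proportion of source neurons projecting, ``p`` the
    fractional dendritic location of the synapses on the target dendrite,
    ``rho`` the redundancy (synapses per connected axon).
    """

    source: str
    target: str
    alpha: float
    fraction: float = 1.0
    p: float = 0.5
    rho: float = REDUNDANCY
    pattern: str = "focused"       # focused | diffuse
    transmitter: str = "glutamate"  # glutamate | GABA
    delay: float = DEFAULT_DELAY_MS  # ms

    @property
    def name(self) -> str:
        return f"{self.source}->{self.target}"

    def validate(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"{self.name}: alpha must be >= 0")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"{self.name}: projection fraction must be in [0,1]")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"{self.name}: synapse location must be in [0,1]")
        if self.rho < 1.0:
            raise ValueError(f"{self.name}: redundancy must be >= 1")
        if self.pattern not in ("focused", "diffuse"):
            raise ValueError(f"{self.name}: pattern must be focused or diffuse")
        if self.transmitter not in ("glutamate", "GABA"):
            raise ValueError(f"{self.name}: unknown transmitter {self.transmitter!r}")
        if self.delay < 0:
            raise ValueError(f"{self.name}: delay must be >= 0")


@dataclass
class Parameterization:
    """A complete model instance: constants, nuclei, projections, topology."""

    fixed: FixedParams = field(default_factory=FixedParams)
    nuclei: list = field(default_factory=list)        # list[NucleusSpec]
    projections: list = field(default_factory=list)   # list[ProjectionSpec]
    n_channels: int = 1
    scale: float = 1.0
    meta: dict = field(default_factory=dict)

    def nucleus(self, name: str) -> NucleusSpec:
        for spec in self.nuclei:
            if spec.name == name:
                return spec
        raise KeyError(f"nucleus {name!r} not in parameterization")

    def projection(self, source: str, target: str) -> ProjectionSpec:
        for spec in self.projections:
            if spec.source == source and spec.target == target:
                return spec
        raise KeyError(f"projection {source}->{target} not in parameterization")

    def has_projection(self, source: str, target: str) -> bool:
        return any(s.source == source and s.target == target for s in self.projections)

    @property
    def scaled_input_pool(self) -> int:
        """Input-pool size at the current population scale."""
        return max(1, int(round(self.fixed.input_pool_size * self.scale)))

    def population_size(self, name: str) -> int:
        """Total size of a population across channels (shared pool for CM/Pf)."""
        if name in INPUT_POPULATIONS:
            pool = self.scaled_input_pool
            return pool if name == "CMPf" else pool * self.n_channels
        return self.nucleus(name).n_per_channel * self.n_channels

    def copy(self) -> "Parameterization":
        return copy.deepcopy(self)


@dataclass
class ValidationReport:
    """Outcome of an anatomical-plausibility check."""

    violations: list = field(default_factory=list)  # (parameter, value, low, high)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "anatomical objective satisfied"
        lines = [f"{len(self.violations)} parameter(s) outside optimized ranges:"]
        for name, value, low, high in self.violations:
            lines.append(f"  {name} = {value:g} outside [{low:g}, {high:g}]")
        return "\n".join(lines)


class AnatomyError(ValueError):
    """Raised in strict mode when the anatomical objective is violated."""


def _check_structure(param: Parameterization) -> None:
    present = {s.name for s in param.nuclei}
    missing = [n for n in NUCLEI if n not in present]
    if missing:
        raise AnatomyError(f"missing nucleus specification(s): {', '.join(missing)}")
    for source, target in DEFAULT_EDGES:
        if not param.has_projection(source, target):
            raise AnatomyError(f"missing projection {source}->{target}")


def _full_scale_alpha(param: Parameterization, proj: ProjectionSpec) -> float:
    """Bouton count expressed at full population scale.

    ``scale_populations`` rescales alpha to preserve per-neuron in-degrees
    under rounded population counts; the anatomical intervals apply to the
    full-scale value, recovered here from the preserved in-degree and the
    unscaled population ratio kept in ``fixed``.
    """
    if param.scale == 1.0:
        return proj.alpha
    if proj.source in INPUT_POPULATIONS:
        full_src = param.fixed.input_pool_size
        cur_src = param.scaled_input_pool
    else:
        full_src = param.fixed.neurons_per_channel[proj.source]
        cur_src = param.nucleus(proj.source).n_per_channel
    full_tgt = param.fixed.neurons_per_channel[proj.target]
    cur_tgt = param.nucleus(proj.target).n_per_channel
    return proj.alpha * (cur_src / cur_tgt) / (full_src / full_tgt)


def validate_anatomy(param: Parameterization, strict: bool = False) -> ValidationReport:
    """Check every ranged parameter against its optimized interval.

    An empty report means the anatomical objective is satisfied.  Pallidal
    edges onto the striatum (GPe->MSN, GPe->FSI) have no printed bouton
    intervals; when present in a parameterization they are accepted as-is.
    With ``strict=True`` a structural defect or any range violation raises
    :class:`AnatomyError`.
    """
    _check_structure(param)
    report = ValidationReport()

    for proj in param.projections:
        proj.validate()
        key = (proj.source, proj.target)
        if key in ALPHA_RANGE:
            low, high = ALPHA_RANGE[key]
            alpha = _full_scale_alpha(param, proj)
            if not low - 1e-9 <= alpha <= high + 1e-9:
                report.violations.append((f"alpha({proj.name})", alpha, low, high))
        if key in P_RANGE:
            low, high = P_RANGE[key]
            if not low <= proj.p <= high:
                report.violations.append((f"p({proj.name})", proj.p, low, high))

    for spec in param.nuclei:
        spec.validate()
        low, high = THETA_RANGE[spec.name]
        if not low <= spec.theta <= high:
            report.violations.append((f"theta({spec.name})", spec.theta, low, high))

    if strict and not report.ok:
        raise AnatomyError(str(report))
    return report


def _midpoint(rng_pair) -> float:
    return 0.5 * (rng_pair[0] + rng_pair[1])


#: decay time from alpha-kernel peak to half peak, in units of tau:
#: the positive root u of u*exp(1-u) = 1/2, minus 1 (~1.6783)
ALPHA_HALF_DECAY = brentq(lambda u: u * math.exp(1.0 - u) - 0.5, 1.0, 20.0) - 1.0


def tau_from_half_time(half_time: float, mode: str = "peak-to-half") -> float:
    """Alpha-kernel time constant from the published PSP half-time.

    ``peak-to-half`` (default) reads the half-time as the decay time from the
    kernel peak to half the peak amplitude, giving tau = D / 1.6783...;
    ``log2`` reads it as a bare exponential half-life, tau = D / ln 2.
    """
    if mode == "peak-to-half":
        return half_time / ALPHA_HALF_DECAY
    if mode == "log2":
        return half_time / math.log(2.0)
    raise ValueError(f"unknown half-time mode {mode!r}")


def _mean_synaptic_drive(param: "Parameterization", target: str,
                         rates: dict) -> float:
    """First-order stationary mean of the synaptic input potential (mV).

    Each projection contributes nu * gamma * rate * integral(kernel), with
    the alpha-kernel time integral A * e * tau per receptor; glutamatergic
    contacts drive AMPA and NMDA together, GABAergic ones GABA_A (negative).
    """
    from .network import attenuation, electrotonic_length  # local: avoid cycle

    fixed = param.fixed
    spec = param.nucleus(target)
    L = electrotonic_length(spec.dendrite_length, spec.dendrite_diameter,
                            fixed.r_i, fixed.r_m)
    kernel_area = {
        r: fixed.psp_amplitude[r] * math.e
        * tau_from_half_time(fixed.psp_half_time[r])
        for r in RECEPTORS
    }
    total = 0.0
    for proj in param.projections:
        if proj.target != target:
            continue
        nu = expected_synapse_count(param, proj)
        gamma = attenuation(L, proj.p)
        if proj.source in INPUT_POPULATIONS:
            rate = fixed.input_base_rate[proj.source]
        else:
            rate = rates[proj.source]
        rate_per_ms = rate / 1000.0
        if proj.transmitter == "glutamate":
            area = kernel_area["AMPA"] + kernel_area["NMDA"]
            total += nu * gamma * area * rate_per_ms
        else:
            total -= nu * gamma * kernel_area["GABAA"] * rate_per_ms
    return total


def steady_state_vc(param: "Parameterization",
                    target_rates: dict | None = None) -> dict:
    """Tonic-input estimate putting each nucleus near a target rest rate.

    Inverts the constant-drive LIF rate ISI = t_ref + tau_m ln(mu/(mu-theta))
    for the total mean drive mu at the target rate, subtracts the stationary
    mean synaptic input (computed with all populations at their target
    rates), and returns the remainder as the tonic input V_C per nucleus.
    For near-silent populations the deterministic inversion degenerates to
    mu -> theta; the estimate then sits at threshold and firing is carried by
    input fluctuations.  This is a moment-level initialization: the grid
    calibration remains the precise instrument.
    """
    rates = dict(target_rates or TARGET_REST_RATE)
    out = {}
    for spec in param.nuclei:
        rate = rates[spec.name]
        isi_ms = 1000.0 / rate if rate > 0 else math.inf
        expo = (isi_ms - spec.t_ref) / spec.tau_m
        if expo > 50.0 or not math.isfinite(expo):
            mu = spec.theta  # fluctuation-driven regime
        else:
            x = math.exp(expo)
            mu = spec.theta * x / (x - 1.0)
        mu -= VC_MARGIN[spec.name]
        out[spec.name] = mu - _mean_synaptic_drive(param, spec.name, rates)
    return out


def sample_parameterization(seed: int, n_channels: int = 1) -> Parameterization:
    """Draw a parameterization uniformly inside the optimized intervals.

    Each bouton count, firing threshold and tonic input is drawn uniformly in
    its interval; synapse locations use the interval midpoint (point values
    can be configured afterwards).  Deterministic for a fixed seed, and always
    satisfies ``validate_anatomy`` by construction.
    """
    rng = np.random.default_rng(seed)
    fixed = FixedParams()

    nuclei = []
    for name in NUCLEI:
        theta = rng.uniform(*THETA_RANGE[name])
        nuclei.append(NucleusSpec(
            name=name,
            n_per_channel=fixed.neurons_per_channel[name],
            theta=theta,
            v_c=0.0,  # filled from the steady-state estimate below
            tau_m=fixed.tau_m[name],
            t_ref=fixed.t_ref,
            dendrite_length=fixed.dendrite_length[name],
            dendrite_diameter=fixed.dendrite_diameter[name],
        ))

    projections = []
    for source, target in DEFAULT_EDGES:
        alpha = rng.uniform(*ALPHA_RANGE[(source, target)])
        projections.append(ProjectionSpec(
            source=source,
            target=target,
            alpha=alpha,
            fraction=PROJECTION_FRACTION.get((source, target), 1.0),
            p=_midpoint(P_RANGE[(source, target)]),
            rho=REDUNDANCY,
            pattern="diffuse" if source in _DIFFUSE_SOURCES else "focused",
            transmitter=TRANSMITTER[source],
            delay=DEFAULT_DELAY_MS,
        ))

    param = Parameterization(
        fixed=fixed, nuclei=nuclei, projections=projections,
        n_channels=n_channels, scale=1.0, meta={"seed": int(seed)},
    )
    vc = steady_state_vc(param)
    for spec in param.nuclei:
        spec.v_c = vc[spec.name] + rng.uniform(-VC_JITTER, VC_JITTER)
    return param


def expected_synapse_count(param: Parameterization, proj: ProjectionSpec) -> float:
    """Mean synapses per target neuron, nu = P * (n_Y / n_X) * alpha.

    The size ratio uses per-channel counts for the nuclei (the ratio is the
    same per channel or in total) and the input-pool size for the extrinsic
    afferents, matching the re-scaling convention of the bouton counts.
    """
    if proj.source in INPUT_POPULATIONS:
        n_src = param.scaled_input_pool
    else:
        n_src = param.nucleus(proj.source).n_per_channel
    n_tgt = param.nucleus(proj.target).n_per_channel
    return proj.fraction * (n_src / n_tgt) * proj.alpha


def scale_populations(param: Parameterization, factor: float) -> Parameterization:
    """Shrink every population by ``factor`` while preserving per-neuron in-degrees.

    Neuron counts and input pools are multiplied by ``factor`` (rounded, at
    least 1) and each projection's bouton count is rescaled so the expected
    synapse count nu per target neuron is unchanged up to rounding.
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError("scale factor must be in (0, 1]")
    scaled = param.copy()
    if factor == 1.0:
        return scaled

    nu_before = {p.name: expected_synapse_count(param, p) for p in param.projections}

    for spec in scaled.nuclei:
        spec.n_per_channel = max(1, int(round(spec.n_per_channel * factor)))
    scaled.scale = param.scale * factor
    scaled.meta = dict(param.meta, scaled_by=factor)

    for proj in scaled.projections:
        nu_target = nu_before[proj.name]
        if proj.source in INPUT_POPULATIONS:
            n_src = scaled.scaled_input_pool
        else:
            n_src = scaled.nucleus(proj.source).n_per_channel
        n_tgt = scaled.nucleus(proj.target).n_per_channel
        denom = proj.fraction * (n_src / n_tgt)
        proj.alpha = nu_target / denom if denom > 0 else 0.0
    return scaled


# ---------------------------------------------------------------------------
# persistence

def _to_dict(param: Parameterization) -> dict:
    return {
        "fixed": dataclasses.asdict(param.fixed),
        "nuclei": [dataclasses.asdict(s) for s in param.nuclei],
        "projections": [dataclasses.asdict(s) for s in param.projections],
        "meta": {
            "n_channels": param.n_channels,
            "scale": param.scale,
            **param.meta,
        },
    }


def save_parameterization(param: Parameterization, path) -> None:
    """Write a parameterization to a YAML document (units as in the tables)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(param), fh, sort_keys=False)


def load_parameterization(path) -> Parameterization:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    meta = dict(raw.get("meta", {}))
    n_channels = int(meta.pop("n_channels", 1))
    scale = float(meta.pop("scale", 1.0))
    return Parameterization(
        fixed=FixedParams(**raw["fixed"]),
        nuclei=[NucleusSpec(**d) for d in raw["nuclei"]],
        projections=[ProjectionSpec(**d) for d in raw["projections"]],
        n_channels=n_channels,
        scale=scale,
        meta=meta,
    )
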