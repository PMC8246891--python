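"""Action-selection characterization: salience grids, efficiency, distortion.

A competing option ("channel") is promoted by raising the firing rate of a
random subset of its cortical afferents: salience s in [0, 1] maps linearly
onto the activated cortico-striatal rate 2 + s*(20-2) Hz and pyramidal-tract
rate 15 + s*(46-15) Hz.  Selection is read out at the inhibitory output stage:
a channel is selected insofar as its GPi rate drops below the rest reference,

    e_i = max(0, 1 - y_i / y_rest)            (efficiency)
    e_w = max_i e_i                           (winner efficiency)
    d_w = (sum_i e_i - e_w) / sum_i e_i       (distortion; undefined at sum 0)

and grid-level quality is summarized by e_sigma (sum of e_w over all salience
conditions) and d_sigma (sum of d_w over the defined conditions).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import params as P
from .network import Disruption, build_network
from .simulate import Activation, StimulationProgram, run
from .analysis import population_rate

#: default number of activated afferents per population and channel
DEFAULT_SUBSET = 500

#: default salience grid: 0 to 1 in increments of 0.1 on each channel
DEFAULT_SALIENCES = tuple(np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10))


def salience_to_rate(population: str, s: float) -> float:
    """Linear map from salience in [0,1] to an activated input rate in Hz."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("salience must be in [0, 1]")
    lo = P.INPUT_BASE_RATE[population]
    hi = P.INPUT_MAX_RATE[population]
    return lo + s * (hi - lo)


def efficiency(y: float, y_rest: float) -> float:
    """Fractional suppression of a channel's GPi output relative to rest."""
    if y_rest <= 0:
        raise ValueError("rest reference rate must be > 0")
    if y < 0:
        raise ValueError("rates must be >= 0")
    return max(0.0, 1.0 - y / y_rest)


def distortion(e) -> tuple:
    """(winner efficiency, distortion) from per-channel efficiencies.

    Distortion is undefined (returned as None) when no channel is selected
    at all (all efficiencies zero).
    """
    e = [float(x) for x in e]
    if any(not 0.0 <= x <= 1.0 for x in e):
        raise ValueError("efficiencies must be in [0, 1]")
    e_w = max(e) if e else 0.0
    total = sum(e)
    if total == 0.0:
        return e_w, None
    return e_w, (total - e_w) / total


@dataclass
class SelectionGrid:
    """Per-condition selection metrics plus the grid-summed globals."""

    table: pd.DataFrame      # s1, s2, y1, y2, e1, e2, e_w, d_w, winner
    y_rest: float
    saliences: tuple
    meta: dict = field(default_factory=dict)

    @property
    def e_sigma(self) -> float:
        return float(self.table.e_w.sum())

    @property
    def d_sigma(self) -> float:
        return float(self.table.d_w.sum(skipna=True))

    @property
    def mean_e_w(self) -> float:
        return float(self.table.e_w.mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> dict:
        return {"e_sigma": self.e_sigma, "d_sigma": self.d_sigma,
                "mean_e_w": self.mean_e_w, "y_rest_hz": self.y_rest,
                **self.meta}


def selection_bounds(saliences=DEFAULT_SALIENCES) -> tuple:
    """Analytic extremes of (e_sigma, d_sigma) over a salience grid.

    For every condition the winner efficiency is bounded by 1 (attained when
    the winning channel's GPi output is fully silenced) and the distortion is
    bounded below by 0 (attained when the losing channel keeps its rest
    output).  Summing the per-condition extremes over the grid gives the best
    selectivity possible.
    """
    e_max = 0.0
    d_min = 0.0
    for _s1, _s2 in itertools.product(saliences, repeat=2):
        # winner fully selected, loser untouched
        e_best = [efficiency(0.0, 1.0), efficiency(1.0, 1.0)]
        e_w, d_w = distortion(e_best)
        e_max += e_w
        d_min += 0.0 if d_w is None else d_w
    return e_max, d_min


def winner_label(e1: float, e2: float, tie_threshold: float = 0.1,
                 tie_rule: str = "abs") -> str:
    """Which channel wins a two-channel condition, or "both"/"none".

    The default tie rule declares "both" when the absolute efficiency
    difference is below 0.1; the alternative ``rel`` rule uses a 5% relative
    difference.
    """
    if e1 == 0.0 and e2 == 0.0:
        return "none"
    delta = abs(e1 - e2)
    if tie_rule == "abs":
        tied = delta < tie_threshold
    elif tie_rule == "rel":
        tied = delta < 0.05 * max(e1, e2)
    else:
        raise ValueError("tie_rule must be 'abs' or 'rel'")
    if tied:
        return "both"
    return "1" if e1 > e2 else "2"


def _condition_program(param, s1, s2, subset, cmpf_rate):
    acts = []
    size = max(1, int(round(subset * param.scale)))
    size = min(size, param.scaled_input_pool)
    for ch, s in ((0, s1), (1, s2)):
        for pop in ("CSN", "PTN"):
            acts.append(Activation(population=pop, channel=ch, size=size,
                                   schedule=salience_to_rate(pop, s)))
    if not math.isclose(cmpf_rate, P.INPUT_BASE_RATE["CMPf"]):
        acts.append(Activation(population="CMPf", channel=None, size=None,
                               schedule=float(cmpf_rate)))
    return StimulationProgram(activations=acts)


def rest_gpi_rate(param, net, seed, duration, warmup, dt) -> float:
    rec = run(net, None, duration=duration, warmup=warmup, dt=dt, seed=seed)
    return population_rate(rec, "GPi")


def run_selection_grid(param: P.Parameterization,
                       disruptions: list | None = None,
                       saliences=DEFAULT_SALIENCES,
                       subset: int = DEFAULT_SUBSET,
                       cmpf_rate: float = 4.0,
                       seed: int = 0,
                       duration: float = 2000.0, warmup: float = 1000.0,
                       dt: float = 0.1,
                       tie_threshold: float = 0.1, tie_rule: str = "abs",
                       y_rest: float | None = None) -> SelectionGrid:
    """Measure selection metrics over a two-channel salience grid.

    The model needs at least 2 channels (3 by default, the third held at
    baseline to provide an unstimulated surround).  The rest reference
    ``y_rest`` is measured from an unstimulated run of the same network
    unless supplied.
    """
    if param.n_channels < 2:
        raise ValueError("selection needs at least 2 channels")
    net = build_network(param, disruptions=disruptions, seed=seed)
    if y_rest is None:
        y_rest = rest_gpi_rate(param, net, seed, duration, warmup, dt)
    if y_rest <= 0:
        raise ValueError("uncalibrated model: GPi rest rate is zero")

    rows = []
    for i, (s1, s2) in enumerate(itertools.product(saliences, repeat=2)):
        program = _condition_program(param, s1, s2, subset, cmpf_rate)
        rec = run(net, program, duration=duration, warmup=warmup, dt=dt,
                  seed=seed * 100003 + i)
        y1 = population_rate(rec, "GPi", channel=0)
        y2 = population_rate(rec, "GPi", channel=1)
        e1, e2 = efficiency(y1, y_rest), efficiency(y2, y_rest)
        e_w, d_w = distortion([e1, e2])
        rows.append({"s1": s1, "s2": s2, "y1": y1, "y2": y2,
                     "e1": e1, "e2": e2, "e_w": e_w,
                     "d_w": np.nan if d_w is None else d_w,
                     "winner": winner_label(e1, e2, tie_threshold, tie_rule)})
    table = pd.DataFrame(rows)
    return SelectionGrid(table=table, y_rest=float(y_rest), saliences=tuple(saliences),
                         meta={"seed": seed, "cmpf_rate": cmpf_rate,
                               "subset": subset})


#: the four circuit disruptions probed against the intact model
DISRUPTION_VARIANTS = ("intact", "poissonify_MSN_MSN", "poissonify_FSI_MSN",
                       "focused_STN_GPi", "focused_STN_GPe")


def _variant_disruptions(variant: str, msn_rest: float, fsi_rest: float) -> list:
    if variant == "intact":
        return []
    if variant == "poissonify_MSN_MSN":
        return [Disruption(kind="poissonify_projection", source="MSN",
                           target="MSN", rate=msn_rest)]
    if variant == "poissonify_FSI_MSN":
        return [Disruption(kind="poissonify_projection", source="FSI",
                           target="MSN", rate=fsi_rest)]
    if variant == "focused_STN_GPi":
        return [Disruption(kind="make_focused", source="STN", target="GPi")]
    if variant == "focused_STN_GPe":
        return [Disruption(kind="make_focused", source="STN", target="GPe")]
    raise ValueError(f"unknown variant {variant!r}")


def disruption_comparison(param: P.Parameterization, seeds,
                          saliences=DEFAULT_SALIENCES,
                          variants=DISRUPTION_VARIANTS,
                          **grid_kw) -> pd.DataFrame:
    """(e_sigma, d_sigma) for the intact circuit and each disruption.

    Poissonified projections replay the rest-state rate of their source
    population, measured from an intact rest run with the same seed.
    Returns one row per (variant, seed) with shared seeds across variants.
    """
    duration = grid_kw.get("duration", 2000.0)
    warmup = grid_kw.get("warmup", 1000.0)
    dt = grid_kw.get("dt", 0.1)
    rows = []
    for seed in seeds:
        net = build_network(param, seed=seed)
        rest = run(net, None, duration=duration, warmup=warmup, dt=dt, seed=seed)
        msn_rest = population_rate(rest, "MSN")
        fsi_rest = population_rate(rest, "FSI")
        y_rest = population_rate(rest, "GPi")
        for variant in variants:
            disruptions = _variant_disruptions(variant, msn_rest, fsi_rest)
            grid = run_selection_grid(param, disruptions=disruptions,
                                      saliences=saliences, seed=seed,
                                      y_rest=y_rest, **grid_kw)
            rows.append({"variant": variant, "seed": seed,
                         "e_sigma": grid.e_sigma, "d_sigma": grid.d_sigma})
    return pd.DataFrame(rows)


def cmpf_sweep(param: P.Parameterization, levels=(4.0, 5.0, 6.0, 7.0),
               saliences=DEFAULT_SALIENCES, seed: int = 0,
               **grid_kw) -> dict:
    """Selection grids at increasing constant CM/Pf drive.

    The rest reference is measured once at the baseline CM/Pf level, so the
    per-level grids quantify how thalamic drive erodes selectivity.  Returns
    ``{level: SelectionGrid}``; the summary statistic is each grid's mean
    winner efficiency.
    """
    base = P.INPUT_BASE_RATE["CMPf"]
    if any(level < base for level in levels):
        raise ValueError(f"CM/Pf levels must be >= the {base} Hz baseline")
    duration = grid_kw.get("duration", 2000.0)
    warmup = grid_kw.get("warmup", 1000.0)
    dt = grid_kw.get("dt", 0.1)
    net = build_network(param, seed=seed)
    y_rest = rest_gpi_rate(param, net, seed, duration, warmup, dt)
    out = {}
    for level in levels:
        out[float(level)] = run_selection_grid(
            param, saliences=saliences, cmpf_rate=float(level), seed=seed,
            y_rest=y_rest, **grid_kw)
    return out


#: trend symbols used by the sensitivity classification
UP, DOWN, FLAT = "up", "down", "flat"

DEFAULT_SWEEP_SIZES = (250, 500, 1000, 2000, 4000)


def classify_trend(input_rates, responses, baseline: float,
                   min_change: float = 0.05, rel_change: float = 0.10) -> str:
    """Label a nucleus response to an input ramp as up / down / flat.

    A linear fit of the response on the input rate is called a trend when the
    fitted total change across the ramp exceeds max(0.05 Hz, 10% of the
    baseline response); otherwise the response is flat.  The absolute floor
    sits above the rate-estimation noise of pooled desk-scale runs yet below
    the dynamic range of the near-silent striatal projection neurons.
    """
    x = np.asarray(input_rates, dtype=float)
    y = np.asarray(responses, dtype=float)
    span = x.max() - x.min()
    if span == 0:
        return FLAT
    slope = np.polyfit(x, y, 1)[0]
    change = slope * span
    threshold = max(min_change, rel_change * abs(baseline))
    if abs(change) <= threshold:
        return FLAT
    return UP if change > 0 else DOWN


def input_sensitivity_sweep(param: P.Parameterization, population: str,
                            sizes=DEFAULT_SWEEP_SIZES,
                            rates=None, seeds=(0,),
                            duration: float = 2000.0, warmup: float = 1000.0,
                            dt: float = 0.1) -> pd.DataFrame:
    """Ramp one input population and classify every nucleus's response.

    For each activated-subset size and input rate the five nuclei's mean
    rates are recorded (pooled over seeds); each (nucleus, size) pair is then
    classified as up/down/flat from a linear fit of rate on input rate.
    Returns the tidy table of rates with the trend labels merged in.
    """
    if population not in P.INPUT_POPULATIONS:
        raise ValueError(f"unknown input population {population!r}")
    lo, hi = P.INPUT_BASE_RATE[population], P.INPUT_MAX_RATE[population]
    if rates is None:
        rates = np.linspace(lo, hi, 4)
    for r in rates:
        if not lo <= r <= hi + 1e-9:
            raise ValueError(f"rate {r} outside the {population} span [{lo}, {hi}]")

    channel = None if population == "CMPf" else 0
    rows = []
    for seed in seeds:
        net = build_network(param, seed=seed)
        for size in sizes:
            scaled = max(1, int(round(size * param.scale)))
            pool = net.inputs_of(population, channel).size
            if scaled > pool:
                raise ValueError(f"subset {scaled} exceeds {population} pool {pool}")
            for rate in rates:
                program = StimulationProgram(activations=[
                    Activation(population=population, channel=channel,
                               size=scaled, schedule=float(rate))])
                rec = run(net, program, duration=duration, warmup=warmup,
                          dt=dt, seed=seed)
                for nucleus in P.NUCLEI:
                    rows.append({"population": population, "size": size,
                                 "input_rate_hz": float(rate), "seed": seed,
                                 "nucleus": nucleus,
                                 "rate_hz": population_rate(rec, nucleus)})
    table = pd.DataFrame(rows)

    trends = []
    for (size, nucleus), grp in table.groupby(["size", "nucleus"]):
        baseline = grp[grp.input_rate_hz == grp.input_rate_hz.min()].rate_hz.mean()
        trend = classify_trend(grp.input_rate_hz, grp.rate_hz, baseline)
        trends.append({"size": size, "nucleus": nucleus, "trend": trend})
    return table.merge(pd.DataFrame(trends), on=["size", "nucleus"])
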