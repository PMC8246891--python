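"""Physiological plausibility scoring and tonic-input calibration.

A model translation is physiologically plausible when its simulated firing
rates fall inside published per-nucleus intervals, both at rest and under a
battery of emulated antagonist injections (receptor deactivations in GPe or
GPi).  The score F counts the satisfied comparisons; with the default battery
(5 rest rows + 9 deactivation rows) F ranges over 0-14.

The tonic inputs V_C (one per nucleus) are the free parameters of the
population-to-spiking translation.  They are calibrated by evaluating F on a
regular 5-D grid and picking the most central point of the plausible domain:
the feasible grid point whose distance to the nearest infeasible grid point
is maximal (the centre of the largest ball fitting inside the domain).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import params as P
from .network import build_network
from .simulate import Activation, StimulationProgram, block_receptors, run
from .analysis import population_rate

#: default deactivation battery: (targeted nucleus, blocked receptors)
DEFAULT_BATTERY = (
    ("GPe", ("AMPA",)),
    ("GPe", ("NMDA",)),
    ("GPe", ("AMPA", "NMDA")),
    ("GPe", ("GABAA",)),
    ("GPi", ("AMPA",)),
    ("GPi", ("NMDA",)),
    ("GPi", ("AMPA", "NMDA")),
    ("GPi", ("GABAA",)),
    ("GPi", ("AMPA", "NMDA", "GABAA")),
)

#: plausible rest-rate intervals printed for the striatal populations (Hz)
DEFAULT_REST_RANGES = {"MSN": (0.05, 1.0), "FSI": (7.8, 14.0)}


def condition_id(nucleus: str, receptors) -> str:
    return f"{nucleus}:{'+'.join(receptors)}"


@dataclass
class PlausibilityTable:
    """Per-(condition, nucleus) firing-rate intervals.

    Rows: ``condition_id`` ("rest" or "<nucleus>:<receptors>"), ``nucleus``,
    ``low_hz``, ``high_hz`` and an optional provenance note.
    """

    rows: pd.DataFrame

    def __post_init__(self):
        required = {"condition_id", "nucleus", "low_hz", "high_hz"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"plausibility table missing columns: {missing}")
        if (self.rows.low_hz > self.rows.high_hz).any():
            raise ValueError("plausibility rows need low_hz <= high_hz")

    def __len__(self) -> int:
        return len(self.rows)

    def interval(self, condition: str, nucleus: str):
        sel = self.rows[(self.rows.condition_id == condition)
                        & (self.rows.nucleus == nucleus)]
        if sel.empty:
            raise KeyError(f"no plausibility row for ({condition}, {nucleus})")
        r = sel.iloc[0]
        return float(r.low_hz), float(r.high_hz)

    @classmethod
    def from_rows(cls, rows) -> "PlausibilityTable":
        return cls(pd.DataFrame(rows,
                   columns=["condition_id", "nucleus", "low_hz", "high_hz"]))

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "PlausibilityTable":
        return cls(pd.read_csv(path))


def deactivation_battery(param: P.Parameterization, seeds,
                         battery=DEFAULT_BATTERY,
                         duration: float = 2000.0, warmup: float = 1000.0,
                         dt: float = 0.1) -> dict:
    """Simulate rest plus the deactivation battery, averaging across seeds.

    Returns ``{"rest": {nucleus: rate}, "<nucleus>:<receptors>": rate}`` with
    each deactivation entry holding the targeted nucleus's mean rate.
    """
    seeds = list(seeds)
    rest_acc = {n: [] for n in P.NUCLEI}
    deact_acc = {condition_id(n, r): [] for n, r in battery}
    for seed in seeds:
        net = build_network(param, seed=seed)
        rest = run(net, duration=duration, warmup=warmup, dt=dt, seed=seed)
        for nucleus in P.NUCLEI:
            rest_acc[nucleus].append(population_rate(rest, nucleus))
        for nucleus, receptors in battery:
            blocked = block_receptors(net, nucleus, receptors)
            rec = run(blocked, duration=duration, warmup=warmup, dt=dt, seed=seed)
            deact_acc[condition_id(nucleus, receptors)].append(
                population_rate(rec, nucleus))
    out = {"rest": {n: float(np.mean(v)) for n, v in rest_acc.items()}}
    out.update({cid: float(np.mean(v)) for cid, v in deact_acc.items()})
    return out


@dataclass
class ScoreResult:
    """Outcome of the physiological-value objective."""

    comparisons: pd.DataFrame   # condition, nucleus, low, high, rate, passed
    rates: dict                 # raw battery output

    @property
    def f(self) -> int:
        return int(self.comparisons.passed.sum())

    @property
    def n_comparisons(self) -> int:
        return len(self.comparisons)

    def to_json_dict(self) -> dict:
        return {"F": self.f, "n_comparisons": self.n_comparisons,
                "rows": self.comparisons.to_dict(orient="records")}


def score_rates(rates: dict, table: PlausibilityTable) -> ScoreResult:
    """Compare simulated battery rates against a plausibility table."""
    rows = []
    for _, r in table.rows.iterrows():
        cond, nucleus = r.condition_id, r.nucleus
        if cond == "rest":
            rate = rates["rest"][nucleus]
        else:
            if cond not in rates:
                raise KeyError(f"battery produced no rate for condition {cond!r}")
            rate = rates[cond]
        rows.append({
            "condition": cond, "nucleus": nucleus,
            "low_hz": float(r.low_hz), "high_hz": float(r.high_hz),
            "rate_hz": float(rate),
            "passed": bool(r.low_hz <= rate <= r.high_hz),
        })
    return ScoreResult(comparisons=pd.DataFrame(rows), rates=rates)


def physiological_score(param: P.Parameterization, table: PlausibilityTable,
                        seeds, **sim_kw) -> ScoreResult:
    """Run the battery and score it against the plausibility table."""
    rates = deactivation_battery(param, seeds, **sim_kw)
    return score_rates(rates, table)


@dataclass
class GridSpec:
    """Regular tonic-input grid: per-nucleus (low, high, step) in mV."""

    axes: dict  # nucleus -> (low, high, step)

    def axis_values(self, nucleus: str) -> np.ndarray:
        low, high, step = self.axes[nucleus]
        n = int(round((high - low) / step)) + 1
        return low + step * np.arange(n)

    def points(self):
        """All grid points in lexicographic nucleus order (params.NUCLEI)."""
        axes = [self.axis_values(n) for n in P.NUCLEI]
        return np.array(list(itertools.product(*axes)))

    def grid_units(self, points: np.ndarray) -> np.ndarray:
        steps = np.array([self.axes[n][2] for n in P.NUCLEI])
        lows = np.array([self.axes[n][0] for n in P.NUCLEI])
        return (points - lows) / steps


@dataclass
class CalibrationResult:
    center: dict                 # nucleus -> calibrated V_C (mV)
    f_at_center: int
    f_max_achieved: int
    feasible_count: int
    radius: float                # grid-unit distance to nearest infeasible point
    feasible_empty: bool
    scores: np.ndarray = field(repr=False, default=None)
    points: np.ndarray = field(repr=False, default=None)


def calibrate_on_grid(score_fn, grid: GridSpec, f_target: int,
                      metric: str = "euclidean") -> CalibrationResult:
    """Pick the most central fully-plausible tonic-input grid point.

    ``score_fn(point_dict) -> int`` evaluates the physiological score at one
    grid point.  Feasible points score ``f_target``; the returned centre is
    the feasible point maximizing the distance (in grid units, Euclidean by
    default, Chebyshev optionally) to its nearest infeasible grid point.
    Ties are broken by proximity to the componentwise median of the feasible
    set, then lexicographically.  With an empty feasible set the best-scoring
    point is reported instead.
    """
    if metric not in ("euclidean", "chebyshev"):
        raise ValueError("metric must be 'euclidean' or 'chebyshev'")
    points = grid.points()
    scores = np.array([score_fn(dict(zip(P.NUCLEI, pt))) for pt in points])

    feasible = scores >= f_target
    best_f = int(scores.max()) if scores.size else 0
    if not feasible.any():
        best = int(np.argmax(scores))
        return CalibrationResult(
            center=dict(zip(P.NUCLEI, points[best])),
            f_at_center=best_f, f_max_achieved=best_f,
            feasible_count=0, radius=0.0, feasible_empty=True,
            scores=scores, points=points)

    units = grid.grid_units(points)
    feas_pts = units[feasible]
    infeas_pts = units[~feasible]
    if infeas_pts.size == 0:
        dist = np.full(feas_pts.shape[0], np.inf)
    else:
        p_norm = 2 if metric == "euclidean" else np.inf
        tree = cKDTree(infeas_pts)
        dist, _ = tree.query(feas_pts, k=1, p=p_norm)

    best_d = dist.max()
    cand = np.flatnonzero(np.isclose(dist, best_d) | (dist == best_d))
    if cand.size > 1:
        median = np.median(feas_pts, axis=0)
        to_med = np.linalg.norm(feas_pts[cand] - median, axis=1)
        cand = cand[np.isclose(to_med, to_med.min())]
        if cand.size > 1:
            order = np.lexsort(feas_pts[cand].T[::-1])
            cand = cand[order[:1]]
    chosen = cand[0]
    center_pt = points[feasible][chosen]
    return CalibrationResult(
        center=dict(zip(P.NUCLEI, center_pt)),
        f_at_center=int(scores[feasible][chosen]),
        f_max_achieved=best_f,
        feasible_count=int(feasible.sum()),
        radius=float(best_d),
        feasible_empty=False,
        scores=scores, points=points)


def hypersphere_calibrate(param: P.Parameterization, table: PlausibilityTable,
                          grid: GridSpec, seeds,
                          metric: str = "euclidean",
                          **sim_kw) -> CalibrationResult:
    """Grid-search the 5-D tonic-input vector by simulated physiological score.

    Each grid point is simulated (rest + battery) and scored against the
    table; the most central point of the F = table-size region is returned.
    """
    f_target = len(table)

    def score_fn(vc: dict) -> int:
        trial = param.copy()
        for spec in trial.nuclei:
            spec.v_c = float(vc[spec.name])
        return physiological_score(trial, table, seeds, **sim_kw).f

    return calibrate_on_grid(score_fn, grid, f_target, metric=metric)


@dataclass
class ScreenResult:
    accepted: bool
    msn_rate_hz: float
    threshold_hz: float = 4.0


def screen_csn_response(param: P.Parameterization, seed: int = 0,
                        n_activated: int = 4000, rate_hz: float = 20.0,
                        duration: float = 2000.0, warmup: float = 1000.0,
                        dt: float = 0.1) -> ScreenResult:
    """Reject translations whose MSNs barely react to vigorous cortical drive.

    Activates ``n_activated`` cortico-striatal generators (scaled with the
    parameterization) at ``rate_hz`` in every channel and accepts the model
    iff the MSN mean rate reaches 4 Hz (the bound itself is accepted).
    """
    net = build_network(param, seed=seed)
    size = max(1, int(round(n_activated * param.scale)))
    size = min(size, param.scaled_input_pool)
    program = StimulationProgram(activations=[
        Activation(population="CSN", channel=ch, size=size, schedule=rate_hz)
        for ch in range(param.n_channels)
    ])
    rec = run(net, program, duration=duration, warmup=warmup, dt=dt, seed=seed)
    rate = population_rate(rec, "MSN")
    return ScreenResult(accepted=rate >= 4.0, msn_rate_hz=float(rate))
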