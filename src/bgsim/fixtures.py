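"""Desk-scale fixture generation.

The published study retained a specific set of parameter vectors whose point
values are not part of the open tables; what the tables do fix are the
optimized intervals.  Fixtures therefore sample a parameterization inside
those intervals, shrink the populations (preserving in-degrees) to a size
that simulates in seconds, and derive a synthetic plausibility table from a
pilot run of the sampled model itself, so that the full scoring and
calibration machinery is exercisable without any external data.
"""

from __future__ import annotations

import numpy as np

from . import params as P
from .params import Parameterization, sample_parameterization, scale_populations
from .calibrate import (DEFAULT_BATTERY, PlausibilityTable, deactivation_battery)


def make_fixture(seed: int = 0, scale: float = 0.05, n_channels: int = 1,
                 width: float = 0.20, floor_hz: float = 0.5,
                 duration: float = 2000.0, warmup: float = 1000.0,
                 dt: float = 0.1) -> tuple:
    """Sample a scaled parameterization plus a matching plausibility table.

    The table's intervals are centred on a pilot run's measured rates with a
    relative half-width of ``width`` (an absolute floor of ``floor_hz``
    tolerates near-zero rates and seed-to-seed variation), which guarantees a
    non-empty feasible region for calibration around the sampled tonic
    inputs.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must be in (0, 1]")
    param = sample_parameterization(seed, n_channels=n_channels)
    param = scale_populations(param, scale)

    rates = deactivation_battery(param, seeds=[seed], duration=duration,
                                 warmup=warmup, dt=dt)

    def interval(rate: float) -> tuple:
        half = max(width * rate, floor_hz)
        return max(0.0, rate - half), rate + half

    rows = []
    for nucleus in P.NUCLEI:
        low, high = interval(rates["rest"][nucleus])
        rows.append({"condition_id": "rest", "nucleus": nucleus,
                     "low_hz": low, "high_hz": high})
    for nucleus, receptors in DEFAULT_BATTERY:
        cid = f"{nucleus}:{'+'.join(receptors)}"
        low, high = interval(rates[cid])
        rows.append({"condition_id": cid, "nucleus": nucleus,
                     "low_hz": low, "high_hz": high})
    table = PlausibilityTable.from_rows(rows)
    param.meta["fixture"] = {"seed": int(seed), "scale": float(scale),
                             "pilot_rates": rates}
    return param, table
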