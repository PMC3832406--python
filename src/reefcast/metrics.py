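"""Management-facing trajectory summaries.

Recovery between two scheduled bleaching events, time until coral cover
falls to a collapse threshold, and per-year ensemble summaries of every
state variable (plus the combined algae series).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import DAYS_PER_YEAR, STATE_VARIABLES, Trajectory
from .scenarios import EnsembleResult

__all__ = [
    "RecoveryMetrics",
    "coral_recovery",
    "time_to_collapse",
    "ensemble_summary",
]


@dataclass
class RecoveryMetrics:
    """Coral recovery between two bleaching events.

    Covers are in % of area. ``cover_post_event`` is read the day after
    the first event; the endpoint is read the day before the second event.
    ``relative_increase`` = 100 * absolute / post-event cover (reported
    only when there was recovery). ``recovered`` is False when cover did
    not increase — the tabulated convention is a dash in that case.
    """

    cover_post_event: float
    cover_pre_second_event: float
    absolute_increase: float
    relative_increase: float | None
    recovered: bool

    def table_row(self) -> dict:
        """Whole-percent table rendering (dashes for no recovery)."""
        post = round(self.cover_post_event)
        if not self.recovered:
            return {"cover_post": post, "absolute": "-", "relative": "-"}
        absolute = round(self.absolute_increase)
        relative = round(100.0 * self.absolute_increase / self.cover_post_event)
        return {"cover_post": post, "absolute": absolute, "relative": relative}


def coral_recovery(
    traj: Trajectory, first_event_year: int, second_event_year: int
) -> RecoveryMetrics:
    """Measure coral recovery between two scheduled bleaching events."""
    if not first_event_year < second_event_year:
        raise ValueError("bleaching events out of order")
    n_days = len(traj) - 1
    day_post = first_event_year * DAYS_PER_YEAR + 1
    day_pre = second_event_year * DAYS_PER_YEAR - 1
    if day_post > n_days or day_pre > n_days:
        raise ValueError("event years beyond simulated horizon")

    post = float(traj.coral[day_post]) * 100.0
    pre2 = float(traj.coral[day_pre]) * 100.0
    absolute = pre2 - post
    recovered = absolute > 0 and post > 0
    relative = 100.0 * absolute / post if recovered else None
    return RecoveryMetrics(
        cover_post_event=post,
        cover_pre_second_event=pre2,
        absolute_increase=max(absolute, 0.0) if not recovered else absolute,
        relative_increase=relative,
        recovered=recovered,
    )


def time_to_collapse(traj: Trajectory, threshold: float = 0.5) -> int | None:
    """First year coral cover reaches the collapse threshold.

    ``threshold`` is in % cover; the default 0.5% is the largest cover
    that still rounds to a printed 0%. Returns the day of first crossing
    converted to whole years (rounded up), or None if never reached.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    coral_pct = np.asarray(traj.coral, dtype=float) * 100.0
    hits = np.nonzero(coral_pct <= threshold + 1e-9)[0]
    if len(hits) == 0:
        return None
    return int(np.ceil(hits[0] / DAYS_PER_YEAR))


def ensemble_summary(
    ensemble: EnsembleResult, years: list[int] | None = None
) -> pd.DataFrame:
    """Per-year ensemble mean and standard deviation of every variable.

    Also emits the combined ``algae`` series (macroturf + macroalgae
    cover). Covers are reported in %, biomasses in g m^-2. The spread is
    the between-replicate standard deviation (ddof=1; 0 for a single
    replicate).
    """
    n_days = len(ensemble.trajectory) - 1
    horizon = n_days // DAYS_PER_YEAR
    if years is None:
        years = list(range(horizon + 1))
    for y in years:
        if not 0 <= y <= horizon:
            raise ValueError(f"year {y} outside simulated horizon 0..{horizon}")

    states = ensemble.trajectory.states  # (days+1, reps, 7)
    rows = []
    for y in years:
        snap = states[y * DAYS_PER_YEAR]  # (reps, 7)
        scaled = snap.copy()
        scaled[:, :4] *= 100.0
        ddof = 1 if snap.shape[0] > 1 else 0
        for i, name in enumerate(STATE_VARIABLES):
            rows.append({
                "year": y, "variable": name,
                "mean": float(scaled[:, i].mean()),
                "sd": float(scaled[:, i].std(ddof=ddof)),
            })
        algae = scaled[:, 2] + scaled[:, 3]
        rows.append({
            "year": y, "variable": "algae",
            "mean": float(algae.mean()),
            "sd": float(algae.std(ddof=ddof)),
        })
    return pd.DataFrame(rows)
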