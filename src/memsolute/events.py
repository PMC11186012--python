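"""Membrane insertion events from the solute z series.

An insertion event is a maximal interval during which the solute COM stays
within ``threshold`` (default 3.0 nm) of the membrane COM along z, trimmed
by a ``lag`` (default 10 ns) at both ends to discard the equilibration after
entry and before exit.  Intervals shorter than twice the lag produce no
event; their frames are labelled ``excluded-lag``.  An interval still open
when the trajectory ends yields a right-censored event that is kept for
state masks but excluded from mean residence times.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import AnalysisError, ConfigurationError

__all__ = ["Event", "EventTable", "detect_events", "residence_time_stats"]

MEMBRANE, WATER, EXCLUDED = "membrane", "water", "excluded-lag"


@dataclass
class Event:
    solute_id: int
    t_start: float      # ns
    t_end: float        # ns
    censored: bool = False

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class EventTable:
    events: list
    state_mask: np.ndarray = field(repr=False)   # per-frame labels
    times: np.ndarray = field(repr=False)        # ns

    @property
    def completed(self) -> list:
        return [e for e in self.events if not e.censored]

    @property
    def censored(self) -> list:
        return [e for e in self.events if e.censored]

    def mask(self, state: str) -> np.ndarray:
        return self.state_mask == state


def detect_events(z_series, dt: float, threshold: float = 3.0,
                  lag: float = 10.0, solute_id: int = 0,
                  times=None) -> EventTable:
    """Detect insertion events on a uniformly sampled z series.

    ``z_series`` in nm (folded internally to |z|), ``dt`` and ``lag`` in ns.
    """
    if threshold <= 0 or lag <= 0:
        raise ConfigurationError("threshold and lag must be positive")
    z = np.abs(np.asarray(z_series, dtype=float).ravel())
    n = z.size
    if n == 0:
        raise AnalysisError("empty z series")
    t = (np.arange(n) * dt) if times is None else np.asarray(times, float)

    inside = z < threshold
    mask = np.where(inside, EXCLUDED, WATER).astype(object)
    events = []
    eps = 1e-9  # guards >= comparisons on a floating-point time grid
    # maximal runs of `inside`
    padded = np.concatenate(([False], inside, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])   # exclusive frame index
    t_final = t[-1]
    for s, e in zip(starts, ends):
        t_in = t[s]
        open_at_end = e == n
        # exit time: first frame at/above threshold (one step past the run)
        t_out = t_final if open_at_end else t[e]
        if open_at_end:
            if t_final - t_in >= lag - eps:
                ev = Event(solute_id, t_in + lag, t_final, censored=True)
                events.append(ev)
                sel = (t >= ev.t_start - eps) & (t <= ev.t_end + eps) & inside
                mask[sel] = MEMBRANE
        elif t_out - t_in >= 2.0 * lag - eps:
            ev = Event(solute_id, t_in + lag, t_out - lag)
            events.append(ev)
            sel = (t >= ev.t_start - eps) & (t <= ev.t_end + eps) & inside
            mask[sel] = MEMBRANE
    return EventTable(events=events, state_mask=mask, times=t)


def residence_time_stats(table: EventTable, confidence: float = 0.95) -> dict:
    """Mean residence time of completed events with a t-based CI (ns).

    Censored events are excluded from the mean and reported as a count.
    """
    durations = np.array([e.duration for e in table.completed])
    n_cens = len(table.censored)
    if durations.size == 0:
        raise AnalysisError(
            f"no completed events ({n_cens} censored)")
    mean = float(durations.mean())
    if durations.size == 1:
        return {"mean": mean, "ci_halfwidth": float("nan"), "n": 1,
                "n_censored": n_cens, "ci_defined": False}
    se = durations.std(ddof=1) / np.sqrt(durations.size)
    tcrit = sps.t.ppf(0.5 + confidence / 2.0, durations.size - 1)
    return {"mean": mean, "ci_halfwidth": float(tcrit * se),
            "n": int(durations.size), "n_censored": n_cens, "ci_defined": True}
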