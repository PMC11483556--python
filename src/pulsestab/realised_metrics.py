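"""Classic ("realised") stability metrics computed directly from a trajectory.

The four metrics quantify different aspects of a population's observed
response to pulse disturbances:

* **temporal stability** — inverse coefficient of variation of the series
  (invariability): larger means weaker fluctuations;
* **resistance** — abundance at the first sample at/after the disturbance
  relative to the pre-disturbance abundance (1 = unaffected);
* **recovery** — abundance long after the disturbance relative to the
  pre-disturbance abundance (1 = fully recovered);
* **resilience** — per-capita rate at which the displacement from
  equilibrium x(t) = |N(t) - K| shrinks after the disturbance, reported
  positive while recovering.

All four are confounded with the organism's growth rate; see
:mod:`pulsestab.intrinsic_metrics` for the growth-rate-corrected versions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from pulsestab.dynamics_sim import Trajectory

__all__ = [
    "RealisedStability",
    "temporal_stability_realised",
    "resistance_realised",
    "recovery_realised",
    "resilience_realised",
    "pre_disturbance_abundance",
]


@dataclass
class RealisedStability:
    """The four realised metrics for one case (NaN where not applicable)."""

    temporal_stability: float
    resistance: float
    recovery: float
    resilience: float


def temporal_stability_realised(values: Sequence[float]) -> float:
    """Invariability: mean(values) / std(values), sample (n-1) denominator.

    Returns ``math.inf`` with a warning for a constant series; raises for
    an all-zero series (the ratio 0/0 has no meaning).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("temporal stability needs at least 2 observations")
    m = float(np.mean(v))
    s = float(np.std(v, ddof=1))
    if s == 0.0:
        if m == 0.0:
            raise ValueError("temporal stability undefined for an all-zero series")
        warnings.warn("constant series: temporal stability is infinite")
        return math.inf
    return m / s


def pre_disturbance_abundance(traj: Trajectory, t_dist: float) -> float:
    """Abundance at the last observation strictly before ``t_dist``.

    Falls back to the recorded ``n_pre`` (and to ``params.K``) when the
    series has no sample before the disturbance.
    """
    before = np.nonzero(traj.times < t_dist)[0]
    if len(before):
        return float(traj.values[before[-1]])
    if traj.n_pre is not None:
        return float(traj.n_pre)
    if traj.params is not None:
        return float(traj.params.K)
    raise ValueError("no observation before the disturbance and no n_pre/K known")


def _event_time(traj: Trajectory, event_index: int) -> float:
    if len(traj.event_times) == 0:
        raise ValueError("trajectory records no disturbance events")
    if event_index >= len(traj.event_times):
        raise IndexError(
            f"event_index {event_index} out of range "
            f"({len(traj.event_times)} events recorded)"
        )
    return float(traj.event_times[event_index])


def resistance_realised(traj: Trajectory, event_index: int = 0) -> float:
    """N at the first observation at/after the disturbance, over N_pre.

    Values close to 1 indicate small disturbance impact. Because sampling
    is discrete, a fast grower can partly recover before the first
    post-disturbance sample, inflating its realised resistance.
    """
    t_dist = _event_time(traj, event_index)
    n_pre = pre_disturbance_abundance(traj, t_dist)
    if n_pre == 0.0:
        raise ValueError("resistance undefined: pre-disturbance abundance is 0")
    after = np.nonzero(traj.times >= t_dist)[0]
    if len(after) == 0:
        raise ValueError("no observation at or after the disturbance")
    return float(traj.values[after[0]]) / n_pre


def recovery_realised(
    traj: Trajectory, t_end: Optional[float] = None, event_index: int = 0
) -> float:
    """N(t_end) / N_pre; values near 1 indicate complete recovery.

    ``t_end`` must be an observation time at/after the disturbance;
    defaults to the last observation.
    """
    t_dist = _event_time(traj, event_index)
    if t_end is None:
        t_end = float(traj.times[-1])
    if t_end < t_dist:
        raise ValueError(f"t_end={t_end} precedes the disturbance at {t_dist}")
    idx = np.nonzero(np.isclose(traj.times, t_end))[0]
    if len(idx) == 0:
        raise ValueError(f"t_end={t_end} is not an observation time")
    n_pre = pre_disturbance_abundance(traj, t_dist)
    if n_pre == 0.0:
        raise ValueError("recovery undefined: pre-disturbance abundance is 0")
    return float(traj.values[idx[0]]) / n_pre


def resilience_realised(
    traj: Trajectory,
    K: Optional[float] = None,
    window: Optional[Tuple[float, float]] = None,
    event_index: int = 0,
    average: bool = False,
    rel_threshold: float = 0.05,
) -> float:
    """Per-capita rate of return toward equilibrium after a disturbance.

    For displacement x(t) = |N(t) - K| and two post-disturbance
    observation times t and t+eps, the statistic is

        -(x(t + eps) - x(t)) / (x_bar(t) * eps),   x_bar = (x(t) + x(t+eps)) / 2,

    positive while the population moves toward K. By default the first
    post-disturbance pair of observations is used; with ``average=True``
    the statistic is averaged over all consecutive post-disturbance pairs
    while x(t) exceeds ``rel_threshold * K`` (the estimate degrades once
    the displacement dives into the noise floor near equilibrium).
    ``window`` overrides the pair choice with explicit (t, t+eps) times.

    Invariant to rescaling abundances (N -> cN, K -> cK).
    """
    t_dist = _event_time(traj, event_index)
    if K is None:
        if traj.params is None:
            raise ValueError("equilibrium K required (no params on trajectory)")
        K = traj.params.K
    post = np.nonzero(traj.times >= t_dist)[0]
    if len(post) < 2:
        raise ValueError("need at least 2 post-disturbance observations")
    x = np.abs(traj.values[post] - K)
    t = traj.times[post]

    def pair_rate(i: int, j: int) -> float:
        eps = t[j] - t[i]
        x_bar = (x[i] + x[j]) / 2.0
        if x_bar == 0.0:
            raise ValueError("resilience undefined: already at equilibrium")
        return -(x[j] - x[i]) / (x_bar * eps)

    if window is not None:
        i = int(np.nonzero(np.isclose(t, window[0]))[0][0])
        j = int(np.nonzero(np.isclose(t, window[1]))[0][0])
        if x[i] == 0.0:
            raise ValueError("resilience undefined: x(t) = 0 at window start")
        return pair_rate(i, j)

    if x[0] == 0.0:
        raise ValueError("resilience undefined: displacement is 0 at the disturbance")
    if not average:
        return pair_rate(0, 1)
    rates = [
        pair_rate(i, i + 1)
        for i in range(len(post) - 1)
        if x[i] > rel_threshold * K
    ]
    if not rates:
        raise ValueError("no post-disturbance pairs above the displacement threshold")
    return float(np.mean(rates))


def realised_report(
    traj: Trajectory,
    K: Optional[float] = None,
    t_end: Optional[float] = None,
    pulse_train: bool = False,
) -> RealisedStability:
    """All four realised metrics for one trajectory.

    Temporal stability is reported only for pulse-train (stochastic-regime)
    data; for single-pulse data it is meaningless and flagged NaN. For
    pulse-train data the event-referenced metrics (resistance, recovery,
    resilience) reference the first event.
    """
    ts = temporal_stability_realised(traj.values) if pulse_train else math.nan
    return RealisedStability(
        temporal_stability=ts,
        resistance=resistance_realised(traj),
        recovery=recovery_realised(traj, t_end),
        resilience=resilience_realised(traj, K),
    )
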