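"""Growth-rate-corrected ("intrinsic") stability metrics.

The corrections rescale the time axis to growth-scaled time
``tau = r * (t - t_dist)``, on which one unit represents the same amount of
potential growth for every species, so that species differing only in
their growth rate ``r`` obtain the same value:

* intrinsic temporal stability = realised invariability / sqrt(r)
  (the stationary variance of the linearised jump process scales as 1/r,
  so the realised CV scales as 1/sqrt(r));
* intrinsic resilience = realised resilience / r (dN/dtau instead of dN/dt);
* intrinsic recovery evaluates N at the common growth-scaled horizon
  tau_ref shared by all cases under comparison;
* intrinsic resistance stretches the fastest grower's sampling lag
  dt_fast to (r_fast / r) * dt_fast for each slower grower, giving every
  species the same opportunity to rebound before it is "sampled".

Abundances between observations are obtained by linear interpolation;
extrapolation beyond a case's series is refused, so a slow grower whose
series is too short reports a missing value rather than a guess.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from pulsestab.dynamics_sim import Trajectory
from pulsestab.realised_metrics import pre_disturbance_abundance

__all__ = [
    "IntrinsicStability",
    "temporal_stability_intrinsic",
    "resilience_intrinsic",
    "recovery_intrinsic",
    "resistance_intrinsic",
    "rescaled_sampling_interval",
    "shared_tau_span",
    "value_at",
    "first_post_disturbance_lag",
]


@dataclass
class IntrinsicStability:
    """The four intrinsic metrics for one case (NaN = not computable)."""

    temporal_stability: float
    resistance: float
    recovery: float
    resilience: float


def temporal_stability_intrinsic(ts_real: float, r: float) -> float:
    """Divide realised invariability (1/CV) by sqrt(r)."""
    if not r > 0:
        raise ValueError(f"growth rate r must be > 0, got {r}")
    return ts_real / math.sqrt(r)


def resilience_intrinsic(res_real: float, r: float) -> float:
    """Realised resilience divided by r: the recovery rate per unit tau."""
    if not r > 0:
        raise ValueError(f"growth rate r must be > 0, got {r}")
    return res_real / r


def value_at(traj: Trajectory, t: float) -> float:
    """Abundance at time ``t``, linearly interpolated between observations.

    Exact at observation times; refuses to extrapolate.
    """
    if t < traj.times[0] or t > traj.times[-1]:
        raise ValueError(
            f"t={t} outside the observed range "
            f"[{traj.times[0]}, {traj.times[-1]}]; extrapolation refused"
        )
    return float(np.interp(t, traj.times, traj.values))


def shared_tau_span(
    growth_rates: Sequence[float],
    t_dists: Sequence[float],
    t_ends: Sequence[float],
) -> float:
    """The growth-scaled time span common to all cases under comparison.

    Each case covers tau in [0, r_i * (t_end_i - t_dist_i)]; the shared
    span is the minimum, the only region where every case can be evaluated
    without extrapolation.
    """
    spans = [
        r * (te - td) for r, td, te in zip(growth_rates, t_dists, t_ends, strict=True)
    ]
    if not spans:
        raise ValueError("no cases supplied")
    if min(spans) < 0:
        raise ValueError("t_end precedes t_dist for some case")
    return float(min(spans))


def recovery_intrinsic(
    traj: Trajectory,
    r: float,
    tau_ref: float,
    event_index: int = 0,
) -> float:
    """Recovery at the common growth-scaled horizon: N(t_dist + tau_ref/r)/N_pre.

    ``tau_ref`` is the reference point on the tau axis, normally the
    shared span of the comparison set (see :func:`shared_tau_span`); each
    case is evaluated at its own clock time t_dist + tau_ref / r, so the
    slow grower is sampled later and gets the same growth opportunity.
    """
    if not r > 0:
        raise ValueError(f"growth rate r must be > 0, got {r}")
    if tau_ref < 0:
        raise ValueError(f"tau_ref must be >= 0, got {tau_ref}")
    if len(traj.event_times) == 0:
        raise ValueError("trajectory records no disturbance events")
    t_dist = float(traj.event_times[event_index])
    n_pre = pre_disturbance_abundance(traj, t_dist)
    if n_pre == 0.0:
        raise ValueError("recovery undefined: pre-disturbance abundance is 0")
    t_eval = t_dist + tau_ref / r
    return value_at(traj, t_eval) / n_pre


def rescaled_sampling_interval(r: float, r_fast: float, dt_fast: float) -> float:
    """The post-disturbance sampling lag equivalent to ``dt_fast``.

    For logistic growth starting from the same fractional displacement, a
    grower with rate ``r`` needs ``(r_fast / r) * dt_fast`` to achieve the
    same rebound as the fastest grower achieves in ``dt_fast``.
    """
    if not r > 0 or not r_fast > 0:
        raise ValueError("growth rates must be > 0")
    if dt_fast < 0:
        raise ValueError(f"dt_fast must be >= 0, got {dt_fast}")
    return (r_fast / r) * dt_fast


def resistance_intrinsic(
    traj: Trajectory,
    r: float,
    r_fast: float,
    dt_fast: float,
    event_index: int = 0,
) -> float:
    """Resistance with the sampling lag stretched to match the fastest grower.

    Evaluates N(t_dist + (r_fast / r) * dt_fast) / N_pre, interpolating
    between the nearest samples when no observation falls exactly at the
    rescaled time. ``dt_fast`` is the lag between the disturbance and the
    fastest grower's first post-disturbance observation; ``r_fast`` that
    grower's rate. Raises when the rescaled time falls beyond the series
    (callers report the case as missing rather than extrapolate).
    """
    if r > r_fast:
        warnings.warn(
            f"case growth rate r={r} exceeds the reference r_fast={r_fast}; "
            "the rescaled interval is shorter than dt_fast"
        )
    dt_slow = rescaled_sampling_interval(r, r_fast, dt_fast)
    if len(traj.event_times) == 0:
        raise ValueError("trajectory records no disturbance events")
    t_dist = float(traj.event_times[event_index])
    n_pre = pre_disturbance_abundance(traj, t_dist)
    if n_pre == 0.0:
        raise ValueError("resistance undefined: pre-disturbance abundance is 0")
    return value_at(traj, t_dist + dt_slow) / n_pre


def first_post_disturbance_lag(traj: Trajectory, event_index: int = 0) -> float:
    """Lag from the disturbance to the first observation at/after it."""
    if len(traj.event_times) == 0:
        raise ValueError("trajectory records no disturbance events")
    t_dist = float(traj.event_times[event_index])
    after = np.nonzero(traj.times >= t_dist)[0]
    if len(after) == 0:
        raise ValueError("no observation at or after the disturbance")
    return float(traj.times[after[0]]) - t_dist
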