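"""Classification of motor-induced microtubule sliding events.

A sliding event is the trajectory of a mobile microtubule's reference
point along the axis of a surface-immobilized microtubule (µm, plus-end
positive, typically imaged for 400 s at 10 s intervals).  Events are
classified as directional (plus or minus), bi-directional, or static:

* directional — total start-to-finish displacement larger than the
  amplitude threshold (0.64 µm) and no opposite-direction excursion that
  is both larger than the threshold and longer than 30% of the total
  moving time;
* bi-directional — excursions larger than the threshold to both sides,
  with less than 70% of the moving time spent in the main direction;
* static — everything else.

"Moving time" counts only frames with actual displacement; pauses are
excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SlidingTrack",
    "Excursion",
    "SlidingClassification",
    "UndefinedVelocityError",
    "segment_excursions",
    "classify_sliding",
    "plus_end_velocity",
    "summarize_events",
    "AMP_THRESHOLD_UM",
    "OPP_TIME_FRACTION",
    "MAIN_TIME_FRACTION",
    "DEFAULT_NOISE_FLOOR_UM",
]

AMP_THRESHOLD_UM = 0.64
OPP_TIME_FRACTION = 0.30
MAIN_TIME_FRACTION = 0.70
#: Reversals smaller than this are treated as jitter and merged
#: (~2 px at 0.1 µm/px).
DEFAULT_NOISE_FLOOR_UM = 0.2

LABELS = ("directional_plus", "directional_minus", "bidirectional", "static")


class UndefinedVelocityError(ValueError):
    """Raised when a velocity is requested for a track with no such motion."""


@dataclass
class SlidingTrack:
    event_id: str
    t: np.ndarray   # s
    x: np.ndarray   # µm, signed, plus-end positive

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.size < 2:
            raise ValueError("sliding track needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class Excursion:
    direction: int        # +1 or -1
    amplitude_um: float   # unsigned net displacement of the run
    duration_s: float     # moving time within the run (pauses excluded)
    t_start: float
    t_end: float


@dataclass
class SlidingClassification:
    label: str
    net_displacement_um: float
    excursions: list[Excursion]
    main_direction_time_fraction: float | None  # None when nothing moves


def segment_excursions(
    track: SlidingTrack,
    noise_floor_um: float = DEFAULT_NOISE_FLOOR_UM,
    pause_eps_um: float = 0.0,
) -> list[Excursion]:
    """Split a track into monotone runs, merging sub-floor reversals.

    A new excursion starts when the position retraces more than
    ``noise_floor_um`` from the running extremum of the current run.
    Within a run, frames whose displacement magnitude is not larger than
    ``pause_eps_um`` are pauses and do not count toward the excursion's
    duration.
    """
    if noise_floor_um < 0:
        raise ValueError("noise_floor must be >= 0")
    t, x = track.t, track.x
    pivots = [0]
    direction = 0
    ext_idx = 0  # index of the running extremum of the current run
    for i in range(1, x.size):
        if direction == 0:
            if abs(x[i] - x[pivots[-1]]) > noise_floor_um:
                direction = 1 if x[i] > x[pivots[-1]] else -1
                ext_idx = i
            continue
        if (x[i] - x[ext_idx]) * direction >= 0:
            ext_idx = i
        elif abs(x[i] - x[ext_idx]) > noise_floor_um:
            pivots.append(ext_idx)
            direction = -direction
            ext_idx = i
    pivots.append(x.size - 1)

    out: list[Excursion] = []
    for a, b in zip(pivots[:-1], pivots[1:]):
        if b <= a:
            continue
        net = x[b] - x[a]
        if net == 0:
            continue
        seg_dx = np.diff(x[a : b + 1])
        seg_dt = np.diff(t[a : b + 1])
        moving = np.abs(seg_dx) > pause_eps_um
        out.append(
            Excursion(
                direction=1 if net > 0 else -1,
                amplitude_um=abs(float(net)),
                duration_s=float(np.sum(seg_dt[moving])),
                t_start=float(t[a]),
                t_end=float(t[b]),
            )
        )
    return out


def classify_sliding(
    track: SlidingTrack,
    amp_threshold_um: float = AMP_THRESHOLD_UM,
    opp_time_fraction: float = OPP_TIME_FRACTION,
    main_time_fraction: float = MAIN_TIME_FRACTION,
    noise_floor_um: float = DEFAULT_NOISE_FLOOR_UM,
) -> SlidingClassification:
    """Apply the directional / bi-directional / static rule set to a track."""
    if min(amp_threshold_um, opp_time_fraction, main_time_fraction) <= 0:
        raise ValueError("thresholds must be positive")
    exc = segment_excursions(track, noise_floor_um=noise_floor_um)
    net = float(track.x[-1] - track.x[0])
    moving = [e for e in exc if e.amplitude_um > noise_floor_um]
    moving_time = sum(e.duration_s for e in moving)
    plus_time = sum(e.duration_s for e in moving if e.direction > 0)
    minus_time = moving_time - plus_time
    main_frac = (
        max(plus_time, minus_time) / moving_time if moving_time > 0 else None
    )

    label = "static"
    if abs(net) > amp_threshold_um:
        sign = 1 if net > 0 else -1
        disqualifying = any(
            e.direction == -sign
            and e.amplitude_um > amp_threshold_um
            and e.duration_s > opp_time_fraction * moving_time
            for e in moving
        )
        if not disqualifying:
            label = "directional_plus" if sign > 0 else "directional_minus"
    if label == "static" and moving_time > 0:
        both_ways = (
            any(e.direction > 0 and e.amplitude_um > amp_threshold_um for e in moving)
            and any(
                e.direction < 0 and e.amplitude_um > amp_threshold_um for e in moving
            )
        )
        if both_ways and main_frac is not None and main_frac < main_time_fraction:
            label = "bidirectional"
    return SlidingClassification(
        label=label,
        net_displacement_um=net,
        excursions=exc,
        main_direction_time_fraction=main_frac,
    )


def plus_end_velocity(
    track: SlidingTrack,
    noise_floor_um: float = DEFAULT_NOISE_FLOOR_UM,
    pause_eps_um: float = 0.0,
) -> float:
    """Plus-end directed sliding velocity in nm/s.

    Sum of continuous plus-direction displacement divided by the moving
    time it took (pauses excluded).  Raises
    :class:`UndefinedVelocityError` if the track has no plus-directed
    excursion.
    """
    exc = segment_excursions(
        track, noise_floor_um=noise_floor_um, pause_eps_um=pause_eps_um
    )
    plus = [e for e in exc if e.direction > 0 and e.amplitude_um > noise_floor_um]
    if not plus:
        raise UndefinedVelocityError(
            f"track {track.event_id} has no plus-directed excursion"
        )
    dist_um = sum(e.amplitude_um for e in plus)
    time_s = sum(e.duration_s for e in plus)
    if time_s <= 0:
        raise UndefinedVelocityError("zero plus-directed moving time")
    return 1000.0 * dist_um / time_s


def summarize_events(
    classified: Sequence[SlidingClassification],
    velocities_nm_s: Sequence[float] | None = None,
) -> dict:
    """Label fractions plus the plus-end velocity summary.

    ``velocities_nm_s`` aligns with ``classified``; velocity statistics are
    taken over events classified as plus-end directed (NaN entries — e.g.
    undefined velocities — are dropped).  SEM is None when fewer than two
    velocities contribute.
    """
    if len(classified) == 0:
        raise ValueError("summarize_events needs at least 1 event")
    n = len(classified)
    fractions = {
        lab: sum(c.label == lab for c in classified) / n for lab in LABELS
    }
    mean_v = sem_v = None
    n_v = 0
    if velocities_nm_s is not None:
        vs = np.array(
            [
                v
                for c, v in zip(classified, velocities_nm_s)
                if c.label == "directional_plus" and v is not None and math.isfinite(v)
            ]
        )
        n_v = int(vs.size)
        if n_v >= 1:
            mean_v = float(np.mean(vs))
        if n_v >= 2:
            sem_v = float(np.std(vs, ddof=1) / math.sqrt(n_v))
    return {
        "n_events": n,
        "fractions": fractions,
        "plus_velocity_mean_nm_s": mean_v,
        "plus_velocity_sem_nm_s": sem_v,
        "n_plus_velocities": n_v,
    }
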