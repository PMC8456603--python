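"""Mean-displacement velocity analysis of single-molecule tracks.

Tracks are one-dimensional signed positions along the microtubule axis
(plus-end positive, so minus-end directed motors have negative
velocities).  The mean displacement MD(t) averages, over all tracks alive
at elapsed time t from their own start, the signed displacement
x(t0 + t) − x(t0); the velocity is the slope of the through-origin linear
fit MD = v·t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .photobleach import UnitCalibration

__all__ = [
    "Track",
    "TrackSet",
    "MDProfile",
    "select_motile",
    "mean_displacement",
    "fit_velocity",
    "run_lengths",
    "DEFAULT_ONSET_WINDOW_S",
    "DEFAULT_NOISE_FLOOR_NM",
]

#: Motility is analyzed only for motors that start moving within this window,
#: so that fluorophore bleaching (lifetime ~23 s) does not bias the sample.
DEFAULT_ONSET_WINDOW_S = 30.0

#: Onset criterion |x - x0| > floor; 50 nm is ~3x the localization error of
#: a typical single-molecule rig.
DEFAULT_NOISE_FLOOR_NM = 50.0


@dataclass
class Track:
    track_id: str
    t: np.ndarray          # s
    x: np.ndarray          # nm, signed along the MT axis
    intensity: np.ndarray | None = None  # a.u.

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.size < 2:
            raise ValueError("track needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("track times must be strictly increasing")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)

    @property
    def mean_intensity(self) -> float | None:
        if self.intensity is None:
            return None
        return float(np.mean(self.intensity))


@dataclass
class TrackSet:
    tracks: list[Track]
    ground_truth: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            for i in range(tr.t.size):
                rows.append(
                    {
                        "track_id": tr.track_id,
                        "t_s": tr.t[i],
                        "x_nm": tr.x[i],
                        "intensity_au": (
                            tr.intensity[i] if tr.intensity is not None else np.nan
                        ),
                    }
                )
        return pd.DataFrame(rows, columns=["track_id", "t_s", "x_nm", "intensity_au"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrackSet":
        tracks = []
        for tid, g in df.groupby("track_id", sort=False):
            g = g.sort_values("t_s")
            inten = None
            if "intensity_au" in g and not g["intensity_au"].isna().all():
                inten = g["intensity_au"].to_numpy()
            tracks.append(
                Track(str(tid), g["t_s"].to_numpy(), g["x_nm"].to_numpy(), inten)
            )
        return cls(tracks)


@dataclass
class MDProfile:
    lags: np.ndarray            # s, elapsed time from track start
    md: np.ndarray              # nm, mean signed displacement
    n_per_lag: np.ndarray       # tracks contributing at each lag
    per_track: np.ndarray | None = None    # tracks x lags displacement, NaN-padded
    fitted_velocity: float | None = None   # nm/s
    velocity_sd: float | None = None


def select_motile(
    tracks: TrackSet,
    onset_window: float = DEFAULT_ONSET_WINDOW_S,
    gate: UnitCalibration | None = None,
    noise_floor_nm: float = DEFAULT_NOISE_FLOOR_NM,
) -> TrackSet:
    """Keep tracks that start moving early and pass the single-molecule gate.

    Motion onset is the first sample with |x − x(0)| > ``noise_floor_nm``;
    tracks whose onset exceeds ``onset_window`` (s, from the track start),
    or that never move, are dropped.  If a calibration gate is given,
    tracks whose mean intensity is at or above the gate are dropped too.
    """
    if not onset_window > 0:
        raise ValueError("onset_window must be positive")
    kept = []
    for tr in tracks:
        disp = np.abs(tr.x - tr.x[0])
        moving = np.nonzero(disp > noise_floor_nm)[0]
        if moving.size == 0:
            continue
        onset = tr.t[moving[0]] - tr.t[0]
        if onset > onset_window:
            continue
        if gate is not None and tr.intensity is not None:
            if tr.mean_intensity >= gate.max_single_intensity:
                continue
        kept.append(tr)
    return TrackSet(kept, ground_truth=dict(tracks.ground_truth))


def mean_displacement(tracks: TrackSet) -> MDProfile:
    """Mean signed displacement vs elapsed time from each track's own start.

    Tracks are aligned on their first sample; displacements are binned on
    the common frame grid (inferred from the smallest sampling interval).
    """
    if len(tracks) == 0:
        raise ValueError("mean_displacement needs at least 1 track")
    dt = min(float(np.min(np.diff(tr.t))) for tr in tracks)
    per_track_idx = []
    max_idx = 0
    for tr in tracks:
        elapsed = tr.t - tr.t[0]
        disp = tr.x - tr.x[0]
        idx = np.rint(elapsed / dt).astype(int)
        per_track_idx.append((idx, disp))
        max_idx = max(max_idx, int(idx.max()))
    grid = np.full((len(tracks), max_idx + 1), np.nan)
    for i, (idx, disp) in enumerate(per_track_idx):
        grid[i, idx] = disp
    n = np.sum(~np.isnan(grid), axis=0)
    keep = n > 0
    with np.errstate(invalid="ignore"):
        md = np.nanmean(grid[:, keep], axis=0)
    lags = np.arange(max_idx + 1)[keep] * dt
    return MDProfile(lags=lags, md=md, n_per_lag=n[keep], per_track=grid[:, keep])


def fit_velocity(
    profile: MDProfile, min_tracks_per_lag: int = 5
) -> tuple[float, float]:
    """Least-squares slope of MD = v·t through the origin.

    Lags supported by fewer than ``min_tracks_per_lag`` tracks are dropped
    to avoid tail noise.  Returns (v nm/s, sd of the slope estimate); the
    fitted values are also stored on the profile.  The slope SD is the
    standard error of per-track through-origin slopes — MD values at
    different lags share tracks, so a residual-based error would be
    optimistic.
    """
    use = (profile.n_per_lag >= min_tracks_per_lag) & (profile.lags > 0)
    t = profile.lags[use]
    y = profile.md[use]
    if t.size < 3:
        raise ValueError("need at least 3 usable lags to fit a velocity")
    stt = float(np.sum(t * t))
    v = float(np.sum(y * t) / stt)
    if profile.per_track is not None:
        slopes = []
        for row in profile.per_track[:, use]:
            ok = ~np.isnan(row)
            if ok.sum() >= 1 and np.sum(t[ok] ** 2) > 0:
                slopes.append(float(np.sum(row[ok] * t[ok]) / np.sum(t[ok] ** 2)))
        slopes = np.asarray(slopes)
        sd = (
            float(np.std(slopes, ddof=1) / math.sqrt(slopes.size))
            if slopes.size > 1
            else 0.0
        )
    else:
        resid = y - v * t
        sd = float(math.sqrt(np.sum(resid**2) / (t.size - 1) / stt))
    profile.fitted_velocity = v
    profile.velocity_sd = sd
    return v, sd


def run_lengths(tracks: TrackSet) -> tuple[np.ndarray, float, float | None]:
    """Net start-to-end displacement magnitude per track, in µm.

    Returns (per-track lengths µm, mean, SEM); SEM is None for a single
    track.
    """
    if len(tracks) == 0:
        raise ValueError("run_lengths needs at least 1 track")
    lengths = np.array([abs(tr.x[-1] - tr.x[0]) / 1000.0 for tr in tracks])
    mean = float(np.mean(lengths))
    sem = (
        float(np.std(lengths, ddof=1) / math.sqrt(lengths.size))
        if lengths.size > 1
        else None
    )
    return lengths, mean, sem
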