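"""Threshold-based saccade detection and per-event kinematics.

Two detectors, matched to the two recording configurations:

* head-fixed (200 Hz, 1-D azimuth): trigger on a per-frame displacement
  above 0.75 deg, require monotone movement over at least 3 successive
  frames and a peak amplitude of at least 3 deg;
* freely moving (90 Hz, 2-D): trigger on a per-frame displacement above
  5.5 deg in any direction (~500 deg/s, above head-movement speeds, so the
  events are not vestibulo-ocular image stabilisation), back-track the
  onset to the first frame exceeding 200 deg/s, require at least 2 frames
  of motion with successive displacement vectors within 45 deg of each
  other.

Thresholds are stored with their native frame duration and rescaled as
velocities when a trace's frame rate differs from the detector's design
rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .eye_geometry import EyeTrace

__all__ = [
    "DetectorParams",
    "HEAD_FIXED_PARAMS",
    "FREELY_MOVING_PARAMS",
    "detect_head_fixed",
    "detect_freely_moving",
    "isolation_filter",
    "kinematics",
    "bin_directions",
    "axis_bias_test",
    "SECTOR_LABELS",
]

EVENT_COLUMNS = [
    "onset_t",
    "offset_t",
    "amplitude",
    "direction_deg",
    "direction_label",
    "rise_time_10_90_ms",
    "rise_time_0_90_ms",
    "mean_speed",
    "isolated",
]


@dataclass(frozen=True)
class DetectorParams:
    """Detection thresholds, stored with their design frame duration."""

    frame_ms: float                 # frame duration the thresholds refer to
    step_threshold_deg: float       # per-frame displacement trigger
    min_monotone_frames: int        # minimum frames of consistent movement
    min_amplitude_deg: float        # minimum peak amplitude (0 = none)
    onset_speed_deg_s: float | None = None   # back-tracking speed (2-D only)
    max_vector_angle_deg: float | None = None  # inter-frame direction change cap
    quiet_period_ms: float = 500.0
    quiet_motion_deg: float = 0.2   # per-frame motion regarded as "still"

    def rescaled(self, frame_rate: float) -> "DetectorParams":
        """Rescale per-frame thresholds to a different frame rate.

        Per-frame displacement thresholds are treated as velocity
        thresholds (deg per design frame -> deg/s -> deg per actual frame);
        frame-count minima are treated as durations.
        """
        native_rate = 1000.0 / self.frame_ms
        if abs(frame_rate - native_rate) / native_rate <= 0.10:
            return self
        warnings.warn(
            f"trace frame rate {frame_rate:.1f} Hz differs from the "
            f"detector's design rate {native_rate:.1f} Hz; rescaling "
            "per-frame thresholds as velocities",
            stacklevel=3,
        )
        scale = native_rate / frame_rate  # new frame duration / old
        n_frames = max(2, int(round(self.min_monotone_frames
                                    * self.frame_ms * frame_rate / 1000.0)))
        return replace(
            self,
            frame_ms=1000.0 / frame_rate,
            step_threshold_deg=self.step_threshold_deg * scale,
            min_monotone_frames=n_frames,
            quiet_motion_deg=self.quiet_motion_deg * scale,
        )


HEAD_FIXED_PARAMS = DetectorParams(
    frame_ms=5.0,
    step_threshold_deg=0.75,
    min_monotone_frames=3,
    min_amplitude_deg=3.0,
)

FREELY_MOVING_PARAMS = DetectorParams(
    frame_ms=1000.0 / 90.0,
    step_threshold_deg=5.5,
    min_monotone_frames=2,
    min_amplitude_deg=0.0,
    onset_speed_deg_s=200.0,
    max_vector_angle_deg=45.0,
)


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=EVENT_COLUMNS)


def detect_head_fixed(
    trace: EyeTrace, params: DetectorParams = HEAD_FIXED_PARAMS
) -> pd.DataFrame:
    """Detect horizontal saccades in a head-fixed trace.

    Returns a DataFrame of events (columns ``onset_t``, ``offset_t``,
    ``amplitude``, ``direction_label`` in {nasal, temporal}, kinematics).
    Nasal is the positive-azimuth direction.
    """
    params = params.rescaled(trace.frame_rate)
    x = trace.azimuth
    t = trace.t
    dx = np.diff(x)
    trigger = np.abs(dx) > params.step_threshold_deg
    if not trigger.any():
        return _empty_events()

    rows = []
    used_until = -1
    for i in np.flatnonzero(trigger):
        if i <= used_until:
            continue
        sign = np.sign(dx[i])
        # extend the run of same-direction movement around the trigger frame
        start = i
        while start > 0 and np.isfinite(dx[start - 1]) and np.sign(dx[start - 1]) == sign and dx[start - 1] != 0:
            start -= 1
        end = i
        while end + 1 < len(dx) and np.isfinite(dx[end + 1]) and np.sign(dx[end + 1]) == sign and dx[end + 1] != 0:
            end += 1
        used_until = end
        n_frames = end - start + 1
        if n_frames < params.min_monotone_frames:
            continue
        amplitude = abs(x[end + 1] - x[start])
        if amplitude < params.min_amplitude_deg:
            continue
        rows.append(
            {
                "onset_t": t[start],
                "offset_t": t[end + 1],
                "onset_index": start,
                "offset_index": end + 1,
                "amplitude": amplitude,
                "direction_deg": 0.0 if sign > 0 else 180.0,
                "direction_label": "nasal" if sign > 0 else "temporal",
                "isolated": False,
            }
        )
    if not rows:
        return _empty_events()
    events = pd.DataFrame(rows)
    return _attach_kinematics(trace, events, two_d=False)


def detect_freely_moving(
    trace: EyeTrace, params: DetectorParams = FREELY_MOVING_PARAMS
) -> pd.DataFrame:
    """Detect 2-D saccades in a freely-moving trace."""
    params = params.rescaled(trace.frame_rate)
    t = trace.t
    pos = np.column_stack([trace.azimuth, trace.elevation])
    step = np.diff(pos, axis=0)                      # (n-1, 2)
    step_norm = np.hypot(step[:, 0], step[:, 1])
    dt = 1.0 / trace.frame_rate
    speed = step_norm / dt
    trigger = step_norm > params.step_threshold_deg
    if not trigger.any():
        return _empty_events()
    fast = speed > (params.onset_speed_deg_s or 0.0)

    rows = []
    used_until = -1
    for i in np.flatnonzero(trigger):
        if i <= used_until:
            continue
        # back-track onset to the first frame of the uninterrupted
        # above-onset-speed run that contains the trigger frame
        start = i
        while start > 0 and fast[start - 1]:
            start -= 1
        end = i
        while end + 1 < len(step_norm) and fast[end + 1]:
            end += 1
        used_until = end
        n_frames = end - start + 1
        if n_frames < params.min_monotone_frames:
            continue
        # successive movement vectors must agree in direction
        angles = np.degrees(np.arctan2(step[start : end + 1, 1], step[start : end + 1, 0]))
        dang = np.abs((np.diff(angles) + 180.0) % 360.0 - 180.0)
        if dang.size and np.max(dang) > (params.max_vector_angle_deg or 180.0):
            continue
        net = pos[end + 1] - pos[start]
        amplitude = float(np.hypot(net[0], net[1]))
        if amplitude < params.min_amplitude_deg:
            continue
        direction = float(np.degrees(np.arctan2(net[1], net[0])) % 360.0)
        rows.append(
            {
                "onset_t": t[start],
                "offset_t": t[end + 1],
                "onset_index": start,
                "offset_index": end + 1,
                "amplitude": amplitude,
                "direction_deg": direction,
                "direction_label": _nt_label(direction),
                "isolated": False,
            }
        )
    if not rows:
        return _empty_events()
    events = pd.DataFrame(rows)
    return _attach_kinematics(trace, events, two_d=True)


def _nt_label(direction_deg: float) -> str:
    d = direction_deg % 360.0
    if d <= 90.0 or d > 270.0:
        return "nasal"
    return "temporal"


def isolation_filter(
    events: pd.DataFrame,
    trace: EyeTrace,
    quiet_ms: float = 500.0,
    quiet_motion_deg: float = 0.2,
) -> pd.DataFrame:
    """Keep only saccades preceded by a quiet period of ``quiet_ms``.

    "Quiet" means no frame-to-frame displacement above ``quiet_motion_deg``
    (per frame) in the window before onset; events starting with less than
    ``quiet_ms`` of recorded history are dropped.  Displacements are
    averaged over 3 frames before thresholding so single-frame tracking
    jitter does not count as movement.  The returned frame carries
    ``isolated=True`` for the survivors.
    """
    if events.empty:
        return events
    events = events.sort_values("onset_t").reset_index(drop=True)
    pos = np.column_stack([trace.azimuth, trace.elevation])
    step = np.diff(pos, axis=0)
    # 3-frame moving average: genuine movement persists, jitter cancels
    kernel = np.ones(3) / 3.0
    step = np.column_stack(
        [np.convolve(step[:, 0], kernel, mode="same"),
         np.convolve(step[:, 1], kernel, mode="same")]
    )
    step_norm = np.hypot(step[:, 0], step[:, 1])
    moving = step_norm > quiet_motion_deg
    t = trace.t
    keep = np.zeros(len(events), dtype=bool)
    for k, onset in enumerate(events["onset_t"].to_numpy()):
        w0 = onset - quiet_ms / 1000.0
        if w0 < t[0]:
            continue  # insufficient history
        i0 = np.searchsorted(t, w0, side="left")
        i1 = np.searchsorted(t, onset, side="left")
        # step j spans t[j] -> t[j+1]; steps fully inside [w0, onset)
        if i1 > i0 and moving[i0 : max(i1 - 1, i0)].any():
            continue
        keep[k] = True
    out = events.loc[keep].reset_index(drop=True)
    out["isolated"] = True
    return out


def kinematics(trace: EyeTrace, event: pd.Series, settle_ms: float = 20.0) -> dict:
    """Amplitude, rise times and mean speed for one detected event.

    Amplitude is the displacement from the onset position to the
    post-saccade plateau (median position over ``settle_ms`` after offset).
    Rise times come from linearly interpolated crossings of 10% and 90% of
    the displacement; mean speed is amplitude over the onset-offset
    duration.
    """
    i0 = int(event["onset_index"])
    i1 = int(event["offset_index"])
    t = trace.t
    two_d = trace.condition == "freely_moving"
    if two_d:
        pos = np.column_stack([trace.azimuth, trace.elevation])
    else:
        pos = trace.azimuth[:, None]
    p0 = pos[i0]
    j1 = np.searchsorted(t, t[i1] + settle_ms / 1000.0, side="right")
    plateau_flagged = False
    if j1 > i1 + 1:
        plateau = np.nanmedian(pos[i1:j1], axis=0)
    else:
        plateau = pos[i1]
        plateau_flagged = True
    disp_vec = plateau - p0
    amplitude = float(np.linalg.norm(disp_vec))
    # displacement projected on the saccade direction, relative to onset
    u = disp_vec / amplitude if amplitude > 0 else disp_vec
    proj = (pos[i0 : i1 + 1] - p0) @ u
    tt = t[i0 : i1 + 1]

    def crossing(level: float) -> float:
        target = level * amplitude
        above = np.flatnonzero(proj >= target)
        if above.size == 0:
            return float(tt[-1])
        j = above[0]
        if j == 0:
            return float(tt[0])
        frac = (target - proj[j - 1]) / (proj[j] - proj[j - 1])
        return float(tt[j - 1] + frac * (tt[j] - tt[j - 1]))

    t10, t90 = crossing(0.10), crossing(0.90)
    t0 = float(tt[0])
    duration = float(t[i1] - t[i0])
    return {
        "amplitude": amplitude,
        "rise_time_10_90_ms": (t90 - t10) * 1000.0,
        "rise_time_0_90_ms": (t90 - t0) * 1000.0,
        "mean_speed": amplitude / duration if duration > 0 else np.nan,
        "plateau_flagged": plateau_flagged,
    }


def _attach_kinematics(trace: EyeTrace, events: pd.DataFrame, two_d: bool) -> pd.DataFrame:
    kin = pd.DataFrame([kinematics(trace, row) for _, row in events.iterrows()])
    events = events.copy()
    for col in ["rise_time_10_90_ms", "rise_time_0_90_ms", "mean_speed"]:
        events[col] = kin[col].to_numpy()
    # keep the threshold-rule amplitude for gating; expose the plateau one too
    events["amplitude_plateau"] = kin["amplitude"].to_numpy()
    return events


SECTOR_LABELS = [
    "nasal",
    "naso-dorsal",
    "dorsal",
    "dorso-temporal",
    "temporal",
    "temporo-ventral",
    "ventral",
    "ventro-nasal",
]


def bin_directions(directions_deg: np.ndarray, n_sectors: int = 8) -> np.ndarray:
    """Assign each direction to one of ``n_sectors`` even sectors.

    Sectors are centred on 0, 45, ..., 315 deg (sector 0 = nasal).  A
    direction exactly on a boundary (e.g. 22.5 deg) goes to the lower
    sector.
    """
    d = np.asarray(directions_deg, dtype=float) % 360.0
    width = 360.0 / n_sectors
    half = width / 2.0
    # boundary d = k*width + half belongs to sector k (the lower one)
    idx = np.ceil((d - half) / width - 1e-12).astype(int) % n_sectors
    return idx


def axis_bias_test(n_horizontal: int, n_vertical: int) -> float:
    """Two-sided exact binomial test for a horizontal-vs-vertical bias.

    Under the null, a saccade is horizontal with probability 1/2.
    """
    if n_horizontal < 0 or n_vertical < 0:
        raise ValueError("counts must be non-negative")
    n = n_horizontal + n_vertical
    if n == 0:
        raise ValueError("at least one saccade required")
    return float(stats.binomtest(n_horizontal, n, p=0.5, alternative="two-sided").pvalue)
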