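"""Angular eye position from video-oculography landmarks.

The camera sees the pupil as an ellipse.  The angular position of the eye
follows the projection geometry ``sin(alpha) = d / Rp``, where ``d`` is the
projected distance between the pupil centre and a stationary corneal
reference point, and ``Rp`` is the radius of the circle that the pupil
centre travels on as the eye rotates.  ``Rp`` is not constant: the plane of
the pupil moves away from the rotational centre as the pupil constricts, so
``Rp`` shrinks linearly with pupil diameter, ``Rp = r - a * Dp``.

The calibration swings the camera (with its reference light source) by known
angles ``gamma`` about the rotational centre of the eye; the measured
displacements ``d(gamma)`` determine ``Rp`` per luminance condition, and the
regression of ``Rp`` on pupil diameter yields ``(r, a)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import EllipseModel

__all__ = [
    "CalibrationModel",
    "PupilEllipse",
    "EyeTrace",
    "fit_pupil_ellipse",
    "pupil_radius_on_sphere",
    "angular_position",
    "calibrate_from_swing",
    "trace_from_landmarks",
]


class GeometryError(ValueError):
    """Raised when a geometric precondition is violated."""


@dataclass(frozen=True)
class CalibrationModel:
    """Linear pupil-size calibration ``Rp = r - a * Dp``.

    Parameters
    ----------
    r : float
        Effective eyeball radius term, mm.  Must be positive.
    a : float
        Dimensionless slope of the pupil-plane recession with pupil
        diameter; physiologically around 0.05-0.25.
    valid_dp_range : (float, float)
        Pupil-diameter range (mm) over which the line was fitted.
    slope_identified : bool
        False when all calibration measurements shared one pupil diameter
        and only ``r`` could be estimated (``a`` fixed at 0).
    """

    r: float
    a: float
    valid_dp_range: tuple[float, float] = (0.3, 2.5)
    slope_identified: bool = True

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise GeometryError(f"eyeball radius term must be positive, got {self.r}")


@dataclass(frozen=True)
class PupilEllipse:
    """Ellipse fitted to pupil-edge landmarks (image coordinates)."""

    center: tuple[float, float]
    major_axis: float
    minor_axis: float
    orientation_deg: float

    def __post_init__(self) -> None:
        if not (self.major_axis >= self.minor_axis > 0):
            raise GeometryError(
                f"need major >= minor > 0, got {self.major_axis}, {self.minor_axis}"
            )


@dataclass
class EyeTrace:
    """Gaze-angle time series.

    Azimuth is nasal-positive and elevation dorsal-positive, in degrees.
    ``t`` is strictly increasing, approximately uniform at ``frame_rate``.
    Frames where the landmark fit failed are NaN (flagged gaps, never
    interpolated).
    """

    t: np.ndarray
    azimuth: np.ndarray
    elevation: np.ndarray
    pupil_diameter: np.ndarray
    frame_rate: float
    condition: str = "head_fixed"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.azimuth = np.asarray(self.azimuth, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        self.pupil_diameter = np.asarray(self.pupil_diameter, dtype=float)
        if not (len(self.t) == len(self.azimuth) == len(self.elevation)):
            raise ValueError("t, azimuth, elevation must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "azimuth_deg": self.azimuth,
                "elevation_deg": self.elevation,
                "pupil_mm": self.pupil_diameter,
            }
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, frame_rate: float, condition: str = "head_fixed"
    ) -> "EyeTrace":
        return cls(
            t=df["t_s"].to_numpy(),
            azimuth=df["azimuth_deg"].to_numpy(),
            elevation=df["elevation_deg"].to_numpy(),
            pupil_diameter=df["pupil_mm"].to_numpy()
            if "pupil_mm" in df
            else np.full(len(df), np.nan),
            frame_rate=frame_rate,
            condition=condition,
        )


def fit_pupil_ellipse(points: np.ndarray) -> PupilEllipse:
    """Fit an ellipse to pupil-edge landmarks by direct least squares.

    Parameters
    ----------
    points : (n, 2) array
        At least 5 non-collinear (x, y) landmark positions.

    Returns
    -------
    PupilEllipse
        ``major_axis``/``minor_axis`` are full axis lengths (twice the
        semi-axes): pupil diameter is conventionally the long axis of the
        fitted ellipse.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise GeometryError(f"need >= 5 (x, y) points, got shape {pts.shape}")
    # collinearity check: rank of centered coordinates
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise GeometryError("landmarks are collinear; ellipse fit is degenerate")
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(pts)
        if not model:
            raise GeometryError("ellipse fit failed to converge")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:  # scikit-image < 0.26
        model = EllipseModel()
        if not model.estimate(pts):
            raise GeometryError("ellipse fit failed to converge")
        xc, yc, a, b, theta = model.params
    if not np.isfinite([xc, yc, a, b, theta]).all() or a <= 0 or b <= 0:
        raise GeometryError("degenerate ellipse fit")
    if a < b:  # normalise so the major axis comes first
        a, b = b, a
        theta += np.pi / 2.0
    orient = np.rad2deg(theta) % 180.0
    if orient >= 90.0:  # report orientation in (-90, 90]
        orient -= 180.0
    return PupilEllipse(
        center=(float(xc), float(yc)),
        major_axis=2.0 * float(a),
        minor_axis=2.0 * float(b),
        orientation_deg=float(orient),
    )


def pupil_radius_on_sphere(dp: float, calib: CalibrationModel) -> float:
    """Pupil-circle radius ``Rp = r - a * Dp`` for pupil diameter ``dp`` (mm)."""
    rp = calib.r - calib.a * float(dp)
    if rp <= 0:
        raise GeometryError(
            f"Rp = {calib.r} - {calib.a} * {dp} = {rp} <= 0; "
            "pupil diameter outside the calibrated geometry"
        )
    return rp


def angular_position(d: float | np.ndarray, rp: float) -> float | np.ndarray:
    """Eye angle ``alpha = arcsin(d / Rp)`` in degrees (nasal/dorsal positive).

    NaN inputs propagate (gap frames); any finite ``|d| > Rp`` violates the
    projection geometry and raises.
    """
    d = np.asarray(d, dtype=float)
    finite = np.isfinite(d)
    if np.any(np.abs(d[finite]) > rp * (1 + 1e-12)):
        raise GeometryError(f"|d| exceeds Rp = {rp}; geometry violated")
    alpha = np.degrees(np.arcsin(np.clip(d / rp, -1.0, 1.0)))
    alpha = np.where(finite, alpha, np.nan)
    return float(alpha) if alpha.ndim == 0 else alpha


def calibrate_from_swing(
    measurements: pd.DataFrame | np.ndarray,
) -> CalibrationModel:
    """Estimate ``(r, a)`` from camera-swing calibration measurements.

    Each measurement is ``(gamma_deg, d_mm, dp_mm)``: the camera was swung by
    ``gamma`` about the rotational centre of the eye and the projected
    pupil-to-reference distance ``d`` recorded, at pupil diameter ``dp``.

    Within one luminance condition (one ``dp`` level) the model is
    ``d = Rp * sin(gamma + alpha0)`` with unknown resting angle ``alpha0``.
    Expanding, ``d = A sin(gamma) + B cos(gamma)`` is linear in
    ``(A, B) = Rp (cos(alpha0), sin(alpha0))``, so each condition yields
    ``Rp = hypot(A, B)`` by ordinary least squares.  ``(r, a)`` then come
    from the regression ``Rp = r - a * Dp`` across conditions.
    """
    if isinstance(measurements, pd.DataFrame):
        gamma = measurements["gamma_deg"].to_numpy(dtype=float)
        d = measurements["d_mm"].to_numpy(dtype=float)
        dp = measurements["dp_mm"].to_numpy(dtype=float)
    else:
        arr = np.asarray(measurements, dtype=float)
        gamma, d, dp = arr[:, 0], arr[:, 1], arr[:, 2]

    rps, dps = [], []
    for level in np.unique(dp):
        sel = dp == level
        if np.unique(gamma[sel]).size < 2:
            raise GeometryError(
                f"need >= 2 distinct swing angles at pupil diameter {level}"
            )
        g = np.radians(gamma[sel])
        design = np.column_stack([np.sin(g), np.cos(g)])
        (A, B), *_ = np.linalg.lstsq(design, d[sel], rcond=None)
        rps.append(float(np.hypot(A, B)))
        dps.append(float(level))

    rps_arr = np.asarray(rps)
    dps_arr = np.asarray(dps)
    if np.unique(dps_arr).size < 2:
        warnings.warn(
            "all calibration measurements share one pupil diameter; "
            "slope a is unidentifiable, returning r-only model (a = 0)",
            stacklevel=2,
        )
        return CalibrationModel(
            r=float(rps_arr.mean()),
            a=0.0,
            valid_dp_range=(float(dps_arr.min()), float(dps_arr.max())),
            slope_identified=False,
        )
    # Rp = r - a * Dp
    design = np.column_stack([np.ones_like(dps_arr), -dps_arr])
    (r, a), *_ = np.linalg.lstsq(design, rps_arr, rcond=None)
    return CalibrationModel(
        r=float(r),
        a=float(a),
        valid_dp_range=(float(dps_arr.min()), float(dps_arr.max())),
    )


def trace_from_landmarks(
    frames: pd.DataFrame,
    calib: CalibrationModel,
    px_to_mm: float,
    frame_rate: float,
    condition: str = "head_fixed",
    azimuth_sign: float = 1.0,
    elevation_sign: float = 1.0,
) -> EyeTrace:
    """Build an :class:`EyeTrace` from per-frame pupil landmarks.

    ``frames`` must contain columns ``t_s``, ``x1..x8``/``y1..y8`` pupil-edge
    landmarks (px) and ``ref_x``/``ref_y`` (px), the corneal reference.
    Frames whose ellipse fit fails are emitted as NaN gaps.  The sign
    arguments map image axes onto the nasal-positive / dorsal-positive
    convention (camera mirroring differs between rigs).
    """
    n = len(frames)
    xcols = [c for c in frames.columns if c.startswith("x") and c[1:].isdigit()]
    ycols = [c for c in frames.columns if c.startswith("y") and c[1:].isdigit()]
    if len(xcols) < 5 or len(ycols) != len(xcols):
        raise GeometryError("need matching x1..xk / y1..yk landmark columns, k >= 5")
    xcols = sorted(xcols, key=lambda c: int(c[1:]))
    ycols = sorted(ycols, key=lambda c: int(c[1:]))

    az = np.full(n, np.nan)
    el = np.full(n, np.nan)
    dp_mm = np.full(n, np.nan)
    n_failed = 0
    X = frames[xcols].to_numpy(dtype=float)
    Y = frames[ycols].to_numpy(dtype=float)
    refx = frames["ref_x"].to_numpy(dtype=float)
    refy = frames["ref_y"].to_numpy(dtype=float)
    for i in range(n):
        pts = np.column_stack([X[i], Y[i]])
        if not np.isfinite(pts).all():
            n_failed += 1
            continue
        try:
            ell = fit_pupil_ellipse(pts)
        except GeometryError:
            n_failed += 1
            continue
        dp = ell.major_axis * px_to_mm
        try:
            rp = pupil_radius_on_sphere(dp, calib)
            dx = (ell.center[0] - refx[i]) * px_to_mm
            dy = (ell.center[1] - refy[i]) * px_to_mm
            az[i] = azimuth_sign * angular_position(dx, rp)
            el[i] = elevation_sign * angular_position(dy, rp)
            dp_mm[i] = dp
        except GeometryError:
            n_failed += 1
    if n and n_failed / n > 0.20:
        warnings.warn(
            f"{n_failed}/{n} frames failed the ellipse fit or geometry check",
            stacklevel=2,
        )
    return EyeTrace(
        t=frames["t_s"].to_numpy(dtype=float),
        azimuth=az,
        elevation=el,
        pupil_diameter=dp_mm,
        frame_rate=frame_rate,
        condition=condition,
        meta={"n_failed_frames": n_failed},
    )
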