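"""Offset center-of-rotation divergent-beam geometry.

The system is a straight source--mask--object--detector line.  The
rotation axis (COR) is displaced by ``delta_cor`` perpendicular to the
source--detector axis.  All quantities used by the redundancy weighting
and the reconstruction are derived here.

Coordinate conventions
----------------------
* The COR sits at the origin; the sample frame is fixed, and the
  source/detector pair rotates about the origin (equivalent to a
  rotating-sample scan).
* At view angle ``alpha = 0`` the source is at ``(delta_cor, -z_so)``
  and the detector center at ``(delta_cor, zod)``; the detector column
  axis points along ``+x``.  Angles increase counter-clockwise.
* The detector coordinate ``x`` is the signed distance from the
  detector center (meters); pixel ``i`` is centered at
  ``(i - (n_col - 1)/2) * p`` so index 0 sits on the ``-x`` edge.
* ``tau`` is the signed angle between the central ray (source to
  detector center) and the ray through the COR.  With ``delta_cor > 0``
  the COR ray lands on the ``-x`` half of the detector
  (``tau = -atan(delta_cor / z_so)``), which leaves the ``+x`` half
  singly covered: the field-of-view extension side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SystemGeometry",
    "DerivedGeometry",
    "RedundantRegion",
    "ViewGeometry",
    "AcquisitionPlan",
    "derive_geometry",
    "redundant_bounds",
    "view_vectors",
    "plan_scan",
    "geometry_from_fov",
]


@dataclass(frozen=True)
class SystemGeometry:
    """Physical description of the scanner.

    Parameters
    ----------
    zsm : float
        Source-to-mask distance (m).  Systems without a mask may fold
        this into ``zmo``.
    zmo : float
        Mask-to-object (COR) distance (m).
    zod : float
        Object (COR)-to-detector distance (m).
    p : float
        Detector pixel pitch (m).
    n_col, n_row : int
        Detector columns / rows.
    delta_cor : float
        Signed COR offset (m), perpendicular to the source--detector
        axis at the COR plane.  Positive maps the extended (singly
        covered) region to the ``+x`` side of the detector.
    """

    zsm: float
    zmo: float
    zod: float
    p: float
    n_col: int
    n_row: int = 1
    delta_cor: float = 0.0

    def __post_init__(self) -> None:
        for name in ("zsm", "zmo", "zod", "p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_col < 1 or self.n_row < 1:
            raise ValueError("n_col and n_row must be >= 1")
        z_so = self.zsm + self.zmo
        R = z_so + self.zod
        fov_native = self.p * self.n_col * z_so / R
        if abs(self.delta_cor) >= fov_native:
            raise ValueError(
                f"|delta_cor| = {abs(self.delta_cor):g} m leaves no redundant "
                f"region (native FOV at the COR plane is {fov_native:g} m)"
            )

    @property
    def z_so(self) -> float:
        """Source-to-COR distance along the axis (m)."""
        return self.zsm + self.zmo

    @property
    def R(self) -> float:
        """Total source-to-detector distance (m)."""
        return self.zsm + self.zmo + self.zod

    def detector_columns(self) -> np.ndarray:
        """Signed detector-column center coordinates (m)."""
        return (np.arange(self.n_col) - (self.n_col - 1) / 2.0) * self.p


@dataclass(frozen=True)
class DerivedGeometry:
    """Quantities derived from a :class:`SystemGeometry`.

    ``fov_extended`` uses the first-order sample-plane convention
    ``fov_native + 2 |delta_cor|``; the exact radii of the always-seen
    circle C1 (``r1``) and the ever-seen circle C2 (``r2``) are exposed
    separately.
    """

    R: float
    z_so: float
    z_so_eff: float  # sqrt(z_so^2 + delta_cor^2): source-to-COR distance
    M: float
    tau: float
    gamma_max: float
    fov_native: float
    fov_extended: float
    extension_factor: float
    r1: float
    r2: float


@dataclass(frozen=True)
class RedundantRegion:
    """Detector interval [d0, d_end] whose rays are measured twice."""

    d0: float
    d_end: float

    def __post_init__(self) -> None:
        if not self.d0 < self.d_end:
            raise ValueError("require d0 < d_end")

    @property
    def width(self) -> float:
        return self.d_end - self.d0


@dataclass(frozen=True)
class ViewGeometry:
    """Source/detector pose for a single view, vectors in meters."""

    alpha: float
    source: np.ndarray
    detector_center: np.ndarray
    col_axis: np.ndarray
    row_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )

    @property
    def central_axis(self) -> np.ndarray:
        """Unit vector from the source toward the detector center."""
        d = self.detector_center - self.source
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class AcquisitionPlan:
    """Angular and dither sampling of a scan."""

    n_angles: int
    angular_range: float = 2.0 * math.pi
    n_dither: int = 1
    t_exposure: float = 1.0

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.n_dither < 1:
            raise ValueError("n_angles and n_dither must be >= 1")
        if self.t_exposure <= 0:
            raise ValueError("t_exposure must be positive")

    def angles(self) -> np.ndarray:
        """View angles (rad), equally spaced, endpoint excluded."""
        return np.arange(self.n_angles) * (self.angular_range / self.n_angles)


def derive_geometry(g: SystemGeometry) -> DerivedGeometry:
    """Derive magnification, fan angles, FOV and coverage circles.

    The half-fan angle is ``gamma_max = atan(p n_col / (2R))``.  The COR
    ray makes the signed angle ``tau = -atan(delta_cor / z_so)`` with
    the central ray (see module notes on the sign).  Offsetting the COR
    extends the sample-plane FOV from ``fov_native = p n_col / M`` to
    ``fov_native + 2 |delta_cor|``.
    """
    R = g.R
    z_so = g.z_so
    M = R / z_so
    tau = -math.atan2(g.delta_cor, z_so)
    gamma_max = math.atan2(g.p * g.n_col / 2.0, R)
    fov_native = g.p * g.n_col / M
    fov_extended = fov_native + 2.0 * abs(g.delta_cor)
    z_so_eff = math.hypot(z_so, g.delta_cor)
    r1 = z_so_eff * math.sin(gamma_max - abs(tau))
    r2 = z_so_eff * math.sin(gamma_max + abs(tau))
    return DerivedGeometry(
        R=R,
        z_so=z_so,
        z_so_eff=z_so_eff,
        M=M,
        tau=tau,
        gamma_max=gamma_max,
        fov_native=fov_native,
        fov_extended=fov_extended,
        extension_factor=fov_extended / fov_native,
        r1=r1,
        r2=r2,
    )


def redundant_bounds(dg: DerivedGeometry, g: SystemGeometry) -> RedundantRegion:
    """Detector interval of doubly-measured rays.

    Over 360 degrees a line at signed distance ``s`` from the COR is
    seen twice when ``|s| <= r1``; on the detector those rays span an
    interval of width ``|p n_col / 2 + R tan(gamma_max - 2|tau|)|``
    anchored at the detector edge on the doubly-covered side.
    """
    tau = dg.tau
    if abs(tau) > dg.gamma_max:
        raise ValueError(
            "no redundant region: |tau| exceeds the half-fan angle "
            f"({abs(tau):g} > {dg.gamma_max:g} rad)"
        )
    edge = g.p * g.n_col / 2.0
    inner = dg.R * math.tan(dg.gamma_max - 2.0 * abs(tau))
    if tau <= 0:  # delta_cor >= 0: extension on +x, redundancy on -x side
        return RedundantRegion(d0=-edge, d_end=inner)
    return RedundantRegion(d0=-inner, d_end=edge)


def view_vectors(
    dg: DerivedGeometry,
    g: SystemGeometry,
    angles: Sequence[float] | np.ndarray,
) -> list[ViewGeometry]:
    """Source/detector poses for a set of view angles.

    The rotating-sample acquisition is expressed as the equivalent
    rotation of the rigidly coupled source--detector pair about the COR
    at the origin; ``delta_cor`` is a transverse shift of that pair,
    identical for every view.
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size == 0:
        raise ValueError("empty angle sequence")
    views = []
    for a in angles:
        c, s = math.cos(a), math.sin(a)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        source0 = np.array([g.delta_cor, -dg.z_so, 0.0])
        det0 = np.array([g.delta_cor, g.zod, 0.0])
        col0 = np.array([1.0, 0.0, 0.0])
        views.append(
            ViewGeometry(
                alpha=float(a),
                source=rot @ source0,
                detector_center=rot @ det0,
                col_axis=rot @ col0,
                row_axis=np.array([0.0, 0.0, 1.0]),
            )
        )
    return views


def plan_scan(plan: AcquisitionPlan) -> dict:
    """Totals for an acquisition plan.

    Returns total frame count, total exposure time (s), and the divisor
    by which dithering refines the sampling pitch.
    """
    total_frames = plan.n_angles * plan.n_dither
    return {
        "total_frames": total_frames,
        "total_exposure": total_frames * plan.t_exposure,
        "effective_pitch_divisor": plan.n_dither,
    }


def geometry_from_fov(
    fov_native: float,
    delta_cor: float,
    *,
    zsm: float = 0.3,
    zmo: float = 0.2,
    zod: float = 0.5,
    n_col: int = 512,
    n_row: int = 1,
) -> SystemGeometry:
    """Build a geometry realizing a requested native sample-plane FOV.

    Convenience constructor for configurations quoted by their
    sample-plane coverage rather than detector size: the pixel pitch is
    solved from ``fov_native = p n_col / M``.
    """
    z_so = zsm + zmo
    R = z_so + zod
    p = fov_native * (R / z_so) / n_col
    return SystemGeometry(
        zsm=zsm, zmo=zmo, zod=zod, p=p, n_col=n_col, n_row=n_row,
        delta_cor=delta_cor,
    )
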