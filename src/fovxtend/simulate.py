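"""Virtual scanner: analytic phantoms, sinograms, beamlet frames,
Fresnel propagation and noise.

Phantoms are unions of constant-density disks and ellipses, so every
line integral has a closed form (the chord length through each primitive
times its density).  This provides exact ground truth for the
reconstruction, retrieval and phase-retrieval modules without any
numerical forward projector in the loop.

Three densities are carried per primitive:

* ``mu``      linear attenuation (1/m), line integral is dimensionless;
* ``delta``   refractive-index decrement (dimensionless), line integral
  ``integral(delta dz)`` is in meters and its transverse derivative is
  the refraction angle;
* ``scatter`` angular-variance density (rad^2/m), line integral is the
  dark-field signal in rad^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from fovxtend.beamtracking import MaskSpec
from fovxtend.geometry import (
    SystemGeometry,
    derive_geometry,
    view_vectors,
)
from fovxtend.recon import ProjectionSet

__all__ = [
    "Primitive",
    "Phantom",
    "NoiseSpec",
    "analytic_sinogram",
    "synthesize_bt_frames",
    "fresnel_propagate",
    "add_noise",
    "phantom_from_dicts",
]

SinogramChannel = Literal["attenuation", "phase", "darkfield", "refraction"]

_CHANNEL_DENSITY = {"attenuation": "mu", "phase": "delta", "darkfield": "scatter"}


@dataclass(frozen=True)
class Primitive:
    """Constant-density disk or ellipse.

    ``axes`` are the semi-axes (m); a disk has equal axes.  ``rot`` is
    the CCW rotation of the first axis from +x (rad).
    """

    center: tuple[float, float]
    axes: tuple[float, float]
    rot: float = 0.0
    mu: float = 0.0
    delta: float = 0.0
    scatter: float = 0.0

    def __post_init__(self) -> None:
        if min(self.axes) <= 0:
            raise ValueError("semi-axes must be positive")
        if self.scatter < 0:
            raise ValueError("scatter density must be >= 0")

    @classmethod
    def disk(cls, center, radius, **densities) -> "Primitive":
        return cls(center=tuple(center), axes=(radius, radius), **densities)


@dataclass(frozen=True)
class Phantom:
    """Union of primitives; overlapping densities add."""

    primitives: tuple[Primitive, ...]

    def __init__(self, primitives: Iterable[Primitive]):
        object.__setattr__(self, "primitives", tuple(primitives))

    def translated(self, offset: Sequence[float]) -> "Phantom":
        ox, oy = offset
        return Phantom(
            replace(p, center=(p.center[0] + ox, p.center[1] + oy))
            for p in self.primitives
        )

    def line_integrals(
        self,
        source: np.ndarray,
        directions: np.ndarray,
        density: str,
    ) -> np.ndarray:
        """Exact line integrals of one density along rays ``source +
        t * directions`` (directions unit, shape (n, 2))."""
        S = np.asarray(source, dtype=float)[:2]
        d = np.asarray(directions, dtype=float)
        out = np.zeros(d.shape[0])
        for prim in self.primitives:
            rho = getattr(prim, density)
            if rho == 0.0:
                continue
            cr, sr = math.cos(prim.rot), math.sin(prim.rot)
            # map to the primitive's unit-circle frame
            A = np.array(
                [[cr / prim.axes[0], sr / prim.axes[0]],
                 [-sr / prim.axes[1], cr / prim.axes[1]]]
            )
            q0 = A @ (S - np.asarray(prim.center))
            qd = d @ A.T
            a = np.einsum("ij,ij->i", qd, qd)
            b = qd @ q0
            c = q0 @ q0 - 1.0
            disc = b * b - a * c
            hit = disc > 0
            chord = np.zeros_like(out)
            chord[hit] = 2.0 * np.sqrt(disc[hit]) / a[hit]
            out += rho * chord
        return out


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for synthesized frames."""

    model: Literal["none", "poisson"] = "none"
    peak_counts: float = 1.0e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model == "poisson" and self.peak_counts <= 0:
            raise ValueError("peak_counts must be positive for poisson noise")


def _detector_rays(view, g: SystemGeometry, x: np.ndarray):
    """Unit ray directions from the view's source through detector
    coordinates ``x`` (m from the detector center)."""
    S = view.source[:2]
    pts = view.detector_center[:2] + x[:, None] * view.col_axis[:2]
    d = pts - S
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return S, d


def analytic_sinogram(
    ph: Phantom,
    g: SystemGeometry,
    angles: np.ndarray,
    channel: SinogramChannel,
) -> ProjectionSet:
    """Exact divergent-beam sinogram of a phantom.

    The refraction channel is the central finite difference of the phase
    sinogram along x, divided by the column pitch at the COR plane.
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    dg = derive_geometry(g)
    views = view_vectors(dg, g, angles)
    x = g.detector_columns()
    if channel == "refraction":
        base = "delta"
    elif channel in _CHANNEL_DENSITY:
        base = _CHANNEL_DENSITY[channel]
    else:
        raise ValueError(f"unknown channel {channel!r}")
    sino = np.empty((angles.size, g.n_col))
    for i, view in enumerate(views):
        S, d = _detector_rays(view, g, x)
        sino[i] = ph.line_integrals(S, d, base)
    if channel == "refraction":
        pitch_cor = g.p * g.z_so / g.R
        sino = np.gradient(sino, pitch_cor, axis=1)
    data = np.repeat(sino[:, None, :], g.n_row, axis=1)
    side = "low_x" if g.delta_cor > 0 else ("high_x" if g.delta_cor < 0 else "none")
    return ProjectionSet(
        data=data,
        angles=angles,
        channel=channel,
        geometry=g,
        truncated_side=side,
    )


def synthesize_bt_frames(
    ph: Phantom,
    g: SystemGeometry,
    mask: MaskSpec,
    angles: np.ndarray,
    n_dither: int = 1,
    noise: NoiseSpec = NoiseSpec(),
    *,
    flat_amplitude: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Flat and sample beamlet frames for a beam-tracking scan.

    Each beamlet is a Gaussian of width ``mask.beamlet_sigma`` in the
    flat frame.  The sample multiplies its area by ``exp(-integral mu)``,
    shifts it by ``zod * theta`` (``theta`` the transverse derivative of
    the projected phase at the beamlet ray) and broadens it to
    ``sqrt(sigma_f^2 + zod^2 * integral scatter)``.  Successive dither
    steps translate the sample so the comb advances by
    ``period / n_dither`` across it, matching the interlacing order of
    :func:`fovxtend.beamtracking.interlace_dither`.

    Returns ``(flat, frames)`` with ``flat`` of shape (n_row, n_col) and
    ``frames`` of shape (n_angles, n_dither, n_row, n_col).  Beamlet
    physics is applied at the beamlet center (no intra-beamlet
    gradient), valid for phantoms varying slowly over one period.
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    dg = derive_geometry(g)
    views = view_vectors(dg, g, angles)
    xpix = g.detector_columns()
    centers = mask.centers()
    amp = flat_amplitude if flat_amplitude is not None else (
        noise.peak_counts if noise.model == "poisson" else 1.0
    )
    sig_f = mask.beamlet_sigma
    flat_row = (
        amp * np.exp(-0.5 * ((xpix[None, :] - centers[:, None]) / sig_f) ** 2)
    ).sum(axis=0)
    flat = np.tile(flat_row, (g.n_row, 1))

    step_sample = mask.period_at_detector / n_dither * g.z_so / g.R
    h = g.p  # detector-plane spacing of the phase finite difference
    frames = np.empty((angles.size, n_dither, g.n_row, g.n_col))
    for i, view in enumerate(views):
        u = view.col_axis[:2]
        for j in range(n_dither):
            # comb advances +x across the sample <=> sample moves -x
            ph_j = ph.translated(-j * step_sample * u)
            S, d0 = _detector_rays(view, g, centers)
            _, dp = _detector_rays(view, g, centers + h)
            _, dm = _detector_rays(view, g, centers - h)
            mu_li = ph_j.line_integrals(S, d0, "mu")
            sc_li = ph_j.line_integrals(S, d0, "scatter")
            phi_p = ph_j.line_integrals(S, dp, "delta")
            phi_m = ph_j.line_integrals(S, dm, "delta")
            theta = (phi_p - phi_m) / (2.0 * h * g.z_so / g.R)
            t = np.exp(-mu_li)
            sig_s = np.sqrt(sig_f**2 + g.zod**2 * sc_li)
            c_s = centers + g.zod * theta
            if np.any(np.diff(np.sort(c_s)) < 4.0 * sig_s.max()) and len(c_s) > 1:
                if np.min(np.diff(np.sort(c_s))) < 4.0 * sig_s.max():
                    warnings.warn("beamlets overlap after refraction shift",
                                  stacklevel=2)
            a_s = amp * t * sig_f / sig_s
            row = (
                a_s[:, None]
                * np.exp(-0.5 * ((xpix[None, :] - c_s[:, None]) / sig_s[:, None]) ** 2)
            ).sum(axis=0)
            frames[i, j] = row
    if noise.model == "poisson":
        rng = np.random.default_rng(noise.seed)
        flat = rng.poisson(flat).astype(float)
        frames = rng.poisson(frames).astype(float)
    return flat, frames


def fresnel_propagate(
    field: np.ndarray,
    distance: float,
    wavelength: float,
    pixel: float,
) -> np.ndarray:
    """Free-space intensity after angular-spectrum propagation.

    ``field`` is the complex transmission function sampled at ``pixel``
    pitch (1-D or 2-D).  Returns ``|u(z)|^2``.  Evanescent components
    are attenuated; a warning is emitted when the propagation distance
    exceeds the aliasing-free bound ``N * pixel^2 / wavelength``.
    """
    u = np.asarray(field, dtype=complex)
    if distance == 0.0:
        return np.abs(u) ** 2
    n_min = min(u.shape)
    if abs(distance) > n_min * pixel**2 / wavelength:
        warnings.warn(
            "propagation distance exceeds the angular-spectrum sampling "
            "bound; expect wrap-around artefacts",
            stacklevel=2,
        )
    k = 2.0 * np.pi / wavelength
    if u.ndim == 1:
        kx = 2.0 * np.pi * np.fft.fftfreq(u.shape[0], d=pixel)
        kz2 = k**2 - kx**2
    elif u.ndim == 2:
        ky = 2.0 * np.pi * np.fft.fftfreq(u.shape[0], d=pixel)
        kx = 2.0 * np.pi * np.fft.fftfreq(u.shape[1], d=pixel)
        kz2 = k**2 - kx[None, :] ** 2 - ky[:, None] ** 2
    else:
        raise ValueError("field must be 1-D or 2-D")
    kz = np.sqrt(kz2.astype(complex))
    H = np.exp(1j * kz * distance)
    out = np.fft.ifftn(np.fft.fftn(u) * H)
    return np.abs(out) ** 2


def phantom_from_dicts(entries: Sequence[dict]) -> Phantom:
    """Build a phantom from the JSON schema used by the CLI.

    Each entry: ``{"shape": "disk"|"ellipse", "center_mm": [x, y],
    "axes_mm": [a, b] or radius, "rot_deg": r, "mu_per_m": m,
    "delta": d, "scatter_per_m": s}``.
    """
    prims = []
    for e in entries:
        axes = e.get("axes_mm", 1.0)
        if np.isscalar(axes):
            axes = (float(axes), float(axes))
        prims.append(
            Primitive(
                center=tuple(1e-3 * np.asarray(e.get("center_mm", (0, 0)), float)),
                axes=(1e-3 * axes[0], 1e-3 * axes[1]),
                rot=math.radians(float(e.get("rot_deg", 0.0))),
                mu=float(e.get("mu_per_m", 0.0)),
                delta=float(e.get("delta", 0.0)),
                scatter=float(e.get("scatter_per_m", 0.0)),
            )
        )
    return Phantom(prims)


def add_noise(image: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Seeded, expectation-preserving noise."""
    img = np.asarray(image, dtype=float)
    if noise.model == "none":
        return img.copy()
    if noise.model == "poisson":
        if np.any(img < 0):
            raise ValueError("poisson noise requires a non-negative image")
        rng = np.random.default_rng(noise.seed)
        return rng.poisson(img).astype(float)
    raise ValueError(f"unknown noise model {noise.model!r}")
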