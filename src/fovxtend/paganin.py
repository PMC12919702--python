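"""Single-distance phase retrieval by transport-of-intensity inversion.

For a homogeneous object with a fixed ratio ``delta/beta`` of refractive
decrement to absorption index, the projected thickness follows from a
single flat-corrected propagation image ``I/I0`` at effective distance
``z_eff``:

    T = -(1/mu) * ln( F^-1 [ F(I/I0) / (1 + (delta/beta) *
        z_eff * lambda |k|^2 / (4 pi)) ] ),   mu = 4 pi beta / lambda.

The low-pass denominator removes propagation fringes; the k = 0 limit
reduces to plain -ln transmission.  On a divergent (cone-beam) system
the Fresnel scaling theorem applies with ``z_eff = zod / M`` and the
effective sample-plane pixel ``p / M``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.fft

__all__ = ["PaganinParams", "PaganinResult", "paganin_filter",
           "wavelength_from_energy"]

#: hc in keV * m
_HC_KEV_M = 1.2398419843320026e-9


def wavelength_from_energy(energy_kev: float) -> float:
    """Photon wavelength (m) for an energy in keV."""
    if energy_kev <= 0:
        raise ValueError("energy must be positive")
    return _HC_KEV_M / energy_kev


@dataclass(frozen=True)
class PaganinParams:
    """Retrieval parameters.

    delta_beta : ratio delta/beta of the homogeneous-object assumption
        (default 25, favoring under-retrieval for resolution on soft
        tissue).
    wavelength : m (default 8 keV).
    z_eff : effective propagation distance (m); on a cone-beam system
        the object-detector distance divided by the magnification.
    pixel : effective sample-plane pixel (m).
    """

    delta_beta: float = 25.0
    wavelength: float = wavelength_from_energy(8.0)
    z_eff: float = 0.1
    pixel: float = 1.0e-6

    def __post_init__(self) -> None:
        for name in ("delta_beta", "wavelength", "z_eff", "pixel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PaganinResult:
    """Retrieved maps.

    ``mu_thickness`` is the dimensionless ``mu * T`` (a -ln transmission
    equivalent, always available); ``thickness`` (m) and ``phase`` (rad,
    ``-2 pi delta T / lambda``) are filled when ``delta`` is known.
    """

    mu_thickness: np.ndarray
    thickness: np.ndarray | None = None
    phase: np.ndarray | None = None


def paganin_filter(
    intensity: np.ndarray,
    prm: PaganinParams,
    *,
    delta: float | None = None,
) -> PaganinResult:
    """Retrieve projected thickness from one flat-corrected image.

    Non-positive intensities are masked (replaced by the smallest
    positive value) with a warning.  The image is mirror-padded by half
    its size on every edge before the FFT to suppress wrap-around.
    """
    img = np.asarray(intensity, dtype=float)
    if img.ndim not in (1, 2):
        raise ValueError("intensity must be 1-D or 2-D")
    bad = ~(img > 0)
    if bad.any():
        warnings.warn(f"masking {bad.sum()} non-positive intensity values",
                      stacklevel=2)
        img = np.where(bad, img[~bad].min() if (~bad).any() else 1.0, img)

    pads = [(s // 2, s // 2) for s in img.shape]
    padded = np.pad(img, pads, mode="symmetric")

    coef = prm.delta_beta * prm.z_eff * prm.wavelength / (4.0 * np.pi)
    if padded.ndim == 1:
        kx = 2.0 * np.pi * scipy.fft.fftfreq(padded.shape[0], d=prm.pixel)
        k2 = kx**2
    else:
        ky = 2.0 * np.pi * scipy.fft.fftfreq(padded.shape[0], d=prm.pixel)
        kx = 2.0 * np.pi * scipy.fft.fftfreq(padded.shape[1], d=prm.pixel)
        k2 = ky[:, None] ** 2 + kx[None, :] ** 2
    filt = np.fft.ifftn(np.fft.fftn(padded) / (1.0 + coef * k2)).real
    sl = tuple(slice(p[0], p[0] + s) for p, s in zip(pads, img.shape))
    filt = filt[sl]

    mu_t = -np.log(np.clip(filt, np.finfo(float).tiny, None))
    result = PaganinResult(mu_thickness=mu_t)
    if delta is not None:
        beta = delta / prm.delta_beta
        mu = 4.0 * np.pi * beta / prm.wavelength
        result.thickness = mu_t / mu
        result.phase = -2.0 * np.pi * delta * result.thickness / prm.wavelength
    return result
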