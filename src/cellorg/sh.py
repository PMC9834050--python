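"""Real spherical harmonic basis utilities.

A closed star-convex surface is described by its radius function
``r(theta, phi)`` about an interior centroid, expanded in the real
spherical harmonic basis.  Degree ``lmax`` gives ``(lmax + 1)**2`` real
coefficients, stored flat with index ``l*l + l + m`` for
``-l <= m <= l``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "sh_index",
    "n_coeffs",
    "real_sh_basis",
    "fit_grid",
    "grid_basis",
    "eval_radius",
]


def sh_index(l: int, m: int) -> int:
    """Flat index of the real coefficient of degree ``l`` and order ``m``."""
    return l * l + l + m


def n_coeffs(lmax: int) -> int:
    return (lmax + 1) ** 2


def real_sh_basis(theta: np.ndarray, phi: np.ndarray, lmax: int) -> np.ndarray:
    """Evaluate the real spherical harmonic basis at given directions.

    Parameters
    ----------
    theta
        Polar angles in ``[0, pi]`` (0 at the +z pole).
    phi
        Azimuthal angles in ``[0, 2*pi)`` measured from +x towards +y.
    lmax
        Maximum expansion degree.

    Returns
    -------
    numpy.ndarray
        Matrix of shape ``(theta.size, (lmax + 1)**2)``.
    """
    th = np.asarray(theta, dtype=float).ravel()
    ph = np.asarray(phi, dtype=float).ravel()
    if th.shape != ph.shape:
        raise ValueError("theta and phi must have the same size")
    basis = np.empty((th.size, n_coeffs(lmax)))
    sqrt2 = np.sqrt(2.0)
    for l in range(lmax + 1):
        basis[:, sh_index(l, 0)] = sph_harm_y(l, 0, th, ph).real
        for m in range(1, l + 1):
            y = sph_harm_y(l, m, th, ph)
            sign = -1.0 if m % 2 else 1.0
            basis[:, sh_index(l, m)] = sqrt2 * sign * y.real
            basis[:, sh_index(l, -m)] = sqrt2 * sign * y.imag
    return basis


def fit_grid(nlat: int, nlon: int) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centred equiangular latitude-longitude grid (avoids the poles)."""
    theta = (np.arange(nlat) + 0.5) * np.pi / nlat
    phi = np.arange(nlon) * 2.0 * np.pi / nlon
    tg, pg = np.meshgrid(theta, phi, indexing="ij")
    return tg.ravel(), pg.ravel()


@lru_cache(maxsize=16)
def grid_basis(lmax: int, nlat: int, nlon: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cached ``(theta, phi, basis)`` for the cell-centred fit grid."""
    theta, phi = fit_grid(nlat, nlon)
    basis = real_sh_basis(theta, phi, lmax)
    basis.setflags(write=False)
    return theta, phi, basis


def directions(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Unit direction vectors in image (z, y, x) axis order."""
    st = np.sin(theta)
    return np.stack([np.cos(theta), st * np.sin(phi), st * np.cos(phi)], axis=-1)


def eval_radius(coeffs: np.ndarray, theta: np.ndarray, phi: np.ndarray, lmax: int) -> np.ndarray:
    """Radius function of a coefficient vector at arbitrary directions."""
    return real_sh_basis(theta, phi, lmax) @ np.asarray(coeffs, dtype=float)
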