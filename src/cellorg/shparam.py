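"""Alignment and spherical harmonic parameterization of cell/nuclear surfaces.

Workflow per cell: rotate the segmented channels in the xy plane so the
longest cell axis (or a supplied outward direction) lies along +x, then
expand the cell and nuclear surfaces as radius-versus-direction spherical
harmonic series about their own centroids.  The nuclear centroid position
relative to the cell centroid is carried on the coefficient record so the
nucleus can be placed back when reconstructing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from cellorg import sh

__all__ = [
    "AlignmentRecord",
    "SHECoefficients",
    "SurfaceMesh",
    "align_cell",
    "compute_she",
    "parameterize_cell",
    "reconstruct_mesh",
    "voxelize",
    "flip_180",
]

DEFAULT_LMAX = 16
DEFAULT_VOXEL_SIZE_UM = 0.108333


@dataclass(frozen=True)
class AlignmentRecord:
    """xy rotation applied to one cell (z axis is never rotated)."""

    theta_cell: float  # degrees, in [-180, 180)
    mode: str  # 'longest_axis' | 'edge_axis'
    cell_centroid: np.ndarray  # (z, y, x) voxel coordinates, aligned frame

    def __post_init__(self):
        if not -180.0 <= self.theta_cell < 180.0:
            raise ValueError("theta_cell must be in [-180, 180)")


@dataclass
class SHECoefficients:
    """Real expansion coefficients of one closed surface.

    ``coeffs`` has length ``(lmax + 1)**2`` and is indexed by
    :func:`cellorg.sh.sh_index`.  ``centroid`` is the surface centroid in
    voxel coordinates of the aligned image frame; ``centroid_offset``
    positions this surface relative to the cell centroid.
    """

    coeffs: np.ndarray
    lmax: int
    surface_label: str
    centroid: np.ndarray
    centroid_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    star_convex: bool = True

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.centroid_offset = np.asarray(self.centroid_offset, dtype=float)
        if self.coeffs.size != sh.n_coeffs(self.lmax):
            raise ValueError(
                f"expected {sh.n_coeffs(self.lmax)} coefficients for lmax={self.lmax}, "
                f"got {self.coeffs.size}"
            )

    @property
    def n_coeffs(self) -> int:
        return self.coeffs.size

    def radius(self, theta, phi) -> np.ndarray:
        return sh.eval_radius(self.coeffs, theta, phi, self.lmax)

    def mean_radius(self) -> float:
        # only the l=0 term has nonzero spherical mean
        return float(self.coeffs[0] / (2.0 * np.sqrt(np.pi)))

    def to_dict(self) -> dict:
        entries = {}
        for l in range(self.lmax + 1):
            for m in range(-l, l + 1):
                entries[f"{self.surface_label}_L{l}M{m}"] = float(self.coeffs[sh.sh_index(l, m)])
        return entries

    def save_json(self, path) -> None:
        payload = {
            "lmax": self.lmax,
            "surface_label": self.surface_label,
            "centroid": self.centroid.tolist(),
            "centroid_offset": self.centroid_offset.tolist(),
            "voxel_size_um": self.voxel_size_um,
            "star_convex": bool(self.star_convex),
            "coeffs": self.coeffs.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load_json(cls, path) -> "SHECoefficients":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            coeffs=np.asarray(payload["coeffs"]),
            lmax=payload["lmax"],
            surface_label=payload["surface_label"],
            centroid=np.asarray(payload["centroid"]),
            centroid_offset=np.asarray(payload["centroid_offset"]),
            voxel_size_um=payload["voxel_size_um"],
            star_convex=payload["star_convex"],
        )


@dataclass
class SurfaceMesh:
    """Closed triangulated surface in physical (micrometre) coordinates."""

    vertices: np.ndarray  # (n, 3) in (z, y, x) order, micrometres
    faces: np.ndarray  # (m, 3) vertex index triples
    provenance: str = ""

    def save_obj(self, path) -> None:
        with open(path, "w") as fh:
            for v in self.vertices:
                fh.write(f"v {v[2]:.6f} {v[1]:.6f} {v[0]:.6f}\n")
            for f in self.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")

    def save_vtk(self, path) -> None:
        """Legacy ASCII VTK polydata."""
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\nsurface\nASCII\nDATASET POLYDATA\n")
            fh.write(f"POINTS {len(self.vertices)} float\n")
            for v in self.vertices:
                fh.write(f"{v[2]:.6f} {v[1]:.6f} {v[0]:.6f}\n")
            fh.write(f"POLYGONS {len(self.faces)} {4 * len(self.faces)}\n")
            for f in self.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _xy_angle_of_longest_axis(mask: np.ndarray) -> float | None:
    """Angle (degrees) of the longest in-plane axis; None if degenerate."""
    zyx = np.argwhere(mask)
    xy = zyx[:, [2, 1]].astype(float)  # (x, y)
    xy -= xy.mean(axis=0)
    cov = xy.T @ xy / len(xy)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] - evals[0] <= 1e-9 * max(evals[1], 1.0):
        return None  # rotationally symmetric in xy
    vx, vy = evecs[:, 1]
    return float(np.degrees(np.arctan2(vy, vx)))


def _normalize_angle(theta: float) -> float:
    return float((theta + 180.0) % 360.0 - 180.0)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labeled, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
    return labeled == (1 + int(np.argmax(sizes)))


def _rotate_channel(img: np.ndarray, theta_cell: float, order: int,
                    clean: bool = False) -> np.ndarray:
    # ndimage.rotate with axes=(1, 2) moves a feature at xy angle a to a - angle,
    # so applying the content rotation theta_cell requires angle = -theta_cell.
    out = ndimage.rotate(img.astype(float), -theta_cell, axes=(1, 2), order=order, reshape=True)
    if order == 0:
        out = out > 0.5
        if clean:  # nearest-neighbour aliasing can shed isolated specks
            out = _largest_component(out)
    return out


def align_cell(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    structure_image: np.ndarray | None = None,
    mode: str = "longest_axis",
    outward_vector: np.ndarray | None = None,
    structure_order: int = 0,
):
    """Rotate all channels in the xy plane into the cell-aligned frame.

    In ``longest_axis`` mode the longest in-plane axis of the cell mask is
    brought onto the x axis; the remaining 180-degree ambiguity is resolved
    by requiring the third moment (skewness) of the aligned x coordinates to
    be non-negative.  In ``edge_axis`` mode the supplied outward vector
    (z, y, x) is mapped onto +x.

    Returns ``(cell, nucleus, structure, AlignmentRecord)``; ``structure``
    is None when no structure image is given.
    """
    cell_mask = np.asarray(cell_mask).astype(bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    nucleus_mask = np.asarray(nucleus_mask).astype(bool)

    if mode == "longest_axis":
        angle = _xy_angle_of_longest_axis(cell_mask)
        theta = 0.0 if angle is None else _normalize_angle(-angle)
    elif mode == "edge_axis":
        if outward_vector is None:
            raise ValueError("edge_axis mode requires an outward vector")
        _, oy, ox = np.asarray(outward_vector, dtype=float)
        if ox == 0.0 and oy == 0.0:
            raise ValueError("outward vector has no xy component")
        theta = _normalize_angle(-np.degrees(np.arctan2(oy, ox)))
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")

    def _apply(theta_cell):
        c = _rotate_channel(cell_mask, theta_cell, order=0, clean=True)
        n = _rotate_channel(nucleus_mask, theta_cell, order=0, clean=True)
        s = None
        if structure_image is not None:
            s = _rotate_channel(np.asarray(structure_image), theta_cell, order=structure_order)
        return c, n, s

    cell_rot, nuc_rot, struct_rot = _apply(theta)
    if mode == "longest_axis":
        xs = np.argwhere(cell_rot)[:, 2].astype(float)
        skew = np.mean((xs - xs.mean()) ** 3)
        if skew < 0.0:
            theta = _normalize_angle(theta + 180.0)
            cell_rot, nuc_rot, struct_rot = _apply(theta)

    record = AlignmentRecord(
        theta_cell=theta,
        mode=mode,
        cell_centroid=np.asarray(ndimage.center_of_mass(cell_rot)),
    )
    return cell_rot, nuc_rot, struct_rot, record


def _ray_radii(mask: np.ndarray, centroid: np.ndarray, theta: np.ndarray, phi: np.ndarray,
               step: float = 0.25) -> tuple[np.ndarray, bool]:
    """Boundary radius along each direction, plus a star-convexity verdict.

    Samples the (linearly interpolated) mask along rays from the centroid
    and takes the first 0.5 crossing; multiple crossings on >2% of rays
    mark the surface as not star-convex.
    """
    dirs = sh.directions(theta, phi)  # (ndirs, 3) in (z, y, x)
    corner = np.maximum(centroid, np.asarray(mask.shape) - 1 - centroid)
    rmax = float(np.linalg.norm(corner)) + 1.0
    rs = np.arange(0.0, rmax + step, step)
    coords = centroid[:, None, None] + dirs.T[:, :, None] * rs[None, None, :]
    vals = ndimage.map_coordinates(
        mask.astype(np.float32), coords.reshape(3, -1), order=1, mode="constant", cval=0.0
    ).reshape(len(dirs), len(rs))

    inside = vals >= 0.5
    # first exit per ray
    exits = np.argmax(~inside, axis=1)  # 0 if ray starts outside (centroid on boundary)
    exits = np.where(inside.any(axis=1), np.maximum(exits, 1), 1)
    prev = vals[np.arange(len(dirs)), exits - 1]
    nxt = vals[np.arange(len(dirs)), exits]
    denom = np.where(prev - nxt == 0.0, 1.0, prev - nxt)
    frac = np.clip((prev - 0.5) / denom, 0.0, 1.0)
    radii = rs[exits - 1] + frac * step

    transitions = np.abs(np.diff(inside.astype(np.int8), axis=1)).sum(axis=1)
    star_convex = bool(np.mean(transitions > 1) <= 0.02)
    return radii, star_convex


def compute_she(
    mask: np.ndarray,
    lmax: int = DEFAULT_LMAX,
    surface_label: str = "cell",
    reference_centroid: np.ndarray | None = None,
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
) -> SHECoefficients:
    """Expand a single star-convex binary mask to degree ``lmax``.

    The radius function about the mask centroid is sampled on an
    oversampled equiangular grid (``2*(lmax+1) x 4*(lmax+1)``) and fitted
    by dense least squares against the real harmonic basis, giving exactly
    ``(lmax + 1)**2`` coefficients.

    ``reference_centroid`` (typically the cell centroid) fixes the origin
    recorded in ``centroid_offset``.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    _, n_components = ndimage.label(mask)
    if n_components != 1:
        raise ValueError(f"mask has {n_components} connected components; expected 1")

    centroid = np.asarray(ndimage.center_of_mass(mask))
    theta, phi, basis = sh.grid_basis(lmax, 2 * (lmax + 1), 4 * (lmax + 1))
    radii, star_convex = _ray_radii(mask, centroid, theta, phi)
    if not star_convex:
        warnings.warn(
            f"{surface_label} mask is not star-convex about its centroid; "
            "coefficients fitted anyway", stacklevel=2,
        )
    coeffs, *_ = np.linalg.lstsq(basis, radii, rcond=None)

    offset = np.zeros(3) if reference_centroid is None else centroid - np.asarray(reference_centroid, float)
    return SHECoefficients(
        coeffs=coeffs,
        lmax=lmax,
        surface_label=surface_label,
        centroid=centroid,
        centroid_offset=offset,
        voxel_size_um=voxel_size_um,
        star_convex=star_convex,
    )


def parameterize_cell(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    lmax: int = DEFAULT_LMAX,
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
) -> tuple[SHECoefficients, SHECoefficients]:
    """Cell and nuclear coefficient sets, nucleus offset relative to the cell."""
    cell = compute_she(cell_mask, lmax, "cell", voxel_size_um=voxel_size_um)
    nuc = compute_she(
        nucleus_mask, lmax, "nucleus",
        reference_centroid=cell.centroid, voxel_size_um=voxel_size_um,
    )
    return cell, nuc


def joint_descriptor(cell: SHECoefficients, nucleus: SHECoefficients) -> np.ndarray:
    """Concatenated cell + nucleus coefficient vector (PCA input)."""
    return np.concatenate([cell.coeffs, nucleus.coeffs])


def split_descriptor(vec: np.ndarray, lmax: int = DEFAULT_LMAX) -> tuple[np.ndarray, np.ndarray]:
    n = sh.n_coeffs(lmax)
    vec = np.asarray(vec, dtype=float)
    if vec.size != 2 * n:
        raise ValueError(f"expected descriptor of length {2 * n}, got {vec.size}")
    return vec[:n], vec[n:]


def reconstruct_mesh(coeffs: SHECoefficients, grid_resolution: int = 32) -> SurfaceMesh:
    """Triangulated surface of a coefficient set (UV-sphere topology).

    Vertices are placed at ``centroid_offset + r(theta, phi) * direction``
    and scaled to micrometres.  Raises if the radius function goes
    negative anywhere on the evaluation grid.
    """
    nlat = grid_resolution + 1
    nlon = 2 * grid_resolution
    theta_rings = np.linspace(0.0, np.pi, nlat)[1:-1]
    phi_ring = np.arange(nlon) * 2.0 * np.pi / nlon
    tg, pg = np.meshgrid(theta_rings, phi_ring, indexing="ij")
    theta_all = np.concatenate([[0.0], tg.ravel(), [np.pi]])
    phi_all = np.concatenate([[0.0], pg.ravel(), [0.0]])
    r = coeffs.radius(theta_all, phi_all)
    if np.any(r <= 0.0):
        raise ValueError("reconstructed radius is non-positive; invalid coefficient set")
    verts = coeffs.centroid_offset[None, :] + r[:, None] * sh.directions(theta_all, phi_all)
    verts = verts * coeffs.voxel_size_um

    faces = []
    n_rings = len(theta_rings)

    def ring(i, j):  # vertex index of ring i (0-based), longitude j
        return 1 + i * nlon + (j % nlon)

    south = 1 + n_rings * nlon
    for j in range(nlon):  # north pole fan
        faces.append([0, ring(0, j), ring(0, j + 1)])
    for i in range(n_rings - 1):  # quad strips
        for j in range(nlon):
            a, b = ring(i, j), ring(i, j + 1)
            c, d = ring(i + 1, j), ring(i + 1, j + 1)
            faces.append([a, c, b])
            faces.append([b, c, d])
    for j in range(nlon):  # south pole fan
        faces.append([south, ring(n_rings - 1, j + 1), ring(n_rings - 1, j)])

    return SurfaceMesh(
        vertices=verts,
        faces=np.asarray(faces, dtype=int),
        provenance=f"{coeffs.surface_label} lmax={coeffs.lmax} grid={grid_resolution}",
    )


@lru_cache(maxsize=8)
def _table_basis(lmax: int, nlat: int, nlon: int):
    theta = np.linspace(0.0, np.pi, nlat)
    phi = np.linspace(0.0, 2.0 * np.pi, nlon)  # endpoint duplicates phi=0
    tg, pg = np.meshgrid(theta, phi % (2.0 * np.pi), indexing="ij")
    basis = sh.real_sh_basis(tg.ravel(), pg.ravel(), lmax)
    basis.setflags(write=False)
    return theta, phi, basis


def _radius_table(coeffs: SHECoefficients, nlat: int = 128, nlon: int = 257):
    """Radius lookup table with wrap-around longitude for interpolation."""
    theta, phi, basis = _table_basis(coeffs.lmax, nlat, nlon)
    r = (basis @ coeffs.coeffs).reshape(nlat, nlon)
    return RegularGridInterpolator((theta, phi), r, bounds_error=False, fill_value=None)


def voxelize(
    coeffs: SHECoefficients,
    shape: tuple[int, int, int],
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Rasterize the surface interior onto a voxel grid.

    A voxel is inside when its distance from the surface centre does not
    exceed the radius function in its direction.  ``center`` defaults to
    ``centroid`` (aligned-frame position) of the coefficient record.
    """
    center = coeffs.centroid if center is None else np.asarray(center, dtype=float)
    interp = _radius_table(coeffs)
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    rel = np.stack([zz - center[0], yy - center[1], xx - center[2]], axis=0)
    r = np.sqrt((rel ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, rel[0] / np.where(r > 0, r, 1.0), 1.0), -1.0, 1.0))
    phi = np.mod(np.arctan2(rel[1], rel[2]), 2.0 * np.pi)
    r_surf = interp(np.stack([theta.ravel(), phi.ravel()], axis=-1)).reshape(shape)
    return r <= r_surf


def sphere_coeffs(
    radius: float,
    lmax: int = DEFAULT_LMAX,
    centroid: np.ndarray | None = None,
    surface_label: str = "cell",
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
) -> SHECoefficients:
    """Exact coefficient set of a sphere of the given radius (voxels)."""
    coeffs = np.zeros(sh.n_coeffs(lmax))
    coeffs[0] = radius * 2.0 * np.sqrt(np.pi)
    return SHECoefficients(
        coeffs=coeffs,
        lmax=lmax,
        surface_label=surface_label,
        centroid=np.zeros(3) if centroid is None else np.asarray(centroid, float),
        voxel_size_um=voxel_size_um,
    )


def flip_180(coeffs: np.ndarray, lmax: int) -> np.ndarray:
    """Coefficient vector of the same surface rotated 180 degrees in xy.

    The rotation phi -> phi + pi multiplies each order-``m`` term by
    ``(-1)**m``.
    """
    out = np.asarray(coeffs, dtype=float).copy()
    for l in range(lmax + 1):
        for m in range(-l, l + 1):
            if m % 2:
                out[sh.sh_index(l, m)] *= -1.0
    return out
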