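"""Parameterized intracellular location representation (PILR).

Harmonic coefficients of the nuclear-centroid sphere, the nuclear surface
and the cell surface are linearly interpolated (coefficients and centroid
offsets alike) into a family of nested shells.  Structure presence (or
intensity) is sampled at each shell mesh point into a shells x grid
matrix; the inverse mapping paints a PILR into any other cell/nuclear
shape ("morphing").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from cellorg import sh
from cellorg.shparam import SHECoefficients, voxelize

__all__ = [
    "ShellFamily",
    "PILRMatrix",
    "MorphedCell",
    "nuclear_centroid_coeffs",
    "interpolate_shells",
    "build_shell_family",
    "sample_pilr",
    "morph",
    "average_pilr",
]

DEFAULT_N_NUCLEAR_SHELLS = 32
DEFAULT_N_CYTO_SHELLS = 64
DEFAULT_GRID = (32, 64)  # latitudes x longitudes per shell
CENTROID_SPHERE_RADIUS_UM = 0.108


@dataclass
class ShellFamily:
    """Nested shells from the nuclear centroid out to the cell surface.

    Shell 0 is the one-pixel-radius sphere at the nuclear centroid, shell
    ``n_nuclear_shells - 1`` the nuclear surface, the last shell the cell
    surface.
    """

    shell_coeffs: list[SHECoefficients]
    n_nuclear_shells: int
    n_cyto_shells: int
    grid: tuple[int, int]

    @property
    def n_shells(self) -> int:
        return len(self.shell_coeffs)

    @property
    def n_grid_points(self) -> int:
        return self.grid[0] * self.grid[1]

    def mesh_points(self) -> np.ndarray:
        """(n_shells, n_grid_points, 3) mesh coordinates in (z, y, x) voxels."""
        nlat, nlon = self.grid
        lmax = self.shell_coeffs[0].lmax
        theta, phi, basis = sh.grid_basis(lmax, nlat, nlon)
        dirs = sh.directions(theta, phi)
        coeff_mat = np.stack([c.coeffs for c in self.shell_coeffs])
        radii = coeff_mat @ basis.T  # (n_shells, n_pts)
        centers = np.stack([c.centroid for c in self.shell_coeffs])
        return centers[:, None, :] + radii[:, :, None] * dirs[None, :, :]


@dataclass
class PILRMatrix:
    """Shell-by-grid-point record of structure presence or intensity."""

    values: np.ndarray  # (n_shells, n_grid_points)
    compartment_split: int  # first cytoplasmic row index
    source_cell_id: str = ""
    grid: tuple[int, int] = DEFAULT_GRID
    mode: str = "binary"
    out_of_bounds_count: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("PILR values must be a 2D matrix")
        if self.mode == "binary":
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0.0, 1.0))) and not self.meta.get("averaged"):
                raise ValueError("binary PILR must contain only 0/1 values")

    @property
    def nuclear_rows(self) -> np.ndarray:
        return self.values[: self.compartment_split]

    @property
    def cytoplasmic_rows(self) -> np.ndarray:
        return self.values[self.compartment_split:]

    def save(self, path) -> None:
        """Plain-text export: values as CSV plus a JSON sidecar."""
        np.savetxt(path, self.values, delimiter=",")
        sidecar = {
            "compartment_split": self.compartment_split,
            "source_cell_id": self.source_cell_id,
            "grid": list(self.grid),
            "mode": self.mode,
            "out_of_bounds_count": self.out_of_bounds_count,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh)


@dataclass
class MorphedCell:
    """Structure likelihood painted into a target cell/nuclear shape."""

    image: np.ndarray
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    provenance: str = ""


def nuclear_centroid_coeffs(nucleus: SHECoefficients,
                            radius_um: float = CENTROID_SPHERE_RADIUS_UM) -> SHECoefficients:
    """l=0-only coefficient set: a one-pixel-radius sphere at the nuclear centroid."""
    coeffs = np.zeros_like(nucleus.coeffs)
    radius_vox = radius_um / nucleus.voxel_size_um
    coeffs[0] = radius_vox * 2.0 * np.sqrt(np.pi)  # c00 * Y00 = radius
    return SHECoefficients(
        coeffs=coeffs,
        lmax=nucleus.lmax,
        surface_label="nuclear_centroid",
        centroid=nucleus.centroid.copy(),
        centroid_offset=nucleus.centroid_offset.copy(),
        voxel_size_um=nucleus.voxel_size_um,
    )


def interpolate_shells(inner: SHECoefficients, outer: SHECoefficients,
                       n_shells: int) -> list[SHECoefficients]:
    """Linear interpolation in coefficient space at evenly spaced fractions.

    Fraction 0 reproduces ``inner`` exactly and fraction 1 ``outer``;
    centroids are interpolated alongside the coefficients.
    """
    if inner.lmax != outer.lmax:
        raise ValueError(f"lmax mismatch: {inner.lmax} != {outer.lmax}")
    if n_shells < 2:
        raise ValueError("n_shells must be >= 2")
    shells = []
    for f in np.linspace(0.0, 1.0, n_shells):
        shells.append(SHECoefficients(
            coeffs=(1.0 - f) * inner.coeffs + f * outer.coeffs,
            lmax=inner.lmax,
            surface_label="shell",
            centroid=(1.0 - f) * inner.centroid + f * outer.centroid,
            centroid_offset=(1.0 - f) * inner.centroid_offset + f * outer.centroid_offset,
            voxel_size_um=inner.voxel_size_um,
        ))
    return shells


def build_shell_family(
    cell: SHECoefficients,
    nucleus: SHECoefficients,
    n_nuclear_shells: int = DEFAULT_N_NUCLEAR_SHELLS,
    n_cyto_shells: int = DEFAULT_N_CYTO_SHELLS,
    grid: tuple[int, int] = DEFAULT_GRID,
) -> ShellFamily:
    """Centroid sphere -> nuclear surface -> cell surface shell family."""
    center = nuclear_centroid_coeffs(nucleus)
    nuclear = interpolate_shells(center, nucleus, n_nuclear_shells)
    cyto = interpolate_shells(nucleus, cell, n_cyto_shells + 1)[1:]
    return ShellFamily(
        shell_coeffs=nuclear + cyto,
        n_nuclear_shells=n_nuclear_shells,
        n_cyto_shells=n_cyto_shells,
        grid=grid,
    )


def sample_pilr(
    structure_image: np.ndarray,
    cell: SHECoefficients,
    nucleus: SHECoefficients,
    n_nuclear_shells: int = DEFAULT_N_NUCLEAR_SHELLS,
    n_cyto_shells: int = DEFAULT_N_CYTO_SHELLS,
    grid: tuple[int, int] = DEFAULT_GRID,
    mode: str = "binary",
    source_cell_id: str = "",
) -> PILRMatrix:
    """Sample the aligned structure image at every shell mesh point.

    ``values[i, j]`` is the image value at the voxel nearest to mesh point
    ``j`` of shell ``i``; mesh points outside the image sample as 0 and
    are counted in ``out_of_bounds_count``.
    """
    if mode not in ("binary", "intensity"):
        raise ValueError("mode must be 'binary' or 'intensity'")
    img = np.asarray(structure_image)
    family = build_shell_family(cell, nucleus, n_nuclear_shells, n_cyto_shells, grid)
    pts = np.rint(family.mesh_points()).astype(int)  # nearest voxel
    shape = np.asarray(img.shape)
    in_bounds = np.all((pts >= 0) & (pts < shape), axis=-1)
    vals = np.zeros(pts.shape[:2], dtype=float)
    idx = pts[in_bounds]
    vals[in_bounds] = img[idx[:, 0], idx[:, 1], idx[:, 2]]
    if mode == "binary":
        vals = (vals > 0).astype(float)
    return PILRMatrix(
        values=vals,
        compartment_split=n_nuclear_shells,
        source_cell_id=source_cell_id,
        grid=grid,
        mode=mode,
        out_of_bounds_count=int((~in_bounds).sum()),
    )


def _default_shape(cell: SHECoefficients) -> tuple[int, int, int]:
    theta, phi, _ = sh.grid_basis(cell.lmax, 64, 128)
    rmax = float(cell.radius(theta, phi).max())
    extent = int(np.ceil(rmax)) + 3
    return tuple(int(2 * extent + 1) for _ in range(3))


def morph(
    pilr: PILRMatrix,
    target_cell: SHECoefficients,
    target_nucleus: SHECoefficients,
    shape: tuple[int, int, int] | None = None,
) -> MorphedCell:
    """Paint a PILR into a target cell/nuclear shape.

    Every target voxel receives the value of its nearest (shell, grid
    point) mesh coordinate of the *target* shell family, nuclear rows
    mapping only inside the target nucleus and cytoplasmic rows only into
    the target cytoplasm — a hole-free inverse lookup.
    """
    if shape is None:
        center = (np.asarray(_default_shape(target_cell)) - 1) / 2.0
        target_cell = SHECoefficients(
            coeffs=target_cell.coeffs, lmax=target_cell.lmax,
            surface_label=target_cell.surface_label,
            centroid=center,
            centroid_offset=target_cell.centroid_offset,
            voxel_size_um=target_cell.voxel_size_um,
        )
        target_nucleus = SHECoefficients(
            coeffs=target_nucleus.coeffs, lmax=target_nucleus.lmax,
            surface_label=target_nucleus.surface_label,
            centroid=center + target_nucleus.centroid_offset,
            centroid_offset=target_nucleus.centroid_offset,
            voxel_size_um=target_nucleus.voxel_size_um,
        )
        shape = _default_shape(target_cell)

    cell_mask = voxelize(target_cell, shape)
    nuc_mask = voxelize(target_nucleus, shape)
    overflow = np.count_nonzero(nuc_mask & ~cell_mask)
    if overflow > 0.02 * max(np.count_nonzero(nuc_mask), 1):
        raise ValueError("target nucleus is not inside the target cell")
    nuc_mask &= cell_mask

    family = build_shell_family(
        target_cell, target_nucleus,
        n_nuclear_shells=pilr.compartment_split,
        n_cyto_shells=pilr.values.shape[0] - pilr.compartment_split,
        grid=pilr.grid,
    )
    pts = family.mesh_points()
    split = pilr.compartment_split
    nuc_pts = pts[:split].reshape(-1, 3)
    cyto_pts = pts[split:].reshape(-1, 3)
    nuc_vals = pilr.values[:split].ravel()
    cyto_vals = pilr.values[split:].ravel()

    out = np.zeros(shape, dtype=float)
    nv = np.argwhere(nuc_mask)
    if len(nv):
        _, nearest = cKDTree(nuc_pts).query(nv, k=1)
        out[nv[:, 0], nv[:, 1], nv[:, 2]] = nuc_vals[nearest]
    cv = np.argwhere(cell_mask & ~nuc_mask)
    if len(cv):
        _, nearest = cKDTree(cyto_pts).query(cv, k=1)
        out[cv[:, 0], cv[:, 1], cv[:, 2]] = cyto_vals[nearest]

    return MorphedCell(
        image=out, cell_mask=cell_mask, nucleus_mask=nuc_mask,
        provenance=f"morph of {pilr.source_cell_id or 'pilr'} into "
                   f"{target_cell.surface_label}",
    )


def average_pilr(pilrs: list[PILRMatrix]) -> PILRMatrix:
    """Elementwise mean of same-discretization PILRs."""
    if not pilrs:
        raise ValueError("need at least one PILR")
    ref = pilrs[0]
    for p in pilrs[1:]:
        if p.values.shape != ref.values.shape or p.compartment_split != ref.compartment_split:
            raise ValueError("PILR shape/discretization mismatch")
    mean = np.mean([p.values for p in pilrs], axis=0)
    return PILRMatrix(
        values=mean,
        compartment_split=ref.compartment_split,
        source_cell_id=f"average_of_{len(pilrs)}",
        grid=ref.grid,
        mode=ref.mode,
        meta={"averaged": True, "n": len(pilrs)},
    )
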