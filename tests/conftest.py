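"""Shared fixtures: synthetic cells, parameterizations and PILR populations.

Expensive generated datasets are session-scoped so unit and acceptance
tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from cellorg import fixtures as fx
from cellorg import pilr as pilr_mod
from cellorg import shparam


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def sphere_mask():
    """Voxelized sphere of radius 8 centred in a 24^3 image."""
    shape = (24, 24, 24)
    c = np.array([11.5] * 3)
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    mask = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= 8.0 ** 2
    return mask, c, 8.0


@pytest.fixture(scope="session")
def noisy_cell():
    """Noisy star-convex cell + interior nucleus (masks)."""
    spec = fx.SyntheticCellSpec(
        cell_base_radius=11, shape_noise_amplitude=0.1,
        nucleus_volume_fraction=0.25, seed=2,
    )
    return fx.generate_cell_shape(spec)


@pytest.fixture(scope="session")
def noisy_cell_coeffs(noisy_cell):
    """Degree-16 parameterization of the noisy cell."""
    return shparam.parameterize_cell(*noisy_cell)


@pytest.fixture(scope="session")
def concentric_sphere_coeffs():
    """Analytic concentric spheres: nucleus radius 5 inside cell radius 10."""
    center = np.array([15.0, 15.0, 15.0])
    cell = shparam.sphere_coeffs(10.0, lmax=16, centroid=center, surface_label="cell")
    nuc = shparam.sphere_coeffs(5.0, lmax=16, centroid=center, surface_label="nucleus")
    return cell, nuc


def _small_pilr(kind: str, bias: float, density: float, seed: int,
                base_radius: float = 9.0) -> pilr_mod.PILRMatrix:
    spec = fx.SyntheticCellSpec(cell_base_radius=base_radius,
                                shape_noise_amplitude=0.05, seed=seed)
    cell, nuc = fx.generate_cell_shape(spec)
    pattern = fx.StructurePattern(kind=kind, density=density,
                                  polarization_bias=bias, seed=seed + 1)
    struct = fx.generate_structure(pattern, cell, nuc)
    cc, nc = shparam.parameterize_cell(cell, nuc, lmax=8)
    return pilr_mod.sample_pilr(struct.astype(np.uint8), cc, nc,
                                n_nuclear_shells=8, n_cyto_shells=16,
                                grid=(12, 24))


@pytest.fixture(scope="session")
def polarization_populations():
    """64 uniform-puncta and 64 +x-polarized-puncta PILRs (planted effect)."""
    pilrs, labels = [], []
    for i in range(64):
        pilrs.append(_small_pilr("polarized_punctate", 0.0, 40, 1000 + 7 * i))
        labels.append("uniform")
    for i in range(64):
        pilrs.append(_small_pilr("polarized_punctate", 1.0, 40, 5000 + 7 * i))
        labels.append("polarized")
    return pilrs, labels


@pytest.fixture(scope="session")
def robustness_dataset():
    """Shape-varying population with shape-independent structure placement.

    Cell radius varies (a strong volume-like mode); reticular and nuclear
    patterns are placed by rules that ignore the planted mode.  Returns
    (pilrs_by_cell, structure_by_cell, descriptor matrix, cell ids).
    """
    rng = np.random.default_rng(42)
    pilrs, structs, desc, ids = {}, {}, [], []
    for i in range(60):
        radius = float(rng.uniform(8.5, 13.0))
        spec = fx.SyntheticCellSpec(
            cell_base_radius=radius, shape_noise_amplitude=0.04,
            nucleus_volume_fraction=0.25, seed=int(rng.integers(1 << 30)))
        cell, nuc = fx.generate_cell_shape(spec)
        kind = "reticular" if i % 2 == 0 else "nuclear"
        pattern = fx.StructurePattern(
            kind=kind, density=0.4 if kind == "reticular" else 8,
            seed=int(rng.integers(1 << 30)))
        struct = fx.generate_structure(pattern, cell, nuc)
        cc, nc = shparam.parameterize_cell(cell, nuc, lmax=8)
        cid = str(i)
        pilrs[cid] = pilr_mod.sample_pilr(
            struct.astype(np.uint8), cc, nc, n_nuclear_shells=8,
            n_cyto_shells=16, grid=(12, 24), source_cell_id=cid)
        structs[cid] = kind
        desc.append(np.concatenate([cc.coeffs, nc.coeffs]))
        ids.append(cid)
    return pilrs, structs, np.stack(desc), ids
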