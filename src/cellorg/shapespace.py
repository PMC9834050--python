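"""PCA shape space over joint cell + nucleus harmonic descriptors.

The joint 578-length descriptor (289 coefficients per surface at degree
16) is reduced to 8 orthonormal modes.  Mode values are z-scored by the
per-mode standard deviation of the fitting set, so coordinates are in
sigma units and the origin is the mean cell and nuclear shape.  Cells in
the extreme 1% tails of any raw mode are flagged excluded for downstream
statistics (the PCA itself is fitted on all cells).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "ShapeSpaceModel",
    "ShapeCoordinates",
    "MapPointBin",
    "fit_shape_space",
    "transform",
    "inverse_transform",
    "bin_cells",
    "enumerate_map_points",
    "select_sphere",
]

N_MODES = 8
BIN_CENTERS = np.arange(-2.0, 2.5, 0.5)  # nine centres, -2sigma .. 2sigma
BIN_HALF_WIDTH = 0.25


@dataclass
class ShapeSpaceModel:
    """Fitted PCA basis with scaling, sign and exclusion conventions."""

    mean_vector: np.ndarray  # per-column descriptor means, full length
    components: np.ndarray  # (n_modes, n_kept_columns), orthonormal rows
    sigma: np.ndarray  # per-mode std of raw scores (fit set)
    sign_flips: np.ndarray  # per-mode +-1
    percentile_bounds: np.ndarray  # (n_modes, 2): raw 1st/99th percentiles
    explained_variance_ratio: np.ndarray
    n_fit: int
    kept_columns: np.ndarray  # indices of non-degenerate descriptor columns
    n_features: int

    @property
    def n_modes(self) -> int:
        return len(self.sigma)

    def save_json(self, path) -> None:
        payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load_json(cls, path) -> "ShapeSpaceModel":
        with open(path) as fh:
            payload = json.load(fh)
        arrays = {"mean_vector", "components", "sigma", "sign_flips",
                  "percentile_bounds", "explained_variance_ratio", "kept_columns"}
        kwargs = {k: (np.asarray(v) if k in arrays else v) for k, v in payload.items()}
        return cls(**kwargs)


@dataclass
class ShapeCoordinates:
    """Per-cell 8-mode coordinates in sigma units."""

    values: np.ndarray  # (n_cells, n_modes)
    cell_ids: list = field(default_factory=list)
    excluded: np.ndarray | None = None  # percentile-exclusion flags

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("shape coordinates must be finite")
        if not self.cell_ids:
            self.cell_ids = list(range(len(self.values)))
        if self.excluded is None:
            self.excluded = np.zeros(len(self.values), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"mode{i + 1}": self.values[:, i] for i in range(self.values.shape[1])}
        return pd.DataFrame({"cell_id": self.cell_ids, **cols,
                             "excluded_flag": self.excluded})


@dataclass(frozen=True)
class MapPointBin:
    mode: int  # 1-based
    center: float  # sigma units
    member_cell_ids: tuple

    def __post_init__(self):
        if not 1 <= self.mode <= N_MODES:
            raise ValueError("mode must be in 1..8")


def fit_shape_space(
    descriptors: np.ndarray,
    n_modes: int = N_MODES,
    sign_covariate: np.ndarray | None = None,
) -> ShapeSpaceModel:
    """Fit the PCA model on all rows of an ``n x p`` descriptor matrix.

    Mode signs are chosen so each mode correlates positively with
    ``sign_covariate`` when given (e.g. cell volume); otherwise the sign
    making the raw score distribution positively skewed is used.
    """
    X = np.asarray(descriptors, dtype=float)
    if X.ndim != 2:
        raise ValueError("descriptor matrix must be 2D")
    n, p = X.shape
    if n < 9:
        raise ValueError(f"need at least 9 cells to fit the shape space, got {n}")

    variances = X.var(axis=0)
    kept = np.flatnonzero(variances > 0)
    if len(kept) < p:
        warnings.warn(f"dropping {p - len(kept)} zero-variance descriptor columns",
                      stacklevel=2)
    n_modes = min(n_modes, len(kept), n - 1)

    pca = PCA(n_components=n_modes, svd_solver="full")
    scores = pca.fit_transform(X[:, kept])

    flips = np.ones(n_modes)
    for j in range(n_modes):
        s = scores[:, j]
        if sign_covariate is not None:
            c = np.corrcoef(s, np.asarray(sign_covariate, dtype=float))[0, 1]
        else:
            c = np.mean(((s - s.mean()) / max(s.std(), 1e-300)) ** 3)  # skewness
        if c < 0:
            flips[j] = -1.0
    scores = scores * flips

    sigma = scores.std(axis=0, ddof=1)
    if np.any(sigma <= 0):
        raise ValueError("degenerate mode with zero variance")
    bounds = np.stack([np.percentile(scores, 1, axis=0),
                       np.percentile(scores, 99, axis=0)], axis=1)

    return ShapeSpaceModel(
        mean_vector=X.mean(axis=0),
        components=pca.components_ * flips[:, None],
        sigma=sigma,
        sign_flips=flips,
        percentile_bounds=bounds,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_fit=n,
        kept_columns=kept,
        n_features=p,
    )


def transform(
    model: ShapeSpaceModel,
    descriptors: np.ndarray,
    cell_ids: list | None = None,
    apply_exclusion: bool = True,
) -> ShapeCoordinates:
    """Project descriptors into sigma-unit shape coordinates.

    ``apply_exclusion=False`` is used when projecting a second population
    with the baseline model (no percentile filtering).
    """
    X = np.atleast_2d(np.asarray(descriptors, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(f"descriptor length {X.shape[1]} != expected {model.n_features}")
    centered = X[:, model.kept_columns] - model.mean_vector[model.kept_columns]
    raw = centered @ model.components.T
    excluded = np.zeros(len(X), dtype=bool)
    if apply_exclusion:
        lo, hi = model.percentile_bounds[:, 0], model.percentile_bounds[:, 1]
        excluded = np.any((raw < lo) | (raw > hi), axis=1)
    return ShapeCoordinates(values=raw / model.sigma,
                            cell_ids=list(cell_ids) if cell_ids is not None else [],
                            excluded=excluded)


def inverse_transform(model: ShapeSpaceModel, coords: np.ndarray) -> np.ndarray:
    """Map sigma-unit coordinates back to full-length descriptors.

    The origin maps to the mean descriptor (the mean cell and nuclear
    shape); dropped columns are restored at their means.
    """
    C = np.atleast_2d(np.asarray(coords, dtype=float))
    if C.shape[1] != model.n_modes:
        raise ValueError(f"expected {model.n_modes}-mode coordinates")
    raw = C * model.sigma
    full = np.tile(model.mean_vector, (len(C), 1))
    full[:, model.kept_columns] += raw @ model.components
    return full if np.asarray(coords).ndim == 2 else full[0]


def bin_cells(coords: ShapeCoordinates, mode: int,
              include_excluded: bool = False) -> list[MapPointBin]:
    """Assign cells to the nine map-point bins of one mode.

    A cell joins the nearest bin centre on that mode when within
    ``BIN_HALF_WIDTH`` of it; cells farther out are unassigned.
    """
    if not 1 <= mode <= N_MODES:
        raise ValueError("mode must be in 1..8")
    vals = coords.values[:, mode - 1]
    keep = np.ones(len(vals), dtype=bool) if include_excluded else ~coords.excluded
    nearest = np.clip(np.round(vals / 0.5) * 0.5, BIN_CENTERS[0], BIN_CENTERS[-1])
    in_bin = np.abs(vals - nearest) <= BIN_HALF_WIDTH + 1e-12
    bins = []
    for center in BIN_CENTERS:
        sel = keep & in_bin & (nearest == center)
        members = tuple(cid for cid, s in zip(coords.cell_ids, sel) if s)
        bins.append(MapPointBin(mode=mode, center=float(center), member_cell_ids=members))
    return bins


def enumerate_map_points(n_modes: int = N_MODES) -> list[tuple[float, ...]]:
    """All distinct map points: nine centres per mode, shared origin."""
    points = {tuple(0.0 for _ in range(n_modes))}
    for mode in range(n_modes):
        for center in BIN_CENTERS:
            pt = [0.0] * n_modes
            pt[mode] = float(center)
            points.add(tuple(pt))
    return sorted(points)


def select_sphere(coords: ShapeCoordinates, radius: float = 2.1,
                  include_excluded: bool = False) -> list:
    """Cell ids whose 8D Euclidean norm is within ``radius`` sigma."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    norms = np.linalg.norm(coords.values, axis=1)
    keep = norms <= radius
    if not include_excluded:
        keep &= ~coords.excluded
    return [cid for cid, k in zip(coords.cell_ids, keep) if k]
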