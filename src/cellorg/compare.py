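"""Comparison of a query population against a baseline population.

Covers shape matching by nearest neighbour in the 8-mode shape space,
the PCA + LDA axis summarizing a structure's average location difference
between two populations, threshold flagging of stereotypy/concordance
differences, and the timing-of-change bookkeeping across three sequential
stages (i -> m1 -> m2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

__all__ = [
    "ShapeMatchedDataset",
    "LDAAxisModel",
    "TOCTable",
    "match_shapes",
    "fit_lda_axis",
    "project_cells",
    "reconstruct_along_axis",
    "flag_differences",
    "toc_categories",
    "stereotypy_concordance_relationship",
]

RHO_MIN = 0.03
RHO_DIFF_MIN = 0.02
MAX_REDUCED_DIM = 32
TOC_CATEGORIES = ("m1_only", "stepwise", "m2_change", "no_change")


@dataclass
class ShapeMatchedDataset:
    query_cell_ids: list
    matched_baseline_ids: list  # unique, order of first flagging
    nearest_by_query: dict  # query id -> baseline id
    duplicate_flag_count: int
    combined_mean_coords: np.ndarray


@dataclass
class LDAAxisModel:
    pca: PCA
    direction: np.ndarray  # unit vector in reduced space
    axis_scale: float  # pooled projection standard deviation
    group_means: dict  # population label -> mean axis position (sigma units)
    labels: tuple  # (population A, population B); B mean positive
    reduced_dim: int
    regularized: bool = False


@dataclass
class TOCTable:
    labels: list[str]
    categories: pd.DataFrame  # entry in TOC_CATEGORIES
    measurable: pd.DataFrame  # bool; False entries annotated undetermined
    annotations: dict = field(default_factory=dict)


def match_shapes(baseline_coords, query_coords,
                 baseline_ids: list | None = None,
                 query_ids: list | None = None) -> ShapeMatchedDataset:
    """Flag each query cell's nearest baseline neighbour in 8D shape space.

    Ties are broken towards the lowest baseline cell id.  Repeatedly
    flagged baseline cells collapse to a unique set;
    ``duplicate_flag_count`` counts queries whose neighbour was already
    flagged.
    """
    B = np.atleast_2d(np.asarray(getattr(baseline_coords, "values", baseline_coords), float))
    Q = np.atleast_2d(np.asarray(getattr(query_coords, "values", query_coords), float))
    if B.size == 0:
        raise ValueError("baseline coordinate set is empty")
    if baseline_ids is None:
        baseline_ids = getattr(baseline_coords, "cell_ids", None) or list(range(len(B)))
    if query_ids is None:
        query_ids = getattr(query_coords, "cell_ids", None) or list(range(len(Q)))

    order = np.argsort(np.asarray(baseline_ids, dtype=object), kind="stable")
    B_sorted = B[order]
    ids_sorted = [baseline_ids[i] for i in order]
    dists = cdist(Q, B_sorted)
    nn = dists.argmin(axis=1)  # argmin takes the first == lowest id on ties

    nearest = {qid: ids_sorted[j] for qid, j in zip(query_ids, nn)}
    matched, seen, dupes = [], set(), 0
    for qid in query_ids:
        bid = nearest[qid]
        if bid in seen:
            dupes += 1
        else:
            seen.add(bid)
            matched.append(bid)
    pos = {bid: i for i, bid in enumerate(ids_sorted)}
    combined = np.vstack([B_sorted[[pos[b] for b in matched]], Q])
    return ShapeMatchedDataset(
        query_cell_ids=list(query_ids),
        matched_baseline_ids=matched,
        nearest_by_query=nearest,
        duplicate_flag_count=dupes,
        combined_mean_coords=combined.mean(axis=0),
    )


def _flat(p) -> np.ndarray:
    vals = p.values if hasattr(p, "values") else np.asarray(p)
    return np.asarray(vals, dtype=float).ravel()


def fit_lda_axis(pilrs: list, population_labels: list,
                 max_dim: int = MAX_REDUCED_DIM) -> LDAAxisModel:
    """PCA to at most 32 dimensions, then a two-class linear discriminant.

    The axis is the unit direction in reduced space maximizing between- vs
    within-class separation; positions along it are z-scored by the pooled
    standard deviation of the projections.  The second population (sorted
    label order) has positive mean by convention.
    """
    labels = np.asarray(population_labels, dtype=object)
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two populations required, got {uniq}")
    for u in uniq:
        if (labels == u).sum() < 3:
            raise ValueError(f"population {u!r} has fewer than 3 cells")

    X = np.stack([_flat(p) for p in pilrs])
    n = len(X)
    reduced_dim = min(max_dim, n, X.shape[1])
    pca = PCA(n_components=reduced_dim, svd_solver="randomized", random_state=0)
    Xr = pca.fit_transform(X)
    reduced_dim = Xr.shape[1]

    m = {u: Xr[labels == u].mean(axis=0) for u in uniq}
    Sw = np.zeros((reduced_dim, reduced_dim))
    for u in uniq:
        D = Xr[labels == u] - m[u]
        Sw += D.T @ D
    regularized = False
    if np.linalg.cond(Sw) > 1e10:
        warnings.warn("singular within-class scatter; applying ridge regularization",
                      stacklevel=2)
        Sw = Sw + 1e-6 * np.trace(Sw) / reduced_dim * np.eye(reduced_dim)
        regularized = True
    w = np.linalg.solve(Sw, m[uniq[1]] - m[uniq[0]])
    w = w / np.linalg.norm(w)

    proj = Xr @ w
    if proj[labels == uniq[1]].mean() < proj[labels == uniq[0]].mean():
        w = -w
        proj = -proj
    scale = proj.std(ddof=1)
    if scale == 0:
        raise ValueError("degenerate projections: no variance along the axis")
    group_means = {u: float(proj[labels == u].mean() / scale) for u in uniq}
    return LDAAxisModel(pca=pca, direction=w, axis_scale=float(scale),
                        group_means=group_means, labels=tuple(uniq),
                        reduced_dim=reduced_dim, regularized=regularized)


def project_cells(model: LDAAxisModel, pilrs: list) -> np.ndarray:
    """Axis position (sigma units) of each PILR."""
    X = np.stack([_flat(p) for p in pilrs])
    return (model.pca.transform(X) @ model.direction) / model.axis_scale


def reconstruct_along_axis(model: LDAAxisModel, positions) -> np.ndarray:
    """Flattened PILRs reconstructed at given axis positions (sigma units)."""
    positions = np.atleast_1d(np.asarray(positions, dtype=float))
    if not np.all(np.isfinite(positions)):
        raise ValueError("axis positions must be finite")
    Xr = positions[:, None] * model.axis_scale * model.direction[None, :]
    return model.pca.inverse_transform(Xr)


def _as_frame(mat, labels=None) -> pd.DataFrame:
    if isinstance(mat, pd.DataFrame):
        return mat
    if hasattr(mat, "to_frame"):
        return mat.to_frame()
    return pd.DataFrame(np.asarray(mat, dtype=float), index=labels, columns=labels)


def flag_differences(
    mat_a,
    mat_b,
    rho_min: float = RHO_MIN,
    rho_diff_min: float = RHO_DIFF_MIN,
    reference: str = "a",
    relative_override: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag stereotypy/concordance entries that changed between conditions.

    An entry is *measurable* when its reference-condition value (``a`` by
    convention, the earlier stage) is at least ``rho_min``; it is
    *flagged* when measurable and ``|a - b| >= rho_diff_min``.
    ``relative_override`` (e.g. 0.05), when set, suppresses flags whose
    relative difference ``|a - b| / |ref|`` stays below it.
    Returns ``(flags, measurable)`` boolean frames.
    """
    A, B = _as_frame(mat_a), _as_frame(mat_b)
    if not (A.index.equals(B.index) and A.columns.equals(B.columns)):
        raise ValueError("matrices do not share labels")
    ref = A if reference == "a" else B
    measurable = (ref >= rho_min) & ref.notna() & A.notna() & B.notna()
    diff = (A - B).abs()
    flags = measurable & (diff >= rho_diff_min)
    if relative_override is not None:
        small = diff / ref.abs().where(ref.abs() > 0) < relative_override
        flags &= ~small.fillna(False)
    return flags.fillna(False).astype(bool), measurable.fillna(False).astype(bool)


def _toc_rule(f_i1m1: bool, f_i2m2: bool, f_m1m2: bool) -> str:
    if f_i1m1 and f_m1m2:
        return "stepwise"
    if f_i1m1:
        return "m1_only"
    if f_m1m2 or f_i2m2:
        return "m2_change"
    return "no_change"


def toc_categories(
    flags_i1m1: pd.DataFrame,
    flags_i2m2: pd.DataFrame,
    flags_m1m2: pd.DataFrame,
    measurable_i1m1: pd.DataFrame | None = None,
    measurable_i2m2: pd.DataFrame | None = None,
    measurable_m1m2: pd.DataFrame | None = None,
) -> TOCTable:
    """Combine the three comparison flag matrices into TOC categories.

    m1_only: flagged i1-m1 but not m1-m2; stepwise: flagged in both;
    m2_change: not flagged i1-m1 but flagged m1-m2 or i2-m2; otherwise
    no_change.  Entries unmeasurable in any comparison are categorized
    no_change with an "undetermined" annotation.
    """
    F1, F2, F3 = (_as_frame(f).astype(bool) for f in (flags_i1m1, flags_i2m2, flags_m1m2))
    labels = list(F1.index)
    cats = pd.DataFrame("no_change", index=F1.index, columns=F1.columns, dtype=object)
    for i in F1.index:
        for j in F1.columns:
            cats.loc[i, j] = _toc_rule(F1.loc[i, j], F2.loc[i, j], F3.loc[i, j])

    if measurable_i1m1 is not None:
        meas = (_as_frame(measurable_i1m1).astype(bool)
                & _as_frame(measurable_i2m2).astype(bool)
                & _as_frame(measurable_m1m2).astype(bool))
    else:
        meas = pd.DataFrame(True, index=F1.index, columns=F1.columns)
    annotations = {}
    for i in F1.index:
        for j in F1.columns:
            if not meas.loc[i, j]:
                cats.loc[i, j] = "no_change"
                annotations[(i, j)] = "undetermined"
    return TOCTable(labels=labels, categories=cats, measurable=meas,
                    annotations=annotations)


_CHANGE_TIMES = {
    "no_change": frozenset(),
    "m1_only": frozenset({"m1"}),
    "m2_change": frozenset({"m2"}),
    "stepwise": frozenset({"m1", "m2"}),
}
_STAGE_ORDER = {"m1": 0, "m2": 1}


def _relationship(stereo_a: str, stereo_b: str, conc: str) -> tuple[str, bool]:
    """Consolidated category for one structure pair.

    Returns ``(category, at_first_change)`` with category one of
    ``no_changes``, ``co_timed``, ``independent``.
    """
    S = _CHANGE_TIMES[stereo_a] | _CHANGE_TIMES[stereo_b]
    C = _CHANGE_TIMES[conc]
    if not S and not C:
        return "no_changes", False
    if C and C <= S:
        first_s = min(S, key=_STAGE_ORDER.get)
        first_c = min(C, key=_STAGE_ORDER.get)
        return "co_timed", first_c == first_s
    return "independent", False


def stereotypy_concordance_relationship(
    stereotypy_toc: TOCTable,
    concordance_toc: TOCTable,
) -> pd.DataFrame:
    """Relate each pair's concordance TOC to its members' stereotypy TOCs.

    Categories: ``no_changes`` (nothing changed), ``co_timed`` (every
    concordance change co-timed with a stereotypy change of at least one
    member; ``at_first_change`` marks co-timing with the first stereotypy
    change) and ``independent`` (a concordance change without a
    co-timed stereotypy change, or vice versa).
    """
    labels = concordance_toc.labels
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            sa = stereotypy_toc.categories.loc[a, a]
            sb = stereotypy_toc.categories.loc[b, b]
            cc = concordance_toc.categories.loc[a, b]
            cat, first = _relationship(sa, sb, cc)
            rows.append({"structure_a": a, "structure_b": b,
                         "stereotypy_a": sa, "stereotypy_b": sb,
                         "concordance": cc, "category": cat,
                         "at_first_change": first})
    return pd.DataFrame(rows)
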