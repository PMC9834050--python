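"""Location similarity, stereotypy, concordance and size-scaling statistics.

All correlation measures are pixel-wise Pearson correlations between
flattened PILR matrices.  *Average location similarity* correlates the
per-structure average PILRs; *stereotypy* (diagonal) and *concordance*
(off-diagonal) average the individual cell-pair correlations within and
across structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

__all__ = [
    "SimilarityMatrix",
    "AverageCorrelationMatrix",
    "location_similarity",
    "cluster_structures",
    "linkage_to_newick",
    "pairwise_cell_correlations",
    "stereotypy_concordance",
    "per_mappoint_statistics",
    "volume_scaling",
]


@dataclass
class SimilarityMatrix:
    """Symmetric structure-by-structure Pearson correlation matrix."""

    labels: list[str]
    values: np.ndarray
    missing: dict = field(default_factory=dict)  # label/pair -> reason

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class AverageCorrelationMatrix:
    """Diagonal = stereotypy, off-diagonal = concordance."""

    labels: list[str]
    values: np.ndarray
    n_pairs: np.ndarray  # cell pairs behind each entry
    missing: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def stereotypy(self, label: str) -> float:
        i = self.labels.index(label)
        return float(self.values[i, i])

    def concordance(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _flatten(p) -> np.ndarray:
    vals = p.values if hasattr(p, "values") else np.asarray(p)
    return np.asarray(vals, dtype=float).ravel()


def location_similarity(avg_pilrs: dict) -> SimilarityMatrix:
    """Pearson correlation between the average PILRs of every structure pair.

    Zero-variance average PILRs produce missing (NaN) entries with a
    recorded reason rather than an exception.
    """
    labels = list(avg_pilrs)
    flat = {k: _flatten(v) for k, v in avg_pilrs.items()}
    sizes = {v.size for v in flat.values()}
    if len(sizes) > 1:
        raise ValueError("average PILRs do not share a discretization")
    degenerate = {k for k, v in flat.items() if np.std(v) == 0.0}

    n = len(labels)
    vals = np.full((n, n), np.nan)
    missing = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels[i:], start=i):
            if a in degenerate or b in degenerate:
                bad = a if a in degenerate else b
                missing[(a, b)] = f"zero-variance average PILR for {bad!r}"
                continue
            r = 1.0 if i == j else float(np.corrcoef(flat[a], flat[b])[0, 1])
            vals[i, j] = vals[j, i] = r
    return SimilarityMatrix(labels=labels, values=vals, missing=missing)


def cluster_structures(similarity: SimilarityMatrix):
    """Average-linkage agglomeration of structures by similarity profile.

    Each structure's row of the similarity matrix is its feature vector
    (Euclidean metric), matching the practice of feeding the correlation
    matrix to an average-linkage routine.  Returns a scipy linkage matrix.
    """
    if np.isnan(similarity.values).any():
        bad = sorted(str(k) for k in similarity.missing)
        raise ValueError(f"similarity matrix has missing entries: {bad}")
    return linkage(similarity.values, method="average", metric="euclidean")


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    n = len(labels)
    nodes = {i: (labels[i], 0.0) for i in range(n)}
    for k, (a, b, height, _) in enumerate(Z):
        (sa, ha), (sb, hb) = nodes.pop(int(a)), nodes.pop(int(b))
        node = f"({sa}:{height / 2 - ha / 2:.6g},{sb}:{height / 2 - hb / 2:.6g})"
        nodes[n + k] = (node, height)
    (tree, _), = nodes.values()
    return tree + ";"


def pairwise_cell_correlations(pilrs: list, cell_ids: list | None = None):
    """n x n matrix of pixel-wise Pearson correlations between cell PILRs.

    Cells with zero-variance PILRs are excluded; returns
    ``(matrix, kept_ids, excluded_report)``.
    """
    if len(pilrs) < 2:
        raise ValueError("need at least 2 cells")
    if cell_ids is None:
        cell_ids = [getattr(p, "source_cell_id", "") or str(i) for i, p in enumerate(pilrs)]
    X = np.stack([_flatten(p) for p in pilrs])
    keep = X.std(axis=1) > 0.0
    excluded = {cid: "zero-variance PILR" for cid, k in zip(cell_ids, keep) if not k}
    kept_ids = [cid for cid, k in zip(cell_ids, keep) if k]
    if keep.sum() < 2:
        raise ValueError("fewer than 2 cells with non-degenerate PILRs")
    mat = np.corrcoef(X[keep])
    return mat, kept_ids, excluded


def stereotypy_concordance(cell_matrix: np.ndarray, labels: list[str],
                           structure_labels: list[str] | None = None) -> AverageCorrelationMatrix:
    """Average the cell-pair correlation matrix within structure pairs.

    Stereotypy of a structure is the mean over distinct unordered cell
    pairs within it (self-pairs excluded); concordance of two structures
    is the mean over all cross-structure cell pairs.  A structure with a
    single cell has undefined stereotypy (NaN, with a reason).
    """
    cell_matrix = np.asarray(cell_matrix, dtype=float)
    labels = list(labels)
    if cell_matrix.shape[0] != len(labels):
        raise ValueError("per-cell labels do not match matrix size")
    structures = structure_labels or sorted(set(labels))
    idx = {s: np.flatnonzero(np.asarray(labels, dtype=object) == s) for s in structures}

    n = len(structures)
    vals = np.full((n, n), np.nan)
    npairs = np.zeros((n, n), dtype=int)
    missing = {}
    for i, s in enumerate(structures):
        ii = idx[s]
        if len(ii) >= 2:
            block = cell_matrix[np.ix_(ii, ii)]
            iu = np.triu_indices(len(ii), k=1)
            vals[i, i] = block[iu].mean()
            npairs[i, i] = len(iu[0])
        else:
            missing[(s, s)] = f"stereotypy undefined: {len(ii)} cell(s) for {s!r}"
        for j in range(i + 1, n):
            jj = idx[structures[j]]
            if len(ii) >= 1 and len(jj) >= 1:
                block = cell_matrix[np.ix_(ii, jj)]
                vals[i, j] = vals[j, i] = block.mean()
                npairs[i, j] = npairs[j, i] = block.size
            else:
                missing[(s, structures[j])] = "no cells in one structure of the pair"
    return AverageCorrelationMatrix(labels=structures, values=vals,
                                    n_pairs=npairs, missing=missing)


def per_mappoint_statistics(
    pilrs_by_cell: dict,
    structure_by_cell: dict,
    coords,
    statistic: str = "similarity",
    min_cells: int = 5,
) -> dict:
    """One statistic matrix per (mode, bin-centre) map point.

    ``statistic`` is one of ``similarity``, ``stereotypy_concordance``.
    Structures with fewer than ``min_cells`` members in a bin are dropped
    from that bin's matrix (missing, not zero); bins with fewer than two
    eligible structures (similarity) or no eligible entries are reported
    as None.
    """
    from cellorg import shapespace

    if statistic not in ("similarity", "stereotypy_concordance"):
        raise ValueError(f"unknown statistic {statistic!r}")
    out = {}
    for mode in range(1, coords.values.shape[1] + 1):
        for b in shapespace.bin_cells(coords, mode):
            members = [cid for cid in b.member_cell_ids if cid in pilrs_by_cell]
            by_struct: dict[str, list] = {}
            for cid in members:
                by_struct.setdefault(structure_by_cell[cid], []).append(cid)
            eligible = {s: ids for s, ids in by_struct.items() if len(ids) >= min_cells}
            key = (mode, b.center)
            if not eligible:
                out[key] = None
                continue
            if statistic == "similarity":
                from cellorg.pilr import average_pilr
                avg = {s: average_pilr([pilrs_by_cell[c] for c in ids])
                       for s, ids in eligible.items()}
                out[key] = location_similarity(avg) if len(avg) >= 2 else None
            else:
                ids = [c for s in sorted(eligible) for c in eligible[s]]
                mat, kept, _ = pairwise_cell_correlations(
                    [pilrs_by_cell[c] for c in ids], ids)
                lbls = [structure_by_cell[c] for c in kept]
                out[key] = stereotypy_concordance(mat, lbls, sorted(eligible))
    return out


def volume_scaling(structure_volumes: dict, size_metrics: pd.DataFrame) -> pd.DataFrame:
    """Linear scaling of structure volume with cell/nuclear size metrics.

    For each structure: the total R-squared of the ordinary least squares
    model on all metrics, and each metric's unique contribution, defined
    as R2(full) - R2(full without that metric).
    """
    M = np.asarray(size_metrics, dtype=float)
    n, k = M.shape
    if n < 30:
        raise ValueError("need at least 30 cells for the scaling analysis")
    if np.any(M <= 0):
        raise ValueError("size metrics must be positive")
    Ms = (M - M.mean(axis=0)) / M.std(axis=0)  # scale-free collinearity check
    cond = np.linalg.cond(Ms)
    if cond > 1e6:
        warnings.warn("size metrics are nearly collinear; unique contributions "
                      "may be unstable", stacklevel=2)

    def r2(X, y):
        X1 = np.column_stack([np.ones(len(y)), X])
        beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
        resid = y - X1 @ beta
        tss = np.sum((y - y.mean()) ** 2)
        return 1.0 - np.sum(resid ** 2) / tss if tss > 0 else np.nan

    rows = []
    cols = list(size_metrics.columns)
    for sname, y in structure_volumes.items():
        y = np.asarray(y, dtype=float)
        total = r2(M, y)
        row = {"structure": sname, "total_r2": total}
        for j, c in enumerate(cols):
            reduced = r2(np.delete(M, j, axis=1), y)
            row[f"unique_{c}"] = total - reduced
        rows.append(row)
    return pd.DataFrame(rows).set_index("structure")
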