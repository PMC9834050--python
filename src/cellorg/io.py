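"""Manifest data model, configuration and pipeline orchestration.

A dataset is a plain CSV manifest pointing at per-cell 3D TIFF masks
(cell, nucleus, structure) with axis order (z, y, x) and isotropic
voxels.  ``run_pipeline`` chains the stages — surface parameterization,
shape space, PILR sampling, statistics — writing each stage's artifacts
plus provenance metadata to the configured output directory.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CellRecord", "RunConfig", "load_dataset", "run_pipeline"]

REQUIRED_COLUMNS = ("cell_id", "population", "structure_name",
                    "path_cell", "path_nucleus", "path_structure")
STAGES = ("shparam", "shapespace", "pilr", "stats")
STAGE_DEPS = {"shparam": (), "shapespace": ("shparam",),
              "pilr": ("shparam", "shapespace"), "stats": ("pilr",)}


@dataclass
class CellRecord:
    cell_id: str
    population: str
    structure_name: str
    path_cell: str
    path_nucleus: str
    path_structure: str
    voxel_size_um: float = 0.108333
    outward_vector: tuple | None = None
    qc_flags: list = field(default_factory=list)


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run."""

    manifest: str = "manifest.csv"
    output_dir: str = "cellorg_out"
    lmax: int = 16
    n_nuclear_shells: int = 32
    n_cyto_shells: int = 64
    grid: tuple = (32, 64)
    bin_half_width: float = 0.25
    sphere_radius: float = 2.1
    rho_min: float = 0.03
    rho_diff_min: float = 0.02
    alignment_mode: str = "longest_axis"
    percentile_exclusion: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("lmax", "n_nuclear_shells", "n_cyto_shells",
                     "bin_half_width", "sphere_radius", "rho_min", "rho_diff_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.grid = tuple(int(g) for g in self.grid)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        payload.pop("qc_flags", None)
        return cls(**payload)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_dataset(manifest_path, strict: bool = False):
    """Read and validate a manifest CSV into :class:`CellRecord` rows.

    Invalid rows are reported (row number + reason) and skipped unless
    ``strict``; zero valid rows is always an error.
    """
    df = pd.read_csv(manifest_path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing required columns: {missing}")

    records, failures = [], []
    for i, row in df.iterrows():
        reason = None
        for col in ("path_cell", "path_nucleus", "path_structure"):
            if not os.path.exists(str(row[col])):
                reason = f"missing file {row[col]!r}"
                break
        if reason is None and not str(row["cell_id"]).strip():
            reason = "empty cell_id"
        if reason is not None:
            failures.append((int(i), reason))
            continue
        outward = None
        if "outward_z" in df.columns and pd.notna(row.get("outward_z")):
            outward = (float(row["outward_z"]), float(row["outward_y"]),
                       float(row["outward_x"]))
        records.append(CellRecord(
            cell_id=str(row["cell_id"]),
            population=str(row["population"]),
            structure_name=str(row["structure_name"]),
            path_cell=str(row["path_cell"]),
            path_nucleus=str(row["path_nucleus"]),
            path_structure=str(row["path_structure"]),
            voxel_size_um=float(row.get("voxel_size_um", 0.108333)),
            outward_vector=outward,
        ))
    if strict and failures:
        raise ValueError(f"manifest validation failed: {failures}")
    if not records:
        raise ValueError(f"no valid rows in manifest ({len(failures)} failures)")
    return records, failures


def _write_provenance(out_dir: str, config: RunConfig, stage: str) -> None:
    import cellorg
    payload = {"stage": stage, "config": asdict(config),
               "config_digest": config.digest(),
               "package_version": cellorg.__version__,
               "numpy_version": np.__version__, "seed": config.seed}
    with open(os.path.join(out_dir, f"provenance_{stage}.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def _stage_artifact(out_dir: str, stage: str) -> str:
    return {
        "shparam": os.path.join(out_dir, "coeffs.csv"),
        "shapespace": os.path.join(out_dir, "shape_coords.csv"),
        "pilr": os.path.join(out_dir, "pilr_values.npz"),
        "stats": os.path.join(out_dir, "similarity.csv"),
    }[stage]


def _run_shparam(records, config, out_dir):
    import tifffile
    from cellorg import shparam

    rows, align_rows = [], []
    for rec in records:
        cell = tifffile.imread(rec.path_cell) > 0
        nuc = tifffile.imread(rec.path_nucleus) > 0
        struct = tifffile.imread(rec.path_structure)
        mode = config.alignment_mode if rec.outward_vector is None else "edge_axis"
        cell_a, nuc_a, struct_a, arec = shparam.align_cell(
            cell, nuc, struct, mode=mode, outward_vector=rec.outward_vector)
        cc, nc = shparam.parameterize_cell(cell_a, nuc_a, lmax=config.lmax,
                                           voxel_size_um=rec.voxel_size_um)
        row = {"cell_id": rec.cell_id, **cc.to_dict(), **nc.to_dict()}
        for ax, v in zip("zyx", nc.centroid_offset):
            row[f"nucleus_offset_{ax}"] = v
        rows.append(row)
        align_rows.append({"cell_id": rec.cell_id, "theta_cell": arec.theta_cell,
                           "mode": arec.mode})
        np.save(os.path.join(out_dir, f"aligned_{rec.cell_id}.npy"),
                np.stack([cell_a, nuc_a, struct_a > 0]).astype(np.uint8))
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "coeffs.csv"), index=False)
    pd.DataFrame(align_rows).to_csv(os.path.join(out_dir, "alignment.csv"), index=False)


def _load_coeffs(out_dir, config):
    from cellorg import sh, shparam

    df = pd.read_csv(os.path.join(out_dir, "coeffs.csv"))
    nc = sh.n_coeffs(config.lmax)
    out = {}
    for _, row in df.iterrows():
        cvec = np.empty(nc)
        nvec = np.empty(nc)
        for l in range(config.lmax + 1):
            for m in range(-l, l + 1):
                cvec[sh.sh_index(l, m)] = row[f"cell_L{l}M{m}"]
                nvec[sh.sh_index(l, m)] = row[f"nucleus_L{l}M{m}"]
        offset = np.array([row[f"nucleus_offset_{ax}"] for ax in "zyx"])
        cell = shparam.SHECoefficients(cvec, config.lmax, "cell", np.zeros(3))
        nuc = shparam.SHECoefficients(nvec, config.lmax, "nucleus", offset,
                                      centroid_offset=offset)
        out[str(row["cell_id"])] = (cell, nuc)
    return out


def _run_shapespace(records, config, out_dir):
    from cellorg import shapespace, shparam

    coeffs = _load_coeffs(out_dir, config)
    ids = [r.cell_id for r in records if r.cell_id in coeffs]
    X = np.stack([shparam.joint_descriptor(*coeffs[c]) for c in ids])
    volumes = None  # volume covariate from the l=0 cell term (monotone proxy)
    volumes = X[:, 0]
    model = shapespace.fit_shape_space(X, sign_covariate=volumes)
    coords = shapespace.transform(model, X, cell_ids=ids)
    model.save_json(os.path.join(out_dir, "shape_model.json"))
    coords.to_frame().to_csv(os.path.join(out_dir, "shape_coords.csv"), index=False)


def _run_pilr(records, config, out_dir):
    from cellorg import pilr as pilr_mod
    from cellorg import shapespace

    coeffs = _load_coeffs(out_dir, config)
    coords_df = pd.read_csv(os.path.join(out_dir, "shape_coords.csv"))
    mode_cols = [c for c in coords_df.columns if c.startswith("mode")]
    coords = shapespace.ShapeCoordinates(
        values=coords_df[mode_cols].to_numpy(),
        cell_ids=[str(c) for c in coords_df["cell_id"]],
        excluded=coords_df["excluded_flag"].to_numpy(bool),
    )
    selected = set(shapespace.select_sphere(
        coords, config.sphere_radius,
        include_excluded=not config.percentile_exclusion))

    arrays, meta = {}, {}
    for rec in records:
        if rec.cell_id not in selected or rec.cell_id not in coeffs:
            continue
        chans = np.load(os.path.join(out_dir, f"aligned_{rec.cell_id}.npy"))
        cell, nuc = coeffs[rec.cell_id]
        # place coefficients at the aligned-image centroids
        from scipy import ndimage
        cell_centroid = np.asarray(ndimage.center_of_mass(chans[0] > 0))
        cell = pilr_mod.SHECoefficients(cell.coeffs, cell.lmax, "cell", cell_centroid)
        nuc = pilr_mod.SHECoefficients(nuc.coeffs, nuc.lmax, "nucleus",
                                       cell_centroid + nuc.centroid_offset,
                                       centroid_offset=nuc.centroid_offset)
        p = pilr_mod.sample_pilr(
            chans[2], cell, nuc,
            n_nuclear_shells=config.n_nuclear_shells,
            n_cyto_shells=config.n_cyto_shells,
            grid=config.grid, source_cell_id=rec.cell_id)
        arrays[rec.cell_id] = p.values
        meta[rec.cell_id] = rec.structure_name
    if not arrays:
        raise ValueError("no cells inside the selection sphere; nothing to sample")
    np.savez_compressed(os.path.join(out_dir, "pilr_values.npz"), **arrays)
    with open(os.path.join(out_dir, "pilr_meta.json"), "w") as fh:
        json.dump({"structures": meta,
                   "compartment_split": config.n_nuclear_shells,
                   "grid": list(config.grid)}, fh, indent=2, sort_keys=True)


def _run_stats(records, config, out_dir):
    from cellorg import pilr as pilr_mod
    from cellorg import stats

    data = np.load(os.path.join(out_dir, "pilr_values.npz"))
    meta = json.load(open(os.path.join(out_dir, "pilr_meta.json")))
    split = meta["compartment_split"]
    grid = tuple(meta["grid"])
    by_struct: dict[str, list] = {}
    pilrs, ids = [], []
    for cid in sorted(data.files):
        p = pilr_mod.PILRMatrix(values=data[cid], compartment_split=split,
                                source_cell_id=cid, grid=grid)
        pilrs.append(p)
        ids.append(cid)
        by_struct.setdefault(meta["structures"][cid], []).append(p)

    avg = {s: pilr_mod.average_pilr(ps) for s, ps in sorted(by_struct.items())}
    sim = stats.location_similarity(avg)
    sim.to_frame().to_csv(os.path.join(out_dir, "similarity.csv"))
    if len(avg) >= 2 and not np.isnan(sim.values).any():
        Z = stats.cluster_structures(sim)
        with open(os.path.join(out_dir, "dendrogram.nwk"), "w") as fh:
            fh.write(stats.linkage_to_newick(Z, sim.labels))
    if len(pilrs) >= 2:
        mat, kept, _ = stats.pairwise_cell_correlations(pilrs, ids)
        labels = [meta["structures"][c] for c in kept]
        acm = stats.stereotypy_concordance(mat, labels)
        acm.to_frame().to_csv(os.path.join(out_dir, "stereotypy_concordance.csv"))


_STAGE_RUNNERS = {"shparam": _run_shparam, "shapespace": _run_shapespace,
                  "pilr": _run_pilr, "stats": _run_stats}


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Run the requested stages in order, enforcing stage dependencies.

    Artifacts from earlier runs satisfy dependencies of stages not in
    ``stages``.  Returns a dict of stage -> primary artifact path.
    """
    requested = set(stages)
    unknown = requested - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in requested]
    out_dir = config.output_dir
    os.makedirs(out_dir, exist_ok=True)

    for s in stages:
        for dep in STAGE_DEPS[s]:
            if dep not in stages and not os.path.exists(_stage_artifact(out_dir, dep)):
                raise ValueError(f"stage {s!r} requires missing upstream stage {dep!r}")

    records, failures = load_dataset(config.manifest)
    artifacts = {}
    for s in stages:
        _STAGE_RUNNERS[s](records, config, out_dir)
        _write_provenance(out_dir, config, s)
        artifacts[s] = _stage_artifact(out_dir, s)
    if failures:
        with open(os.path.join(out_dir, "manifest_failures.json"), "w") as fh:
            json.dump(failures, fh)
    return artifacts
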