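"""Readers and writers for all on-disk formats, study config and provenance.

Formats are deliberately plain: comma-separated UTF-8 text with a mandatory
header for tables, standard 7-column SWC for traced arbors, YAML for study
configuration.  Mosaic coordinates are in mm (whole-mount scale), SWC
coordinates in µm (single-cell scale); no implicit conversion anywhere.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidSpecError, LoadError
from .morphometry import S1_Z_UM, S5_Z_UM, NeuriteTree
from .mosaic import CellMosaic, MosaicStatsResult
from .reference import MEAN_DENSITY_MM2
from .region import RegionPolygon
from .synthetic import DEFAULT_DONOR_AGES

__all__ = [
    "MOSAIC_COLUMNS",
    "REGION_COLUMNS",
    "STUDY_COLUMNS",
    "read_region",
    "write_region",
    "read_mosaic",
    "write_mosaic",
    "read_swc",
    "write_swc",
    "write_swc_type_sidecar",
    "read_cell_metadata",
    "read_study_table",
    "write_study_table",
    "write_mosaic_stats",
    "write_histogram",
    "StudyConfig",
    "load_config",
    "write_provenance",
    "write_aging_dataset",
]

MOSAIC_COLUMNS = ["cell_id", "x_mm", "y_mm", "subtype", "layer", "donor_id", "age_years"]
REGION_COLUMNS = ["vertex_id", "x_mm", "y_mm"]
STUDY_COLUMNS = ["donor_id", "age_years", "age_group", "subtype", "metric", "value", "n_cells"]

#: SWC type codes (de-facto standard); stratum is encoded by the node z plane.
SWC_TYPE_CODES = {1: "soma", 2: "axon", 3: "dendrite", 4: "dendrite"}


# ---------------------------------------------------------------------------
# regions and mosaics
# ---------------------------------------------------------------------------


def write_region(region: RegionPolygon, path) -> None:
    df = pd.DataFrame(
        {"vertex_id": np.arange(len(region.vertices)),
         "x_mm": region.vertices[:, 0], "y_mm": region.vertices[:, 1]}
    )
    df.to_csv(path, index=False)


def read_region(path) -> RegionPolygon:
    df = _read_table(path, REGION_COLUMNS)
    df = df.sort_values("vertex_id")
    return RegionPolygon(df[["x_mm", "y_mm"]].to_numpy(dtype=float))


def write_mosaic(mosaic: CellMosaic, cells_path, region_path=None) -> None:
    n = mosaic.n
    df = pd.DataFrame(
        {
            "cell_id": mosaic.cell_ids,
            "x_mm": mosaic.points[:, 0],
            "y_mm": mosaic.points[:, 1],
            "subtype": mosaic.subtype if mosaic.subtype is not None else [""] * n,
            "layer": mosaic.layer if mosaic.layer is not None else [""] * n,
            "donor_id": [mosaic.donor_id or ""] * n,
            "age_years": [mosaic.donor_age if mosaic.donor_age is not None else ""] * n,
        }
    )
    # default float repr is the shortest exact representation: coordinates
    # round-trip without loss
    df.to_csv(cells_path, index=False)
    if region_path is not None:
        write_region(mosaic.region, region_path)


def _read_table(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{path.name}: missing column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    # python float() is correctly rounded, so written values reload exactly
    vals = np.empty(len(df))
    bad = []
    for i, s in enumerate(df[col].tolist()):
        if s == "":
            vals[i] = np.nan
            continue
        try:
            vals[i] = float(s)
        except ValueError:
            bad.append(i)
    if bad:
        raise LoadError(f"{Path(path).name}: unparseable {col} at data row(s) {bad[:10]}")
    return pd.Series(vals, index=df.index)


def read_mosaic(cells_path, region_path, strict: bool = True) -> CellMosaic:
    """Load a mosaic table and its region polygon.

    In strict mode (default) any point outside the region is an error naming
    the rows; with ``strict=False`` such rows are excluded with a warning (the
    exclusion count is reported, never silent).
    """
    import warnings

    region = read_region(region_path)
    df = _read_table(cells_path, ["cell_id", "x_mm", "y_mm"])
    x = _numeric(df, "x_mm", cells_path)
    y = _numeric(df, "y_mm", cells_path)
    points = np.column_stack([x.to_numpy(float), y.to_numpy(float)])
    inside = region.contains_points(points)
    if not inside.all():
        bad = np.flatnonzero(~inside).tolist()
        if strict:
            raise LoadError(
                f"{Path(cells_path).name}: {len(bad)} point(s) outside region "
                f"at data row(s) {bad[:10]}"
            )
        warnings.warn(f"excluded {len(bad)} out-of-region row(s): {bad[:10]}", stacklevel=2)
        df = df.loc[inside].reset_index(drop=True)
        points = points[inside]
    subtype = layer = None
    if "subtype" in df.columns and (df["subtype"] != "").any():
        subtype = df["subtype"].to_numpy(dtype=object)
    if "layer" in df.columns and (df["layer"] != "").any():
        layer = df["layer"].to_numpy(dtype=object)
    donor_id = None
    if "donor_id" in df.columns and (df["donor_id"] != "").any():
        donor_id = str(df["donor_id"].iloc[0])
    donor_age = None
    if "age_years" in df.columns and (df["age_years"] != "").any():
        donor_age = float(_numeric(df, "age_years", cells_path).iloc[0])
    try:
        return CellMosaic(points, region, subtype=subtype, layer=layer,
                          donor_id=donor_id, donor_age=donor_age,
                          cell_ids=df["cell_id"].to_numpy())
    except InvalidSpecError as exc:
        raise LoadError(f"{Path(cells_path).name}: {exc}") from exc


# ---------------------------------------------------------------------------
# SWC trees
# ---------------------------------------------------------------------------


def write_swc(tree: NeuriteTree, path) -> None:
    """Standard 7-column SWC; stratum is carried by the fixed z planes."""
    inv = {"soma": 1, "axon": 2, "dendrite": 3}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# id type x y z radius parent\n")
        fh.write(f"# coordinates um; dendritic strata: S1 z={S1_Z_UM}, S5 z={S5_Z_UM}\n")
        if tree.soma_area is not None:
            fh.write(f"# soma_area_um2 {float(tree.soma_area)!r}\n")
        for k in range(tree.n_nodes):
            fh.write(
                f"{tree.ids[k]} {inv[tree.compartment[k]]} "
                f"{float(tree.xyz[k, 0])!r} {float(tree.xyz[k, 1])!r} "
                f"{float(tree.xyz[k, 2])!r} {float(tree.radius[k])!r} {tree.parents[k]}\n"
            )


def write_swc_type_sidecar(path) -> None:
    """Write the type-code mapping table shipped next to SWC outputs."""
    rows = [
        (1, "soma"),
        (2, "axon"),
        (3, f"dendrite (stratum from z: S1 at z={S1_Z_UM}, S5 at z={S5_Z_UM})"),
        (4, "dendrite (alias)"),
    ]
    pd.DataFrame(rows, columns=["type_code", "meaning"]).to_csv(path, index=False)


def read_swc(
    path,
    soma_area: float | None = None,
    cell_id: str | None = None,
    subtype: str | None = None,
    donor_id: str | None = None,
    age_years: float | None = None,
    type_map: dict | None = None,
) -> NeuriteTree:
    """Parse a 7-column SWC file into a validated :class:`NeuriteTree`.

    ``#`` comments are allowed; cyclic, orphan or duplicate node ids raise
    :class:`LoadError` naming the node.  Dendritic stratum is inferred from
    the node z against the two fixed planes; ``type_map`` can override the
    default type-code meanings.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"file not found: {path}")
    codes = dict(SWC_TYPE_CODES if type_map is None else type_map)
    file_soma_area = None
    rows = []
    for ln, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            parts = s[1:].split()
            if len(parts) == 2 and parts[0] == "soma_area_um2":
                file_soma_area = float(parts[1])
            continue
        parts = s.split()
        if len(parts) != 7:
            raise LoadError(f"{path.name}:{ln}: expected 7 columns, got {len(parts)}")
        try:
            rows.append(
                (int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]),
                 float(parts[4]), float(parts[5]), int(parts[6]))
            )
        except ValueError as exc:
            raise LoadError(f"{path.name}:{ln}: {exc}") from exc
    if not rows:
        raise LoadError(f"{path.name}: no nodes")
    arr = np.array(rows, dtype=float)
    ids = arr[:, 0].astype(int)
    types = arr[:, 1].astype(int)
    parents = arr[:, 6].astype(int)
    unknown = sorted(set(types) - set(codes))
    if unknown:
        raise LoadError(f"{path.name}: unknown SWC type code(s) {unknown}")
    compartment = np.array([codes[t] for t in types], dtype=object)
    z = arr[:, 4]
    stratum = np.array(
        [
            (("S1" if abs(zz - S1_Z_UM) <= abs(zz - S5_Z_UM) else "S5")
             if comp == "dendrite" else None)
            for zz, comp in zip(z, compartment)
        ],
        dtype=object,
    )
    try:
        return NeuriteTree(
            ids=ids, parents=parents, xyz=arr[:, 2:5], radius=arr[:, 5],
            compartment=compartment, stratum=stratum,
            soma_area=soma_area if soma_area is not None else file_soma_area,
            cell_id=cell_id if cell_id is not None else path.stem,
            subtype=subtype, donor_id=donor_id, age_years=age_years,
        )
    except InvalidSpecError as exc:
        raise LoadError(f"{path.name}: {exc}") from exc


def read_cell_metadata(path) -> pd.DataFrame:
    """Sidecar table: cell_id, subtype, soma_area_um2, donor_id, age_years."""
    df = _read_table(path, ["cell_id", "subtype"])
    if "soma_area_um2" in df.columns:
        df["soma_area_um2"] = _numeric(df, "soma_area_um2", path)
    if "age_years" in df.columns:
        df["age_years"] = _numeric(df, "age_years", path)
    return df


# ---------------------------------------------------------------------------
# study tables and statistic outputs
# ---------------------------------------------------------------------------


def write_study_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidSpecError(f"study table missing column(s) {missing}")
    df[STUDY_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_study_table(path) -> pd.DataFrame:
    df = _read_table(path, STUDY_COLUMNS)
    df["age_years"] = _numeric(df, "age_years", path)
    df["value"] = _numeric(df, "value", path)
    df["n_cells"] = _numeric(df, "n_cells", path)
    return df


def write_mosaic_stats(results, path) -> None:
    """Per-mosaic (or per-subtype) statistics as a flat table.

    Columns: subtype, statistic, value, n, null_mean, null_lo95, null_hi95.
    """
    if isinstance(results, MosaicStatsResult):
        results = {"all": results}
    rows = []
    for key, res in results.items():
        stats_map = {
            "n": res.n, "density": res.density, "mean_nnd": res.nnd.mean,
            "sd_nnd": res.nnd.sd, "nnri": res.nnri, "di": res.di,
        }
        if res.vda is not None:
            stats_map.update(mean_vda=res.vda.mean, sd_vda=res.vda.sd, vdri=res.vdri)
        for fit, pref in ((res.fit_nnd, "nnd"), (res.fit_vda, "vda")):
            if fit is not None and not fit.failed and fit.r_squared is not None:
                stats_map[f"r2_{pref}_fit"] = fit.r_squared
        for name, value in stats_map.items():
            null = res.null
            have = null is not None and name in null.observed
            rows.append(
                dict(
                    subtype=key, statistic=name, value=value, n=res.n,
                    null_mean=null.null_mean[name] if have else "",
                    null_lo95=null.null_lo95[name] if have else "",
                    null_hi95=null.null_hi95[name] if have else "",
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def write_histogram(fit, path) -> None:
    """Histogram + fitted-count table: bin_lo, bin_hi, count, fit_count."""
    centers = 0.5 * (fit.bin_edges[:-1] + fit.bin_edges[1:])
    fit_counts = fit.predict(centers) if not fit.failed else np.full(len(centers), np.nan)
    pd.DataFrame(
        {"bin_lo": fit.bin_edges[:-1], "bin_hi": fit.bin_edges[1:],
         "count": fit.bin_counts, "fit_count": fit_counts}
    ).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# study configuration and provenance
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Every analysis and simulation option, with defaults; unknown keys reject."""

    seed: int = 0
    out_dir: str = "out"
    alpha: float = 0.05
    sholl_step: float = 10.0
    null_reps: int = 99
    border_buffer: float | bool = False
    bins: str | int = "fd"
    exclude_boundary_vda: bool = False
    ages: list = field(default_factory=lambda: list(DEFAULT_DONOR_AGES))
    region_width_mm: float = 10.0
    region_height_mm: float = 10.0
    baseline_density: dict = field(default_factory=lambda: dict(MEAN_DENSITY_MM2))
    density_drop_fraction: float = 0.44
    density_onset_age: float = 70.0
    density_ramp_end_age: float | None = None
    morpho_drop_fraction: float = 0.40
    morpho_onset_age: float = 50.0
    morpho_ramp_end_age: float | None = 80.0
    cells_per_subtype: int = 5
    dmin_fraction: float = 0.2
    dmin_sd_fraction: float = 0.04
    metrics: list = field(
        default_factory=lambda: [
            "density_cells_per_mm2", "dendritic_area", "branch_points",
            "terminal_tips", "sholl_area",
        ]
    )

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise LoadError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def scenario(self):
        from .synthetic import AgingScenario, DeclineCurve

        morpho = DeclineCurve(self.morpho_onset_age, self.morpho_drop_fraction,
                              self.morpho_ramp_end_age)
        return AgingScenario(
            ages=tuple(self.ages),
            region=RegionPolygon.rectangle(self.region_width_mm, self.region_height_mm),
            baseline_density=dict(self.baseline_density),
            density_decline=DeclineCurve(self.density_onset_age, self.density_drop_fraction,
                                         self.density_ramp_end_age),
            morpho_decline={"dendritic_area": morpho, "branch_points": morpho},
            dmin_fraction=self.dmin_fraction,
            dmin_sd_fraction=self.dmin_sd_fraction,
            cells_per_subtype=self.cells_per_subtype,
            seed=self.seed,
        )


def load_config(path) -> StudyConfig:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if not isinstance(data, dict):
        raise LoadError(f"{path.name}: config must be a mapping")
    return StudyConfig.from_dict(data)


def write_provenance(out_dir, config: dict, seed: int, extra: dict | None = None) -> Path:
    """Write the run-provenance log: config echo, seed, versions, timestamp."""
    import importlib.metadata

    import scipy
    import shapely
    import statsmodels

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "timestamp_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
        "versions": {
            "retmosaic": __version__, "numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "shapely": shapely.__version__,
            "statsmodels": statsmodels.__version__,
            "click": importlib.metadata.version("click"),
        },
        "config": config,
    }
    if extra:
        payload.update(extra)
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(payload, indent=2, default=str), encoding="utf-8")
    return path


def write_aging_dataset(dataset, out_dir) -> None:
    """Write mosaics, trees, the study table and ground truth under out_dir."""
    out = Path(out_dir)
    (out / "mosaics").mkdir(parents=True, exist_ok=True)
    write_region(dataset.scenario.region, out / "mosaics" / "region.csv")
    for donor_id, mosaic in dataset.mosaics.items():
        write_mosaic(mosaic, out / "mosaics" / f"{donor_id}_cells.csv")
    if dataset.trees:
        (out / "trees").mkdir(exist_ok=True)
        write_swc_type_sidecar(out / "trees" / "swc_type_codes.csv")
        meta_rows = []
        for (donor_id, st), cell_trees in dataset.trees.items():
            for t in cell_trees:
                write_swc(t, out / "trees" / f"{t.cell_id}.swc")
                meta_rows.append(
                    dict(cell_id=t.cell_id, subtype=st, soma_area_um2=t.soma_area,
                         donor_id=donor_id, age_years=t.age_years)
                )
        pd.DataFrame(meta_rows).to_csv(out / "trees" / "cells_meta.csv",
                                       index=False, float_format="%.10g")
    write_study_table(dataset.study_table, out / "study_table.csv")
    dataset.ground_truth.to_csv(out / "ground_truth.csv", index=False, float_format="%.10g")
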