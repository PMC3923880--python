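"""File formats: GeoJSON landscapes, ESRI ASCII grids, long-format CSVs.

Every CSV written here starts with a comment line carrying the config hash
and master seed so any report can be traced to the run that produced it;
readers skip '#' comment lines.  GeoJSON cannot carry comments, so the same
metadata sits in a top-level "metadata" member.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping, shape
from shapely.ops import unary_union

from .landscape import Landscape, OccurrenceSet, ScenarioStack

NODATA = -9999


def _header(meta: dict | None) -> str:
    meta = meta or {}
    parts = " ".join(f"{k}={v}" for k, v in sorted(meta.items()))
    return f"# streamvuln {parts}".rstrip() + "\n"


def write_csv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(meta))
        df.to_csv(fh, index=False, lineterminator="\n")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------- ESRI ASCII


def write_ascii_grid(path, values: np.ndarray, cell_size: float,
                     nodata: float = NODATA) -> None:
    """ESRI ASCII grid; our row 0 is the southern edge, the format's first
    data row is the northern edge, so rows are flipped on write."""
    n_rows, n_cols = values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {n_cols}\n")
        fh.write(f"nrows {n_rows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in values[::-1]:
            fh.write(" ".join(format(v, "g") for v in row) + "\n")


def read_ascii_grid(path):
    """Returns (values, cell_size, nodata_mask); NODATA cells hold NaN."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ESRI ASCII grid missing header field {key!r}")
    data = np.loadtxt(lines[i:], ndmin=2)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid body does not match declared nrows/ncols")
    data = data[::-1]  # back to south-up orientation
    nodata = header.get("nodata_value")
    mask = np.zeros(data.shape, dtype=bool)
    if nodata is not None:
        mask = data == nodata
        data = data.astype(float)
        data[mask] = np.nan
    return data, float(header["cellsize"]), mask


# ------------------------------------------------------------------- GeoJSON


def write_landscape(landscape: Landscape, outdir, meta: dict | None = None) -> None:
    """Write a landscape as GeoJSON subcatchment polygons plus three ESRI
    ASCII grids (elevation, water mask, subcatchment raster)."""
    os.makedirs(outdir, exist_ok=True)
    cs = landscape.cell_size
    write_ascii_grid(os.path.join(outdir, "elevation.asc"), landscape.elevation, cs)
    write_ascii_grid(
        os.path.join(outdir, "water.asc"), landscape.is_water.astype(float), cs
    )
    sub = landscape.sub_index.astype(float).copy()
    sub[landscape.sub_index < 0] = NODATA
    write_ascii_grid(os.path.join(outdir, "subcatchments.asc"), sub, cs)

    features = []
    for k, row in landscape.subcatchments.iterrows():
        rr, cc = np.nonzero(landscape.sub_index == k)
        cells = [box(c * cs, r * cs, (c + 1) * cs, (r + 1) * cs) for r, c in zip(rr, cc)]
        geom = unary_union(cells)
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {
                    "id": row["id"],
                    "centroid_x": row["centroid_x"],
                    "centroid_y": row["centroid_y"],
                    "mean_elev": row["mean_elev"],
                    "region": row["region"],
                    "code": row["code"],
                },
            }
        )
    fc = {
        "type": "FeatureCollection",
        "metadata": {
            "n_rows": landscape.n_rows,
            "n_cols": landscape.n_cols,
            "cell_size": landscape.cell_size,
            "bias_centers": [list(b) for b in landscape.bias_centers],
            **(meta or {}),
        },
        "features": features,
    }
    with open(os.path.join(outdir, "subcatchments.geojson"), "w") as fh:
        json.dump(fc, fh)


def read_landscape(outdir) -> Landscape:
    elev, cs, _ = read_ascii_grid(os.path.join(outdir, "elevation.asc"))
    water, _, _ = read_ascii_grid(os.path.join(outdir, "water.asc"))
    sub, _, sub_mask = read_ascii_grid(os.path.join(outdir, "subcatchments.asc"))
    with open(os.path.join(outdir, "subcatchments.geojson")) as fh:
        fc = json.load(fh)
    rows = [f["properties"] for f in fc["features"]]
    table = pd.DataFrame(rows)
    # geometry round-trip sanity: every feature parses as a valid polygon
    for f in fc["features"]:
        shape(f["geometry"])
    sub_index = np.where(sub_mask | np.isnan(sub), -1, np.nan_to_num(sub, nan=-1))
    ls = Landscape(
        n_rows=elev.shape[0],
        n_cols=elev.shape[1],
        cell_size=cs,
        elevation=np.nan_to_num(elev),
        is_water=water.astype(bool),
        sub_index=sub_index.astype(int),
        subcatchments=table,
        bias_centers=[tuple(b) for b in fc["metadata"].get("bias_centers", [])],
    )
    ls.validate()
    return ls


# ----------------------------------------------------------------- scenarios


def write_scenarios(stacks: list, path, meta: dict | None = None) -> None:
    frames = []
    for s in stacks:
        long = s.factors.reset_index().melt(
            id_vars="subcatchment", var_name="factor", value_name="value"
        )
        long.insert(0, "scenario", s.scenario)
        frames.append(long)
    write_csv(pd.concat(frames, ignore_index=True), path, meta)


def read_scenarios(path) -> list:
    df = read_csv(path)
    stacks = []
    for name, grp in df.groupby("scenario", sort=False):
        wide = grp.pivot(index="subcatchment", columns="factor", values="value")
        wide.index.name = "subcatchment"
        stacks.append(ScenarioStack(name, wide))
    return stacks


# --------------------------------------------------------------- occurrences


def write_occurrences(occ_sets: list, path, meta: dict | None = None) -> None:
    frames = []
    for occ in occ_sets:
        df = occ.records.copy()
        df.insert(0, "species", occ.species)
        frames.append(df)
    cols = ["species", "x", "y", "subcatchment", "year", "stage", "sex"]
    out = pd.concat(frames, ignore_index=True)[cols] if frames else pd.DataFrame(
        columns=cols
    )
    write_csv(out, path, meta)


def read_occurrences(path, landscape: Landscape | None = None) -> list:
    """Read occurrence records grouped by species; with a landscape given,
    every record is validated (on land, subcatchment matches coordinates)
    and violations raise with the offending row number."""
    df = read_csv(path)
    required = {"species", "x", "y", "subcatchment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"occurrence file missing columns: {sorted(missing)}")
    out = []
    for sp, grp in df.groupby("species", sort=True):
        recs = grp.drop(columns="species").reset_index(drop=True)
        occ = OccurrenceSet(str(sp), recs)
        if landscape is not None:
            try:
                occ.validate(landscape)
            except ValueError as err:
                raise ValueError(f"species {sp}: {err}") from err
        out.append(occ)
    return out


# ------------------------------------------------------------------ surfaces


def write_surfaces(surfaces: list, path, meta: dict | None = None) -> None:
    frames = []
    for s in surfaces:
        df = s.values.rename("suitability").reset_index()
        df.insert(0, "scenario", s.scenario)
        df.insert(0, "species", s.species)
        df["tss_threshold"] = s.tss_threshold
        frames.append(df)
    write_csv(pd.concat(frames, ignore_index=True), path, meta)
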