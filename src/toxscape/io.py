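"""Readers, writers and run configuration.

CSV is the canonical exchange format (comma-separated, UTF-8, header row,
"." decimal).  Regions may alternatively arrive as GeoJSON with equivalent
feature properties; weights serialize as GAL; fits and manifests as JSON.
Coordinates are planar miles unless the columns are named ``lon``/``lat``,
which switches the distance engine to great-circle distances.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .containers import DecaySpec, Region, ReleaseSite
from .synthetic import ScenarioConfig, SyntheticScenario

log = logging.getLogger("toxscape")

__all__ = [
    "read_regions",
    "read_regions_ex",
    "read_sites",
    "regions_frame",
    "sites_frame",
    "covariate_matrix",
    "write_regions",
    "write_sites",
    "write_scenario",
    "RunConfig",
]

_REGION_REQUIRED = ("id", "rural_urban_code", "outcome")
_REGION_SPECIAL = {"id", "x", "y", "lon", "lat", "rural_urban_code", "outcome", "external_risk"}
_SITE_REQUIRED = ("id", "region_id", "volume")


def _coord_columns(columns) -> Tuple[str, str, str]:
    """(x-col, y-col, coordinate system) from the available column names."""
    cols = set(columns)
    if {"x", "y"} <= cols:
        return "x", "y", "planar"
    if {"lon", "lat"} <= cols:
        return "lon", "lat", "lonlat"
    raise ValueError("regions/sites need coordinate columns 'x','y' or 'lon','lat'")


def _frame_to_regions(df: pd.DataFrame) -> Tuple[List[Region], str]:
    for col in _REGION_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"missing required region column {col!r}")
    xc, yc, coords = _coord_columns(df.columns)
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate region id(s): {dupes[:5]}")
    cov_cols = [c for c in df.columns if c not in _REGION_SPECIAL]
    n_before = len(df)
    df = df.dropna(subset=list(_REGION_REQUIRED) + [xc, yc] + cov_cols)
    dropped = n_before - len(df)
    if dropped:
        log.warning("dropped %d region row(s) with missing values", dropped)
    regions = []
    for row in df.to_dict("records"):  # preserves per-column dtypes
        ext = row.get("external_risk")
        regions.append(
            Region(
                id=row["id"],
                x=float(row[xc]),
                y=float(row[yc]),
                rural_urban_code=int(row["rural_urban_code"]),
                outcome=float(row["outcome"]),
                covariates={c: float(row[c]) for c in cov_cols},
                external_risk=None if ext is None or pd.isna(ext) else float(ext),
            )
        )
    return regions, coords


def _read_geojson_regions(path: Path) -> pd.DataFrame:
    from shapely.geometry import shape

    with open(path, "r", encoding="utf-8") as fh:
        gj = json.load(fh)
    rows = []
    for feat in gj.get("features", []):
        props = dict(feat.get("properties", {}))
        if ("x" not in props or "y" not in props) and feat.get("geometry"):
            c = shape(feat["geometry"]).centroid
            props.setdefault("x", c.x)
            props.setdefault("y", c.y)
        rows.append(props)
    return pd.DataFrame(rows)


def read_regions_ex(path) -> Tuple[List[Region], str]:
    """Read regions plus the detected coordinate system."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        df = _read_geojson_regions(path)
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    return _frame_to_regions(df)


def read_regions(path) -> List[Region]:
    """Read a validated region list from CSV or GeoJSON.

    Required columns: id, x/y (or lon/lat), rural_urban_code, outcome.
    Unknown columns are preserved as covariates; row order is preserved.
    """
    return read_regions_ex(path)[0]


def read_sites(path) -> List[ReleaseSite]:
    """Read a validated release-site list from CSV.

    Required columns: id, x/y (or lon/lat), region_id, volume; optional
    chemical_class.  Nonpositive volumes raise with the offending row
    number (1-based, excluding the header).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _SITE_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"missing required site column {col!r}")
    xc, yc, _ = _coord_columns(df.columns)
    sites = []
    for idx, row in enumerate(df.to_dict("records")):
        if not (float(row["volume"]) > 0):
            raise ValueError(f"row {idx + 1}: volume must be positive, got {row['volume']}")
        sites.append(
            ReleaseSite(
                id=row["id"],
                x=float(row[xc]),
                y=float(row[yc]),
                region_id=row["region_id"],
                volume=float(row["volume"]),
                chemical_class=str(row.get("chemical_class", "all_carcinogen")),
            )
        )
    return sites


def regions_frame(regions: Sequence[Region]) -> pd.DataFrame:
    """Regions as a tidy DataFrame (id, coordinates, code, outcome, covariates)."""
    cov_names = list(regions[0].covariates) if regions else []
    rows = []
    for r in regions:
        row = {
            "id": r.id,
            "x": r.x,
            "y": r.y,
            "rural_urban_code": r.rural_urban_code,
            "outcome": r.outcome,
        }
        row.update({c: r.covariates.get(c, np.nan) for c in cov_names})
        if r.external_risk is not None:
            row["external_risk"] = r.external_risk
        rows.append(row)
    return pd.DataFrame(rows)


def sites_frame(sites: Sequence[ReleaseSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [s.id for s in sites],
            "x": [s.x for s in sites],
            "y": [s.y for s in sites],
            "region_id": [s.region_id for s in sites],
            "volume": [s.volume for s in sites],
            "chemical_class": [s.chemical_class for s in sites],
        }
    )


def covariate_matrix(
    regions: Sequence[Region], names: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Covariate design matrix (no intercept) in region order."""
    if names is None:
        names = list(regions[0].covariates)
    data = {nm: [r.covariates[nm] for r in regions] for nm in names}
    return pd.DataFrame(data)


def write_regions(regions: Sequence[Region], path) -> None:
    # %.17g keeps float round-trips lossless
    regions_frame(regions).to_csv(path, index=False, float_format="%.17g")


def write_sites(sites: Sequence[ReleaseSite], path) -> None:
    sites_frame(sites).to_csv(path, index=False, float_format="%.17g")


def _decay_to_dict(spec: DecaySpec) -> dict:
    return dataclasses.asdict(spec)


def write_scenario(scenario: SyntheticScenario, outdir, geojson: bool = False) -> None:
    """Write regions.csv, sites.csv, truth.json and config.json (optionally
    regions.geojson with the unit-square cell polygons)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_regions(scenario.regions, outdir / "regions.csv")
    write_sites(scenario.sites, outdir / "sites.csv")
    truth = dict(scenario.truth)
    truth["true_decay"] = _decay_to_dict(truth["true_decay"])
    truth["exposure"] = np.asarray(truth["exposure"]).tolist()
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
    cfg = dataclasses.asdict(scenario.config)
    with open(outdir / "config.json", "w", encoding="utf-8") as fh:
        json.dump(cfg, fh, indent=1)
    if geojson:
        half = scenario.config.cell_size / 2.0
        feats = []
        for r in scenario.regions:
            ring = [
                [r.x - half, r.y - half],
                [r.x + half, r.y - half],
                [r.x + half, r.y + half],
                [r.x - half, r.y + half],
                [r.x - half, r.y - half],
            ]
            props = {
                "id": r.id,
                "x": r.x,
                "y": r.y,
                "rural_urban_code": r.rural_urban_code,
                "outcome": r.outcome,
            }
            props.update(dict(r.covariates))
            feats.append(
                {
                    "type": "Feature",
                    "properties": props,
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                }
            )
        with open(outdir / "regions.geojson", "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


@dataclasses.dataclass
class RunConfig:
    """Configuration for one end-to-end experiment run.

    Exactly one of (``regions_path``+``sites_path``, ``scenario``) must be
    present.  ``weights_mode`` selects the spatial weights used for the lag
    and error regressions: ``distance_band`` (threshold defaults to the
    minimum connecting distance) or ``queen`` (lattice side inferred for
    synthetic scenarios).
    """

    scenario: Optional[ScenarioConfig] = None
    regions_path: Optional[str] = None
    sites_path: Optional[str] = None
    coords: str = "planar"
    grid: Optional[dict] = None
    weights_mode: str = "distance_band"
    weights_threshold: Optional[float] = None
    prune_alpha: Optional[float] = None
    outdir: str = "toxscape_run"
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        has_paths = self.regions_path is not None and self.sites_path is not None
        has_scenario = self.scenario is not None
        if has_paths == has_scenario:
            raise ValueError("exactly one of (regions_path+sites_path, scenario) required")
        if self.weights_mode not in ("distance_band", "queen"):
            raise ValueError("weights_mode must be distance_band or queen")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        scen = d.get("scenario")
        if scen is not None:
            if "true_decay" in scen and isinstance(scen["true_decay"], dict):
                scen = dict(scen)
                scen["true_decay"] = DecaySpec(**scen["true_decay"])
            if "covariate_effects" in scen:
                scen["covariate_effects"] = tuple(scen["covariate_effects"])
            if "chemical_class_probs" in scen:
                scen["chemical_class_probs"] = tuple(scen["chemical_class_probs"])
            d["scenario"] = ScenarioConfig(**scen)
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
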