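"""Raster and vector I/O for co-registered crown imagery.

Rasters are 3-band, 8-bit GeoTIFFs sharing one grid and geotransform
(co-registration is a hard contract, not a best effort: every survey of a
study was orthorectified onto the same master grid, and this module refuses
mismatching layers rather than resampling them).  Crown polygons travel as
GeoJSON with ``crown_id`` and ``species`` attributes, in the raster's metric
CRS.

Rasterization follows the pixel-center rule: a pixel belongs to a polygon
iff its center lies strictly inside.  Pixel (0, 0) is the top-left pixel;
coordinates are 0-based (row, col); x grows with columns, y shrinks with
rows.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
import tifffile
import yaml
from shapely.geometry import mapping as geom_mapping, shape as geom_shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735

CAMERAS = ("RGB", "CIR")
SEASONS = ("spring", "summer", "autumn")


class GeodataError(Exception):
    """Base class for raster/vector contract violations."""


class BandCountError(GeodataError):
    """Raster does not have exactly 3 bands."""


class CoRegistrationError(GeodataError):
    """Layer grid or geotransform differs from the study's reference grid."""


class GeoreferenceError(GeodataError):
    """GeoTIFF lacks the georeferencing tags this pipeline requires."""


class CrownValidationError(GeodataError):
    """Crown vector data violates its contract."""


@dataclass(frozen=True)
class GridTransform:
    """North-up affine geotransform: top-left corner and square pixel size."""

    x_origin: float
    y_origin: float
    gsd: float

    def pixel_center(self, row: np.ndarray, col: np.ndarray):
        x = self.x_origin + (np.asarray(col) + 0.5) * self.gsd
        y = self.y_origin - (np.asarray(row) + 0.5) * self.gsd
        return x, y

    def world_to_pixel(self, x: float, y: float):
        """Fractional (row, col) of a map coordinate."""
        return (self.y_origin - y) / self.gsd, (x - self.x_origin) / self.gsd

    def close_to(self, other: "GridTransform", tol: float = 1e-6) -> bool:
        return (
            abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.gsd - other.gsd) <= tol
        )


@dataclass
class SurveyLayer:
    """One camera's co-registered 3-band raster for one survey date.

    ``bands`` is a ``(3, rows, cols)`` uint8 array.  ``gdd`` (growing degree
    days) is carried as metadata only and never enters any computation.
    """

    survey_id: str
    date: _dt.date
    season: str
    gdd: float
    camera: str
    bands: np.ndarray
    transform: GridTransform
    nodata: int | None = None

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands)
        if self.bands.ndim != 3 or self.bands.shape[0] != 3:
            raise BandCountError(
                f"survey {self.survey_id!r} ({self.camera}): expected 3 bands, "
                f"got array of shape {self.bands.shape}"
            )
        if self.transform.gsd <= 0:
            raise GeodataError(f"gsd must be positive, got {self.transform.gsd}")
        if self.camera not in CAMERAS:
            raise GeodataError(f"camera must be one of {CAMERAS}, got {self.camera!r}")

    @property
    def gsd(self) -> float:
        return self.transform.gsd

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1], self.bands.shape[2]

    @property
    def key(self) -> str:
        return f"{self.survey_id}.{self.camera}"


@dataclass
class CrownRecord:
    """A delineated tree crown: identifier, species label, polygon geometry."""

    crown_id: str
    species: str
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            raise CrownValidationError(
                f"crown {self.crown_id!r}: invalid (self-intersecting?) geometry"
            )
        if self.geometry.area <= 0:
            raise CrownValidationError(f"crown {self.crown_id!r}: zero-area geometry")


@dataclass
class SurveyMeta:
    """Manifest row describing one flight (survey_id, date, season, gdd, camera, path)."""

    survey_id: str
    date: _dt.date
    season: str
    gdd: float
    camera: str
    path: str = ""


# ---------------------------------------------------------------------------
# raster I/O


def _geokey_directory() -> tuple[int, ...]:
    # Minimal GeoTIFF key set: projected model, PixelIsArea, linear unit metre.
    return (
        1, 1, 0, 3,
        1024, 0, 1, 1,      # GTModelTypeGeoKey = Projected
        1025, 0, 1, 1,      # GTRasterTypeGeoKey = PixelIsArea
        3076, 0, 1, 9001,   # ProjLinearUnitsGeoKey = metre
    )


def write_survey(layer: SurveyLayer, path: str | Path) -> Path:
    """Write a SurveyLayer as a georeferenced 3-band 8-bit GeoTIFF."""
    path = Path(path)
    data = np.moveaxis(layer.bands.astype(np.uint8), 0, -1)
    t = layer.transform
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (t.gsd, t.gsd, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x_origin, t.y_origin, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", 16, _geokey_directory()),
    ]
    tifffile.imwrite(path, data, photometric="rgb", extratags=extratags)
    return path


def read_survey(
    path: str | Path,
    metadata: SurveyMeta | Mapping,
    reference: SurveyLayer | None = None,
) -> SurveyLayer:
    """Read one 3-band GeoTIFF into a SurveyLayer.

    ``metadata`` supplies the survey descriptor (id, date, season, gdd,
    camera).  If ``reference`` is given, the new layer must match its grid
    and geotransform exactly (co-registration contract) or a
    CoRegistrationError is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"survey raster not found: {path}")
    if isinstance(metadata, Mapping):
        md = dict(metadata)
        md.pop("path", None)
        metadata = SurveyMeta(path=str(path), **md)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        if arr.ndim != 3 or arr.shape[-1] != 3:
            raise BandCountError(
                f"{path}: expected a 3-band raster, got shape {arr.shape}"
            )
        try:
            scale = page.tags[_MODEL_PIXEL_SCALE].value
            tiepoint = page.tags[_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise GeoreferenceError(
                f"{path}: missing ModelPixelScale/ModelTiepoint GeoTIFF tags"
            ) from exc
    transform = GridTransform(
        x_origin=float(tiepoint[3]), y_origin=float(tiepoint[4]), gsd=float(scale[0])
    )
    layer = SurveyLayer(
        survey_id=metadata.survey_id,
        date=metadata.date,
        season=metadata.season,
        gdd=metadata.gdd,
        camera=metadata.camera,
        bands=np.moveaxis(arr, -1, 0),
        transform=transform,
    )
    if reference is not None:
        if layer.shape != reference.shape or not transform.close_to(reference.transform):
            raise CoRegistrationError(
                f"{path}: grid {layer.shape}/{transform} does not match reference "
                f"{reference.shape}/{reference.transform}; surveys must be co-registered"
            )
    return layer


# ---------------------------------------------------------------------------
# crown vector I/O


def write_crowns(crowns: Sequence[CrownRecord], path: str | Path) -> Path:
    """Write crowns as a GeoJSON FeatureCollection with crown_id/species."""
    path = Path(path)
    features = [
        {
            "type": "Feature",
            "properties": {"crown_id": c.crown_id, "species": c.species},
            "geometry": geom_mapping(c.geometry),
        }
        for c in crowns
    ]
    payload = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(payload, sort_keys=True))
    return path


def read_crowns(path: str | Path, species_set: Iterable[str]) -> list[CrownRecord]:
    """Read and validate crown polygons from GeoJSON.

    Every feature must carry unique ``crown_id`` and a ``species`` drawn
    from ``species_set``; geometries must be valid polygons with positive
    area.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"crown file not found: {path}")
    species_set = set(species_set)
    payload = json.loads(path.read_text())
    crowns: list[CrownRecord] = []
    seen: set[str] = set()
    unknown: list[tuple[str, str]] = []
    for feat in payload.get("features", []):
        props = feat.get("properties") or {}
        if "crown_id" not in props or "species" not in props:
            raise CrownValidationError(
                f"{path}: feature missing crown_id/species properties"
            )
        cid = str(props["crown_id"])
        species = str(props["species"])
        if cid in seen:
            raise CrownValidationError(f"{path}: duplicated crown_id {cid!r}")
        seen.add(cid)
        if species not in species_set:
            unknown.append((cid, species))
            continue
        geom = geom_shape(feat["geometry"])
        try:
            crowns.append(CrownRecord(crown_id=cid, species=species, geometry=geom))
        except CrownValidationError as exc:
            raise CrownValidationError(f"{path}: {exc}") from exc
    if unknown:
        offenders = ", ".join(f"{cid}={sp!r}" for cid, sp in unknown)
        raise CrownValidationError(
            f"{path}: unknown species labels (expected one of "
            f"{sorted(species_set)}): {offenders}"
        )
    return crowns


# ---------------------------------------------------------------------------
# geometry -> pixels


def narrow_crown(
    crown: CrownRecord | BaseGeometry, distance: float = 0.50
) -> BaseGeometry:
    """Shrink a crown polygon inward by ``distance`` metres (negative buffer).

    Removes the mixed border pixels at the crown edge.  An empty result is a
    valid outcome meaning the crown is too small and must be dropped
    downstream.
    """
    if distance < 0:
        raise ValueError(f"buffer distance must be >= 0, got {distance}")
    geom = crown.geometry if isinstance(crown, CrownRecord) else crown
    if distance == 0:
        return geom
    return geom.buffer(-distance)


def pixels_in_polygon(
    polygon: BaseGeometry, transform: GridTransform, shape: tuple[int, int]
) -> np.ndarray:
    """(n, 2) int array of (row, col) pixels whose center lies inside ``polygon``.

    Rows are returned in row-major order.  A polygon entirely off the raster
    yields an empty array (logged, not an error).
    """
    empty = np.empty((0, 2), dtype=np.int64)
    if polygon.is_empty:
        return empty
    rows, cols = shape
    minx, miny, maxx, maxy = polygon.bounds
    r0f, c0f = transform.world_to_pixel(minx, maxy)
    r1f, c1f = transform.world_to_pixel(maxx, miny)
    r0 = max(int(np.floor(r0f)), 0)
    c0 = max(int(np.floor(c0f)), 0)
    r1 = min(int(np.ceil(r1f)), rows - 1)
    c1 = min(int(np.ceil(c1f)), cols - 1)
    if r0 > r1 or c0 > c1:
        logger.info("polygon %s entirely outside raster", polygon.bounds)
        return empty
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    x, y = transform.pixel_center(rr.ravel(), cc.ravel())
    inside = shapely.contains_xy(polygon, x, y)
    if not inside.any():
        logger.info("polygon %s covers no pixel center", polygon.bounds)
        return empty
    return np.column_stack([rr.ravel()[inside], cc.ravel()[inside]])


def crown_pixel_mask(polygon: BaseGeometry, layer: SurveyLayer) -> np.ndarray:
    """Pixel (row, col) mask of ``polygon`` on ``layer``'s grid (center-in rule)."""
    return pixels_in_polygon(polygon, layer.transform, layer.shape)


# ---------------------------------------------------------------------------
# manifests


def write_manifest(
    metas: Sequence[SurveyMeta],
    path: str | Path,
    *,
    crowns_path: str = "crowns.geojson",
    extra: Mapping | None = None,
) -> Path:
    path = Path(path)
    doc = {
        "crowns": crowns_path,
        "surveys": [
            {
                "survey_id": m.survey_id,
                "date": m.date.isoformat(),
                "season": m.season,
                "gdd": m.gdd,
                "camera": m.camera,
                "path": m.path,
            }
            for m in metas
        ],
    }
    if extra:
        doc.update(dict(extra))
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def load_manifest(path: str | Path) -> tuple[list[SurveyMeta], dict]:
    """Return survey descriptors plus any extra manifest keys (preset, seed, ...)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    doc = yaml.safe_load(path.read_text())
    metas = []
    for row in doc.get("surveys", []):
        date = row["date"]
        if isinstance(date, str):
            date = _dt.date.fromisoformat(date)
        metas.append(
            SurveyMeta(
                survey_id=str(row["survey_id"]),
                date=date,
                season=str(row["season"]),
                gdd=float(row.get("gdd", float("nan"))),
                camera=str(row["camera"]),
                path=str(row.get("path", "")),
            )
        )
    extra = {k: v for k, v in doc.items() if k != "surveys"}
    return metas, extra


def read_surveys_from_manifest(path: str | Path) -> list[SurveyLayer]:
    """Load every layer listed in a manifest, enforcing co-registration."""
    path = Path(path)
    metas, _ = load_manifest(path)
    layers: list[SurveyLayer] = []
    reference = None
    for meta in metas:
        raster_path = Path(meta.path)
        if not raster_path.is_absolute():
            raster_path = path.parent / raster_path
        layer = read_survey(raster_path, meta, reference=reference)
        if reference is None:
            reference = layer
        layers.append(layer)
    return layers
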