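"""Crown-level metric extraction: shadow masking, spectral statistics, GLCM texture.

Each (crown, survey, camera) triple yields one metric vector computed on the
crown's *sunlit* pixels only.  Sunlit means: the crown polygon is first
narrowed by a negative buffer (default 0.50 m) to discard mixed border
pixels, then pixels whose mosaic-wide relative intensity falls strictly
below a threshold (default 20 on a 0-100 scale) are discarded as shadow.

Spectral metrics per camera: per-band mean and SD (population form), the
three unordered band-ratio pairs, normalized bands (band mean over the
3-band sum), and three normalized-difference indices — NGRVI, NGBI, NRBI on
the RGB camera (band order B, G, R) and NDVI, GNDVI, NGRVI on the CIR
camera (band order NIR, R, G).

Texture metrics are the seven gray-level co-occurrence matrix statistics
(variance, homogeneity, contrast, dissimilarity, entropy, second moment,
correlation) per band, from an object-level GLCM: pixel values quantized to
equal-width bins over the fixed [0, 255] scale, co-occurrences counted only
for pixel pairs where both pixels belong to the crown mask, symmetrized and
pooled over the offset set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geodata import CoRegistrationError, CrownRecord, SurveyLayer, narrow_crown, pixels_in_polygon

logger = logging.getLogger(__name__)

DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))

GLCM_NAMES = (
    "variance",
    "homogeneity",
    "contrast",
    "dissimilarity",
    "entropy",
    "second_moment",
    "correlation",
)

#: index names by camera; bands are 1-based positions in the layer
INDEX_NAMES = {"RGB": ("ngrvi", "ngbi", "nrbi"), "CIR": ("ndvi", "gndvi", "ngrvi")}


@dataclass
class MetricConfig:
    """Extraction parameters; defaults follow the field protocol this encodes."""

    buffer_m: float = 0.50
    shadow_threshold: float = 20.0
    min_sunlit: int = 10
    glcm_levels: int = 32
    glcm_offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS

    def __post_init__(self) -> None:
        if not 0 <= self.shadow_threshold <= 100:
            raise ValueError("shadow_threshold must lie in [0, 100]")
        if self.glcm_levels < 2:
            raise ValueError("glcm_levels must be >= 2")
        if self.min_sunlit < 1:
            raise ValueError("min_sunlit must be >= 1")


def relative_intensity(layer: SurveyLayer) -> np.ndarray:
    """Mosaic-wide relative intensity in [0, 100] (NaN at nodata pixels).

    Intensity is the sum of the three band values; it is min-max normalized
    over all valid pixels of the mosaic.  A constant-intensity mosaic maps
    to 100 everywhere by convention (nothing classed as shadow).
    """
    intensity = layer.bands.astype(np.int64).sum(axis=0).astype(float)
    if layer.nodata is not None:
        valid = ~(layer.bands == layer.nodata).any(axis=0)
    else:
        valid = np.ones(intensity.shape, dtype=bool)
    if not valid.any():
        raise ValueError(f"layer {layer.key}: all pixels are nodata")
    imin = intensity[valid].min()
    imax = intensity[valid].max()
    if imax == imin:
        ri = np.full(intensity.shape, 100.0)
    else:
        ri = 100.0 * (intensity - imin) / (imax - imin)
    ri[~valid] = np.nan
    return ri


def sunlit_mask(
    mask: np.ndarray, ri: np.ndarray, threshold: float = 20.0
) -> np.ndarray:
    """Keep the pixels of ``mask`` whose relative intensity is >= ``threshold``.

    Pixels strictly below the threshold are discarded as shadow; a pixel
    sitting exactly at the threshold is kept.
    """
    if not 0 <= threshold <= 100:
        raise ValueError("threshold must lie in [0, 100]")
    if len(mask) == 0:
        return mask
    vals = ri[mask[:, 0], mask[:, 1]]
    keep = vals >= threshold  # NaN compares False -> nodata discarded too
    return mask[keep]


def _nd(x: float, y: float) -> float:
    denom = x + y
    if denom == 0:
        logger.info("normalized-difference denominator is zero; index set to 0")
        return 0.0
    return (x - y) / denom


def spectral_metrics(values: np.ndarray, camera: str) -> dict[str, float]:
    """Spectral statistics of an (n, 3) array of sunlit pixel band triples.

    Means/SDs use the population (n-divisor) form; band ratios cover the
    three unordered pairs; indices are computed on the per-crown band means.
    Zero denominators map to 0 by convention (logged).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != 3 or values.shape[0] == 0:
        raise ValueError(f"expected a non-empty (n, 3) array, got {values.shape}")
    if camera not in INDEX_NAMES:
        raise ValueError(f"camera must be one of {sorted(INDEX_NAMES)}, got {camera!r}")
    m = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    out: dict[str, float] = {}
    for b in range(3):
        out[f"mean_{b + 1}"] = float(m[b])
        out[f"sd_{b + 1}"] = float(sd[b])
    for i, j in ((0, 1), (0, 2), (1, 2)):
        if m[j] == 0:
            logger.info("band ratio %d/%d has zero denominator; set to 0", i + 1, j + 1)
            out[f"ratio_{i + 1}{j + 1}"] = 0.0
        else:
            out[f"ratio_{i + 1}{j + 1}"] = float(m[i] / m[j])
    total = m.sum()
    for b in range(3):
        out[f"norm_{b + 1}"] = float(m[b] / total) if total > 0 else 0.0
    if camera == "RGB":  # bands 1,2,3 = B,G,R
        out["ngrvi"] = _nd(m[1], m[2])
        out["ngbi"] = _nd(m[1], m[0])
        out["nrbi"] = _nd(m[2], m[0])
    else:  # CIR bands 1,2,3 = NIR,R,G
        out["ndvi"] = _nd(m[0], m[1])
        out["gndvi"] = _nd(m[0], m[2])
        out["ngrvi"] = _nd(m[2], m[1])
    out["n_sunlit"] = float(values.shape[0])
    return out


def glcm_metrics(
    band: np.ndarray,
    mask: np.ndarray,
    levels: int = 32,
    offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS,
) -> dict[str, float] | None:
    """Seven Haralick-style statistics of the object-level GLCM of one band.

    Values are quantized to ``levels`` equal-width bins over [0, 255];
    co-occurrences are counted for every offset pair whose two pixels both
    lie in ``mask``, symmetrized, pooled over offsets and normalized.
    Returns None (logged) when no valid pixel pair exists.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    if len(mask) == 0:
        logger.info("glcm: empty mask")
        return None
    band = np.asarray(band, dtype=float)
    bin_width = 256.0 / levels
    quant = np.clip(np.floor(band / bin_width).astype(np.int64), 0, levels - 1)

    r0, c0 = mask.min(axis=0)
    r1, c1 = mask.max(axis=0)
    # local window padded by the largest offset reach
    pad = max(max(abs(dr), abs(dc)) for dr, dc in offsets)
    r0 = max(r0 - pad, 0)
    c0 = max(c0 - pad, 0)
    q = quant[r0 : r1 + pad + 1, c0 : c1 + pad + 1]
    in_mask = np.zeros(q.shape, dtype=bool)
    in_mask[mask[:, 0] - r0, mask[:, 1] - c0] = True

    counts = np.zeros((levels, levels), dtype=np.int64)
    h, w = q.shape
    for dr, dc in offsets:
        rs = slice(max(0, -dr), min(h, h - dr))
        cs = slice(max(0, -dc), min(w, w - dc))
        rd = slice(max(0, dr), min(h, h + dr))
        cd = slice(max(0, dc), min(w, w + dc))
        both = in_mask[rs, cs] & in_mask[rd, cd]
        if not both.any():
            continue
        a = q[rs, cs][both]
        b = q[rd, cd][both]
        np.add.at(counts, (a, b), 1)
        np.add.at(counts, (b, a), 1)
    total = counts.sum()
    if total == 0:
        logger.info("glcm: no co-occurring pixel pair in mask")
        return None
    p = counts / total
    i_idx, j_idx = np.indices((levels, levels))
    p_i = p.sum(axis=1)
    grades = np.arange(levels)
    mu = float((grades * p_i).sum())
    var = float(((grades - mu) ** 2 * p_i).sum())
    nz = p[p > 0]
    corr = (
        float((p * (i_idx - mu) * (j_idx - mu)).sum() / var) if var > 0 else 0.0
    )
    return {
        "variance": float((p * (i_idx - mu) ** 2).sum()),
        "homogeneity": float((p / (1.0 + (i_idx - j_idx) ** 2)).sum()),
        "contrast": float((p * (i_idx - j_idx) ** 2).sum()),
        "dissimilarity": float((p * np.abs(i_idx - j_idx)).sum()),
        "entropy": float(-(nz * np.log(nz)).sum()),
        "second_moment": float((p ** 2).sum()),
        "correlation": corr,
    }


@dataclass
class FeatureTable:
    """Crowns x metrics matrix with species labels and a dropped-crown log.

    ``data`` is a DataFrame indexed by crown_id with a ``species`` column and
    metric columns namespaced ``<survey_id>.<camera>.<metric>``.
    """

    data: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> Path:
        """Write the table as CSV plus a JSON sidecar (namespaces + drop log)."""
        path = Path(path)
        self.data.to_csv(path, index_label="crown_id")
        namespaces: dict[str, dict[str, list[str]]] = {}
        for col in self.data.columns:
            if col == "species":
                continue
            survey, camera, metric = col.split(".", 2)
            namespaces.setdefault(survey, {}).setdefault(camera, []).append(metric)
        sidecar = {
            "namespaces": namespaces,
            "dropped": [{"crown_id": cid, "reason": why} for cid, why in self.dropped],
            "species": sorted(self.data["species"].unique().tolist()),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        data = pd.read_csv(path, index_col="crown_id")
        dropped = []
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            doc = json.loads(sidecar.read_text())
            dropped = [(d["crown_id"], d["reason"]) for d in doc.get("dropped", [])]
        return cls(data=data, dropped=dropped)


def feature_columns(
    data: pd.DataFrame,
    surveys: Iterable[str] | None = None,
    cameras: Iterable[str] | None = None,
) -> list[str]:
    """Classifier feature columns, optionally restricted by survey/camera.

    The ``species`` label and the per-layer ``n_sunlit`` pixel counts are
    never features.
    """
    surveys = set(surveys) if surveys is not None else None
    cameras = set(cameras) if cameras is not None else None
    cols = []
    for col in data.columns:
        if col == "species" or "." not in col:
            continue
        survey, camera, metric = col.split(".", 2)
        if metric == "n_sunlit":
            continue
        if surveys is not None and survey not in surveys:
            continue
        if cameras is not None and camera not in cameras:
            continue
        cols.append(col)
    return sorted(cols)


def build_feature_table(
    surveys: Sequence[SurveyLayer],
    crowns: Sequence[CrownRecord],
    config: MetricConfig | None = None,
) -> FeatureTable:
    """Extract the full metric vector of every crown over every layer.

    A crown contributes a row only if it is usable (narrowed polygon
    non-empty, >= ``min_sunlit`` sunlit pixels, valid GLCM pairs) in *all*
    requested layers, so the table has no absent cells.  Dropped crowns are
    logged with their reason.
    """
    config = config or MetricConfig()
    if not surveys:
        raise ValueError("no survey layers given")
    reference = surveys[0]
    for layer in surveys[1:]:
        if layer.shape != reference.shape or not layer.transform.close_to(
            reference.transform
        ):
            raise CoRegistrationError(
                f"layer {layer.key} is not co-registered with {reference.key}"
            )

    ri_cache = {id(layer): relative_intensity(layer) for layer in surveys}

    rows: dict[str, dict[str, float | str]] = {}
    dropped: list[tuple[str, str]] = []
    for crown in crowns:
        narrowed = narrow_crown(crown.geometry, config.buffer_m)
        if narrowed.is_empty:
            dropped.append((crown.crown_id, "empty after negative buffer"))
            logger.warning("crown %s dropped: empty after negative buffer", crown.crown_id)
            continue
        mask = pixels_in_polygon(narrowed, reference.transform, reference.shape)
        if len(mask) == 0:
            dropped.append((crown.crown_id, "no pixel centers inside narrowed polygon"))
            logger.warning("crown %s dropped: no pixel centers", crown.crown_id)
            continue
        row: dict[str, float | str] = {"species": crown.species}
        reason = None
        for layer in surveys:
            sun = sunlit_mask(mask, ri_cache[id(layer)], config.shadow_threshold)
            if len(sun) < config.min_sunlit:
                reason = (
                    f"{layer.key}: {len(sun)} sunlit pixels < min_sunlit "
                    f"{config.min_sunlit}"
                )
                break
            values = layer.bands[:, sun[:, 0], sun[:, 1]].T
            for name, value in spectral_metrics(values, layer.camera).items():
                row[f"{layer.key}.{name}"] = value
            glcm_failed = False
            for b in range(3):
                stats = glcm_metrics(
                    layer.bands[b], sun, config.glcm_levels, config.glcm_offsets
                )
                if stats is None:
                    glcm_failed = True
                    break
                for name, value in stats.items():
                    row[f"{layer.key}.glcm_{name}_{b + 1}"] = value
            if glcm_failed:
                reason = f"{layer.key}: no valid GLCM pixel pair"
                break
        if reason is not None:
            dropped.append((crown.crown_id, reason))
            logger.warning("crown %s dropped: %s", crown.crown_id, reason)
            continue
        rows[crown.crown_id] = row

    if not rows:
        raise ValueError("zero crowns retained; check imagery and parameters")
    data = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    data.index.name = "crown_id"
    cols = ["species"] + sorted(c for c in data.columns if c != "species")
    return FeatureTable(data=data[cols], dropped=dropped)
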