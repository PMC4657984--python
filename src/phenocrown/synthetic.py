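"""Synthetic multitemporal crown scenes with controllable phenology structure.

The generator produces the statistical situation the classification pipeline
assumes: a handful of deciduous species groups whose 4-band (blue, green,
red, near-infrared) mean reflectance follows the growing season, with a
*within-species* spread that is small at the end of leaf flush and large in
early spring and late autumn — the mechanism by which one acquisition window
can dominate species discrimination.  Each preset freezes one regime of that
mechanism:

``null_world``
    every species shares the same spectrum and spread at every date; any
    classifier can only reach chance level.
``separable_world``
    species means are separated by at least ten within-species standard
    deviations at every date; classification is essentially free.
``planted_optimum``
    exactly one date ``t*`` combines wide between-species spacing with a
    small within-species spread; recovering ``t*`` from the date ranking is
    a parameter-recovery problem with a known answer.
``paper_like``
    five species over ten survey dates spanning spring to autumn, with a
    U-shaped within-species spread over the season (high at the first and
    last dates, minimal at the third date).

Radiometry is 8-bit digital numbers (0-255), matching consumer cameras.
Shadows are contiguous blobs attenuated by a factor 0.1; only their
detectability by the downstream relative-intensity rule matters.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import Point

from .geodata import (
    CrownRecord,
    GridTransform,
    SurveyLayer,
    SurveyMeta,
    pixels_in_polygon,
    write_crowns,
    write_manifest,
    write_survey,
)

logger = logging.getLogger(__name__)

PRESETS = ("null_world", "separable_world", "planted_optimum", "paper_like")

DEFAULT_SPECIES = ("birch", "oak", "maple", "ash", "poplar")

#: Survey day-of-year grid mimicking a 10-date spring-to-autumn campaign
#: (27 Apr ... 15 Nov).
PAPER_LIKE_DOYS = (117, 118, 148, 156, 189, 233, 261, 274, 295, 319)

# canopy end-member spectra, DN, band order (B, G, R, NIR)
_GREEN_LEAF = np.array([60.0, 110.0, 70.0, 170.0])
_BUDDING = np.array([80.0, 75.0, 70.0, 90.0])

_SHADOW_ATTENUATION = 0.1

#: Near-collinear mixing applied to the CIR bands when the hot-mirror-removed
#: camera's redundant NIR sensitivity is emulated (rows nearly parallel).
CIR_MIXING_MATRIX = np.array(
    [
        [0.55, 0.27, 0.18],
        [0.52, 0.29, 0.19],
        [0.50, 0.30, 0.20],
    ]
)


@dataclass
class PhenologyParams:
    """Per-species, per-date spectral means and variance components.

    ``mean_spectrum`` has shape (species, dates, 4) in band order B, G, R,
    NIR; ``between_tree_sd`` (species, dates) is the SD of crown-level mean
    offsets; ``within_crown_sd`` the per-pixel noise SD.  ``t_star`` is the
    0-based index of the planted optimal date, where one exists.
    """

    species_names: tuple[str, ...]
    dates: tuple[int, ...]
    mean_spectrum: np.ndarray
    between_tree_sd: np.ndarray
    within_crown_sd: float = 4.0
    shadow_fraction: float = 0.3
    luminosity_gradient: float = 0.0
    cir_band_mixing: bool = False
    preset: str | None = None
    t_star: int | None = None

    def __post_init__(self) -> None:
        s, d = len(self.species_names), len(self.dates)
        self.mean_spectrum = np.asarray(self.mean_spectrum, dtype=float)
        self.between_tree_sd = np.asarray(self.between_tree_sd, dtype=float)
        if self.mean_spectrum.shape != (s, d, 4):
            raise ValueError(
                f"mean_spectrum must have shape {(s, d, 4)}, got {self.mean_spectrum.shape}"
            )
        if self.between_tree_sd.shape != (s, d):
            raise ValueError(
                f"between_tree_sd must have shape {(s, d)}, got {self.between_tree_sd.shape}"
            )
        if (self.between_tree_sd < 0).any():
            raise ValueError("between_tree_sd must be >= 0 everywhere")
        if not 0 < self.shadow_fraction <= 0.5:
            raise ValueError("shadow_fraction must lie in (0, 0.5]")
        self.mean_spectrum = np.clip(self.mean_spectrum, 0.0, 255.0)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_dates(self) -> int:
        return len(self.dates)

    def separation_ratio(self, date_index: int) -> float:
        """(min pairwise distance between species means) / (max between-tree SD)."""
        means = self.mean_spectrum[:, date_index, :]
        dists = [
            float(np.linalg.norm(means[i] - means[j]))
            for i in range(self.n_species)
            for j in range(i + 1, self.n_species)
        ]
        sd = float(self.between_tree_sd[:, date_index].max())
        if sd == 0:
            return math.inf if min(dists) > 0 else 0.0
        return min(dists) / sd


def _axis_offsets(n_species: int, amplitude: float) -> np.ndarray:
    """Species offsets: origin plus axis-aligned bumps of size ``amplitude``."""
    out = np.zeros((n_species, 4))
    for i in range(1, n_species):
        out[i, (i - 1) % 4] = amplitude
    return out


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _paper_like_spectra(dates: np.ndarray) -> np.ndarray:
    """Seasonal 4-band trajectories for the five default species groups.

    Each species greens up at its own onset day, holds a slightly
    species-specific summer spectrum, then senesces toward its own autumn
    colour; birch is early-leafing and late-senescing, ash the opposite,
    oak and maple intermediate, poplar early on both ends.
    """
    # (onset doy, senescence doy, summer offset BGRN, autumn colour BGRN)
    traits = {
        "birch": (95, 290, (4, 8, -4, 10), (70, 140, 150, 120)),
        "oak": (125, 300, (-3, -6, 2, -6), (60, 95, 105, 110)),
        "maple": (123, 280, (2, 5, 6, 4), (55, 120, 160, 130)),
        "ash": (135, 268, (-5, 3, -5, 8), (75, 105, 90, 100)),
        "poplar": (110, 265, (6, -4, 4, -10), (85, 130, 120, 95)),
    }
    spectra = np.zeros((len(traits), len(dates), 4))
    for s, (_, (onset, senescence, offset, autumn)) in enumerate(traits.items()):
        summer = _GREEN_LEAF + np.asarray(offset, dtype=float)
        autumn = np.asarray(autumn, dtype=float)
        for d, doy in enumerate(dates):
            g = float(_logistic((doy - onset) / 8.0))     # leaf flush
            a = float(_logistic((doy - senescence) / 10.0))  # senescence
            foliage = summer * (1 - a) + autumn * a
            spectra[s, d] = _BUDDING * (1 - g) + foliage * g
    return spectra


def make_phenology(
    preset: str,
    seed: int,
    *,
    n_dates: int = 10,
    shadow_fraction: float = 0.3,
    luminosity_gradient: float = 0.0,
    cir_band_mixing: bool = False,
) -> PhenologyParams:
    """Build the per-species spectral parameters for a named preset.

    ``n_dates`` controls the survey-date grid for the synthetic presets
    (``paper_like`` is always the fixed 10-date campaign).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; valid presets: {', '.join(PRESETS)}")
    rng = np.random.default_rng(seed)
    species = DEFAULT_SPECIES
    n_species = len(species)

    if preset == "paper_like":
        dates = np.array(PAPER_LIKE_DOYS)
        mean = _paper_like_spectra(dates)
        # U-shaped within-species spread over the season, minimal at date 2
        sd_profile = np.array([12.0, 9.0, 3.0, 4.0, 5.0, 5.0, 6.0, 8.0, 10.0, 12.0])
        sd = np.tile(sd_profile, (n_species, 1))
        t_star: int | None = 2
    else:
        dates = np.round(np.linspace(117, 319, n_dates)).astype(int)
        if preset == "null_world":
            mean = np.tile(_GREEN_LEAF, (n_species, n_dates, 1))
            sd = np.full((n_species, n_dates), 1.0)
            t_star = None
        elif preset == "separable_world":
            offsets = _axis_offsets(n_species, 30.0)
            mean = _GREEN_LEAF[None, None, :] + offsets[:, None, :]
            mean = np.broadcast_to(mean, (n_species, n_dates, 4)).copy()
            sd = np.full((n_species, n_dates), 2.0)
            t_star = None
        else:  # planted_optimum
            t_star = int(rng.integers(n_dates))
            mean = np.zeros((n_species, n_dates, 4))
            sd = np.zeros((n_species, n_dates))
            for d in range(n_dates):
                if d == t_star:
                    amp, spread = 18.0, 2.0
                else:
                    amp = float(rng.uniform(5.0, 7.0))
                    spread = float(rng.uniform(5.5, 6.5))
                mean[:, d, :] = _GREEN_LEAF[None, :] + _axis_offsets(n_species, amp)
                sd[:, d] = spread

    params = PhenologyParams(
        species_names=species,
        dates=tuple(int(d) for d in dates),
        mean_spectrum=mean,
        between_tree_sd=sd,
        within_crown_sd=4.0,
        shadow_fraction=shadow_fraction,
        luminosity_gradient=luminosity_gradient,
        cir_band_mixing=cir_band_mixing,
        preset=preset,
        t_star=t_star,
    )
    if preset == "planted_optimum":
        ratios = [params.separation_ratio(d) for d in range(params.n_dates)]
        best = int(np.argmax(ratios))
        assert best == t_star, "planted optimum must maximize the separation ratio"
    return params


@dataclass
class SceneConfig:
    """Layout of the synthetic stand: crown count, grid, pixel size, seed."""

    n_crowns_per_species: int = 10
    grid_size: tuple[int, int] = (300, 300)
    gsd: float = 0.20
    crown_radius_range: tuple[float, float] = (1.2, 2.0)
    seed: int = 0
    preset: str | None = None
    background_spectrum: tuple[float, float, float, float] = (12.0, 14.0, 10.0, 18.0)
    max_attempts_per_crown: int = 500

    def __post_init__(self) -> None:
        if self.gsd <= 0:
            raise ValueError("gsd must be positive")
        rmin, rmax = self.crown_radius_range
        if not 0 < rmin <= rmax:
            raise ValueError("crown_radius_range must satisfy 0 < rmin <= rmax")


def _place_crowns(
    phenology: PhenologyParams, config: SceneConfig, rng: np.random.Generator
) -> list[CrownRecord]:
    rows, cols = config.grid_size
    width, height = cols * config.gsd, rows * config.gsd
    margin = 0.2  # metres between crown disks
    centers = np.empty((0, 2))
    radii = np.empty(0)
    crowns: list[CrownRecord] = []
    idx = 0
    for species in phenology.species_names:
        for _ in range(config.n_crowns_per_species):
            placed = False
            for _attempt in range(config.max_attempts_per_crown):
                r = float(rng.uniform(*config.crown_radius_range))
                x = float(rng.uniform(r + margin, width - r - margin))
                y = float(rng.uniform(r + margin, height - r - margin))
                if centers.shape[0]:
                    d = np.hypot(centers[:, 0] - x, centers[:, 1] - y)
                    if (d < radii + r + margin).any():
                        continue
                centers = np.vstack([centers, (x, y)])
                radii = np.append(radii, r)
                crowns.append(
                    CrownRecord(
                        crown_id=f"c{idx:04d}",
                        species=species,
                        geometry=Point(x, y).buffer(r, quad_segs=16),
                    )
                )
                idx += 1
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    "could not place non-overlapping crowns after "
                    f"{config.max_attempts_per_crown} attempts; use fewer "
                    "crowns per species or a larger grid"
                )
    return crowns


def _shadow_sector(
    pixels: np.ndarray, n_target: int, rng: np.random.Generator
) -> np.ndarray:
    """A contiguous, randomly oriented angular sector of ``n_target`` crown pixels.

    Shading one side of the crown keeps the shadowed fraction uniform over
    concentric subregions, so an inward-buffered crown loses the same
    fraction as the full crown.
    """
    center = pixels.mean(axis=0)
    theta0 = float(rng.uniform(0.0, 2.0 * np.pi))
    angles = np.arctan2(pixels[:, 0] - center[0], pixels[:, 1] - center[1])
    order = np.argsort((angles - theta0) % (2.0 * np.pi), kind="stable")
    return pixels[order[:n_target]]


def _season_of(doy: int) -> str:
    if doy < 150:
        return "spring"
    if doy < 245:
        return "summer"
    return "autumn"


def _pseudo_gdd(doy: int) -> float:
    # monotone stand-in for accumulated degree-days; metadata only
    return round(max(0.0, 5.5 * (doy - 100)), 1)


def generate_world(
    phenology: PhenologyParams, config: SceneConfig
) -> tuple[list[CrownRecord], list[SurveyLayer]]:
    """Render the full synthetic study: crowns plus one RGB and one CIR layer per date.

    Crown interiors are filled with crown-level means (species mean plus a
    per-crown, per-date offset drawn with SD ``between_tree_sd``) plus
    per-pixel noise; a contiguous, randomly oriented angular sector holding
    ``shadow_fraction`` of each crown's pixels is attenuated by 0.1 to
    emulate cast shadow (the same geometry for both cameras of a date); the
    background is a distinct low-intensity texture.
    Identical (phenology, config) including seed give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid_size
    transform = GridTransform(x_origin=0.0, y_origin=rows * config.gsd, gsd=config.gsd)

    crowns = _place_crowns(phenology, config, rng)
    species_idx = np.array(
        [phenology.species_names.index(c.species) for c in crowns]
    )
    masks = [
        pixels_in_polygon(c.geometry, transform, (rows, cols)) for c in crowns
    ]
    for crown, mask in zip(crowns, masks):
        if len(mask) == 0:
            logger.warning("crown %s covers no pixel center", crown.crown_id)

    band_order = {"RGB": (0, 1, 2), "CIR": (3, 2, 1)}  # indices into (B,G,R,NIR)
    bg = np.asarray(config.background_spectrum)
    ramp = 1.0 + phenology.luminosity_gradient * (
        np.arange(cols) / max(cols - 1, 1) - 0.5
    )

    layers: list[SurveyLayer] = []
    for d, doy in enumerate(phenology.dates):
        offsets = (
            rng.standard_normal((len(crowns), 4))
            * phenology.between_tree_sd[species_idx, d][:, None]
        )
        shadows = []
        for mask in masks:
            if len(mask) == 0:
                shadows.append(np.empty((0, 2), dtype=np.int64))
                continue
            n_shadow = int(np.ceil(phenology.shadow_fraction * len(mask)))
            shadows.append(_shadow_sector(mask, n_shadow, rng))
        for camera in ("RGB", "CIR"):
            sel = list(band_order[camera])
            img = bg[sel][None, None, :] + rng.standard_normal((rows, cols, 3)) * 2.0
            for k, (crown, mask, shadow) in enumerate(zip(crowns, masks, shadows)):
                if len(mask) == 0:
                    continue
                spectrum = phenology.mean_spectrum[species_idx[k], d] + offsets[k]
                means = spectrum[sel]
                if camera == "CIR" and phenology.cir_band_mixing:
                    means = CIR_MIXING_MATRIX @ means
                vals = means[None, :] + (
                    rng.standard_normal((len(mask), 3)) * phenology.within_crown_sd
                )
                img[mask[:, 0], mask[:, 1]] = vals
                if len(shadow):
                    img[shadow[:, 0], shadow[:, 1]] *= _SHADOW_ATTENUATION
            img *= ramp[None, :, None]
            bands = np.clip(np.rint(img), 0, 255).astype(np.uint8)
            layers.append(
                SurveyLayer(
                    survey_id=f"s{d + 1:02d}",
                    date=_dt.date(2021, 1, 1) + _dt.timedelta(days=int(doy) - 1),
                    season=_season_of(int(doy)),
                    gdd=_pseudo_gdd(int(doy)),
                    camera=camera,
                    bands=np.moveaxis(bands, -1, 0),
                    transform=transform,
                )
            )
    return crowns, layers


def write_world(
    crowns: Sequence[CrownRecord],
    layers: Sequence[SurveyLayer],
    outdir: str | Path,
    *,
    phenology: PhenologyParams | None = None,
    config: SceneConfig | None = None,
) -> Path:
    """Write GeoTIFFs, crowns.geojson and a manifest.yaml under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metas = []
    for layer in layers:
        name = f"{layer.survey_id}_{layer.camera}.tif"
        write_survey(layer, outdir / name)
        metas.append(
            SurveyMeta(
                survey_id=layer.survey_id,
                date=layer.date,
                season=layer.season,
                gdd=layer.gdd,
                camera=layer.camera,
                path=name,
            )
        )
    write_crowns(crowns, outdir / "crowns.geojson")
    extra: dict = {}
    if phenology is not None:
        extra["preset"] = phenology.preset
        if phenology.t_star is not None:
            extra["t_star"] = f"s{phenology.t_star + 1:02d}"
    if config is not None:
        extra["seed"] = config.seed
        extra["gsd"] = config.gsd
    manifest = write_manifest(metas, outdir / "manifest.yaml", extra=extra)
    return manifest
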