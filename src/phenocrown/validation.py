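"""Synthetic-control experiments that exercise the whole pipeline end to end.

These are the package's standing self-checks, each built on a generator
preset with a known answer:

* ``chance_level_control`` — with five statistically identical species the
  averaged OOB error must sit at chance (0.8 for five balanced classes);
  anything else indicates leakage or a broken protocol.
* ``separability_control`` — with species means ten within-species SDs
  apart, the error must be essentially zero.
* ``optimal_window_recovery`` — across independently seeded
  ``planted_optimum`` worlds, the date ranking must recover the planted
  optimal window ``t*`` as the best single date, and ``t*`` must keep
  appearing in the best two-date and three-date combinations.

Problem sizes default to desk scale: 55 crowns per species on an 84 m
square scene, two dates for the controls, six dates and reduced forest
settings (200 trees, 5 repetitions) for the recovery experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classify import ClassificationReport, run_scenario
from .metrics import FeatureTable, MetricConfig, build_feature_table, feature_columns
from .search import RFSettings, enumerate_scenarios, rank_scenarios
from .synthetic import SceneConfig, generate_world, make_phenology

logger = logging.getLogger(__name__)

_CONTROL_SCENE = dict(
    n_crowns_per_species=55,
    grid_size=(420, 420),
    crown_radius_range=(1.2, 1.8),
)


def _world_table(
    preset: str,
    seed: int,
    *,
    n_dates: int,
    n_crowns_per_species: int = 55,
    grid_size: tuple[int, int] = (420, 420),
) -> tuple[FeatureTable, object]:
    phenology = make_phenology(preset, seed, n_dates=n_dates)
    config = SceneConfig(
        n_crowns_per_species=n_crowns_per_species,
        grid_size=grid_size,
        crown_radius_range=(1.2, 1.8),
        seed=seed + 1,
        preset=preset,
    )
    crowns, layers = generate_world(phenology, config)
    table = build_feature_table(layers, crowns, MetricConfig())
    return table, phenology


def chance_level_control(seed: int = 0) -> ClassificationReport:
    """Full-protocol classification of a null world; expect chance-level OOB."""
    table, _ = _world_table("null_world", seed, n_dates=2)
    cols = feature_columns(table.data, surveys=["s01"])
    return run_scenario(table.data, cols, seed=seed)


def separability_control(seed: int = 0) -> ClassificationReport:
    """Full-protocol classification of a separable world; expect ~zero OOB."""
    table, _ = _world_table("separable_world", seed, n_dates=2)
    cols = feature_columns(table.data, surveys=["s01"])
    return run_scenario(table.data, cols, seed=seed)


@dataclass
class RecoveryWorld:
    """Per-world outcome of the optimal-window recovery experiment."""

    world_seed: int
    t_star: str
    k1_rank1: str
    best_oob: dict[int, float]  # family k -> best overall OOB
    t_star_in_top5: dict[int, bool]  # family k -> planted date in top 5


@dataclass
class RecoveryResult:
    worlds: list[RecoveryWorld] = field(default_factory=list)

    @property
    def rank1_hit_rate(self) -> float:
        return float(np.mean([w.k1_rank1 == w.t_star for w in self.worlds]))

    def top5_rate(self, k: int) -> float:
        return float(np.mean([w.t_star_in_top5[k] for w in self.worlds]))

    def mean_best_oob(self, k: int) -> float:
        return float(np.mean([w.best_oob[k] for w in self.worlds]))


def optimal_window_recovery(
    n_worlds: int = 10,
    seed: int = 0,
    *,
    n_dates: int = 6,
    n_crowns_per_species: int = 55,
    settings: RFSettings | None = None,
) -> RecoveryResult:
    """Rank single-, two- and three-date scenarios on planted-optimum worlds.

    Each world gets an independent seed; the forest settings default to the
    reduced search configuration (200 trees, 5 repetitions, 50 per class).
    """
    settings = settings or RFSettings(n_trees=200, n_repetitions=5, n_per_class=50)
    result = RecoveryResult()
    for w in range(n_worlds):
        world_seed = seed + 1000 * w
        table, phenology = _world_table(
            "planted_optimum",
            world_seed,
            n_dates=n_dates,
            n_crowns_per_species=n_crowns_per_species,
        )
        t_star = f"s{phenology.t_star + 1:02d}"
        survey_ids = sorted({c.split(".", 2)[0] for c in table.data.columns if "." in c})
        best_oob: dict[int, float] = {}
        top5: dict[int, bool] = {}
        k1_rank1 = ""
        for k in (1, 2, 3):
            scenarios = enumerate_scenarios(survey_ids, k)
            ranking = rank_scenarios(
                table.data, scenarios, settings=settings, master_seed=world_seed
            )
            best_oob[k] = ranking[0].report.overall_oob
            head = ranking[:5]
            top5[k] = any(t_star in res.spec.survey_ids for res in head)
            if k == 1:
                k1_rank1 = ranking[0].spec.survey_ids[0]
        result.worlds.append(
            RecoveryWorld(
                world_seed=world_seed,
                t_star=t_star,
                k1_rank1=k1_rank1,
                best_oob=best_oob,
                t_star_in_top5=top5,
            )
        )
        logger.info(
            "world %d: t*=%s rank1=%s best oob %s", w, t_star, k1_rank1, best_oob
        )
    return result
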