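"""Enumerate and rank acquisition-date combinations by averaged OOB error.

A *scenario* is a set of one to three survey dates plus the camera feature
namespaces to use (multi-date scenarios combine RGB+CIR per survey, since a
survey is the pair of flights).  Every scenario is classified independently
with the repeated balanced Random-Forest protocol, seeded deterministically
from the master seed and the scenario identity, so adding scenarios never
perturbs existing results.  Scenarios are ranked ascending by overall OOB
error; ties break by earliest survey date, then lexicographic survey id.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import ClassificationReport, run_scenario
from .metrics import feature_columns

_SEED_MOD = 2**31

CAMERA_MODES = {
    "RGB": ("RGB",),
    "CIR": ("CIR",),
    "RGB+CIR": ("RGB", "CIR"),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One classification scenario: survey ids plus camera namespaces."""

    survey_ids: tuple[str, ...]
    cameras: tuple[str, ...]

    @property
    def label(self) -> str:
        return f"{'+'.join(self.survey_ids)}/{'+'.join(self.cameras)}"


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    report: ClassificationReport
    seed: int
    rank: int | None = None


@dataclass
class RFSettings:
    """Random-Forest protocol knobs shared across a scenario family."""

    n_trees: int = 500
    n_repetitions: int = 20
    n_per_class: int = 50


def enumerate_scenarios(
    survey_ids: Sequence[str], k: int, cameras: Iterable[str] = ("RGB", "CIR")
) -> list[ScenarioSpec]:
    """All size-``k`` survey subsets mapped to the requested camera namespaces."""
    if not 1 <= k <= 3:
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    ids = sorted(set(survey_ids))
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of surveys ({len(ids)})")
    cams = tuple(c for c in ("RGB", "CIR") if c in set(cameras))
    if not cams:
        raise ValueError(f"no valid cameras in {tuple(cameras)}")
    return [ScenarioSpec(survey_ids=combo, cameras=cams) for combo in combinations(ids, k)]


def scenario_seed(master_seed: int, spec: ScenarioSpec) -> int:
    """Stable per-scenario seed: hash of (master seed, survey ids, cameras)."""
    key = f"{master_seed}:{','.join(sorted(spec.survey_ids))}:{','.join(sorted(spec.cameras))}"
    digest = hashlib.sha256(key.encode()).hexdigest()
    return int(digest, 16) % _SEED_MOD


def _sort_key(result: ScenarioResult, dates: Mapping[str, _dt.date] | None):
    spec = result.spec
    if dates is not None:
        earliest = min(dates[sid] for sid in spec.survey_ids)
    else:
        earliest = min(spec.survey_ids)
    return (result.report.overall_oob, earliest, spec.survey_ids)


def rank_scenarios(
    table: pd.DataFrame,
    scenarios: Sequence[ScenarioSpec],
    *,
    settings: RFSettings | None = None,
    master_seed: int = 0,
    survey_dates: Mapping[str, _dt.date] | None = None,
) -> list[ScenarioResult]:
    """Classify every scenario and rank ascending by overall OOB error."""
    settings = settings or RFSettings()
    results: list[ScenarioResult] = []
    for spec in scenarios:
        cols = feature_columns(table, surveys=spec.survey_ids, cameras=spec.cameras)
        present = {c.split(".", 2)[0] for c in cols}
        missing = set(spec.survey_ids) - present
        if missing:
            raise ValueError(
                f"scenario {spec.label}: no feature columns for survey(s) {sorted(missing)}"
            )
        seed = scenario_seed(master_seed, spec)
        try:
            report = run_scenario(
                table,
                cols,
                n_repetitions=settings.n_repetitions,
                n_trees=settings.n_trees,
                n_per_class=settings.n_per_class,
                seed=seed,
            )
        except (ValueError, KeyError) as exc:
            raise type(exc)(f"scenario {spec.label}: {exc}") from exc
        results.append(ScenarioResult(spec=spec, report=report, seed=seed))
    results.sort(key=lambda res: _sort_key(res, survey_dates))
    for position, res in enumerate(results, start=1):
        res.rank = position
    return results


def camera_comparison(
    table: pd.DataFrame,
    survey_id: str,
    *,
    settings: RFSettings | None = None,
    seed: int = 0,
) -> dict[str, ScenarioResult]:
    """RGB-only vs CIR-only vs combined feature sets for one survey.

    All three classifications use the identical seed, hence identical
    balanced samples (the table has no absent cells by construction).
    """
    settings = settings or RFSettings()
    for camera in ("RGB", "CIR"):
        if not feature_columns(table, surveys=[survey_id], cameras=[camera]):
            raise ValueError(f"survey {survey_id}: no {camera} feature columns present")
    out: dict[str, ScenarioResult] = {}
    for mode, cams in CAMERA_MODES.items():
        spec = ScenarioSpec(survey_ids=(survey_id,), cameras=cams)
        cols = feature_columns(table, surveys=[survey_id], cameras=cams)
        report = run_scenario(
            table,
            cols,
            n_repetitions=settings.n_repetitions,
            n_trees=settings.n_trees,
            n_per_class=settings.n_per_class,
            seed=seed,
        )
        out[mode] = ScenarioResult(spec=spec, report=report, seed=seed)
    return out


# ---------------------------------------------------------------------------
# result serialization


def results_to_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        row: dict = {
            "scenario": "+".join(res.spec.survey_ids),
            "cameras": "+".join(res.spec.cameras),
            "rank": res.rank,
            "overall_oob": res.report.overall_oob,
            "seed": res.seed,
        }
        for cls, err in res.report.per_class_oob.items():
            row[f"oob_{cls}"] = err
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(results: Sequence[ScenarioResult], path_base: str | Path) -> tuple[Path, Path]:
    """Write a ranking as <base>.csv and <base>.json."""
    base = Path(path_base)
    frame = results_to_frame(results)
    csv_path = base.with_suffix(".csv")
    frame.to_csv(csv_path, index=False)
    payload = [
        {
            "scenario": list(res.spec.survey_ids),
            "cameras": list(res.spec.cameras),
            "rank": res.rank,
            "seed": res.seed,
            "report": res.report.to_dict(),
        }
        for res in results
    ]
    json_path = base.with_suffix(".json")
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return csv_path, json_path


def format_ranking(results: Sequence[ScenarioResult], top: int | None = None) -> str:
    """Plain-text ranking table (one row per scenario, OOB as percent)."""
    chosen = results[:top] if top else list(results)
    classes = chosen[0].report.classes if chosen else ()
    header = ["rank", "scenario", "cameras", "overall"] + list(classes)
    lines = ["\t".join(header)]
    for res in chosen:
        cells = [
            str(res.rank),
            "+".join(res.spec.survey_ids),
            "+".join(res.spec.cameras),
            f"{100 * res.report.overall_oob:.1f}",
        ]
        cells += [f"{100 * res.report.per_class_oob[c]:.0f}" for c in classes]
        lines.append("\t".join(cells))
    return "\n".join(lines)
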