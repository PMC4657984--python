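"""Balanced repeated Random-Forest classification scored by averaged OOB error.

The protocol: before every forest, draw an equal number of crowns per
species (without replacement) to avoid class-imbalance bias; fit a Random
Forest; score it by its out-of-bag misclassification error (each crown
predicted by majority vote of the trees whose bootstrap sample excluded
it); repeat, and average the repetition errors.  Defaults are 20
repetitions of 500-tree forests with 50 crowns per class, with
floor(sqrt(p)) features tried per split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

_SEED_MOD = 2**31


def balanced_sample(
    table: pd.DataFrame, n_per_class: int, seed: int
) -> pd.DataFrame:
    """Draw exactly ``n_per_class`` rows per species, without replacement.

    Deterministic for a fixed seed.  Raises if any class is short, naming
    the class and its count.
    """
    if "species" not in table.columns:
        raise ValueError("table must carry a 'species' column")
    counts = table["species"].value_counts()
    short = {cls: int(n) for cls, n in counts.items() if n < n_per_class}
    if short:
        raise ValueError(
            f"classes below n_per_class={n_per_class}: "
            + ", ".join(f"{cls} has {n}" for cls, n in sorted(short.items()))
        )
    rng = np.random.default_rng(seed)
    parts = []
    for cls in sorted(counts.index):
        positions = np.flatnonzero((table["species"] == cls).to_numpy())
        chosen = rng.choice(positions, size=n_per_class, replace=False)
        parts.append(table.iloc[np.sort(chosen)])
    return pd.concat(parts)


@dataclass
class ClassificationReport:
    """Aggregate of one classification scenario's repeated forests."""

    classes: tuple[str, ...]
    overall_oob: float
    per_class_oob: dict[str, float]
    confusion: np.ndarray  # rows = truth, pooled counts over repetitions
    per_repetition_oob: list[float]
    settings: dict

    @property
    def pooled_oob(self) -> float:
        """1 - trace/total of the pooled confusion matrix."""
        total = self.confusion.sum()
        return float(1.0 - np.trace(self.confusion) / total) if total else float("nan")

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "overall_oob": self.overall_oob,
            "per_class_oob": self.per_class_oob,
            "confusion": self.confusion.tolist(),
            "per_repetition_oob": self.per_repetition_oob,
            "settings": self.settings,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path

    def per_repetition_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {
                "repetition": np.arange(len(self.per_repetition_oob)),
                "oob_error": self.per_repetition_oob,
            }
        ).to_csv(path, index=False)
        return path


def run_scenario(
    table: pd.DataFrame,
    feature_cols: Sequence[str],
    *,
    n_repetitions: int = 20,
    n_trees: int = 500,
    n_per_class: int = 50,
    seed: int = 0,
) -> ClassificationReport:
    """Run the repeated balanced Random-Forest protocol on selected features.

    Rows with any absent metric among ``feature_cols`` are excluded before
    sampling.  Repetition r draws its balanced sample and fits its forest
    with seed ``seed + r``.  OOB vote ties resolve to the first class in
    sorted species order.
    """
    feature_cols = list(feature_cols)
    if not feature_cols:
        raise ValueError("feature column selector matched no columns")
    missing = [c for c in feature_cols if c not in table.columns]
    if missing:
        raise KeyError(f"feature columns absent from table: {missing[:5]}")
    if "species" not in table.columns:
        raise ValueError("table must carry a 'species' column")

    clean = table.dropna(subset=feature_cols)
    classes = tuple(sorted(table["species"].unique()))
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes, got {classes}")
    gone = set(classes) - set(clean["species"].unique())
    if gone:
        raise ValueError(
            f"absent-metric exclusion removed every row of class(es): {sorted(gone)}"
        )

    k = len(classes)
    cls_index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((k, k), dtype=np.int64)
    per_rep: list[float] = []
    per_class_rep = np.full((n_repetitions, k), np.nan)

    for r in range(n_repetitions):
        rep_seed = (seed + r) % _SEED_MOD
        sample = balanced_sample(clean, n_per_class, rep_seed)
        X = sample[feature_cols].to_numpy(dtype=float)
        y = sample["species"].to_numpy()
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            bootstrap=True,
            oob_score=True,
            random_state=rep_seed,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", message="Some inputs do not have OOB scores"
            )
            warnings.filterwarnings("ignore", message="invalid value encountered")
            forest.fit(X, y)
        votes = forest.oob_decision_function_
        valid = np.nan_to_num(votes).sum(axis=1) > 0
        # argmax of the vote shares; ties fall to the first class in
        # sklearn's sorted classes_, i.e. sorted species order
        pred = forest.classes_[np.nan_to_num(votes).argmax(axis=1)]
        errors = pred[valid] != y[valid]
        per_rep.append(float(errors.mean()))
        t_idx = np.array([cls_index[c] for c in y[valid]])
        p_idx = np.array([cls_index[c] for c in pred[valid]])
        np.add.at(confusion, (t_idx, p_idx), 1)
        for c, i in cls_index.items():
            sel = y[valid] == c
            if sel.any():
                per_class_rep[r, i] = float((pred[valid][sel] != c).mean())

    per_class = {
        c: float(np.nanmean(per_class_rep[:, i])) for c, i in cls_index.items()
    }
    return ClassificationReport(
        classes=classes,
        overall_oob=float(np.mean(per_rep)),
        per_class_oob=per_class,
        confusion=confusion,
        per_repetition_oob=per_rep,
        settings={
            "n_trees": n_trees,
            "n_repetitions": n_repetitions,
            "n_per_class": n_per_class,
            "n_features": len(feature_cols),
            "seed": seed,
        },
    )
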