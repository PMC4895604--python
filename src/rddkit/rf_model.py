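"""Random-Forest classification of RDD candidates and attribute ranking.

The classifier consumes the 15 read-alignment-pattern attributes in a fixed
order persisted with the model.  Attribute importance is reported as
information gain of the class given the (discretized) attribute, aggregated
per attribute category and ranked per dataset — the shape of the category
ranking table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .io_formats import FEATURE_CATEGORY, FEATURE_ORDER
from .training_compiler import PredictionTargets, TrainingSet

MODEL_FORMAT_VERSION = 1

DEFAULT_HYPER = dict(n_trees=100, max_depth=None)


@dataclass
class RddPredictor:
    forest: RandomForestClassifier
    feature_order: List[str]
    hyper: Dict
    seed: int
    class_counts: Dict[str, int]


def train(ts: TrainingSet, n_trees: int = 100, max_depth: Optional[int] = None,
          seed: int = 0) -> RddPredictor:
    """Fit the forest (sqrt-features splits, fixed seed).

    A constant feature column draws a warning, not an error: the forest
    simply never splits on it.
    """
    counts = ts.class_counts
    if len(counts) < 2:
        raise ValueError(f"both classes required to train, got {counts}")
    X, y = ts.features(), ts.labels()
    constant = [FEATURE_ORDER[j] for j in range(X.shape[1])
                if np.all(X[:, j] == X[0, j])]
    if constant:
        warnings.warn(f"constant feature columns: {constant}")
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_depth=max_depth, max_features="sqrt",
        random_state=seed, n_jobs=1)
    forest.fit(X, y)
    return RddPredictor(forest=forest, feature_order=list(FEATURE_ORDER),
                        hyper=dict(n_trees=n_trees, max_depth=max_depth),
                        seed=seed, class_counts=counts)


def predict(model: RddPredictor, targets: PredictionTargets,
            threshold: float = 0.5) -> pd.DataFrame:
    """Per-site probability of true editing and the thresholded accept bit.

    Returns one row per target: site columns + prob_editing + accepted.
    """
    missing = [c for c in model.feature_order if c not in targets.df.columns]
    if missing:
        raise ValueError(f"targets missing feature columns {missing}")
    out = targets.df.copy().reset_index(drop=True)
    if len(out) == 0:
        out["prob_editing"] = pd.Series(dtype=float)
        out["accepted"] = pd.Series(dtype=bool)
        return out
    X = out[model.feature_order].to_numpy(dtype=float)
    true_idx = list(model.forest.classes_).index(True)
    prob = model.forest.predict_proba(X)[:, true_idx]
    out["prob_editing"] = prob
    out["accepted"] = prob >= threshold
    return out


def save_model(model: RddPredictor, path) -> None:
    """Single self-describing file: forest + feature order + hyper + seed."""
    joblib.dump({
        "format_version": MODEL_FORMAT_VERSION,
        "feature_order": model.feature_order,
        "hyper": model.hyper,
        "seed": model.seed,
        "class_counts": model.class_counts,
        "forest": model.forest,
    }, path)


def load_model(path) -> RddPredictor:
    blob = joblib.load(path)
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {blob.get('format_version')}")
    return RddPredictor(forest=blob["forest"],
                        feature_order=blob["feature_order"],
                        hyper=blob["hyper"], seed=blob["seed"],
                        class_counts=blob["class_counts"])


# ---------------------------------------------------------------------------
# information gain and category ranking
# ---------------------------------------------------------------------------

def _entropy(labels: np.ndarray) -> float:
    """Shannon entropy in bits."""
    if len(labels) == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _bin_feature(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency discretization (duplicate quantile edges collapsed)."""
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.digitize(values, edges)


def information_gain_scores(ts: TrainingSet, n_bins: int = 10) -> pd.Series:
    """IG(attr) = H(class) - sum_bins p(bin) H(class | bin), in bits."""
    counts = ts.class_counts
    if min(counts.values(), default=0) < 2 or len(counts) < 2:
        raise ValueError(f"need >=2 examples per class, got {counts}")
    y = ts.labels()
    h_class = _entropy(y)
    X = ts.features()
    out = {}
    for j, name in enumerate(FEATURE_ORDER):
        bins = _bin_feature(X[:, j], n_bins=n_bins)
        cond = 0.0
        for b in np.unique(bins):
            mask = bins == b
            cond += mask.mean() * _entropy(y[mask])
        out[name] = max(0.0, h_class - cond)
    return pd.Series(out, name="IG")


def category_scores(ig: pd.Series, aggregate: str = "max") -> pd.Series:
    """One score per attribute category (default: max over member IGs)."""
    groups: Dict[str, List[float]] = {}
    for attr, val in ig.items():
        groups.setdefault(FEATURE_CATEGORY[attr], []).append(val)
    agg = max if aggregate == "max" else (lambda v: sum(v) / len(v))
    if aggregate not in ("max", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return pd.Series({cat: agg(vals) for cat, vals in groups.items()})


def importance_report(datasets: Sequence[TrainingSet], n_bins: int = 10,
                      aggregate: str = "max") -> pd.DataFrame:
    """Category ranking across one or more datasets.

    Columns: per-dataset IG score and rank (descending score, ties as mean
    ranks) plus RankMean across datasets.
    """
    if not datasets:
        raise ValueError("at least one dataset required")
    cols = {}
    ranks = []
    for i, ts in enumerate(datasets):
        label = chr(ord("A") + i)
        scores = category_scores(information_gain_scores(ts, n_bins=n_bins),
                                 aggregate=aggregate)
        rank = pd.Series(stats.rankdata(-scores.to_numpy(), method="average"),
                         index=scores.index)
        cols[f"Data{label}"] = scores
        cols[f"Rank{label}"] = rank
        ranks.append(rank)
    df = pd.DataFrame(cols)
    df["RankMean"] = sum(ranks) / len(ranks)
    return df.sort_values("RankMean")
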