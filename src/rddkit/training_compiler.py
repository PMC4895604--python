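"""Condition-specific training-set assembly.

Positives: candidates matching the known-editing-site consensus database.
Negatives: candidates falling on MES error-prone sites.  Candidates
matching both are dropped (ambiguous labels poison training); candidates on
a supplied test-exclusion list are withheld from training but remain
prediction targets, so evaluation sites never leak into the classifier.
Everything else is a prediction target.  The four bins partition the
candidate table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .io_formats import CandidateTable, FEATURE_ORDER
from .mes_artefacts import ErrorProneSiteSet
from .sites import EditingSiteDB

LABEL_POSITIVE = "positive"
LABEL_NEGATIVE = "negative"


class EmptyClassError(ValueError):
    """Raised when compilation leaves a training class empty."""


@dataclass
class TrainingSet:
    """Labeled feature vectors with label provenance."""

    df: pd.DataFrame          # site cols + features + label + label_source
    excluded: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def class_counts(self) -> Dict[str, int]:
        return self.df["label"].value_counts().to_dict()

    def features(self) -> np.ndarray:
        return self.df[FEATURE_ORDER].to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        return (self.df["label"] == LABEL_POSITIVE).to_numpy()


@dataclass
class PredictionTargets:
    """Candidate rows assigned to neither training label."""

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    def features(self) -> np.ndarray:
        return self.df[FEATURE_ORDER].to_numpy(dtype=float)


def _exclusion_index(test_exclusion: Iterable, window: int = 0) -> Set[Tuple[str, int]]:
    """Expand (chrom, pos) exclusion keys by a +-window-base margin."""
    out: Set[Tuple[str, int]] = set()
    for item in test_exclusion:
        chrom, pos = item[0], int(item[1])
        for p in range(pos - window, pos + window + 1):
            if p >= 1:
                out.add((chrom, p))
    return out


def compile(candidates: CandidateTable,
            positives: EditingSiteDB,
            negatives: ErrorProneSiteSet,
            test_exclusion: Iterable = (),
            match_mode: str = "class",
            window: int = 0,
            require_both_classes: bool = True
            ) -> Tuple[TrainingSet, PredictionTargets]:
    """Partition candidates into {positive, negative, conflict-excluded,
    target}; test-listed sites are excluded from training only and stay
    among the targets.

    Raises :class:`EmptyClassError` when a training class comes out empty
    (no classifier can be fit), unless ``require_both_classes`` is False.
    """
    if not candidates.has_features:
        raise ValueError("candidates must carry complete feature vectors")
    excl = _exclusion_index(test_exclusion, window=window)
    labels, sources = [], []
    n_conflict = n_test = 0
    for row in candidates.df.itertuples(index=False):
        key = (row.chrom, int(row.pos))
        is_pos = positives.matches(row.chrom, int(row.pos), row.ref, row.alt,
                                   mode=match_mode)
        is_neg = key in negatives
        if key in excl:
            # test exclusion wins: the site must stay a prediction target
            labels.append("target")
            sources.append("")
            if is_pos or is_neg:
                n_test += 1
        elif is_pos and is_neg:
            labels.append("conflict")
            sources.append("")
            n_conflict += 1
        elif is_pos:
            labels.append(LABEL_POSITIVE)
            sources.append("db_consensus")
        elif is_neg:
            labels.append(LABEL_NEGATIVE)
            sources.append("mes")
        else:
            labels.append("target")
            sources.append("")
    df = candidates.df.copy()
    df["label"] = labels
    df["label_source"] = sources
    train_df = df[df["label"].isin([LABEL_POSITIVE, LABEL_NEGATIVE])] \
        .reset_index(drop=True)
    target_df = df[df["label"] == "target"] \
        .drop(columns=["label", "label_source"]).reset_index(drop=True)
    ts = TrainingSet(df=train_df,
                     excluded={"test_overlap": n_test,
                               "label_conflict": n_conflict})
    counts = ts.class_counts
    if require_both_classes and (counts.get(LABEL_POSITIVE, 0) == 0
                                 or counts.get(LABEL_NEGATIVE, 0) == 0):
        raise EmptyClassError(
            f"training classes incomplete after compilation: {counts} "
            f"(excluded: {ts.excluded})")
    return ts, PredictionTargets(df=target_df)


def class_balance(ts: TrainingSet, strategy: str = "none",
                  seed: int = 0) -> TrainingSet:
    """Optionally downsample the majority class to the minority size
    (without replacement, seeded).  strategy='none' is the identity."""
    if strategy == "none":
        return ts
    if strategy != "downsample_majority":
        raise ValueError(f"unknown balance strategy {strategy!r}")
    counts = ts.class_counts
    if len(counts) < 2 or len(set(counts.values())) == 1:
        return ts
    minority = min(counts, key=counts.get)
    majority = max(counts, key=counts.get)
    rng = np.random.default_rng(seed)
    maj_df = ts.df[ts.df["label"] == majority]
    keep = rng.choice(len(maj_df), size=counts[minority], replace=False)
    sub = maj_df.iloc[np.sort(keep)]
    out = pd.concat([ts.df[ts.df["label"] == minority], sub]) \
        .sort_values(["chrom", "pos"]).reset_index(drop=True)
    return TrainingSet(df=out, excluded=dict(ts.excluded))


def write_training(ts: TrainingSet, path) -> None:
    cols = list(ts.df.columns)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        ts.df.to_csv(fh, sep="\t", header=False, index=False)


def read_training(path) -> TrainingSet:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")
        df = pd.read_csv(fh, sep="\t", names=header, dtype={"chrom": str},
                         float_precision="round_trip")
    missing = [c for c in FEATURE_ORDER + ["label"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return TrainingSet(df=df)
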