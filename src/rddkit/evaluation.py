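"""Evaluation metrics: reproduction rate, NPV, artefact reduction, folds.

All percentages are rounded half-up to two decimals, the convention of the
published figures these metrics mirror.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd


def round2(x) -> float:
    """Half-up rounding to two decimals (banker's rounding would disagree
    with the printed percentages on exact .xx5 boundaries)."""
    return float(Decimal(x).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _pct(numer: int, denom: int) -> float:
    return round2(Decimal(100 * numer) / Decimal(denom))


def reproduction_rate(n_reproduced: int, n_validated_pos: int) -> float:
    """Percentage of validated editing sites the classifier accepts."""
    if n_validated_pos <= 0:
        raise ValueError("n_validated_pos must be positive")
    if not 0 <= n_reproduced <= n_validated_pos:
        raise ValueError(f"need 0 <= {n_reproduced} <= {n_validated_pos}")
    return _pct(n_reproduced, n_validated_pos)


def npv(tn: int, fn: int) -> float:
    """Negative predictive value, in percent: TN / (TN + FN)."""
    if tn < 0 or fn < 0 or tn + fn == 0:
        raise ValueError("tn + fn must be positive")
    return _pct(tn, tn + fn)


def reduction(candidates: int, accepted: int) -> float:
    """Percentage of raw candidates rejected as potential artefacts."""
    if candidates <= 0 or not 0 <= accepted <= candidates:
        raise ValueError(f"need 0 <= {accepted} <= {candidates}, candidates > 0")
    return _pct(candidates - accepted, candidates)


def fold_compare(row_a: Sequence[int], row_b: Sequence[int],
                 columns: Sequence[str] = ()) -> pd.DataFrame:
    """Elementwise larger/smaller ratio between two count vectors, rounded
    to two decimals — the cross-condition Fold row."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    if any(v <= 0 for v in list(row_a) + list(row_b)):
        raise ValueError("counts must be positive")
    folds = [round2(Decimal(max(a, b)) / Decimal(min(a, b)))
             for a, b in zip(row_a, row_b)]
    cols = list(columns) if columns else [f"col{i}" for i in range(len(row_a))]
    return pd.DataFrame([list(row_a), list(row_b), folds], columns=cols,
                        index=["A", "B", "Fold"])


@dataclass
class EvaluationReport:
    n_validated_pos: int
    n_validated_neg: int
    n_reproduced: int      # validated positives accepted
    tn: int                # validated negatives rejected
    fn: int                # validated positives rejected
    n_unmatched: int       # validation sites absent from the predictions
    n_candidates: int
    n_accepted: int

    @property
    def reproduction_rate(self) -> float:
        return reproduction_rate(self.n_reproduced, self.n_validated_pos)

    @property
    def npv(self) -> float:
        return npv(self.tn, self.fn)

    @property
    def reduction(self) -> float:
        return reduction(self.n_candidates, self.n_accepted)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("validated_positives", self.n_validated_pos),
            ("validated_negatives", self.n_validated_neg),
            ("reproduced", self.n_reproduced),
            ("true_negatives", self.tn),
            ("false_negatives", self.fn),
            ("unmatched_validation_sites", self.n_unmatched),
            ("candidates", self.n_candidates),
            ("accepted", self.n_accepted),
            ("reproduction_rate_pct", self.reproduction_rate),
            ("npv_pct", self.npv),
            ("reduction_pct", self.reduction),
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])


def evaluate(predictions: pd.DataFrame,
             validation: Iterable[Tuple[str, int, str]],
             n_candidates: int = 0) -> EvaluationReport:
    """Join predictions against a labeled validation site list.

    ``validation`` rows are (chrom, pos, label) with label in
    {"positive", "negative"}.  Validation sites absent from the prediction
    set are counted separately, never silently dropped.
    """
    val = list(validation)
    if not val:
        raise ValueError("empty validation set")
    accepted = {(c, int(p)): bool(a) for c, p, a in
                zip(predictions["chrom"], predictions["pos"],
                    predictions["accepted"])}
    n_pos = n_neg = n_rep = tn = fn = unmatched = 0
    for chrom, pos, label in val:
        key = (chrom, int(pos))
        if label not in ("positive", "negative"):
            raise ValueError(f"bad validation label {label!r}")
        if key not in accepted:
            unmatched += 1
            continue
        if label == "positive":
            n_pos += 1
            if accepted[key]:
                n_rep += 1
            else:
                fn += 1
        else:
            n_neg += 1
            if not accepted[key]:
                tn += 1
    n_cand = n_candidates or len(predictions)
    n_acc = int(predictions["accepted"].sum()) if len(predictions) else 0
    return EvaluationReport(n_validated_pos=n_pos, n_validated_neg=n_neg,
                            n_reproduced=n_rep, tn=tn, fn=fn,
                            n_unmatched=unmatched,
                            n_candidates=n_cand, n_accepted=n_acc)


def read_validation(path) -> List[Tuple[str, int, str]]:
    """TSV of chrom, pos, label ('positive'/'negative'); '#' header line."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, pos, label = line.rstrip("\n").split("\t")[:3]
            out.append((chrom, int(pos), label))
    return out


def write_validation(rows: Iterable[Tuple[str, int, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tlabel\n")
        for chrom, pos, label in rows:
            fh.write(f"{chrom}\t{pos}\t{label}\n")
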