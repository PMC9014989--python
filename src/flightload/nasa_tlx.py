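"""Weighted NASA-TLX workload scoring.

The instrument has six dimensions — mental demand (MD), physical demand (PD),
temporal demand (TD), own performance (OP), effort (EF), frustration (FR) —
each rated on a 0–100 line. Weights come from 15 pairwise comparisons (one per
unordered dimension pair): a dimension's weight is the number of pairs it won,
so the weights are integers 0–5 summing to exactly 15. The overall workload
score is the weight-weighted mean of the ratings, Σ(rating·weight)/15.

Arithmetic is exact (``fractions.Fraction``) until the final 2-decimal
rounding. OP is used as marked; reverse-coding is an explicit opt-in flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import pandas as pd

from .errors import ValidationError

__all__ = ["DIMENSIONS", "ALL_PAIRS", "TLXRating", "TLXWeights", "TLXScore",
           "compute_weights", "weighted_score", "score_csv"]

DIMENSIONS = ("md", "pd", "td", "op", "ef", "fr")
ALL_PAIRS = tuple(combinations(DIMENSIONS, 2))  # 15 unordered pairs
N_PAIRS = len(ALL_PAIRS)


@dataclass(frozen=True)
class TLXRating:
    md: float
    pd: float
    td: float
    op: float
    ef: float
    fr: float

    def __post_init__(self):
        for d in DIMENSIONS:
            v = getattr(self, d)
            if not 0 <= v <= 100:
                raise ValidationError(f"rating {d}={v} outside [0, 100]")

    def as_dict(self) -> dict:
        return {d: getattr(self, d) for d in DIMENSIONS}


@dataclass(frozen=True)
class TLXWeights:
    md: int
    pd: int
    td: int
    op: int
    ef: int
    fr: int

    def __post_init__(self):
        total = 0
        for d in DIMENSIONS:
            v = getattr(self, d)
            if not (isinstance(v, int) and 0 <= v <= 5):
                raise ValidationError(f"weight {d}={v} must be an integer in [0, 5]")
            total += v
        if total != N_PAIRS:
            raise ValidationError(f"weights sum to {total}, must be exactly {N_PAIRS}")

    def as_dict(self) -> dict:
        return {d: getattr(self, d) for d in DIMENSIONS}


@dataclass(frozen=True)
class TLXScore:
    overall: float
    contributions: dict  # dimension -> rating*weight/15, rounded to 2 decimals


def compute_weights(pair_choices) -> TLXWeights:
    """Tally pairwise-comparison winners into dimension weights.

    ``pair_choices`` maps each unordered pair (tuple of two dimension codes,
    in any order) to the chosen winner. Exactly one choice per distinct pair
    is required and the winner must belong to its pair.
    """
    normalized = {}
    offending = []
    for pair, winner in dict(pair_choices).items():
        key = tuple(sorted(p.lower() for p in pair))
        if key not in {tuple(sorted(p)) for p in ALL_PAIRS}:
            offending.append(pair)
            continue
        if key in normalized:
            offending.append(pair)
            continue
        if winner.lower() not in key:
            offending.append(pair)
            continue
        normalized[key] = winner.lower()
    missing = [p for p in ALL_PAIRS if tuple(sorted(p)) not in normalized]
    if offending or missing:
        raise ValidationError(
            f"invalid pair choices; offending={offending!r}, missing={missing!r}"
        )
    tally = {d: 0 for d in DIMENSIONS}
    for winner in normalized.values():
        tally[winner] += 1
    return TLXWeights(**tally)


def weighted_score(rating: TLXRating, weights: TLXWeights) -> TLXScore:
    """Overall workload = Σ(rating·weight)/15, exact then rounded to 2 decimals."""
    total = Fraction(0)
    contributions = {}
    for d in DIMENSIONS:
        c = Fraction(getattr(rating, d)).limit_denominator(10**9) * getattr(weights, d) / N_PAIRS
        contributions[d] = float(round(c, 2))
        total += c
    return TLXScore(overall=float(round(total, 2)), contributions=contributions)


def score_csv(in_path, out_path=None) -> pd.DataFrame:
    """Score a CSV of one row per subject × condition.

    Expected columns: ``subject``, ``condition``, the six ratings (``md`` ...
    ``fr``), and 15 pair-choice columns named ``pair_<a>_<b>`` holding the
    winning dimension code.
    """
    df = pd.read_csv(in_path)
    rows = []
    for _, rec in df.iterrows():
        rating = TLXRating(**{d: float(rec[d]) for d in DIMENSIONS})
        choices = {}
        for a, b in ALL_PAIRS:
            col = f"pair_{a}_{b}"
            if col not in rec:
                raise ValidationError(f"missing pair-choice column {col!r}")
            choices[(a, b)] = str(rec[col])
        weights = compute_weights(choices)
        score = weighted_score(rating, weights)
        row = {"subject": rec["subject"], "condition": rec["condition"],
               "tlx_overall": score.overall}
        row.update({f"weight_{d}": getattr(weights, d) for d in DIMENSIONS})
        rows.append(row)
    out = pd.DataFrame(rows)
    if out_path is not None:
        out.to_csv(out_path, index=False)
    return out
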