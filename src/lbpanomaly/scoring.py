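"""Scoring and severity classification for ODI, DASS-21 and PCS-D.

All three instruments are scored deterministically from item-level
responses:

* **ODI** (Oswestry Disability Index): 10 items, each 0–5, individual items
  may be skipped.  The score is the answered-item sum expressed as a
  percentage of the maximum attainable over the answered items,
  ``100 * sum / (5 * n_answered)``, classified into five disability bands.
* **DASS-21**: 21 items, each 0–3, partitioned into three 7-item subscales
  (depression, anxiety, stress).  Each subscale sum is doubled so the score
  is comparable with the full 42-item DASS, then classified with
  subscale-specific severity cut points on the doubled (0–42) scale.
* **PCS-D** (daily Pain Catastrophizing Scale): 14 items, each 0–4, scored
  as the plain sum (0–56); no severity bands are defined here.

Severity bands are integer interval tables; a score is assigned to the
first band whose upper bound is greater than or equal to it, which also
gives a deterministic total mapping for fractional ODI percentages.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass
from typing import Optional, Sequence

from lbpanomaly.errors import ScoringError, ValidationError

__all__ = [
    "OdiScore",
    "DassScores",
    "PcsScore",
    "score_odi",
    "score_dass",
    "score_pcs",
    "score_cohort",
    "DASS_DEPRESSION_ITEMS",
    "DASS_ANXIETY_ITEMS",
    "DASS_STRESS_ITEMS",
    "ODI_BANDS",
    "DASS_BANDS",
]

# Standard DASS-21 item -> subscale assignment (0-based indices into the
# 21-item form; the questionnaire itself fixes this partition).
DASS_DEPRESSION_ITEMS: tuple[int, ...] = (2, 4, 9, 12, 15, 16, 20)
DASS_ANXIETY_ITEMS: tuple[int, ...] = (1, 3, 6, 8, 14, 18, 19)
DASS_STRESS_ITEMS: tuple[int, ...] = (0, 5, 7, 10, 11, 13, 17)

# Band tables: (upper bound, label), ascending.  A score lands in the first
# band whose upper bound >= score.
ODI_BANDS: tuple[tuple[float, str], ...] = (
    (20, "minimal"),
    (40, "moderate"),
    (60, "severe"),
    (80, "disabled"),
    (100, "bedridden"),
)

DASS_BANDS: dict[str, tuple[tuple[float, str], ...]] = {
    "stress": ((10, "normal"), (18, "mild"), (26, "moderate"),
               (34, "severe"), (42, "extremely severe")),
    "anxiety": ((6, "normal"), (9, "mild"), (14, "moderate"),
                (19, "severe"), (42, "extremely severe")),
    # The severe depression band runs 21-27 on the doubled scale.
    "depression": ((9, "normal"), (12, "mild"), (20, "moderate"),
                   (27, "severe"), (42, "extremely severe")),
}


@dataclass(frozen=True)
class OdiScore:
    """ODI result: disability percentage and severity band."""

    pct: float
    band: str
    n_answered: int


@dataclass(frozen=True)
class DassScores:
    """DASS-21 result: doubled subscale scores and per-subscale bands."""

    depression: int
    anxiety: int
    stress: int
    bands: dict[str, str]


@dataclass(frozen=True)
class PcsScore:
    """PCS-D result: total catastrophizing score, 0-56."""

    total: int


def _is_int(v) -> bool:
    return isinstance(v, numbers.Integral) and not isinstance(v, bool)


def _classify(score: float, bands: Sequence[tuple[float, str]]) -> str:
    for upper, label in bands:
        if score <= upper:
            return label
    raise ValidationError(f"score {score} above top band bound {bands[-1][0]}")


def score_odi(items: Sequence[Optional[int]]) -> OdiScore:
    """Score a 10-item ODI response; ``None`` entries are skipped items.

    Returns the disability percentage ``100 * sum / (5 * n_answered)`` and
    its severity band.  Raises :class:`ScoringError` if every item was
    skipped and :class:`ValidationError` for malformed responses.
    """
    if len(items) != 10:
        raise ValidationError(f"ODI expects 10 items, got {len(items)}")
    answered = [v for v in items if v is not None]
    for v in answered:
        if not _is_int(v) or not 0 <= v <= 5:
            raise ValidationError(f"ODI item value {v!r} outside 0..5")
    if not answered:
        raise ScoringError("ODI response with all 10 items skipped")
    pct = 100.0 * sum(answered) / (5.0 * len(answered))
    return OdiScore(pct=pct, band=_classify(pct, ODI_BANDS),
                    n_answered=len(answered))


def score_dass(items: Sequence[int]) -> DassScores:
    """Score a complete 21-item DASS-21 response.

    Each subscale score is twice the sum of its 7 items (0-42, always
    even); bands use the subscale-specific cut points on the doubled scale.
    """
    if len(items) != 21:
        raise ValidationError(f"DASS-21 expects 21 items, got {len(items)}")
    for v in items:
        if not _is_int(v) or not 0 <= v <= 3:
            raise ValidationError(f"DASS item value {v!r} outside 0..3")
    scores = {
        "depression": 2 * sum(items[i] for i in DASS_DEPRESSION_ITEMS),
        "anxiety": 2 * sum(items[i] for i in DASS_ANXIETY_ITEMS),
        "stress": 2 * sum(items[i] for i in DASS_STRESS_ITEMS),
    }
    bands = {k: _classify(s, DASS_BANDS[k]) for k, s in scores.items()}
    return DassScores(depression=scores["depression"],
                      anxiety=scores["anxiety"],
                      stress=scores["stress"],
                      bands=bands)


def score_cohort(cohort) -> "pd.DataFrame":
    """Score every subject of a cohort table.

    Expects the item columns ``odi_q1..odi_q10`` (blank = skipped),
    ``dass_q1..dass_q21`` and ``pcs_q1..pcs_q14``; returns one row per
    subject with ``id``, ``odi_pct``, ``odi_band``, ``dass_stress``,
    ``dass_anxiety``, ``dass_depression``, the three DASS bands and
    ``pcs_total``.
    """
    import pandas as pd

    odi_cols = [f"odi_q{i}" for i in range(1, 11)]
    dass_cols = [f"dass_q{i}" for i in range(1, 22)]
    pcs_cols = [f"pcs_q{i}" for i in range(1, 15)]
    missing = [c for c in odi_cols + dass_cols + pcs_cols
               if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort lacks item columns: {missing}")

    rows = []
    for _, rec in cohort.iterrows():
        odi_items = [None if pd.isna(rec[c]) else int(rec[c])
                     for c in odi_cols]
        odi = score_odi(odi_items)
        dass = score_dass([int(rec[c]) for c in dass_cols])
        pcs = score_pcs([int(rec[c]) for c in pcs_cols])
        rows.append({
            "id": rec["id"],
            "odi_pct": odi.pct,
            "odi_band": odi.band,
            "dass_stress": dass.stress,
            "dass_anxiety": dass.anxiety,
            "dass_depression": dass.depression,
            "dass_stress_band": dass.bands["stress"],
            "dass_anxiety_band": dass.bands["anxiety"],
            "dass_depression_band": dass.bands["depression"],
            "pcs_total": pcs.total,
        })
    return pd.DataFrame(rows)


def score_pcs(items: Sequence[int]) -> PcsScore:
    """Score a complete 14-item PCS-D response: total = sum, range 0-56."""
    if len(items) != 14:
        raise ValidationError(f"PCS-D expects 14 items, got {len(items)}")
    for v in items:
        if not _is_int(v) or not 0 <= v <= 4:
            raise ValidationError(f"PCS item value {v!r} outside 0..4")
    return PcsScore(total=sum(items))
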