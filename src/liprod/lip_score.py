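"""The low-input production (LI-P) scoring engine.

Each cow x date record is scored by quintile rank on 11 variables (yield,
fat+protein solids, SCC and the nine fatty-acid variables) plus a binary
untreated indicator. Records are allocated into five groups of equal
observations per variable and rated 1-5; for desirable variables the highest
group scores 5, for undesirable variables (SCC, saturated FAs, omega-6 and
the omega-6/omega-3 ratio) scoring is reversed. Components combine into a
production score out of 10, a health score out of 6 and an FA score out of
45, and the components into two weighted composites with a maximum of 1:

* health-weighted:     0.3 * production/10 + 0.5 * health/6 + 0.2 * FA/45
* production-weighted: 0.6 * production/10 + 0.3 * health/6 + 0.1 * FA/45

Breed groups are ranked by mean composite (rounded to the reported 2-decimal
precision), ties broken by lower standard deviation, then alphabetically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .herd_model import (
    FA_DESIRABLE,
    FA_UNDESIRABLE,
    HerdDataset,
    HerdError,
    filter_complete_records,
    DATE_CODES,
)

__all__ = [
    "HEALTH_WEIGHTS",
    "PRODUCTION_WEIGHTS",
    "QuintileScheme",
    "ScoreComponents",
    "BreedRanking",
    "ScoringError",
    "quintile_scores",
    "untreated_indicator",
    "score_frame",
    "component_scores",
    "weighted_composites",
    "rank_breeds",
]

#: (production, health, FA) weights of the two composites.
HEALTH_WEIGHTS: tuple[float, float, float] = (0.30, 0.50, 0.20)
PRODUCTION_WEIGHTS: tuple[float, float, float] = (0.60, 0.30, 0.10)

_COMPONENT_MAXIMA = (10.0, 6.0, 45.0)


class ScoringError(HerdError):
    """Scoring cannot proceed (insufficient or missing data)."""


@dataclass(frozen=True)
class QuintileScheme:
    """How one variable was cut into five equal-observation groups."""

    variable: str
    direction: Literal["desirable", "undesirable"]
    boundaries: tuple[int, ...]      # record-index cut points in sorted order
    scope: Literal["pooled", "per_date"] = "pooled"


@dataclass
class ScoreComponents:
    """Per-record quintile sub-scores, component totals and composites."""

    yield_q: int
    solids_q: int
    production_score: int        # out of 10
    scc_q: int
    untreated_flag: int
    health_score: int            # out of 6
    fa_quintiles: dict[str, int]
    fa_score: int                # out of 45
    weighted_health: float
    weighted_production: float


@dataclass
class BreedRanking:
    """Per-breed mean composite +- SD with 1 = best rank."""

    table: pd.DataFrame   # index: breed; columns: n, mean, sd, rank


def quintile_scores(
    values: Sequence[float] | np.ndarray,
    direction: Literal["desirable", "undesirable"],
    keys: Optional[Sequence] = None,
) -> np.ndarray:
    """Allocate records into five equal-observation groups and score 1-5.

    Records are sorted ascending (ties broken by the stable record key, which
    defaults to input position); the record at ordinal rank ``r`` of ``n``
    lands in group ``g = floor(5 r / n) + 1``. Desirable variables score
    ``g``; undesirable variables score ``6 - g``. Group sizes differ by at
    most one.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 5:
        raise ScoringError(f"need at least 5 records to form quintiles, got {n}")
    if np.isnan(x).any():
        raise ScoringError("missing values must be filtered before scoring")
    if direction not in ("desirable", "undesirable"):
        raise ScoringError(f"unknown direction {direction!r}")
    if keys is None:
        order = np.argsort(x, kind="stable")
    else:
        if len(keys) != n:
            raise ScoringError("keys must match values one-to-one")
        key_rank = np.empty(n, dtype=int)
        for r, i in enumerate(sorted(range(n), key=lambda i: keys[i])):
            key_rank[i] = r
        order = np.lexsort((key_rank, x))
    groups = np.empty(n, dtype=int)
    groups[order] = 5 * np.arange(n) // n + 1
    return groups if direction == "desirable" else 6 - groups


def untreated_indicator(treatments_n: int) -> int:
    """1 iff the cow received no treatments since the previous sampling date."""
    if treatments_n < 0:
        raise ScoringError(f"treatments_n must be >= 0, got {treatments_n}")
    return 1 if treatments_n == 0 else 0


def weighted_composites(production: float, health: float, fa: float) -> tuple[float, float]:
    """Health-weighted and production-weighted composites of the three
    component scores (production/10, health/6, FA/45)."""
    for name, v, hi, lo in (("production", production, 10, 2),
                            ("health", health, 6, 1),
                            ("fa", fa, 45, 9)):
        if not lo <= v <= hi:
            raise ScoringError(f"{name} component {v} outside [{lo}, {hi}]")
    parts = (production / 10.0, health / 6.0, fa / 45.0)
    wh = sum(w * p for w, p in zip(HEALTH_WEIGHTS, parts))
    wp = sum(w * p for w, p in zip(PRODUCTION_WEIGHTS, parts))
    return wh, wp


def score_frame(
    df: pd.DataFrame,
    scope: Literal["pooled", "per_date"] = "pooled",
) -> pd.DataFrame:
    """Score a DataFrame of complete records.

    Requires columns cow_id, date_code, yield_l_day, solids_kg_day,
    scc_kcells_ml, treatments_n and the nine FA variables. Returns a copy
    with quintile, component and composite columns appended. ``scope``
    controls whether quintile groups pool all records or are formed within
    each sampling date.
    """
    needed = ["cow_id", "date_code", "yield_l_day", "solids_kg_day",
              "scc_kcells_ml", "treatments_n", *FA_DESIRABLE, *FA_UNDESIRABLE]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ScoringError(f"score_frame missing column(s): {missing}")
    if df[needed].isna().any().any():
        raise ScoringError("records must be complete before scoring")
    if len(df) == 0:
        raise ScoringError("empty cohort: no complete records to score")

    out = df.copy()

    def _score_block(block_idx: np.ndarray) -> None:
        sub = out.loc[block_idx]
        k = list(zip(sub["cow_id"], sub["date_code"]))
        out.loc[block_idx, "yield_q"] = quintile_scores(sub["yield_l_day"], "desirable", k)
        out.loc[block_idx, "solids_q"] = quintile_scores(sub["solids_kg_day"], "desirable", k)
        out.loc[block_idx, "scc_q"] = quintile_scores(sub["scc_kcells_ml"], "undesirable", k)
        for var in FA_DESIRABLE:
            out.loc[block_idx, f"{var}_q"] = quintile_scores(sub[var], "desirable", k)
        for var in FA_UNDESIRABLE:
            out.loc[block_idx, f"{var}_q"] = quintile_scores(sub[var], "undesirable", k)

    if scope == "pooled":
        _score_block(out.index)
    elif scope == "per_date":
        for date in DATE_CODES:
            idx = out.index[out["date_code"] == date]
            if len(idx):
                _score_block(idx)
    else:
        raise ScoringError(f"unknown scope {scope!r}")

    q_cols = ["yield_q", "solids_q", "scc_q"] + [f"{v}_q" for v in (*FA_DESIRABLE, *FA_UNDESIRABLE)]
    out[q_cols] = out[q_cols].astype(int)
    out["untreated_flag"] = (out["treatments_n"] == 0).astype(int)
    out["production_score"] = out["yield_q"] + out["solids_q"]
    out["health_score"] = out["scc_q"] + out["untreated_flag"]
    out["fa_score"] = sum(out[f"{v}_q"] for v in (*FA_DESIRABLE, *FA_UNDESIRABLE))
    hw, pw = HEALTH_WEIGHTS, PRODUCTION_WEIGHTS
    parts = (out["production_score"] / 10.0, out["health_score"] / 6.0, out["fa_score"] / 45.0)
    out["weighted_health"] = sum(w * p for w, p in zip(hw, parts))
    out["weighted_production"] = sum(w * p for w, p in zip(pw, parts))
    return out


def component_scores(
    cohort: HerdDataset | pd.DataFrame,
    scope: Literal["pooled", "per_date"] = "pooled",
) -> list[ScoreComponents]:
    """Score a cohort of complete records, returning one ScoreComponents per
    record in input order."""
    if isinstance(cohort, HerdDataset):
        df = cohort.to_frame()
    else:
        df = cohort
    scored = score_frame(df, scope=scope)
    comps = []
    for _, row in scored.iterrows():
        comps.append(ScoreComponents(
            yield_q=int(row["yield_q"]), solids_q=int(row["solids_q"]),
            production_score=int(row["production_score"]),
            scc_q=int(row["scc_q"]), untreated_flag=int(row["untreated_flag"]),
            health_score=int(row["health_score"]),
            fa_quintiles={v: int(row[f"{v}_q"]) for v in (*FA_DESIRABLE, *FA_UNDESIRABLE)},
            fa_score=int(row["fa_score"]),
            weighted_health=float(row["weighted_health"]),
            weighted_production=float(row["weighted_production"]),
        ))
    return comps


def rank_breeds(
    scored: pd.DataFrame,
    composite: str = "weighted_health",
    breed_col: str = "breed_code",
) -> BreedRanking:
    """Rank breed groups by mean composite score.

    Breeds are ordered by mean composite rounded to 2 decimals (descending);
    where rounded means are equal the lower standard deviation ranks first,
    and any remaining ties break alphabetically.
    """
    if composite not in scored.columns:
        raise ScoringError(f"no composite column {composite!r}")
    grp = scored.groupby(breed_col)[composite]
    sizes = grp.size()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ScoringError(f"breed group(s) with fewer than 2 records: {small}")
    table = pd.DataFrame({
        "n": sizes,
        "mean": grp.mean(),
        "sd": grp.std(ddof=1),
    })
    order = sorted(
        table.index,
        key=lambda b: (-round(table.loc[b, "mean"], 2), table.loc[b, "sd"], b))
    table["rank"] = 0
    for r, b in enumerate(order, start=1):
        table.loc[b, "rank"] = r
    table = table.loc[order]
    return BreedRanking(table=table)


def score_dataset(
    dataset: HerdDataset,
    scope: Literal["pooled", "per_date"] = "pooled",
) -> pd.DataFrame:
    """Filter each date's complete records, pool them and score.

    Convenience wrapper mirroring the study flow: completeness filtering per
    date, then one scored long DataFrame over all dates.
    """
    frames = []
    for date in DATE_CODES:
        sub = filter_complete_records(dataset, date)
        if len(sub):
            frames.append(sub.to_frame())
    if not frames:
        raise ScoringError("empty cohort: no complete records on any date")
    pooled = pd.concat(frames, ignore_index=True)
    return score_frame(pooled, scope=scope)
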