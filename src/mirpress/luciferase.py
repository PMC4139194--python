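"""Dual-luciferase repression: plate values to percent repression.

Each construct carries a Renilla luciferase gene with a single perfectly
complementary miRNA target site in its 3'UTR and an untargeted firefly
luciferase as transfection control.  For each day of transfection the
construct's Renilla/firefly ratio is normalized to the empty vector's ratio
on the same day; percent repression is 100*(1 - mean of the normalized
ratios), and significance is a paired t-test of the per-day ratios against 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

EMPTY_ID = "EMPTY"
DEFAULT_ALPHA = 0.05

PLATE_COLUMNS = ("construct", "day", "renilla", "firefly")


@dataclass(frozen=True)
class PlateRecord:
    construct: str
    day: str
    renilla: float
    firefly: float

    def __post_init__(self) -> None:
        if not (self.renilla > 0 and self.firefly > 0):
            raise ValueError(
                f"{self.construct}/{self.day}: luminescence must be positive"
            )


@dataclass
class RepressionResult:
    """Percent repression of one reporter construct with its paired t-test."""

    construct: str
    day_ratios: dict[str, float]  # day -> normalized R/F ratio q_d
    repression_pct: float
    sd: float
    p_value: float
    significant: bool


def _plate_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    if (df["renilla"] <= 0).any() or (df["firefly"] <= 0).any():
        raise ValueError("luminescence readings must be positive")
    dup = df.duplicated(subset=["construct", "day"])
    if dup.any():
        pairs = df.loc[dup, ["construct", "day"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate plate records for {pairs}")
    return df


def repression_from_raw(
    records: pd.DataFrame | Sequence[PlateRecord],
    alpha: float = DEFAULT_ALPHA,
    empty_id: str = EMPTY_ID,
) -> list[RepressionResult]:
    """Compute per-construct percent repression from raw plate values.

    q_d = (Renilla/firefly)_construct,d / (Renilla/firefly)_empty,d.
    Repression % = 100*(1 - mean_d q_d); negative values (de-repression)
    are reported, not clamped.  The p-value is a two-sided one-sample
    t-test of the q_d against 1 (paired by transfection day); it requires
    at least two days and is NaN otherwise.  The empty construct itself is
    reported with exactly 0% repression and no test.
    """
    df = _plate_frame(records)
    empties = df[df["construct"] == empty_id].set_index("day")
    if empties.empty:
        raise ValueError(f"no {empty_id!r} records in plate table")
    empty_ratio = empties["renilla"] / empties["firefly"]
    results: list[RepressionResult] = []
    for construct, grp in df.groupby("construct", sort=False):
        days = list(grp["day"])
        missing = [d for d in days if d not in empty_ratio.index]
        if missing:
            raise ValueError(
                f"construct {construct!r}: no {empty_id!r} record on day(s) {missing}"
            )
        ratio = (grp["renilla"] / grp["firefly"]).to_numpy(dtype=float)
        q = ratio / empty_ratio.loc[days].to_numpy(dtype=float)
        if construct == empty_id:
            results.append(
                RepressionResult(
                    construct=construct,
                    day_ratios=dict(zip(days, q)),
                    repression_pct=0.0,
                    sd=0.0,
                    p_value=float("nan"),
                    significant=False,
                )
            )
            continue
        per_day_repr = 100.0 * (1.0 - q)
        repression = float(np.mean(per_day_repr))
        sd = float(np.std(per_day_repr, ddof=1)) if len(q) > 1 else 0.0
        if len(q) >= 2 and np.ptp(q) > 0:
            p = float(stats.ttest_1samp(q, popmean=1.0).pvalue)
        elif len(q) >= 2:
            # zero variance: identical ratios every day
            p = 0.0 if q[0] != 1.0 else float("nan")
        else:
            p = float("nan")
        results.append(
            RepressionResult(
                construct=str(construct),
                day_ratios=dict(zip(days, q)),
                repression_pct=repression,
                sd=sd,
                p_value=p,
                significant=bool(p < alpha) if np.isfinite(p) else False,
            )
        )
    return results


def count_nonsignificant(
    results: Sequence[RepressionResult], empty_id: str = EMPTY_ID
) -> tuple[int, list[str]]:
    """Constructs whose repression is not distinguishable from the empty vector."""
    if not results:
        raise ValueError("no repression results")
    names = [
        r.construct
        for r in results
        if r.construct != empty_id and not r.significant
    ]
    return len(names), names


def results_to_frame(results: Sequence[RepressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "construct": r.construct,
                "repression_pct": r.repression_pct,
                "sd": r.sd,
                "p_value": r.p_value,
                "significant": r.significant,
            }
            for r in results
        ]
    ).set_index("construct")
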