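"""RT record cleaning: item eligibility filters, per-item percentile trimming,
and the log transform.

Eligibility rules mirror standard paradata practice for web panels: items must
be presented alone on a page (per-screen timestamps are otherwise shared),
must be closed-ended, and must have been completed by at least 75% of the
survey's respondents.  Per item, RTs above the 99th percentile across
respondents are removed as extreme outliers (respondents stepping away from
the screen), and the remaining RTs are natural-log transformed with sub-second
times floored at 1 s, so log RTs are non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "filter_items",
    "trim_rts",
    "trim_thresholds",
    "log_transform",
    "filter_min_surveys",
    "preprocess",
]


@dataclass
class FilterReport:
    """Record counts kept/dropped by each eligibility rule."""

    n_input: int = 0
    dropped_multi_page: int = 0
    dropped_open_ended: int = 0
    dropped_low_completion: int = 0
    n_kept: int = 0
    items_dropped: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "dropped_multi_page": self.dropped_multi_page,
            "dropped_open_ended": self.dropped_open_ended,
            "dropped_low_completion": self.dropped_low_completion,
            "n_kept": self.n_kept,
        }


def filter_items(
    records: pd.DataFrame,
    item_meta: pd.DataFrame,
    min_completion: float = 0.75,
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep records only for eligible items.

    An item is eligible when it was shown alone on a page (``single_page==1``),
    is closed-ended (``open_ended==0``), and its completion rate — responders
    to the item divided by responders to any item of the same survey — is at
    least ``min_completion``.  Rules are applied in that order for reporting.
    """
    meta = item_meta.set_index("item_id")
    unknown = set(records["item_id"].unique()) - set(meta.index)
    if unknown:
        raise KeyError(
            f"records reference {len(unknown)} item_ids missing from item_meta: "
            f"{sorted(unknown)[:10]}"
        )

    rep = FilterReport(n_input=len(records))
    rec = records.merge(
        item_meta[["item_id", "survey_id", "single_page", "open_ended"]].rename(
            columns={"survey_id": "_meta_survey"}),
        on="item_id", how="left",
    )

    multi = rec["single_page"] != 1
    rep.dropped_multi_page = int(multi.sum())
    rec = rec[~multi]

    open_ended = rec["open_ended"] != 0
    rep.dropped_open_ended = int(open_ended.sum())
    rec = rec[~open_ended]

    # completion rate: responders(item) / responders(survey), computed on the
    # records that survived the layout rules
    survey_resp = rec.groupby("survey_id")["person_id"].nunique()
    item_resp = rec.groupby(["survey_id", "item_id"])["person_id"].nunique()
    rate = item_resp / survey_resp.reindex(
        item_resp.index.get_level_values("survey_id")
    ).to_numpy()
    low_items = set(rate[rate < min_completion].index.get_level_values("item_id"))
    low = rec["item_id"].isin(low_items)
    rep.dropped_low_completion = int(low.sum())
    rec = rec[~low]

    rep.n_kept = len(rec)
    rep.items_dropped = {
        "multi_page": sorted(records.loc[records["item_id"].map(meta["single_page"]) != 1,
                                         "item_id"].unique().tolist()),
        "open_ended": sorted(records.loc[records["item_id"].map(meta["open_ended"]) != 0,
                                         "item_id"].unique().tolist()),
        "low_completion": sorted(low_items),
    }
    return rec.drop(columns=["single_page", "open_ended", "_meta_survey"]), rep


def trim_rts(
    records: pd.DataFrame,
    percentile: float = 0.99,
    thresholds: pd.Series | None = None,
) -> pd.DataFrame:
    """Per item, remove records with ``rt_seconds`` strictly above the
    empirical ``percentile`` quantile (linear-interpolation / type-7).

    Passing precomputed per-item ``thresholds`` (a Series indexed by item_id,
    as produced by :func:`trim_thresholds`) applies those instead; re-applying
    the same thresholds removes nothing.  Never removes records at or below
    the threshold.
    """
    if thresholds is None:
        thresholds = trim_thresholds(records, percentile)
    keep = records["rt_seconds"] <= thresholds.reindex(records["item_id"]).to_numpy()
    return records[keep]


def trim_thresholds(records: pd.DataFrame, percentile: float = 0.99) -> pd.Series:
    """Per-item trim thresholds: the type-7 empirical quantile of rt_seconds."""
    if not 0.0 < percentile < 1.0:
        raise ValueError(f"percentile must be in (0, 1), got {percentile}")
    return records.groupby("item_id")["rt_seconds"].quantile(percentile)


def log_transform(records: pd.DataFrame, sub_second: str = "floor") -> pd.DataFrame:
    """Append ``log_rt = ln(rt_seconds)`` with sub-second RTs floored at 1 s
    (``sub_second="floor"``, the default) or dropped (``sub_second="drop"``).
    """
    if (records["rt_seconds"] <= 0).any():
        bad = int((records["rt_seconds"] <= 0).sum())
        raise ValueError(f"{bad} records have non-positive rt_seconds")
    if sub_second == "drop":
        records = records[records["rt_seconds"] >= 1.0]
    elif sub_second != "floor":
        raise ValueError("sub_second must be 'floor' or 'drop'")
    out = records.copy()
    out["log_rt"] = np.log(np.maximum(out["rt_seconds"].to_numpy(), 1.0))
    return out


def filter_min_surveys(records: pd.DataFrame, min_surveys: int = 5) -> pd.DataFrame:
    """Keep persons who responded in at least ``min_surveys`` distinct surveys."""
    n = records.groupby("person_id")["survey_id"].nunique()
    keep = n[n >= min_surveys].index
    return records[records["person_id"].isin(keep)]


def preprocess(
    records: pd.DataFrame,
    item_meta: pd.DataFrame,
    min_completion: float = 0.75,
    trim_percentile: float = 0.99,
    min_surveys: int = 5,
    sub_second: str = "floor",
) -> tuple[pd.DataFrame, FilterReport]:
    """Full cleaning pipeline: item filters -> person min-survey filter ->
    per-item trim -> log transform.  Never alters ``rt_seconds`` of retained
    records."""
    rec, report = filter_items(records, item_meta, min_completion)
    rec = filter_min_surveys(rec, min_surveys)
    rec = trim_rts(rec, trim_percentile)
    rec = log_transform(rec, sub_second=sub_second)
    return rec, report
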