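"""Site co-occupancy summaries, pair-visit statistics, and camera
operability accounting.

"Occupied" means at least one independent visit of the species at the site
within the scope (one winter, or all winters pooled).  The two directional
co-occupancy percentages (share of A-occupied sites also used by B, and
vice versa) are distinct quantities and need not agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class CooccupancySummary:
    scope: str
    sites_with_a: int
    sites_with_b: int
    sites_with_both: int
    pct_a_sites_coused: float | None  # 100 * both / sites_with_a
    pct_b_sites_coused: float | None


@dataclass
class PairVisitStats:
    n_images: int
    n_pair_images: int
    n_visits: int
    n_pair_visits: int
    pct_pair_images: float | None
    pct_pair_visits: float | None


@dataclass
class OperabilityReport:
    site_days_surveyed: int
    site_days_inoperable: int
    inoperable_rate_pct: float
    max_continuous_inoperable_days: int


def cooccupancy(
    visits: pd.DataFrame,
    species_a: str = "marten",
    species_b: str = "fisher",
    scope: str = "pooled",
) -> list[CooccupancySummary]:
    """Directional co-occupancy percentages.

    ``scope='pooled'`` gives one summary over all winters; ``'per_winter'``
    one per ``year_label``.  A percentage is None when the denominator
    (occupied sites of that species) is zero.
    """
    if scope not in ("pooled", "per_winter"):
        raise ValueError("scope must be 'pooled' or 'per_winter'")
    groups = [("pooled", visits)] if scope == "pooled" else sorted(visits.groupby("year_label"), key=lambda t: t[0])
    out = []
    for label, g in groups:
        sites_a = set(g.loc[g["species"] == species_a, "site_id"])
        sites_b = set(g.loc[g["species"] == species_b, "site_id"])
        both = sites_a & sites_b
        out.append(
            CooccupancySummary(
                scope=str(label),
                sites_with_a=len(sites_a),
                sites_with_b=len(sites_b),
                sites_with_both=len(both),
                pct_a_sites_coused=100.0 * len(both) / len(sites_a) if sites_a else None,
                pct_b_sites_coused=100.0 * len(both) / len(sites_b) if sites_b else None,
            )
        )
    return out


def pair_visit_stats(visits: pd.DataFrame, detections: pd.DataFrame, species: str = "marten") -> PairVisitStats:
    """Counts and shares of multi-individual images and visits for one species.

    A pair visit is a visit containing at least one image with
    ``n_individuals >= 2``.
    """
    det = detections[detections["species"] == species]
    vis = visits[visits["species"] == species]
    pair_ids = set(det.loc[det["n_individuals"] >= 2, "image_id"])
    n_pair_images = len(pair_ids)
    n_pair_visits = int(vis["image_ids"].apply(lambda ids: any(i in pair_ids for i in ids)).sum()) if len(vis) else 0
    return PairVisitStats(
        n_images=len(det),
        n_pair_images=n_pair_images,
        n_visits=len(vis),
        n_pair_visits=n_pair_visits,
        pct_pair_images=100.0 * n_pair_images / len(det) if len(det) else None,
        pct_pair_visits=100.0 * n_pair_visits / len(vis) if len(vis) else None,
    )


def operability(intervals: pd.DataFrame) -> OperabilityReport:
    """Site-day totals, inoperable rate, and the longest inoperable run.

    Interval dates are inclusive on both ends; within a (site, winter),
    inoperable intervals that touch or abut (next start <= previous end +
    1 day) are merged before measuring the maximum continuous run.
    """
    days = (pd.to_datetime(intervals["end"]) - pd.to_datetime(intervals["start"])).dt.days + 1
    surveyed = int(days.sum())
    inop = intervals[~intervals["operable"].astype(bool)]
    inoperable = int(days[inop.index].sum())
    max_run = 0
    for _, g in inop.groupby(["site_id", "year_label"], sort=False):
        g = g.sort_values("start")
        run_start, run_end = None, None
        for _, row in g.iterrows():
            s, e = pd.to_datetime(row["start"]), pd.to_datetime(row["end"])
            if run_end is not None and s <= run_end + pd.Timedelta(days=1):
                run_end = max(run_end, e)
            else:
                if run_end is not None:
                    max_run = max(max_run, (run_end - run_start).days + 1)
                run_start, run_end = s, e
        if run_end is not None:
            max_run = max(max_run, (run_end - run_start).days + 1)
    rate = 100.0 * inoperable / surveyed if surveyed else 0.0
    return OperabilityReport(
        site_days_surveyed=surveyed,
        site_days_inoperable=inoperable,
        inoperable_rate_pct=rate,
        max_continuous_inoperable_days=max_run,
    )
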