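"""Visit segmentation, interference-displacement detection, and the
peri-event histogram of subordinate-species site use around dominant-species
presence.

A *visit* is a maximal run of same-species detections at a site in which
consecutive images are separated by less than the independence gap
(default 30 min); a gap of the full independence interval or more starts a
new, independent visit.

A *displacement event* is scored when the last image of one species' visit
is followed, at the same site, by the first image of the other species'
visit within the displacement window (default 10 min), and the displaced
species records no image for a full independence gap after the displacer's
arrival — i.e. it left and did not come back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

class UnsortedInputError(ValueError):
    """Detection stream is not time-sorted within a (site, species) group."""


def segment_visits(detections: pd.DataFrame, gap_min: float = 30.0) -> pd.DataFrame:
    """Partition detections into independent visits per (site, species).

    Input must already be sorted by timestamp within each (site, species)
    stream; unsorted input raises :class:`UnsortedInputError` rather than
    being silently reordered.  An inter-image gap >= ``gap_min`` starts a
    new visit (a gap of exactly the threshold counts as independent).

    Returns a DataFrame with columns ``site_id, species, year_label, start,
    end, n_images, image_ids`` where ``image_ids`` is the ordered list of
    member images.  Every input record belongs to exactly one visit.
    """
    if detections.empty:
        return pd.DataFrame(
            columns=["site_id", "species", "year_label", "start", "end", "n_images", "image_ids"]
        )
    df = detections.sort_values(["site_id", "species"], kind="mergesort").reset_index(drop=True)
    ts = df["timestamp"].to_numpy()
    same_group = (df["site_id"].to_numpy()[1:] == df["site_id"].to_numpy()[:-1]) & (
        df["species"].to_numpy()[1:] == df["species"].to_numpy()[:-1]
    )
    diffs = np.diff(ts)
    if (same_group & (diffs < np.timedelta64(0, "s"))).any():
        i = int(np.flatnonzero(same_group & (diffs < np.timedelta64(0, "s")))[0])
        raise UnsortedInputError(
            f"detections for site {df['site_id'].iloc[i]}, species {df['species'].iloc[i]} are not time-sorted"
        )
    gap_ns = np.timedelta64(int(round(gap_min * 60_000_000_000)), "ns")
    breaks = np.concatenate(([True], ~same_group | (diffs >= gap_ns)))
    df = df.assign(_visit=np.cumsum(breaks) - 1)
    out = (
        df.groupby("_visit", sort=True)
        .agg(
            site_id=("site_id", "first"),
            species=("species", "first"),
            year_label=("year_label", "first"),
            start=("timestamp", "first"),
            end=("timestamp", "last"),
            n_images=("timestamp", "size"),
            image_ids=("image_id", list),
        )
        .reset_index(drop=True)
    )
    return out.sort_values(["site_id", "species", "start"], kind="mergesort").reset_index(drop=True)


def detect_displacements(
    detections: pd.DataFrame,
    window_min: float = 10.0,
    gap_min: float = 30.0,
) -> pd.DataFrame:
    """Find interference-displacement events between the two focal species.

    For each visit of species A ending at time ``t_A``, an event is emitted
    if the first image of a species-B visit occurs in ``(t_A, t_A + window]``
    and species A records no image at the site within ``gap_min`` after B's
    arrival.  Each A-visit yields at most one event (the earliest qualifying
    B arrival).

    Returns columns ``site_id, year_label, displaced_species,
    displacer_species, last_displaced_time, first_displacer_time, gap_min``.
    """
    visits = segment_visits(detections, gap_min=gap_min)
    window = np.timedelta64(int(round(window_min * 60_000_000_000)), "ns")
    independence = np.timedelta64(int(round(gap_min * 60_000_000_000)), "ns")
    events = []
    det_sorted = detections.sort_values(["site_id", "species", "timestamp"], kind="mergesort")
    times_lookup = {
        key: g["timestamp"].to_numpy()
        for key, g in det_sorted.groupby(["site_id", "species"], sort=False)
    }
    for site, vsite in visits.groupby("site_id", sort=True):
        species_present = sorted(vsite["species"].unique())
        if len(species_present) < 2:
            continue
        by_sp = {
            sp: vsite[vsite["species"] == sp].reset_index(drop=True) for sp in species_present
        }
        for a in species_present:
            va = by_sp[a]
            a_ends = va["end"].to_numpy()
            a_times = times_lookup[(site, a)]
            # earliest heterospecific visit start after each A-visit end
            cand_start = np.full(len(va), np.datetime64("NaT"), dtype="datetime64[ns]")
            cand_species = np.empty(len(va), dtype=object)
            for b in species_present:
                if b == a:
                    continue
                b_starts = by_sp[b]["start"].to_numpy()
                pos = np.searchsorted(b_starts, a_ends, side="right")
                valid = pos < len(b_starts)
                starts = np.where(valid, b_starts[np.minimum(pos, len(b_starts) - 1)], np.datetime64("NaT"))
                better = valid & (np.isnat(cand_start) | (starts < cand_start))
                cand_start[better] = starts[better]
                cand_species[better] = b
            for i in range(len(va)):
                sb = cand_start[i]
                if np.isnat(sb) or sb - a_ends[i] > window:
                    continue
                lo = np.searchsorted(a_times, sb, side="right")
                hi = np.searchsorted(a_times, sb + independence, side="right")
                if hi > lo:  # A returned within the independence gap
                    continue
                events.append(
                    {
                        "site_id": site,
                        "year_label": va["year_label"].iloc[i],
                        "displaced_species": a,
                        "displacer_species": cand_species[i],
                        "last_displaced_time": va["end"].iloc[i],
                        "first_displacer_time": pd.Timestamp(sb),
                        "gap_min": float((sb - a_ends[i]) / np.timedelta64(60, "s")),
                    }
                )
    out = pd.DataFrame(
        events,
        columns=[
            "site_id",
            "year_label",
            "displaced_species",
            "displacer_species",
            "last_displaced_time",
            "first_displacer_time",
            "gap_min",
        ],
    )
    return out.sort_values(["site_id", "first_displacer_time"]).reset_index(drop=True)


@dataclass
class PeriEventHistogram:
    """Counts of target-species images by time offset around reference-species presence.

    ``bin_edges`` are minutes relative to the reference (negative = before
    arrival, positive = after departure under the default 'interval'
    convention); ``counts[i]`` covers ``[bin_edges[i], bin_edges[i+1])``.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_reference_events: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_min": self.bin_edges[:-1],
                "bin_end_min": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def peri_event_histogram(
    target: pd.DataFrame,
    reference: pd.DataFrame,
    bin_min: float = 5.0,
    halfwidth_min: float = 120.0,
    gap_min: float = 30.0,
    convention: str = "interval",
) -> PeriEventHistogram:
    """Histogram of target-species image offsets around reference-species visits.

    Under the default ``'interval'`` convention, time is measured relative
    to the reference-presence interval: target images before a reference
    visit's first image get negative offsets to that arrival; images after
    its last image get positive offsets from that departure; images during
    the reference presence are excluded.  Under ``'arrival'``, all offsets
    are measured from the visit's first image.  Each (target image,
    reference visit) pair within the half-width contributes one count, so
    the counts sum to the number of in-window contributions.
    """
    if convention not in ("interval", "arrival"):
        raise ValueError("convention must be 'interval' or 'arrival'")
    edges = np.arange(-halfwidth_min, halfwidth_min + bin_min, bin_min)
    ref_visits = segment_visits(reference, gap_min=gap_min)
    if ref_visits.empty:
        return PeriEventHistogram(edges, np.zeros(len(edges) - 1, dtype=int), 0)
    offsets: list[float] = []
    for site, rv in ref_visits.groupby("site_id", sort=True):
        tt = target.loc[target["site_id"] == site, "timestamp"].to_numpy()
        if len(tt) == 0:
            continue
        for _, v in rv.iterrows():
            start, end = np.datetime64(v["start"]), np.datetime64(v["end"])
            rel_start = (tt - start) / np.timedelta64(60, "s")
            if convention == "arrival":
                sel = (rel_start >= -halfwidth_min) & (rel_start < halfwidth_min)
                offsets.extend(rel_start[sel])
            else:
                rel_end = (tt - end) / np.timedelta64(60, "s")
                before = (rel_start >= -halfwidth_min) & (rel_start < 0)
                after = (rel_end > 0) & (rel_end <= halfwidth_min)
                offsets.extend(rel_start[before])
                offsets.extend(rel_end[after])
    counts, _ = np.histogram(offsets, bins=edges)
    return PeriEventHistogram(edges, counts.astype(int), int(len(ref_visits)))
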