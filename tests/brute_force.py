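"""Independent brute-force implementations of the event rules, used as
oracles.  Written as literal transcriptions of the definitions over plain
Python lists — deliberately sharing no code with the package.
"""

from __future__ import annotations


def brute_visits(times: list[float], gap: float) -> list[list[float]]:
    """Group sorted times into visits: a gap >= `gap` starts a new visit."""
    visits: list[list[float]] = []
    for t in sorted(times):
        if visits and t - visits[-1][-1] < gap:
            visits[-1].append(t)
        else:
            visits.append([t])
    return visits


def brute_displacements(
    stream: list[tuple[float, str]], window: float, gap: float
) -> list[tuple[str, str, float, float]]:
    """All displacement events in a single-site stream of (time, species).

    An event (displaced, displacer, last_displaced_time, first_displacer_time)
    occurs when the last image of a species-A visit is followed by the first
    image of a species-B visit within `window` minutes, and A has no image in
    the `gap` minutes after B's arrival.  At most one event per A-visit (the
    earliest qualifying B arrival).
    """
    species = sorted({sp for _, sp in stream})
    by_species = {sp: sorted(t for t, s in stream if s == sp) for sp in species}
    visits = {sp: brute_visits(by_species[sp], gap) for sp in species}
    events = []
    for a in species:
        for va in visits[a]:
            end_a = va[-1]
            candidates = []
            for b in species:
                if b == a:
                    continue
                for vb in visits[b]:
                    start_b = vb[0]
                    if end_a < start_b <= end_a + window:
                        a_returned = any(
                            start_b < t <= start_b + gap for t in by_species[a]
                        )
                        if not a_returned:
                            candidates.append((start_b, a, b))
            if candidates:
                start_b, a_, b_ = min(candidates)
                events.append((a_, b_, end_a, start_b))
    return sorted(events, key=lambda e: (e[3], e[0]))
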