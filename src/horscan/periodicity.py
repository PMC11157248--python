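"""Repeat periodicity: MD points, GRM histogram, and MD-line segments.

The *period* of a monomer is the distance, in monomer units, to the next
monomer of the same family along the enumeration.  The set of
(enumeration index, period) pairs is the MD (monomer distance) diagram;
its histogram over periods is the GRM (global repeat map) diagram.  A
peak of period *n* marks an *n*-mer HOR; dense horizontal runs of MD
points (MD-line segments) localise the HOR array along the enumeration,
and shorter co-located segments are subfragments (intra- or inter-copy
same-type distances within a cascading HOR).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "MDPoint",
    "MDSegment",
    "compute_md_points",
    "grm_histogram",
    "detect_segments",
    "classify_segments",
]


@dataclass(frozen=True)
class MDPoint:
    index: int
    period: int


@dataclass
class MDSegment:
    """A dense horizontal run of MD points at one period."""

    period: int
    start_index: int
    end_index: int
    support: int
    kind: str = ""  # "HOR" or "subfragment", set by classify_segments

    def overlap_fraction(self, other: "MDSegment") -> float:
        inter = min(self.end_index, other.end_index) - max(
            self.start_index, other.start_index
        )
        if inter <= 0:
            return 0.0
        shorter = min(
            self.end_index - self.start_index, other.end_index - other.start_index
        )
        return inter / max(shorter, 1)


def compute_md_points(
    labels: Sequence[int], max_period: int = 50
) -> list[MDPoint]:
    """MD points for an ordered family-label sequence.

    For each monomer *i*, if the next monomer *j* of the same family
    satisfies ``j - i <= max_period``, emit the point ``(i, j - i)``.
    The last occurrence of each family emits nothing.
    """
    nxt: dict[int, int] = {}
    points: list[MDPoint] = []
    for i in range(len(labels) - 1, -1, -1):
        lab = labels[i]
        j = nxt.get(lab)
        if j is not None and j - i <= max_period:
            points.append(MDPoint(i, j - i))
        nxt[lab] = i
    points.reverse()
    return points


def grm_histogram(points: Iterable[MDPoint]) -> dict[int, int]:
    """Period -> frequency histogram (the GRM diagram)."""
    return dict(sorted(Counter(p.period for p in points).items()))


def detect_segments(
    points: Sequence[MDPoint],
    min_support: int = 10,
    max_gap: int | None = None,
) -> list[MDSegment]:
    """Split each period's points into dense runs.

    Points of one period belong to the same segment while consecutive
    indices differ by at most ``max_gap``; runs with fewer than
    ``min_support`` points are discarded.  The default gap is
    ``max(5 * period, 50)``: 5x the period for HOR-scale periods, with a
    floor of 50 enumeration units so that subfragment periods whose
    points recur only once per HOR copy (spacing ~ the HOR period, e.g.
    the period-2 doublet inside a 17mer) still chain into one segment.
    """
    by_period: dict[int, list[int]] = {}
    for p in points:
        by_period.setdefault(p.period, []).append(p.index)
    segments: list[MDSegment] = []
    for period in sorted(by_period):
        idxs = sorted(by_period[period])
        gap = max_gap if max_gap is not None else max(5 * period, 50)
        run = [idxs[0]]
        for x in idxs[1:]:
            if x - run[-1] > gap:
                if len(run) >= min_support:
                    segments.append(
                        MDSegment(period, run[0], run[-1] + period, len(run))
                    )
                run = []
            run.append(x)
        if len(run) >= min_support:
            segments.append(MDSegment(period, run[0], run[-1] + period, len(run)))
    segments.sort(key=lambda s: (s.start_index, -s.support))
    return segments


def classify_segments(
    segments: list[MDSegment], min_overlap: float = 0.5
) -> list[MDSegment]:
    """Label each segment as the HOR of its interval or a subfragment.

    Among segments whose enumeration intervals overlap by at least
    ``min_overlap`` (fraction of the shorter interval), the one with the
    greatest support is the HOR; the co-located others are subfragments.
    Segments overlapping nothing are each the HOR of their own interval.
    Classification mutates and returns ``segments``.
    """
    order = sorted(
        range(len(segments)),
        key=lambda i: (-segments[i].support, segments[i].period),
    )
    for i in order:
        seg = segments[i]
        if seg.kind:
            continue
        seg.kind = "HOR"
        for j in order:
            other = segments[j]
            if other.kind or j == i:
                continue
            if seg.overlap_fraction(other) >= min_overlap:
                other.kind = "subfragment"
    return segments
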