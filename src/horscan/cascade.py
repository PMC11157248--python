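"""Cascading HOR schemes: canonical units, copy partition, row layout.

A higher-order repeat (HOR) is a unit of *n* monomers repeated in tandem.
In a *Willard's type* HOR every monomer type occurs once per canonical
copy (tau = n); in a *cascading* HOR at least one type repeats within the
canonical copy (tau < n).  A cascading copy is displayed as a multi-row
scheme: monomers are placed in columns fixed by the canonical type
ordering, and a new row starts whenever the column order would be broken,
so that every row reads left-to-right through strictly increasing columns
and monomers of one type align vertically.

Copies are classified canonical (label sequence equals the canonical unit
exactly) or variant, with a row signature such as ``15 + 2`` (canonical
17mer), ``15 + 15 + 2`` (duplicated first row) or ``(6 + 4)+2`` (a row
with a deleted middle block, written as its contiguous column runs).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .periodicity import (
    classify_segments,
    compute_md_points,
    detect_segments,
)
from .scan import Monomer

__all__ = [
    "ArraySegment",
    "CanonicalUnit",
    "HORCopy",
    "segment_arrays",
    "infer_canonical_unit",
    "partition_copies",
    "cascade_layout",
    "summarize_array",
    "render_scheme",
]


@dataclass
class ArraySegment:
    """A maximal tandemly-organised run of monomers."""

    start_index: int
    end_index: int  # exclusive, in monomer enumeration
    hor_period: int | None = None
    subfragment_periods: tuple[int, ...] = ()
    start_bp: int = -1  # 0-based inclusive
    end_bp: int = -1  # 0-based exclusive

    @property
    def n_monomers(self) -> int:
        return self.end_index - self.start_index


@dataclass(frozen=True)
class CanonicalUnit:
    """The canonical HOR copy as an ordered family-label sequence."""

    type_sequence: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.type_sequence)

    @property
    def tau(self) -> int:
        return len(set(self.type_sequence))

    @property
    def is_cascading(self) -> bool:
        return self.tau < self.n


@dataclass
class HORCopy:
    """One repeat-unit instance: a run of monomers with its row layout."""

    start_index: int
    end_index: int
    status: str  # "canonical" or "variant"
    rows: list[list[tuple[int, int]]] = field(default_factory=list)
    # rows of (enumeration index, column); columns are 0-based
    signature: str = ""

    @property
    def n_monomers(self) -> int:
        return self.end_index - self.start_index


def segment_arrays(
    monomers: Sequence[Monomer],
    labels: Sequence[int],
    max_gap_bp: int = 2000,
    min_support: int = 10,
    max_period: int = 50,
) -> list[ArraySegment]:
    """Split the monomer enumeration into arrays at large genomic gaps.

    Consecutive monomers separated by more than ``max_gap_bp`` start a new
    array.  Each array is annotated with its HOR period (the top MD-line
    segment of its interval) and subfragment periods, computed on the
    array's own label slice.
    """
    if not monomers:
        return []
    segments: list[ArraySegment] = []
    run_start = 0
    for i in range(1, len(monomers) + 1):
        if i == len(monomers) or monomers[i].start - monomers[i - 1].end > max_gap_bp:
            seg = ArraySegment(
                run_start,
                i,
                start_bp=monomers[run_start].start,
                end_bp=monomers[i - 1].end,
            )
            _annotate_periods(seg, labels, min_support, max_period)
            segments.append(seg)
            run_start = i
    return segments


def _annotate_periods(
    seg: ArraySegment,
    labels: Sequence[int],
    min_support: int,
    max_period: int,
) -> None:
    local = list(labels[seg.start_index : seg.end_index])
    points = compute_md_points(local, max_period=max_period)
    md_segments = classify_segments(detect_segments(points, min_support=min_support))
    hors = [s for s in md_segments if s.kind == "HOR"]
    if hors:
        top = max(hors, key=lambda s: s.support)
        seg.hor_period = top.period
    seg.subfragment_periods = tuple(
        sorted({s.period for s in md_segments if s.kind == "subfragment"})
    )


def infer_canonical_unit(labels: Sequence[int], n: int) -> CanonicalUnit:
    """Most frequent length-``n`` label substring, up to rotation.

    Windows are counted in cyclic equivalence classes, so that every
    phase of the tandem pattern contributes to the same class.  The
    winning class is then rotated to the phase that most often starts a
    copy: the rotation that most often follows the end of an identical
    copy (tandem-consistent starts), with ties broken towards the
    rotation best matching the start of the label sequence.
    """
    labels = list(labels)
    if len(labels) < 2 * n:
        raise ValueError(
            f"need at least 2 full units ({2 * n} monomers) to infer a "
            f"canonical {n}mer, got {len(labels)}"
        )
    windows = [tuple(labels[p : p + n]) for p in range(len(labels) - n + 1)]
    classes: Counter = Counter()
    for w in windows:
        classes[min(w[r:] + w[:r] for r in range(n))] += 1
    key = min((k for k, c in classes.items() if c == max(classes.values())))
    rotations = sorted({key[r:] + key[:r] for r in range(n)})
    occurrences = {
        rot: {p for p, w in enumerate(windows) if w == rot} for rot in rotations
    }

    def tandem_starts(rot: tuple[int, ...]) -> int:
        occ = occurrences[rot]
        return sum(1 for p in occ if p + n in occ)

    def prefix_match(rot: tuple[int, ...]) -> int:
        m = 0
        for a, b in zip(rot, labels):
            if a != b:
                break
            m += 1
        return m

    best = max(rotations, key=lambda r: (tandem_starts(r), prefix_match(r),
                                         [-x for x in r]))
    return CanonicalUnit(best)


def _column_map(unit: CanonicalUnit) -> dict[int, int]:
    cols: dict[int, int] = {}
    for lab in unit.type_sequence:
        if lab not in cols:
            cols[lab] = len(cols)
    return cols


def _rows_of(
    labels: Sequence[int], cols: dict[int, int]
) -> list[tuple[int, int]]:
    """Row boundaries (start, end) under the increasing-column rule.

    Types absent from the column map are appended as new rightmost
    columns at first appearance (mutates ``cols``).
    """
    rows: list[tuple[int, int]] = []
    start = 0
    prev_col = -1
    for i, lab in enumerate(labels):
        if lab not in cols:
            cols[lab] = len(cols)
        c = cols[lab]
        if c <= prev_col and i > start:
            rows.append((start, i))
            start = i
        prev_col = c
    if start < len(labels):
        rows.append((start, len(labels)))
    return rows


def _prefix_len(row: Sequence[int], unit: Sequence[int]) -> int:
    m = 0
    for a, b in zip(row, unit):
        if a != b:
            break
        m += 1
    return m


def partition_copies(
    labels: Sequence[int], unit: CanonicalUnit
) -> list[HORCopy]:
    """Greedy left-to-right partition of a label sequence into HOR copies.

    A copy opens with either an exact occurrence of the canonical unit
    (``n`` monomers spanning its full row layout) or, failing that, the
    single row at the cursor.  It then absorbs following rows while they
    do not open the next copy: a row identical to the previous row extends
    the copy (row multiplication, as in extended copies), a row that does
    not match the canonical unit's first two labels extends the copy
    (e.g. trailing type-1/type-last doublets), and any other row starts
    the next copy.  A row equal to the complete unit (the Willard case,
    where the whole canonical copy is one row) always starts a new copy.
    A copy is canonical iff its label sequence equals the unit exactly;
    every monomer belongs to exactly one copy.
    """
    labels = list(labels)
    seq = tuple(unit.type_sequence)
    useq = list(seq)
    n = unit.n
    cols = _column_map(unit)
    copies: list[HORCopy] = []
    p = 0
    N = len(labels)
    while p < N:
        if tuple(labels[p : p + n]) == seq:
            end = p + n
            unit_rows = _rows_of(useq, dict(cols))
            rs, re = unit_rows[-1]
            prev_row = useq[rs:re]
        else:
            bounds = _rows_of(labels[p:], dict(cols))
            rs, re = bounds[0]
            end = p + re
            prev_row = labels[p + rs : p + re]
        # absorb rows that do not open the next copy
        while end < N:
            bounds = _rows_of(labels[end:], dict(cols))
            rs, re = bounds[0]
            row = labels[end + rs : end + re]
            duplicate = row == prev_row and row != useq
            if not duplicate and _prefix_len(row, seq) >= min(2, n):
                break
            end += re
            prev_row = row
        status = "canonical" if labels[p:end] == useq else "variant"
        copies.append(HORCopy(p, end, status))
        p = end
    for copy in copies:
        cascade_layout(copy, labels[copy.start_index : copy.end_index], unit)
    return copies


def cascade_layout(
    copy: HORCopy, copy_labels: Sequence[int], unit: CanonicalUnit
) -> HORCopy:
    """Fill in the multi-row aligned layout and signature of one copy.

    Each monomer's column is the position of its type in the canonical
    type ordering (first occurrence); types absent from the canonical unit
    are placed in extra columns to the right in order of appearance.  A new
    row starts whenever the next monomer's column is not to the right of
    the previous one, so columns increase strictly within a row.

    The signature joins row lengths with ``+``.  A row that is not one
    contiguous piece of the canonical layout — i.e. where two neighbours
    in the row are never adjacent within a row of the canonical copy,
    marking a deletion gap — is written as a parenthesised sum of its
    contiguous piece lengths, e.g. ``(6 + 4)+2``.
    """
    cols = _column_map(unit)
    unit_bounds = _rows_of(list(unit.type_sequence), dict(cols))
    adjacent = {
        (unit.type_sequence[i], unit.type_sequence[i + 1])
        for rs, re in unit_bounds
        for i in range(rs, re - 1)
    }
    bounds = _rows_of(copy_labels, cols)
    copy.rows = [
        [(copy.start_index + i, cols[copy_labels[i]]) for i in range(rs, re)]
        for rs, re in bounds
    ]
    parts: list[str] = []
    for rs, re in bounds:
        runs: list[int] = [1]
        for i in range(rs + 1, re):
            if (copy_labels[i - 1], copy_labels[i]) in adjacent:
                runs[-1] += 1
            else:
                runs.append(1)
        if len(runs) == 1:
            parts.append(str(runs[0]))
        else:
            parts.append("(" + " + ".join(str(r) for r in runs) + ")")
    sig = ""
    for i, part in enumerate(parts):
        if i == 0:
            sig = part
        elif sig.endswith(")"):
            sig += "+" + part
        else:
            sig += " + " + part
    copy.signature = sig
    return copy


def summarize_array(
    segment: ArraySegment, copies: Sequence[HORCopy]
) -> dict:
    """Copy counts, percentage canonical, and variant clustering runs."""
    n_canonical = sum(1 for c in copies if c.status == "canonical")
    n_variant = len(copies) - n_canonical
    pct = int(round(100.0 * n_canonical / len(copies))) if copies else 0
    runs: list[int] = []
    cur = 0
    for c in copies:
        if c.status == "variant":
            cur += 1
        elif cur:
            runs.append(cur)
            cur = 0
    if cur:
        runs.append(cur)
    return {
        "n_copies": len(copies),
        "n_canonical": n_canonical,
        "n_variant": n_variant,
        "pct_canonical": pct,
        "variant_runs": runs,
        "hor_period": segment.hor_period,
        "subfragment_periods": list(segment.subfragment_periods),
    }


def render_scheme(
    copies: Sequence[HORCopy],
    labels: Sequence[int],
    monomers: Sequence[Monomer] | None = None,
    label_names: dict[int, str] | None = None,
) -> str:
    """Plain-text aligned scheme: one line per row, columns aligned by type.

    The first row of each copy is prefixed with the 1-based genomic start
    of its first monomer (when monomer coordinates are available) and the
    copy's status and signature are appended to its last row.
    """
    if label_names is None:
        label_names = {}
    all_cols = [c for copy in copies for row in copy.rows for _, c in row]
    ncol = (max(all_cols) + 1) if all_cols else 0
    width = max(
        [len(label_names.get(labels[i], f"t{labels[i] + 1}"))
         for copy in copies for row in copy.rows for i, _ in row] + [2]
    ) + 1
    prefix_w = 12 if monomers is not None else 0
    lines: list[str] = []
    for copy in copies:
        for r, row in enumerate(copy.rows):
            cells = [" " * width] * ncol
            for idx, c in row:
                name = label_names.get(labels[idx], f"t{labels[idx] + 1}")
                cells[c] = name.ljust(width)
            if r == 0 and monomers is not None:
                prefix = str(monomers[copy.start_index].start + 1).rjust(prefix_w - 2) + "  "
            else:
                prefix = " " * prefix_w
            line = prefix + "".join(cells).rstrip()
            if r == len(copy.rows) - 1:
                line += f"   [{copy.status} {copy.signature}]"
            lines.append(line)
        lines.append("")
    return "\n".join(lines)
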