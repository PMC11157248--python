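"""Consensus-based monomer scanning.

Find all occurrences of a satellite consensus (the *query*, nominally the
171-bp alphoid monomer) in a genomic *subject* sequence, on both strands,
by banded edit-distance alignment (edlib).  Detected occurrences are
reported as :class:`Monomer` records, non-overlapping, ordered by genomic
position and enumerated in order of appearance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib

__all__ = ["ConsensusQuery", "Monomer", "divergence", "scan_genome", "revcomp"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_VALID = set("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConsensusQuery:
    """A satellite consensus sequence used as the scanning query.

    The sequence must be uppercase A/C/G/T/N and at least 50 bp long
    (shorter queries do not define a meaningful monomer).
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"query contains non-ACGTN characters: {sorted(bad)}")
        if len(seq) < 50:
            raise ValueError(f"query too short ({len(seq)} bp < 50 bp)")


@dataclass
class Monomer:
    """One detected satellite monomer occurrence.

    Coordinates are 0-based half-open on the subject.  ``sequence`` is
    oriented to match the query strand (reverse-complemented for minus-strand
    hits).  ``index`` is the global enumeration assigned in order of
    appearance along the subject.
    """

    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    index: int = -1
    div_to_query: float = float("nan")

    def __len__(self) -> int:
        return self.end - self.start


def divergence(a: str, b: str) -> float:
    """Normalised edit distance between two sequences.

    Defined as ``edit_distance(a, b) / max(len(a), len(b))``: symmetric,
    bounded in [0, 1], zero iff the sequences are identical, and tolerant
    of length differences caused by indels.
    """
    if not a or not b:
        raise ValueError("divergence of an empty sequence is undefined")
    ed = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return ed / max(len(a), len(b))


def _best_hits(segment: str, queries: list[tuple[str, str]], k: int):
    """Best infix alignment(s) of any query in ``segment``.

    Returns ``(ed, [(start, end_excl, strand), ...])`` for the minimal edit
    distance achieved by either strand, or ``(None, [])`` if nothing scores
    within ``k``.  edlib reports every co-optimal location.
    """
    best_ed = None
    hits: list[tuple[int, int, str]] = []
    for strand, qseq in queries:
        res = edlib.align(qseq, segment, mode="HW", task="locations", k=k)
        ed = res["editDistance"]
        if ed == -1:
            continue
        if best_ed is None or ed < best_ed:
            best_ed = ed
            hits = []
        if ed == best_ed:
            hits.extend((s, e + 1, strand) for s, e in res["locations"])
    return best_ed, hits


def scan_genome(
    subject: str,
    query: ConsensusQuery,
    max_div: float = 0.30,
    min_len: int | None = None,
    max_len: int | None = None,
    chrom: str = "seq",
) -> list[Monomer]:
    """Detect all monomer occurrences of ``query`` in ``subject``.

    Both orientations are searched.  Candidate local alignments with
    normalised edit distance <= ``max_div`` are selected greedily,
    best score first (ties: leftmost start, then plus strand), subject to
    non-overlap, which reproduces the tandem tiling of satellite arrays.
    Monomers are returned sorted by start with enumeration indices 0..N-1.

    ``min_len``/``max_len`` default to 0.5x and 1.5x the query length,
    rejecting fragments and fused dimers.
    """
    if not (0.0 < max_div < 0.5):
        raise ValueError(f"max_div must be in (0, 0.5), got {max_div}")
    subject = subject.upper()
    if not subject:
        return []
    L = len(query.sequence)
    if min_len is None:
        min_len = int(round(0.5 * L))
    if max_len is None:
        max_len = int(round(1.5 * L))
    # ed <= max_div * max(L, span) and span <= L + ed bound the usable band
    k = math.floor(max_div * L / (1.0 - max_div))
    queries = [("+", query.sequence), ("-", revcomp(query.sequence))]

    accepted: list[Monomer] = []
    # best-first over disjoint intervals: the best hit in an interval splits
    # it; candidates never span an accepted hit (they would overlap it)
    stack: list[tuple[int, int]] = [(0, len(subject))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < min_len:
            continue
        ed, hits = _best_hits(subject[lo:hi], queries, k)
        if ed is None:
            continue
        hits.sort(key=lambda h: (h[0], h[2] == "-"))
        taken: list[tuple[int, int, str]] = []
        last_end = -1
        for s, e, strand in hits:
            if s < last_end:
                continue
            taken.append((s, e, strand))
            last_end = e
        prev = lo
        for s, e, strand in taken:
            start, end = lo + s, lo + e
            span = end - start
            if min_len <= span <= max_len and ed / max(L, span) <= max_div:
                seq = subject[start:end]
                if strand == "-":
                    seq = revcomp(seq)
                accepted.append(
                    Monomer(chrom, start, end, strand, seq,
                            div_to_query=ed / max(L, span))
                )
            if start - prev >= min_len:
                stack.append((prev, start))
            prev = end
        if hi - prev >= min_len:
            stack.append((prev, hi))

    accepted.sort(key=lambda m: m.start)
    for i, m in enumerate(accepted):
        m.index = i
    return accepted
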