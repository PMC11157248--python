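"""Monomer family (type) assignment and per-family consensus.

Monomers are clustered into families by single-linkage at a divergence
threshold (default 5%): two monomers are linked when their normalised edit
distance is below the threshold, and families are the connected components
of the link graph.  Family labels are dense integers renumbered by first
occurrence along the monomer enumeration, rendered ``t1, t2, ...`` in
human-readable output.
"""

from __future__ import annotations

from collections import Counter

import edlib
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .scan import divergence

__all__ = [
    "build_divergence_matrix",
    "assign_families",
    "assign_families_from_sequences",
    "family_consensus",
    "family_label",
]

_BASE_ORDER = {b: i for i, b in enumerate("ACGT-")}  # tie-break A<C<G<T


def family_label(f: int) -> str:
    """Render a 0-based family index as the conventional t-label (t1-based)."""
    return f"t{f + 1}"


def build_divergence_matrix(sequences: list[str]) -> np.ndarray:
    """All-vs-all normalised edit distances (symmetric, zero diagonal)."""
    if len(sequences) < 1:
        raise ValueError("need at least one monomer")
    n = len(sequences)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = divergence(sequences[i], sequences[j])
    return d


def _renumber_first_occurrence(raw: np.ndarray) -> np.ndarray:
    remap: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out


def assign_families(matrix: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Single-linkage families from a divergence matrix.

    Connected components of the graph with edges ``d[i, j] < threshold``.
    Returns 0-based dense labels, renumbered by first occurrence (the first
    monomer is always in family 0, i.e. t1).
    """
    if not (0.0 < threshold < 0.5):
        raise ValueError(f"threshold must be in (0, 0.5), got {threshold}")
    adj = csr_matrix(matrix < threshold)
    _, raw = connected_components(adj, directed=False)
    return _renumber_first_occurrence(raw)


class _DSU:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def assign_families_from_sequences(
    sequences: list[str],
    threshold: float = 0.05,
    mode: str = "exact",
) -> np.ndarray:
    """Family labels directly from sequences, without a dense matrix.

    ``mode="exact"`` is single-linkage identical to :func:`assign_families`
    but uses banded alignment (early abort above the threshold band), which
    is much faster than filling the full matrix.  ``mode="greedy"`` is the
    representative-first approximation: each monomer is compared to one
    representative per existing family and joins the first within threshold;
    it agrees with the exact mode whenever families are well separated.
    """
    if not (0.0 < threshold < 0.5):
        raise ValueError(f"threshold must be in (0, 0.5), got {threshold}")
    n = len(sequences)
    if mode == "exact":
        dsu = _DSU(n)
        for i in range(n):
            si, li = sequences[i], len(sequences[i])
            for j in range(i + 1, n):
                if dsu.find(i) == dsu.find(j):
                    continue
                m = max(li, len(sequences[j]))
                kband = int(np.ceil(threshold * m))
                ed = edlib.align(si, sequences[j], mode="NW",
                                 task="distance", k=kband)["editDistance"]
                if ed != -1 and ed / m < threshold:
                    dsu.union(i, j)
        raw = np.array([dsu.find(i) for i in range(n)])
        return _renumber_first_occurrence(raw)
    if mode == "greedy":
        reps: list[int] = []
        labels = np.empty(n, dtype=int)
        for i, seq in enumerate(sequences):
            for f, r in enumerate(reps):
                if divergence(seq, sequences[r]) < threshold:
                    labels[i] = f
                    break
            else:
                labels[i] = len(reps)
                reps.append(i)
        return labels
    raise ValueError(f"unknown mode {mode!r}")


def _star_consensus(members: list[str], medoid: str) -> str:
    """Majority consensus of members star-aligned against the medoid.

    Each member is pairwise-aligned to the medoid; votes are collected per
    medoid column (deletions vote '-'), and insertions between medoid
    columns are kept only when more than half of the members share one.
    Ties are broken alphabetically (A < C < G < T); a majority deletion
    drops the column.
    """
    ncol = len(medoid)
    col_votes: list[Counter] = [Counter() for _ in range(ncol)]
    ins_votes: list[Counter] = [Counter() for _ in range(ncol + 1)]
    for mem in members:
        res = edlib.align(mem, medoid, mode="NW", task="path")
        qi = ti = 0
        pending_ins = ""
        num = ""
        for ch in res["cigar"]:
            if ch.isdigit():
                num += ch
                continue
            run = int(num)
            num = ""
            if ch in "=X":
                if pending_ins:
                    ins_votes[ti][pending_ins] += 1
                    pending_ins = ""
                for _ in range(run):
                    col_votes[ti][mem[qi]] += 1
                    qi += 1
                    ti += 1
            elif ch == "I":  # present in member, absent in medoid
                pending_ins += mem[qi:qi + run]
                qi += run
            elif ch == "D":  # medoid column deleted in member
                if pending_ins:
                    ins_votes[ti][pending_ins] += 1
                    pending_ins = ""
                for _ in range(run):
                    col_votes[ti]["-"] += 1
                    ti += 1
        if pending_ins:
            ins_votes[ti][pending_ins] += 1
    nmem = len(members)
    out: list[str] = []
    for t in range(ncol + 1):
        if ins_votes[t]:
            ins, cnt = sorted(ins_votes[t].items(),
                              key=lambda kv: (-kv[1], kv[0]))[0]
            if cnt * 2 > nmem:
                out.append(ins)
        if t < ncol:
            base, _ = sorted(col_votes[t].items(),
                             key=lambda kv: (-kv[1], _BASE_ORDER.get(kv[0], 9)))[0]
            if base != "-":
                out.append(base)
    return "".join(out)


def family_consensus(
    sequences: list[str],
    labels: np.ndarray,
) -> dict[int, str]:
    """Per-family consensus sequences.

    The family medoid (member minimising summed divergence to the rest of
    the family) anchors a star alignment; the consensus is the per-column
    majority (see :func:`_star_consensus`).
    """
    consensus: dict[int, str] = {}
    for f in sorted(set(int(x) for x in labels)):
        members = [sequences[i] for i in range(len(sequences)) if labels[i] == f]
        if len(members) == 1:
            consensus[f] = members[0]
            continue
        # medoid search; families are tight (<5% spread) so banded distances
        best_i, best_sum = 0, float("inf")
        for i, a in enumerate(members):
            tot = 0.0
            for j, b in enumerate(members):
                if i != j:
                    tot += divergence(a, b)
            if tot < best_sum:
                best_sum, best_i = tot, i
        consensus[f] = _star_consensus(members, members[best_i])
    return consensus
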