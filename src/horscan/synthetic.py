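"""Synthetic alpha-satellite array generator with machine-readable truth.

Emulates the repeat structure the scanner and HOR analysis operate on:
a library of ~171-bp monomer *types* derived from a common ancestral
consensus (pairwise type divergence in the 20-40% band), HOR units that
may repeat types (cascading) or not (Willard's type), tandem copies with
small per-copy mutation (<5%, so copies of one type stay one family),
optional variant events (row duplication, type deletion, row insertion),
non-repetitive flanks, and optional reverse-complement orientation.

Every output is a deterministic function of the spec's seed.  The ground
truth records per-monomer coordinates/types and per-copy status and
signature, so recovery by the full pipeline can be checked exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cascade import CanonicalUnit, HORCopy, cascade_layout, _column_map, _rows_of
from .scan import revcomp

__all__ = ["ArraySpec", "VariantEvent", "make_type_library", "build_array",
           "build_chromosome", "CANONICAL_17MER_UNIT", "WILLARD_10MER_UNIT"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# the worked cascading 17mer: types t1..t15, then t1 again, then t16
CANONICAL_17MER_UNIT = tuple(range(15)) + (0, 15)
WILLARD_10MER_UNIT = tuple(range(10))


@dataclass(frozen=True)
class VariantEvent:
    """A structural deviation applied to one HOR copy.

    kind="duplicate_row": row ``row`` of the canonical layout appears
    ``times`` times in total (times=2 duplicates it once; times=6 gives
    the six-fold extended copy).
    kind="delete_types": all monomers of the given types are removed.
    kind="insert_row": the given label sequence is inserted after row
    ``row`` of the canonical layout.
    """

    copy: int
    kind: str
    row: int = 0
    times: int = 2
    types: tuple[int, ...] = ()
    labels: tuple[int, ...] = ()


@dataclass(frozen=True)
class ArraySpec:
    """Parameters of one synthetic tandem array (plus flanks)."""

    unit: tuple[int, ...] = CANONICAL_17MER_UNIT
    monomer_len: int = 171
    inter_type_div: float = 0.25
    n_copies: int = 100
    per_base_mutation: float = 0.01
    variant_events: tuple[VariantEvent, ...] = ()
    strand: str = "+"
    flank_len: int = 500
    indel_fraction: float = 0.0  # fraction of mutation events that are indels
    seed: int = 0
    # optional shared ancestral consensus (DNA string); when set, type seeds
    # are mutants of it, so several arrays can share one scanning query
    ancestor: str | None = None

    @property
    def k(self) -> int:
        return len(set(self.unit))

    def __post_init__(self) -> None:
        if not self.unit:
            raise ValueError("unit must contain at least one type label")
        if sorted(set(self.unit)) != list(range(self.k)):
            raise ValueError("unit labels must be dense 0..k-1")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(
    rng: np.random.Generator,
    seq: np.ndarray,
    rate: float,
    indel_fraction: float = 0.0,
) -> np.ndarray:
    """Apply i.i.d. mutations; substitutions go to one of the 3 other bases."""
    if rate <= 0:
        return seq.copy()
    hit = rng.random(len(seq)) < rate
    out = seq.copy()
    if indel_fraction <= 0:
        idx = np.nonzero(hit)[0]
        if idx.size:
            shift = rng.integers(1, 4, size=idx.size)
            base_idx = np.array([_B2I[b] for b in out[idx]])
            out[idx] = _BASES[(base_idx + shift) % 4]
        return out
    pieces: list[np.ndarray] = []
    for i, b in enumerate(seq):
        if not hit[i]:
            pieces.append(seq[i : i + 1])
            continue
        r = rng.random()
        if r < indel_fraction / 2:  # deletion
            continue
        if r < indel_fraction:  # insertion before the (kept) base
            pieces.append(_random_dna(rng, 1))
            pieces.append(seq[i : i + 1])
            continue
        base_idx = _B2I[b]
        pieces.append(_BASES[[(base_idx + int(rng.integers(1, 4))) % 4]])
    return np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)


_B2I = {b: i for i, b in enumerate(_BASES)}


def _solve_branch_rate(target_div: float) -> float:
    """Per-type mutation rate so two independent mutants of one ancestor
    differ at ~``target_div`` of positions: 2r - 4r^2/3 = D."""
    return 0.75 * (2.0 - math.sqrt(4.0 - 16.0 * target_div / 3.0)) / 2.0


def make_type_library(
    k: int,
    monomer_len: int = 171,
    inter_type_div: float = 0.25,
    seed: int = 0,
) -> list[str]:
    """``k`` monomer type seed sequences with controlled mutual divergence.

    Types are independent mutants of one random ancestor (mirroring the
    shared alphoid consensus); the construction loop regenerates any type
    closer than 0.8x the requested divergence to an earlier one.
    """
    ancestor, types = _make_library(k, monomer_len, inter_type_div, seed)
    return types


def _make_library(
    k: int,
    monomer_len: int,
    inter_type_div: float,
    seed: int,
    ancestor: str | None = None,
) -> tuple[str, list[str]]:
    from .scan import divergence  # local import to avoid cycle at module load

    if k < 1:
        raise ValueError("k must be >= 1")
    if inter_type_div > 0.75:
        raise ValueError(
            f"inter_type_div {inter_type_div} infeasible (> 0.75 cannot be "
            "guaranteed for 4-letter sequences)"
        )
    rng = np.random.default_rng(seed)
    if ancestor is None:
        anc = _random_dna(rng, monomer_len)
    else:
        anc = np.frombuffer(ancestor.encode(), dtype=np.uint8)
    ancestor_arr = anc
    rate = _solve_branch_rate(inter_type_div)
    floor = 0.8 * inter_type_div
    types: list[np.ndarray] = []
    for _ in range(k):
        for _attempt in range(200):
            cand = _mutate(rng, ancestor_arr, rate)
            cand_s = cand.tobytes().decode()
            if all(
                divergence(cand_s, t.tobytes().decode()) >= floor for t in types
            ):
                types.append(cand)
                break
        else:  # pragma: no cover - construction loop exhausted
            raise RuntimeError("could not satisfy divergence floor")
    return ancestor_arr.tobytes().decode(), [t.tobytes().decode() for t in types]


def _copy_labels(spec: ArraySpec, copy_index: int) -> tuple[list[int], bool]:
    """Label sequence of one copy after applying its variant events."""
    unit = CanonicalUnit(spec.unit)
    cols = _column_map(unit)
    bounds = _rows_of(list(spec.unit), dict(cols))
    rows = [list(spec.unit[s:e]) for s, e in bounds]
    modified = False
    for ev in spec.variant_events:
        if ev.copy != copy_index:
            continue
        modified = True
        if ev.kind == "duplicate_row":
            if not (0 <= ev.row < len(rows)):
                raise ValueError(f"no row {ev.row} in canonical layout")
            rows = (
                rows[: ev.row]
                + [list(rows[ev.row])] * ev.times
                + rows[ev.row + 1 :]
            )
        elif ev.kind == "delete_types":
            drop = set(ev.types)
            rows = [[lab for lab in r if lab not in drop] for r in rows]
            rows = [r for r in rows if r]
        elif ev.kind == "insert_row":
            rows = rows[: ev.row + 1] + [list(ev.labels)] + rows[ev.row + 1 :]
        else:
            raise ValueError(f"unknown variant event kind {ev.kind!r}")
    return [lab for r in rows for lab in r], modified


def build_array(spec: ArraySpec) -> tuple[str, dict]:
    """Construct the array sequence and its ground truth.

    Returns ``(sequence, truth)`` where truth holds the scan query
    (ancestral consensus), the type library, per-monomer records
    (0-based half-open coordinates, strand, type, copy id), per-copy
    status and signature (layout of the truth labels against the
    canonical unit), and the flat label sequence in genomic order.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor, types = _make_library(
        spec.k, spec.monomer_len, spec.inter_type_div, spec.seed,
        ancestor=spec.ancestor,
    )
    type_arrays = [np.frombuffer(t.encode(), dtype=np.uint8) for t in types]
    unit = CanonicalUnit(spec.unit)

    labels: list[int] = []
    copy_of: list[int] = []
    copy_meta: list[dict] = []
    pieces: list[np.ndarray] = []
    monomer_lens: list[int] = []
    for c in range(spec.n_copies):
        clabels, _modified = _copy_labels(spec, c)
        status = "canonical" if clabels == list(spec.unit) else "variant"
        hc = HORCopy(len(labels), len(labels) + len(clabels), status)
        cascade_layout(hc, clabels, unit)
        copy_meta.append(
            {"copy_id": c, "status": status, "signature": hc.signature,
             "n_monomers": len(clabels)}
        )
        for lab in clabels:
            mono = _mutate(
                rng, type_arrays[lab], spec.per_base_mutation, spec.indel_fraction
            )
            pieces.append(mono)
            monomer_lens.append(len(mono))
            labels.append(lab)
            copy_of.append(c)

    left = _random_dna(rng, spec.flank_len)
    right = _random_dna(rng, spec.flank_len)
    body = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
    seq = np.concatenate([left, body, right]).tobytes().decode()

    monomers: list[dict] = []
    pos = spec.flank_len
    for i, (lab, ln) in enumerate(zip(labels, monomer_lens)):
        monomers.append(
            {"start": pos, "end": pos + ln, "strand": "+", "type": lab,
             "copy_id": copy_of[i]}
        )
        pos += ln
    if spec.strand == "-":
        total = len(seq)
        seq = revcomp(seq)
        for m in monomers:
            m["start"], m["end"] = total - m["end"], total - m["start"]
            m["strand"] = "-"
        monomers.reverse()
        labels = [m["type"] for m in monomers]

    truth = {
        "query": ancestor,
        "types": types,
        "unit": spec.unit,
        "n": unit.n,
        "tau": unit.tau,
        "k": spec.k,
        "labels": labels,
        "monomers": monomers,
        "copies": copy_meta,
    }
    return seq, truth

def build_chromosome(
    specs: list[ArraySpec],
    seed: int = 0,
    spacer_len: int = 3000,
    monomer_len: int = 171,
) -> tuple[str, dict]:
    """Several arrays on one sequence, separated by non-repetitive spacers.

    All arrays share one ancestral consensus (derived from ``seed``), as
    real satellite arrays share the alphoid consensus, so a single query
    detects the monomers of every array.  Returns ``(sequence, truth)``;
    truth monomer coordinates are lifted to chromosome coordinates and the
    per-array truths are kept under ``"arrays"``.
    """
    rng = np.random.default_rng(seed)
    ancestor = _random_dna(rng, monomer_len).tobytes().decode()
    pieces: list[str] = []
    truths: list[dict] = []
    monomers: list[dict] = []
    labels: list[int] = []
    offset = 0
    label_offset = 0
    for i, spec in enumerate(specs):
        spec = replace(spec, ancestor=ancestor, monomer_len=monomer_len)
        seq, truth = build_array(spec)
        for m in truth["monomers"]:
            lifted = dict(m)
            lifted["start"] += offset
            lifted["end"] += offset
            lifted["array"] = i
            lifted["type"] += label_offset
            monomers.append(lifted)
        # arrays have disjoint type libraries: lift into one label space
        labels.extend(lab + label_offset for lab in truth["labels"])
        label_offset += spec.k
        truths.append(truth)
        pieces.append(seq)
        offset += len(seq)
        if i < len(specs) - 1:
            spacer = _random_dna(rng, spacer_len).tobytes().decode()
            pieces.append(spacer)
            offset += spacer_len
    return "".join(pieces), {
        "query": ancestor,
        "monomers": monomers,
        "labels": labels,
        "arrays": truths,
    }
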