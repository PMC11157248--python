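"""End-to-end orchestration of the two analysis stages.

Stage 1 (monomer finding) scans a genomic FASTA with a satellite
consensus and emits the ordered monomer list.  Stage 2 (HOR analysis)
clusters monomers into families, computes the GRM/MD diagrams, delimits
arrays, infers canonical units and lays out cascading copy schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import io as hio
from .cascade import (
    ArraySegment,
    CanonicalUnit,
    HORCopy,
    infer_canonical_unit,
    partition_copies,
    render_scheme,
    segment_arrays,
    summarize_array,
)
from .families import assign_families_from_sequences, family_consensus, family_label
from .periodicity import classify_segments, compute_md_points, detect_segments, grm_histogram
from .scan import ConsensusQuery, Monomer, divergence, scan_genome

logger = logging.getLogger("horscan")

__all__ = ["ArrayResult", "GRMHORResult", "run_monfinder", "run_grmhor"]


@dataclass
class ArrayResult:
    """Per-array HOR analysis: unit, copies, summary."""

    segment: ArraySegment
    unit: CanonicalUnit | None = None
    copies: list[HORCopy] = field(default_factory=list)
    summary: dict = field(default_factory=dict)


@dataclass
class GRMHORResult:
    monomers: list[Monomer]
    labels: list[int]
    consensus: dict[int, str]
    md_points: list
    grm: dict[int, int]
    segments: list
    arrays: list[ArrayResult]

    @property
    def n_families(self) -> int:
        return len(set(self.labels))


def run_monfinder(
    subject: str,
    query: ConsensusQuery,
    max_div: float = 0.30,
    chrom: str = "seq",
    out_dir: str | Path | None = None,
) -> list[Monomer]:
    """Scan a subject sequence for monomers; optionally write BED + FASTA."""
    monomers = scan_genome(subject, query, max_div=max_div, chrom=chrom)
    logger.info("monfinder: %d monomers detected on %s", len(monomers), chrom)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hio.write_monomer_bed(out / "monomers.bed", monomers)
        hio.write_monomer_fasta(out / "monomers.fasta", monomers)
    return monomers


def run_grmhor(
    monomers: Sequence[Monomer],
    threshold: float = 0.05,
    max_period: int = 50,
    min_support: int = 10,
    max_gap_bp: int = 2000,
    out_dir: str | Path | None = None,
) -> GRMHORResult:
    """Family assignment, GRM/MD diagrams, array segmentation and schemes."""
    seqs = [m.sequence for m in monomers]
    if len(seqs) < 2:
        logger.warning("grmhor: fewer than 2 monomers; diagrams are empty")
        labels = [0] * len(seqs)
        result = GRMHORResult(list(monomers), labels, {}, [], {}, [], [])
        if out_dir is not None:
            _write_outputs(Path(out_dir), result)
        return result

    labels = [int(x) for x in assign_families_from_sequences(seqs, threshold=threshold)]
    consensus = family_consensus(seqs, labels)
    logger.info("grmhor: %d monomers in %d families", len(seqs), len(consensus))

    points = compute_md_points(labels, max_period=max_period)
    grm = grm_histogram(points)
    segments = classify_segments(detect_segments(points, min_support=min_support))
    logger.info("grmhor: %d MD points, %d MD-line segments", len(points), len(segments))

    arrays: list[ArrayResult] = []
    for seg in segment_arrays(
        monomers, labels, max_gap_bp=max_gap_bp,
        min_support=min_support, max_period=max_period,
    ):
        res = ArrayResult(seg)
        n = seg.hor_period
        local = labels[seg.start_index : seg.end_index]
        if n is not None and len(local) >= 2 * n:
            res.unit = infer_canonical_unit(local, n)
            copies = partition_copies(local, res.unit)
            for c in copies:  # lift copy indices to the global enumeration
                c.start_index += seg.start_index
                c.end_index += seg.start_index
                c.rows = [[(i + seg.start_index, col) for i, col in row]
                          for row in c.rows]
            res.copies = copies
            res.summary = summarize_array(seg, copies)
            res.summary["n"] = res.unit.n
            res.summary["tau"] = res.unit.tau
            res.summary["unit"] = [family_label(t) for t in res.unit.type_sequence]
            res.summary["start_bp"] = seg.start_bp + 1
            res.summary["end_bp"] = seg.end_bp
            logger.info(
                "grmhor: array %d-%d: %dmer (tau=%d), %d copies, %d%% canonical",
                seg.start_index, seg.end_index, res.unit.n, res.unit.tau,
                len(copies), res.summary["pct_canonical"],
            )
        arrays.append(res)

    result = GRMHORResult(list(monomers), labels, consensus, points, grm,
                          segments, arrays)
    if out_dir is not None:
        _write_outputs(Path(out_dir), result)
    return result


def _write_outputs(out: Path, result: GRMHORResult) -> None:
    out.mkdir(parents=True, exist_ok=True)
    div_to_cons = None
    if result.consensus:
        div_to_cons = [
            divergence(m.sequence, result.consensus[result.labels[i]])
            if result.consensus.get(result.labels[i]) else 0.0
            for i, m in enumerate(result.monomers)
        ]
    hio.write_families_tsv(out / "families.tsv", result.labels, div_to_cons)
    hio.write_consensus_fasta(out / "family_consensus.fasta", result.consensus)
    hio.write_md_tsv(out / "md_points.tsv", result.md_points)
    hio.write_grm_tsv(out / "grm.tsv", result.grm)
    hio.write_segments_tsv(out / "md_segments.tsv", result.segments)
    summary = {"n_monomers": len(result.monomers),
               "n_families": result.n_families,
               "n_md_points": len(result.md_points),
               "arrays": [a.summary for a in result.arrays]}
    hio.write_summary_json(out / "summary.json", summary)
    scheme_parts = []
    for a in result.arrays:
        if a.copies:
            scheme_parts.append(
                render_scheme(a.copies, result.labels, result.monomers)
            )
    (out / "scheme.txt").write_text("\n".join(scheme_parts))
    all_copies = [c for a in result.arrays for c in a.copies]
    hio.write_scheme_tsv(out / "scheme.tsv", all_copies, result.monomers)
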