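"""File formats: FASTA, BED6, TSV tables, scheme text, summary JSON.

Coordinates are 0-based half-open in BED and in memory; 1-based inclusive
in FASTA headers and the human-readable scheme, following genome-browser
convention.
"""

from __future__ import annotations

import json
import re
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .families import family_label
from .scan import ConsensusQuery, Monomer

__all__ = [
    "read_fasta",
    "write_fasta",
    "packaged_consensus",
    "write_monomer_bed",
    "write_monomer_fasta",
    "read_monomer_fasta",
    "write_families_tsv",
    "write_consensus_fasta",
    "write_md_tsv",
    "write_grm_tsv",
    "write_segments_tsv",
    "write_scheme_tsv",
    "write_summary_json",
]

_HEADER_RE = re.compile(r"^m(\d+)\|([^:]+):(\d+)-(\d+)\|([+-])$")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        str(path),
        "fasta",
    )


def packaged_consensus() -> ConsensusQuery:
    """The default 171-bp alphoid-style scanning consensus shipped with the
    package (a synthetic stand-in generated to alphoid base composition;
    replace with a published alphoid consensus for real assemblies)."""
    ref = resources.files("horscan.data") / "alphoid_consensus_synthetic.fasta"
    with resources.as_file(ref) as path:
        (name, seq), = read_fasta(path)
    return ConsensusQuery(name, seq)


def write_monomer_bed(path: str | Path, monomers: list[Monomer]) -> None:
    """BED6: name mN, score 1000*(1 - divergence-to-query)."""
    with open(path, "w") as fh:
        for m in monomers:
            score = int(round(1000 * (1.0 - m.div_to_query)))
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\tm{m.index}\t{score}\t{m.strand}\n"
            )


def write_monomer_fasta(path: str | Path, monomers: list[Monomer]) -> None:
    write_fasta(
        path,
        [
            (f"m{m.index}|{m.chrom}:{m.start + 1}-{m.end}|{m.strand}", m.sequence)
            for m in monomers
        ],
    )


def read_monomer_fasta(path: str | Path) -> list[Monomer]:
    """Read monomers back from the header convention of
    :func:`write_monomer_fasta`; plain headers are accepted as an ordered
    monomer list with synthetic coordinates."""
    monomers: list[Monomer] = []
    pos = 0
    for i, (name, seq) in enumerate(read_fasta(path)):
        m = _HEADER_RE.match(name)
        if m:
            idx, chrom, start1, end, strand = m.groups()
            monomers.append(
                Monomer(chrom, int(start1) - 1, int(end), strand, seq, int(idx))
            )
        else:
            monomers.append(Monomer("monomers", pos, pos + len(seq), "+", seq, i))
        pos += len(seq)
    monomers.sort(key=lambda m: m.index)
    return monomers


def write_families_tsv(path, labels, div_to_consensus=None) -> None:
    df = pd.DataFrame(
        {
            "monomer_index": range(len(labels)),
            "family_label": [family_label(int(x)) for x in labels],
        }
    )
    if div_to_consensus is not None:
        df["div_to_family_consensus"] = [round(d, 5) for d in div_to_consensus]
    df.to_csv(path, sep="\t", index=False)


def write_consensus_fasta(path, consensus: dict[int, str]) -> None:
    write_fasta(path, [(family_label(f), seq) for f, seq in sorted(consensus.items())])


def write_md_tsv(path, points) -> None:
    pd.DataFrame(
        {"index": [p.index for p in points], "period": [p.period for p in points]}
    ).to_csv(path, sep="\t", index=False)


def write_grm_tsv(path, histogram: dict[int, int]) -> None:
    pd.DataFrame(
        {"period": list(histogram), "count": list(histogram.values())}
    ).to_csv(path, sep="\t", index=False)


def write_segments_tsv(path, segments) -> None:
    pd.DataFrame(
        [
            {
                "period": s.period,
                "start_index": s.start_index,
                "end_index": s.end_index,
                "support": s.support,
                "kind": s.kind,
            }
            for s in segments
        ],
        columns=["period", "start_index", "end_index", "support", "kind"],
    ).to_csv(path, sep="\t", index=False)


def write_scheme_tsv(path, copies, monomers) -> None:
    pd.DataFrame(
        [
            {
                "copy_id": i,
                "start_bp": monomers[c.start_index].start + 1,
                "n_monomers": c.n_monomers,
                "status": c.status,
                "signature": c.signature,
            }
            for i, c in enumerate(copies)
        ],
        columns=["copy_id", "start_bp", "n_monomers", "status", "signature"],
    ).to_csv(path, sep="\t", index=False)


def write_summary_json(path, summary: dict) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
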