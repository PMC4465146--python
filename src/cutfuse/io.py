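"""Standard-format input/output: FASTA, FASTQ, SAM, BED, TSV.

FASTA records carry topology in the description (``[topology=circular]``) so
construct round trips preserve it.  SAM output is minimal but IGV-loadable:
header plus one line per read with POS/CIGAR against the junction reference.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .junctions import Amplicon, JunctionRef
from .quant import AlignedRead, SpectrumReport
from .seqs import Feature, NucSeq


def write_fasta(seqs: Iterable[NucSeq], path: str | Path) -> None:
    records = []
    for s in seqs:
        desc = f"[topology={s.topology}]"
        records.append(SeqRecord(Seq(s.symbols), id=s.name or "seq", description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[NucSeq]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        topology = "circular" if "[topology=circular]" in rec.description else "linear"
        out.append(NucSeq(str(rec.seq), topology=topology, name=rec.id))
    return out


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, qual_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq)))
    return out


def write_features_bed(features: Sequence[Feature], chrom: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{chrom}\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand}\n")


def write_sam(
    alignments: Sequence[AlignedRead], junction: JunctionRef, path: str | Path
) -> None:
    ref_name = junction.sequence.name or junction.label
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{ref_name}\tLN:{len(junction.sequence)}\n")
        for a in alignments:
            if a.mapped:
                fh.write(
                    f"{a.read_id}\t0\t{ref_name}\t{a.ref_start + 1}\t60\t"
                    f"{a.cigar()}\t*\t0\t0\t{a.read_seq}\t*\n"
                )
            else:
                fh.write(f"{a.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{a.read_seq}\t*\n")


SPECTRUM_COLUMNS = [
    "Name",
    "Replicate",
    "Position",
    "Ref",
    "Indel",
    "reads_ref",
    "reads_var",
    "VarFreq",
    "p_value",
    "representation",
]


def spectrum_to_frame(report: SpectrumReport) -> pd.DataFrame:
    """Table-shaped spectrum: one row per indel observation."""
    rep = report.indel_representation
    rows = []
    for o in report.observations:
        rows.append(
            {
                "Name": report.sample,
                "Replicate": report.replicate,
                "Position": o.indel.position,
                "Ref": o.indel.ref_base or ".",
                "Indel": o.indel.token,
                "reads_ref": o.ref_reads,
                "reads_var": o.var_reads,
                "VarFreq": round(o.var_freq, 6),
                "p_value": o.p_value,
                "representation": round(rep.get(o.indel.token, 0.0), 6),
            }
        )
    return pd.DataFrame(rows, columns=SPECTRUM_COLUMNS)


def write_spectrum_tsv(report: SpectrumReport, path: str | Path) -> None:
    spectrum_to_frame(report).to_csv(path, sep="\t", index=False)


def write_amplicons_tsv(
    rows: Sequence[tuple[str, str, Amplicon]], path: str | Path
) -> None:
    """TSV of (template, primer pair, amplicon size/coords)."""
    df = pd.DataFrame(
        [
            {
                "template": tmpl,
                "primer_pair": pp,
                "start": a.start,
                "end": a.end,
                "size": a.size,
                "orientation": a.orientation,
            }
            for tmpl, pp, a in rows
        ],
        columns=["template", "primer_pair", "start", "end", "size", "orientation"],
    )
    df.to_csv(path, sep="\t", index=False)
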