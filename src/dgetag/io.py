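"""File formats: FASTA transcripts, tag-count TSVs, FASTQ tag reads, GMT sets."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import RawTagLibrary


def write_fasta(transcripts: list[tuple[str, str]], path) -> None:
    records = [SeqRecord(Seq(seq), id=gene_id, description="") for gene_id, seq in transcripts]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_tag_counts(counts: pd.Series, path) -> None:
    """Two-column TSV: tag sequence <TAB> count, sorted by sequence."""
    df = counts.sort_index().rename("count").rename_axis("sequence").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_tag_counts(path, library_id: str | None = None) -> RawTagLibrary:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "count": int})
    counts = df.set_index("sequence")["count"]
    lib_id = library_id or Path(path).stem
    return RawTagLibrary(lib_id, counts)


def read_fastq_tags(path, library_id: str | None = None) -> RawTagLibrary:
    """Collapse FASTQ reads into a tag-count multiset (sequences as read)."""
    counts: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = str(rec.seq).upper()
        counts[seq] = counts.get(seq, 0) + 1
    lib_id = library_id or Path(path).stem
    series = pd.Series(counts, dtype=int).sort_index()
    series.index.name = "sequence"
    return RawTagLibrary(lib_id, series)


def write_gmt(terms: dict[str, set[str]], path, names: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term in sorted(terms):
            desc = (names or {}).get(term, term)
            members = "\t".join(sorted(terms[term]))
            fh.write(f"{term}\t{desc}\t{members}\n")
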