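"""Clean-tag mapping against the reference tag database and gene quantification.

Each distinct clean tag is resolved with at most one mismatch, by tier
priority: exact sense > exact antisense > 1-mismatch sense > 1-mismatch
antisense.  Within the winning tier a tag hitting more than one gene is
*ambiguous*; within one gene the most-3' site (smallest rank) is recorded.
Only unambiguous sense tags contribute to gene counts, which are normalized
to tags per million (TPM) against the library's total clean tags.
"""

from __future__ import annotations

import pandas as pd

from .cleaning import CleanTagLibrary
from .reference import ReferenceTagDB

CATEGORIES = ("unambiguous-sense", "ambiguous", "antisense", "unmapped")

_BASES = "ACGT"


def one_mismatch_variants(seq: str):
    """All 3*len(seq) sequences at Hamming distance exactly 1 (ACGT alphabet)."""
    for i, b in enumerate(seq):
        for nb in _BASES:
            if nb != b:
                yield seq[:i] + nb + seq[i + 1:]


def _resolve(tag: str, db: ReferenceTagDB):
    """(category, gene_id, site_rank, mismatches, strand) for one clean tag."""
    for mism in (0, 1):
        for strand in ("sense", "antisense"):
            if mism == 0:
                hits = db.lookup(tag, strand)
            else:
                hits: dict[str, int] = {}
                for var in one_mismatch_variants(tag):
                    for gene, rank in db.lookup(var, strand).items():
                        prev = hits.get(gene)
                        hits[gene] = rank if prev is None else min(prev, rank)
            if not hits:
                continue
            if len(hits) > 1:
                return "ambiguous", None, None, mism, strand
            (gene, rank), = hits.items()
            cat = "unambiguous-sense" if strand == "sense" else "antisense"
            return cat, gene, rank, mism, strand
    return "unmapped", None, None, None, None


def map_tags(clean: CleanTagLibrary, db: ReferenceTagDB) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align every distinct clean tag to the reference database.

    Returns ``(alignments, summary)``.  ``alignments`` has one row per
    distinct clean tag: sequence, count, category, gene_id, site_rank,
    mismatches, strand.  ``summary`` reports, per category, the fraction of
    distinct and of total clean tags (fractions partition the library).
    """
    rows = []
    for seq, count in clean.counts.items():
        cat, gene, rank, mism, strand = _resolve(seq, db)
        rows.append((seq, int(count), cat, gene, rank, mism, strand))
    alignments = pd.DataFrame(
        rows, columns=["sequence", "count", "category", "gene_id",
                       "site_rank", "mismatches", "strand"],
    )
    total = alignments["count"].sum()
    distinct = len(alignments)
    summary_rows = []
    for cat in CATEGORIES:
        sub = alignments[alignments["category"] == cat]
        summary_rows.append({
            "category": cat,
            "distinct_tags": len(sub),
            "total_tags": int(sub["count"].sum()),
            "distinct_fraction": len(sub) / distinct if distinct else 0.0,
            "total_fraction": sub["count"].sum() / total if total else 0.0,
        })
    return alignments, pd.DataFrame(summary_rows)


def tag_position_report(alignments: pd.DataFrame, weight: str = "count") -> pd.Series:
    """Distribution of matched CATG site rank among unambiguous sense tags.

    ``weight='count'`` shares are over tag occurrences (what the sequencer
    sees); ``weight='distinct'`` over distinct tag sequences.  Shares sum to 1
    when any sense alignment exists; an empty input yields an empty series.
    """
    hit = alignments[alignments["category"] == "unambiguous-sense"]
    if hit.empty:
        return pd.Series(dtype=float, name="share")
    if weight == "count":
        dist = hit.groupby("site_rank")["count"].sum().astype(float)
    elif weight == "distinct":
        dist = hit.groupby("site_rank").size().astype(float)
    else:
        raise ValueError(f"weight must be 'count' or 'distinct', got {weight!r}")
    dist /= dist.sum()
    dist.name = "share"
    dist.index = dist.index.astype(int)
    return dist


def quantify(
    per_library: dict[str, tuple[pd.DataFrame, CleanTagLibrary]],
    genes: list[str],
    rank1_only: bool = False,
) -> "GeneExpressionTable":
    """Gene x library raw counts and TPM from unambiguous sense alignments.

    ``per_library`` maps library_id -> (alignments, clean library).  With
    ``rank1_only`` only tags matching the 3'-most site of their gene are
    counted.  TPM(g) = count(g) / total_clean * 1e6; genes never seen get 0.
    """
    counts = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"),
                          columns=list(per_library), dtype=int)
    totals = {}
    for lib_id, (alignments, clean) in per_library.items():
        if clean.total_clean == 0:
            raise ValueError(f"library {lib_id}: total_clean is 0, cannot normalize")
        hit = alignments[alignments["category"] == "unambiguous-sense"]
        if rank1_only:
            hit = hit[hit["site_rank"] == 1]
        per_gene = hit.groupby("gene_id")["count"].sum()
        per_gene = per_gene[per_gene.index.isin(counts.index)]
        counts.loc[per_gene.index, lib_id] = per_gene.astype(int)
        totals[lib_id] = clean.total_clean
    return GeneExpressionTable(counts=counts, total_clean=pd.Series(totals, name="total_clean"))


class GeneExpressionTable:
    """Gene x library raw attributable counts plus the TPM view."""

    def __init__(self, counts: pd.DataFrame, total_clean: pd.Series):
        self.counts = counts
        self.total_clean = total_clean.astype(int)

    @property
    def tpm(self) -> pd.DataFrame:
        return self.counts / self.total_clean * 1e6

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def condition_series(self, design: pd.DataFrame, condition: str,
                         t_slice: slice | None = None) -> pd.DataFrame:
        """TPM sub-matrix of one condition's time course, columns in time order."""
        sub = design[design["condition"] == condition].sort_values("t_index")
        if t_slice is not None:
            sub = sub.iloc[t_slice]
        return self.tpm[sub["library_id"].tolist()]
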