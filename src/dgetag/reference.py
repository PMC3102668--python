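"""Reference tag database construction.

In NlaIII-anchored DGE tag profiling, every transcript is represented by the
21-nt sequences starting at a CATG restriction site ("CATG + 17 nt" tags).
Sequenced tags are identified by alignment against the set of all such tags
derivable from the annotated transcriptome, on both strands.  A tag sequence
carried by exactly one gene is *unambiguous*; only unambiguous sense tags are
used for quantification downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

TAG_LENGTH = 21
ANCHOR = "CATG"
DOWNSTREAM = TAG_LENGTH - len(ANCHOR)  # 17 nt after the anchor

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

logger = logging.getLogger(__name__)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceTag:
    """One CATG+17 tag of one gene.

    ``site_rank`` counts CATG sites from the 3' end of the (strand-oriented)
    transcript: rank 1 is the 3'-most site, the one the assay is expected to
    produce under complete digestion.
    """

    sequence: str
    gene_id: str
    strand: str  # "sense" | "antisense"
    site_rank: int

    def __post_init__(self) -> None:
        if len(self.sequence) != TAG_LENGTH:
            raise ValueError(f"tag must be {TAG_LENGTH} nt, got {len(self.sequence)}")
        if not self.sequence.startswith(ANCHOR):
            raise ValueError(f"tag must start with {ANCHOR}: {self.sequence}")
        if self.strand not in ("sense", "antisense"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.site_rank < 1:
            raise ValueError("site_rank must be >= 1")


@dataclass
class ReferenceTagDB:
    """All reference tags of a transcript set plus ambiguity bookkeeping.

    ``ambiguity_index`` maps each distinct tag sequence to the set of genes
    carrying it on either strand (strand-collapsed): a sequence is unambiguous
    iff that set has size one.
    """

    tags: list[ReferenceTag]
    ambiguity_index: dict[str, frozenset[str]]
    n_genes_with_site: int = 0
    n_genes_without_site: int = 0
    n_sites_skipped_for_n: int = 0
    # fast lookup tables: sequence -> {gene_id: min site_rank} per strand
    _sense: dict[str, dict[str, int]] = field(default_factory=dict, repr=False)
    _antisense: dict[str, dict[str, int]] = field(default_factory=dict, repr=False)

    @property
    def n_tag_records(self) -> int:
        return len(self.tags)

    @property
    def n_unambiguous_records(self) -> int:
        return sum(1 for t in self.tags if len(self.ambiguity_index[t.sequence]) == 1)

    @property
    def n_distinct_sequences(self) -> int:
        return len(self.ambiguity_index)

    def lookup(self, sequence: str, strand: str) -> dict[str, int]:
        """Genes carrying ``sequence`` on ``strand`` with their best (lowest) site rank."""
        table = self._sense if strand == "sense" else self._antisense
        return table.get(sequence, {})

    def is_unambiguous(self, sequence: str) -> bool:
        genes = self.ambiguity_index.get(sequence)
        return genes is not None and len(genes) == 1


def _scan_tags(seq: str) -> list[tuple[int, str]]:
    """All (position, 21-mer) for CATG sites with >=17 nt downstream, 5'->3'."""
    out = []
    pos = seq.find(ANCHOR)
    while pos != -1:
        if pos + TAG_LENGTH <= len(seq):
            out.append((pos, seq[pos : pos + TAG_LENGTH]))
        pos = seq.find(ANCHOR, pos + 1)
    return out


def extract_reference_tags(
    transcripts: Iterable[tuple[str, str]] | Mapping[str, str],
    max_rank: int | None = None,
) -> ReferenceTagDB:
    """Build the reference tag database from (gene_id, sequence) pairs.

    Every CATG occurrence with at least 17 nt downstream yields one sense tag;
    the reverse complement is scanned identically for antisense tags.  Sites
    whose 21-mer contains an N are skipped (counted).  Transcripts without any
    qualifying site on the sense strand contribute nothing and are tallied in
    ``n_genes_without_site``.  Multiple transcripts of one gene are merged:
    identical (sequence, strand) records keep the smallest rank.

    Parameters
    ----------
    transcripts:
        Mapping or iterable of ``(gene_id, sequence)``; sequences are 5'->3'
        mRNA over A/C/G/T/N (case-insensitive).
    max_rank:
        If given, keep only tags with ``site_rank <= max_rank``.
    """
    if isinstance(transcripts, Mapping):
        items: Iterable[tuple[str, str]] = transcripts.items()
    else:
        items = transcripts

    # per gene & strand: sequence -> min rank
    per_gene: dict[tuple[str, str], dict[str, int]] = {}
    genes_seen: set[str] = set()
    genes_with_site: set[str] = set()
    n_skipped = 0

    for gene_id, raw_seq in items:
        seq = str(raw_seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"transcript {gene_id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        genes_seen.add(gene_id)
        for strand, s in (("sense", seq), ("antisense", reverse_complement(seq))):
            sites = _scan_tags(s)
            kept = []
            for pos, tag in sites:
                if "N" in tag:
                    n_skipped += 1
                    logger.debug("skipping N-containing site at %d of %s", pos, gene_id)
                    continue
                kept.append(tag)
            if not kept:
                continue
            if strand == "sense":
                genes_with_site.add(gene_id)
            # rank 1 = 3'-most = last occurrence in 5'->3' scan order
            store = per_gene.setdefault((gene_id, strand), {})
            n = len(kept)
            for i, tag in enumerate(kept):
                rank = n - i
                if tag in store:
                    store[tag] = min(store[tag], rank)
                else:
                    store[tag] = rank

    tags: list[ReferenceTag] = []
    ambiguity: dict[str, set[str]] = {}
    for (gene_id, strand), seq_ranks in sorted(per_gene.items()):
        for tag_seq, rank in sorted(seq_ranks.items()):
            if max_rank is not None and rank > max_rank:
                continue
            tags.append(ReferenceTag(tag_seq, gene_id, strand, rank))
            ambiguity.setdefault(tag_seq, set()).add(gene_id)

    db = ReferenceTagDB(
        tags=tags,
        ambiguity_index={s: frozenset(g) for s, g in ambiguity.items()},
        n_genes_with_site=len(genes_with_site),
        n_genes_without_site=len(genes_seen - genes_with_site),
        n_sites_skipped_for_n=n_skipped,
    )
    for t in tags:
        table = db._sense if t.strand == "sense" else db._antisense
        gene_ranks = table.setdefault(t.sequence, {})
        prev = gene_ranks.get(t.gene_id)
        gene_ranks[t.gene_id] = t.site_rank if prev is None else min(prev, t.site_rank)
    return db


def ambiguity_classify(db: ReferenceTagDB) -> tuple[dict[str, bool], dict[str, int]]:
    """Label each distinct tag sequence unambiguous iff exactly one gene carries it.

    Returns the per-sequence flag plus summary counts in the vocabulary used to
    report reference databases: total tag records, unambiguous records,
    distinct sequences, unambiguous distinct sequences.
    """
    flags = {seq: len(genes) == 1 for seq, genes in db.ambiguity_index.items()}
    summary = {
        "total_reference_tags": db.n_tag_records,
        "unambiguous_reference_tags": db.n_unambiguous_records,
        "distinct_sequences": db.n_distinct_sequences,
        "unambiguous_distinct_sequences": sum(flags.values()),
        "genes_with_site": db.n_genes_with_site,
        "genes_without_site": db.n_genes_without_site,
    }
    return flags, summary
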