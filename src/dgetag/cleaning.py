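"""Raw tag library cleaning and library-level diagnostics.

Raw libraries are filtered to *clean tags* by removing, in order, adaptor
tags, low-quality (N-containing) tags, and copy-number-1 tags, keeping a
conservation ledger (raw total = clean total + removed per class).  The
diagnostics mirror how tag libraries are usually characterized: the
copy-number distribution (share of total vs distinct clean tags per
copy-number bin) and the saturation curve (distinct tags / genes discovered
as a function of subsampled depth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import RawTagLibrary

DEFAULT_BINS: tuple[tuple[int, float], ...] = (
    (2, 5), (6, 10), (11, 20), (21, 50), (51, 100), (101, np.inf),
)


@dataclass
class CleanTagLibrary:
    """Clean tags of one library plus the filter ledger."""

    library_id: str
    counts: pd.Series            # sequence -> count, all counts >= 2
    filter_ledger: dict[str, int] = field(default_factory=dict)

    @property
    def total_clean(self) -> int:
        """Quantity of all clean tags sequenced (sum of counts)."""
        return int(self.counts.sum())

    @property
    def distinct_clean(self) -> int:
        """Type quantity of different clean tags (number of distinct sequences)."""
        return int(len(self.counts))


def clean_tags(raw: RawTagLibrary, adaptor: str = "TCGTATGCC") -> CleanTagLibrary:
    """Filter a raw library to clean tags.

    Filter order: malformed (length != 21) -> adaptor prefix -> N-containing
    (low quality) -> copy number 1 (singletons judged after the first two
    filters, i.e. on assay-valid tags).  The ledger counts tag occurrences
    removed per class, so ``total_raw == total_clean + sum(ledger)``.
    """
    counts = raw.counts
    ledger = {"malformed": 0, "adaptor": 0, "low_quality": 0, "singleton": 0}
    if counts.empty:
        warnings.warn(f"library {raw.library_id}: empty raw library")
        return CleanTagLibrary(raw.library_id, counts.astype(int), ledger)

    seqs = counts.index.to_numpy(dtype=object)
    vals = counts.to_numpy()

    lengths = np.array([len(s) for s in seqs])
    ok = lengths == 21
    ledger["malformed"] = int(vals[~ok].sum())
    seqs, vals = seqs[ok], vals[ok]

    is_adaptor = np.array([s.startswith(adaptor) for s in seqs]) if adaptor else np.zeros(len(seqs), bool)
    ledger["adaptor"] = int(vals[is_adaptor].sum())
    seqs, vals = seqs[~is_adaptor], vals[~is_adaptor]

    has_n = np.array(["N" in s for s in seqs]) if len(seqs) else np.zeros(0, bool)
    ledger["low_quality"] = int(vals[has_n].sum())
    seqs, vals = seqs[~has_n], vals[~has_n]

    single = vals == 1
    ledger["singleton"] = int(vals[single].sum())
    seqs, vals = seqs[~single], vals[~single]

    clean = pd.Series(vals.astype(int), index=pd.Index(seqs, name="sequence"),
                      name=raw.library_id).sort_index()
    return CleanTagLibrary(raw.library_id, clean, ledger)


def copy_number_distribution(
    clean: CleanTagLibrary,
    bins: tuple[tuple[int, float], ...] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Share of total and of distinct clean tags per copy-number bin.

    ``bins`` must partition [2, inf) into contiguous closed intervals
    (the last upper bound may be inf).  Both share columns sum to 1 for a
    non-empty library.
    """
    lo = 2
    for b_lo, b_hi in bins:
        if b_lo != lo:
            raise ValueError(f"bins must partition [2, inf) contiguously; got lower bound "
                             f"{b_lo} where {lo} was expected")
        if b_hi < b_lo:
            raise ValueError(f"bin ({b_lo}, {b_hi}) is empty")
        lo = int(b_hi) + 1 if np.isfinite(b_hi) else None
        if lo is None:
            break
    counts = clean.counts.to_numpy()
    total = counts.sum()
    distinct = len(counts)
    rows = []
    for b_lo, b_hi in bins:
        in_bin = (counts >= b_lo) & (counts <= b_hi)
        rows.append({
            "bin": f"{b_lo}-{int(b_hi)}" if np.isfinite(b_hi) else f">{b_lo - 1}",
            "total_share": counts[in_bin].sum() / total if total else 0.0,
            "distinct_share": in_bin.sum() / distinct if distinct else 0.0,
        })
    return pd.DataFrame(rows)


def saturation_curve(
    raw: RawTagLibrary,
    grid: list[int] | np.ndarray,
    refdb=None,
    adaptor: str = "TCGTATGCC",
    seed: int = 0,
) -> pd.DataFrame:
    """Discovery curve under nested subsampling without replacement.

    One shuffled stream of tag occurrences is drawn once; each grid point is a
    prefix of it, so curves are monotone nondecreasing per seed.  Reported per
    grid point: distinct raw tags seen, clean total/distinct after filtering
    the subsample, and (if ``refdb`` is given) genes identified by unambiguous
    sense mapping.
    """
    from .mapping import map_tags  # local import to avoid a cycle

    grid = sorted(int(g) for g in grid)
    total = raw.total_raw
    kept = [g for g in grid if g <= total]
    if len(kept) < len(grid):
        warnings.warn(f"saturation grid truncated at total_raw={total}")
    grid = kept

    rng = np.random.default_rng(seed)
    seq_idx = np.repeat(np.arange(len(raw.counts)), raw.counts.to_numpy())
    rng.shuffle(seq_idx)
    seqs = raw.counts.index.to_numpy(dtype=object)

    rows = []
    for g in grid:
        prefix = seq_idx[:g]
        uniq, cnt = np.unique(prefix, return_counts=True)
        sub = RawTagLibrary(raw.library_id,
                            pd.Series(cnt, index=pd.Index(seqs[uniq], name="sequence")))
        clean = clean_tags(sub, adaptor=adaptor)
        row = {
            "n_tags": g,
            "distinct_raw": len(uniq),
            "total_clean": clean.total_clean,
            "distinct_clean": clean.distinct_clean,
        }
        if refdb is not None:
            aln, _ = map_tags(clean, refdb)
            hit = aln[aln["category"] == "unambiguous-sense"]
            row["genes_identified"] = hit["gene_id"].nunique()
        rows.append(row)
    return pd.DataFrame(rows)
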