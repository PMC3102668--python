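"""Gene-set over-representation tests (GO terms, pathways).

For a DE list of n genes out of a universe of N, and a term of M genes of
which m are DE, significance is the one-sided hypergeometric (Fisher exact)
tail, with a chi-squared test (continuity-corrected) reported alongside, BH
FDR across terms, and the enrichment ratio Re = (m/n) / (M/N) as the effect
size: Re > 1 iff the term is over-represented among DE genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr


@dataclass
class GeneSetCollection:
    """Term -> member genes, intersected with a background universe."""

    terms: dict[str, set[str]]
    universe: set[str]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for term, members in self.terms.items():
            kept = set(members) & self.universe
            if kept:
                cleaned[term] = kept
            else:
                warnings.warn(f"term {term!r} has no members in the universe; dropped")
        self.terms = cleaned


def read_gmt(path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (term, description, members..., tab-separated)."""
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            terms[parts[0]] = {g for g in parts[2:] if g}
            names[parts[0]] = parts[1]
    if universe is None:
        universe = set().union(*terms.values()) if terms else set()
    return GeneSetCollection(terms=terms, universe=universe, names=names)


def overrep_pvalue(m, n, M, N, under: bool = False):
    """One-sided hypergeometric (Fisher exact) tail; vectorized.

    Over-representation: P(X >= m) for X ~ Hypergeom(N, M, n); with
    ``under=True`` the lower tail P(X <= m).
    """
    m = np.asarray(m)
    if under:
        p = stats.hypergeom.cdf(m, N, M, n)
    else:
        p = stats.hypergeom.sf(m - 1, N, M, n)
    return float(p) if np.ndim(p) == 0 else p


def enrichment_ratio(m: int, n: int, M: int, N: int) -> float:
    """Re = (m/n) / (M/N); the standard fold-enrichment of a 2x2 table."""
    for name, v in (("n", n), ("M", M), ("N", N)):
        if v <= 0:
            raise ValueError(f"enrichment_ratio: {name} must be > 0, got {v}")
    return (m / n) / (M / N)


def fisher_enrich(
    de_genes: set[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    under: bool = False,
) -> pd.DataFrame:
    """Per-term over-representation results, sorted by Fisher p.

    Columns: m (DE in term), n (DE in universe), M (term size), N (universe
    size), Re, p_fisher (one-sided hypergeometric tail; under-representation
    with ``under=True``), p_chi2 (continuity-corrected, NaN on degenerate
    tables), fdr_q (BH over p_fisher), significant (p_fisher < alpha, the
    conventional selection criterion).
    """
    de = set(de_genes) & collection.universe
    stray = set(de_genes) - collection.universe
    if stray:
        raise ValueError(f"{len(stray)} DE genes outside the universe, e.g. {sorted(stray)[:3]}")
    N = len(collection.universe)
    n = len(de)
    if n == 0:
        warnings.warn("fisher_enrich: empty DE list")
        return pd.DataFrame(columns=["term", "name", "m", "n", "M", "N", "Re",
                                     "p_fisher", "p_chi2", "fdr_q", "significant"])
    rows = []
    for term, members in sorted(collection.terms.items()):
        M = len(members)
        m = len(de & members)
        p = overrep_pvalue(m, n, M, N, under=under)
        table = np.array([[m, n - m], [M - m, (N - n) - (M - m)]])
        if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            p_chi2 = stats.chi2_contingency(table, correction=True)[1]
        else:
            p_chi2 = np.nan
        rows.append({
            "term": term,
            "name": collection.names.get(term, term),
            "m": m, "n": n, "M": M, "N": N,
            "Re": enrichment_ratio(m, n, M, N),
            "p_fisher": float(p),
            "p_chi2": p_chi2,
        })
    out = pd.DataFrame(rows)
    out["fdr_q"] = bh_fdr(out["p_fisher"].to_numpy())
    out["significant"] = out["p_fisher"] < alpha
    return out.sort_values(["p_fisher", "term"], kind="mergesort").reset_index(drop=True)
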