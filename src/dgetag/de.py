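"""Differential expression between two tag libraries.

With a single library per condition there is no replicate dispersion to
estimate; the appropriate exact statistic is the Audic-Claverie test for a
difference between two counts x and y observed in libraries of total size N1
and N2.  Conditional on x, the null law of y is

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) )

which is a negative binomial with size x+1 and success probability
N1/(N1+N2); both tails are therefore regularized incomplete beta integrals
and can be evaluated to machine precision without explicit summation.
Two-sided p doubles the smaller tail (capped at 1).  Genes are called at a
p-value, Benjamini-Hochberg FDR, and |log2 fold change| threshold; two named
presets ship: ``methods`` (p<0.005, FDR<0.01, |lfc|>0.5) and ``results``
(p<0.009, FDR<0.02, |lfc|>0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

#: named threshold presets (p, fdr, min |log2fc|)
PRESETS: dict[str, dict[str, float]] = {
    "methods": {"p": 0.005, "fdr": 0.01, "abs_log2fc": 0.5},
    "results": {"p": 0.009, "fdr": 0.02, "abs_log2fc": 0.5},
}


@dataclass
class DEContrast:
    """Per-gene counts of one library pair plus the TPM denominators."""

    name: str
    x: pd.Series  # counts in library A
    y: pd.Series  # counts in library B
    n1: int       # total clean tags of A
    n2: int       # total clean tags of B

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("library totals must be positive")
        if not self.x.index.equals(self.y.index):
            raise ValueError("x and y must share a gene index")


def _two_sided_conditional(x, y, n1, n2):
    """2 * min tail of the law of y given x (NB(x+1, n1/(n1+n2))), capped at 1."""
    q = n1 / (n1 + n2)
    # P(Y <= y) = I_q(x+1, y+1); P(Y >= y) = I_{1-q}(y, x+1) for y >= 1, else 1
    lower = special.betainc(x + 1.0, y + 1.0, q)
    with np.errstate(invalid="ignore"):
        upper = np.where(y >= 1.0, special.betainc(np.maximum(y, 1.0), x + 1.0, 1.0 - q), 1.0)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def audic_claverie_p(x, y, n1, n2):
    """Two-sided Audic-Claverie p-value(s); vectorized over x, y.

    Each conditioning direction gives 2 * min(P(Y <= y | x), P(Y >= y | x))
    under the conditional negative-binomial law; the tails of that law are not
    exactly swap-symmetric, so the reported p is the maximum over the two
    conditionings — conservative, and exactly invariant under
    (x, N1) <-> (y, N2).  x = y = 0 returns 1 (no evidence).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    p = np.maximum(_two_sided_conditional(x, y, n1, n2),
                   _two_sided_conditional(y, x, n2, n1))
    p = np.where((x == 0) & (y == 0), 1.0, p)
    return float(p) if p.ndim == 0 else p


def log2_fold(x, y, n1, n2, pseudo: float = 1.0):
    """log2 of the normalized y/x ratio; pseudo-counted only when a count is 0.

    Returns log2((y/N2)/(x/N1)) when both counts are positive, otherwise
    log2(((y+pseudo)/N2)/((x+pseudo)/N1)).
    """
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    zero = (x == 0) | (y == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.log2((y / n2) / (x / n1))
    padded = np.log2(((y + pseudo) / n2) / ((x + pseudo) / n1))
    out = np.where(zero, padded, raw)
    return float(out) if out.ndim == 0 else out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (empty in -> empty out)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    contrast: DEContrast,
    thresholds: dict[str, float] | str = "methods",
    pseudo: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene DE table and the up/down summary for one contrast.

    A gene is called ``up`` (in B vs A) when log2fc exceeds +abs_log2fc and
    both p and BH q pass; ``down`` symmetric.  Summary: total / up / down.
    """
    if isinstance(thresholds, str):
        thresholds = PRESETS[thresholds]
    x = contrast.x.to_numpy()
    y = contrast.y.to_numpy()
    p = audic_claverie_p(x, y, contrast.n1, contrast.n2)
    q = bh_fdr(p)
    lfc = log2_fold(x, y, contrast.n1, contrast.n2, pseudo=pseudo)
    passing = (p < thresholds["p"]) & (q < thresholds["fdr"]) & \
        (np.abs(lfc) > thresholds["abs_log2fc"])
    call = np.where(passing & (lfc > 0), "up",
                    np.where(passing & (lfc < 0), "down", "null"))
    table = pd.DataFrame(
        {"x": x.astype(int), "y": y.astype(int), "log2fc": lfc,
         "p_value": p, "fdr_q": q, "call": call},
        index=contrast.x.index,
    )
    summary = {
        "total": int((table["call"] != "null").sum()),
        "up": int((table["call"] == "up").sum()),
        "down": int((table["call"] == "down").sum()),
    }
    return table, summary
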