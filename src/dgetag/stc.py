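"""Series Test of Cluster (STC): model-profile clustering of short time series.

A set of *model profiles* — integer change vectors between consecutive time
points, bounded by c — is selected independently of the data by greedy
max-min dispersion over the candidate space.  Each gene's expression series
(log2 ratios anchored at the first time point) is assigned to the profile
with the highest Pearson correlation.  Profile significance is assessed by
permuting the order of time points: the expected assigned count under
permutation gives a binomial null for the observed count, corrected across
profiles by Benjamini-Hochberg.  Significant profiles can be grouped by
single linkage on profile-profile correlation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelProfile:
    """One model temporal pattern.

    ``changes`` are T-1 integers in [-c, c] (positive = up-regulation between
    consecutive points, negative = down); ``values`` is the implied series
    starting at 0.
    """

    profile_id: int
    changes: tuple[int, ...]

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.changes, dtype=float)])


def _candidate_values(T: int, c: int) -> np.ndarray:
    """Value series of all (2c+1)^(T-1) candidate profiles, in lexicographic
    order of their change vectors (digits -c..c)."""
    base = 2 * c + 1
    n = base ** (T - 1)
    idx = np.arange(n)
    digits = np.empty((n, T - 1), dtype=np.int64)
    for j in range(T - 2, -1, -1):
        digits[:, j] = idx % base - c
        idx //= base
    values = np.zeros((n, T), dtype=np.float32)
    np.cumsum(digits, axis=1, out=digits)
    values[:, 1:] = digits
    return values


def _standardize_rows(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows centered and scaled to unit norm; zero-variance rows left at 0."""
    m = m - m.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(m, axis=1, keepdims=True)
    flat = norm.ravel() == 0
    norm[flat[:, None]] = 1.0
    return m / norm, flat


def select_model_profiles(T: int, c: int = 2, m: int = 80) -> list[ModelProfile]:
    """Greedy max-min selection of m model profiles, a pure function of (T, c, m).

    Starting from the flat profile, iteratively add the candidate maximizing
    the minimum distance (1 - Pearson correlation of value series) to the
    already-selected set; ties (within 1e-9) break to the lexicographically
    smallest change vector.  Correlations involving a zero-variance series are
    treated as 0 (so the flat profile, once taken, never recurs).
    """
    if T < 3:
        raise ValueError(f"T must be >= 3, got {T}")
    if c < 1:
        raise ValueError(f"c must be >= 1, got {c}")
    space = (2 * c + 1) ** (T - 1)
    if m > space:
        raise ValueError(f"m={m} exceeds the candidate space (2c+1)^(T-1) = {space}")

    values = _candidate_values(T, c)
    z, flat = _standardize_rows(values.astype(np.float64))
    flat_idx = int(np.nonzero(flat)[0][0])  # the all-zero change vector

    selected = [flat_idx]
    # distance to the flat profile: correlation treated as 0 => distance 1,
    # except the flat candidate itself (distance 0)
    min_dist = np.ones(len(values))
    min_dist[flat_idx] = -np.inf  # never reselect
    while len(selected) < m:
        # first index within 1e-9 of the max: lexicographic tie-breaking that
        # is robust to float rounding in the incremental distance updates
        nxt = int(np.argmax(min_dist >= min_dist.max() - 1e-9))
        selected.append(nxt)
        d = 1.0 - z @ z[nxt]
        if flat[nxt]:
            d = np.ones(len(values))
        d[flat] = 1.0
        np.minimum(min_dist, d, out=min_dist)
        min_dist[nxt] = -np.inf

    base = 2 * c + 1
    profiles = []
    for pid, idx in enumerate(selected):
        digits, rem = [], idx
        for _ in range(T - 1):
            digits.append(rem % base - c)
            rem //= base
        profiles.append(ModelProfile(pid, tuple(reversed(digits))))
    return profiles


def normalize_gene_series(
    tpm: pd.DataFrame,
    pseudo: float = 1.0,
    min_max_tpm: float = 5.0,
) -> pd.DataFrame:
    """log2 ratio series anchored at the first time point.

    v_t = log2((TPM_t + pseudo) / (TPM_1 + pseudo)), so v_1 = 0.  Genes whose
    maximum TPM falls below ``min_max_tpm`` (including all-zero series) are
    excluded before assignment; exclusions are logged.
    """
    keep = tpm.max(axis=1) >= min_max_tpm
    dropped = int((~keep).sum())
    if dropped:
        logger.info("normalize_gene_series: excluded %d genes below min max TPM %.3g",
                    dropped, min_max_tpm)
    sub = tpm.loc[keep]
    anchored = np.log2(sub.add(pseudo).div(sub.iloc[:, 0] + pseudo, axis=0))
    return anchored


def assign_genes(series: pd.DataFrame, profiles: list[ModelProfile]) -> pd.DataFrame:
    """Assign each gene to the best-correlated model profile.

    Ties break to the lowest profile_id; zero-variance gene series go to the
    flat profile (recorded with correlation 1, since an anchored all-zero
    series *is* the flat pattern).  Correlations with a zero-variance profile
    or gene are otherwise treated as 0.
    """
    pvals = np.stack([p.values for p in profiles])
    zp, flat_p = _standardize_rows(pvals)
    zg, flat_g = _standardize_rows(series.to_numpy(dtype=float))
    corr = zg @ zp.T
    corr[:, flat_p] = 0.0
    corr[flat_g, :] = 0.0
    best = np.argmax(corr, axis=1)  # first max => lowest profile_id on ties
    best_corr = corr[np.arange(len(corr)), best]
    flat_ids = [i for i, p in enumerate(profiles) if not np.any(p.changes)]
    if flat_ids and flat_g.any():
        best[flat_g] = flat_ids[0]
        best_corr[flat_g] = 1.0
    return pd.DataFrame(
        {"profile_id": [profiles[i].profile_id for i in best], "correlation": best_corr},
        index=series.index,
    )


def _profile_counts(assign: pd.DataFrame, profiles: list[ModelProfile]) -> np.ndarray:
    counts = np.zeros(len(profiles), dtype=int)
    vc = assign["profile_id"].value_counts()
    id_to_pos = {p.profile_id: i for i, p in enumerate(profiles)}
    for pid, n in vc.items():
        counts[id_to_pos[pid]] = n
    return counts


def permutation_test(
    tpm: pd.DataFrame,
    profiles: list[ModelProfile],
    n_perm: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
    pseudo: float = 1.0,
    min_max_tpm: float = 5.0,
) -> pd.DataFrame:
    """Profile significance under permutations of the time-point order.

    For each permuted ordering the raw TPM columns are reordered, the series
    re-anchored and re-assigned; the expected count per profile is the mean
    over orderings.  If T! <= n_perm all T! orderings are enumerated exactly,
    otherwise n_perm are sampled.  p = P(X >= observed) with
    X ~ Binomial(G, expected/G), BH-adjusted across profiles.
    """
    T = tpm.shape[1]
    observed_series = normalize_gene_series(tpm, pseudo=pseudo, min_max_tpm=min_max_tpm)
    G = len(observed_series)
    observed = _profile_counts(assign_genes(observed_series, profiles), profiles)

    import math
    n_fact = math.factorial(T)
    if n_fact <= n_perm:
        orders = [list(p) for p in itertools.permutations(range(T))]
    else:
        rng = np.random.default_rng(seed)
        orders = [list(rng.permutation(T)) for _ in range(n_perm)]

    counts = np.zeros((len(orders), len(profiles)), dtype=float)
    raw = tpm.to_numpy(dtype=float)
    keep = tpm.max(axis=1) >= min_max_tpm
    raw = raw[keep.to_numpy()]
    for k, order in enumerate(orders):
        perm = raw[:, order]
        anchored = np.log2((perm + pseudo) / (perm[:, [0]] + pseudo))
        assign = assign_genes(pd.DataFrame(anchored), profiles)
        counts[k] = _profile_counts(assign, profiles)

    expected = counts.mean(axis=0)
    rate = np.clip(expected / max(G, 1), 0.0, 1.0)
    p = stats.binom.sf(observed - 1, G, rate)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = bh_fdr(p)
    return pd.DataFrame({
        "profile_id": [p_.profile_id for p_ in profiles],
        "changes": [",".join(map(str, p_.changes)) for p_ in profiles],
        "observed": observed,
        "expected": expected,
        "p_value": p,
        "fdr_q": q,
        "significant": q < alpha,
    })


def group_significant_profiles(
    profiles: list[ModelProfile],
    significance: pd.DataFrame,
    correlation_threshold: float = 0.7,
) -> list[list[int]]:
    """Single-linkage grouping of significant profiles by Pearson correlation.

    Two significant profiles join the same cluster when connected through
    pairwise correlations >= threshold (transitive closure).  Returns lists of
    profile_ids; zero-variance (flat) profiles correlate 0 with everything and
    form singletons.
    """
    if not 0.0 < correlation_threshold <= 1.0:
        raise ValueError("correlation_threshold must be in (0, 1]")
    sig_ids = significance.loc[significance["significant"], "profile_id"].tolist()
    sig = [p for p in profiles if p.profile_id in set(sig_ids)]
    if not sig:
        return []
    z, flat = _standardize_rows(np.stack([p.values for p in sig]))
    corr = z @ z.T
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 1.0)
    # union-find transitive closure over the thresholded graph
    parent = list(range(len(sig)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(sig)):
        for j in range(i + 1, len(sig)):
            if corr[i, j] >= correlation_threshold:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i, p in enumerate(sig):
        clusters.setdefault(find(i), []).append(p.profile_id)
    return sorted((sorted(c) for c in clusters.values()), key=lambda c: c[0])
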