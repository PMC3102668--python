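"""Reproducible benchmark experiments for the pipeline's statistical claims.

Each function runs a self-contained planted-truth experiment — exact-test
calibration, differential-expression recovery, mapping-oracle agreement,
temporal-profile detection, network sign recovery — and returns summary
metrics.  These are the experiments behind the package's verification story;
they are deliberately cheap enough to re-run from scratch.
"""

from __future__ import annotations

from math import exp, lgamma, log

import numpy as np
import pandas as pd

from . import stc
from .cleaning import clean_tags
from .de import DEContrast, audic_claverie_p, call_de
from .mapping import map_tags
from .reference import extract_reference_tags
from .simulate import SimulationConfig, simulate_study


def audic_claverie_p_bruteforce(x: int, y: int, n1: float, n2: float) -> float:
    """Slow reference: both tails of the conditional law by direct log-space
    summation (upper tail summed term by term, never via 1 - CDF), maximized
    over the two conditionings like the fast path."""

    def two_sided(x: int, y: int, n1: float, n2: float) -> float:
        r = n2 / n1

        def logpmf(k: int) -> float:
            return (k * log(r) + lgamma(x + k + 1) - lgamma(x + 1)
                    - lgamma(k + 1) - (x + k + 1) * log(1.0 + r))

        lower = sum(exp(logpmf(k)) for k in range(0, y + 1))
        upper, k = 0.0, y
        while True:
            term = exp(logpmf(k))
            upper += term
            k += 1
            if term < 1e-18 * max(upper, 1e-300) and k > (x + 1) * r + y + 10:
                break
        return min(1.0, 2.0 * min(lower, upper))

    return max(two_sided(x, y, n1, n2), two_sided(y, x, n2, n1))


def ac_oracle_max_relative_error(n_cases: int = 200, seed: int = 0) -> float:
    """Max relative |fast - brute force| / brute force over a random grid of
    (x, y <= 200) with depth ratios in {0.5, 1, 2}."""
    rng = np.random.default_rng([seed, 1])
    worst = 0.0
    for _ in range(n_cases):
        x = int(rng.integers(0, 201))
        y = int(rng.integers(0, 201))
        ratio = float(rng.choice([0.5, 1.0, 2.0]))
        n1 = 1e5
        fast = audic_claverie_p(x, y, n1, n1 * ratio)
        slow = audic_claverie_p_bruteforce(x, y, n1, n1 * ratio)
        worst = max(worst, abs(fast - slow) / slow)
    return worst


def null_type_one_error(
    n_sims: int = 50, n_genes: int = 1000, depth: int = 200_000, seed: int = 0,
) -> dict[str, float]:
    """Null multinomial libraries with equal true abundances.

    Returns the fraction of genes with p < 0.005 and the mean number of DE
    calls per contrast under the standard preset (p<0.005, FDR<0.01, |lfc|>0.5).
    """
    rng = np.random.default_rng([seed, 2])
    hits = trials = 0
    calls = []
    genes = [f"g{i}" for i in range(n_genes)]
    for _ in range(n_sims):
        p = rng.lognormal(0, 2, n_genes)
        p /= p.sum()
        x = rng.multinomial(depth, p)
        y = rng.multinomial(depth, p)
        pv = audic_claverie_p(x, y, depth, depth)
        hits += int((pv < 0.005).sum())
        trials += n_genes
        table, summary = call_de(
            DEContrast("null", pd.Series(x, index=genes), pd.Series(y, index=genes),
                       depth, depth), thresholds="methods")
        calls.append(summary["total"])
    return {"fraction_p_below_005": hits / trials,
            "mean_calls_per_contrast": float(np.mean(calls)),
            "n_tests": trials}


def de_recovery(
    n_seeds: int = 20, n_genes: int = 1000, n_planted: int = 50,
    depth: int = 200_000, log2fc: float = 2.0, seed: int = 0,
) -> dict[str, float]:
    """Planted fold-change recovery at the standard thresholds.

    Planted genes sit between the 50th and 90th abundance percentile
    (detectable, non-dominant) with alternating up/down effects of
    2^log2fc.  Returns mean sensitivity and false-discovery proportion.
    """
    sens_list, fdp_list = [], []
    genes = [f"g{i}" for i in range(n_genes)]
    for s in range(n_seeds):
        rng = np.random.default_rng([seed, 3, s])
        base = rng.lognormal(0, 2, n_genes)
        lo, hi = np.quantile(base, [0.5, 0.9])
        detectable = np.nonzero((base >= lo) & (base <= hi))[0]
        planted = rng.choice(detectable, size=n_planted, replace=False)
        factor = np.ones(n_genes)
        factor[planted[::2]] = 2.0 ** log2fc
        factor[planted[1::2]] = 2.0 ** (-log2fc)
        pa = base / base.sum()
        pb = base * factor
        pb /= pb.sum()
        x = rng.multinomial(depth, pa)
        y = rng.multinomial(depth, pb)
        table, _ = call_de(
            DEContrast("planted", pd.Series(x, index=genes),
                       pd.Series(y, index=genes), depth, depth),
            thresholds="methods")
        called = set(np.nonzero((table["call"] != "null").to_numpy())[0])
        planted_set = set(planted.tolist())
        sens_list.append(len(called & planted_set) / n_planted)
        fdp_list.append(len(called - planted_set) / max(len(called), 1))
    return {"sensitivity": float(np.mean(sens_list)),
            "fdp": float(np.mean(fdp_list))}


def mapping_oracle_agreement(n_tags: int = 1000, n_genes: int = 120,
                             seed: int = 0) -> dict[str, float]:
    """Fraction of random query tags on which tier-prioritized mapping agrees
    with an exhaustive Hamming scan of the whole reference database."""
    from .cleaning import CleanTagLibrary

    rng = np.random.default_rng([seed, 4])
    transcripts = [(f"T{i:03d}",
                    "".join(rng.choice(list("ACGT"),
                                       size=int(rng.integers(80, 250)))))
                   for i in range(n_genes)]
    db = extract_reference_tags(transcripts)
    ref = [(t.sequence, t.gene_id, t.strand, t.site_rank) for t in db.tags]
    ref_seqs = [r[0] for r in ref]
    tags: dict[str, int] = {}
    for _ in range(n_tags):
        u = rng.random()
        base = ref_seqs[int(rng.integers(0, len(ref_seqs)))]
        if u < 0.4:
            seq = base
        elif u < 0.8:
            pos = int(rng.integers(0, 21))
            alt = str(rng.choice([b for b in "ACGT" if b != base[pos]]))
            seq = base[:pos] + alt + base[pos + 1:]
        else:
            seq = "".join(rng.choice(list("ACGT"), size=21))
        tags[seq] = tags.get(seq, 0) + 1
    counts = pd.Series(tags, dtype=int)
    counts.index.name = "sequence"
    aln, _ = map_tags(CleanTagLibrary("bench", counts, {}), db)

    def oracle(tag: str):
        best: dict[tuple[int, int], dict[str, int]] = {}
        for seq, gene, strand, rank in ref:
            d = sum(a != b for a, b in zip(tag, seq))
            if d <= 1:
                tier = (d, 0 if strand == "sense" else 1)
                slot = best.setdefault(tier, {})
                prev = slot.get(gene)
                slot[gene] = rank if prev is None else min(prev, rank)
        if not best:
            return ("unmapped", None)
        tier = min(best)
        hits = best[tier]
        if len(hits) > 1:
            return ("ambiguous", None)
        (gene, _), = hits.items()
        return ("unambiguous-sense" if tier[1] == 0 else "antisense", gene)

    agree = 0
    for _, row in aln.iterrows():
        cat, gene = oracle(row["sequence"])
        ok = row["category"] == cat
        if cat in ("unambiguous-sense", "antisense"):
            ok = ok and row["gene_id"] == gene
        agree += ok
    return {"agreement": agree / len(aln), "n_tags": len(aln)}


def errorfree_unmapped_fraction(seed: int = 0) -> float:
    """Distinct unmapped fraction of a clean library simulated without errors."""
    cfg = SimulationConfig(n_genes=100, library_depth=30_000, n_timepoints=3,
                           base_error_rate=0.0, adaptor_rate=0.0, lowq_rate=0.0,
                           antisense_rate=0.0, catg_free_fraction=0.0,
                           profile_changes=[(1, 1)], seed=seed)
    _, refdb, _, libs = simulate_study(cfg)
    clean = clean_tags(libs[0], adaptor=cfg.adaptor)
    _, summary = map_tags(clean, refdb)
    return float(summary.set_index("category").loc["unmapped", "distinct_fraction"])


def stc_planted_detection(
    n_seeds: int = 20, n_genes: int = 1000, n_planted: int = 200,
    T: int = 4, seed: int = 0,
) -> dict[str, float]:
    """Detection rate of a profile carrying planted members, and the
    significant-profile rate on label-shuffled data (both over n_seeds)."""
    profiles = stc.select_model_profiles(T=T, c=2, m=20)
    target = profiles[5]
    detected = 0
    null_sig = 0
    for s in range(n_seeds):
        rng = np.random.default_rng([seed, 5, s])
        planted = np.exp2(np.tile(target.values, (n_planted, 1))
                          + rng.normal(0, 0.2, (n_planted, T))) * 50
        null = rng.uniform(1, 300, size=(n_genes - n_planted, T))
        tpm = pd.DataFrame(np.vstack([planted, null]))
        sig = stc.permutation_test(
            tpm, profiles, n_perm=50, seed=s, min_max_tpm=0.0)
        row = sig.set_index("profile_id").loc[target.profile_id]
        detected += bool(row["significant"])

        shuffled = rng.uniform(1, 300, size=(n_genes, T))
        for r in shuffled:
            rng.shuffle(r)
        sig0 = stc.permutation_test(pd.DataFrame(shuffled), profiles, n_perm=50,
                                    seed=s, min_max_tpm=0.0)
        null_sig += int(sig0["significant"].sum())
    return {"detection_rate": detected / n_seeds,
            "null_significant_rate": null_sig / (n_seeds * len(profiles))}


def ctrnn_recovery(n_seeds: int = 20, seed: int = 0) -> dict[str, float]:
    """Mean signed-edge precision/recall of the planted-network experiment."""
    from .ctrnn import signed_edge_recovery

    res = [signed_edge_recovery(seed=int(np.random.default_rng([seed, 6, s])
                                         .integers(0, 2**31)))
           for s in range(n_seeds)]
    return {"precision": float(np.mean([r["precision"] for r in res])),
            "recall": float(np.mean([r["recall"] for r in res]))}
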