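"""Synthetic DGE study generator with planted ground truth.

Emulates a two-condition developmental time-course tag-profiling study
(two pig breeds x ten stages = twenty libraries in the motivating design):
a transcriptome with CATG sites, heavy-tailed expression, planted
differential and temporal genes, a planted signed regulatory network, and
error-bearing raw tag libraries (sequencing errors, adaptor contaminants,
N-containing low-quality tags, antisense tags).  Every library retains a
per-tag origin audit so the downstream pipeline can be verified exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .reference import ReferenceTagDB, extract_reference_tags

BASES = np.frombuffer(b"ACGT", dtype="S1")

#: default adaptor prefix used to mark adaptor-contaminant tags
DEFAULT_ADAPTOR = "TCGTATGCC"

#: stage labels of the motivating 10-point design (5 prenatal, 5 postnatal)
DEFAULT_STAGES_10 = (
    "35 dpc", "49 dpc", "63 dpc", "77 dpc", "91 dpc",
    "2 dpn", "28 dpn", "90 dpn", "120 dpn", "180 dpn",
)


def default_profile_changes(n_timepoints: int) -> list[tuple[int, ...]]:
    """A small set of planted temporal shapes (unit steps between time points)."""
    k = n_timepoints - 1
    up = tuple([1] * k)
    down = tuple([-1] * k)
    pulse = tuple([1] * (k // 2) + [-1] * (k - k // 2))
    late = tuple([0] * (k // 2) + [1] * (k - k // 2))
    return [up, down, pulse, late]


def default_network_spec(n_regulators: int = 5) -> list[tuple[int, int, int]]:
    """Planted signed edges (source index, target index, sign) on a small motif."""
    edges = [(0, 1, 1), (1, 2, 1), (2, 3, -1), (3, 4, 1), (0, 3, -1)]
    return [(s, t, g) for s, t, g in edges if s < n_regulators and t < n_regulators]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Depth defaults to 2e5 tags per library, a ~20x scale-down of the
    ~4.2e6-tag libraries the assay produces in practice; full scale is a
    config change.  All rates are probabilities in [0, 1].
    """

    n_genes: int = 1000
    transcript_length_range: tuple[int, int] = (300, 1500)
    n_conditions: int = 2
    n_timepoints: int = 10
    library_depth: int = 200_000
    base_error_rate: float = 1e-3
    adaptor_rate: float = 0.02
    lowq_rate: float = 0.03
    antisense_rate: float = 0.10
    de_fraction: float = 0.10
    effect_log2fc: float = 2.0
    # planted DE/profile genes are drawn above this baseline-abundance quantile:
    # exact count tests have no power on genes sampled at a handful of tags
    de_baseline_quantile: float = 0.5
    profile_changes: list[tuple[int, ...]] | None = None
    network_spec: list[tuple[int, int, int]] | None = None
    seed: int = 0
    # secondary knobs
    catg_free_fraction: float = 0.05
    n_shared_tag_pairs: int = 2
    site_rank_probs: tuple[float, ...] = (0.85, 0.12, 0.03)
    lognormal_sigma: float = 2.0
    expression_noise_sd: float = 0.1  # per-library log2 jitter on true abundance
    divergence_boundary: int = 5      # condition effects act on t < boundary
    adaptor: str = DEFAULT_ADAPTOR
    condition_labels: tuple[str, ...] = ("LR", "LT")
    timepoint_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("base_error_rate", "adaptor_rate", "lowq_rate",
                     "antisense_rate", "de_fraction", "catg_free_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_timepoints < 3:
            raise ValueError(f"n_timepoints must be >= 3, got {self.n_timepoints}")
        if self.library_depth < 1_000:
            raise ValueError(f"library_depth must be >= 1e3, got {self.library_depth}")
        lo, hi = self.transcript_length_range
        if lo < 25:
            raise ValueError(
                f"transcript_length_range.min must be >= 25 (room for a CATG+17 tag), got {lo}"
            )
        if hi < lo:
            raise ValueError("transcript_length_range must be (min, max) with max >= min")
        if self.n_genes < 0:
            raise ValueError(f"n_genes must be >= 0, got {self.n_genes}")

    # -- derived labels -------------------------------------------------
    @property
    def conditions(self) -> list[str]:
        labels = list(self.condition_labels)
        while len(labels) < self.n_conditions:
            labels.append(f"C{len(labels) + 1}")
        return labels[: self.n_conditions]

    @property
    def timepoints(self) -> list[str]:
        if self.timepoint_labels is not None:
            return list(self.timepoint_labels)[: self.n_timepoints]
        if self.n_timepoints == len(DEFAULT_STAGES_10):
            return list(DEFAULT_STAGES_10)
        return [f"t{i + 1}" for i in range(self.n_timepoints)]

    @property
    def library_ids(self) -> list[str]:
        return [f"{c}{t + 1}" for c in self.conditions for t in range(self.n_timepoints)]

    def library_design(self) -> pd.DataFrame:
        """library_id, condition, timepoint index and label, one row per library."""
        rows = [
            (f"{c}{t + 1}", c, t, self.timepoints[t])
            for c in self.conditions
            for t in range(self.n_timepoints)
        ]
        return pd.DataFrame(rows, columns=["library_id", "condition", "t_index", "stage"])

    def rng(self, stream: int, extra: int | None = None) -> np.random.Generator:
        key = [self.seed, stream] if extra is None else [self.seed, stream, extra]
        return np.random.default_rng(key)


@dataclass
class GroundTruth:
    """Planted truth of one simulated study.

    ``expression`` holds true relative abundances (columns are libraries and
    sum to one).  DE labels are derived from this realized matrix, so every
    labeled gene genuinely carries the planted fold change.
    """

    expression: pd.DataFrame                  # genes x libraries, columns sum to 1
    design: pd.DataFrame                      # library design table
    condition_de_genes: list[str]             # genes with a planted condition effect
    profile_labels: pd.Series                 # gene -> planted profile index, -1 if none
    profile_changes: list[tuple[int, ...]]    # planted change vectors
    network_edges: pd.DataFrame               # source, target, sign, weight
    effect_log2fc: float

    def true_log2fc(self, lib_a: str, lib_b: str) -> pd.Series:
        """log2(abundance in B / abundance in A); zero-abundance genes -> NaN."""
        a = self.expression[lib_a]
        b = self.expression[lib_b]
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = np.log2(b / a)
        return pd.Series(np.where((a > 0) & (b > 0), lfc, np.nan),
                         index=self.expression.index, name="true_log2fc")

    def de_labels(self, lib_a: str, lib_b: str, min_abs_log2fc: float | None = None) -> pd.Series:
        """Per-gene truth for a contrast: 'up' / 'down' (in B vs A) / 'null'."""
        thr = self.effect_log2fc if min_abs_log2fc is None else min_abs_log2fc
        lfc = self.true_log2fc(lib_a, lib_b)
        lab = pd.Series("null", index=lfc.index, name="true_call")
        lab[lfc >= thr] = "up"
        lab[lfc <= -thr] = "down"
        return lab


@dataclass
class RawTagLibrary:
    """One raw (uncleaned) tag library as a sequence -> count multiset."""

    library_id: str
    counts: pd.Series                 # index: 21-nt tag sequence, values: raw count
    audit: pd.DataFrame | None = None  # sequence, gene_id, category, mutated, count

    @property
    def total_raw(self) -> int:
        return int(self.counts.sum())

    @property
    def distinct_raw(self) -> int:
        return int(len(self.counts))


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _scrub_catg(seq: str, rng: np.random.Generator) -> str:
    """Remove every CATG occurrence by mutating its G (re-scanning after each fix)."""
    chars = list(seq)
    s = "".join(chars)
    while True:
        pos = s.find("CATG")
        if pos == -1:
            return s
        chars[pos + 3] = "ACT"[rng.integers(0, 3)]
        s = "".join(chars)


def generate_transcriptome(config: SimulationConfig) -> list[tuple[str, str]]:
    """Random transcript set as (gene_id, sequence) pairs.

    Most transcripts get a CATG site planted near the 3' end (with >= 17 nt
    downstream); a ``catg_free_fraction`` Bernoulli draw per gene yields
    transcripts with no CATG at all (invisible to the assay), and
    ``n_shared_tag_pairs`` pairs of genes share their 3'-most tag to exercise
    ambiguous mapping.
    """
    rng = config.rng(stream=1)
    lo, hi = config.transcript_length_range
    records: list[tuple[str, str]] = []
    catg_free = rng.random(config.n_genes) < config.catg_free_fraction
    for i in range(config.n_genes):
        gene_id = f"G{i:05d}"
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length).tobytes().decode()
        if catg_free[i]:
            seq = _scrub_catg(seq, rng)
        else:
            # plant a qualifying CATG near the 3' end
            margin = int(rng.integers(0, min(40, length - 21) + 1))
            pos = length - 21 - margin
            seq = seq[:pos] + "CATG" + seq[pos + 4:]
        records.append((gene_id, seq))

    # shared 3'-most tags: copy the tail from the 3'-most CATG of gene A into gene B
    bearing = [i for i in range(config.n_genes) if not catg_free[i]]
    n_pairs = min(config.n_shared_tag_pairs, len(bearing) // 2)
    for k in range(n_pairs):
        ia, ib = bearing[2 * k], bearing[2 * k + 1]
        ga, sa = records[ia]
        gb, sb = records[ib]
        pos = _last_qualifying_catg(sa)
        tail = sa[pos:]
        if len(sb) > len(tail):
            records[ib] = (gb, sb[: len(sb) - len(tail)] + tail)
    return records


def _last_qualifying_catg(seq: str) -> int:
    pos = -1
    start = seq.find("CATG")
    while start != -1:
        if start + 21 <= len(seq):
            pos = start
        start = seq.find("CATG", start + 1)
    if pos == -1:
        raise ValueError("no qualifying CATG site")
    return pos


# ---------------------------------------------------------------------------
# expression program
# ---------------------------------------------------------------------------

def simulate_expression(config: SimulationConfig) -> GroundTruth:
    """Plant the true expression program.

    Baseline abundances are log-normal (heavy-tailed, so high-copy tags will
    dominate total tags while being a small minority of distinct tags).  Of
    the ``de_fraction`` planted genes, half receive a condition effect of
    ``±effect_log2fc`` at the prenatal time points (t < divergence_boundary)
    and half follow a planted temporal profile whose unit step equals
    ``effect_log2fc`` in log2 units, in both conditions.
    """
    rng = config.rng(stream=2)
    n = config.n_genes
    genes = [f"G{i:05d}" for i in range(n)]
    design = config.library_design()

    baseline = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=n)

    n_de = int(round(config.de_fraction * n))
    if config.de_fraction > 0 and n_de < 1:
        warnings.warn("de_fraction * n_genes < 1: no DE genes planted")
    # plant effects on detectable but non-dominant genes: below the lower
    # bound an exact count test has no power, and multiplying the extreme
    # tail shifts the whole library composition (spurious global fold change)
    if n:
        lo = np.quantile(baseline, config.de_baseline_quantile)
        hi = np.quantile(baseline, max(config.de_baseline_quantile, 0.95))
        eligible = np.nonzero((baseline >= lo) & (baseline <= hi))[0]
    else:
        eligible = np.array([], dtype=int)
    n_de = min(n_de, len(eligible))
    de_idx = rng.choice(eligible, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    n_cond = n_de // 2
    cond_idx = de_idx[:n_cond]
    prof_idx = de_idx[n_cond:]

    profiles = (config.profile_changes if config.profile_changes is not None
                else default_profile_changes(config.n_timepoints))
    profiles = [tuple(p) for p in profiles]
    for p in profiles:
        if len(p) != config.n_timepoints - 1:
            raise ValueError(
                f"profile change vector length {len(p)} != n_timepoints-1 "
                f"({config.n_timepoints - 1})"
            )

    profile_labels = pd.Series(-1, index=genes, dtype=int, name="profile")
    log2_expr = np.tile(np.log2(baseline)[:, None], (1, len(design)))

    t_index = design["t_index"].to_numpy()
    cond_of = design["condition"].to_numpy()
    second = config.conditions[1] if config.n_conditions >= 2 else None

    # condition effect: alternate up/down in condition 2 at prenatal stages
    for j, gi in enumerate(cond_idx):
        sign = 1.0 if j % 2 == 0 else -1.0
        if second is None:
            break
        mask = (cond_of == second) & (t_index < config.divergence_boundary)
        log2_expr[gi, mask] += sign * config.effect_log2fc

    # temporal profiles: value series rescaled so the planted amplitude
    # (max |log2 deviation from t1|) equals effect_log2fc, keeping planted
    # genes from dominating the library composition
    for j, gi in enumerate(prof_idx):
        pid = j % len(profiles) if profiles else -1
        if pid < 0:
            break
        values = np.concatenate([[0.0], np.cumsum(profiles[pid])])
        peak = np.abs(values).max()
        if peak > 0:
            values = values * (config.effect_log2fc / peak)
        profile_labels.iloc[gi] = pid
        log2_expr[gi, :] += values[t_index]

    if config.expression_noise_sd > 0:
        log2_expr += rng.normal(0.0, config.expression_noise_sd, size=log2_expr.shape)

    expr = np.exp2(log2_expr)
    expr /= expr.sum(axis=0, keepdims=True)
    expression = pd.DataFrame(expr, index=genes, columns=design["library_id"].tolist())

    spec = (config.network_spec if config.network_spec is not None
            else default_network_spec(min(5, n)))
    edges = pd.DataFrame(
        [(genes[s], genes[t], g, float(g) * 2.0) for s, t, g in spec],
        columns=["source", "target", "sign", "weight"],
    )

    return GroundTruth(
        expression=expression,
        design=design,
        condition_de_genes=[genes[i] for i in cond_idx],
        profile_labels=profile_labels,
        profile_changes=profiles,
        network_edges=edges,
        effect_log2fc=config.effect_log2fc,
    )


# ---------------------------------------------------------------------------
# tag libraries
# ---------------------------------------------------------------------------

def _mutate(tags: np.ndarray, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-base substitution on an (n, 21) byte matrix; returns (tags, mutated mask)."""
    if rate <= 0 or tags.size == 0:
        return tags, np.zeros(len(tags), dtype=bool)
    mask = rng.random(tags.shape) < rate
    if mask.any():
        # substitute with a uniformly chosen *different* base
        shift = rng.integers(1, 4, size=int(mask.sum()))
        idx = np.searchsorted(BASES, tags[mask])
        tags = tags.copy()
        tags[mask] = BASES[(idx + shift) % 4]
    return tags, mask.any(axis=1)


def _to_matrix(seqs: list[str]) -> np.ndarray:
    if not seqs:
        return np.empty((0, 21), dtype="S1")
    return np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), 21)


def _rows_to_strs(mat: np.ndarray) -> list[str]:
    if len(mat) == 0:
        return []
    return mat.view(f"S{mat.shape[1]}").ravel().astype(str).tolist()


def simulate_tag_library(
    truth: GroundTruth,
    transcripts: Sequence[tuple[str, str]],
    library_index: int,
    config: SimulationConfig,
    refdb: ReferenceTagDB | None = None,
) -> RawTagLibrary:
    """Sample one raw tag library.

    Total raw tags ~ Poisson(depth); each tag is an adaptor contaminant, an
    N-containing low-quality tag, an antisense tag, or a sense tag, with the
    gene of origin multinomial on the true abundances (restricted to genes
    that actually carry a reference tag on the relevant strand).  Sense tags
    are drawn from the gene's 3'-most sites with ``site_rank_probs`` and each
    gene-derived tag is mutated per base at ``base_error_rate``.  The audit
    table records every tag's origin before aggregation.
    """
    rng = config.rng(stream=3, extra=library_index)
    lib_id = truth.design["library_id"].iloc[library_index]
    if refdb is None:
        refdb = extract_reference_tags(transcripts)

    # per-gene sense tags ordered by rank, and 3'-most antisense tag
    sense_by_gene: dict[str, list[str]] = {}
    anti_by_gene: dict[str, str] = {}
    for t in refdb.tags:
        if t.strand == "sense":
            sense_by_gene.setdefault(t.gene_id, []).append((t.site_rank, t.sequence))
        elif t.site_rank == 1:
            anti_by_gene[t.gene_id] = t.sequence
    sense_by_gene = {g: [s for _, s in sorted(v)] for g, v in sense_by_gene.items()}

    n_raw = int(rng.poisson(config.library_depth))
    if n_raw == 0:
        return RawTagLibrary(lib_id, pd.Series(dtype=int),
                             audit=pd.DataFrame(columns=["sequence", "gene_id", "category",
                                                         "mutated", "count"]))

    p_cat = np.array([config.adaptor_rate, config.lowq_rate, config.antisense_rate])
    p_cat = np.append(p_cat, max(0.0, 1.0 - p_cat.sum()))
    n_adaptor, n_lowq, n_anti, n_sense = rng.multinomial(n_raw, p_cat)

    abund = truth.expression[lib_id]
    records: list[tuple[str, str, str, bool]] = []  # sequence, gene, category, mutated

    def _gene_draw(eligible: list[str], size: int) -> np.ndarray:
        p = abund[eligible].to_numpy()
        tot = p.sum()
        if size == 0 or tot <= 0 or not eligible:
            return np.zeros(len(eligible), dtype=int)
        return rng.multinomial(size, p / tot)

    # sense tags with rank choice
    sense_genes = [g for g in abund.index if g in sense_by_gene]
    counts = _gene_draw(sense_genes, n_sense)
    seqs: list[str] = []
    origins: list[str] = []
    rank_p = np.asarray(config.site_rank_probs, dtype=float)
    for g, c in zip(sense_genes, counts):
        if c == 0:
            continue
        tags = sense_by_gene[g]
        k = min(len(tags), len(rank_p))
        p = rank_p[:k] / rank_p[:k].sum()
        per_rank = rng.multinomial(c, p)
        for r, cr in enumerate(per_rank):
            seqs.extend([tags[r]] * int(cr))
            origins.extend([g] * int(cr))
    mat, mutated = _mutate(_to_matrix(seqs), config.base_error_rate, rng)
    for s, g, m in zip(_rows_to_strs(mat), origins, mutated):
        records.append((s, g, "sense", bool(m)))

    # antisense tags (3'-most antisense reference tag of the gene)
    anti_genes = [g for g in abund.index if g in anti_by_gene]
    counts = _gene_draw(anti_genes, n_anti)
    seqs, origins = [], []
    for g, c in zip(anti_genes, counts):
        seqs.extend([anti_by_gene[g]] * int(c))
        origins.extend([g] * int(c))
    mat, mutated = _mutate(_to_matrix(seqs), config.base_error_rate, rng)
    for s, g, m in zip(_rows_to_strs(mat), origins, mutated):
        records.append((s, g, "antisense", bool(m)))

    # low-quality tags: a sense-like tag with >= 1 position set to N
    counts = _gene_draw(sense_genes, n_lowq)
    for g, c in zip(sense_genes, counts):
        base_tag = sense_by_gene[g][0]
        for _ in range(int(c)):
            pos = int(rng.integers(0, 21))
            records.append((base_tag[:pos] + "N" + base_tag[pos + 1:], g, "lowq", False))

    # adaptor contaminants: fixed prefix + random filler
    for _ in range(int(n_adaptor)):
        filler = _random_seq(rng, 21 - len(config.adaptor)).tobytes().decode()
        records.append((config.adaptor + filler, "", "adaptor", False))

    audit = pd.DataFrame(records, columns=["sequence", "gene_id", "category", "mutated"])
    audit = (audit.groupby(["sequence", "gene_id", "category", "mutated"], sort=True)
             .size().rename("count").reset_index())
    counts_series = audit.groupby("sequence", sort=True)["count"].sum().astype(int)
    counts_series.name = lib_id
    return RawTagLibrary(lib_id, counts_series, audit=audit)


def simulate_study(config: SimulationConfig):
    """Transcriptome + truth + all raw libraries, with one shared reference DB.

    Returns ``(transcripts, refdb, truth, libraries)``.
    """
    transcripts = generate_transcriptome(config)
    refdb = extract_reference_tags(transcripts)
    truth = simulate_expression(config)
    libraries = [
        simulate_tag_library(truth, transcripts, i, config, refdb=refdb)
        for i in range(len(truth.design))
    ]
    return transcripts, refdb, truth, libraries
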