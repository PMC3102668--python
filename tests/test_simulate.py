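"""Synthetic study generator: determinism, planted structure, error model."""

import io as _io

import numpy as np
import pytest
from scipy import stats

from dgetag.cleaning import clean_tags
from dgetag.mapping import map_tags
from dgetag.reference import extract_reference_tags
from dgetag.simulate import (SimulationConfig, generate_transcriptome,
                             simulate_expression, simulate_study,
                             simulate_tag_library)
from dgetag.io import write_fasta


def test_zero_genes_yields_empty_collection():
    cfg = SimulationConfig(n_genes=0, seed=1)
    assert generate_transcriptome(cfg) == []


def test_fixed_seed_gives_byte_identical_fasta(tmp_path):
    cfg = SimulationConfig(n_genes=40, seed=5)
    paths = []
    for k in range(2):
        p = tmp_path / f"run{k}.fasta"
        write_fasta(generate_transcriptome(cfg), p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_invalid_config_names_offending_field():
    with pytest.raises(ValueError, match="transcript_length_range.min"):
        SimulationConfig(transcript_length_range=(20, 100))
    with pytest.raises(ValueError, match="adaptor_rate"):
        SimulationConfig(adaptor_rate=1.5)
    with pytest.raises(ValueError, match="n_timepoints"):
        SimulationConfig(n_timepoints=2)


def test_catg_free_count_is_binomial_across_seeds():
    """Fraction of CATG-free transcripts ~ Binomial(n, 0.05): the total over
    200 independent seeds must sit inside a 5-sigma binomial band."""
    n_genes, n_seeds, p = 100, 200, 0.05
    total_free = 0
    for seed in range(n_seeds):
        cfg = SimulationConfig(n_genes=n_genes, transcript_length_range=(60, 120),
                               seed=seed)
        for _, seq in generate_transcriptome(cfg):
            has_site = any(seq[i:i + 4] == "CATG" and i + 21 <= len(seq)
                           for i in range(len(seq)))
            total_free += not has_site
    n = n_genes * n_seeds
    sd = np.sqrt(n * p * (1 - p))
    assert abs(total_free - n * p) < 5 * sd


def test_most_transcripts_carry_a_qualifying_site():
    cfg = SimulationConfig(n_genes=300, seed=11)
    transcripts = generate_transcriptome(cfg)
    db = extract_reference_tags(transcripts)
    assert db.n_genes_with_site >= 0.9 * cfg.n_genes


def test_shared_tag_pairs_produce_ambiguous_sequences():
    cfg = SimulationConfig(n_genes=60, n_shared_tag_pairs=3, seed=2)
    db = extract_reference_tags(generate_transcriptome(cfg))
    shared = [s for s, genes in db.ambiguity_index.items() if len(genes) > 1]
    assert len(shared) >= 3


def test_zero_de_fraction_plants_nothing():
    cfg = SimulationConfig(n_genes=50, de_fraction=0.0, n_timepoints=4,
                           profile_changes=[(1, 1, 1)], seed=3)
    truth = simulate_expression(cfg)
    assert truth.condition_de_genes == []
    assert (truth.profile_labels == -1).all()


def test_abundances_sum_to_one_per_library(small_study):
    _, _, truth, _ = small_study
    np.testing.assert_allclose(truth.expression.sum(axis=0), 1.0, rtol=1e-12)


def test_planted_condition_genes_carry_the_effect():
    cfg = SimulationConfig(n_genes=200, n_timepoints=4, effect_log2fc=2.0,
                           expression_noise_sd=0.0, divergence_boundary=2,
                           profile_changes=[(1, 1, 1)], seed=9)
    truth = simulate_expression(cfg)
    lfc = truth.true_log2fc("LR1", "LT1")  # between conditions at a prenatal stage
    planted = truth.condition_de_genes
    # composition renormalization shifts are the only deviation from +-2
    assert (lfc[planted].abs() > 1.5).all()
    labels = truth.de_labels("LR1", "LT1", min_abs_log2fc=1.5)
    assert set(labels[planted]) <= {"up", "down"}


def test_heavy_tail_top_genes_dominate_mass():
    """With the default log-normal sigma the top 3% of genes carry > 50% of
    the expression mass (direct summation over the generated matrix)."""
    cfg = SimulationConfig(n_genes=1000, seed=13)
    truth = simulate_expression(cfg)
    col = truth.expression.iloc[:, 0].sort_values(ascending=False)
    top = col.iloc[: int(0.03 * len(col))].sum()
    assert top > 0.5


def test_errorfree_library_contains_only_exact_sense_tags(errorfree_study):
    transcripts, refdb, truth, libraries = errorfree_study
    ref_sense = {t.sequence for t in refdb.tags if t.strand == "sense"}
    for lib in libraries[:2]:
        assert set(lib.counts.index) <= ref_sense


def test_single_gene_library_collapses_to_one_clean_tag():
    cfg = SimulationConfig(n_genes=1, library_depth=10_000, n_timepoints=3,
                           base_error_rate=0.0, adaptor_rate=0.0, lowq_rate=0.0,
                           antisense_rate=0.0, catg_free_fraction=0.0,
                           site_rank_probs=(1.0,), de_fraction=0.0,
                           profile_changes=[(0, 0)], expression_noise_sd=0.0, seed=4)
    transcripts, refdb, truth, libs = (lambda s: s)(simulate_study(cfg))
    clean = clean_tags(libs[0], adaptor=cfg.adaptor)
    assert clean.distinct_clean == 1
    assert clean.total_clean == libs[0].total_raw


def test_mutated_tag_fraction_matches_closed_form():
    """P(tag carries >= 1 substitution) = 1 - (1-e)^21; the empirical fraction
    over ~1e5 gene-derived tags must fall within 3 binomial SDs."""
    e = 1e-3
    cfg = SimulationConfig(n_genes=100, library_depth=100_000, n_timepoints=3,
                           base_error_rate=e, adaptor_rate=0.0, lowq_rate=0.0,
                           antisense_rate=0.0, catg_free_fraction=0.0,
                           profile_changes=[(1, 1)], seed=21)
    transcripts = generate_transcriptome(cfg)
    truth = simulate_expression(cfg)
    lib = simulate_tag_library(truth, transcripts, 0, cfg)
    gene_tags = lib.audit[lib.audit["category"].isin(["sense", "antisense"])]
    n = gene_tags["count"].sum()
    frac = gene_tags.loc[gene_tags["mutated"], "count"].sum() / n
    expected = 1.0 - (1.0 - e) ** 21
    assert expected == pytest.approx(0.0208, abs=2e-4)
    sd = np.sqrt(expected * (1 - expected) / n)
    assert abs(frac - expected) < 3 * sd


def test_library_composition_converges_to_truth():
    """Sense-tag share per gene approaches the true abundance as depth grows
    (multinomial conservation, checked at depth 1e6 within 3 SDs for the
    most abundant genes)."""
    cfg = SimulationConfig(n_genes=50, library_depth=1_000_000, n_timepoints=3,
                           base_error_rate=0.0, adaptor_rate=0.0, lowq_rate=0.0,
                           antisense_rate=0.0, catg_free_fraction=0.0,
                           de_fraction=0.0, expression_noise_sd=0.0,
                           profile_changes=[(0, 0)], seed=17)
    transcripts = generate_transcriptome(cfg)
    truth = simulate_expression(cfg)
    lib = simulate_tag_library(truth, transcripts, 0, cfg)
    sense = lib.audit[lib.audit["category"] == "sense"]
    per_gene = sense.groupby("gene_id")["count"].sum()
    n = per_gene.sum()
    p = truth.expression.iloc[:, 0]
    for gene in p.sort_values(ascending=False).index[:10]:
        observed = per_gene.get(gene, 0) / n
        sd = np.sqrt(p[gene] * (1 - p[gene]) / n)
        assert abs(observed - p[gene]) < 3 * sd + 1e-12


def test_errorfree_roundtrip_maps_every_clean_tag(errorfree_study):
    transcripts, refdb, truth, libraries = errorfree_study
    clean = clean_tags(libraries[0], adaptor="TCGTATGCC")
    _, summary = map_tags(clean, refdb)
    unmapped = summary.set_index("category").loc["unmapped", "distinct_tags"]
    assert unmapped == 0


def test_identical_seed_identical_libraries(small_config):
    lib_a = simulate_study(small_config)[3][0]
    lib_b = simulate_study(small_config)[3][0]
    assert lib_a.counts.equals(lib_b.counts)
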