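"""End-to-end pipeline: simulate -> reference -> clean -> map -> quantify ->
differential expression -> temporal clustering -> enrichment -> similarity ->
network, with a reproducibility manifest.

Every stage writes plain TSV/FASTA/Newick/JSON files under the output
directory and the manifest records each file's SHA-256 checksum together with
the parameters and seed, so a rerun with the same configuration is
byte-verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cleaning, ctrnn, de, enrichment, io, mapping, similarity, stc
from .reference import extract_reference_tags, ambiguity_classify
from .simulate import GroundTruth, SimulationConfig, simulate_study

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    """All stage parameters behind one object (YAML-loadable)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: str = "dgetag_run"
    preset: str = "methods"        # DE threshold preset: "methods" | "results"
    stc_c: int = 2
    stc_m: int = 80
    stc_n_perm: int = 50
    stc_min_max_tpm: float = 5.0
    prenatal_boundary: int = 5     # STC splits the series at this time index
    profile_correlation_threshold: float = 0.7
    linkage: str = "average"
    network_threshold: float = 0.2
    network_lambda: float = 0.001
    network_epochs: int = 5000
    rank1_only: bool = False
    n_random_gene_sets: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        for tup_field in ("transcript_length_range", "site_rank_probs",
                          "condition_labels", "timepoint_labels"):
            if tup_field in sim_raw and sim_raw[tup_field] is not None:
                sim_raw[tup_field] = tuple(sim_raw[tup_field])
        if "profile_changes" in sim_raw and sim_raw["profile_changes"] is not None:
            sim_raw["profile_changes"] = [tuple(p) for p in sim_raw["profile_changes"]]
        if "network_spec" in sim_raw and sim_raw["network_spec"] is not None:
            sim_raw["network_spec"] = [tuple(e) for e in sim_raw["network_spec"]]
        return cls(simulation=SimulationConfig(**sim_raw), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def contrast_plan(conditions: list[str], timepoints: list[str]) -> pd.DataFrame:
    """Within-condition consecutive-stage contrasts plus between-condition
    same-stage contrasts.

    Labels follow the "COND-later/earlier" convention (e.g. "LR-49 dpc/35 dpc")
    for consecutive stages and "C2/C1-stage" for between-condition pairs; the
    second library of each pair is the numerator (the "y" side).
    """
    T = len(timepoints)
    if T < 2:
        raise ValueError("need at least 2 time points")
    rows = []
    for c in conditions:
        for t in range(1, T):
            rows.append({
                "lib_a": f"{c}{t}", "lib_b": f"{c}{t + 1}",
                "label": f"{c}-{timepoints[t]}/{timepoints[t - 1]}",
                "kind": "within",
            })
    if len(conditions) >= 2:
        c1, c2 = conditions[0], conditions[1]
        for t in range(T):
            rows.append({
                "lib_a": f"{c1}{t + 1}", "lib_b": f"{c2}{t + 1}",
                "label": f"{c2}/{c1}-{timepoints[t]}",
                "kind": "between",
            })
    return pd.DataFrame(rows)


def make_synthetic_gene_sets(
    truth: GroundTruth, universe: list[str], n_random: int = 10, seed: int = 0,
) -> dict[str, set[str]]:
    """Gene sets with known structure: the planted DE genes, each planted
    temporal profile's members, and random terms as the null background."""
    rng = np.random.default_rng([seed, 17])
    uni = [g for g in universe]
    terms: dict[str, set[str]] = {}
    planted = set(truth.condition_de_genes) & set(uni)
    if planted:
        terms["PLANTED_DE"] = planted
    for pid in sorted(set(truth.profile_labels[truth.profile_labels >= 0])):
        members = set(truth.profile_labels[truth.profile_labels == pid].index) & set(uni)
        if members:
            terms[f"PROFILE_{pid}"] = members
    for k in range(n_random):
        size = int(rng.integers(10, max(11, len(uni) // 10)))
        terms[f"RANDOM_{k:02d}"] = set(rng.choice(uni, size=min(size, len(uni)), replace=False))
    return terms


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the manifest (also written).

    Stage failures propagate with the failing stage named; outputs of earlier
    stages remain on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    stage = "simulate"
    try:
        manifest: dict = {"seed": sim.seed, "params": config.to_dict(), "files": {}}

        # --- simulate ---------------------------------------------------
        transcripts, refdb, truth, libraries = simulate_study(sim)
        io.write_fasta(transcripts, out / "transcripts.fasta")
        gt_dir = out / "ground_truth"
        gt_dir.mkdir(exist_ok=True)
        _write_tsv(truth.expression.rename_axis("gene_id"), gt_dir / "expression.tsv", index=True)
        _write_tsv(truth.profile_labels.rename_axis("gene_id").reset_index(),
                   gt_dir / "profile_labels.tsv")
        _write_tsv(truth.network_edges, gt_dir / "network_edges.tsv")
        _write_tsv(truth.design, gt_dir / "design.tsv")
        raw_dir = out / "raw"
        raw_dir.mkdir(exist_ok=True)
        for lib in libraries:
            io.write_tag_counts(lib.counts, raw_dir / f"{lib.library_id}.tsv")

        # --- reference ----------------------------------------------------
        stage = "build-ref"
        flags, ref_summary = ambiguity_classify(refdb)
        ref_dir = out / "reference"
        ref_dir.mkdir(exist_ok=True)
        ref_df = pd.DataFrame(
            [(t.sequence, t.gene_id, t.strand, t.site_rank, flags[t.sequence])
             for t in refdb.tags],
            columns=["sequence", "gene_id", "strand", "site_rank", "unambiguous"],
        )
        _write_tsv(ref_df, ref_dir / "tags.tsv")
        _write_tsv(pd.DataFrame([ref_summary]), ref_dir / "summary.tsv")

        # --- clean ----------------------------------------------------------
        stage = "clean"
        clean_dir = out / "clean"
        clean_dir.mkdir(exist_ok=True)
        cleans = {}
        ledger_rows = []
        for lib in libraries:
            cl = cleaning.clean_tags(lib, adaptor=sim.adaptor)
            cleans[cl.library_id] = cl
            io.write_tag_counts(cl.counts, clean_dir / f"{cl.library_id}.tsv")
            ledger_rows.append({"library_id": cl.library_id,
                                "total_raw": lib.total_raw,
                                "total_clean": cl.total_clean,
                                "distinct_clean": cl.distinct_clean,
                                **cl.filter_ledger})
        _write_tsv(pd.DataFrame(ledger_rows), clean_dir / "ledger.tsv")

        # diagnostics on the first library
        stage = "diagnostics"
        diag_dir = out / "diagnostics"
        diag_dir.mkdir(exist_ok=True)
        first = libraries[0]
        _write_tsv(cleaning.copy_number_distribution(cleans[first.library_id]),
                   diag_dir / "copy_number.tsv")
        grid = [max(1, int(f * first.total_raw)) for f in (0.1, 0.25, 0.5, 0.75, 1.0)]
        _write_tsv(cleaning.saturation_curve(first, grid, refdb=refdb,
                                             adaptor=sim.adaptor, seed=sim.seed),
                   diag_dir / "saturation.tsv")

        # --- map + quantify -------------------------------------------------
        stage = "map"
        map_dir = out / "mapping"
        map_dir.mkdir(exist_ok=True)
        per_library = {}
        summaries = []
        for lib_id, cl in cleans.items():
            aln, summ = mapping.map_tags(cl, refdb)
            per_library[lib_id] = (aln, cl)
            summ.insert(0, "library_id", lib_id)
            summaries.append(summ)
        _write_tsv(pd.concat(summaries, ignore_index=True), map_dir / "category_summary.tsv")
        pos = mapping.tag_position_report(per_library[libraries[0].library_id][0])
        _write_tsv(pos.rename_axis("site_rank").reset_index(), map_dir / "tag_positions.tsv")

        stage = "quantify"
        genes = list(truth.expression.index)
        expr = mapping.quantify(per_library, genes, rank1_only=config.rank1_only)
        _write_tsv(expr.counts.rename_axis("gene_id"), map_dir / "counts.tsv", index=True)
        _write_tsv(expr.tpm.rename_axis("gene_id"), map_dir / "tpm.tsv", index=True)

        # --- differential expression -----------------------------------------
        stage = "de"
        de_dir = out / "de"
        de_dir.mkdir(exist_ok=True)
        plan = contrast_plan(sim.conditions, sim.timepoints)
        _write_tsv(plan, de_dir / "contrast_plan.tsv")
        de_summary_rows = []
        de_genes_all: set[str] = set()
        for _, row in plan.iterrows():
            contrast = de.DEContrast(
                name=row["label"],
                x=expr.counts[row["lib_a"]],
                y=expr.counts[row["lib_b"]],
                n1=int(expr.total_clean[row["lib_a"]]),
                n2=int(expr.total_clean[row["lib_b"]]),
            )
            table, summary = de.call_de(contrast, thresholds=config.preset)
            safe = row["label"].replace("/", "_vs_").replace(" ", "")
            _write_tsv(table.rename_axis("gene_id"), de_dir / f"{safe}.tsv", index=True)
            de_summary_rows.append({"contrast": row["label"], **summary})
            de_genes_all |= set(table.index[table["call"] != "null"])
        _write_tsv(pd.DataFrame(de_summary_rows), de_dir / "summary.tsv")

        # --- STC ---------------------------------------------------------------
        stage = "stc"
        stc_dir = out / "stc"
        stc_dir.mkdir(exist_ok=True)
        profile_cache: dict[int, list[stc.ModelProfile]] = {}
        boundary = config.prenatal_boundary
        segments = {
            "prenatal": slice(0, boundary),
            "postnatal": slice(boundary, sim.n_timepoints),
            "full": slice(0, sim.n_timepoints),
        }
        for cond in sim.conditions:
            for seg_name, seg in segments.items():
                tpm_seg = expr.condition_series(truth.design, cond, seg)
                T = tpm_seg.shape[1]
                if T < 3:
                    continue
                if T not in profile_cache:
                    space = (2 * config.stc_c + 1) ** (T - 1)
                    profile_cache[T] = stc.select_model_profiles(
                        T, config.stc_c, min(config.stc_m, space))
                profiles = profile_cache[T]
                sig = stc.permutation_test(
                    tpm_seg, profiles, n_perm=config.stc_n_perm,
                    seed=sim.seed, min_max_tpm=config.stc_min_max_tpm)
                series = stc.normalize_gene_series(tpm_seg, min_max_tpm=config.stc_min_max_tpm)
                assign = stc.assign_genes(series, profiles)
                clusters = stc.group_significant_profiles(
                    profiles, sig, config.profile_correlation_threshold)
                tag = f"{cond}_{seg_name}"
                _write_tsv(sig, stc_dir / f"{tag}_significance.tsv")
                _write_tsv(assign.rename_axis("gene_id").reset_index(),
                           stc_dir / f"{tag}_assignments.tsv")
                with open(stc_dir / f"{tag}_clusters.tsv", "w") as fh:
                    fh.write("cluster\tprofile_ids\n")
                    for k, cl in enumerate(clusters):
                        fh.write(f"{k}\t{','.join(map(str, cl))}\n")

        # --- enrichment ---------------------------------------------------------
        stage = "enrich"
        enr_dir = out / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        detected = [g for g in genes if expr.counts.loc[g].sum() > 0]
        terms = make_synthetic_gene_sets(truth, detected,
                                         n_random=config.n_random_gene_sets, seed=sim.seed)
        io.write_gmt(terms, enr_dir / "gene_sets.gmt")
        collection = enrichment.GeneSetCollection(terms=terms, universe=set(detected))
        de_in_universe = de_genes_all & set(detected)
        if de_in_universe:
            res = enrichment.fisher_enrich(de_in_universe, collection)
            _write_tsv(res, enr_dir / "de_enrichment.tsv")

        # --- similarity ------------------------------------------------------------
        stage = "similarity"
        sim_dir = out / "similarity"
        sim_dir.mkdir(exist_ok=True)
        corr = similarity.correlation_matrix(expr.tpm)
        _write_tsv(corr.rename_axis("library_id"), sim_dir / "correlation.tsv", index=True)
        (sim_dir / "tree.nwk").write_text(
            similarity.hierarchical_cluster(corr, method=config.linkage) + "\n")

        # --- network ------------------------------------------------------------------
        stage = "network"
        net_dir = out / "network"
        net_dir.mkdir(exist_ok=True)
        prior = ctrnn.PriorNetwork(truth.network_edges[["source", "target", "sign"]]
                                   .assign(direct=True))
        net_genes = [g for g in prior.nodes if g in expr.tpm.index]
        for cond in sim.conditions:
            tpm_cond = expr.condition_series(truth.design, cond).loc[net_genes]
            series = stc.normalize_gene_series(tpm_cond, min_max_tpm=0.0)
            z = series.sub(series.mean(axis=1), axis=0)
            sd = series.std(axis=1).replace(0.0, 1.0)
            z = z.div(sd, axis=0)
            model = ctrnn.fit_ctrnn(z, prior, lam=config.network_lambda,
                                    epochs=config.network_epochs, seed=sim.seed)
            inferred, net_summary = ctrnn.score_interactions(
                model, prior, threshold=config.network_threshold,
                de_genes=de_genes_all)
            _write_tsv(inferred, net_dir / f"{cond}_edges.tsv")
            (net_dir / f"{cond}_summary.json").write_text(
                json.dumps(net_summary, sort_keys=True) + "\n")

        # --- manifest ------------------------------------------------------------------
        stage = "manifest"
        for path in sorted(out.rglob("*")):
            if path.is_file() and path.name != "manifest.json":
                manifest["files"][str(path.relative_to(out))] = _sha256(path)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
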