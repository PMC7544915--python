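"""End-to-end orchestration: filter -> coexpression -> rewiring -> cross-layer
-> differential expression -> enrichment -> prediction, from one config.

Every threshold appears once here with its conventional default (2 / 1 CPM
in >= 5 samples; |r| > 0.98 at FDR < 0.02 for the all-sample network;
0.99 / 0.1 / 1.95 rewiring constants; |r| > 0.85 cross-layer; p <= 0.03
consensus with eFDR <= 0.05; enrichment FDR < 0.10; panel FDR < 0.03;
5000 / 10000 permutations; 2000-seed sweep). A JSON manifest records the
config, seed and package version so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coexpression import network_edges
from .crosslayer import cross_correlation, cross_layer_rewiring, efdr_cross_layer, overlay_interactions
from .diffexpr import efdr_de, loo_validation, run_de
from .enrichment import run_enrichment
from .io import (
    CountMatrix,
    FeatureAnnotation,
    Outcome,
    SampleTable,
    compute_cpm,
    filter_expressed,
    log2_cpm,
    read_annotation,
    read_counts,
    read_sample_table,
    subset_biotype,
)
from .prediction import seed_sweep, select_panel, vst_transform
from .rewiring import RewireThresholds, consensus_rewired_edges, efdr_rewiring, groupwise_correlation

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths, thresholds and stage toggles for one pipeline run."""

    # inputs
    mrna_counts: str | None = None
    mirna_counts: str | None = None
    sample_table: str | None = None
    annotation: str | None = None
    interactions: str | None = None  # optional miRNA-target two-column TSV
    gene_sets: str | None = None  # optional term_id/gene_id TSV
    out_dir: str = "rewirenet_out"

    # filtering
    min_cpm_mrna: float = 2.0
    min_cpm_mirna: float = 1.0
    min_samples: int = 5

    # all-sample network
    network_min_abs_r: float = 0.98
    network_max_fdr: float = 0.02

    # rewiring rules
    inverted_gap: float = 1.95
    present_abs_r: float = 0.99
    absent_band: float = 0.1
    n_perm_rewiring: int = 5000

    # cross-layer
    cross_min_abs_r: float = 0.85
    n_perm_cross: int = 5000

    # differential expression
    de_p_cut: float = 0.03
    de_max_efdr: float = 0.05
    n_perm_de: int = 10000
    de_focal: str = Outcome.NON_PREG.value
    de_reference: str = Outcome.AI_PREG.value

    # enrichment
    enrichment_max_fdr: float = 0.10
    n_enrichment_samplings: int = 10000

    # prediction
    panel_max_fdr: float = 0.03
    n_prediction_runs: int = 2000
    train_year: int = 1
    test_year: int = 2

    seed: int = 17
    stages: tuple[str, ...] = ("filter", "coexpr", "rewire", "mirna", "de", "enrich", "predict")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def manifest(self) -> dict:
        cfg = dataclasses.asdict(self)
        cfg["stages"] = list(self.stages)
        blob = json.dumps(cfg, sort_keys=True, default=str)
        return {
            "package": "rewirenet",
            "version": __version__,
            "config": cfg,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        }


def _rewire_thresholds(cfg: RunConfig) -> RewireThresholds:
    return RewireThresholds(cfg.inverted_gap, cfg.present_abs_r, cfg.absent_band)


def run_pipeline(
    cfg: RunConfig,
    mrna: CountMatrix | None = None,
    mirna: CountMatrix | None = None,
    samples: SampleTable | None = None,
    annotation: FeatureAnnotation | None = None,
) -> dict:
    """Execute the toggled stages; in-memory inputs take precedence over
    paths. Stage outputs are written under ``cfg.out_dir`` and returned in a
    result bundle; a failing stage halts with its name and cause."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if mrna is None and cfg.mrna_counts:
        mrna = read_counts(cfg.mrna_counts, "mRNA")
    if mirna is None and cfg.mirna_counts:
        mirna = read_counts(cfg.mirna_counts, "miRNA")
    if samples is None and cfg.sample_table:
        samples = read_sample_table(cfg.sample_table)
    if annotation is None and cfg.annotation:
        annotation = read_annotation(cfg.annotation)
    if mrna is None or samples is None:
        raise ValueError("stage inputs: need at least an mRNA count matrix and sample table")
    samples.check_covers(mrna)

    def _stage(name: str) -> bool:
        return name in cfg.stages

    def _fail(name: str, exc: Exception):
        raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    # ----- filter -----------------------------------------------------
    try:
        if _stage("filter"):
            report = {}
            report["mrna_raw"] = mrna.n_features
            mrna_f = filter_expressed(compute_cpm(mrna), mrna, cfg.min_cpm_mrna, cfg.min_samples)
            report["mrna_expressed"] = mrna_f.n_features
            if annotation is not None:
                mrna_f = subset_biotype(mrna_f, annotation, "protein_coding")
            report["mrna_protein_coding"] = mrna_f.n_features
            mrna = mrna_f
            if mirna is not None:
                report["mirna_raw"] = mirna.n_features
                mirna_f = filter_expressed(
                    compute_cpm(mirna), mirna, cfg.min_cpm_mirna, cfg.min_samples
                )
                report["mirna_expressed"] = mirna_f.n_features
                if annotation is not None:
                    mirna_f = subset_biotype(mirna_f, annotation, "miRNA")
                report["mirna_kept"] = mirna_f.n_features
                mirna = mirna_f
            mrna.counts.to_csv(out / "filtered_mrna_counts.tsv", sep="\t", index_label="feature_id")
            compute_cpm(mrna).values.to_csv(out / "mrna_cpm.tsv", sep="\t", index_label="feature_id")
            (out / "filter_report.json").write_text(json.dumps(report, indent=1))
            results["filter_report"] = report
    except Exception as exc:
        _fail("filter", exc)

    em = log2_cpm(mrna)
    em_mi = log2_cpm(mirna) if mirna is not None else None
    th = _rewire_thresholds(cfg)

    # ----- all-sample coexpression network ----------------------------
    try:
        if _stage("coexpr"):
            edges = network_edges(em, cfg.network_min_abs_r, cfg.network_max_fdr)
            edges.to_csv(out / "coexpression_edges.tsv", sep="\t", index=False)
            results["coexpression_edges"] = edges
    except Exception as exc:
        _fail("coexpr", exc)

    # ----- rewiring ----------------------------------------------------
    try:
        if _stage("rewire"):
            gct = groupwise_correlation(em, samples)
            rew = consensus_rewired_edges(gct, th)
            ef = efdr_rewiring(
                em, samples, th, cfg.n_perm_rewiring, seed=cfg.seed
            )
            rew["efdr"] = ef.efdr
            rew.to_csv(out / "rewired_edges.tsv", sep="\t", index=False)
            (out / "rewiring_efdr.json").write_text(
                json.dumps(
                    {
                        "observed": ef.observed,
                        "mean_scrambled": ef.mean_scrambled,
                        "efdr": ef.efdr,
                        "per_class": {
                            k: v.efdr for k, v in (ef.per_class or {}).items()
                        },
                    },
                    indent=1,
                )
            )
            results["rewired_edges"] = rew
            results["rewiring_efdr"] = ef
    except Exception as exc:
        _fail("rewire", exc)

    # ----- cross-layer --------------------------------------------------
    try:
        if _stage("mirna") and em_mi is not None:
            pairs = cross_correlation(em_mi, em, cfg.cross_min_abs_r)
            ef = efdr_cross_layer(
                em_mi, em, cfg.cross_min_abs_r, cfg.n_perm_cross, seed=cfg.seed
            )
            rew = cross_layer_rewiring(em_mi, em, samples, th)
            if cfg.interactions:
                inter = pd.read_csv(cfg.interactions, sep="\t")
                pairs = overlay_interactions(pairs, inter)
                rew = overlay_interactions(rew, inter)
            pairs[pairs["selected"]].to_csv(out / "crosslayer_pairs.tsv", sep="\t", index=False)
            rew.to_csv(out / "crosslayer_rewired.tsv", sep="\t", index=False)
            results["crosslayer_pairs"] = pairs
            results["crosslayer_efdr"] = ef
            results["crosslayer_rewired"] = rew
    except Exception as exc:
        _fail("mirna", exc)

    # ----- differential expression --------------------------------------
    try:
        if _stage("de"):
            de = run_de(mrna, samples, cfg.de_focal, cfg.de_reference, cfg.de_p_cut)
            ef = efdr_de(
                mrna, samples, cfg.de_focal, cfg.de_reference, cfg.de_p_cut,
                cfg.n_perm_de, seed=cfg.seed,
            )
            de["efdr"] = ef.efdr
            loo = loo_validation(
                mrna, samples, cfg.de_focal, cfg.de_reference, cfg.de_p_cut,
                genes=list(de.index[de["consensus"]]),
            )
            de["loo_pass"] = loo.reindex(de.index, fill_value=False)
            de.to_csv(out / "de_table.tsv", sep="\t", index_label="gene_id")
            results["de_table"] = de
            results["de_efdr"] = ef
    except Exception as exc:
        _fail("de", exc)

    # ----- enrichment ----------------------------------------------------
    try:
        if _stage("enrich") and cfg.gene_sets and annotation is not None:
            if "de_table" not in results:
                raise ValueError("enrichment needs the 'de' stage output")
            de = results["de_table"]
            selected = list(de.index[de["consensus"] & de["loo_pass"]])
            from .enrichment import read_gene_sets

            gs = read_gene_sets(cfg.gene_sets)
            enr = run_enrichment(
                gs, selected, list(de.index), annotation.table["length_bp"],
                cfg.n_enrichment_samplings, seed=cfg.seed,
            )
            if not enr.empty:
                enr["significant"] = enr["fdr_by"] < cfg.enrichment_max_fdr
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            results["enrichment"] = enr
    except Exception as exc:
        _fail("enrich", exc)

    # ----- prediction ----------------------------------------------------
    try:
        if _stage("predict"):
            years = samples.years(mrna.sample_ids)
            if set(years.unique()) < {cfg.train_year, cfg.test_year}:
                raise ValueError("prediction needs both cohort years present")
            panel = select_panel(
                mrna, samples, Outcome.AI_PREG.value, Outcome.NON_PREG.value,
                cfg.panel_max_fdr,
            )
            keep = samples.outcomes(mrna.sample_ids).isin(
                [Outcome.AI_PREG.value, Outcome.NON_PREG.value]
            )
            ids = pd.Index(mrna.sample_ids)[keep.to_numpy()]
            train_ids = [s for s in ids if samples.years([s]).iloc[0] == cfg.train_year]
            test_ids = [s for s in ids if samples.years([s]).iloc[0] == cfg.test_year]
            train = vst_transform(mrna.subset_samples(train_ids), panel, fit=True)
            test = vst_transform(mrna.subset_samples(test_ids), panel)
            labels = samples.outcomes(mrna.sample_ids)
            runs, hist, importance = seed_sweep(
                train, test, labels, labels,
                n_runs=cfg.n_prediction_runs, base_seed=cfg.seed,
            )
            hist.to_csv(out / "prediction_histogram.tsv", sep="\t", index=False)
            importance.to_csv(out / "variable_importance.tsv", sep="\t", index_label="gene_id")
            pd.DataFrame(
                {"seed": [r.seed for r in runs], "n_correct": [r.n_correct for r in runs],
                 "accuracy": [r.accuracy for r in runs]}
            ).to_csv(out / "prediction_runs.tsv", sep="\t", index=False)
            results["prediction_runs"] = runs
            results["prediction_histogram"] = hist
            results["variable_importance"] = importance
            results["panel"] = panel
    except Exception as exc:
        _fail("predict", exc)

    (out / "manifest.json").write_text(json.dumps(cfg.manifest(), indent=1))
    results["manifest"] = cfg.manifest()
    return results
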