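"""End-to-end orchestration: simulate (or load) elution data, build
features, label pairs, train and calibrate the scorer, threshold the
network, detect complexes, and run the validation statistics — all from a
single config with one global seed and per-stage substreams.

Labeled pairs are split group-exclusively into a training portion and a
fully withheld test portion.  The score threshold is calibrated on the
pooled out-of-fold scores of the grouped cross-validation over the
training portion (every training pair scored by the model that did not
see its complex group), and the withheld portion is used only once, to
measure the empirical FDR of the thresholded network.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from ._rng import spawn_seed
from .complexes import cut_hierarchy, max_f1_over_cuts, walktrap_cluster, \
    write_partition_tsv
from .elution import concatenate_by_species, filter_min_abundance, \
    read_elution_tsv, write_elution_tsv
from .features import build_feature_table, write_feature_table
from .goldstd import ComplexSet, GoldStandard, filter_complex_size, \
    make_labels, read_complexes, split_train_test, stratify_positives, \
    write_labels_tsv
from .scoring import build_network, precision_recall_curve, score_pairs, \
    select_features, select_threshold, train_scorer
from .synthetic import SimulationParams, generate_truth, \
    simulate_all_experiments, simulate_annotations, simulate_external_assay, \
    write_annotations_tsv, write_complexes_tsv, write_evidence_tsv
from .validation import enrichment_report, propagate_annotations, \
    random_seed_null, read_annotations_tsv, read_evidence_tsv

log = logging.getLogger("coelute")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


class NoiseConfig(BaseModel):
    lam: float = Field(1.0, ge=0)
    eps: float = Field(0.1, ge=0)
    reps: int = Field(3, ge=1)


class SyntheticConfig(BaseModel):
    """Mirrors :class:`coelute.synthetic.SimulationParams`."""

    n_species: int = 3
    experiments_per_species: int = 2
    fractions_per_experiment: int = 40
    n_complexes: int = 35
    n_monomers: int = 25
    min_complex_size: int = 2
    max_complex_size: int = 8
    abundance_mu: float = float(np.log(50.0))
    abundance_sigma: float = 0.75
    peak_sd: float = 2.0
    coelution_jitter_sd: float = 0.6
    dropout_prob: float = 0.10
    species_retention: float = 0.90
    assay_sensitivity: float = 0.7
    assay_fp_rate: float = 0.01
    n_annotation_terms: int = 12

    def params(self, seed: int) -> SimulationParams:
        fields = SimulationParams.__dataclass_fields__
        kw = {k: v for k, v in self.model_dump().items() if k in fields}
        return SimulationParams(seed=seed, **kw)


class InputPaths(BaseModel):
    """Pre-existing artifacts for a non-synthetic run.

    ``elution`` maps species -> list of elution TSVs (declared experiment
    order); ``complexes`` is a gold-standard complex file; ``evidence``
    maps name -> {pairs, kind, bait, prey}; annotations are a term table
    plus child->parent edges.
    """

    elution: dict[str, list[str]]
    complexes: str
    evidence: dict[str, dict] = {}
    annotation_terms: Optional[str] = None
    annotation_edges: Optional[str] = None


class PipelineConfig(BaseModel):
    synthetic: Optional[SyntheticConfig] = None
    inputs: Optional[InputPaths] = None
    min_psms: float = Field(60, ge=0)
    noise: NoiseConfig = NoiseConfig()
    max_complex_size: int = Field(30, ge=2)
    neg_ratio: float = Field(3.0, gt=0)
    per_group_cap: int = Field(100, ge=1)
    train_frac: float = Field(0.75, gt=0, lt=1)
    n_splits: int = Field(5, ge=1)  # train/test resplits kept in labels.tsv
    n_folds: int = Field(5, ge=2)
    top_k: int = Field(100, ge=1)
    n_estimators: int = Field(256, ge=1)
    target_fdr: float = Field(0.08, gt=0, le=1)
    fdr_smoothing: str = "jeffreys"  # conservative small-sample calibration
    walk_length: int = Field(4, ge=1)
    bin_scheme: str = "paper"
    null_reps: int = Field(1000, ge=1)
    null_seed_size: int = Field(10, ge=1)
    min_annotation_size: int = Field(5, ge=1)
    jaccard_threshold: float = Field(0.5, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _one_source(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("configure exactly one of 'synthetic' or 'inputs'")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    """Key quantities and in-memory artifacts of one pipeline run."""

    config: PipelineConfig
    feature_table: pd.DataFrame
    gold: GoldStandard
    scores: pd.Series
    threshold: float
    network: "ScoredNetwork"  # noqa: F821
    hierarchy: object
    empirical_fdr: float | None
    n_eval_edges: int
    cluster_max_f1: float
    null_auroc: np.ndarray | None
    summary: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute every stage in order and write all artifacts under
    ``outdir``.  Deterministic for a fixed config (including seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "validation").mkdir(exist_ok=True)
    seed = config.seed
    checksums: dict[str, str] = {}

    # -- stage 1: elution matrices -----------------------------------------
    truth = None
    evidence: dict[str, "ExternalEvidence"] = {}  # noqa: F821
    annotations = None
    if config.synthetic is not None:
        log.info("simulating synthetic study")
        params = config.synthetic.params(seed)
        truth = generate_truth(params)
        by_species = simulate_all_experiments(truth, params)
        complexes_all = ComplexSet({
            f"cpx{i:04d}": c for i, c in enumerate(truth.complexes)
        })
        for kind in ("all_by_all", "bait_prey"):
            evidence[kind] = simulate_external_assay(
                truth, kind, config.synthetic.assay_sensitivity,
                config.synthetic.assay_fp_rate,
                seed=spawn_seed(seed, "assay", kind),
            )
        annotations = simulate_annotations(
            truth, config.synthetic.n_annotation_terms,
            seed=spawn_seed(seed, "annotations"),
        )
        write_complexes_tsv(truth.complexes, outdir / "truth_complexes.tsv")
        for kind, ev in evidence.items():
            write_evidence_tsv(ev, outdir / f"evidence_{kind}.tsv")
        write_annotations_tsv(*annotations, outdir / "annotation_terms.tsv",
                              outdir / "annotation_edges.tsv")
    else:
        log.info("loading elution matrices")
        by_species = {
            sp: [read_elution_tsv(p) for p in paths]
            for sp, paths in config.inputs.elution.items()
        }
        complexes_all = read_complexes(config.inputs.complexes)
        for name, spec_ in config.inputs.evidence.items():
            evidence[name] = read_evidence_tsv(
                spec_["pairs"], kind=spec_.get("kind", "all_by_all"),
                bait_path=spec_.get("bait"), prey_path=spec_.get("prey"),
            )
        if config.inputs.annotation_terms:
            annotations = read_annotations_tsv(
                config.inputs.annotation_terms, config.inputs.annotation_edges
            )

    flat = [m for mats in by_species.values() for m in mats]
    log.info("abundance filter at >= %g total PSMs", config.min_psms)
    retained, filtered = filter_min_abundance(flat, config.min_psms)
    by_species_f = {}
    i = 0
    for sp, mats in by_species.items():
        by_species_f[sp] = filtered[i:i + len(mats)]
        i += len(mats)
    concats = concatenate_by_species(by_species_f)
    for m in filtered + list(concats.values()):
        p = outdir / f"elution_{m.experiment_id}.tsv"
        write_elution_tsv(m, p)
        checksums[p.name] = _sha256(p)

    # -- stage 2: features --------------------------------------------------
    log.info("building pair feature table (%d orthogroups)", len(retained))
    matrices = {m.experiment_id: m for m in filtered}
    matrices.update({m.experiment_id: m for m in concats.values()})
    table = build_feature_table(
        matrices, noise_lam=config.noise.lam, noise_eps=config.noise.eps,
        noise_reps=config.noise.reps, seed=spawn_seed(seed, "features"),
    )
    write_feature_table(table, outdir / "features.tsv")

    # -- stage 3: gold standard + splits ------------------------------------
    log.info("labeling gold-standard pairs")
    complexes = filter_complex_size(complexes_all, config.max_complex_size)
    observed = {og for pair in table.index for og in pair}
    gold = make_labels(complexes, observed, neg_ratio=config.neg_ratio,
                       seed=spawn_seed(seed, "labels"), exclude=complexes_all)
    gold = stratify_positives(gold, per_group_cap=config.per_group_cap,
                              seed=spawn_seed(seed, "stratify"))
    gold = split_train_test(gold, config.train_frac, config.n_splits,
                            seed=spawn_seed(seed, "split"))
    write_labels_tsv(gold, outdir / "labels.tsv")

    # -- stage 4: scorer -----------------------------------------------------
    top_k = min(config.top_k, table.shape[1])
    log.info("selecting %d features and training", top_k)
    feats = select_features(table, gold, top_k=top_k,
                            seed=spawn_seed(seed, "select"),
                            n_estimators=config.n_estimators)
    scorer = train_scorer(table, gold, feats, n_folds=config.n_folds,
                          seed=spawn_seed(seed, "train"),
                          n_estimators=config.n_estimators)
    scorer.save_metadata(outdir / "model_meta.json")
    scores = score_pairs(scorer, table)
    scores.rename("cfms_score").to_csv(outdir / "scores.tsv", sep="\t")

    # -- stage 5: calibration + network --------------------------------------
    # threshold calibrated on pooled out-of-fold scores of the grouped CV
    # over the training split; the withheld test split is never touched
    curve = precision_recall_curve(scorer.oof_scores, scorer.oof_labels)
    curve.to_frame().to_csv(outdir / "pr_curve.tsv", sep="\t", index=False)
    threshold = select_threshold(curve, target_fdr=config.target_fdr,
                                 smoothing=config.fdr_smoothing)
    log.info("threshold %.3f at target FDR %.2f", threshold, config.target_fdr)
    network = build_network(scores, threshold)
    network.write_tsv(outdir / "network.tsv")

    # empirical FDR on the fully withheld test split
    roles = gold.fold_roles(0)
    ev_tab = gold.table[roles == "test"]
    ev_keys = pd.MultiIndex.from_arrays([ev_tab.id1, ev_tab.id2])
    ev_scores = scores.loc[ev_keys].to_numpy()
    above = ev_scores >= threshold
    n_eval_edges = int(above.sum())
    if n_eval_edges:
        emp_fdr = float((ev_tab.label.to_numpy()[above] == 0).mean())
    else:
        emp_fdr = None

    # -- stage 6: complexes ---------------------------------------------------
    log.info("walktrap clustering (%d nodes, %d edges)",
             network.n_nodes, network.n_edges)
    hierarchy = walktrap_cluster(network, walk_length=config.walk_length)
    cuts = {}
    for name in ("coarse", "fine"):
        part = cut_hierarchy(hierarchy, name)
        write_partition_tsv(part, outdir / f"partition_{name}.tsv")
        cuts[name] = {
            "n_clusters": len(set(part.values())),
            "modularity": hierarchy.modularity_at(len(set(part.values()))),
        }
    complex_sets = [set(c) for c in complexes.complexes.values()]
    best_f1, best_k = max_f1_over_cuts(hierarchy, complex_sets)
    cuts["best_f1"] = {"f1": best_f1, "n_clusters": best_k}
    (outdir / "cuts.json").write_text(json.dumps(
        {"walk_length": config.walk_length, **cuts}, indent=2))

    # -- stage 7: validation --------------------------------------------------
    log.info("validation statistics")
    for name, ev in evidence.items():
        rep = enrichment_report(scores, ev, scheme=config.bin_scheme)
        rep.to_csv(outdir / "validation" / f"enrichment_{name}.tsv",
                   sep="\t", index=False)
    null = None
    if network.n_nodes > config.null_seed_size:
        null = random_seed_null(
            network, config.null_seed_size, n_reps=config.null_reps,
            min_annotation_size=min(config.min_annotation_size,
                                    config.null_seed_size),
            seed=spawn_seed(seed, "null"),
        )
        pd.DataFrame({"auroc": null}).to_csv(
            outdir / "validation" / "auroc_null.tsv", sep="\t", index=False)
    if annotations is not None:
        mapping = propagate_annotations(
            annotations[0], annotations[1],
            training_complexes=complex_sets,
            jaccard_threshold=config.jaccard_threshold,
        )
        pd.DataFrame([
            {"term": t, "n_orthogroups": len(s),
             "max_jaccard": mapping.max_jaccard[t],
             "high_overlap": mapping.high_overlap[t]}
            for t, s in sorted(mapping.term_to_ogs.items())
        ]).to_csv(outdir / "validation" / "ontology_terms.tsv",
                  sep="\t", index=False)

    summary = {
        "n_orthogroups_retained": len(retained),
        "n_pairs_scored": int(len(scores)),
        "n_positives": int((gold.table.label == 1).sum()),
        "n_negatives": int((gold.table.label == 0).sum()),
        "threshold": threshold,
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
        "empirical_fdr_eval": emp_fdr,
        "n_eval_edges": n_eval_edges,
        "cluster_max_f1": best_f1,
        "null_auroc_mean": float(null.mean()) if null is not None else None,
    }
    manifest = {
        "coelute_version": __version__,
        "seed": seed,
        "config": json.loads(config.model_dump_json()),
        "input_checksums": checksums,
        "summary": summary,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(config, table, gold, scores, threshold, network,
                          hierarchy, emp_fdr, n_eval_edges, best_f1, null,
                          summary)
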