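"""End-to-end orchestration: simulate -> DE -> score -> peaks -> stats -> TMT.

``run_full`` executes the whole integrative analysis from one config and
writes per-stage TSVs, a machine-readable ``summary.json`` and a run log
into the output directory.  Everything is deterministic given the config's
seeds; running twice on one config yields byte-identical summaries.

When the input is the synthetic study, planted ground truth is available
and the summary additionally reports recovery metrics (sensitivity and
precision of the selected target set and of the TMT interactor calls).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, peaks as pk, qplex, scoring, stats
from .io import (
    GeneSetCollection,
    read_bed,
    read_channel_design,
    read_counts,
    read_design,
    read_gene_models,
    read_gmt,
    read_tmt,
    write_contrast_table,
)
from .simulate import GroundTruth, SimulationConfig, simulate_all, write_simulation

__all__ = ["PipelineConfig", "run_full"]

logger = logging.getLogger("tfdep")


class PipelineConfigError(ValueError):
    """The pipeline configuration is incomplete or inconsistent."""


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs (or a simulation), thresholds, seeds."""

    outdir: str = "tfdep_out"
    simulation: SimulationConfig | None = None
    # file inputs, used when simulation is None
    counts_path: str | None = None
    design_path: str | None = None
    gene_models_path: str | None = None
    peaks_tf_scr: str | None = None
    peaks_tf_kd: str | None = None
    peaks_cofactor_scr: str | None = None
    gene_sets_path: str | None = None
    tmt_path: str | None = None
    channel_design_path: str | None = None
    # thresholds
    alpha: float = scoring.DEFAULT_ALPHA
    fc_threshold: float = scoring.DEFAULT_FC_THRESHOLD
    is_cutoff: float = scoring.DEFAULT_IS_CUTOFF
    annotation_window: int = pk.DEFAULT_WINDOW
    promoter_halfwidth: int = pk.DEFAULT_PROMOTER_HALFWIDTH
    qplex_lfc_cut: float = qplex.DEFAULT_LFC_CUT
    qplex_alpha: float = qplex.DEFAULT_ALPHA
    pseudocount: float = 1.0
    gsea_n_perm: int = 2000
    gsea_seed: int = 0

    def validate(self) -> None:
        if not (0 < self.alpha <= 1) or not (0 < self.qplex_alpha <= 1):
            raise PipelineConfigError("alpha thresholds must lie in (0, 1]")
        if self.fc_threshold <= 1:
            raise PipelineConfigError("fc_threshold must exceed 1")
        if self.annotation_window <= 0 or self.promoter_halfwidth <= 0:
            raise PipelineConfigError("window parameters must be positive")
        if self.simulation is None:
            required = {
                "counts_path": self.counts_path,
                "design_path": self.design_path,
                "gene_models_path": self.gene_models_path,
                "peaks_tf_scr": self.peaks_tf_scr,
                "peaks_tf_kd": self.peaks_tf_kd,
                "peaks_cofactor_scr": self.peaks_cofactor_scr,
            }
            missing = [k for k, v in required.items() if v is None]
            if missing:
                raise PipelineConfigError(
                    f"no simulation configured and missing input path(s): {missing}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha1(path: Path) -> str:
    h = hashlib.sha1()
    h.update(path.read_bytes())
    return h.hexdigest()[:12]


def _stage(log: list[str], name: str, **info) -> None:
    parts = " ".join(f"{k}={v}" for k, v in info.items())
    line = f"stage={name} {parts}"
    log.append(line)
    logger.info(line)


def run_full(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the summary dict (also written as JSON)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    summary: dict = {"thresholds": {
        "alpha": config.alpha,
        "fc_threshold": config.fc_threshold,
        "is_cutoff": config.is_cutoff,
        "annotation_window": config.annotation_window,
        "promoter_halfwidth": config.promoter_halfwidth,
        "qplex_lfc_cut": config.qplex_lfc_cut,
        "qplex_alpha": config.qplex_alpha,
    }}

    # ---- inputs -----------------------------------------------------------
    truth: GroundTruth | None = None
    gene_sets: GeneSetCollection | None = None
    tmt = channels = None
    if config.simulation is not None:
        bundle = simulate_all(config.simulation)
        write_simulation(bundle, out / "inputs")
        counts, design = bundle["counts"], bundle["design"]
        peak_sets = bundle["peaks"]
        tf_scr = peak_sets["tf"]["scr"]
        tf_kd = peak_sets["tf"]["kd"]
        cof_scr = peak_sets["cofactor"]["scr"]
        gene_models = bundle["truth"].gene_models
        gene_sets = bundle["gene_sets"]
        tmt, channels = bundle["tmt"], bundle["channels"]
        truth = bundle["truth"]
        summary["seed"] = config.simulation.seed
        _stage(log, "simulate", seed=config.simulation.seed,
               n_genes=config.simulation.n_genes)
    else:
        counts, _ = read_counts(config.counts_path)
        design = read_design(config.design_path)
        gene_models = read_gene_models(config.gene_models_path)
        tf_scr = read_bed(config.peaks_tf_scr)
        tf_kd = read_bed(config.peaks_tf_kd)
        cof_scr = read_bed(config.peaks_cofactor_scr)
        if config.gene_sets_path:
            gene_sets = read_gmt(config.gene_sets_path)
        if config.tmt_path and config.channel_design_path:
            tmt, _ = read_tmt(config.tmt_path)
            channels = read_channel_design(config.channel_design_path)
        for p in (config.counts_path, config.peaks_tf_scr):
            _stage(log, "read", path=p, sha1=_sha1(Path(p)))

    # ---- differential expression -----------------------------------------
    c_scr = diffexpr.contrast(counts, design, ("SCR", "Dox"), ("SCR", "Con"),
                              pseudocount=config.pseudocount, name="scr_dox_vs_con")
    c_kd = diffexpr.contrast(counts, design, ("KD", "Dox"), ("KD", "Con"),
                             pseudocount=config.pseudocount, name="kd_dox_vs_con")
    write_contrast_table(c_scr, out / "contrast_scr.tsv")
    write_contrast_table(c_kd, out / "contrast_kd.tsv")
    _stage(log, "de", n_genes=len(c_scr))

    # ---- categorization and impact score ----------------------------------
    categories = scoring.categorize_genes(c_scr, config.fc_threshold, config.alpha)
    n_up = int((categories["category"] == "UP").sum())
    n_down = int((categories["category"] == "DOWN").sum())
    records = scoring.impact_score(c_scr, c_kd)
    impaired = scoring.filter_impaired_activation(records, categories, config.is_cutoff)
    is_table = records.merge(categories, on="gene_id")
    is_table["passes_filter"] = is_table["gene_id"].isin(impaired)
    is_table.to_csv(out / "impact_scores.tsv", sep="\t", index=False)
    summary["n_up"] = n_up
    summary["n_down"] = n_down
    summary["n_impaired"] = len(impaired)
    _stage(log, "score", n_up=n_up, n_down=n_down, n_impaired=len(impaired))

    # ---- peak analysis -----------------------------------------------------
    cobound_genes = pk.cobound_gene_set(tf_scr, cof_scr, gene_models,
                                        window=config.annotation_window)
    lost, gained, retained = pk.condition_specific_peaks(tf_scr, tf_kd)
    cobound_peaks = pk.intersect_unique(tf_scr, cof_scr)
    cobound_names = {iv.name for iv in cobound_peaks}
    lost_names = {iv.name for iv in lost}
    n_cb_lost = len(cobound_names & lost_names)
    n_cb_ret = len(cobound_names - lost_names)
    n_other_lost = len(lost_names - cobound_names)
    n_other_ret = len(tf_scr) - n_cb_lost - n_cb_ret - n_other_lost
    ann = pk.annotation_table(
        pk.annotate(cobound_peaks, gene_models, window=config.annotation_window,
                    promoter_halfwidth=config.promoter_halfwidth))
    ann.to_csv(out / "cobound_annotation.tsv", sep="\t", index=False)
    summary["peaks"] = {
        "n_tf_scr": len(tf_scr),
        "n_tf_kd": len(tf_kd),
        "n_tf_lost": len(lost),
        "n_tf_gained": len(gained),
        "n_cobound_peaks": len(cobound_peaks),
        "n_cobound_genes": len(cobound_genes),
        "frac_promoter_cobound": round(
            float((ann["context"] == "promoter").mean()) if len(ann) else 0.0, 6),
    }
    _stage(log, "peaks", n_cobound=len(cobound_peaks), n_lost=len(lost))

    # chi-square: are co-bound TF peaks preferentially lost after knockdown?
    if min(n_cb_lost + n_cb_ret, n_other_lost + n_other_ret) > 0 and len(lost):
        oe = stats.observed_expected_chi2(
            [[n_cb_lost, n_cb_ret], [n_other_lost, n_other_ret]])
        summary["cobound_loss_chi2"] = {
            "table": [[n_cb_lost, n_cb_ret], [n_other_lost, n_other_ret]],
            "oe_ratio": round(oe.oe_ratio, 6),
            "chi2": round(oe.chi2, 6),
            "log10_p": round(oe.log10_p, 6),
        }
        _stage(log, "chisq", oe_ratio=round(oe.oe_ratio, 3))

    # ---- target selection --------------------------------------------------
    targets = scoring.select_dependent_targets(impaired, cobound_genes)
    pd.DataFrame({"gene_id": targets}).to_csv(out / "targets.tsv", sep="\t",
                                              index=False)
    summary["n_targets"] = len(targets)
    _stage(log, "targets", n=len(targets))

    # ---- enrichment statistics --------------------------------------------
    universe = set(c_scr["gene_id"])
    if impaired and cobound_genes:
        ms = stats.multiset_intersection_test(
            [set(impaired), set(cobound_genes) & universe], len(universe))
        summary["target_overlap_test"] = {
            "observed": ms.observed,
            "expected": round(ms.expected, 6),
            "fold": round(ms.fold, 6) if np.isfinite(ms.fold) else None,
            "log_p": round(ms.log_p, 6),
        }
    if gene_sets is not None and len(gene_sets):
        ora = stats.ora_collection(set(targets), gene_sets, universe)
        ora.to_csv(out / "ora.tsv", sep="\t", index=False)
        if len(ora):
            best = ora.sort_values(["adj_p", "set_name"]).iloc[0]
            summary["ora_top"] = {"set_name": str(best["set_name"]),
                                  "adj_p": round(float(best["adj_p"]), 8)}
        ranked = pd.Series(-records["impact_score"].to_numpy(),
                           index=records["gene_id"])
        gsea_set = ("PLANTED_DEPENDENT" if "PLANTED_DEPENDENT" in gene_sets
                    else next(iter(gene_sets)))
        g = stats.gsea_preranked(ranked, gene_sets[gsea_set],
                                 n_perm=config.gsea_n_perm,
                                 seed=config.gsea_seed, set_name=gsea_set)
        summary["gsea"] = {"set_name": g.set_name, "es": round(g.es, 6),
                           "p": round(g.p, 8)}
        _stage(log, "stats", gsea_set=gsea_set, es=round(g.es, 3))

    # ---- qPLEX interactome -------------------------------------------------
    if tmt is not None and channels is not None:
        norm = qplex.normalize_channels(tmt)
        enr = qplex.enrichment_call(norm, channels, condition="Dox",
                                    lfc_cut=config.qplex_lfc_cut,
                                    alpha=config.qplex_alpha)
        rew = qplex.condition_contrast(norm, channels,
                                       lfc_cut=config.qplex_lfc_cut,
                                       alpha=config.qplex_alpha)
        enr.to_csv(out / "qplex_enrichment.tsv", sep="\t", index=False)
        rew.to_csv(out / "qplex_condition_contrast.tsv", sep="\t", index=False)
        summary["qplex"] = {
            "n_enriched": int((enr["call"] == "enriched").sum()),
            "n_rewired_up": int((rew["call"] == "enriched").sum()),
            "n_rewired_down": int((rew["call"] == "depleted").sum()),
        }
        _stage(log, "qplex", n_enriched=summary["qplex"]["n_enriched"])

    # ---- planted-truth recovery -------------------------------------------
    if truth is not None:
        planted = truth.planted_dependent & truth.planted_cobound
        found = set(targets)
        tp = len(found & planted)
        summary["recovery"] = {
            "n_planted_targets": len(planted),
            "target_sensitivity": round(tp / len(planted), 6) if planted else None,
            "target_precision": round(tp / len(found), 6) if found else None,
        }
        if truth.proteins is not None and tmt is not None:
            pl_enr = set(truth.proteins.loc[truth.proteins["enriched"], "protein_id"])
            called = set(enr.loc[enr["call"] == "enriched", "protein_id"])
            tp_p = len(called & pl_enr)
            summary["recovery"]["tmt_sensitivity"] = (
                round(tp_p / len(pl_enr), 6) if pl_enr else None)
            summary["recovery"]["tmt_precision"] = (
                round(tp_p / len(called), 6) if called else None)
        _stage(log, "recovery", **{k: v for k, v in summary["recovery"].items()})

    # ---- outputs -----------------------------------------------------------
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run.log", "w", encoding="utf-8") as fh:
        fh.write("\n".join(log) + "\n")
    return summary
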