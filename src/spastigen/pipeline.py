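"""End-to-end pipeline: simulate/load -> QC -> kinship -> h2 -> association
-> filter cascade -> random-forest consensus -> LD & gene mapping.

A single TOML config drives the run; every analysis threshold is a named
key with the standard value as its default (call rates 0.90, het excess
0.499, MAF screens 1e-5 and 0.2, chi-square 0.05, polarity 0.3, pFDR
tiers 1/5/10%, 100 forests x 75 trees, 2 Mb gene window, r^2 0.2).  The
manifest records the config snapshot, seeds, content digests of every
output, per-stage row counts and timings, so deterministic stages can be
verified byte-for-byte across re-runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as gio
from .filters import apply_cascade
from .forest import (evaluate_prediction, intersect_with_gqls,
                     replicate_forests, top_frequency_regions, _align)
from .gqls import chromosome_pfdr, manhattan_table, run_gwas
from .kinship import Pedigree, build_A
from .ld import map_snps_to_genes, read_gene_annotation, solid_spine_blocks, \
    syntenic_ld_screen
from .liability import estimate_h2_observed_reml, estimate_h2_pql_probit
from .qc import qc_filter
from .sim import config_from_dict, simulate_cohort, write_cohort

log = logging.getLogger("spastigen")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"stage '{stage}': {msg}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    outputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    stage_counts: dict[str, int] = field(default_factory=dict)
    timestamps: dict[str, float] = field(default_factory=dict)
    completed: list[str] = field(default_factory=list)

    def record(self, path: Path) -> None:
        self.outputs[path.name] = hashlib.sha256(
            path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str)
                        + "\n")


def load_config(path) -> dict:
    import tomllib
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def cohort_summary(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Case/control counts and prevalence (percent, 2 dp) of a cohort."""
    n_aff = int(phenotypes["status"].sum())
    n_tot = int(len(phenotypes))
    return pd.DataFrame([
        {"group": "affected", "n": n_aff},
        {"group": "control", "n": n_tot - n_aff},
        {"group": "total", "n": n_tot},
        {"group": "prevalence_pct", "n": round(100.0 * n_aff / n_tot, 2)}])


DEMO_CONFIG: dict = {
    "seed": 1,
    "simulate": {
        "n_chromosomes": 5, "snps_per_chromosome": 400,
        "chromosome_length_bp": 80_000_000, "n_qtl": 3,
        "qtl_effect_sd": 0.45, "missing_rate": 0.01,
    },
    "h2": {"enabled": True},
    "rf": {"n_forests": 10, "n_trees": 25},
}


def run_pipeline(config: dict, out_dir) -> RunManifest:
    """Execute the enabled stages in order and write all report artifacts.

    Returns the manifest; raises ``PipelineError`` naming the failing
    stage (the partially filled manifest is still written to disk).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(config=config, seed=seed)
    manifest.timestamps["start"] = time.time()

    def emit(df: pd.DataFrame, name: str, stage: str) -> Path:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        manifest.record(path)
        manifest.stage_counts[f"{stage}:{name}"] = len(df)
        return path

    try:
        # ---- cohort -----------------------------------------------------
        stage = "cohort"
        if "simulate" in config:
            sim_cfg = dict(config["simulate"])
            sim_cfg.setdefault("seed", seed)
            cfg = config_from_dict(sim_cfg)
            bundle = simulate_cohort(cfg)
            paths = write_cohort(bundle, out / "cohort")
            for p in paths.values():
                manifest.record(Path(p))
            genotypes = bundle.genotypes.subset(
                animal_ids=bundle.phenotypes.animal_ids)
            phenotypes = bundle.phenotypes.to_frame()
            pedigree = bundle.pedigree
            genes = read_gene_annotation(paths["genes"])
            train_ids = bundle.training_ids
            test_ids = bundle.testing_ids
        else:
            inputs = config.get("inputs", {})
            for key in ("ped", "map", "phenotypes", "pedigree"):
                if key not in inputs:
                    raise PipelineError(stage,
                                        f"required input '{key}' missing")
                if not Path(inputs[key]).exists():
                    raise PipelineError(
                        stage, f"input file not found: {inputs[key]}")
            genotypes = gio.read_plink_text(inputs["ped"], inputs["map"])
            phenotypes = gio.read_phenotypes(inputs["phenotypes"])
            pedigree = Pedigree.read_csv(inputs["pedigree"])
            genes = (read_gene_annotation(inputs["genes"])
                     if "genes" in inputs else None)
            train_ids = (gio.read_id_list(inputs["train_ids"])
                         if "train_ids" in inputs else None)
            test_ids = (gio.read_id_list(inputs["test_ids"])
                        if "test_ids" in inputs else None)

        summary = cohort_summary(phenotypes)
        emit(summary, "cohort_summary.tsv", stage)
        log.info("cohort: %d animals (%d affected)", len(phenotypes),
                 int(phenotypes["status"].sum()))

        # ---- QC ---------------------------------------------------------
        stage = "qc"
        qc_cfg = config.get("qc", {})
        g_qc, report = qc_filter(
            genotypes,
            ind_call_rate=qc_cfg.get("ind_call_rate", 0.90),
            snp_call_rate=qc_cfg.get("snp_call_rate", 0.90),
            het_excess_max=qc_cfg.get("het_excess_max", 0.499),
            maf_min=qc_cfg.get("maf_min", 0.00001))
        (out / "qc_report.json").write_text(report.to_json() + "\n")
        manifest.record(out / "qc_report.json")
        manifest.stage_counts["qc:snps_out"] = report.n_snps_out
        phenotypes = phenotypes[phenotypes["animal"].isin(
            g_qc.animal_ids)].reset_index(drop=True)
        manifest.completed.append(stage)

        # ---- kinship ----------------------------------------------------
        stage = "kinship"
        A = build_A(pedigree)
        manifest.stage_counts["kinship:animals"] = len(A.ids)
        manifest.completed.append(stage)

        # ---- heritability -----------------------------------------------
        stage = "h2"
        if config.get("h2", {}).get("enabled", True):
            est = estimate_h2_pql_probit(
                phenotypes, pedigree,
                tol=config.get("h2", {}).get("tol", 1e-6))
            est2 = estimate_h2_observed_reml(phenotypes, pedigree)
            (out / "heritability.json").write_text(json.dumps(
                {"pql_probit": est.to_dict(),
                 "observed_reml_transformed": est2.to_dict()}, indent=2)
                + "\n")
            manifest.record(out / "heritability.json")
            log.info("h2 underlying %.3f (observed %.3f at prevalence %.3f)",
                     est.h2_underlying, est.h2_observed,
                     est.prevalence_alpha)
        manifest.completed.append(stage)

        # ---- GQLS GWAS --------------------------------------------------
        stage = "gwas"
        gwas_cfg = config.get("gwas", {})
        K = A.submatrix(phenotypes["animal"].tolist())
        assoc = run_gwas(g_qc, phenotypes, K,
                         estimate_dispersion=gwas_cfg.get(
                             "estimate_dispersion", False))
        assoc = chromosome_pfdr(
            assoc, cutoffs=tuple(gwas_cfg.get("tiers", (0.01, 0.05, 0.10))))
        emit(assoc, "association.tsv", stage)
        emit(manhattan_table(assoc), "manhattan.tsv", stage)
        manifest.completed.append(stage)

        # ---- filter cascade ---------------------------------------------
        stage = "filter"
        f_cfg = config.get("filters", {})
        cascade = apply_cascade(
            assoc, g_qc, phenotypes,
            maf_min=f_cfg.get("maf_min", 0.2),
            chi2_alpha=f_cfg.get("chi2_alpha", 0.05),
            polarity_min=f_cfg.get("polarity_min", 0.3))
        emit(cascade.per_snp, "filter_cascade.tsv", stage)
        emit(cascade.per_chromosome, "filter_cascade_by_chromosome.tsv",
             stage)
        manifest.stage_counts["filter:survivors"] = cascade.survivors[-1]
        manifest.completed.append(stage)

        # ---- random forest ----------------------------------------------
        stage = "rf"
        rf_cfg = config.get("rf", {})
        if train_ids and test_ids:
            train = phenotypes[phenotypes["animal"].isin(train_ids)]
            test = phenotypes[phenotypes["animal"].isin(test_ids)]
            Xtr, ytr, _ = _align(g_qc.subset(animal_ids=train["animal"]
                                             .tolist()), train)
            consensus, results = replicate_forests(
                Xtr, ytr, g_qc.marker_map.df["snp_id"].tolist(),
                n_forests=rf_cfg.get("n_forests", 100),
                n_trees=rf_cfg.get("n_trees", 75), base_seed=seed)
            consensus = top_frequency_regions(consensus)
            emit(consensus, "rf_consensus.tsv", stage)
            Xte, yte, _ = _align(g_qc.subset(animal_ids=test["animal"]
                                             .tolist()), test)
            errors = evaluate_prediction(results, Xte, yte)
            emit(errors, "rf_errors.tsv", stage)
            sig = assoc[assoc["pfdr_tier"] != "ns"].merge(
                cascade.per_snp[["snp_id", "maf", "polarity"]],
                on="snp_id", how="left", suffixes=("", "_cascade"))
            common = intersect_with_gqls(consensus, sig)
            emit(common, "rf_gqls_common.tsv", stage)
        manifest.completed.append(stage)

        # ---- LD and gene mapping ----------------------------------------
        stage = "ld"
        ld_cfg = config.get("ld", {})
        window = ld_cfg.get("window_bp", 2_000_000)
        r2_min = ld_cfg.get("r2_min", 0.2)
        sig = assoc[assoc["pfdr_tier"] != "ns"]
        top_n = ld_cfg.get("max_significant_snps", 20)
        sig = sig.nsmallest(top_n, "p_value")
        if genes is not None and not sig.empty:
            gene_map = map_snps_to_genes(sig, genes, window_bp=window)
            emit(gene_map, "gene_mapping.tsv", stage)
            mm = g_qc.marker_map.df
            gene_snps: list[str] = []
            block_rows = []
            for _, gn in genes.iterrows():
                inside = mm[(mm["chromosome"] == gn["chromosome"])
                            & (mm["position_bp"] >= gn["start_bp"])
                            & (mm["position_bp"] <= gn["end_bp"])]
                gene_snps += inside["snp_id"].tolist()
                if len(inside) >= 2:
                    region = g_qc.subset(snp_mask=inside.index.to_numpy())
                    for b in solid_spine_blocks(
                            region,
                            strong_ld_min=ld_cfg.get("strong_ld_min", 0.2)):
                        block_rows.append({
                            "gene_id": gn["gene_id"],
                            "chromosome": b.chromosome,
                            "start_bp": b.start_bp, "end_bp": b.end_bp,
                            "n_snps": b.n_snps,
                            "snp_ids": ",".join(b.snp_ids)})
            emit(pd.DataFrame(block_rows,
                              columns=["gene_id", "chromosome", "start_bp",
                                       "end_bp", "n_snps", "snp_ids"]),
                 "haplotype_blocks.tsv", stage)
            pairs = []
            for chrom in sig["chromosome"].unique():
                s_ids = sig.loc[sig["chromosome"] == chrom,
                                "snp_id"].tolist()
                snp_chrom = {s: c for s, c in zip(mm["snp_id"],
                                                  mm["chromosome"])}
                g_ids = [s for s in gene_snps if snp_chrom.get(s) == chrom]
                if s_ids and g_ids:
                    pairs.append(syntenic_ld_screen(s_ids, g_ids, g_qc,
                                                    r2_min=r2_min))
            syn = (pd.concat(pairs, ignore_index=True) if pairs
                   else pd.DataFrame(columns=["snp_i", "snp_j",
                                              "chromosome", "r2",
                                              "d_prime", "n_used"]))
            emit(syn, "syntenic_ld.tsv", stage)
        manifest.completed.append(stage)

    except PipelineError:
        manifest.timestamps["end"] = time.time()
        manifest.write(out / "manifest.json")
        raise
    except Exception as exc:
        manifest.timestamps["end"] = time.time()
        manifest.write(out / "manifest.json")
        raise PipelineError(stage, str(exc)) from exc

    manifest.timestamps["end"] = time.time()
    manifest.write(out / "manifest.json")
    return manifest
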