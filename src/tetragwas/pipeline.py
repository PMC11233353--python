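"""Stage wiring for the end-to-end analysis: configuration, provenance and reports.

Stages run in dependency order:

    simulate -> qc -> structure -> ld -> gwas -> qtl (-> pheno summaries)

Every output TSV carries a provenance header (package version, config
hash, seed) so that re-runs with the same configuration are byte
identical. Per-stage marker and sample counts are logged as a funnel.
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

from . import __version__
from .genotypes import QCThresholds, qc_filter, read_dosage_vcf
from .gwas import ENCODINGS, GwasModel
from .ld import decay_summary, fit_decay, fits_to_table, pairwise_r2
from .pheno import blues, heritability, trait_correlations
from .popstruct import choose_q_kmeans, compute_grm, grm_diagnostics, pca
from .qtl import (DEFAULT_HOTSPOT_GAP_BP, DEFAULT_WINDOW_BP, dedup_encodings,
                  hotspots, significant_mtas, window_filter)
from .simulate import SimConfig, TraitConfig, simulate_phenotypes, \
    simulate_population, write_panel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "tetragwas_out"
    vcf: str | None = None            # None -> simulate a panel
    phenotypes: str | None = None
    genes: str | None = None
    seed: int = 0
    qc: QCThresholds = field(default_factory=QCThresholds)
    sim: SimConfig = field(default_factory=SimConfig)
    trait: TraitConfig = field(default_factory=lambda: TraitConfig())
    n_pcs: int = 3
    k_max: int = 8
    ld_tau: float = 0.90
    ld_max_pairs: int = 500_000
    encodings: tuple[str, ...] = ENCODINGS
    models: tuple[str, ...] = ("K", "QK")
    alpha: float = 0.05
    meff_window: int = 100
    qtl_window_bp: int = DEFAULT_WINDOW_BP
    hotspot_gap_bp: int = DEFAULT_HOTSPOT_GAP_BP

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QCThresholds(**d["qc"])
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig(**d["sim"])
        if "trait" in d and isinstance(d["trait"], dict):
            t = dict(d["trait"])
            t.pop("qtl", None)  # planted QTL are code-level, not config-level
            d["trait"] = TraitConfig(**t)
        for key in ("encodings", "models"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        d["trait"].pop("qtl", None)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded: the hash marks
        what was computed, not where it was written)."""
        d = self.to_dict()
        for key in ("outdir", "vcf", "phenotypes", "genes"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tetragwas {__version__} config={config.config_hash()} "
                 f"seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def run(config: PipelineConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Execute the pipeline; returns a dict of in-memory stage results.

    ``stages`` restricts execution (downstream requirements are computed
    on the fly from upstream results held in memory).
    """
    want = set(stages or ("simulate", "qc", "structure", "ld", "gwas",
                          "qtl", "pheno"))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # --- genotype input ---------------------------------------------------
    if config.vcf is None:
        panel = simulate_population(config.sim)
        tcfg = dataclasses.replace(config.trait, seed=config.seed)
        plots, truth = simulate_phenotypes(panel, tcfg)
        if "simulate" in want:
            write_panel(panel, plots, out / "panel.vcf", out / "markers.bed",
                        out / "phenotypes.tsv")
        dm = panel.dosages
        results["panel"] = panel
        results["truth"] = truth
    else:
        dm = read_dosage_vcf(config.vcf, thresholds=config.qc)
        plots = (pd.read_csv(config.phenotypes, sep="\t", comment="#")
                 if config.phenotypes else None)
    logger.info("input: %d markers x %d samples", dm.n_markers, dm.n_samples)

    # --- QC ---------------------------------------------------------------
    dm_qc, report = qc_filter(dm, config.qc)
    if "qc" in want:
        _write_tsv(report.to_frame(), out / "qc_report.tsv", config)
    logger.info("qc funnel: %d -> %d markers", report.n_input, report.n_output)
    results["dosages"] = dm_qc
    results["qc_report"] = report

    # --- population structure --------------------------------------------
    grm = compute_grm(dm_qc)
    pca_res = pca(grm)
    results["grm"], results["pca"] = grm, pca_res
    if "structure" in want:
        clus = choose_q_kmeans(pca_res, k_max=config.k_max, seed=config.seed)
        mean_d, mean_o, _, _ = grm_diagnostics(grm)
        logger.info("GRM mean diagonal %.3f, mean off-diagonal %.4f; "
                    "chosen Q=%d", mean_d, mean_o, clus.chosen_k)
        results["clusters"] = clus
        _write_tsv(pd.DataFrame({
            "sample": grm.samples,
            "cluster": clus.assignments,
            **{f"PC{i + 1}": pca_res.scores[:, i]
               for i in range(min(config.n_pcs, pca_res.scores.shape[1]))}}),
            out / "structure.tsv", config)

    # --- LD decay ---------------------------------------------------------
    if "ld" in want:
        fits = {}
        for chrom in dm_qc.markers["chrom"].unique():
            pairs = pairwise_r2(dm_qc, chrom, max_pairs=config.ld_max_pairs,
                                seed=config.seed)
            if pairs.r2.size >= 100:
                fits[chrom] = fit_decay(pairs, tau=config.ld_tau)
        if fits:
            summ = decay_summary(fits)
            results["ld_fits"], results["ld_summary"] = fits, summ
            _write_tsv(fits_to_table(fits), out / "ld_decay.tsv", config)
            logger.info("LD decay means: %s", summ["means"])

    # --- phenotype preparation -------------------------------------------
    trait_names = []
    if plots is not None:
        trait_names = [c for c in plots.columns
                       if c not in ("genotype", "environment", "replicate")]
        blue_tabs = {t: blues(plots, t) for t in trait_names}
        results["blues"] = blue_tabs
        if "pheno" in want:
            h2 = {t: heritability(plots, t)[1] for t in trait_names}
            results["heritability"] = h2
            blue_mat = pd.DataFrame({t: tab["mean"]
                                     for t, tab in blue_tabs.items()})
            if len(trait_names) >= 2:
                results["correlations"] = trait_correlations(blue_mat)
            _write_tsv(blue_mat, out / "blues.tsv", config, index=True)
            _write_tsv(pd.Series(h2, name="H2").rename_axis("trait").reset_index(),
                       out / "heritability.tsv", config)

    # --- GWAS + QTL -------------------------------------------------------
    if "gwas" in want and plots is not None and trait_names:
        blue_mat = pd.DataFrame({t: results["blues"][t]["mean"]
                                 for t in trait_names})
        model = GwasModel(dm_qc, blue_mat, grm=grm, pca_result=pca_res,
                          encodings=config.encodings, models=config.models,
                          n_pcs=config.n_pcs, alpha=config.alpha,
                          meff_window=config.meff_window)
        res = model.fit()
        results["gwas"] = res
        _write_tsv(res.table, out / "gwas_results.tsv", config)
        _write_tsv(res.lambda_table, out / "lambda_gc.tsv", config)

        if "qtl" in want:
            sig = significant_mtas(res.table, models=config.models)
            thinned = window_filter(sig, window_bp=config.qtl_window_bp)
            unique = dedup_encodings(thinned)
            hs = hotspots(unique, max_gap_bp=config.hotspot_gap_bp)
            logger.info("MTA funnel: %d significant -> %d per-window -> "
                        "%d unique; %d hotspots", len(sig), len(thinned),
                        len(unique), len(hs))
            results["mtas"] = sig
            results["qtl_mtas"] = unique
            results["hotspots"] = hs
            _write_tsv(unique, out / "qtl_mtas.tsv", config)
            _write_tsv(hs, out / "hotspots.tsv", config)

    return results
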