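"""Staged pipeline with persisted intermediates and resumability.

Stages: preprocess -> select-ivs -> infer (+ bootstrap) -> partition.
Each stage writes its outputs under the run directory and records itself
in ``manifest.json`` together with the configuration hash; a re-run with
the same configuration skips completed stages.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as iio
from .bootstrap import BootstrapNetwork, threshold
from .config import RunConfig
from .containers import ExpressionMatrix
from .iv import IVSelector
from .partition import fast_greedy_partition, subnetworks
from .preprocess import (
    Residualizer,
    filter_genes_gtex,
    filter_genes_tcga,
    genotype_pcs,
    impute_major_allele,
    log2_transform,
    median_of_ratios_factors,
    qc_genotypes,
    tmm_normalize,
)
from .spls import TwoStagePLS

logger = logging.getLogger(__name__)

STAGES = ("preprocess", "select_ivs", "infer", "bootstrap", "partition")


class Pipeline:
    def __init__(self, config: RunConfig):
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = (json.loads(self.manifest_path.read_text())
                         if self.manifest_path.exists() else {"stages": {}})

    # -- manifest helpers --------------------------------------------------
    def _stage_done(self, stage: str) -> bool:
        rec = self.manifest["stages"].get(stage)
        if not rec or rec.get("config_hash") != self.cfg.content_hash():
            return False
        return all(Path(p).exists() for p in rec["outputs"])

    def _record(self, stage: str, outputs: list[str]) -> None:
        self.manifest["stages"][stage] = {
            "config_hash": self.cfg.content_hash(),
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "seed": self.cfg.seed,
            "outputs": [str(o) for o in outputs],
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    # -- stages ------------------------------------------------------------
    def preprocess(self) -> None:
        if self._stage_done("preprocess"):
            logger.info("preprocess: up to date, skipping")
            return
        cfg = self.cfg
        counts = iio.read_expression(cfg.expression)
        genos = iio.read_genotypes(cfg.dosage, cfg.variant_table)
        common = [s for s in counts.sample_ids if s in set(genos.sample_ids)]
        counts = counts.subset_samples(common)
        genos = genos.subset_samples([genos.sample_ids.index(s) for s in common])

        if cfg.mode == "gtex":
            tpm = iio.read_expression(cfg.tpm).subset_samples(common)
            keep, report = filter_genes_gtex(counts, tpm, cfg.tpm_threshold,
                                             cfg.count_threshold, cfg.min_expressed_fraction)
            counts = counts.subset_genes(keep)
            factors = tmm_normalize(counts, logratio_trim=cfg.logratio_trim,
                                    sum_trim=cfg.sum_trim)
            expr = log2_transform(counts, factors)
        elif cfg.mode == "tcga":
            keep, report = filter_genes_tcga(counts, cfg.tcga_min_total, cfg.tcga_max_missing)
            counts = counts.subset_genes(keep)
            factors = median_of_ratios_factors(counts)
            expr = log2_transform(counts, factors)
        else:
            expr, report = counts, None

        genos, qc_report = qc_genotypes(genos, cfg.max_variant_missing,
                                        cfg.max_sample_missing, cfg.hwe_alpha,
                                        cfg.min_mac, cfg.hwe_test)
        genos = impute_major_allele(genos)
        kept_samples = [s for s in expr.sample_ids if s in set(genos.sample_ids)]
        expr = expr.subset_samples(kept_samples)
        genos = genos.subset_samples([genos.sample_ids.index(s) for s in kept_samples])

        covars = iio.read_covariates(self.cfg.covariates) if cfg.covariates else None
        pcs = genotype_pcs(genos, cfg.n_pcs) if cfg.n_pcs else None
        # expression for network inference: covariates only, no PCs
        expr_net = (Residualizer(covars, None).fit_transform(expr)
                    if covars is not None else expr)
        # expression for IV discovery: covariates + genotype PCs
        expr_iv = Residualizer(covars, pcs).fit_transform(expr)

        out = self.outdir
        iio.write_expression(expr_net, out / "expression.network.tsv")
        iio.write_expression(expr_iv, out / "expression.iv.tsv")
        iio.write_genotypes(genos, out / "genotypes.qc.tsv", out / "variants.qc.tsv")
        frames = [qc_report.to_frame()] + ([report.to_frame()] if report else [])
        pd.concat(frames).to_csv(out / "qc_report.tsv", sep="\t", index=False)
        self._record("preprocess", [
            out / "expression.network.tsv", out / "expression.iv.tsv",
            out / "genotypes.qc.tsv", out / "variants.qc.tsv", out / "qc_report.tsv",
        ])

    def select_ivs(self) -> None:
        if self._stage_done("select_ivs"):
            logger.info("select-ivs: up to date, skipping")
            return
        cfg = self.cfg
        expr_iv = iio.read_expression(self.outdir / "expression.iv.tsv")
        genos = iio.read_genotypes(self.outdir / "genotypes.qc.tsv",
                                   self.outdir / "variants.qc.tsv")
        ann = iio.read_annotation(cfg.annotation)
        sel = IVSelector(alpha=cfg.iv_alpha, flank=cfg.flank, max_k=cfg.max_instruments,
                         max_corr=cfg.max_instrument_corr, alpha0=cfg.asum_alpha0,
                         n_perm=cfg.n_perm, seed=cfg.seed)
        sel.fit(expr_iv, genos, ann)
        out = self.outdir
        sel.table_.to_csv(out / "iv_table.tsv", sep="\t", index=False)
        pool = pd.DataFrame(sel.pool_, index=expr_iv.sample_ids, columns=sel.pool_ids_)
        pool.to_csv(out / "iv_pool.tsv", sep="\t", index_label="sample_id")
        (out / "iv_pool_index.json").write_text(json.dumps(sel.pool_index_, indent=0))
        self._record("select_ivs", [out / "iv_table.tsv", out / "iv_pool.tsv",
                                    out / "iv_pool_index.json"])

    def _load_inference_inputs(self):
        expr = iio.read_expression(self.outdir / "expression.network.tsv")
        pool_df = pd.read_csv(self.outdir / "iv_pool.tsv", sep="\t", index_col=0)
        pool_index = json.loads((self.outdir / "iv_pool_index.json").read_text())
        return expr, pool_df.to_numpy(dtype=float), pool_index

    def infer(self) -> None:
        if self._stage_done("infer"):
            logger.info("infer: up to date, skipping")
            return
        expr, pool, pool_index = self._load_inference_inputs()
        est = TwoStagePLS(**self.cfg.spls_params()).fit(expr, pool, pool_index)
        paths = iio.write_network(est.network_, self.outdir / "network")
        if est.failures_:
            (self.outdir / "inference_failures.json").write_text(
                json.dumps(est.failures_, indent=2))
        self._record("infer", list(paths))

    def bootstrap(self) -> None:
        if self._stage_done("bootstrap"):
            logger.info("bootstrap: up to date, skipping")
            return
        expr, pool, pool_index = self._load_inference_inputs()
        bn = BootstrapNetwork(n_bootstraps=self.cfg.n_bootstraps, seed=self.cfg.seed,
                              **{k: v for k, v in self.cfg.spls_params().items()
                                 if k != "seed"})
        bn.fit(expr, pool, pool_index)
        paths = iio.write_network(bn.summary_, self.outdir / "frequency")
        self._record("bootstrap", list(paths))

    def partition(self) -> None:
        if self._stage_done("partition"):
            logger.info("partition: up to date, skipping")
            return
        summary = iio.read_bootstrap_summary(self.outdir / "frequency.triplets.tsv")
        graph = threshold(summary, self.cfg.cutoff)
        comps = subnetworks(graph)
        rows = []
        if graph.n_edges > 0:
            part = fast_greedy_partition(graph)
            q = part.modularity
            for gene, lab in sorted(part.assignment.items()):
                rows.append((gene, lab))
        else:
            q = float("nan")
            rows = [(g, i) for i, g in enumerate(graph.gene_ids)]
        out = self.outdir
        pd.DataFrame(rows, columns=["gene", "community"]).to_csv(
            out / "communities.tsv", sep="\t", index=False)
        comp_rows = [(i, g) for i, comp in enumerate(comps) for g in comp]
        pd.DataFrame(comp_rows, columns=["component", "gene"]).to_csv(
            out / "components.tsv", sep="\t", index=False)
        (out / "partition_summary.json").write_text(json.dumps({
            "cutoff": self.cfg.cutoff,
            "n_edges": graph.n_edges,
            "n_components": len(comps),
            "modularity": None if np.isnan(q) else q,
        }, indent=2))
        self._record("partition", [out / "communities.tsv", out / "components.tsv",
                                   out / "partition_summary.json"])

    def run_all(self, with_bootstrap: bool = True) -> None:
        self.preprocess()
        self.select_ivs()
        self.infer()
        if with_bootstrap:
            self.bootstrap()
        self.partition()
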