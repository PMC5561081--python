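"""End-to-end workflow: simulate/preprocess -> pairwise similarity -> RMT
threshold -> network -> modules -> enrichment -> neighbor-voting evaluation.

Every stage writes its artifact plus a small JSON sidecar carrying the run
configuration hash, and each stage is resumable from the prior outputs. The
unit of parallel distribution is a pair-index window over the upper
triangle; chunked similarity runs merge to the unchunked output because
per-pair seeds depend only on pair identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import gem as gemio
from .enrich import clinical_enrichment, read_gmt, functional_enrichment
from .linkcomm import detect_modules
from .network import extract_network, write_network
from .pairwise import (
    PairwiseConfig,
    count_pairs,
    iter_pair_results,
    write_pair_results,
)
from .rmt import find_threshold
from .simulate import SynthConfig, generate_gem
from .voting import build_annotation_matrix, network_adjacency, neighbor_voting_auroc

log = logging.getLogger("comodnet")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Union of stage configurations; serializable to a single JSON file."""

    out_dir: str
    gem_path: Optional[str] = None          # input GEM; None -> simulate
    annotations_path: Optional[str] = None  # sample annotation TSV
    terms_path: Optional[str] = None        # GMT for enrichment/evaluation
    seed: int = 0
    # preprocessing
    do_log2: bool = True
    do_quantile: bool = True
    ks_cutoff: float = 0.15
    # pairwise
    method: str = "spearman"
    use_gmm: bool = True
    min_cluster_size: int = 30
    min_expression_range: float = 0.1
    k_max: int = 5
    restarts: int = 3
    outlier_rule: str = "iqr_1_5"
    # thresholding; tau set -> skip the RMT scan
    tau: Optional[float] = None
    tau_start: float = 0.5
    tau_step: float = 0.001
    rmt_min_size: int = 100
    # enrichment / evaluation
    enrich_fraction: float = 0.95
    alpha: float = 0.001
    folds: int = 3
    # simulation fallback (JSON dict mirroring SynthConfig) when gem_path is None
    synth: Optional[dict] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def pairwise_config(self) -> PairwiseConfig:
        return PairwiseConfig(
            method=self.method,
            use_gmm=self.use_gmm,
            min_cluster_size=self.min_cluster_size,
            min_expression_range=self.min_expression_range,
            K_max=self.k_max,
            restarts=self.restarts,
            seed=self.seed,
            outlier_rule=self.outlier_rule,
        )


def _sidecar(path: Path, cfg: RunConfig, stage: str, **extra) -> None:
    meta = {"stage": stage, "config_hash": cfg.config_hash(), **extra}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2)
    )


def run_all(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full workflow; returns the artifact paths per stage."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(cfg.to_json())
    artifacts: dict[str, Path] = {}

    # --- input GEM -------------------------------------------------------
    annotations: Optional[pd.DataFrame] = None
    if cfg.gem_path is None:
        synth_kwargs = dict(cfg.synth or {})
        if "modules" in synth_kwargs:
            from .simulate import ModuleSpec

            synth_kwargs["modules"] = [
                ModuleSpec(**m) if isinstance(m, dict) else m
                for m in synth_kwargs["modules"]
            ]
        if "conditions" in synth_kwargs:
            synth_kwargs["conditions"] = [
                tuple(c) for c in synth_kwargs["conditions"]
            ]
        synth_kwargs.setdefault("seed", cfg.seed)
        scfg = SynthConfig(**synth_kwargs)
        g, truth, annotations = generate_gem(scfg)
        gem_path = out / "gem.tsv"
        gemio.write_gem(g, gem_path)
        annotations.to_csv(out / "samples.tsv", sep="\t", index_label="sample_id")
        with open(out / "truth.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene_a\tgene_b\tactive_conditions\n")
            for a, b, conds in truth.planted_pairs:
                fh.write(f"{a}\t{b}\t{','.join(conds)}\n")
        artifacts["gem"] = gem_path
        log.info("simulated GEM: %d x %d", g.n_transcripts, g.n_samples)
        # synthetic data is generated on an already-normalized log2 scale
        do_log2 = False
        do_quantile = False
    else:
        gem_path = Path(cfg.gem_path)
        g = gemio.read_gem(gem_path)
        do_log2 = cfg.do_log2
        do_quantile = cfg.do_quantile
    if cfg.annotations_path:
        annotations = pd.read_csv(
            cfg.annotations_path, sep="\t", index_col=0
        )

    # --- preprocess ------------------------------------------------------
    if do_log2:
        g = gemio.log2_transform(g)
    report = gemio.ks_outlier_screen(g, cutoff=cfg.ks_cutoff)
    rep_path = out / "ks_report.tsv"
    with open(rep_path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tD_N\tflagged\n")
        flagged = {s for s, _ in report.flagged_samples}
        for sid, d in report.statistics:
            fh.write(f"{sid}\t{d:.6g}\t{int(sid in flagged)}\n")
    if do_quantile:
        g = gemio.quantile_normalize(g)
    pre_path = out / "preprocessed.tsv"
    gemio.write_gem(g, pre_path)
    _sidecar(pre_path, cfg, "preprocess", flagged=len(report.flagged_samples))
    artifacts["preprocessed"] = pre_path
    log.info("preprocessed GEM: %d flagged samples", len(report.flagged_samples))

    # --- pairwise similarity --------------------------------------------
    sim_dir = out / "similarity"
    sim_dir.mkdir(exist_ok=True)
    pcfg = cfg.pairwise_config()
    sim_path = sim_dir / "chunk-0.tsv"
    results = list(iter_pair_results(g, pcfg))
    write_pair_results(results, sim_path, method=cfg.method)
    _sidecar(sim_path, cfg, "similarity", pairs=count_pairs(g.n_transcripts))
    artifacts["similarity"] = sim_path
    n_clusters = sum(len(r.clusters) for r in results)
    log.info(
        "similarity: %d pairs, %d clusters tested",
        count_pairs(g.n_transcripts), n_clusters,
    )

    # --- threshold -------------------------------------------------------
    if cfg.tau is not None:
        tau = cfg.tau
        log.info("threshold: user override tau=%.4f", tau)
    else:
        scan = find_threshold(
            results,
            tau_start=cfg.tau_start,
            tau_step=cfg.tau_step,
            min_size=cfg.rmt_min_size,
        )
        scan_path = out / "scan.tsv"
        with open(scan_path, "w", encoding="utf-8") as fh:
            fh.write("tau\tmatrix_size\tchi2\n")
            for t, s, c in zip(scan.taus, scan.sizes, scan.chi2):
                fh.write(f"{t:.4f}\t{s}\t{c:.6g}\n")
        artifacts["scan"] = scan_path
        if scan.chosen_tau is None:
            raise RuntimeError(
                f"threshold stage failed: no RMT threshold found "
                f"({scan.diagnostic}); set an explicit tau"
            )
        tau = scan.chosen_tau
        log.info("threshold: RMT chose tau=%.4f", tau)

    # --- network ---------------------------------------------------------
    net = extract_network(results, tau, sample_ids=g.sample_ids, method=cfg.method)
    net_path = out / "net.tsv"
    write_network(net, net_path, sidecar={"config_hash": cfg.config_hash()})
    artifacts["network"] = net_path
    log.info("network: %d nodes, %d edges kept", len(net.nodes), len(net.edges))

    # --- modules ---------------------------------------------------------
    partition = detect_modules(net)
    mod_path = out / "modules.tsv"
    with open(mod_path, "w", encoding="utf-8") as fh:
        fh.write("module_id\tgene_a\tgene_b\tcluster_index\trho\n")
        for mid, e in zip(partition.edge_assignment, net.edges):
            fh.write(
                f"{mid}\t{e.gene_a}\t{e.gene_b}\t{e.cluster_index}\t"
                f"{e.rho:.10g}\n"
            )
    summary_path = out / "modules_summary.tsv"
    with open(summary_path, "w", encoding="utf-8") as fh:
        fh.write("module_id\tm_c\tn_c\n")
        for mod in partition.modules:
            fh.write(f"{mod.module_id}\t{mod.m_c}\t{mod.n_c}\n")
    _sidecar(mod_path, cfg, "modules", n_modules=len(partition.modules),
             partition_density=partition.partition_density)
    artifacts["modules"] = mod_path
    log.info(
        "modules: %d modules, partition density %.4f",
        len(partition.modules), partition.partition_density,
    )

    # --- enrichment ------------------------------------------------------
    if annotations is not None and net.edges:
        enr = clinical_enrichment(
            partition, net, annotations,
            fraction=cfg.enrich_fraction, alpha=cfg.alpha,
        )
        enr_path = out / "enrichment.tsv"
        enr.to_csv(enr_path, sep="\t", index=False)
        artifacts["enrichment"] = enr_path
        log.info("enrichment: %d tests", len(enr))
    if cfg.terms_path and net.edges:
        terms = read_gmt(cfg.terms_path)
        background = set(g.transcript_ids)
        rows = []
        for mod in partition.modules:
            genes = mod.genes
            for rec in functional_enrichment(
                genes, terms, background, alpha=cfg.alpha,
                module_id=mod.module_id,
            ):
                rows.append(rec)
        fun_path = out / "functional_enrichment.tsv"
        pd.DataFrame(
            [
                {
                    "module_id": r.module_id, "term": r.category,
                    "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                    "p": r.p, "p_bonferroni": r.p_bonferroni, "p_bh": r.p_bh,
                }
                for r in rows
            ]
        ).to_csv(fun_path, sep="\t", index=False)
        artifacts["functional_enrichment"] = fun_path

    # --- evaluation ------------------------------------------------------
    if cfg.terms_path and net.edges:
        adj, genes = network_adjacency(net)
        ann_mat, kept = build_annotation_matrix(genes, read_gmt(cfg.terms_path))
        if kept:
            rep = neighbor_voting_auroc(
                adj, ann_mat, folds=cfg.folds, seed=cfg.seed,
                function_ids=kept,
            )
            auroc_path = out / "auroc.tsv"
            with open(auroc_path, "w", encoding="utf-8") as fh:
                fh.write("function\tauroc\n")
                for fid, a in zip(rep.function_ids, rep.per_function):
                    fh.write(f"{fid}\t{a:.6f}\n")
                fh.write(f"MEAN\t{rep.mean_auroc:.6f}\n")
            artifacts["auroc"] = auroc_path
            log.info("evaluation: mean AUROC %.4f over %d functions",
                     rep.mean_auroc, len(rep.per_function))
    return artifacts
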