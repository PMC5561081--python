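"""Synthetic mixed-condition expression fixtures with planted co-expression.

The generator emulates a compendium pooled from several biological
conditions: planted modules of genes co-express (at a configurable latent
correlation) only in their active conditions, sit at a shifted mean there
(creating a separated second mode in pairwise scatters against the inactive
conditions), and everything else is independent log-scale Gaussian noise
with a configurable missing-value rate. Truth tables accompany each matrix
so recovery can be scored quantitatively.

Module genes in an active condition follow

    x_gs = mu_g + shift + noise_sd * (sqrt(r) z_cs + sqrt(1 - r) eps_gs)

with one latent factor z per (module, sample), so the within-module pairwise
correlation is r by construction. Inactive conditions and background genes
are mu_g + noise_sd * eps. An optional compendium-wide latent factor
(``background_correlation``) correlates every gene at a low level,
emulating global covariation such as library-size effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .gem import GEM
from .network import Network

__all__ = [
    "ModuleSpec",
    "SynthConfig",
    "TruthTable",
    "RecoveryReport",
    "default_config",
    "generate_gem",
    "score_recovery",
]


@dataclass
class ModuleSpec:
    gene_count: int
    active_conditions: tuple[str, ...]
    latent_correlation: float = 0.9
    mean_shift: float = 4.0  # log2 units added in active conditions

    def __post_init__(self) -> None:
        self.active_conditions = tuple(self.active_conditions)
        if self.gene_count <= 0:
            raise ValueError("gene_count must be positive")
        if not 0.0 < self.latent_correlation < 1.0:
            raise ValueError("latent_correlation must be in (0, 1)")


@dataclass
class SynthConfig:
    conditions: list[tuple[str, int]]
    modules: list[ModuleSpec]
    background_genes: int = 200
    noise_sd: float = 1.0
    missing_rate: float = 0.02
    # correlation shared by every gene via one global latent factor
    # (compendium-wide covariation, e.g. library-size-like effects); module
    # latent correlations must be >= this value
    background_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_correlation < 1.0:
            raise ValueError("background_correlation must be in [0, 1)")
        for mod in self.modules:
            if mod.latent_correlation < self.background_correlation:
                raise ValueError(
                    "module latent_correlation below background_correlation"
                )
        if any(n <= 0 for _, n in self.conditions):
            raise ValueError("condition sample counts must be positive")
        if self.background_genes < 0:
            raise ValueError("background_genes must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        names = [c for c, _ in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate condition names")
        for mod in self.modules:
            unknown = set(mod.active_conditions) - set(names)
            if unknown:
                raise ValueError(f"unknown active conditions {unknown}")


@dataclass
class TruthTable:
    planted_pairs: list[tuple[str, str, tuple[str, ...]]]
    module_genes: dict[str, list[str]]
    module_conditions: dict[str, tuple[str, ...]]
    sample_conditions: dict[str, str]

    def pair_set(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.planted_pairs}


@dataclass
class RecoveryReport:
    precision: Optional[float]  # None when the network is empty
    recall: float
    purity: Optional[float]


def default_config(seed: int = 0) -> SynthConfig:
    """The default desk-scale fixture: five conditions of 60 samples each
    (mirroring a five-subtype compendium), two single-condition planted
    modules, one module shared by two conditions, and 200 background genes."""
    conditions = [(f"COND{k}", 60) for k in range(1, 6)]
    modules = [
        ModuleSpec(10, ("COND1",)),
        ModuleSpec(10, ("COND2",)),
        ModuleSpec(10, ("COND1", "COND2")),
    ]
    return SynthConfig(
        conditions=conditions,
        modules=modules,
        background_genes=200,
        noise_sd=1.0,
        missing_rate=0.02,
        seed=seed,
    )


def generate_gem(cfg: SynthConfig) -> tuple[GEM, TruthTable, pd.DataFrame]:
    """Generate (GEM, TruthTable, sample annotations), fully seeded.

    The annotation table is indexed by sample id with a ``condition``
    column; module genes are named PM<m>_G<g>, background genes BG<g>.
    """
    rng = np.random.default_rng(cfg.seed)
    sample_ids: list[str] = []
    sample_cond: dict[str, str] = {}
    cond_of: list[str] = []
    for cname, n in cfg.conditions:
        for k in range(1, n + 1):
            sid = f"{cname}_S{k:03d}"
            sample_ids.append(sid)
            sample_cond[sid] = cname
            cond_of.append(cname)
    M = len(sample_ids)
    cond_arr = np.array(cond_of)

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    module_genes: dict[str, list[str]] = {}
    module_conditions: dict[str, tuple[str, ...]] = {}
    planted: list[tuple[str, str, tuple[str, ...]]] = []

    r_bg = cfg.background_correlation
    z_bg = rng.standard_normal(M) if r_bg > 0 else np.zeros(M)
    w_bg = math.sqrt(r_bg)

    for m_idx, mod in enumerate(cfg.modules, start=1):
        mname = f"PM{m_idx}"
        active = np.isin(cond_arr, mod.active_conditions)
        z = rng.standard_normal(M)  # latent factor, one per sample
        genes = [f"{mname}_G{g:02d}" for g in range(1, mod.gene_count + 1)]
        module_genes[mname] = genes
        module_conditions[mname] = mod.active_conditions
        r = mod.latent_correlation
        w_mod = math.sqrt(r - r_bg)
        for gname in genes:
            mu = rng.uniform(4.0, 10.0)
            eps = rng.standard_normal(M)
            x = mu + cfg.noise_sd * (w_bg * z_bg + math.sqrt(1.0 - r_bg) * eps)
            x[active] = (
                mu
                + mod.mean_shift
                + cfg.noise_sd
                * (
                    w_bg * z_bg[active]
                    + w_mod * z[active]
                    + math.sqrt(1.0 - r) * eps[active]
                )
            )
            gene_ids.append(gname)
            rows.append(x)
        for a in range(len(genes)):
            for b in range(a + 1, len(genes)):
                planted.append((genes[a], genes[b], mod.active_conditions))

    for g in range(1, cfg.background_genes + 1):
        gname = f"BG{g:04d}"
        mu = rng.uniform(4.0, 10.0)
        gene_ids.append(gname)
        rows.append(
            mu
            + cfg.noise_sd
            * (w_bg * z_bg + math.sqrt(1.0 - r_bg) * rng.standard_normal(M))
        )

    values = np.array(rows)
    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        values[mask] = np.nan

    gem = GEM(gene_ids, sample_ids, values)
    truth = TruthTable(
        planted_pairs=planted,
        module_genes=module_genes,
        module_conditions=module_conditions,
        sample_conditions=sample_cond,
    )
    ann = pd.DataFrame(
        {"condition": [sample_cond[s] for s in sample_ids]}, index=sample_ids
    )
    return gem, truth, ann


def score_recovery(network: Network, truth: TruthTable) -> RecoveryReport:
    """Precision/recall of network gene pairs against planted pairs, and the
    condition purity of matched edges' sample strings.

    Purity is the mean, over matched edge records, of the fraction of that
    edge's '1' samples belonging to the planted active condition set.
    """
    planted = {tuple(sorted((a, b))): conds for a, b, conds in truth.planted_pairs}
    net_pairs = {e.pair for e in network.edges}
    if not net_pairs:
        return RecoveryReport(precision=None, recall=0.0, purity=None)
    hit_pairs = net_pairs & set(planted)
    precision = len(hit_pairs) / len(net_pairs)
    recall = len(hit_pairs) / len(planted) if planted else 0.0

    sample_ids = network.sample_ids
    purities: list[float] = []
    if sample_ids:
        for e in network.edges:
            conds = planted.get(e.pair)
            if conds is None:
                continue
            members = [
                sample_ids[k] for k, d in enumerate(e.sample_string) if d == "1"
            ]
            if not members:
                continue
            in_cond = sum(
                1 for s in members if truth.sample_conditions.get(s) in conds
            )
            purities.append(in_cond / len(members))
    purity = float(np.mean(purities)) if purities else None
    return RecoveryReport(precision=precision, recall=recall, purity=purity)
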