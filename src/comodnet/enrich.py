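"""Module enrichment of sample-level clinical annotations and gene-level
functional terms.

Clinical enrichment works through the edge sample strings: a module's sample
set is the set of samples present (digit '1') in at least 95% of the
module's edges; a one-sided Fisher's exact test then asks whether a clinical
category is over-represented in that set. Functional enrichment tests module
genes against GMT term lists over a genomic background, with Bonferroni and
Benjamini-Hochberg corrections reported alongside the raw p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .linkcomm import ModulePartition
from .network import Network

__all__ = [
    "EnrichmentRecord",
    "read_gmt",
    "module_sample_set",
    "fisher_enrichment",
    "functional_enrichment",
    "clinical_enrichment",
]


@dataclass
class EnrichmentRecord:
    module_id: str
    attribute: str
    category: str
    a: int  # selected & in category
    b: int  # selected & not in category
    c: int  # not selected & in category
    d: int  # not selected & not in category
    p: float
    p_bonferroni: float = math.nan
    p_bh: float = math.nan


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """Parse a GMT file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    terms: dict[str, tuple[str, set[str]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            terms[fields[0]] = (fields[1], {g for g in fields[2:] if g})
    return terms


def module_sample_set(
    sample_strings: Sequence[str], fraction: float = 0.95
) -> set[int]:
    """Sample indices with digit '1' in >= ceil(fraction * m_c) of the
    module's edge sample strings."""
    if not sample_strings:
        raise ValueError("module has no edges")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    m = len(sample_strings)
    # round before ceil so 0.95 * 20 counts as exactly 19
    need = math.ceil(round(fraction * m, 9))
    counts: dict[int, int] = {}
    for s in sample_strings:
        for k, d in enumerate(s):
            if d == "1":
                counts[k] = counts.get(k, 0) + 1
    return {k for k, c in counts.items() if c >= need}


def fisher_enrichment(
    selected: set,
    members: set,
    background: set,
    alternative: str = "greater",
    module_id: str = "",
    attribute: str = "",
    category: str = "",
) -> EnrichmentRecord:
    """One-sided (over-representation) Fisher's exact test on the 2x2 table
    of selected/background vs category membership."""
    if not background:
        raise ValueError("empty background")
    if not selected <= background or not members <= background:
        raise ValueError("selected and members must be subsets of background")
    a = len(selected & members)
    b = len(selected - members)
    c = len(members - selected)
    d = len(background) - a - b - c
    p = float(fisher_exact([[a, b], [c, d]], alternative=alternative).pvalue)
    return EnrichmentRecord(
        module_id=module_id, attribute=attribute, category=category,
        a=a, b=b, c=c, d=d, p=p,
    )


def _correct(records: list[EnrichmentRecord]) -> None:
    if not records:
        return
    ps = [r.p for r in records]
    n = len(ps)
    bh = multipletests(ps, method="fdr_bh")[1]
    for r, adj in zip(records, bh):
        r.p_bonferroni = min(1.0, r.p * n)
        r.p_bh = float(adj)


def functional_enrichment(
    module_genes: set[str],
    term_map: Mapping[str, tuple[str, set[str]]],
    background: set[str],
    alpha: float = 0.001,
    alternative: str = "greater",
    module_id: str = "",
) -> list[EnrichmentRecord]:
    """Per-term Fisher test of module genes vs the genomic background.

    Terms with no background members are skipped. Corrections are applied
    across the tested terms; the significance convention is raw p < alpha.
    """
    if not term_map:
        raise ValueError("term_map is empty")
    module_genes = module_genes & background
    records: list[EnrichmentRecord] = []
    for term, (_desc, genes) in term_map.items():
        members = genes & background
        if not members:
            continue
        records.append(
            fisher_enrichment(
                module_genes, members, background,
                alternative=alternative,
                module_id=module_id, attribute="function", category=term,
            )
        )
    _correct(records)
    records.sort(key=lambda r: r.p)
    return records


def clinical_enrichment(
    partition: ModulePartition,
    network: Network,
    annotations: pd.DataFrame,
    fraction: float = 0.95,
    alpha: float = 0.001,
    alternative: str = "greater",
    attributes: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Clinical-annotation enrichment for every module.

    ``annotations``: DataFrame indexed by sample id, one column per
    attribute (condition/subtype, stage, sex, ...). Samples lacking a value
    for an attribute are dropped from that attribute's background.
    Corrections are applied per attribute across all module x category
    tests.
    """
    sample_ids = network.sample_ids
    if not sample_ids:
        raise ValueError("network carries no sample ids")
    cols = list(attributes) if attributes is not None else list(annotations.columns)
    records: list[EnrichmentRecord] = []
    per_attr: dict[str, list[EnrichmentRecord]] = {c: [] for c in cols}
    for mod in partition.modules:
        strings = [network.edges[i].sample_string for i in mod.edge_indices]
        idx_set = module_sample_set(strings, fraction=fraction)
        mod_samples = {sample_ids[k] for k in idx_set}
        for attr in cols:
            series = annotations[attr].dropna()
            bg = set(series.index) & set(sample_ids)
            if not bg:
                continue
            sel = mod_samples & bg
            for cat in sorted(series.unique()):
                members = set(series[series == cat].index) & bg
                rec = fisher_enrichment(
                    sel, members, bg, alternative=alternative,
                    module_id=mod.module_id, attribute=attr, category=str(cat),
                )
                per_attr[attr].append(rec)
                records.append(rec)
    for attr_records in per_attr.values():
        _correct(attr_records)
    df = pd.DataFrame(
        [
            {
                "module_id": r.module_id,
                "attribute": r.attribute,
                "category": r.category,
                "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                "p": r.p,
                "p_bonferroni": r.p_bonferroni,
                "p_bh": r.p_bh,
                "significant": r.p < alpha,
            }
            for r in records
        ]
    )
    return df.sort_values(["module_id", "attribute", "p"]).reset_index(drop=True)
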