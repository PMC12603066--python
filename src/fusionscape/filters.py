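"""The fusion filter cascade: seven removal rules plus the cohort-level
read-support requirement, applied in a fixed order with full audit.

Stage order: same_gene -> blacklist -> paralog -> normal_panel -> proximity
-> consensus -> promiscuity -> cohort_support. Per-record stages run first
(they commute, so order only affects reason attribution); consensus then
thins the set before the two cohort-level stages, so hub-gene partner
counts are not inflated by records already known to be noise. The
promiscuity basis is configurable (``surviving`` vs ``raw``).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from .io import ResourceBundle
from .model import (
    ARTIFACT_BIOTYPES,
    FilterConfig,
    HarmonizedFusion,
    RemovalRecord,
    gene_distance,
    breakpoint_distance,
)

log = logging.getLogger(__name__)

STAGE_ORDER = ("same_gene", "blacklist", "paralog", "normal_panel",
               "proximity", "consensus", "promiscuity", "cohort_support")


def _split(fusions: Iterable[HarmonizedFusion], keep: Callable) -> tuple[list, list]:
    kept, removed = [], []
    for f in fusions:
        (kept if keep(f) else removed).append(f)
    return kept, removed


def filter_same_gene(fusions: Iterable[HarmonizedFusion]) -> tuple[list, list]:
    """Drop self-fusions (both partners the same gene)."""
    return _split(fusions, lambda f: f.gene5 != f.gene3)


def _is_blacklisted(gene: str, resources: ResourceBundle) -> bool:
    if gene in resources.blacklist:
        return True
    gm = resources.gene_models.get(gene)
    if gm is None:
        log.warning("unannotated partner %s; treating as not blacklisted", gene)
        return False
    return gm.biotype_class in ARTIFACT_BIOTYPES


def filter_blacklist(fusions: Iterable[HarmonizedFusion],
                     resources: ResourceBundle) -> tuple[list, list]:
    """Drop fusions with a blacklisted partner (explicit list entries plus
    uncharacterized / immunoglobulin / mitochondrial gene classes)."""
    return _split(fusions, lambda f: not (_is_blacklisted(f.gene5, resources)
                                          or _is_blacklisted(f.gene3, resources)))


def filter_paralog(fusions: Iterable[HarmonizedFusion],
                   resources: ResourceBundle) -> tuple[list, list]:
    """Drop fusions whose unordered partner pair is a known paralog pair."""
    pairs = resources.paralog_pairs
    return _split(fusions, lambda f: frozenset((f.gene5, f.gene3)) not in pairs)


def filter_normal_panel(fusions: Iterable[HarmonizedFusion],
                        resources: ResourceBundle) -> tuple[list, list]:
    """Drop fusions whose ordered pair appears in the normal-tissue panel."""
    panel = resources.normal_panel_pairs
    return _split(fusions, lambda f: (f.gene5, f.gene3) not in panel)


def filter_proximity(fusions: Iterable[HarmonizedFusion], resources: ResourceBundle,
                     config: FilterConfig) -> tuple[list, list]:
    """Drop likely read-throughs: same-chromosome partners closer than the
    proximity threshold (default: gene-gap < 300 kb, strict).

    The distance metric is configurable between the inter-gene gap
    (``gene_gap``) and the representative breakpoint distance
    (``breakpoint``); partners on different chromosomes always pass, and an
    unannotated partner passes with a warning under the gene-gap metric.
    """
    def keep(f: HarmonizedFusion) -> bool:
        if config.proximity_metric == "breakpoint":
            dist = breakpoint_distance(f.bp5, f.bp3)
        else:
            a = resources.gene_models.get(f.gene5)
            b = resources.gene_models.get(f.gene3)
            if a is None or b is None:
                log.warning("proximity: unannotated partner in %s--%s; kept",
                            f.gene5, f.gene3)
                return True
            dist = gene_distance(a, b)
        if dist is None:
            return True
        if config.proximity_inclusive:
            return dist > config.proximity_threshold_bp
        return dist >= config.proximity_threshold_bp

    return _split(fusions, keep)


def filter_consensus(fusions: Iterable[HarmonizedFusion],
                     config: FilterConfig) -> tuple[list, list]:
    """Require support from at least ``min_callers`` independent callers."""
    return _split(fusions, lambda f: len(f.callers) >= config.min_callers)


def filter_promiscuity(fusions: Iterable[HarmonizedFusion],
                       config: FilterConfig) -> tuple[list, list]:
    """Drop fusions involving promiscuous hub genes.

    A gene's promiscuity is its number of distinct partner genes (either
    orientation) across all samples of the input set; every record touching
    a gene at or above ``promiscuity_threshold`` partners is removed.
    """
    fusions = list(fusions)
    partners: dict[str, set] = defaultdict(set)
    for f in fusions:
        partners[f.gene5].add(f.gene3)
        partners[f.gene3].add(f.gene5)
    thr = config.promiscuity_threshold
    return _split(fusions, lambda f: len(partners[f.gene5]) < thr
                  and len(partners[f.gene3]) < thr)


def filter_cohort_support(fusions: Iterable[HarmonizedFusion],
                          config: FilterConfig) -> tuple[list, list]:
    """Cohort-level read-support rule.

    A fusion pair survives iff, across all samples carrying it, at least one
    sample has >= ``min_junction_reads`` junction reads or at least one
    sample has >= ``min_spanning_reads`` spanning reads; otherwise every
    record of the pair is removed.
    """
    fusions = list(fusions)
    supported = set()
    for f in fusions:
        if (f.junction_reads >= config.min_junction_reads
                or f.spanning_reads >= config.min_spanning_reads):
            supported.add(f.pair)
    return _split(fusions, lambda f: f.pair in supported)


@dataclass
class CascadeResult:
    kept: list
    removals: list
    per_stage_counts: dict = field(default_factory=dict)


def run_cascade(fusions: Iterable[HarmonizedFusion], resources: ResourceBundle,
                config: Optional[FilterConfig] = None,
                skip_stages: Iterable[str] = ()) -> CascadeResult:
    """Apply the full filter cascade; each removed record carries the first
    failing stage as its reason, and per-stage counts sum to |input|-|kept|.

    ``skip_stages`` disables named stages (useful for sensitivity checks,
    e.g. comparing kept sets with and without the promiscuity rule).
    """
    if config is None:
        config = FilterConfig()
    skip = set(skip_stages)
    unknown = skip - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages to skip: {sorted(unknown)}")

    stages: dict[str, Callable] = {
        "same_gene": lambda fs: filter_same_gene(fs),
        "blacklist": lambda fs: filter_blacklist(fs, resources),
        "paralog": lambda fs: filter_paralog(fs, resources),
        "normal_panel": lambda fs: filter_normal_panel(fs, resources),
        "proximity": lambda fs: filter_proximity(fs, resources, config),
        "consensus": lambda fs: filter_consensus(fs, config),
        "promiscuity": lambda fs: filter_promiscuity(fs, config),
        "cohort_support": lambda fs: filter_cohort_support(fs, config),
    }

    current = list(fusions)
    if config.promiscuity_basis == "raw" and "promiscuity" not in skip:
        # partner counts computed on the unfiltered input instead of the
        # post-consensus surviving set
        raw_kept, _ = filter_promiscuity(current, config)
        raw_ids = {(f.sample_id, f.gene5, f.gene3) for f in raw_kept}
        stages["promiscuity"] = lambda fs: _split(
            fs, lambda f: (f.sample_id, f.gene5, f.gene3) in raw_ids)

    removals: list[RemovalRecord] = []
    per_stage_counts: dict[str, int] = {}
    for index, name in enumerate(STAGE_ORDER):
        if name in skip:
            per_stage_counts[name] = 0
            continue
        current, removed = stages[name](current)
        per_stage_counts[name] = len(removed)
        removals.extend(RemovalRecord(fusion=f, reason=name, stage_index=index)
                        for f in removed)
    return CascadeResult(kept=current, removals=removals,
                         per_stage_counts=per_stage_counts)
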