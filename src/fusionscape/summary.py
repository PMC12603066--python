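"""Cohort-level landscape statistics: recurrence fractions, configuration
distribution, per-sample fusion burden, prevalence, and kinase/druggable
summaries, with optional stratification by sample metadata.

Percentages use half-up rounding (2 decimals by default); exact fractions
are kept alongside so any printed precision can be recovered. The
unique/recurrent denominator is the number of *distinct ordered pairs*, not
per-sample events — a cohort-level total of "fusion genes" counts each pair
once however many samples carry it.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional

from .annotate import (
    BURDEN_BINS,
    CONFIGURATION_LABELS,
    AnnotatedFusion,
    bin_fusion_burden,
    count_recurrence,
)

log = logging.getLogger(__name__)


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Half-up percentage, e.g. percent(5678, 6156) -> 92.24."""
    if denominator == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(numerator) / Decimal(denominator) * 100).quantize(
        q, rounding=ROUND_HALF_UP))


@dataclass
class GroupPrevalence:
    n_samples: int
    n_positive: int
    prevalence_pct: float
    prevalence_pct_1dp: float


@dataclass
class CohortSummary:
    n_samples: int
    n_fusion_events: int                     # (sample, pair) records
    n_distinct_pairs: int
    n_unique_pairs: int
    n_recurrent_pairs: int
    pct_unique: float
    pct_recurrent: float
    configuration_counts: dict = field(default_factory=dict)
    configuration_pct: dict = field(default_factory=dict)
    n_fusion_positive_samples: int = 0
    prevalence_pct: float = 0.0
    burden_bin_counts: dict = field(default_factory=dict)
    n_kinase_positive_samples: int = 0
    pct_kinase_of_positive: float = 0.0
    n_kinase_fusion_pairs: int = 0
    pct_druggable_kinase: float = 0.0
    n_novel_pairs: int = 0
    by_tissue_class: dict = field(default_factory=dict)
    by_subtype: dict = field(default_factory=dict)


def _group_prevalence(sample_ids: Iterable[str], positive: set) -> GroupPrevalence:
    ids = list(sample_ids)
    n_pos = sum(1 for s in ids if s in positive)
    return GroupPrevalence(n_samples=len(ids), n_positive=n_pos,
                           prevalence_pct=percent(n_pos, len(ids)),
                           prevalence_pct_1dp=percent(n_pos, len(ids), decimals=1))


def summarize(annotated: Iterable[AnnotatedFusion],
              sample_ids: Optional[Iterable[str]] = None,
              metadata: Optional[dict] = None) -> CohortSummary:
    """Compute the full landscape summary of a filtered, annotated cohort.

    ``sample_ids`` is the complete cohort sample list (needed for prevalence
    and the zero-burden bin; defaults to the samples observed in the
    records). ``metadata`` optionally maps sample_id -> {"subtype": ...,
    "tissue_class": "tumor"|"paratumor"} for stratified prevalence.
    """
    annotated = list(annotated)
    fusions = [a.fusion for a in annotated]
    observed = {f.sample_id for f in fusions}
    if sample_ids is None:
        all_samples = sorted(observed)
    else:
        all_samples = list(dict.fromkeys(sample_ids))
        extra = observed - set(all_samples)
        if extra:
            log.warning("records for %d samples not in sample_ids; adding them",
                        len(extra))
            all_samples.extend(sorted(extra))
    if metadata:
        orphans = sorted(set(metadata) - set(all_samples))
        if orphans:
            log.warning("metadata sample_ids not in cohort: %s", orphans[:10])

    recurrence = count_recurrence(fusions)
    n_pairs = len(recurrence)
    n_recurrent = sum(1 for r in recurrence.values() if r.recurrent)
    n_unique = n_pairs - n_recurrent
    pct_unique = percent(n_unique, n_pairs)
    # complement after rounding so the two shares always total 100 exactly
    pct_recurrent = round(100.0 - pct_unique, 2) if n_pairs else 0.0

    config_counts = Counter(a.configuration for a in annotated)
    configuration_counts = {lbl: config_counts.get(lbl, 0) for lbl in CONFIGURATION_LABELS}
    configuration_pct = {lbl: percent(configuration_counts[lbl], len(annotated))
                         for lbl in CONFIGURATION_LABELS}

    burden = Counter(f.sample_id for f in fusions)
    burden_bin_counts = {b: 0 for b in BURDEN_BINS}
    for sid in all_samples:
        burden_bin_counts[bin_fusion_burden(burden.get(sid, 0))] += 1
    positive = {sid for sid in all_samples if burden.get(sid, 0) > 0}

    kinase_records = [a for a in annotated if a.kinase is not None]
    kinase_samples = {a.fusion.sample_id for a in kinase_records}
    kinase_pairs = {a.fusion.pair for a in kinase_records}
    druggable_pairs = {a.fusion.pair for a in kinase_records if a.kinase.druggable}
    novel_pairs = {a.fusion.pair for a in annotated if a.novel}

    by_tissue: dict[str, GroupPrevalence] = {}
    by_subtype: dict[str, GroupPrevalence] = {}
    if metadata:
        tissue_groups: dict[str, list] = defaultdict(list)
        subtype_groups: dict[str, list] = defaultdict(list)
        for sid in all_samples:
            meta = metadata.get(sid, {})
            if "tissue_class" in meta:
                tissue_groups[meta["tissue_class"]].append(sid)
            if "subtype" in meta:
                subtype_groups[meta["subtype"]].append(sid)
        by_tissue = {k: _group_prevalence(v, positive) for k, v in sorted(tissue_groups.items())}
        by_subtype = {k: _group_prevalence(v, positive) for k, v in sorted(subtype_groups.items())}

    return CohortSummary(
        n_samples=len(all_samples),
        n_fusion_events=len(fusions),
        n_distinct_pairs=n_pairs,
        n_unique_pairs=n_unique,
        n_recurrent_pairs=n_recurrent,
        pct_unique=pct_unique,
        pct_recurrent=pct_recurrent,
        configuration_counts=configuration_counts,
        configuration_pct=configuration_pct,
        n_fusion_positive_samples=len(positive),
        prevalence_pct=percent(len(positive), len(all_samples)),
        burden_bin_counts=burden_bin_counts,
        n_kinase_positive_samples=len(kinase_samples),
        pct_kinase_of_positive=percent(len(kinase_samples), len(positive)),
        n_kinase_fusion_pairs=len(kinase_pairs),
        pct_druggable_kinase=percent(len(druggable_pairs), len(kinase_pairs)),
        n_novel_pairs=len(novel_pairs),
        by_tissue_class=by_tissue,
        by_subtype=by_subtype,
    )


def top_recurrent(cohort_or_recurrence, min_samples: int = 5) -> list:
    """Pairs carried by at least ``min_samples`` distinct samples, ranked by
    count (descending) then lexicographically.

    Accepts either a cohort of records or a precomputed recurrence map.
    """
    if isinstance(cohort_or_recurrence, dict):
        recurrence = cohort_or_recurrence
    else:
        recurrence = count_recurrence(cohort_or_recurrence)
    ranked = [(pair, info.sample_count) for pair, info in recurrence.items()
              if info.sample_count >= min_samples]
    return sorted(ranked, key=lambda pc: (-pc[1], pc[0]))
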