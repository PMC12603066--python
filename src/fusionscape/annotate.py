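"""Breakpoint-configuration taxonomy, recurrence, fusion-burden bins, and
kinase-fusion annotation (domain retention, novelty, druggability).

Configuration labels follow the standard chimeric-transcript taxonomy:

* ``interchromosomal`` — breakpoints on different chromosomes;
* ``noncolinear`` — same chromosome, breakpoints on different strands;
* ``colinear_agr`` — same chromosome and strand with breakpoints within the
  adjacent-gene-rearrangement distance (default 500 kb), the classic
  read-through geometry;
* ``intrachromosomal`` — same chromosome and strand, breakpoints farther
  apart.

Strand comparisons use the caller-reported breakpoint (fusion-transcript)
strand, not the annotated gene strand.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Optional

from .io import ResourceBundle
from .model import (
    FilterConfig,
    GeneModel,
    HarmonizedFusion,
    InvalidRecordError,
    breakpoint_distance,
)

log = logging.getLogger(__name__)

CONFIGURATION_LABELS = ("interchromosomal", "noncolinear", "colinear_agr",
                        "intrachromosomal")

BURDEN_BINS = ("0", "1", "2-5", "6-10", ">10")

DOMAIN_STATUSES = ("retained", "partial", "lost", "unknown")


@dataclass(frozen=True)
class KinaseAnnotation:
    """Kinase-fusion annotation for one harmonized record."""

    kinase_gene: str
    kinase_position: str          # five_prime | three_prime | both
    domain_status: str = "unknown"
    druggable: bool = False
    novel: bool = False


@dataclass(frozen=True)
class RecurrenceInfo:
    sample_count: int
    recurrent: bool               # seen in >= 2 distinct samples
    display_tier: bool            # seen in > 4 distinct samples


@dataclass(frozen=True)
class AnnotatedFusion:
    """A filtered fusion with its configuration, recurrence and kinase flags."""

    fusion: HarmonizedFusion
    configuration: str
    recurrence_count: int
    recurrent: bool
    novel: bool
    kinase: Optional[KinaseAnnotation] = None


def classify_configuration(fusion: HarmonizedFusion,
                           config: Optional[FilterConfig] = None) -> str:
    """Assign exactly one configuration label to a fusion (total function)."""
    agr = (config or FilterConfig()).agr_threshold_bp
    bp5, bp3 = fusion.bp5, fusion.bp3
    if bp5.chrom != bp3.chrom:
        return "interchromosomal"
    if bp5.strand != bp3.strand:
        return "noncolinear"
    dist = breakpoint_distance(bp5, bp3)
    if dist is not None and dist <= agr:
        return "colinear_agr"
    return "intrachromosomal"


def count_recurrence(cohort: Iterable[HarmonizedFusion]) -> dict:
    """Per ordered gene pair, the number of distinct samples carrying it.

    A pair is *recurrent* at >= 2 distinct samples and *display-tier* at
    > 4 (the usual landscape-figure cutoff); two records of the same pair in
    one sample count once.
    """
    samples: dict[tuple, set] = defaultdict(set)
    for f in cohort:
        samples[f.pair].add(f.sample_id)
    return {pair: RecurrenceInfo(sample_count=len(s), recurrent=len(s) >= 2,
                                 display_tier=len(s) > 4)
            for pair, s in samples.items()}


def bin_fusion_burden(n: int) -> str:
    """Map a per-sample fusion count onto the standard burden bins
    {0, 1, 2-5, 6-10, >10}."""
    if not isinstance(n, int) or isinstance(n, bool) or n < 0:
        raise InvalidRecordError(f"fusion burden must be a non-negative integer, got {n!r}")
    if n == 0:
        return "0"
    if n == 1:
        return "1"
    if n <= 5:
        return "2-5"
    if n <= 10:
        return "6-10"
    return ">10"


def flag_kinase_fusion(fusion: HarmonizedFusion,
                       resources: ResourceBundle) -> Optional[KinaseAnnotation]:
    """Annotate a fusion whose 5' and/or 3' partner is a kinase; None otherwise.

    When both partners are kinases the 5' partner is reported as the primary
    kinase gene (position ``both``).
    """
    k5 = fusion.gene5 in resources.kinase_genes
    k3 = fusion.gene3 in resources.kinase_genes
    if not (k5 or k3):
        return None
    if k5 and k3:
        return KinaseAnnotation(kinase_gene=fusion.gene5, kinase_position="both")
    if k5:
        return KinaseAnnotation(kinase_gene=fusion.gene5, kinase_position="five_prime")
    return KinaseAnnotation(kinase_gene=fusion.gene3, kinase_position="three_prime")


def retained_interval(gene: GeneModel, breakpoint_pos: int,
                      position: str) -> Optional[tuple[int, int]]:
    """Genomic interval of ``gene`` retained in the fusion transcript.

    The 5' partner retains the transcript-upstream side of its breakpoint
    and the 3' partner the transcript-downstream side, where transcript
    orientation follows the gene strand; the junction base itself is
    retained. Returns None when the breakpoint lies outside the gene.
    """
    if not (gene.start <= breakpoint_pos <= gene.end):
        return None
    upstream_side = (gene.start, breakpoint_pos) if gene.strand == "+" \
        else (breakpoint_pos, gene.end)
    downstream_side = (breakpoint_pos, gene.end) if gene.strand == "+" \
        else (gene.start, breakpoint_pos)
    return upstream_side if position == "five_prime" else downstream_side


def domain_retention(fusion: HarmonizedFusion, resources: ResourceBundle) -> str:
    """Kinase-domain status of the fusion's kinase partner, from its breakpoint.

    ``retained`` if every annotated kinase-domain interval lies inside the
    retained region, ``lost`` if none of the domain bases do, ``partial``
    otherwise; ``unknown`` when the gene has no domain intervals or the
    breakpoint falls outside the gene model. For kinase--kinase fusions the
    5' partner is assessed.
    """
    ann = flag_kinase_fusion(fusion, resources)
    if ann is None:
        return "unknown"
    position = "five_prime" if ann.kinase_position in ("five_prime", "both") \
        else "three_prime"
    gene = resources.gene_models.get(ann.kinase_gene)
    if gene is None or not gene.kinase_domains:
        return "unknown"
    bp = fusion.bp5 if position == "five_prime" else fusion.bp3
    region = retained_interval(gene, bp.pos, position)
    if region is None:
        log.warning("breakpoint %s outside kinase gene %s [%d,%d]",
                    bp, gene.symbol, gene.start, gene.end)
        return "unknown"
    lo, hi = region
    fully_in = all(lo <= ds and de <= hi for ds, de in gene.kinase_domains)
    if fully_in:
        return "retained"
    any_base = any(ds <= hi and lo <= de for ds, de in gene.kinase_domains)
    return "partial" if any_base else "lost"


def flag_novel(fusion: HarmonizedFusion, resources: ResourceBundle) -> bool:
    """True iff the ordered pair is absent from the known-fusion database list."""
    return fusion.pair not in resources.known_fusion_pairs


def flag_druggable(annotation: KinaseAnnotation, resources: ResourceBundle) -> bool:
    """True iff the annotated kinase gene is on the druggable-kinase list."""
    return annotation.kinase_gene in resources.druggable_kinases


def annotate_cohort(cohort: Iterable[HarmonizedFusion], resources: ResourceBundle,
                    config: Optional[FilterConfig] = None) -> list:
    """Full annotation pass over a filtered cohort."""
    cohort = list(cohort)
    recurrence = count_recurrence(cohort)
    out = []
    for f in cohort:
        rec = recurrence[f.pair]
        kin = flag_kinase_fusion(f, resources)
        if kin is not None:
            kin = replace(kin,
                          domain_status=domain_retention(f, resources),
                          druggable=flag_druggable(kin, resources),
                          novel=flag_novel(f, resources))
        out.append(AnnotatedFusion(
            fusion=f,
            configuration=classify_configuration(f, config),
            recurrence_count=rec.sample_count,
            recurrent=rec.recurrent,
            novel=flag_novel(f, resources),
            kinase=kin))
    return out


ANNOTATED_COLUMNS = ["configuration", "recurrence_count", "recurrent",
                     "kinase_gene", "kinase_position", "domain_status",
                     "novel", "druggable"]


def write_annotated_table(annotated: Iterable[AnnotatedFusion], path: str) -> None:
    """Annotated-fusion TSV: the harmonized columns plus annotation columns."""
    import csv

    from .io import HARMONIZED_COLUMNS, _fusion_row

    rows = sorted(annotated, key=lambda a: a.fusion.sort_key())
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(HARMONIZED_COLUMNS + ANNOTATED_COLUMNS)
        for a in rows:
            kin = a.kinase
            w.writerow(_fusion_row(a.fusion) + [
                a.configuration, a.recurrence_count, a.recurrent,
                kin.kinase_gene if kin else "",
                kin.kinase_position if kin else "",
                kin.domain_status if kin else "",
                a.novel,
                kin.druggable if kin else False,
            ])
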