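"""Core domain types and elementary breakpoint/read-support arithmetic.

Coordinates are 1-based inclusive throughout (GTF convention). A fusion is
always an *ordered* gene pair: the 5' partner donates the transcript start,
the 3' partner the tail, so A->B and B->A are distinct events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

STAR_FUSION = "star_fusion"
ARRIBA = "arriba"
CALLERS = frozenset({STAR_FUSION, ARRIBA})

IN_FRAME = "in_frame"
OUT_OF_FRAME = "out_of_frame"
UNKNOWN = "unknown"
FRAMES = (IN_FRAME, OUT_OF_FRAME, UNKNOWN)

BIOTYPE_CLASSES = (
    "characterized",
    "uncharacterized",
    "immunoglobulin",
    "mitochondrial",
    "other",
)
#: biotype classes treated as blacklisted even without an explicit list entry
ARTIFACT_BIOTYPES = frozenset({"uncharacterized", "immunoglobulin", "mitochondrial"})


class FusionscapeError(Exception):
    """Base class for all package errors."""


class InvalidRecordError(FusionscapeError):
    """A record violates a field-level invariant (e.g. a negative count)."""


class ConfigError(FusionscapeError):
    """Invalid configuration or resource setup."""


class FormatError(FusionscapeError):
    """An input file does not match the expected dialect."""


@dataclass(frozen=True, order=True)
class Breakpoint:
    """One side of a fusion junction: chromosome, 1-based position, strand."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise InvalidRecordError("breakpoint chrom must be non-empty")
        if not isinstance(self.pos, int) or self.pos < 1:
            raise InvalidRecordError(f"breakpoint pos must be >= 1, got {self.pos!r}")
        if self.strand not in ("+", "-"):
            raise InvalidRecordError(f"breakpoint strand must be + or -, got {self.strand!r}")

    def __str__(self) -> str:  # chrom:pos:strand, the STAR-Fusion encoding
        return f"{self.chrom}:{self.pos}:{self.strand}"


def _check_count(value: int, name: str) -> int:
    if not isinstance(value, int) or isinstance(value, bool) or value < 0:
        raise InvalidRecordError(f"{name} must be a non-negative integer, got {value!r}")
    return value


@dataclass(frozen=True)
class FusionCall:
    """A single caller's record of one candidate fusion in one sample.

    Arriba reports split_reads1 / split_reads2 / discordant_mates separately;
    STAR-Fusion reports only a junction-read and a spanning-fragment count.
    ``junction_reads`` and ``spanning_reads`` are always populated (for the
    Arriba dialect: junction = split1 + split2, spanning = discordant mates)
    so downstream support rules are dialect-independent.
    """

    sample_id: str
    caller: str
    gene5: str
    gene3: str
    bp5: Breakpoint
    bp3: Breakpoint
    split_reads1: int = 0
    split_reads2: int = 0
    discordant_mates: int = 0
    junction_reads: int = 0
    spanning_reads: int = 0
    frame: str = UNKNOWN

    def __post_init__(self) -> None:
        if not self.gene5 or not self.gene3:
            raise InvalidRecordError("gene5 and gene3 must be non-empty")
        if self.caller not in CALLERS:
            raise InvalidRecordError(f"unknown caller {self.caller!r}")
        if self.frame not in FRAMES:
            raise InvalidRecordError(f"unknown frame label {self.frame!r}")
        for name in ("split_reads1", "split_reads2", "discordant_mates",
                     "junction_reads", "spanning_reads"):
            _check_count(getattr(self, name), name)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)


@dataclass(frozen=True)
class HarmonizedFusion:
    """Per-sample consensus record after cross-caller merging.

    Read-support fields hold the maximum over supporting callers (both
    callers count the same underlying reads, so summing would double-count).
    """

    sample_id: str
    gene5: str
    gene3: str
    bp5: Breakpoint
    bp3: Breakpoint
    callers: frozenset
    total_supporting_reads: int
    junction_reads: int
    spanning_reads: int
    frame: str = UNKNOWN

    def __post_init__(self) -> None:
        if len(self.callers) < 1:
            raise InvalidRecordError("a harmonized fusion needs at least one caller")
        if not self.callers <= CALLERS:
            raise InvalidRecordError(f"unknown callers {set(self.callers) - set(CALLERS)}")
        for name in ("total_supporting_reads", "junction_reads", "spanning_reads"):
            _check_count(getattr(self, name), name)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)

    def sort_key(self):
        return (self.sample_id, self.gene5, self.gene3, self.bp5, self.bp3)


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: symbol, strand, genomic extent, and kinase metadata.

    ``kinase_domains`` holds genomic (start, end) sub-intervals of annotated
    kinase domains; empty unless ``is_kinase``.
    """

    symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype_class: str = "characterized"
    is_kinase: bool = False
    kinase_domains: tuple = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvalidRecordError(f"{self.symbol}: start {self.start} > end {self.end}")
        if self.biotype_class not in BIOTYPE_CLASSES:
            raise InvalidRecordError(f"{self.symbol}: unknown biotype class {self.biotype_class!r}")
        if self.kinase_domains and not self.is_kinase:
            raise InvalidRecordError(f"{self.symbol}: kinase domains on a non-kinase gene")
        for ds, de in self.kinase_domains:
            if not (self.start <= ds <= de <= self.end):
                raise InvalidRecordError(
                    f"{self.symbol}: domain [{ds},{de}] outside gene [{self.start},{self.end}]")


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade.

    Defaults mirror the curation rules the pipeline implements: consensus of
    two callers, promiscuity at 25 distinct partners, proximity under 300 kb
    (gene-gap metric, strict '<'), cohort support of >=2 junction reads or
    >=1 spanning read in at least one sample, and a 500-kb colinear-AGR
    breakpoint distance for configuration classification.
    """

    promiscuity_threshold: int = 25
    proximity_threshold_bp: int = 300_000
    min_callers: int = 2
    min_junction_reads: int = 2
    min_spanning_reads: int = 1
    agr_threshold_bp: int = 500_000
    # boundary/metric switches; the published rules don't pin these down
    proximity_inclusive: bool = False          # True: remove at exactly the threshold too
    proximity_metric: str = "gene_gap"         # or "breakpoint"
    promiscuity_basis: str = "surviving"       # or "raw"

    def __post_init__(self) -> None:
        for name in ("promiscuity_threshold", "proximity_threshold_bp", "min_callers",
                     "min_junction_reads", "min_spanning_reads", "agr_threshold_bp"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.proximity_metric not in ("gene_gap", "breakpoint"):
            raise ConfigError(f"unknown proximity_metric {self.proximity_metric!r}")
        if self.promiscuity_basis not in ("surviving", "raw"):
            raise ConfigError(f"unknown promiscuity_basis {self.promiscuity_basis!r}")


REMOVAL_REASONS = (
    "same_gene", "blacklist", "paralog", "normal_panel",
    "proximity", "consensus", "promiscuity", "cohort_support",
)


@dataclass(frozen=True)
class RemovalRecord:
    """Audit-trail entry: a removed fusion, its first failing stage, and why."""

    fusion: HarmonizedFusion
    reason: str
    stage_index: int

    def __post_init__(self) -> None:
        if self.reason not in REMOVAL_REASONS:
            raise InvalidRecordError(f"unknown removal reason {self.reason!r}")


def total_supporting_reads(call: FusionCall) -> int:
    """Total read support for one caller's record.

    For the Arriba dialect this is split reads 1 + split reads 2 +
    discordant mates. STAR-Fusion does not split its junction count in two,
    so its junction + spanning totals play the same role.
    """
    if call.caller == ARRIBA:
        return call.split_reads1 + call.split_reads2 + call.discordant_mates
    return call.junction_reads + call.spanning_reads


def breakpoint_distance(bp5: Breakpoint, bp3: Breakpoint) -> Optional[int]:
    """|pos5 - pos3| on the same chromosome; None across chromosomes."""
    if bp5.chrom != bp3.chrom:
        return None
    return abs(bp5.pos - bp3.pos)


def gene_distance(a: GeneModel, b: GeneModel) -> Optional[int]:
    """Gap in bases between two gene intervals; 0 on overlap, None across chromosomes.

    For non-overlapping genes on one chromosome this is the number of bases
    strictly between them (downstream start - upstream end - 1), the
    conventional genomic gap.
    """
    if a.chrom != b.chrom:
        return None
    if a.start <= b.end and b.start <= a.end:
        return 0
    if a.end < b.start:
        return b.start - a.end - 1
    return a.start - b.end - 1
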