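"""Readers and writers for caller TSV dialects, GTF gene models, resource lists,
and the pipeline's harmonized/removal/summary tables.

Two caller dialects are supported:

* STAR-Fusion predictions: ``#FusionName`` ("GENE5--GENE3"),
  ``JunctionReadCount``, ``SpanningFragCount``, ``LeftBreakpoint`` /
  ``RightBreakpoint`` encoded ``chrom:pos:strand``.
* Arriba fusions: ``#gene1``/``gene2``, ``strand1(gene/fusion)`` /
  ``strand2(gene/fusion)``, ``breakpoint1``/``breakpoint2`` (``chrom:pos``),
  ``split_reads1``, ``split_reads2``, ``discordant_mates``, ``reading_frame``.

Malformed rows are skipped with a logged warning; the skip count is returned
alongside the records so callers can assert rows_in == records_out + skipped.
"""

from __future__ import annotations

import csv
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import gffutils

from .model import (
    ARRIBA,
    STAR_FUSION,
    IN_FRAME,
    OUT_OF_FRAME,
    UNKNOWN,
    Breakpoint,
    FormatError,
    FusionCall,
    GeneModel,
    HarmonizedFusion,
    InvalidRecordError,
    RemovalRecord,
)

log = logging.getLogger(__name__)

STAR_FUSION_COLUMNS = ("#FusionName", "JunctionReadCount", "SpanningFragCount",
                       "LeftBreakpoint", "RightBreakpoint")
ARRIBA_COLUMNS = ("#gene1", "gene2", "strand1(gene/fusion)", "strand2(gene/fusion)",
                  "breakpoint1", "breakpoint2", "split_reads1", "split_reads2",
                  "discordant_mates", "reading_frame")

_ARRIBA_FRAME = {"in-frame": IN_FRAME, "out-of-frame": OUT_OF_FRAME, ".": UNKNOWN,
                 "stop-codon": OUT_OF_FRAME}
_STAR_FRAME = {"INFRAME": IN_FRAME, "FRAMESHIFT": OUT_OF_FRAME, ".": UNKNOWN}


@dataclass
class ResourceBundle:
    """All curation resources the cascade and annotation stages consume."""

    gene_models: dict = field(default_factory=dict)          # symbol -> GeneModel
    blacklist: set = field(default_factory=set)
    paralog_pairs: set = field(default_factory=set)          # frozenset pairs
    normal_panel_pairs: set = field(default_factory=set)     # ordered tuples
    kinase_genes: set = field(default_factory=set)
    known_fusion_pairs: set = field(default_factory=set)     # ordered tuples
    druggable_kinases: set = field(default_factory=set)

    def validate(self) -> None:
        for sym, gm in self.gene_models.items():
            if gm.kinase_domains and sym not in self.kinase_genes:
                raise InvalidRecordError(
                    f"{sym} carries kinase-domain intervals but is not in kinase_genes")


def _normalize_chrom(chrom: str, style: Optional[str]) -> str:
    if style == "chr" and not chrom.startswith("chr"):
        return "chr" + chrom
    if style == "plain" and chrom.startswith("chr"):
        return chrom[3:]
    return chrom


def detect_caller_format(path: str) -> str:
    """Recognize a caller dialect from the TSV header signature."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if "#FusionName" in header or "FusionName" in header:
        return STAR_FUSION
    if "#gene1" in header or "gene1" in header:
        return ARRIBA
    raise FormatError(f"{path}: header matches neither caller dialect: {header[:5]}")


def _require_columns(header: list, required: Iterable[str], path: str) -> dict:
    index = {}
    for col in required:
        if col in header:
            index[col] = header.index(col)
        elif col.lstrip("#") in header:  # tolerate missing '#' on first column
            index[col] = header.index(col.lstrip("#"))
        else:
            raise FormatError(f"{path}: missing required column {col!r}")
    return index


def _parse_star_breakpoint(token: str, chrom_style: Optional[str]) -> Breakpoint:
    chrom, pos, strand = token.rsplit(":", 2)
    return Breakpoint(_normalize_chrom(chrom, chrom_style), int(pos), strand)


def read_star_fusion(path: str, sample_id: str,
                     chrom_style: Optional[str] = None) -> tuple[list, int]:
    """Read a STAR-Fusion predictions TSV -> (calls, n_skipped_rows)."""
    calls: list[FusionCall] = []
    skipped = 0
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, no header")
        idx = _require_columns(header, STAR_FUSION_COLUMNS, path)
        frame_idx = header.index("PROT_FUSION_TYPE") if "PROT_FUSION_TYPE" in header else None
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                name = row[idx["#FusionName"]]
                gene5, gene3 = name.split("--", 1)
                bp5 = _parse_star_breakpoint(row[idx["LeftBreakpoint"]], chrom_style)
                bp3 = _parse_star_breakpoint(row[idx["RightBreakpoint"]], chrom_style)
                junction = int(row[idx["JunctionReadCount"]])
                spanning = int(row[idx["SpanningFragCount"]])
                frame = UNKNOWN
                if frame_idx is not None and frame_idx < len(row):
                    frame = _STAR_FRAME.get(row[frame_idx], UNKNOWN)
                calls.append(FusionCall(
                    sample_id=sample_id, caller=STAR_FUSION,
                    gene5=gene5, gene3=gene3, bp5=bp5, bp3=bp3,
                    junction_reads=junction, spanning_reads=spanning, frame=frame))
            except (ValueError, IndexError, InvalidRecordError) as exc:
                skipped += 1
                log.warning("%s:%d: skipping malformed row (%s)", path, lineno, exc)
    return calls, skipped


def _parse_arriba_strand(token: str, gene_fallback: bool = True) -> str:
    # "gene/fusion" pair, e.g. "+/+" or "-/."; prefer the fusion strand
    gene_s, _, fusion_s = token.partition("/")
    strand = fusion_s if fusion_s and fusion_s != "." else gene_s
    return strand


def read_arriba(path: str, sample_id: str,
                chrom_style: Optional[str] = None) -> tuple[list, int]:
    """Read an Arriba fusions TSV -> (calls, n_skipped_rows)."""
    calls: list[FusionCall] = []
    skipped = 0
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, no header")
        idx = _require_columns(header, ARRIBA_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                chrom1, pos1 = row[idx["breakpoint1"]].rsplit(":", 1)
                chrom2, pos2 = row[idx["breakpoint2"]].rsplit(":", 1)
                s1 = _parse_arriba_strand(row[idx["strand1(gene/fusion)"]])
                s2 = _parse_arriba_strand(row[idx["strand2(gene/fusion)"]])
                split1 = int(row[idx["split_reads1"]])
                split2 = int(row[idx["split_reads2"]])
                discordant = int(row[idx["discordant_mates"]])
                frame = _ARRIBA_FRAME.get(row[idx["reading_frame"]], UNKNOWN)
                calls.append(FusionCall(
                    sample_id=sample_id, caller=ARRIBA,
                    gene5=row[idx["#gene1"]], gene3=row[idx["gene2"]],
                    bp5=Breakpoint(_normalize_chrom(chrom1, chrom_style), int(pos1), s1),
                    bp3=Breakpoint(_normalize_chrom(chrom2, chrom_style), int(pos2), s2),
                    split_reads1=split1, split_reads2=split2,
                    discordant_mates=discordant,
                    junction_reads=split1 + split2, spanning_reads=discordant,
                    frame=frame))
            except (ValueError, IndexError, InvalidRecordError) as exc:
                skipped += 1
                log.warning("%s:%d: skipping malformed row (%s)", path, lineno, exc)
    return calls, skipped


def read_caller_file(path: str, sample_id: str, fmt: str = "auto",
                     chrom_style: Optional[str] = None) -> tuple[list, int]:
    if fmt == "auto":
        fmt = detect_caller_format(path)
    if fmt == STAR_FUSION:
        return read_star_fusion(path, sample_id, chrom_style)
    if fmt == ARRIBA:
        return read_arriba(path, sample_id, chrom_style)
    raise FormatError(f"unknown caller format {fmt!r}")


def read_gtf(path: str, biotype_classes: Optional[dict] = None) -> dict:
    """Parse a GTF into symbol-indexed :class:`GeneModel` records.

    Gene symbols come from the ``gene_name`` attribute. Extent is taken from
    ``gene`` features, falling back to the min/max over that gene's
    transcripts when no gene feature exists. Duplicate symbols are resolved
    to the widest covering interval with a warning.

    ``biotype_classes`` optionally maps symbol -> biotype class for genes
    whose class is known out-of-band (the GTF ``gene_biotype`` attribute is
    used when present: IG_*-prefixed biotypes map to ``immunoglobulin``,
    ``Mt_*`` to ``mitochondrial``).
    """
    try:
        db = gffutils.create_db(path, dbfn=":memory:", force=True, keep_order=True,
                                merge_strategy="create_unique",
                                disable_infer_genes=True, disable_infer_transcripts=True)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse GTF ({exc})") from exc

    spans: dict[str, list] = {}

    def _note(symbol, chrom, start, end, strand, biotype):
        rec = spans.get(symbol)
        if rec is None:
            spans[symbol] = [chrom, start, end, strand, biotype, 1]
        else:
            if rec[0] != chrom:
                log.warning("gene %s on multiple chromosomes; keeping %s", symbol, rec[0])
                return
            rec[1] = min(rec[1], start)
            rec[2] = max(rec[2], end)
            rec[5] += 1

    seen_with_gene_feature = set()
    for feat in db.features_of_type("gene"):
        symbol = feat.attributes.get("gene_name", feat.attributes.get("gene_id", [None]))[0]
        if symbol is None:
            continue
        biotype = (feat.attributes.get("gene_biotype") or [None])[0]
        _note(symbol, feat.seqid, feat.start, feat.end, feat.strand, biotype)
        seen_with_gene_feature.add(symbol)
    for feat in db.features_of_type("transcript"):
        symbol = feat.attributes.get("gene_name", feat.attributes.get("gene_id", [None]))[0]
        if symbol is None or symbol in seen_with_gene_feature:
            continue
        biotype = (feat.attributes.get("gene_biotype") or [None])[0]
        _note(symbol, feat.seqid, feat.start, feat.end, feat.strand, biotype)

    if not spans:
        raise FormatError(f"{path}: no gene records parseable")

    models: dict[str, GeneModel] = {}
    for symbol, (chrom, start, end, strand, biotype, n) in sorted(spans.items()):
        if n > 1:
            log.warning("gene %s has %d records; merged to widest interval [%d,%d]",
                        symbol, n, start, end)
        cls = "characterized"
        if biotype_classes and symbol in biotype_classes:
            cls = biotype_classes[symbol]
        elif biotype:
            if biotype.startswith("IG_"):
                cls = "immunoglobulin"
            elif biotype.startswith("Mt_") or biotype.startswith("MT_"):
                cls = "mitochondrial"
        models[symbol] = GeneModel(symbol=symbol, chrom=chrom,
                                   strand=strand if strand in ("+", "-") else "+",
                                   start=start, end=end, biotype_class=cls)
    return models


def _strip_lines(path: str):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_gene_list(path: str) -> set:
    """One gene symbol per line; '#' comments ignored."""
    return {line for _, line in _strip_lines(path)}


def read_pair_list(path: str, ordered: bool) -> set:
    """One gene pair per line, tab- or '--'-separated.

    Unordered pairs are stored as frozensets; ordered pairs as (g5, g3)
    tuples. Lines without a separator are skipped with a warning.
    """
    pairs = set()
    for lineno, line in _strip_lines(path):
        if "\t" in line:
            parts = line.split("\t")
        elif "--" in line:
            parts = line.split("--")
        else:
            log.warning("%s:%d: pair line without separator, skipped: %r", path, lineno, line)
            continue
        a, b = parts[0].strip(), parts[1].strip()
        if ordered:
            pairs.add((a, b))
        else:
            pairs.add(frozenset((a, b)))
    return pairs


def read_kinase_domains(path: str) -> dict:
    """TSV of gene<TAB>start<TAB>end genomic kinase-domain intervals per gene."""
    domains: dict[str, list] = {}
    for lineno, line in _strip_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            log.warning("%s:%d: expected gene/start/end, skipped", path, lineno)
            continue
        domains.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    return {g: sorted(iv) for g, iv in domains.items()}


# default file names of a resource directory (the simulator writes this layout)
RESOURCE_FILES = {
    "gtf": "genes.gtf",
    "blacklist": "blacklist.txt",
    "paralogs": "paralogs.txt",
    "normal_panel": "normal_panel.txt",
    "kinase_genes": "kinase_genes.txt",
    "kinase_domains": "kinase_domains.tsv",
    "known_fusions": "known_fusions.txt",
    "druggable": "druggable_kinases.txt",
}


def load_resources(directory: str) -> ResourceBundle:
    """Load a resource directory (missing optional lists default to empty)."""
    def p(key):
        return os.path.join(directory, RESOURCE_FILES[key])

    gtf = p("gtf")
    if not os.path.exists(gtf):
        raise FormatError(f"missing gene annotation: {gtf}")
    models = read_gtf(gtf)
    kinases = read_gene_list(p("kinase_genes")) if os.path.exists(p("kinase_genes")) else set()
    domains = read_kinase_domains(p("kinase_domains")) if os.path.exists(p("kinase_domains")) else {}
    out = {}
    for sym, gm in models.items():
        if sym in kinases:
            out[sym] = GeneModel(symbol=gm.symbol, chrom=gm.chrom, strand=gm.strand,
                                 start=gm.start, end=gm.end, biotype_class=gm.biotype_class,
                                 is_kinase=True,
                                 kinase_domains=tuple(domains.get(sym, ())))
        else:
            out[sym] = gm
    bundle = ResourceBundle(
        gene_models=out,
        blacklist=read_gene_list(p("blacklist")) if os.path.exists(p("blacklist")) else set(),
        paralog_pairs=read_pair_list(p("paralogs"), ordered=False)
        if os.path.exists(p("paralogs")) else set(),
        normal_panel_pairs=read_pair_list(p("normal_panel"), ordered=True)
        if os.path.exists(p("normal_panel")) else set(),
        kinase_genes=kinases,
        known_fusion_pairs=read_pair_list(p("known_fusions"), ordered=True)
        if os.path.exists(p("known_fusions")) else set(),
        druggable_kinases=read_gene_list(p("druggable")) if os.path.exists(p("druggable")) else set(),
    )
    bundle.validate()
    return bundle


HARMONIZED_COLUMNS = ["sample_id", "gene5", "gene3", "chrom5", "pos5", "strand5",
                      "chrom3", "pos3", "strand3", "callers", "junction_reads",
                      "spanning_reads", "total_supporting_reads", "frame"]


def _fusion_row(f: HarmonizedFusion) -> list:
    return [f.sample_id, f.gene5, f.gene3,
            f.bp5.chrom, f.bp5.pos, f.bp5.strand,
            f.bp3.chrom, f.bp3.pos, f.bp3.strand,
            ",".join(sorted(f.callers)), f.junction_reads, f.spanning_reads,
            f.total_supporting_reads, f.frame]


def write_fusion_table(fusions: Iterable[HarmonizedFusion], path: str,
                       removals: Optional[Iterable[RemovalRecord]] = None,
                       removals_path: Optional[str] = None) -> None:
    """Write harmonized fusions (and optionally a removals audit table).

    Rows sort deterministically by (sample_id, gene5, gene3, breakpoints);
    the table round-trips losslessly through :func:`read_fusion_table`.
    """
    rows = sorted(fusions, key=lambda f: f.sort_key())
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(HARMONIZED_COLUMNS)
        for f in rows:
            w.writerow(_fusion_row(f))
    if removals is not None:
        if removals_path is None:
            raise ValueError("removals given without removals_path")
        rrows = sorted(removals, key=lambda r: (r.stage_index, r.fusion.sort_key()))
        with open(removals_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(HARMONIZED_COLUMNS + ["reason", "stage_index"])
            for r in rrows:
                w.writerow(_fusion_row(r.fusion) + [r.reason, r.stage_index])


def read_fusion_table(path: str) -> list:
    """Read a harmonized-fusion TSV back into records."""
    fusions = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(HARMONIZED_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            fusions.append(HarmonizedFusion(
                sample_id=row["sample_id"], gene5=row["gene5"], gene3=row["gene3"],
                bp5=Breakpoint(row["chrom5"], int(row["pos5"]), row["strand5"]),
                bp3=Breakpoint(row["chrom3"], int(row["pos3"]), row["strand3"]),
                callers=frozenset(row["callers"].split(",")),
                junction_reads=int(row["junction_reads"]),
                spanning_reads=int(row["spanning_reads"]),
                total_supporting_reads=int(row["total_supporting_reads"]),
                frame=row["frame"]))
    return fusions


def write_summary(summary, path: str) -> None:
    """Serialize a cohort summary to JSON (dataclasses become plain dicts)."""
    try:
        payload = asdict(summary)
    except TypeError:
        payload = summary
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
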