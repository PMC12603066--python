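"""Seeded generator of caller-format fusion cohorts with planted ground truth.

The generator emulates the statistical structure the curation cascade
assumes: a cohort of samples whose STAR-Fusion- and Arriba-dialect call
tables contain (a) planted *true* fusions — supported by both callers, with
junction/spanning read counts that satisfy the cohort support rule, laid
out on a toy genome so that each fusion realizes a prescribed breakpoint
configuration — and (b) planted *artifacts*, one flavour per filter stage
(self-fusions, blacklisted partners, paralog pairs, normal-panel pairs,
proximal read-throughs, promiscuous hubs, single-caller calls, low-support
calls).

Artifacts are constructed, not sampled: each one passes every cascade stage
before its own and fails exactly its own, so filter attribution is testable
without probabilistic slack. All randomness flows from the single config
seed through named substreams, and emitted files are byte-identical across
runs with the same seed.
"""

from __future__ import annotations

import csv
import math
import os
import random
from dataclasses import dataclass, field
from typing import Optional

from .io import ARRIBA_COLUMNS, STAR_FUSION_COLUMNS, ResourceBundle
from .model import (
    ARRIBA,
    STAR_FUSION,
    IN_FRAME,
    OUT_OF_FRAME,
    UNKNOWN,
    Breakpoint,
    ConfigError,
    FusionCall,
    FusionscapeError,
    GeneModel,
)

ARTIFACT_CLASSES = ("same_gene", "blacklisted", "paralog", "normal_panel",
                    "proximal_readthrough", "promiscuous_hub", "single_caller",
                    "low_support")

#: which cascade stage removes each artifact class
ARTIFACT_REASON = {
    "same_gene": "same_gene",
    "blacklisted": "blacklist",
    "paralog": "paralog",
    "normal_panel": "normal_panel",
    "proximal_readthrough": "proximity",
    "promiscuous_hub": "promiscuity",
    "single_caller": "consensus",
    "low_support": "cohort_support",
}

GENE_LENGTH = 20_000
ALLOC_MARGIN = 2_000_000      # spacing between unrelated loci; far beyond every distance rule


def _default_artifact_counts() -> dict:
    return {c: 1 for c in ARTIFACT_CLASSES}


def _default_mix() -> dict:
    # roughly the landscape observed in breast tumours: about half the
    # events cis-near (colinear AGR), the rest split across the other labels
    return {"colinear_agr": 0.45, "interchromosomal": 0.30,
            "noncolinear": 0.15, "intrachromosomal": 0.10}


@dataclass
class SimulationConfig:
    """Study conditions of a simulated cohort."""

    seed: int
    n_samples: int = 200
    n_genes: int = 250                 # total genes incl. filler loci
    chrom_count: int = 5
    chrom_length: int = 200_000_000
    n_true_fusions: int = 30
    recurrent_fraction: float = 0.3    # true fusions carried by >= 2 samples
    kinase_fraction: float = 0.2       # true fusions whose 3' partner is a kinase
    known_fraction: float = 0.3        # true fusions present in the known-fusion list
    configuration_mix: dict = field(default_factory=_default_mix)
    artifact_counts: dict = field(default_factory=_default_artifact_counts)
    hub_partner_count: int = 25
    caller_dropout: float = 0.0        # per-caller dropout prob. for true fusions
    junction_geom_p: float = 0.4       # junction ~ 2 + Geom(p) in the anchor sample
    spanning_geom_p: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        if abs(sum(self.configuration_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("configuration_mix proportions must sum to 1")
        unknown = set(self.artifact_counts) - set(ARTIFACT_CLASSES)
        if unknown:
            raise ConfigError(f"unknown artifact classes: {sorted(unknown)}")
        if any(v < 0 for v in self.artifact_counts.values()):
            raise ConfigError("artifact counts must be non-negative")
        if not (0.0 <= self.caller_dropout <= 1.0):
            raise ConfigError("caller_dropout must be in [0, 1]")
        if self.chrom_count < 2:
            raise ConfigError("need >= 2 chromosomes to host interchromosomal events")
        if set(self.configuration_mix) - {"interchromosomal", "noncolinear",
                                          "colinear_agr", "intrachromosomal"}:
            raise ConfigError("configuration_mix has unknown labels")


@dataclass(frozen=True)
class PlannedFusion:
    """One planted event: the pair, its breakpoints, class, and expected fate."""

    gene5: str
    gene3: str
    bp5: Breakpoint
    bp3: Breakpoint
    klass: str                     # "true" or an artifact class
    frame: str
    expected_fate: str             # "kept" or "removed:<reason>"
    configuration: Optional[str] = None
    callers: tuple = (STAR_FUSION, ARRIBA)
    low_support: bool = False


@dataclass
class AnnotationPlan:
    """Toy genome + resource lists + the fusion layout they host."""

    resources: ResourceBundle
    planned: list
    gene_order: list


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    gene5: str
    gene3: str
    klass: str
    expected_fate: str


class _Allocator:
    """Places non-overlapping gene loci on the toy chromosomes."""

    def __init__(self, config: SimulationConfig):
        self.chroms = [f"chr{i + 1}" for i in range(config.chrom_count)]
        self.cursor = {c: 1_000_000 for c in self.chroms}
        self.limit = config.chrom_length
        self._round_robin = 0
        self._n = 0

    def _next_symbol(self) -> str:
        self._n += 1
        return f"GENE{self._n:04d}"

    def place_gene(self, chrom: Optional[str] = None, strand: str = "+") -> GeneModel:
        if chrom is None:
            chrom = self.chroms[self._round_robin % len(self.chroms)]
            self._round_robin += 1
        start = self.cursor[chrom]
        end = start + GENE_LENGTH - 1
        if end > self.limit:
            raise ConfigError(f"chromosome {chrom} exhausted; raise chrom_length "
                              f"or chrom_count")
        self.cursor[chrom] = end + 1 + ALLOC_MARGIN
        return GeneModel(symbol=self._next_symbol(), chrom=chrom, strand=strand,
                         start=start, end=end)

    def place_pair(self, gap: int, strand5: str = "+",
                   strand3: str = "+") -> tuple[GeneModel, GeneModel]:
        """Two genes on one chromosome separated by exactly ``gap`` bases."""
        chrom = self.chroms[self._round_robin % len(self.chroms)]
        self._round_robin += 1
        start5 = self.cursor[chrom]
        end5 = start5 + GENE_LENGTH - 1
        start3 = end5 + 1 + gap
        end3 = start3 + GENE_LENGTH - 1
        if end3 > self.limit:
            raise ConfigError(f"chromosome {chrom} exhausted placing a pair")
        self.cursor[chrom] = end3 + 1 + ALLOC_MARGIN
        g5 = GeneModel(symbol=self._next_symbol(), chrom=chrom, strand=strand5,
                       start=start5, end=end5)
        g3 = GeneModel(symbol=self._next_symbol(), chrom=chrom, strand=strand3,
                       start=start3, end=end3)
        return g5, g3


def _mid_breakpoint(gene: GeneModel, offset: int = 10_000) -> Breakpoint:
    return Breakpoint(gene.chrom, gene.start + offset, gene.strand)


def _apportion(total: int, mix: dict) -> dict:
    """Largest-remainder apportionment of ``total`` over the mix proportions."""
    labels = sorted(mix)
    raw = {lbl: total * mix[lbl] for lbl in labels}
    counts = {lbl: math.floor(raw[lbl]) for lbl in labels}
    short = total - sum(counts.values())
    for lbl in sorted(labels, key=lambda l: (-(raw[l] - counts[l]), l))[:short]:
        counts[lbl] += 1
    return counts


def _true_pair_geometry(alloc: _Allocator, configuration: str):
    """Place a gene pair realizing one breakpoint configuration while passing
    the proximity filter (gene gap >= 300 kb whenever on one chromosome)."""
    if configuration == "interchromosomal":
        g5 = alloc.place_gene()
        g3 = alloc.place_gene()
        while g3.chrom == g5.chrom:
            g3 = alloc.place_gene()
        return g5, g3
    if configuration == "colinear_agr":
        # gap 330 kb passes the 300-kb rule; breakpoint distance 350 kb <= 500 kb
        return alloc.place_pair(gap=330_000, strand5="+", strand3="+")
    if configuration == "intrachromosomal":
        return alloc.place_pair(gap=2_000_000, strand5="+", strand3="+")
    if configuration == "noncolinear":
        return alloc.place_pair(gap=2_000_000, strand5="+", strand3="-")
    raise ConfigError(f"unknown configuration {configuration!r}")


def generate_annotation(config: SimulationConfig,
                        outdir: Optional[str] = None) -> AnnotationPlan:
    """Build the toy genome, resource lists, and fusion layout.

    Writes ``genes.gtf`` plus the resource list files when ``outdir`` is
    given; identical seeds give byte-identical files.
    """
    rng = random.Random(f"{config.seed}:annotation")
    alloc = _Allocator(config)
    genes: list[GeneModel] = []
    planned: list[PlannedFusion] = []
    blacklist: set = set()
    paralogs: set = set()
    normal_panel: set = set()
    kinase_genes: set = set()
    kinase_domains: dict = {}
    known_pairs: set = set()
    druggable: set = set()

    # --- planted true fusions ---------------------------------------------
    counts = _apportion(config.n_true_fusions, config.configuration_mix)
    true_specs = []
    for configuration in sorted(counts):
        true_specs.extend([configuration] * counts[configuration])
    n_kinase = round(config.kinase_fraction * config.n_true_fusions)
    n_known = round(config.known_fraction * config.n_true_fusions)
    for i, configuration in enumerate(true_specs):
        g5, g3 = _true_pair_geometry(alloc, configuration)
        if i < n_kinase:
            dom_start = g3.start + 12_000
            doms = ((dom_start, dom_start + 4_000),)
            g3 = GeneModel(symbol=g3.symbol, chrom=g3.chrom, strand=g3.strand,
                           start=g3.start, end=g3.end, is_kinase=True,
                           kinase_domains=doms)
            kinase_genes.add(g3.symbol)
            kinase_domains[g3.symbol] = list(doms)
            if i % 2 == 0:
                druggable.add(g3.symbol)
        genes.extend([g5, g3])
        if i < n_known:
            known_pairs.add((g5.symbol, g3.symbol))
        frame = IN_FRAME if i % 3 != 2 else OUT_OF_FRAME
        planned.append(PlannedFusion(
            gene5=g5.symbol, gene3=g3.symbol,
            bp5=_mid_breakpoint(g5), bp3=_mid_breakpoint(g3),
            klass="true", frame=frame, expected_fate="kept",
            configuration=configuration))

    # --- artifacts, one flavour per filter stage --------------------------
    ac = {**_default_artifact_counts(), **config.artifact_counts}

    for _ in range(ac.get("same_gene", 0)):
        g = alloc.place_gene()
        genes.append(g)
        planned.append(PlannedFusion(
            gene5=g.symbol, gene3=g.symbol,
            bp5=Breakpoint(g.chrom, g.start + 5_000, g.strand),
            bp3=Breakpoint(g.chrom, g.start + 15_000, g.strand),
            klass="same_gene", frame=UNKNOWN,
            expected_fate="removed:same_gene"))

    def _cross_chrom_pair():
        g5 = alloc.place_gene()
        g3 = alloc.place_gene()
        while g3.chrom == g5.chrom:
            g3 = alloc.place_gene()
        genes.extend([g5, g3])
        return g5, g3

    for _ in range(ac.get("blacklisted", 0)):
        g5, g3 = _cross_chrom_pair()
        blacklist.add(g5.symbol)
        planned.append(PlannedFusion(
            gene5=g5.symbol, gene3=g3.symbol,
            bp5=_mid_breakpoint(g5), bp3=_mid_breakpoint(g3),
            klass="blacklisted", frame=UNKNOWN,
            expected_fate="removed:blacklist"))

    for _ in range(ac.get("paralog", 0)):
        g5, g3 = _cross_chrom_pair()
        paralogs.add(frozenset((g5.symbol, g3.symbol)))
        planned.append(PlannedFusion(
            gene5=g5.symbol, gene3=g3.symbol,
            bp5=_mid_breakpoint(g5), bp3=_mid_breakpoint(g3),
            klass="paralog", frame=UNKNOWN,
            expected_fate="removed:paralog"))

    for _ in range(ac.get("normal_panel", 0)):
        g5, g3 = _cross_chrom_pair()
        normal_panel.add((g5.symbol, g3.symbol))
        planned.append(PlannedFusion(
            gene5=g5.symbol, gene3=g3.symbol,
            bp5=_mid_breakpoint(g5), bp3=_mid_breakpoint(g3),
            klass="normal_panel", frame=UNKNOWN,
            expected_fate="removed:normal_panel"))

    for _ in range(ac.get("proximal_readthrough", 0)):
        g5, g3 = alloc.place_pair(gap=100_000, strand5="+", strand3="+")
        genes.extend([g5, g3])
        planned.append(PlannedFusion(
            gene5=g5.symbol, gene3=g3.symbol,
            bp5=_mid_breakpoint(g5), bp3=_mid_breakpoint(g3),
            klass="proximal_readthrough", frame=UNKNOWN,
            expected_fate="removed:proximity"))

    for _ in range(ac.get("promiscuous_hub", 0)):
        hub = alloc.place_gene()
        genes.append(hub)
        for _k in range(config.hub_partner_count):
            p = alloc.place_gene()
            while p.chrom == hub.chrom:
                p = alloc.place_gene()
            genes.append(p)
            planned.append(PlannedFusion(
                gene5=hub.symbol, gene3=p.symbol,
                bp5=_mid_breakpoint(hub), bp3=_mid_breakpoint(p),
                klass="promiscuous_hub", frame=UNKNOWN,
                expected_fate="removed:promiscuity"))

    for _ in range(ac.get("single_caller", 0)):
        g5, g3 = _cross_chrom_pair()
        planned.append(PlannedFusion(
            gene5=g5.symbol, gene3=g3.symbol,
            bp5=_mid_breakpoint(g5), bp3=_mid_breakpoint(g3),
            klass="single_caller", frame=UNKNOWN,
            expected_fate="removed:consensus",
            callers=(STAR_FUSION,)))

    for _ in range(ac.get("low_support", 0)):
        g5, g3 = _cross_chrom_pair()
        planned.append(PlannedFusion(
            gene5=g5.symbol, gene3=g3.symbol,
            bp5=_mid_breakpoint(g5), bp3=_mid_breakpoint(g3),
            klass="low_support", frame=UNKNOWN,
            expected_fate="removed:cohort_support",
            low_support=True))

    # --- filler loci, fusion-free -----------------------------------------
    while len(genes) < config.n_genes:
        genes.append(alloc.place_gene(strand=rng.choice("+-")))

    models = {g.symbol: g for g in genes}
    resources = ResourceBundle(
        gene_models=models, blacklist=blacklist, paralog_pairs=paralogs,
        normal_panel_pairs=normal_panel, kinase_genes=kinase_genes,
        known_fusion_pairs=known_pairs, druggable_kinases=druggable)
    resources.validate()
    plan = AnnotationPlan(resources=resources, planned=planned,
                          gene_order=[g.symbol for g in genes])
    if outdir is not None:
        write_annotation(plan, outdir, kinase_domains)
    return plan


def write_annotation(plan: AnnotationPlan, outdir: str,
                     kinase_domains: Optional[dict] = None) -> None:
    os.makedirs(outdir, exist_ok=True)
    res = plan.resources
    if kinase_domains is None:
        kinase_domains = {s: list(res.gene_models[s].kinase_domains)
                          for s in sorted(res.kinase_genes)}
    with open(os.path.join(outdir, "genes.gtf"), "w") as fh:
        for sym in plan.gene_order:
            g = res.gene_models[sym]
            attrs = (f'gene_id "{g.symbol}"; gene_name "{g.symbol}"; '
                     f'gene_biotype "protein_coding";')
            fh.write(f"{g.chrom}\tfusionscape_sim\tgene\t{g.start}\t{g.end}\t."
                     f"\t{g.strand}\t.\t{attrs}\n")

    def _write_lines(name: str, lines) -> None:
        with open(os.path.join(outdir, name), "w") as fh:
            for line in lines:
                fh.write(line + "\n")

    _write_lines("blacklist.txt", sorted(res.blacklist))
    _write_lines("paralogs.txt", sorted("\t".join(sorted(p)) for p in res.paralog_pairs))
    _write_lines("normal_panel.txt", sorted(f"{a}\t{b}" for a, b in res.normal_panel_pairs))
    _write_lines("kinase_genes.txt", sorted(res.kinase_genes))
    _write_lines("kinase_domains.tsv",
                 [f"{g}\t{s}\t{e}" for g in sorted(kinase_domains)
                  for s, e in kinase_domains[g]])
    _write_lines("known_fusions.txt", sorted(f"{a}\t{b}" for a, b in res.known_fusion_pairs))
    _write_lines("druggable_kinases.txt", sorted(res.druggable_kinases))


def _geom(rng: random.Random, p: float) -> int:
    """Number of failures before the first success; support {0, 1, 2, ...}."""
    n = 0
    while rng.random() >= p:
        n += 1
    return n


def _assign_carriers(config: SimulationConfig, plan: AnnotationPlan,
                     rng: random.Random) -> dict:
    """Deterministically assign planted events to carrying samples."""
    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    carriers: dict[int, list] = {}
    n_recurrent = round(config.recurrent_fraction * config.n_true_fusions)
    true_seen = 0
    hub_cursor = 0
    for idx, pf in enumerate(plan.planned):
        if pf.klass == "true":
            k = 2 + (true_seen % 4) if true_seen < n_recurrent else 1
            true_seen += 1
            carriers[idx] = sorted(rng.sample(sample_ids, min(k, len(sample_ids))))
        elif pf.klass == "promiscuous_hub":
            carriers[idx] = [sample_ids[hub_cursor % len(sample_ids)]]
            hub_cursor += 1
        else:
            carriers[idx] = [rng.choice(sample_ids)]
    return carriers


def generate_cohort(config: SimulationConfig, plan: Optional[AnnotationPlan] = None,
                    outdir: Optional[str] = None):
    """Emit per-sample caller calls plus the truth table.

    Returns ``(per_sample_calls, truth)`` where ``per_sample_calls`` maps
    sample_id -> list of :class:`FusionCall` (both dialects mixed) and
    ``truth`` is a list of :class:`TruthRecord`. When ``outdir`` is given,
    writes ``<sample>.star-fusion.tsv`` / ``<sample>.arriba.tsv`` for every
    sample plus ``truth.tsv``.
    """
    if plan is None:
        plan = generate_annotation(config)
    rng_assign = random.Random(f"{config.seed}:cohort")
    rng_reads = random.Random(f"{config.seed}:reads")
    rng_drop = random.Random(f"{config.seed}:dropout")

    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    carriers = _assign_carriers(config, plan, rng_assign)

    per_sample: dict[str, list] = {sid: [] for sid in sample_ids}
    truth: list[TruthRecord] = []

    for idx, pf in enumerate(plan.planned):
        for anchor, sid in enumerate(carriers[idx]):
            if pf.low_support:
                junction, spanning = 1, 0
            elif pf.klass == "true":
                # the first carrying sample anchors cohort support (>= 2
                # junction reads); later carriers may dip to 1
                base = 2 if anchor == 0 else 1
                junction = base + _geom(rng_reads, config.junction_geom_p)
                spanning = _geom(rng_reads, config.spanning_geom_p)
            else:
                junction = 3 + _geom(rng_reads, config.junction_geom_p)
                spanning = 1 + _geom(rng_reads, config.spanning_geom_p)

            emit = list(pf.callers)
            if pf.klass == "true" and config.caller_dropout > 0:
                emit = [c for c in emit if rng_drop.random() >= config.caller_dropout]
                if not emit:  # at least one caller always reports a true event
                    emit = [rng_drop.choice(list(pf.callers))]
            expected = pf.expected_fate
            if pf.klass == "true" and len(emit) < 2:
                expected = "removed:consensus"

            if STAR_FUSION in emit:
                per_sample[sid].append(FusionCall(
                    sample_id=sid, caller=STAR_FUSION,
                    gene5=pf.gene5, gene3=pf.gene3, bp5=pf.bp5, bp3=pf.bp3,
                    junction_reads=junction, spanning_reads=spanning,
                    frame=UNKNOWN))
            if ARRIBA in emit:
                split1 = (junction + 1) // 2
                per_sample[sid].append(FusionCall(
                    sample_id=sid, caller=ARRIBA,
                    gene5=pf.gene5, gene3=pf.gene3, bp5=pf.bp5, bp3=pf.bp3,
                    split_reads1=split1, split_reads2=junction - split1,
                    discordant_mates=spanning,
                    junction_reads=junction, spanning_reads=spanning,
                    frame=pf.frame))
            truth.append(TruthRecord(sample_id=sid, gene5=pf.gene5,
                                     gene3=pf.gene3, klass=pf.klass,
                                     expected_fate=expected))

    truth.sort(key=lambda t: (t.sample_id, t.gene5, t.gene3))
    for sid in per_sample:
        per_sample[sid].sort(key=lambda c: (c.gene5, c.gene3, c.caller))

    if outdir is not None:
        write_cohort(per_sample, truth, outdir)
    return per_sample, truth


_FRAME_TO_ARRIBA = {IN_FRAME: "in-frame", OUT_OF_FRAME: "out-of-frame", UNKNOWN: "."}


def write_cohort(per_sample: dict, truth: list, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    for sid in sorted(per_sample):
        calls = per_sample[sid]
        with open(os.path.join(outdir, f"{sid}.star-fusion.tsv"), "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(STAR_FUSION_COLUMNS)
            for c in calls:
                if c.caller != STAR_FUSION:
                    continue
                w.writerow([f"{c.gene5}--{c.gene3}", c.junction_reads,
                            c.spanning_reads, str(c.bp5), str(c.bp3)])
        with open(os.path.join(outdir, f"{sid}.arriba.tsv"), "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(ARRIBA_COLUMNS)
            for c in calls:
                if c.caller != ARRIBA:
                    continue
                w.writerow([c.gene5, c.gene3,
                            f"{c.bp5.strand}/{c.bp5.strand}",
                            f"{c.bp3.strand}/{c.bp3.strand}",
                            f"{c.bp5.chrom}:{c.bp5.pos}",
                            f"{c.bp3.chrom}:{c.bp3.pos}",
                            c.split_reads1, c.split_reads2, c.discordant_mates,
                            _FRAME_TO_ARRIBA[c.frame]])
    with open(os.path.join(outdir, "truth.tsv"), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "gene5", "gene3", "class", "expected_fate"])
        for t in truth:
            w.writerow([t.sample_id, t.gene5, t.gene3, t.klass, t.expected_fate])


def read_truth(path: str) -> list:
    truth = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            truth.append(TruthRecord(sample_id=row["sample_id"], gene5=row["gene5"],
                                     gene3=row["gene3"], klass=row["class"],
                                     expected_fate=row["expected_fate"]))
    return truth


@dataclass
class EvaluationSummary:
    per_class: dict
    sensitivity: float
    artifact_removal_rate: dict


def evaluate(kept: list, removals: list, truth: list) -> EvaluationSummary:
    """Compare pipeline fates with the planted truth.

    ``kept`` holds surviving harmonized records, ``removals`` the cascade's
    :class:`~fusionscape.model.RemovalRecord` audit entries. Raises if the
    two sides' (sample, pair) key sets differ, listing the orphans.
    """
    truth_by_key = {(t.sample_id, t.gene5, t.gene3): t for t in truth}
    fates: dict[tuple, str] = {}
    for f in kept:
        fates[(f.sample_id, f.gene5, f.gene3)] = "kept"
    for r in removals:
        f = r.fusion
        fates[(f.sample_id, f.gene5, f.gene3)] = f"removed:{r.reason}"

    orphan_pipeline = sorted(set(fates) - set(truth_by_key))
    orphan_truth = sorted(set(truth_by_key) - set(fates))
    if orphan_pipeline or orphan_truth:
        raise FusionscapeError(
            f"truth/pipeline key mismatch; pipeline-only={orphan_pipeline[:5]}, "
            f"truth-only={orphan_truth[:5]}")

    classes = sorted({t.klass for t in truth})
    per_class = {c: {"planted": 0, "kept": 0, "removed_correct_reason": 0,
                     "removed_other_reason": 0, "fate_mismatches": 0}
                 for c in classes}
    for key, t in truth_by_key.items():
        fate = fates[key]
        row = per_class[t.klass]
        row["planted"] += 1
        if fate == "kept":
            row["kept"] += 1
        elif fate == t.expected_fate:
            row["removed_correct_reason"] += 1
        else:
            row["removed_other_reason"] += 1
        if fate != t.expected_fate:
            row["fate_mismatches"] += 1

    true_row = per_class.get("true", {"planted": 0, "kept": 0})
    sensitivity = (true_row["kept"] / true_row["planted"]) if true_row["planted"] else 0.0
    removal_rate = {}
    for c in classes:
        if c == "true":
            continue
        row = per_class[c]
        removal_rate[c] = (row["removed_correct_reason"] / row["planted"]
                           if row["planted"] else 0.0)
    return EvaluationSummary(per_class=per_class, sensitivity=sensitivity,
                             artifact_removal_rate=removal_rate)
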