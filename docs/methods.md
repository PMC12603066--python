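# Methods

## Data model and conventions

All genomic coordinates are 1-based inclusive (GTF convention); readers
convert on input. A fusion is an ordered gene pair — the 5′ partner donates
the transcript head, the 3′ partner the tail — so A→B and B→A are distinct
events throughout (recurrence, novelty, the normal panel). Paralog pairs
are the one deliberately unordered resource, since cross-mapping between
paralogs is symmetric.

Per-caller read support is totalled additively as split reads 1 + split
reads 2 + discordant mates. The STAR-Fusion dialect reports a single
junction-read count and a spanning-fragment count rather than the Arriba
triplet; its `junction + spanning` total plays the same role, so the
formula degrades gracefully across dialects.

## Harmonization

Caller records are merged per sample at gene-pair level. Breakpoint-level
intersection was considered and rejected as the default: the two callers
frequently report junctions a few bases apart for the same event, and
pair-level matching with orientation preserved is the robust common
denominator (a breakpoint-tolerance hook can be layered on the match key if
needed). Aggregation uses **max**, not sum, across callers — both callers
count the same underlying sequencing reads, so summing would double-count.
The representative breakpoint pair comes from the contributing record with
the highest total support, with ties broken toward Arriba (whose breakpoints
are exon-boundary-aware) and then toward the lexicographically smallest
breakpoints so merging is order-independent. Frame reconciliation prefers
`in_frame` over `out_of_frame` over `unknown`: a caller that managed to
phase the junction carries more information than one that did not.

## Filter cascade

Stages run in a fixed order: same-gene → blacklist → paralog → normal panel
→ proximity → consensus → promiscuity → cohort support. The first six are
per-record predicates and commute (property-tested); their order only
affects which reason a doubly-bad record is attributed to, and the first
failing stage wins. Promiscuity and cohort support are cohort-level and run
last, on the post-consensus surviving set, so hub-gene partner counts are
not inflated by records already known to be noise; `promiscuity_basis="raw"`
switches to counting on the unfiltered input.

Numerical choices where the rule's inequality direction is not recoverable
from its usual phrasing:

* "within 300 kb" is strict — a gene gap of exactly 300,000 bp survives;
  `proximity_inclusive=True` flips the boundary.
* The proximity metric is the **inter-gene gap** (downstream start −
  upstream end − 1, zero on overlap), not breakpoint distance — the filter
  targets read-throughs between neighbouring gene bodies. The breakpoint
  metric is available via `proximity_metric="breakpoint"`.
* The colinear-AGR threshold for *classification* is 500 kb **inclusive**
  on **breakpoint** distance. Proximity filtering and configuration
  classification deliberately use different distances: one asks whether two
  gene bodies are adjacent, the other how far apart the junction ends are.
* Promiscuity counts distinct partner genes in either orientation across
  the whole cohort; ≥ 25 partners removes every record touching the gene.
* Cohort support: a pair survives iff at least one carrying sample has
  ≥ 2 junction reads **or** at least one has ≥ 1 spanning read; junction
  and spanning here are the harmonized (max-over-caller) values.

An unannotated partner (absent from the GTF) passes the blacklist and
proximity stages with a logged warning rather than being dropped: symbol
mismatches between caller output and annotation are a data-hygiene issue,
not evidence of artifact.

## Configuration taxonomy

The decision tree gives strand precedence over distance: different
chromosomes → interchromosomal; same chromosome but different breakpoint
strands → noncolinear (at any distance); same chromosome and strand within
500 kb → colinear AGR; otherwise intrachromosomal. Strands are the
caller-reported breakpoint (fusion-transcript) strands, not annotated gene
strands. Whether a close-by opposite-strand pair should instead count as a
"noncolinear AGR" is genuinely ambiguous in the standard taxonomy; the
strand-first tree is used consistently and the AGR distance is
configurable.

## Kinase-domain retention

The retained region of the kinase partner is derived from its breakpoint,
the gene's strand, and its position in the fusion: a 5′ partner retains the
transcript-upstream side of the breakpoint, a 3′ partner the
transcript-downstream side, where transcript orientation follows gene
strand (on −-strand genes, upstream means higher genomic coordinates). The
junction base itself counts as retained on either side. Status is
`retained` when every annotated kinase-domain interval lies inside the
retained region, `lost` when no domain base does, `partial` otherwise, and
`unknown` when the gene has no domain intervals or the breakpoint falls
outside the gene model (with a warning). Domain intervals are accepted in
genomic space; mapping protein-space domain coordinates to the genome is
the resource curator's job. For kinase–kinase fusions the 5′ partner is
assessed. The implementation is interval arithmetic; the test suite checks
it against an independent oracle that literally enumerates retained bases
and intersects them with domain bases on randomized toy genes.

## Summary statistics

Percentages are computed from exact integer fractions with half-up decimal
rounding, 2 decimals by default and a 1-decimal variant for prevalence-style
figures. The unique/recurrent denominator is the number of distinct ordered
pairs; per-sample event counts are reported separately to keep the two
totals unambiguous. The recurrent share is taken as 100 minus the rounded
unique share so the two always total 100.00 exactly. Recurrence counts
distinct samples (a pair twice in one sample counts once); multi-sample
patients are not collapsed. The landscape display tier lists pairs carried
by more than four samples.

## Synthetic cohorts

The simulator emulates the *decision structure* of real caller output, not
its sequence content: a toy genome of 20-kb genes spaced 2 Mb apart (so no
unintended pair falls under any distance rule), with specific placements
hosting each planted geometry — colinear-AGR true fusions use a 330-kb gene
gap (passing the 300-kb filter) with breakpoints 350 kb apart (inside the
500-kb AGR window); proximal read-through artifacts use a 100-kb gap.

Defaults describe a mid-sized tumour cohort: 200 samples, 30 planted true
fusions (30 % recurrent, carried by 2–5 samples), a configuration mix of
45 % colinear AGR / 30 % interchromosomal / 15 % noncolinear / 10 %
intrachromosomal assigned deterministically by largest remainder, 20 % of
true fusions with a kinase 3′ partner (half druggable), 30 % present in the
known-fusion list, and one artifact per class with a 25-partner hub.
Junction reads for true fusions are 2 + Geometric(0.4) in the first
carrying sample — anchoring the cohort-support rule — and 1 + Geometric
elsewhere; spanning reads are Geometric(0.5); low-support artifacts are
pinned at junction 1 / spanning 0. Artifacts are **constructed, not
sampled**: each passes every cascade stage before its own and fails exactly
its own, which makes reason attribution exactly testable. (A self-fusion
necessarily also has gene distance zero; attribution is still unambiguous
because the same-gene stage precedes proximity.) Each submodule draws from
its own RNG stream named from the master seed, so adding an artifact class
does not perturb unrelated draws, and emitted files are byte-identical
under a fixed seed.

What passing on synthetic cohorts does **not** show: robustness to symbol
aliasing between caller output and annotation, breakpoint jitter between
callers (the simulator emits identical breakpoints to both), realistic
read-count overdispersion, or expression-dependent artifact rates. Those
belong to validation on real cohorts.

## Verification problem sizes

The test suite and the acceptance script run the default 200-sample
simulation, worked-ratio cohorts of 6,156 constructed records, prevalence
cohorts of 1,110 + 148 samples, and 1,000 randomized domain-retention
cases; the full suite completes in a few seconds on one CPU.

## Known limitations

Gene symbols are matched verbatim (no alias resolution); frame is
caller-provided, never recomputed; sub-exonic transcript structure and
fusion protein sequences are out of scope; the known-fusion and druggable
lists are user-supplied stand-ins for public databases, so novelty and
druggability are only as good as those lists.
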