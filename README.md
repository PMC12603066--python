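# fusionscape

Curation and landscape analysis of gene-fusion calls from bulk RNA-seq.

Fusion callers such as STAR-Fusion and Arriba emit generous candidate lists
in which genuine somatic fusions sit among transcriptional read-throughs,
cross-mapping artifacts between paralogs, immunoglobulin rearrangements and
alignment noise. `fusionscape` turns per-sample caller output into a curated
cohort-level fusion landscape:

1. **Harmonize** — merge both callers' records per sample at the ordered
   gene-pair level (A→B ≠ B→A), aggregating read support with *max*
   semantics and reconciling reading-frame labels.
2. **Filter** — an audited eight-stage cascade: self-fusions; blacklisted
   partners (explicit list plus uncharacterized / immunoglobulin /
   mitochondrial genes); paralog pairs; normal-panel pairs; proximal
   read-throughs (gene gap < 300 kb); two-caller consensus; promiscuous
   hubs (≥ 25 distinct partners cohort-wide); and a cohort support rule
   (a pair survives iff some sample has ≥ 2 junction reads or some sample
   has ≥ 1 spanning read). Every removed record carries the first failing
   stage as its reason.
3. **Annotate** — breakpoint-configuration taxonomy (interchromosomal /
   noncolinear / colinear AGR within 500 kb / intrachromosomal), recurrence
   across samples, per-sample fusion-burden bins {0, 1, 2–5, 6–10, >10},
   and kinase-fusion annotation: which partner is the kinase, whether its
   annotated kinase domain is retained / partial / lost given the
   breakpoint and gene strand, novelty against a known-fusion database
   list, and druggability against a druggable-kinase list.
4. **Summarize** — unique vs recurrent fractions over distinct pairs,
   configuration distribution, prevalence (overall and stratified by
   tissue class / subtype metadata), burden bins, kinase statistics.

A seeded simulator (`fusionscape.simulate`) generates caller-format cohorts
on a toy genome with planted true fusions and one planted artifact flavour
per filter stage, each constructed to fail exactly its own rule, so the
whole pipeline is testable offline with known ground truth.

Total read support per caller record follows the additive convention
`total = split reads1 + split reads2 + discordant mates` (for the
STAR-Fusion dialect, which does not split its junction count, the
equivalent `junction + spanning`).

## Worked example

```sh
fusionscape simulate --seed 7 --outdir run/sim --n-samples 40
fusionscape run-all --calls-dir run/sim/calls \
    --resources-dir run/sim/resources --outdir run/out
```

prints

```
wrote 83 harmonized records to run/out/harmonized.tsv
kept 51 / 83 records (32 removed)
wrote 51 annotated records to run/out/annotated.tsv
cohort of 40 samples: 30 distinct pairs (70.0% unique, 30.0% recurrent), prevalence 70.0%
```

83 caller-consensus records contain the 30 planted true fusion pairs plus
32 planted artifacts; the cascade removes exactly the artifacts (one per
per-record stage, 25 hub records, one single-caller and one low-support
event — see `run/out/removals.tsv` for per-record reasons) and keeps every
true fusion. The same stages are available individually (`harmonize`,
`filter`, `annotate`, `summarize`) with thresholds exposed as flags
(`--promiscuity-threshold`, `--proximity-bp`, `--min-callers`,
`--min-junction`, `--min-spanning`, `--agr-bp`).

As a library:

```python
from fusionscape import merge_cohort, run_cascade, annotate_cohort, summarize
from fusionscape.simulate import SimulationConfig, generate_annotation, generate_cohort

cfg = SimulationConfig(seed=1)
plan = generate_annotation(cfg)
per_sample, truth = generate_cohort(cfg, plan)
cohort = merge_cohort(per_sample.values())
result = run_cascade(cohort, plan.resources)
summary = summarize(annotate_cohort(result.kept, plan.resources),
                    sample_ids=sorted(per_sample))
print(summary.pct_unique, summary.configuration_counts)
```

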