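"""The filter cascade: individual rules, ordering, audit conservation."""

import random

import pytest

from fusionscape.filters import (
    STAGE_ORDER,
    filter_blacklist,
    filter_cohort_support,
    filter_consensus,
    filter_normal_panel,
    filter_paralog,
    filter_promiscuity,
    filter_proximity,
    filter_same_gene,
    run_cascade,
)
from fusionscape.io import ResourceBundle
from fusionscape.model import FilterConfig

from .conftest import make_fusion, make_gene


class TestSameGene:
    def test_self_fusion_removed(self):
        kept, removed = filter_same_gene([make_fusion(gene5="A", gene3="A")])
        assert kept == [] and len(removed) == 1

    def test_distinct_pair_kept(self):
        kept, removed = filter_same_gene([make_fusion(gene5="A", gene3="B")])
        assert len(kept) == 1 and removed == []

    def test_empty(self):
        assert filter_same_gene([]) == ([], [])


class TestBlacklist:
    def test_listed_gene_removed(self, basic_resources):
        kept, removed = filter_blacklist([make_fusion(gene5="BAD", gene3="B")],
                                         basic_resources)
        assert kept == [] and len(removed) == 1

    def test_immunoglobulin_class_removed_without_list_entry(self, basic_resources):
        kept, removed = filter_blacklist([make_fusion(gene5="A", gene3="IGX")],
                                         basic_resources)
        assert kept == [] and len(removed) == 1

    def test_characterized_unlisted_kept(self, basic_resources):
        kept, _ = filter_blacklist([make_fusion(gene5="A", gene3="B")],
                                   basic_resources)
        assert len(kept) == 1

    def test_unannotated_partner_kept(self, basic_resources):
        kept, _ = filter_blacklist([make_fusion(gene5="A", gene3="MYSTERY")],
                                   basic_resources)
        assert len(kept) == 1


class TestParalogAndPanel:
    def test_paralog_pair_removed_either_orientation(self, basic_resources):
        for g5, g3 in (("A", "C"), ("C", "A")):
            kept, removed = filter_paralog([make_fusion(gene5=g5, gene3=g3)],
                                           basic_resources)
            assert kept == [] and len(removed) == 1

    def test_non_paralog_kept(self, basic_resources):
        kept, _ = filter_paralog([make_fusion(gene5="A", gene3="D")], basic_resources)
        assert len(kept) == 1

    def test_normal_panel_ordered_semantics(self, basic_resources):
        listed = make_fusion(gene5="C", gene3="D")
        reverse = make_fusion(gene5="D", gene3="C")
        kept, removed = filter_normal_panel([listed, reverse], basic_resources)
        assert [f.pair for f in removed] == [("C", "D")]
        assert [f.pair for f in kept] == [("D", "C")]

    def test_empty_lists_are_identity(self, empty_resources):
        fusions = [make_fusion(gene5="A", gene3="B")]
        assert filter_paralog(fusions, empty_resources)[0] == fusions
        assert filter_normal_panel(fusions, empty_resources)[0] == fusions


class TestProximity:
    def _resources(self, gap):
        a = make_gene("A", start=1_000_000, end=1_020_000)
        b = make_gene("B", start=a.end + 1 + gap, end=a.end + gap + 20_000)
        return ResourceBundle(gene_models={"A": a, "B": b})

    def test_gap_below_threshold_removed(self):
        kept, removed = filter_proximity([make_fusion(gene5="A", gene3="B")],
                                         self._resources(299_999), FilterConfig())
        assert kept == [] and len(removed) == 1

    def test_gap_above_threshold_kept(self):
        kept, _ = filter_proximity([make_fusion(gene5="A", gene3="B")],
                                   self._resources(300_001), FilterConfig())
        assert len(kept) == 1

    def test_exact_threshold_kept_by_default_strict_rule(self):
        kept, _ = filter_proximity([make_fusion(gene5="A", gene3="B")],
                                   self._resources(300_000), FilterConfig())
        assert len(kept) == 1

    def test_exact_threshold_removed_when_inclusive(self):
        config = FilterConfig(proximity_inclusive=True)
        kept, removed = filter_proximity([make_fusion(gene5="A", gene3="B")],
                                         self._resources(300_000), config)
        assert kept == [] and len(removed) == 1

    def test_different_chromosomes_kept(self, basic_resources):
        kept, _ = filter_proximity([make_fusion(gene5="A", gene3="B")],
                                   basic_resources, FilterConfig())
        assert len(kept) == 1

    def test_breakpoint_metric(self, basic_resources):
        from .conftest import make_breakpoint
        f = make_fusion(gene5="A", gene3="D",
                        bp5=make_breakpoint("chr1", 1000),
                        bp3=make_breakpoint("chr1", 200_000))
        config = FilterConfig(proximity_metric="breakpoint")
        kept, removed = filter_proximity([f], basic_resources, config)
        assert kept == [] and len(removed) == 1


class TestConsensus:
    def test_single_caller_removed(self):
        kept, removed = filter_consensus([make_fusion(callers=("star_fusion",))],
                                         FilterConfig())
        assert kept == [] and len(removed) == 1

    def test_two_callers_kept(self):
        kept, _ = filter_consensus([make_fusion()], FilterConfig())
        assert len(kept) == 1

    def test_min_callers_one_is_identity(self):
        fusions = [make_fusion(callers=("arriba",))]
        kept, removed = filter_consensus(fusions, FilterConfig(min_callers=1))
        assert kept == fusions and removed == []


def _hub_cohort(n_partners):
    return [make_fusion(sample=f"S{i}", gene5="HUB", gene3=f"P{i}")
            for i in range(n_partners)]


class TestPromiscuity:
    def test_hub_at_threshold_removed(self):
        kept, removed = filter_promiscuity(_hub_cohort(25), FilterConfig())
        assert kept == [] and len(removed) == 25

    def test_hub_below_threshold_kept(self):
        kept, removed = filter_promiscuity(_hub_cohort(24), FilterConfig())
        assert len(kept) == 24 and removed == []

    def test_single_fusion_kept(self):
        kept, _ = filter_promiscuity([make_fusion()], FilterConfig())
        assert len(kept) == 1

    def test_counts_both_orientations(self):
        cohort = [make_fusion(sample=f"S{i}", gene5="HUB", gene3=f"P{i}")
                  for i in range(13)]
        cohort += [make_fusion(sample=f"T{i}", gene5=f"Q{i}", gene3="HUB")
                   for i in range(12)]
        kept, removed = filter_promiscuity(cohort, FilterConfig())
        assert kept == [] and len(removed) == 25


class TestCohortSupport:
    def test_junction_rule(self):
        cohort = [make_fusion(sample=s, junction=j, spanning=0)
                  for s, j in zip("XYZ", (1, 1, 2))]
        kept, removed = filter_cohort_support(cohort, FilterConfig())
        assert len(kept) == 3 and removed == []

    def test_spanning_rule(self):
        cohort = [make_fusion(sample="X", junction=1, spanning=0),
                  make_fusion(sample="Y", junction=1, spanning=1)]
        kept, removed = filter_cohort_support(cohort, FilterConfig())
        assert len(kept) == 2 and removed == []

    def test_unsupported_pair_fully_removed(self):
        cohort = [make_fusion(sample="X", junction=1, spanning=0),
                  make_fusion(sample="Y", junction=1, spanning=0)]
        kept, removed = filter_cohort_support(cohort, FilterConfig())
        assert kept == [] and len(removed) == 2

    def test_pairs_judged_independently(self):
        good = make_fusion(sample="X", gene5="A", gene3="B", junction=5)
        bad = make_fusion(sample="X", gene5="A", gene3="C", junction=1, spanning=0)
        kept, removed = filter_cohort_support([good, bad], FilterConfig())
        assert [f.pair for f in kept] == [("A", "B")]
        assert [f.pair for f in removed] == [("A", "C")]


def _random_cohort(rng, resources):
    genes = list(resources.gene_models) + ["MYSTERY"]
    cohort = []
    for _ in range(rng.randint(0, 25)):
        cohort.append(make_fusion(
            sample=f"S{rng.randint(1, 6)}",
            gene5=rng.choice(genes), gene3=rng.choice(genes),
            callers=rng.choice([("arriba",), ("star_fusion",),
                                ("arriba", "star_fusion")]),
            junction=rng.randint(0, 5), spanning=rng.randint(0, 2)))
    return cohort


class TestCascade:
    def test_first_failure_attribution(self, basic_resources):
        # BAD->BAD fails both same_gene and blacklist; same_gene comes first
        result = run_cascade([make_fusion(gene5="BAD", gene3="BAD")],
                             basic_resources)
        (removal,) = result.removals
        assert removal.reason == "same_gene"

    def test_all_passing_cohort(self, basic_resources):
        cohort = [make_fusion(gene5="A", gene3="B", junction=5)]
        result = run_cascade(cohort, basic_resources)
        assert result.kept == cohort and result.removals == []

    def test_conservation_at_every_stage(self, basic_resources):
        rng = random.Random(11)
        for _ in range(20):
            cohort = _random_cohort(rng, basic_resources)
            result = run_cascade(cohort, basic_resources)
            assert len(result.kept) + len(result.removals) == len(cohort)
            assert sum(result.per_stage_counts.values()) == len(result.removals)

    def test_per_call_stage_commutativity(self, basic_resources):
        """Any order of the per-record stages keeps the same record set."""
        per_call = STAGE_ORDER[:6]
        config = FilterConfig()
        stage_fns = {
            "same_gene": lambda fs: filter_same_gene(fs)[0],
            "blacklist": lambda fs: filter_blacklist(fs, basic_resources)[0],
            "paralog": lambda fs: filter_paralog(fs, basic_resources)[0],
            "normal_panel": lambda fs: filter_normal_panel(fs, basic_resources)[0],
            "proximity": lambda fs: filter_proximity(fs, basic_resources, config)[0],
            "consensus": lambda fs: filter_consensus(fs, config)[0],
        }
        rng = random.Random(5)
        orders = [per_call, tuple(reversed(per_call))] + [
            tuple(rng.sample(per_call, 6)) for _ in range(3)]
        for _ in range(100):
            cohort = _random_cohort(rng, basic_resources)
            kept_sets = []
            for order in orders:
                fs = cohort
                for name in order:
                    fs = stage_fns[name](fs)
                kept_sets.append({id(f) for f in fs})
            assert all(s == kept_sets[0] for s in kept_sets[1:])

    def test_cascade_subset_of_no_promiscuity_run(self, basic_resources):
        rng = random.Random(23)
        for _ in range(20):
            cohort = _random_cohort(rng, basic_resources)
            full = run_cascade(cohort, basic_resources)
            relaxed = run_cascade(cohort, basic_resources,
                                  skip_stages=["promiscuity"])
            full_ids = {id(f) for f in full.kept}
            relaxed_ids = {id(f) for f in relaxed.kept}
            assert full_ids <= relaxed_ids

    def test_unknown_skip_stage_rejected(self, basic_resources):
        with pytest.raises(ValueError):
            run_cascade([], basic_resources, skip_stages=["nonsense"])

    def test_stage_order_fixed(self):
        assert STAGE_ORDER == ("same_gene", "blacklist", "paralog", "normal_panel",
                               "proximity", "consensus", "promiscuity",
                               "cohort_support")
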