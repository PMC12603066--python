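import pytest
from hypothesis import settings

from fusionscape.io import ResourceBundle

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")
from fusionscape.model import Breakpoint, FusionCall, GeneModel, HarmonizedFusion


def make_breakpoint(chrom="chr1", pos=1000, strand="+"):
    return Breakpoint(chrom, pos, strand)


def make_call(sample="S1", caller="arriba", gene5="A", gene3="B",
              bp5=None, bp3=None, split1=0, split2=0, discordant=0,
              junction=None, spanning=None, frame="unknown"):
    if caller == "arriba":
        junction = split1 + split2 if junction is None else junction
        spanning = discordant if spanning is None else spanning
    else:
        junction = junction or 0
        spanning = spanning or 0
    return FusionCall(
        sample_id=sample, caller=caller, gene5=gene5, gene3=gene3,
        bp5=bp5 or make_breakpoint("chr1", 100), bp3=bp3 or make_breakpoint("chr2", 200),
        split_reads1=split1, split_reads2=split2, discordant_mates=discordant,
        junction_reads=junction, spanning_reads=spanning, frame=frame)


def make_fusion(sample="S1", gene5="A", gene3="B", bp5=None, bp3=None,
                callers=("star_fusion", "arriba"), junction=5, spanning=2,
                frame="unknown", total=None):
    return HarmonizedFusion(
        sample_id=sample, gene5=gene5, gene3=gene3,
        bp5=bp5 or make_breakpoint("chr1", 100), bp3=bp3 or make_breakpoint("chr2", 200),
        callers=frozenset(callers),
        total_supporting_reads=total if total is not None else junction + spanning,
        junction_reads=junction, spanning_reads=spanning, frame=frame)


def make_gene(symbol, chrom="chr1", strand="+", start=100, end=200, **kw):
    return GeneModel(symbol=symbol, chrom=chrom, strand=strand,
                     start=start, end=end, **kw)


@pytest.fixture
def empty_resources():
    return ResourceBundle()


@pytest.fixture
def basic_resources():
    """A handful of genes far apart on two chromosomes, with curation lists."""
    genes = [
        make_gene("A", "chr1", start=1_000_000, end=1_020_000),
        make_gene("B", "chr2", start=1_000_000, end=1_020_000),
        make_gene("C", "chr1", start=5_000_000, end=5_020_000),
        make_gene("D", "chr2", start=9_000_000, end=9_020_000),
        make_gene("BAD", "chr1", start=20_000_000, end=20_020_000),
        make_gene("IGX", "chr2", start=20_000_000, end=20_020_000,
                  biotype_class="immunoglobulin"),
        make_gene("NEAR1", "chr1", start=40_000_000, end=40_020_000),
        make_gene("NEAR2", "chr1", start=40_120_000, end=40_140_000),
        make_gene("KIN", "chr2", start=30_000_000, end=30_010_000,
                  is_kinase=True, kinase_domains=((30_004_000, 30_006_000),)),
    ]
    return ResourceBundle(
        gene_models={g.symbol: g for g in genes},
        blacklist={"BAD"},
        paralog_pairs={frozenset(("A", "C"))},
        normal_panel_pairs={("C", "D")},
        kinase_genes={"KIN"},
        known_fusion_pairs={("A", "B")},
        druggable_kinases={"KIN"},
    )
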