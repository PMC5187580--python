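import numpy as np
import pandas as pd
import pytest

from pirna_soma import synthetic_data as sim
from pirna_soma.locus_analysis import (
    assign_cluster,
    cluster_counts,
    cluster_coverage,
    cluster_fold_ratio,
    genic_region_counts,
    rpkm,
    sense_fraction,
    unique_genome_alignments,
    _cluster_trees,
)
from pirna_soma.mini_align import Alignment
from pirna_soma.preprocess import ReadRecord, preprocess_library
from pirna_soma.refio import (
    CDS,
    FIVE_UTR,
    THREE_UTR,
    Interval,
    IntervalSet,
    SequenceDB,
    build_gene_regions,
)


def _aln(start, end, strand="+", chrom="chr1", read="r"):
    return Alignment(read, chrom, start, end, strand, 0)


class TestUniqueAlignments:
    def test_repeated_sequence_is_suppressed(self):
        rng = np.random.default_rng(3)
        core = "".join(rng.choice(list("ACGT"), 25))
        pad = lambda n: "".join(rng.choice(list("ACGT"), n))
        genome = SequenceDB("g", {"chr1": pad(50) + core + pad(50) + core + pad(50)},
                            "genome")
        reads = [ReadRecord("dup", core)]
        assert unique_genome_alignments(reads, genome, size_window=None) == []

    def test_size_window_applied(self):
        rng = np.random.default_rng(5)
        genome = SequenceDB("g", {"chr1": "".join(rng.choice(list("ACGT"), 300))},
                            "genome")
        seq22 = genome.records["chr1"][10:32]
        seq25 = genome.records["chr1"][100:125]
        reads = [ReadRecord("a", seq22), ReadRecord("b", seq25)]
        alns = unique_genome_alignments(reads, genome, size_window=(23, 29))
        assert [a.read_id for a in alns] == ["b"]


class TestClusters:
    def _clusters(self):
        return IntervalSet("c", [Interval("chr1", 0, 1000, "+", "flam"),
                                 Interval("chr1", 1500, 2500, "-", "c2")])

    def test_alignment_inside_cluster_counts(self):
        counts = cluster_counts([_aln(100, 125)], self._clusters())
        assert counts["flam"] == 1 and counts["c2"] == 0

    def test_one_bp_overlap_suffices(self):
        counts = cluster_counts([_aln(999, 1024)], self._clusters())
        assert counts["flam"] == 1

    def test_gap_spanning_alignment_goes_to_larger_overlap(self):
        clusters = IntervalSet("c", [Interval("chr1", 0, 1000, "+", "a"),
                                     Interval("chr1", 1010, 2000, "+", "b")])
        trees = _cluster_trees(clusters)
        assert assign_cluster(_aln(995, 1020), trees) == "b"  # 5 vs 10 bases

    def test_overlapping_clusters_rejected(self):
        bad = IntervalSet("c", [Interval("chr1", 0, 1000, "+", "a"),
                                Interval("chr1", 500, 1500, "+", "b")])
        with pytest.raises(ValueError, match="overlapping"):
            cluster_counts([], bad)

    def test_fold_ratio_identity_and_depletion(self):
        ctrl = pd.Series({"flam": 100, "c2": 50})
        same = cluster_fold_ratio(ctrl, ctrl, 10_000, 10_000)
        assert np.allclose(same["ratio"], 1.0)
        mut = pd.Series({"flam": 10, "c2": 50})
        dep = cluster_fold_ratio(mut, ctrl, 10_000, 10_000, pseudocount=1e-9)
        assert dep.loc["flam", "ratio"] == pytest.approx(0.1)
        assert list(dep.index)[0] == "flam"  # ranked most-depleted first

    def test_zero_normalizer_is_error(self):
        with pytest.raises(ValueError):
            cluster_fold_ratio(pd.Series(dtype=int), pd.Series(dtype=int), 0, 10)


class TestClusterCoverage:
    def test_depth_and_scaling(self):
        cluster = Interval("chr1", 100, 300, "+", "flam")
        plus, minus = cluster_coverage([_aln(110, 135)], cluster, 1_000_000)
        assert (plus[10:35] == 1.0).all() and plus.sum() == 25.0
        assert minus.sum() == 0.0
        plus2, _ = cluster_coverage([_aln(110, 135)], cluster, 2_000_000)
        assert np.allclose(plus, 2 * plus2)

    def test_no_reads_gives_zero_vector(self):
        cluster = Interval("chr1", 0, 50, "+", "flam")
        plus, minus = cluster_coverage([], cluster, 1_000_000)
        assert not plus.any() and not minus.any()

    def test_strand_split(self):
        cluster = Interval("chr1", 0, 100, "+", "flam")
        plus, minus = cluster_coverage([_aln(5, 30, "-")], cluster, 1_000_000)
        assert plus.sum() == 0 and (minus[5:30] == 1.0).all()


class TestGenicCounts:
    @pytest.fixture()
    def regions(self):
        models = IntervalSet("m", [
            Interval("chr1", 0, 300, "+", "gplus", "exon"),
            Interval("chr1", 50, 250, "+", "gplus", "CDS"),
            Interval("chr1", 1000, 1300, "-", "gminus", "exon"),
            Interval("chr1", 1050, 1250, "-", "gminus", "CDS"),
        ])
        return build_gene_regions(models)

    def _cell(self, df, gene, region):
        row = df[(df["gene"] == gene) & (df["region"] == region)].iloc[0]
        return int(row["sense"]), int(row["antisense"])

    def test_sense_and_antisense_in_3utr(self, regions):
        df = genic_region_counts([_aln(260, 285, "+"), _aln(255, 280, "-")],
                                 regions)
        assert self._cell(df, "gplus", THREE_UTR) == (1, 1)

    def test_majority_rule_spanning_cds_boundary(self, regions):
        # 25-base alignment with 15 bases in the 3'UTR, 10 in the CDS
        df = genic_region_counts([_aln(240, 265, "+")], regions)
        assert self._cell(df, "gplus", THREE_UTR) == (1, 0)
        assert self._cell(df, "gplus", CDS) == (0, 0)

    def test_tie_breaks_to_more_3prime_region(self, regions):
        # 10 bases in CDS [240,250), 10 in 3'UTR [250,260)
        df = genic_region_counts([_aln(240, 260, "+")], regions)
        assert self._cell(df, "gplus", THREE_UTR) == (1, 0)
        # minus-strand gene: 3'UTR is the leftmost block [1000,1050)
        df2 = genic_region_counts([_aln(1040, 1060, "-")], regions)
        assert self._cell(df2, "gminus", THREE_UTR) == (1, 0)

    def test_strand_relation_respects_gene_strand(self, regions):
        # '-' alignment on a '-' gene is sense
        df = genic_region_counts([_aln(1010, 1035, "-")], regions)
        assert self._cell(df, "gminus", THREE_UTR) == (1, 0)
        df2 = genic_region_counts([_aln(1010, 1035, "+")], regions)
        assert self._cell(df2, "gminus", THREE_UTR) == (0, 1)


class TestSenseFraction:
    def _table(self, sense, antisense):
        return pd.DataFrame([
            {"gene": "g", "region": THREE_UTR, "sense": sense,
             "antisense": antisense},
        ])

    def test_mixed(self):
        _, agg = sense_fraction(self._table(87, 13))
        assert agg == pytest.approx(0.87)

    def test_all_sense(self):
        _, agg = sense_fraction(self._table(10, 0))
        assert agg == 1.0

    def test_zero_denominator_is_missing_not_zero(self):
        per_gene, agg = sense_fraction(self._table(0, 0))
        assert agg is None
        assert per_gene.isna().all()


class TestRpkm:
    def test_formula(self):
        out = rpkm(pd.Series({"g": 10}), pd.Series({"g": 2000}), 1_000_000)
        assert out["g"] == pytest.approx(5.0)

    def test_zero_count(self):
        assert rpkm(pd.Series({"g": 0}), pd.Series({"g": 500}), 10_000)["g"] == 0.0

    def test_scaling_identity(self):
        a = rpkm(pd.Series({"g": 10}), pd.Series({"g": 2000}), 1_000_000)
        b = rpkm(pd.Series({"g": 20}), pd.Series({"g": 2000}), 2_000_000)
        assert a["g"] == b["g"]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rpkm(pd.Series({"g": 1}), pd.Series({"g": 0}), 100)
        with pytest.raises(ValueError):
            rpkm(pd.Series({"g": 1}), pd.Series({"g": 10}), 0)


def test_cluster_noncluster_partition(catalog, small_control):
    """Cluster hits plus non-cluster hits account for every unique 23-29 nt
    genome alignment."""
    cfg, reads, _ = small_control
    clean, _ = preprocess_library(reads, cfg.adapter, catalog.rrna)
    alns = unique_genome_alignments(clean, catalog.genome)
    counts = cluster_counts(alns, catalog.clusters)
    trees = _cluster_trees(catalog.clusters)
    outside = sum(1 for a in alns if assign_cluster(a, trees) is None)
    assert counts.sum() + outside == len(alns)


def test_simulated_cluster_reads_land_in_planted_cluster(catalog):
    cfg = sim.SimConfig(seed=31, n_reads=4000, error_rate=0.0)
    reads, manifest = sim.simulate_library(cfg, "control", catalog)
    clean, _ = preprocess_library(reads, cfg.adapter, catalog.rrna)
    alns = unique_genome_alignments(clean, catalog.genome)
    truth = manifest.reads.set_index("read_id")
    trees = _cluster_trees(catalog.clusters)
    checked = 0
    for a in alns:
        if truth.loc[a.read_id, "class"] == "cluster_piRNA":
            assert assign_cluster(a, trees) == truth.loc[a.read_id, "source"]
            checked += 1
    assert checked > 100
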