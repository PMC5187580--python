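
import numpy as np
import pandas as pd
import pytest

from oracle import align_all_bruteforce, rc
from pirna_soma.preprocess import ReadRecord
from pirna_soma.refio import SequenceDB
from pirna_soma.te_quant import (
    count_te_families,
    fold_change_threshold,
    log2_fold_change,
    norm_loci_unique_count,
    normalize_smrna,
    percent_change,
    select_heatmap_tes,
    te_coverage_profile,
)


class TestFamilyCounting:
    def test_read_hitting_two_instances_of_one_family_counts_once(self):
        rng = np.random.default_rng(2)
        core = "".join(rng.choice(list("ACGT"), 30))
        db = SequenceDB(
            "te",
            {"gypsy_i1": "AAAA" + core, "gypsy_i2": core + "TTTT"},
            "TE_consensus",
        )
        fam = {"gypsy_i1": "gypsy", "gypsy_i2": "gypsy"}
        counts = count_te_families([ReadRecord("r", core[:25])], db, fam)
        assert counts["gypsy"] == 1

    def test_read_hitting_two_families_counts_in_each(self):
        rng = np.random.default_rng(8)
        shared = "".join(rng.choice(list("ACGT"), 25))
        db = SequenceDB(
            "te",
            {"gypsy": shared + "".join(rng.choice(list("ACGT"), 50)),
             "copia": "".join(rng.choice(list("ACGT"), 50)) + shared},
            "TE_consensus",
        )
        counts = count_te_families([ReadRecord("r", shared)], db)
        assert counts["gypsy"] == 1 and counts["copia"] == 1

    def test_non_aligning_read_increments_nothing(self):
        db = SequenceDB("te", {"a": "ACGTACGTACGTACGTACGTACGTAC"}, "TE_consensus")
        counts = count_te_families([ReadRecord("r", "G" * 25)], db)
        assert counts.sum() == 0

    def test_empty_catalog_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            count_te_families([], SequenceDB("te", {}, "TE_consensus"))

    def test_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(14)
        bases = list("ACGT")
        records = {
            f"inst{i}": "".join(rng.choice(bases, int(rng.integers(60, 300))))
            for i in range(6)
        }
        fam = {f"inst{i}": f"fam{i % 3}" for i in range(6)}
        db = SequenceDB("te", records, "TE_consensus")
        reads = []
        for i in range(80):
            if rng.random() < 0.7:
                rid = f"inst{rng.integers(6)}"
                L = int(rng.integers(20, 30))
                s = int(rng.integers(0, len(records[rid]) - L + 1))
                seq = records[rid][s : s + L]
                if rng.random() < 0.5:
                    seq = rc(seq)
            else:
                seq = "".join(rng.choice(bases, 25))
            reads.append(ReadRecord(f"r{i}", seq))
        got = count_te_families(reads, db, fam, v=1)
        expected = pd.Series(0, index=sorted(set(fam.values())))
        for read in reads:
            hits = align_all_bruteforce(read.sequence, records, 1)
            for f in {fam[h[0]] for h in hits}:
                expected[f] += 1
        assert got.to_dict() == expected.to_dict()


class TestNormalization:
    def test_per_million_scaling_equalizes_proportional_samples(self):
        ctrl = normalize_smrna(pd.Series({"gypsy": 200}), 1000)
        mut = normalize_smrna(pd.Series({"gypsy": 100}), 500)
        assert ctrl["gypsy"] == mut["gypsy"] == 200_000

    def test_norm_count_maps_to_one_million(self):
        counts = pd.Series({"norm_loci": 2500, "gypsy": 100})
        normed = normalize_smrna(counts, 2500)
        assert normed["norm_loci"] == pytest.approx(1e6)

    def test_zero_normalizer_is_error(self):
        with pytest.raises(ValueError, match="> 0"):
            normalize_smrna(pd.Series({"a": 1}), 0)


class TestFoldChange:
    def test_identity_and_doubling(self):
        fc = log2_fold_change(pd.Series({"a": 100.0, "b": 199.0}),
                              pd.Series({"a": 100.0, "b": 99.0}), pseudocount=1)
        assert fc.loc["a", "log2fc"] == 0.0
        assert fc.loc["b", "log2fc"] == pytest.approx(1.0)

    def test_zero_counts_give_zero(self):
        fc = log2_fold_change(pd.Series({"a": 0.0}), pd.Series({"a": 0.0}))
        assert fc.loc["a", "log2fc"] == 0.0

    def test_antisymmetry(self):
        m = pd.Series({"a": 37.0, "b": 250.0})
        c = pd.Series({"a": 110.0, "b": 31.0})
        fwd = log2_fold_change(m, c)["log2fc"]
        rev = log2_fold_change(c, m)["log2fc"]
        assert np.allclose(fwd, -rev)

    def test_invalid_pseudocount(self):
        with pytest.raises(ValueError):
            log2_fold_change(pd.Series(dtype=float), pd.Series(dtype=float),
                             pseudocount=0)


class TestHeatmapSelection:
    def test_threshold_is_log2_of_1p2(self):
        assert round(fold_change_threshold(1.2), 3) == 0.263

    def test_strictly_greater_selection(self):
        fc = pd.DataFrame({"log2fc": [0.30, 0.20, 0.27, 0.263]},
                          index=["a", "b", "c", "d"])
        sel = select_heatmap_tes(fc)
        assert list(sel.index) == ["a", "c"]  # 0.263 itself excluded

    def test_empty_table(self):
        sel = select_heatmap_tes(pd.DataFrame({"log2fc": []}))
        assert len(sel) == 0

    def test_smrna_pairing(self):
        rn = pd.DataFrame({"log2fc": [0.5]}, index=["a"])
        sm = pd.DataFrame({"log2fc": [-1.2]}, index=["a"])
        sel = select_heatmap_tes(rn, sm)
        assert sel.loc["a", "smrna_log2fc"] == -1.2


class TestCoverage:
    def test_unique_read_paints_its_span(self):
        rng = np.random.default_rng(6)
        cons = "".join(rng.choice(list("ACGT"), 120))
        db = SequenceDB("te", {"teA": cons}, "TE_consensus")
        depth = te_coverage_profile([ReadRecord("r", cons[0:25])], db, "teA",
                                    library_unique_total=1_000_000)
        assert (depth[0:25] == 1.0).all() and (depth[25:] == 0.0).all()

    def test_multimapping_read_contributes_nothing(self):
        rng = np.random.default_rng(13)
        core = "".join(rng.choice(list("ACGT"), 25))
        filler = "".join(rng.choice(list("ACGT"), 30))
        cons = core + filler + core
        db = SequenceDB("te", {"teA": cons}, "TE_consensus")
        depth = te_coverage_profile([ReadRecord("r", core)], db, "teA",
                                    library_unique_total=1_000_000)
        assert (depth == 0.0).all()

    def test_doubling_library_total_halves_depth(self):
        rng = np.random.default_rng(19)
        cons = "".join(rng.choice(list("ACGT"), 80))
        db = SequenceDB("te", {"teA": cons}, "TE_consensus")
        reads = [ReadRecord("r", cons[10:35])]
        d1 = te_coverage_profile(reads, db, "teA", 1_000_000)
        d2 = te_coverage_profile(reads, db, "teA", 2_000_000)
        assert np.allclose(d1, 2 * d2)


class TestPercentChange:
    @pytest.mark.parametrize(
        "control,mutant,expected",
        [(100.0, 29.5, 70.5), (42.0, 42.0, 0.0), (100.0, 120.0, -20.0)],
    )
    def test_values(self, control, mutant, expected):
        assert percent_change(control, mutant) == pytest.approx(expected)

    def test_zero_control_is_error(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 10.0)


def test_norm_loci_unique_count_suppresses_multimappers():
    rng = np.random.default_rng(44)
    uniq = "".join(rng.choice(list("ACGT"), 100))
    dup = "".join(rng.choice(list("ACGT"), 30))
    db = SequenceDB("n", {"locus1": uniq, "locus2": dup + "A" * 40 + dup},
                    "norm_loci")
    reads = [ReadRecord("u", uniq[5:30]), ReadRecord("m", dup[:25]),
             ReadRecord("x", "G" * 25)]
    assert norm_loci_unique_count(reads, db) == 1
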