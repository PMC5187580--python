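import filecmp

import numpy as np
import pytest
from scipy import stats

from pirna_soma import synthetic_data as sim
from pirna_soma.mini_align import revcomp
from pirna_soma.preprocess import preprocess_library
from pirna_soma.refio import extract_sequence
from pirna_soma.signatures import split_te_reads


class TestCatalogConstruction:
    def test_identical_seed_gives_byte_identical_files(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        sim.build_toy_references(seed=42).write(str(a))
        sim.build_toy_references(seed=42).write(str(b))
        files = sorted(p.name for p in a.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(a, b, files, shallow=False)
        assert mismatch == [] and errors == [] and len(match) == len(files)

    def test_te_instances_extract_to_consensus(self, catalog):
        for fam, iv in catalog.te_instances:
            seq = extract_sequence(catalog.genome, iv)
            cons = catalog.te_consensus.records[fam]
            assert seq == (revcomp(cons) if iv.strand == "-" else cons)

    def test_master_cluster_carries_antisense_fragments_of_two_families(
        self, catalog
    ):
        master = next(iv for iv in catalog.clusters
                      if iv.name == catalog.master_cluster)
        cluster_seq = extract_sequence(catalog.genome, master)
        fams_found = sum(
            1
            for cons in catalog.te_consensus.records.values()
            if revcomp(cons[100:160]) in cluster_seq
        )
        assert fams_found >= 2

    def test_infeasible_packing_is_error(self):
        with pytest.raises(ValueError, match="infeasible packing"):
            sim.build_toy_references(seed=1, genome_length=5_000)

    def test_catalog_hash_differs_across_seeds(self):
        assert (
            sim.build_toy_references(seed=1).catalog_hash
            != sim.build_toy_references(seed=2).catalog_hash
        )


class TestConfigValidation:
    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            sim.SimConfig(class_weights={**sim.DEFAULT_WEIGHTS, "miRNA": -0.1})

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sim.SimConfig(class_weights={c: 0.0 for c in sim.ALL_CLASSES})

    def test_depletion_factor_bounds(self):
        with pytest.raises(ValueError):
            sim.SimConfig(d_te=0.0)
        with pytest.raises(ValueError):
            sim.SimConfig(d_te=1.5)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            sim.SimConfig(first_u_prob=1.2)

    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        cfg = sim.SimConfig(seed=9, n_reads=1234, first_u_prob=0.75)
        path = tmp_path / "sim.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert sim.SimConfig.from_yaml(str(path)) == cfg


class TestLibrarySimulation:
    def test_identical_seed_gives_byte_identical_fastq(self, catalog, tmp_path):
        cfg = sim.SimConfig(seed=5, n_reads=2_000)
        for sub in ("a", "b"):
            reads, manifest = sim.simulate_library(cfg, "control", catalog)
            sim.write_library(reads, manifest, str(tmp_path / sub))
        assert (tmp_path / "a/control.fastq").read_bytes() == (
            tmp_path / "b/control.fastq"
        ).read_bytes()

    def test_manifest_rows_match_emitted_reads(self, catalog):
        cfg = sim.SimConfig(seed=6, n_reads=3_000)
        reads, manifest = sim.simulate_library(cfg, "control", catalog)
        assert len(reads) == len(manifest.reads) == 3_000
        assert [r.read_id for r in reads] == list(manifest.reads["read_id"])

    def test_mutant_removes_rather_than_replaces(self, catalog):
        cfg = sim.SimConfig(seed=6, n_reads=5_000)  # strong default depletions
        reads, _ = sim.simulate_library(cfg, "mutant", catalog)
        assert len(reads) < 5_000

    def test_constant_depth_mode_restores_depth(self, catalog):
        cfg = sim.SimConfig(seed=6, n_reads=2_000, constant_depth=True)
        reads, _ = sim.simulate_library(cfg, "mutant", catalog)
        assert len(reads) == 2_000

    def test_zero_error_reads_realign_to_planted_source(self, catalog):
        from pirna_soma.mini_align import align_all

        cfg = sim.SimConfig(seed=8, n_reads=1_500, error_rate=0.0)
        reads, manifest = sim.simulate_library(cfg, "control", catalog)
        truth = manifest.reads.set_index("read_id")
        for read in reads[:400]:
            row = truth.loc[read.read_id]
            insert = read.sequence[: row["length"]]
            if row["class"] == "TE_piRNA":
                hits = align_all("q", insert, catalog.te_consensus, 1)
                assert any(h.ref_id == row["source"] for h in hits)
                # only the (possibly forced) first base may mismatch
                assert all(h.mismatches <= 1 for h in hits)
            elif row["class"] == "miRNA":
                assert insert == catalog.mirna.records[row["source"]]

    def test_realized_class_counts_match_weights(self, catalog):
        pvals = []
        classes = list(sim.ALL_CLASSES)
        for seed in range(5):
            cfg = sim.SimConfig(seed=100 + seed, n_reads=20_000)
            _, manifest = sim.simulate_library(cfg, "control", catalog)
            counts = manifest.class_counts().reindex(classes, fill_value=0)
            expected = cfg.normalized_weights() * 20_000
            pvals.append(stats.chisquare(counts, expected).pvalue)
        assert all(p > 0.001 for p in pvals)

    def test_depletion_monotonicity(self, catalog):
        te_counts = []
        for d in (1.0, 0.5, 0.1):
            cfg = sim.SimConfig(seed=55, n_reads=8_000, d_te=d, d_cluster=1.0,
                                d_3utr=1.0)
            _, manifest = sim.simulate_library(cfg, "mutant", catalog)
            te_counts.append((manifest.reads["class"] == "TE_piRNA").sum())
        assert te_counts[0] > te_counts[1] > te_counts[2]

    def test_planted_antisense_fraction_recovered(self, catalog):
        cfg = sim.SimConfig(seed=77, n_reads=20_000)
        reads, _ = sim.simulate_library(cfg, "control", catalog)
        clean, _ = preprocess_library(reads, cfg.adapter, catalog.rrna)
        window = [r for r in clean if 23 <= len(r.sequence) <= 29]
        sense, antisense = split_te_reads(window, catalog.te_consensus)
        frac = len(antisense) / (len(sense) + len(antisense))
        se = np.sqrt(0.8 * 0.2 / (len(sense) + len(antisense)))
        assert abs(frac - 0.8) < 3 * se + 0.01
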