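"""Seeded generator of toy references and genotype-paired small-RNA
libraries with planted ground truth.

The generator emulates an oxidized somatic small-RNA library: a narrow 21 nt
siRNA peak, a broad 23-29 nt piRNA peak split between TE-consensus-derived,
cluster-derived and genic-3'UTR-derived reads, miRNA and rRNA contamination,
genotype-stable normalization loci (cisNAT-like), a 3' sequencing adapter on
every read, and per-base substitution errors. A mutant genotype removes
piRNA-class reads (not resampling them) by configurable depletion factors:
``d_te`` thins TE piRNAs, ``d_cluster`` thins reads from the designated
master (flamenco-like) cluster — the other clusters are genotype-independent
unless ``depletion_scope="all"`` — and ``d_3utr`` thins *sense* genic 3'UTR
reads, leaving the antisense minority untouched.

Every read carries a manifest entry (class, source feature, strand relation,
intended length, first base before errors); identical (seed, config) inputs
reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import refio
from .mini_align import revcomp
from .preprocess import ReadRecord, write_fastq
from .refio import (
    GeneRegions,
    Interval,
    IntervalSet,
    SequenceDB,
    build_gene_regions,
    write_bed,
    write_fasta,
    write_gff,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

PIRNA_CLASSES = ("TE_piRNA", "cluster_piRNA", "genic_3UTR_piRNA")

ALL_CLASSES = (
    "miRNA",
    "siRNA_21nt",
    "TE_piRNA",
    "cluster_piRNA",
    "genic_3UTR_piRNA",
    "rRNA_contam",
    "norm_loci",
)

#: default class weights: 63% of reads are 23-29 nt piRNAs, split so that
#: TE : cluster : genic = 49 : 34 : 17 as in the headline wild-type
#: composition; the remainder is miRNA, 21 nt siRNA, rRNA carry-over and
#: 21 nt normalization-locus reads.
DEFAULT_WEIGHTS = {
    "miRNA": 0.10,
    "siRNA_21nt": 0.10,
    "TE_piRNA": 0.3087,
    "cluster_piRNA": 0.2142,
    "genic_3UTR_piRNA": 0.1071,
    "rRNA_contam": 0.12,
    "norm_loci": 0.05,
}

#: broad unimodal piRNA length profile over 23-29 nt
DEFAULT_PIRNA_LENGTHS = {23: 0.10, 24: 0.14, 25: 0.18, 26: 0.20, 27: 0.17,
                         28: 0.12, 29: 0.09}


@dataclass
class SimConfig:
    """Study conditions for one simulated library pair."""

    seed: int = 0
    n_reads: int = 50_000
    class_weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    pirna_length_dist: dict = field(default_factory=lambda: dict(DEFAULT_PIRNA_LENGTHS))
    te_antisense_fraction: float = 0.8  # alpha
    first_u_prob: float = 0.85  # beta
    genic_sense_fraction: float = 0.87  # gamma
    error_rate: float = 0.001  # epsilon, per base
    adapter: str = "AGATCGGAAGAGC"
    read_cycles: int = 50
    # mutant depletion factors (multiplicative on emission; reads removed)
    d_te: float = 0.295
    d_cluster: float = 0.1
    d_3utr: float = 0.825
    depletion_scope: str = "master"  # d_cluster hits master only, or "all"
    master_cluster_weight: float = 0.35  # share of cluster emission
    constant_depth: bool = False

    def __post_init__(self) -> None:
        if set(self.class_weights) != set(ALL_CLASSES):
            raise ValueError(f"class_weights must have keys {ALL_CLASSES}")
        w = np.array([self.class_weights[c] for c in ALL_CLASSES], dtype=float)
        if (w < 0).any():
            raise ValueError("class weights must be >= 0")
        if w.sum() == 0:
            raise ValueError("class weight vector is all zero")
        for name in ("te_antisense_fraction", "first_u_prob",
                     "genic_sense_fraction", "error_rate"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        for name in ("d_te", "d_cluster", "d_3utr"):
            val = getattr(self, name)
            if not 0.0 < val <= 1.0:
                raise ValueError(f"{name} must be in (0,1]")
        if self.depletion_scope not in {"master", "all"}:
            raise ValueError("depletion_scope must be 'master' or 'all'")

    def normalized_weights(self) -> np.ndarray:
        w = np.array([self.class_weights[c] for c in ALL_CLASSES], dtype=float)
        return w / w.sum()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "class_weights" in d:
            d["class_weights"] = {k: float(v) for k, v in d["class_weights"].items()}
        if "pirna_length_dist" in d:
            d["pirna_length_dist"] = {int(k): float(v)
                                      for k, v in d["pirna_length_dist"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TruthManifest:
    """Per-read planted labels plus the generating configuration."""

    reads: pd.DataFrame  # read_id, class, source, strand_relation, length, first_base
    config: dict
    genotype: str

    def class_counts(self) -> pd.Series:
        return self.reads["class"].value_counts()

    def write(self, outdir: str, prefix: str = "truth") -> None:
        os.makedirs(outdir, exist_ok=True)
        self.reads.to_csv(os.path.join(outdir, f"{prefix}.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, f"{prefix}_config.json"), "w") as fh:
            json.dump({"genotype": self.genotype, "config": self.config},
                      fh, indent=2, sort_keys=True)


@dataclass
class ReferenceCatalog:
    """Toy genome plus every compartment database and annotation set."""

    genome: SequenceDB
    sno_trna: SequenceDB
    mirna: SequenceDB
    te_consensus: SequenceDB
    exon: SequenceDB
    intergenic: SequenceDB
    rrna: SequenceDB
    norm_loci: SequenceDB
    clusters: IntervalSet
    gene_models: IntervalSet
    gene_regions: dict[str, GeneRegions]
    te_instances: list[tuple[str, Interval]]
    master_cluster: str
    #: genome spans of the TE fragments embedded in the master cluster;
    #: cluster piRNA emission avoids them so that cluster-labelled reads are
    #: never TE-mapping (TE-derived piRNAs are their own class)
    master_fragment_zones: list[tuple[int, int]] = field(default_factory=list)

    def compartment_dbs(self) -> list[SequenceDB]:
        """The five classification databases in pipeline priority order."""
        return [self.sno_trna, self.mirna, self.te_consensus, self.exon,
                self.intergenic]

    @property
    def catalog_hash(self) -> str:
        h = hashlib.sha256()
        for db in (self.genome, self.sno_trna, self.mirna, self.te_consensus,
                   self.exon, self.intergenic, self.rrna, self.norm_loci):
            for rid in sorted(db.records):
                h.update(rid.encode())
                h.update(db.records[rid].encode())
        for iv in self.clusters:
            h.update(f"{iv.chrom}:{iv.start}-{iv.end}:{iv.strand}:{iv.name}".encode())
        for iv in self.gene_models:
            h.update(f"{iv.chrom}:{iv.start}-{iv.end}:{iv.strand}:{iv.name}:"
                     f"{iv.feature_class}".encode())
        return h.hexdigest()

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        write_fasta(self.genome, os.path.join(outdir, "genome.fa"))
        write_fasta(self.sno_trna, os.path.join(outdir, "sno_trna.fa"))
        write_fasta(self.mirna, os.path.join(outdir, "mirna.fa"))
        write_fasta(self.te_consensus, os.path.join(outdir, "te_consensus.fa"))
        write_fasta(self.exon, os.path.join(outdir, "exon.fa"))
        write_fasta(self.intergenic, os.path.join(outdir, "intergenic.fa"))
        write_fasta(self.rrna, os.path.join(outdir, "rrna.fa"))
        write_fasta(self.norm_loci, os.path.join(outdir, "norm_loci.fa"))
        write_bed(self.clusters, os.path.join(outdir, "clusters.bed"))
        write_gff(self.gene_models, os.path.join(outdir, "genes.gff3"))
        truth = {
            "te_instances": [
                {"family": fam, "chrom": iv.chrom, "start": iv.start,
                 "end": iv.end, "strand": iv.strand}
                for fam, iv in self.te_instances
            ],
            "master_cluster": self.master_cluster,
        }
        with open(os.path.join(outdir, "planted_features.json"), "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, n).tobytes().decode()


def build_toy_references(
    seed: int,
    genome_length: int = 120_000,
    n_te_families: int = 4,
    te_length: int = 400,
    instances_per_family: int = 2,
    n_clusters: int = 6,
    cluster_length: int = 2_000,
    n_genes: int = 8,
    n_mirnas: int = 8,
    n_sno: int = 6,
    n_norm_loci: int = 3,
) -> ReferenceCatalog:
    """Build a deterministic desk-scale reference catalog.

    The genome embeds TE instances (one per family reverse-complemented),
    single-exon genes with 5'UTR/CDS/3'UTR structure, piRNA clusters — the
    first of which is the master (flamenco-like) cluster carrying antisense
    fragments of two TE families — miRNA, sno/tRNA and normalization loci.
    The intergenic compartment database is the genomic complement of the
    sno/miRNA/TE/exon features, so cluster and normalization loci classify
    as intergenic, as they do for the real annotations.
    """
    if genome_length > 500_000:
        raise ValueError("desk-scale generator: genome_length too large")
    rng = np.random.default_rng(seed)
    genome_arr = rng.choice(_BASES, genome_length)

    te_names = [f"TE{i + 1}" for i in range(n_te_families)]
    consensi = {name: _random_seq(rng, te_length) for name in te_names}

    cursor = 0
    covered: list[tuple[int, int]] = []  # excluded from the intergenic DB

    def _place(length: int) -> tuple[int, int]:
        nonlocal cursor
        gap = int(rng.integers(150, 400))
        start = cursor + gap
        end = start + length
        if end > genome_length:
            raise ValueError("infeasible packing: features exceed genome length")
        cursor = end
        return start, end

    def _overwrite(start: int, seq: str) -> None:
        genome_arr[start : start + len(seq)] = np.frombuffer(seq.encode(), np.uint8)

    # sno/tRNA loci
    sno_records: dict[str, str] = {}
    for i in range(n_sno):
        length = int(rng.integers(80, 150))
        s, e = _place(length)
        covered.append((s, e))
        sno_records[f"snoRNA{i + 1}"] = genome_arr[s:e].tobytes().decode()

    # miRNA loci (22 nt hairpin-mature stand-ins)
    mirna_records: dict[str, str] = {}
    for i in range(n_mirnas):
        s, e = _place(22)
        covered.append((s, e))
        mirna_records[f"mir{i + 1}"] = genome_arr[s:e].tobytes().decode()

    # TE instances: full consensus copies, one per family on the minus strand
    te_instances: list[tuple[str, Interval]] = []
    for name in te_names:
        for j in range(instances_per_family):
            s, e = _place(te_length)
            covered.append((s, e))
            strand = "-" if j == 1 else "+"
            seq = revcomp(consensi[name]) if strand == "-" else consensi[name]
            _overwrite(s, seq)
            te_instances.append(
                (name, Interval("chr1", s, e, strand, f"{name}_ins{j + 1}", "TE"))
            )

    # single-exon genes: 150 nt 5'UTR, 900 nt CDS, 450 nt 3'UTR
    utr5_len, cds_len, utr3_len = 150, 900, 450
    gene_len = utr5_len + cds_len + utr3_len
    gene_ivs: list[Interval] = []
    for i in range(n_genes):
        s, e = _place(gene_len)
        covered.append((s, e))
        strand = "+" if i % 2 == 0 else "-"
        gene = f"gene{i + 1}"
        gene_ivs.append(Interval("chr1", s, e, strand, gene, "gene"))
        gene_ivs.append(Interval("chr1", s, e, strand, gene, "exon"))
        if strand == "+":
            cds = Interval("chr1", s + utr5_len, s + utr5_len + cds_len, strand,
                           gene, "CDS")
        else:
            cds = Interval("chr1", s + utr3_len, s + utr3_len + cds_len, strand,
                           gene, "CDS")
        gene_ivs.append(cds)
    gene_models = IntervalSet("gene_models", gene_ivs)
    gene_regions = build_gene_regions(gene_models)

    # piRNA clusters; cluster 1 is the flamenco-like master with embedded
    # antisense TE fragments
    cluster_ivs: list[Interval] = []
    frag_len = 60
    fragment_zones: list[tuple[int, int]] = []
    for i in range(n_clusters):
        s, e = _place(cluster_length)
        strand = "+" if i % 2 == 0 else "-"
        name = "flamenco_like" if i == 0 else f"cluster{i + 1}"
        if i == 0:
            for k, fam in enumerate(te_names[:2]):
                off = 300 + k * 600
                frag = revcomp(consensi[fam][100 : 100 + frag_len])
                _overwrite(s + off, frag)
                fragment_zones.append((s + off, s + off + frag_len))
        cluster_ivs.append(Interval("chr1", s, e, strand, name, "piRNA_cluster"))
    clusters = IntervalSet("piRNA_clusters", cluster_ivs)

    # genotype-stable normalization loci (cisNAT / structured-locus stand-ins)
    norm_records: dict[str, str] = {}
    norm_ivs: list[Interval] = []
    for i in range(n_norm_loci):
        s, e = _place(500)
        name = f"cisNAT{i + 1}"
        norm_records[name] = genome_arr[s:e].tobytes().decode()
        norm_ivs.append(Interval("chr1", s, e, "+", name, "norm_locus"))

    genome_seq = genome_arr.tobytes().decode()
    genome = SequenceDB("toy_genome", {"chr1": genome_seq}, "genome")

    exon_records = {
        gr.gene_id: genome_seq[gr.span()[0] : gr.span()[1]]
        for gr in gene_regions.values()
    }

    # intergenic = complement of sno/miRNA/TE/exon features, in chunks
    covered_sorted = sorted(covered)
    intergenic_records: dict[str, str] = {}
    prev = 0
    k = 0
    for s, e in covered_sorted + [(genome_length, genome_length)]:
        if s - prev >= 200:
            k += 1
            intergenic_records[f"intergenic{k}"] = genome_seq[prev:s]
        prev = max(prev, e)

    rrna_records = {
        "rRNA_2S": _random_seq(rng, 30),
        "rRNA_frag": _random_seq(rng, 120),
    }

    catalog = ReferenceCatalog(
        genome=genome,
        sno_trna=SequenceDB("sno_trna", sno_records, "sno_tRNA"),
        mirna=SequenceDB("mirna", mirna_records, "miRNA"),
        te_consensus=SequenceDB("te_consensus", consensi, "TE_consensus"),
        exon=SequenceDB("exon", exon_records, "exon"),
        intergenic=SequenceDB("intergenic", intergenic_records, "intergenic"),
        rrna=SequenceDB("rrna", rrna_records, "rRNA"),
        norm_loci=SequenceDB("norm_loci", norm_records, "norm_loci"),
        clusters=clusters,
        gene_models=gene_models,
        gene_regions=gene_regions,
        te_instances=te_instances,
        master_cluster="flamenco_like",
        master_fragment_zones=fragment_zones,
    )
    clusters.validate_against(genome)
    clusters.validate_nonoverlapping()
    return catalog


def _keep_probability(config: SimConfig, cls: str, source: str,
                      strand_rel: str, master: str) -> float:
    if cls == "TE_piRNA":
        return config.d_te
    if cls == "cluster_piRNA":
        if config.depletion_scope == "all" or source == master:
            return config.d_cluster
        return 1.0
    if cls == "genic_3UTR_piRNA":
        # piwi-dependent genic piRNAs are the sense 3'UTR class
        if config.depletion_scope == "all" or strand_rel == "sense":
            return config.d_3utr
        return 1.0
    return 1.0


def simulate_library(
    config: SimConfig,
    genotype: str,
    catalog: ReferenceCatalog,
    seed: int | None = None,
) -> tuple[list[ReadRecord], TruthManifest]:
    """Draw one library of raw reads (insert + 3' adapter, truncated to the
    sequencing cycle count, with substitution errors) and its manifest.

    ``genotype`` is ``"control"`` or ``"mutant"``; the mutant removes
    piRNA-class reads per the depletion factors, shrinking the library,
    unless ``config.constant_depth`` resamples to full depth.
    """
    if genotype not in {"control", "mutant"}:
        raise ValueError("genotype must be 'control' or 'mutant'")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    weights = config.normalized_weights()
    lengths = sorted(config.pirna_length_dist)
    lweights = np.array([config.pirna_length_dist[L] for L in lengths], dtype=float)
    lweights = lweights / lweights.sum()

    genome_seq = catalog.genome.records["chr1"]
    te_names = sorted(catalog.te_consensus.records)
    mirna_ids = sorted(catalog.mirna.records)
    rrna_ids = sorted(catalog.rrna.records)
    norm_ids = sorted(catalog.norm_loci.records)
    cluster_ivs = list(catalog.clusters)
    master = catalog.master_cluster
    others = [iv for iv in cluster_ivs if iv.name != master]
    master_iv = next(iv for iv in cluster_ivs if iv.name == master)
    genes = sorted(catalog.gene_regions)
    utr3 = {
        g: [iv for iv in catalog.gene_regions[g].regions
            if iv.feature_class == refio.THREE_UTR]
        for g in genes
    }

    records: list[ReadRecord] = []
    rows: list[tuple] = []
    mutant = genotype == "mutant"

    def _pirna_len() -> int:
        return int(rng.choice(lengths, p=lweights))

    attempts = 0
    max_attempts = config.n_reads * 20
    while attempts < max_attempts:
        if config.constant_depth:
            if len(records) >= config.n_reads:
                break
        elif attempts >= config.n_reads:
            break
        attempts += 1
        cls = ALL_CLASSES[int(rng.choice(len(ALL_CLASSES), p=weights))]

        force_u = False
        if cls == "miRNA":
            rid = mirna_ids[int(rng.integers(len(mirna_ids)))]
            insert, source, strand_rel = catalog.mirna.records[rid], rid, "sense"
        elif cls == "siRNA_21nt":
            fam = te_names[int(rng.integers(len(te_names)))]
            cons = catalog.te_consensus.records[fam]
            s = int(rng.integers(len(cons) - 21 + 1))
            window = cons[s : s + 21]
            if rng.random() < 0.5:
                insert, strand_rel = revcomp(window), "antisense"
            else:
                insert, strand_rel = window, "sense"
            source = fam
        elif cls == "TE_piRNA":
            fam = te_names[int(rng.integers(len(te_names)))]
            cons = catalog.te_consensus.records[fam]
            L = _pirna_len()
            s = int(rng.integers(len(cons) - L + 1))
            window = cons[s : s + L]
            if rng.random() < config.te_antisense_fraction:
                insert, strand_rel = revcomp(window), "antisense"
            else:
                insert, strand_rel = window, "sense"
            source, force_u = fam, True
        elif cls == "cluster_piRNA":
            if rng.random() < config.master_cluster_weight or not others:
                civ = master_iv
            else:
                civ = others[int(rng.integers(len(others)))]
            L = _pirna_len()
            while True:
                s = int(rng.integers(civ.start, civ.end - L + 1))
                # emit from the cluster backbone only: reads overlapping the
                # embedded TE fragments belong to the TE_piRNA class
                if civ.name != master or not any(
                    s < hi and s + L > lo for lo, hi in catalog.master_fragment_zones
                ):
                    break
            window = genome_seq[s : s + L]
            insert = window if civ.strand == "+" else revcomp(window)
            source, strand_rel, force_u = civ.name, "sense", True
        elif cls == "genic_3UTR_piRNA":
            g = genes[int(rng.integers(len(genes)))]
            iv = utr3[g][int(rng.integers(len(utr3[g])))]
            L = _pirna_len()
            s = int(rng.integers(iv.start, iv.end - L + 1))
            window = genome_seq[s : s + L]
            on_gene_strand = window if iv.strand == "+" else revcomp(window)
            if rng.random() < config.genic_sense_fraction:
                insert, strand_rel = on_gene_strand, "sense"
            else:
                insert, strand_rel = (revcomp(on_gene_strand), "antisense")
            # genic 3'UTR piRNAs are primary piRNAs too: same 1U bias
            source, force_u = g, True
        elif cls == "rRNA_contam":
            rid = rrna_ids[int(rng.integers(len(rrna_ids)))]
            rec = catalog.rrna.records[rid]
            L = int(rng.integers(18, min(30, len(rec)) + 1))
            s = int(rng.integers(len(rec) - L + 1))
            insert, source, strand_rel = rec[s : s + L], rid, "sense"
        else:  # norm_loci
            rid = norm_ids[int(rng.integers(len(norm_ids)))]
            rec = catalog.norm_loci.records[rid]
            s = int(rng.integers(len(rec) - 21 + 1))
            insert, source, strand_rel = rec[s : s + 21], rid, "sense"

        if mutant:
            keep = _keep_probability(config, cls, source, strand_rel, master)
            if keep < 1.0 and rng.random() >= keep:
                continue  # read removed, not replaced

        if force_u:
            # position-1 base is T with probability beta, else uniform on
            # A/C/G, so the measured 1U frequency estimates beta directly
            if rng.random() < config.first_u_prob:
                insert = "T" + insert[1:]
            else:
                insert = "ACG"[int(rng.integers(3))] + insert[1:]

        raw = (insert + config.adapter)[: config.read_cycles]
        read_id = f"{genotype}_{len(records) + 1:06d}"
        records.append(ReadRecord(read_id, raw))
        rows.append((read_id, cls, source, strand_rel, len(insert), insert[0]))

    # substitution errors, vectorized over the library
    if config.error_rate > 0 and records:
        raw_lens = np.array([len(r.sequence) for r in records])
        n_err = rng.binomial(raw_lens, config.error_rate)
        for i in np.nonzero(n_err)[0]:
            seq = list(records[i].sequence)
            for _ in range(int(n_err[i])):
                p = int(rng.integers(len(seq)))
                old = seq[p]
                choices = [b for b in "ACGT" if b != old]
                seq[p] = choices[int(rng.integers(3))]
            records[i] = ReadRecord(records[i].read_id, "".join(seq))

    manifest = TruthManifest(
        reads=pd.DataFrame(
            rows,
            columns=["read_id", "class", "source", "strand_relation",
                     "length", "first_base"],
        ),
        config={**config.to_dict(), "realized_seed": config.seed if seed is None else seed},
        genotype=genotype,
    )
    return records, manifest


def write_library(
    reads: list[ReadRecord],
    manifest: TruthManifest,
    outdir: str,
    prefix: str | None = None,
) -> str:
    """Write FASTQ + manifest TSV + config echo; returns the FASTQ path."""
    os.makedirs(outdir, exist_ok=True)
    prefix = prefix or manifest.genotype
    fastq = os.path.join(outdir, f"{prefix}.fastq")
    write_fastq(reads, fastq)
    manifest.write(outdir, prefix=f"{prefix}_truth")
    return fastq
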