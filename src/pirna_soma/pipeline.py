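"""End-to-end orchestration: one library to a report bundle, and the
control-vs-mutant genotype comparison.

Stage order follows the analysis it reproduces: adapter trim -> rRNA removal
-> size selection -> genome filter + compartment classification -> signature
statistics -> TE family quantification (cisNAT-normalized) -> cluster and
genic accounting. Every bundle carries the config and catalog hashes so a
comparison refuses to mix libraries processed against different references.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass
from typing import Sequence

import pandas as pd

from .compartments import assign_compartments, composition_summary
from .locus_analysis import (
    PIRNA_WINDOW,
    cluster_counts,
    cluster_fold_ratio,
    genic_region_counts,
    sense_fraction,
    unique_genome_alignments,
    unique_total_excluding,
)
from .preprocess import ReadRecord, preprocess_library
from .signatures import (
    PositionFrequencyMatrix,
    first_position_bias,
    length_histogram,
    size_profile,
    split_te_reads,
)
from .synthetic_data import ReferenceCatalog
from .te_quant import (
    HEATMAP_THRESHOLD,
    count_te_families,
    log2_fold_change,
    norm_loci_unique_count,
    normalize_smrna,
    percent_change,
    select_heatmap_tes,
)


@dataclass
class PipelineConfig:
    adapter: str = "AGATCGGAAGAGC"
    min_overlap: int = 5
    max_error_rate: float = 0.1
    discard_untrimmed: bool = False
    rrna_max_mismatches: int = 1
    min_len: int = 18
    max_len: int = 50
    v: int = 1
    pirna_window: tuple[int, int] = PIRNA_WINDOW
    pseudocount: float = 1.0
    heatmap_threshold: float = HEATMAP_THRESHOLD

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pirna_window"] = list(d["pirna_window"])
        return d

    @property
    def config_hash(self) -> str:
        """Stable across key order: hash of the canonical sorted-key JSON."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class ReportBundle:
    """All tables the pipeline emits for one library."""

    name: str
    accounting: pd.DataFrame
    composition_all: pd.DataFrame
    composition_pirna: pd.DataFrame
    size_profile_total: pd.Series
    te_sense_profile: pd.Series
    te_antisense_profile: pd.Series
    pfm: PositionFrequencyMatrix | None
    family_counts: pd.Series
    family_counts_norm: pd.Series
    norm_loci_unique: int
    total_pirna_norm: float
    te_pirna_norm: float
    utr3_sense_norm: float
    cluster_counts: pd.Series
    cluster_normalizer: int
    genic_table: pd.DataFrame
    genic_3utr_sense_fraction: float | None
    n_input_reads: int
    config_hash: str
    catalog_hash: str

    def summary(self) -> dict:
        return {
            "name": self.name,
            "n_input_reads": self.n_input_reads,
            "norm_loci_unique": self.norm_loci_unique,
            "total_pirna_norm": self.total_pirna_norm,
            "te_pirna_norm": self.te_pirna_norm,
            "utr3_sense_norm": self.utr3_sense_norm,
            "cluster_normalizer": self.cluster_normalizer,
            "genic_3utr_sense_fraction": self.genic_3utr_sense_fraction,
            "config_hash": self.config_hash,
            "catalog_hash": self.catalog_hash,
        }

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.accounting.to_csv(os.path.join(outdir, "accounting.tsv"),
                               sep="\t", index=False)
        self.composition_all.to_csv(os.path.join(outdir, "composition_all.tsv"),
                                    sep="\t", index=False)
        self.composition_pirna.to_csv(
            os.path.join(outdir, "composition_pirna.tsv"), sep="\t", index=False
        )
        profiles = pd.DataFrame(
            {
                "total": self.size_profile_total,
                "te_sense": self.te_sense_profile,
                "te_antisense": self.te_antisense_profile,
            }
        )
        profiles.to_csv(os.path.join(outdir, "size_profiles.tsv"), sep="\t")
        if self.pfm is not None:
            self.pfm.to_frame().to_csv(os.path.join(outdir, "pfm.tsv"), sep="\t")
            pd.Series(self.pfm.information, index=range(1, self.pfm.width + 1),
                      name="bits").rename_axis("position").to_csv(
                os.path.join(outdir, "pfm_information.tsv"), sep="\t"
            )
        self.family_counts.to_frame().assign(
            normalized=self.family_counts_norm
        ).to_csv(os.path.join(outdir, "te_family_counts.tsv"), sep="\t")
        self.cluster_counts.to_csv(os.path.join(outdir, "cluster_counts.tsv"),
                                   sep="\t")
        self.genic_table.to_csv(os.path.join(outdir, "genic_counts.tsv"),
                                sep="\t", index=False)
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, outdir: str) -> "ReportBundle":
        """Reload the fields a genotype comparison needs from a bundle dir."""
        with open(os.path.join(outdir, "summary.json")) as fh:
            s = json.load(fh)
        fam = pd.read_csv(os.path.join(outdir, "te_family_counts.tsv"),
                          sep="\t", index_col=0)
        clus = pd.read_csv(os.path.join(outdir, "cluster_counts.tsv"),
                           sep="\t", index_col=0)["count"]
        genic = pd.read_csv(os.path.join(outdir, "genic_counts.tsv"), sep="\t")
        empty = pd.DataFrame()
        return cls(
            name=s["name"], accounting=empty, composition_all=empty,
            composition_pirna=empty, size_profile_total=pd.Series(dtype=int),
            te_sense_profile=pd.Series(dtype=int),
            te_antisense_profile=pd.Series(dtype=int), pfm=None,
            family_counts=fam["count"], family_counts_norm=fam["normalized"],
            norm_loci_unique=s["norm_loci_unique"],
            total_pirna_norm=s["total_pirna_norm"],
            te_pirna_norm=s["te_pirna_norm"],
            utr3_sense_norm=s["utr3_sense_norm"],
            cluster_counts=clus, cluster_normalizer=s["cluster_normalizer"],
            genic_table=genic,
            genic_3utr_sense_fraction=s["genic_3utr_sense_fraction"],
            n_input_reads=s["n_input_reads"], config_hash=s["config_hash"],
            catalog_hash=s["catalog_hash"],
        )


def run_pipeline(
    reads: Sequence[ReadRecord],
    catalog: ReferenceCatalog,
    config: PipelineConfig | None = None,
    name: str = "library",
) -> ReportBundle:
    """Run every analysis stage on one raw library."""
    config = config or PipelineConfig()
    lo, hi = config.pirna_window

    clean, stages = preprocess_library(
        reads,
        adapter=config.adapter,
        rrna_db=catalog.rrna,
        min_overlap=config.min_overlap,
        max_error_rate=config.max_error_rate,
        discard_untrimmed=config.discard_untrimmed,
        rrna_max_mismatches=config.rrna_max_mismatches,
        min_len=config.min_len,
        max_len=config.max_len,
    )

    assignments, comp_stats = assign_compartments(
        clean, catalog.genome, catalog.compartment_dbs(), v=config.v
    )
    stages.append({"stage": "classify", **comp_stats})
    composition_all = composition_summary(assignments)
    composition_pirna = composition_summary(assignments, size_window=(lo, hi))

    profile_total = size_profile(clean, catalog.mirna, v=config.v)

    te_sense, te_antisense = split_te_reads(clean, catalog.te_consensus, v=config.v)
    sense_prof = length_histogram(te_sense)
    anti_prof = length_histogram(te_antisense)

    window_anti = [r for r in te_antisense if lo <= len(r.sequence) <= hi]
    pfm = (
        first_position_bias(window_anti, size_window=(lo, hi))
        if window_anti
        else None
    )

    window_reads = [r for r in clean if lo <= len(r.sequence) <= hi]
    family_counts = count_te_families(window_reads, catalog.te_consensus, v=config.v)
    norm_unique = norm_loci_unique_count(clean, catalog.norm_loci, v=config.v)
    family_norm = normalize_smrna(family_counts, norm_unique)

    te_window = sum(
        1 for r in (*te_sense, *te_antisense) if lo <= len(r.sequence) <= hi
    )
    te_pirna_norm = te_window * 1e6 / norm_unique

    # total piRNAs: reads in the piRNA window, miRNA-aligning reads excluded
    total_window = int(profile_total.loc[lo:hi].sum())
    total_pirna_norm = total_window * 1e6 / norm_unique

    uniq = unique_genome_alignments(window_reads, catalog.genome, v=config.v,
                                    size_window=None)
    clus_counts = cluster_counts(uniq, catalog.clusters)
    clus_norm = unique_total_excluding(
        window_reads, catalog.genome, [catalog.sno_trna, catalog.mirna],
        v=config.v,
    )
    genic = genic_region_counts(uniq, catalog.gene_regions)
    _, agg_sense = sense_fraction(genic)
    utr3_sense_total = int(
        genic.loc[genic["region"] == "three_prime_UTR", "sense"].sum()
    )
    utr3_sense_norm = utr3_sense_total * 1e6 / norm_unique

    return ReportBundle(
        name=name,
        accounting=pd.DataFrame(stages),
        composition_all=composition_all,
        composition_pirna=composition_pirna,
        size_profile_total=profile_total,
        te_sense_profile=sense_prof,
        te_antisense_profile=anti_prof,
        pfm=pfm,
        family_counts=family_counts,
        family_counts_norm=family_norm,
        norm_loci_unique=norm_unique,
        total_pirna_norm=total_pirna_norm,
        te_pirna_norm=te_pirna_norm,
        utr3_sense_norm=utr3_sense_norm,
        cluster_counts=clus_counts,
        cluster_normalizer=clus_norm,
        genic_table=genic,
        genic_3utr_sense_fraction=agg_sense,
        n_input_reads=len(reads),
        config_hash=config.config_hash,
        catalog_hash=catalog.catalog_hash,
    )


@dataclass
class GenotypeComparison:
    smrna_fold_change: pd.DataFrame
    cluster_ratios: pd.DataFrame
    percent_changes: dict[str, float]
    heatmap: pd.DataFrame | None

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.smrna_fold_change.to_csv(
            os.path.join(outdir, "smrna_fold_change.tsv"), sep="\t"
        )
        self.cluster_ratios.to_csv(os.path.join(outdir, "cluster_ratios.tsv"),
                                   sep="\t")
        if self.heatmap is not None:
            self.heatmap.to_csv(os.path.join(outdir, "heatmap.tsv"), sep="\t")
        with open(os.path.join(outdir, "percent_changes.json"), "w") as fh:
            json.dump(self.percent_changes, fh, indent=2, sort_keys=True)


def compare_genotypes(
    control: ReportBundle,
    mutant: ReportBundle,
    rnaseq_control: pd.Series | None = None,
    rnaseq_mutant: pd.Series | None = None,
    pseudocount: float = 1.0,
    heatmap_threshold: float = HEATMAP_THRESHOLD,
) -> GenotypeComparison:
    """Mutant-vs-control report: family fold changes, cluster ratio ranking,
    percent-change summaries, and (when RNA-seq family counts are supplied)
    the heat-map family selection."""
    if control.catalog_hash != mutant.catalog_hash:
        raise ValueError(
            "bundles were built against different reference catalogs"
        )
    smrna_fc = log2_fold_change(mutant.family_counts_norm,
                                control.family_counts_norm, pseudocount)
    ratios = cluster_fold_ratio(
        mutant.cluster_counts, control.cluster_counts,
        mutant.cluster_normalizer, control.cluster_normalizer, pseudocount
    )
    pct = {
        "total_pirna": percent_change(control.total_pirna_norm,
                                      mutant.total_pirna_norm),
        "te_pirna": percent_change(control.te_pirna_norm, mutant.te_pirna_norm),
        "utr3_sense_pirna": percent_change(control.utr3_sense_norm,
                                           mutant.utr3_sense_norm),
    }
    heatmap = None
    if rnaseq_control is not None and rnaseq_mutant is not None:
        ctrl_n = rnaseq_control * 1e6 / rnaseq_control.sum()
        mut_n = rnaseq_mutant * 1e6 / rnaseq_mutant.sum()
        rnaseq_fc = log2_fold_change(mut_n, ctrl_n, pseudocount)
        heatmap = select_heatmap_tes(rnaseq_fc, smrna_fc, heatmap_threshold)
    return GenotypeComparison(
        smrna_fold_change=smrna_fc,
        cluster_ratios=ratios,
        percent_changes=pct,
        heatmap=heatmap,
    )
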