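"""Per-genome and multi-genome orchestration of the codon-usage analysis.

``run_genome`` executes the full single-genome chain — filter, codon counts,
positional composition, RSCU/RFSC with the preferred and HF screens,
ENc/PR2/neutrality diagnostics, correspondence analysis of the gene x 59
RSCU matrix, SCUO/MILC and their correlation — and returns a result bundle
whose TSV surfaces mirror the summary-table layout of a plastome CUB study.
``run_comparative`` adds the cross-genome products: shared preferred and HF
codon sets, the species x 59 RSCU matrix, the squared-Euclidean distance
matrix, the between-groups dendrogram and its newick export.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, correspondence, diagnostics, expression, metrics
from .composition import genome_composition, positional_gc
from .genetic_code import CodonCounts, GeneticCode, aggregate_counts, count_codons
from .io import CodingSequence, FilterReport, filter_cds


@dataclass
class RunConfig:
    """Mode flags of the pipeline; defaults match the per-module conventions."""

    include_stop_gc: bool = True        # GC1/2/3 over the whole CDS incl. stop
    pr2_mode: str = "fourfold"          # or "all"
    species_rscu: str = "aggregate"     # or "mean" (mean of per-gene RSCU)
    milc_reference: str = "self"        # or "pooled" (cross-genome reference)
    genome_summary: str = "mean"        # SCUO/MILC summary: mean of genes
    n_axes: int = 4
    min_length: int = 300
    table_id: int = 1
    summary_dp: int = 2
    slope_dp: int = 4


@dataclass
class GenomeResult:
    species: str
    filter_report: FilterReport
    genes: list
    gene_table: pd.DataFrame
    composition: object
    index_table: pd.DataFrame
    preferred: frozenset
    high_frequency: frozenset
    neutrality: object
    coa: object
    scuo_milc_r: float
    scuo_milc_p: float
    genome_counts: CodonCounts = None
    summary: dict = field(default_factory=dict)

    def write_outputs(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.filter_report.to_tsv(out / "filter_report.tsv")
        self.gene_table.to_csv(out / "genes.tsv", sep="\t", index=False)
        self.index_table.to_csv(out / "codon_index.tsv", sep="\t")
        g = self.gene_table
        g[["gene", "gc3s", "enc", "enc_expected"]].to_csv(
            out / "enc_gc3s.tsv", sep="\t", index=False)
        g[["gene", "pr2_x", "pr2_y"]].to_csv(out / "pr2.tsv", sep="\t", index=False)
        g[["gene", "gc12", "gc3"]].to_csv(out / "neutrality.tsv", sep="\t", index=False)
        if self.coa is not None:
            self.coa.row_coords.to_csv(out / "coa_genes.tsv", sep="\t")
            self.coa.col_coords.to_csv(out / "coa_codons.tsv", sep="\t")
            pd.DataFrame(
                {"axis": np.arange(1, len(self.coa.inertia_fraction) + 1),
                 "inertia_fraction": self.coa.inertia_fraction}
            ).to_csv(out / "coa_inertia.tsv", sep="\t", index=False)
        pd.DataFrame([self.summary]).to_csv(out / "summary.tsv", sep="\t", index=False)


def run_genome(
    records: list[CodingSequence],
    species: str | None = None,
    config: RunConfig | None = None,
    pooled_reference: CodonCounts | None = None,
) -> GenomeResult:
    """Run the complete single-genome analysis on raw CDS records."""
    config = config or RunConfig()
    code = GeneticCode(config.table_id)
    species = species or (records[0].species if records else "genome")

    genes, report = filter_cds(records, min_length=config.min_length, code=code)
    if not genes:
        raise ValueError(f"{species}: no CDS survived filtering")

    counts_nostop = [count_codons(g, include_stop=False, code=code) for g in genes]
    counts_stop = [count_codons(g, include_stop=True, code=code) for g in genes]
    genome_nostop = aggregate_counts(counts_nostop, scope=f"{species}")
    genome_stop = aggregate_counts(
        [CodonCounts(scope=c.scope + "+stop", counts=c.counts) for c in counts_stop],
        scope=f"{species}+stop",
    )

    comp_genome = genome_composition(
        genes, code, include_stop=config.include_stop_gc, mode="pooled")
    comp_genes = [positional_gc(g, code, include_stop=config.include_stop_gc)
                  for g in genes]

    index_table = metrics.codon_index_table(genome_stop, code, include_ter=True)
    preferred = metrics.preferred_codons(index_table)
    hf = metrics.high_frequency_codons(index_table)

    reference = pooled_reference if config.milc_reference == "pooled" else genome_nostop

    rows = []
    rscu_rows = {}
    for g, cn, pc in zip(genes, counts_nostop, comp_genes):
        enc = diagnostics.enc_observed(cn, code)
        pr2 = diagnostics.pr2_point(cn, code, family_mode=config.pr2_mode)
        sc = expression.scuo(cn, code)
        ml = expression.milc(cn, reference, code)
        rscu_rows[g.id] = metrics.rscu_vector(cn, code)
        rows.append({
            "gene": g.id, "L": cn.L,
            "gc1": pc.gc1, "gc2": pc.gc2, "gc3": pc.gc3, "gc": pc.gc,
            "gc12": pc.gc12, "gc3s": pc.gc3s,
            "t3s": pc.t3s, "c3s": pc.c3s, "a3s": pc.a3s, "g3s": pc.g3s,
            "enc": enc.enc,
            "enc_expected": diagnostics.enc_expected(pc.gc3s)
            if not math.isnan(pc.gc3s) else math.nan,
            "pr2_x": pr2.x, "pr2_y": pr2.y,
            "scuo": sc.scuo, "milc": ml.milc,
        })
    gene_table = pd.DataFrame(rows)

    neutrality = diagnostics.neutrality_fit(comp_genes) if len(comp_genes) >= 3 else None
    try:
        r, p = expression.correlate_scuo_milc(gene_table["scuo"], gene_table["milc"])
    except ValueError:
        r = p = math.nan

    gene_rscu = pd.DataFrame(rscu_rows).T
    gene_gc = gene_table.set_index("gene")["gc"]
    coa = None
    if len(genes) >= 3:
        coa = correspondence.coa_rscu(gene_rscu, n_axes=config.n_axes)
        coa.row_coords = coa.row_coords.assign(gc=gene_gc)

    dp, sdp = config.summary_dp, config.slope_dp
    summary = {
        "species": species,
        "n_cds_input": report.n_input,
        "n_cds_retained": report.n_retained,
        "SCUO": round(float(np.nanmean(gene_table["scuo"])), dp),
        "MILC": round(float(np.nanmean(gene_table["milc"])), dp),
        "GC1%": round(100 * comp_genome.gc1, dp),
        "GC2%": round(100 * comp_genome.gc2, dp),
        "GC3%": round(100 * comp_genome.gc3, dp),
        "GC%": round(100 * comp_genome.gc, dp),
        "mean_ENc": round(float(np.nanmean(gene_table["enc"])), dp),
        "neutrality_slope": round(neutrality.slope, sdp) if neutrality else math.nan,
        "neutrality_r": round(neutrality.pearson_r, sdp) if neutrality else math.nan,
        "scuo_milc_r": round(r, 3) if not math.isnan(r) else math.nan,
        "scuo_milc_p": round(p, 3) if not math.isnan(p) else math.nan,
        "coa_axis1_%": round(100 * coa.inertia_fraction[0], dp)
        if coa is not None and coa.axes_kept >= 1 else math.nan,
        "coa_axis2_%": round(100 * coa.inertia_fraction[1], dp)
        if coa is not None and coa.axes_kept >= 2 else math.nan,
        "n_preferred": len(preferred),
        "n_high_frequency": len(hf),
    }

    return GenomeResult(
        species=species,
        filter_report=report,
        genes=genes,
        gene_table=gene_table,
        composition=comp_genome,
        index_table=index_table,
        preferred=preferred,
        high_frequency=hf,
        neutrality=neutrality,
        coa=coa,
        scuo_milc_r=r,
        scuo_milc_p=p,
        genome_counts=genome_nostop,
        summary=summary,
    )


@dataclass
class ComparativeResult:
    genomes: list
    shared_preferred: frozenset
    shared_preferred_at_ending: int
    common_high_frequency: frozenset
    rscu_matrix: pd.DataFrame
    distances: clustering.DistanceMatrix
    dendrogram: clustering.Dendrogram
    newick: str
    root_split: tuple

    def write_outputs(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([g.summary for g in self.genomes]).to_csv(
            out / "summary.tsv", sep="\t", index=False)
        self.rscu_matrix.to_csv(out / "species_rscu.tsv", sep="\t")
        self.distances.to_tsv(out / "distances.tsv")
        (out / "cluster.nwk").write_text(self.newick + "\n")
        with open(out / "shared_codons.tsv", "w") as fh:
            fh.write("set\tcodons\n")
            fh.write("preferred_common\t" + ",".join(sorted(self.shared_preferred)) + "\n")
            fh.write("hf_common\t" + ",".join(sorted(self.common_high_frequency)) + "\n")
        with open(out / "root_split.tsv", "w") as fh:
            for i, side in enumerate(self.root_split, 1):
                fh.write(f"clade{i}\t" + ",".join(sorted(side)) + "\n")


def run_comparative(
    genome_records: dict[str, list[CodingSequence]],
    config: RunConfig | None = None,
) -> ComparativeResult:
    """Run every genome, then the cross-genome comparative products."""
    config = config or RunConfig()
    code = GeneticCode(config.table_id)
    if len(genome_records) < 2:
        raise ValueError("comparative analysis requires at least 2 genomes")

    pooled = None
    if config.milc_reference == "pooled":
        all_counts = []
        for sp, recs in genome_records.items():
            kept, _ = filter_cds(recs, min_length=config.min_length, code=code)
            all_counts += [count_codons(g, include_stop=False, code=code) for g in kept]
        pooled = aggregate_counts(all_counts, scope="pooled")

    results = []
    for sp, recs in genome_records.items():
        try:
            results.append(run_genome(recs, species=sp, config=config,
                                      pooled_reference=pooled))
        except ValueError as exc:
            warnings.warn(f"{sp}: genome excluded from comparison ({exc})", stacklevel=2)
    if len(results) < 2:
        raise ValueError("fewer than 2 genomes survived; no comparative analysis")

    shared_pref = frozenset.intersection(*[g.preferred for g in results])
    common_hf = frozenset.intersection(*[g.high_frequency for g in results])

    if config.species_rscu == "aggregate":
        mat = metrics.rscu_matrix({g.species: g.genome_counts for g in results}, code)
    else:
        cols = list(code.synonymous_codons)
        mat = pd.DataFrame(
            {g.species: pd.concat(
                [metrics.rscu_vector(count_codons(x, code=code), code) for x in g.genes],
                axis=1).mean(axis=1) for g in results}
        ).T[cols]

    dm = clustering.rscu_distance_matrix(mat)
    dendro = clustering.average_linkage(dm)
    nwk = clustering.to_newick(dendro)

    return ComparativeResult(
        genomes=results,
        shared_preferred=shared_pref,
        shared_preferred_at_ending=sum(metrics.ends_in_at(c) for c in shared_pref),
        common_high_frequency=common_hf,
        rscu_matrix=mat,
        distances=dm,
        dendrogram=dendro,
        newick=nwk,
        root_split=dendro.root_split(),
    )
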