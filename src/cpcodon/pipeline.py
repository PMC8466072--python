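"""Per-species analysis orchestration and cross-species summaries.

:func:`run_species` chains the whole pipeline for one genome — screen
CDS, count codons, RSCU/RFSC and the high-frequency screen, per-gene
indices, ENC-ranked expression libraries and delta-RSCU optimal codons,
the three mutation-selection diagnostics, and correspondence analysis —
writing every intermediate as TSV plus a JSON summary whose numbers are
all recomputable from those TSVs.

:func:`run_comparison` combines two or more species reports: shared
high-frequency codons, shared RSCU > 1 codons (with the A/T-ending
tally) and per-host significant-codon counts against Kazusa-style
frequency tables.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from . import coa as coa_mod
from .cds_io import dedupe_identical, filter_cds, read_cds
from .codon_stats import (
    CodonCountTable,
    compute_rfsc,
    compute_rscu,
    count_codons,
    gc_by_position,
    high_frequency_codons,
    pool_tables,
    rscu_rfsc_tsv,
)
from .genetic_code import CODON_TO_AA, CODONS, SYNONYMOUS_CODONS
from .host_compare import FrequencyTable, compare_hosts, frequency_per_thousand
from .mutation_selection import (
    enc_plot_points,
    fraction_below_curve,
    neutrality_fit,
    pairwise_gc_correlations,
    pr2_point,
    species_pr2,
)
from .optimal_codons import delta_rscu_optimal, split_expression_libraries
from .usage_indices import (
    GeneIndices,
    cbi_fop,
    codon_adaptation_index,
    effective_number_of_codons,
    gene_l_aa,
)

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Thresholds and toggles of the per-species pipeline."""

    min_length: int = 300
    library_fraction: float = 0.10
    delta_threshold: float = 0.08
    pr2_codon_set: str = "fourfold"
    dedupe: bool = False
    neutrality_exclude_met_trp: bool = True
    neutrality_exclude_stops: bool = True
    neutrality_exclude_ile: bool = True
    n_axes: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.library_fraction <= 0.5:
            raise ValueError("library_fraction must be in (0, 0.5]")
        if self.delta_threshold < 0:
            raise ValueError("delta_threshold must be >= 0")
        if self.pr2_codon_set not in ("fourfold", "all_synonymous"):
            raise ValueError(f"unknown pr2_codon_set {self.pr2_codon_set!r}")
        if self.min_length < 3:
            raise ValueError("min_length must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SpeciesReport:
    """In-memory bundle of everything run_species computed."""

    species: str
    n_raw: int
    n_kept: int
    pooled: CodonCountTable
    gene_indices: list[GeneIndices]
    high_frequency: set[str]
    optimal: set[str]
    summary: dict = field(default_factory=dict)


def _fmt(x: float) -> str:
    return "NA" if (isinstance(x, float) and math.isnan(x)) else f"{x:.6f}"


def run_species(
    config: AnalysisConfig,
    input_path: str | Path,
    format: str = "genbank",
    species_label: str | None = None,
    out_dir: str | Path | None = None,
    make_plots: bool = False,
) -> SpeciesReport:
    """Run the full per-species analysis; write TSV/JSON outputs if out_dir."""
    records = read_cds(input_path, format=format, species_label=species_label)
    if not records:
        raise ValueError(f"no CDS found in {input_path}")
    species = species_label or records[0].species_label
    if config.dedupe:
        records = dedupe_identical(records)
    report = filter_cds(records, min_length=config.min_length)
    kept = report.kept
    if not kept:
        raise ValueError("no CDS passed the structural screen")
    log.info("%s: %d/%d CDS kept", species, len(kept), report.n_input)

    gene_tables = count_codons(kept, pool=False)
    pooled = pool_tables(gene_tables)
    pooled_gc = gc_by_position(pooled)

    indices = [
        GeneIndices(
            gene_id=rec.gene_id,
            enc=effective_number_of_codons(tab),
            gc=gc_by_position(tab),
            l_aa=gene_l_aa(tab),
        )
        for rec, tab in zip(kept, gene_tables)
    ]

    # ENC-ranked expression libraries -> reference RSCU, CAI, optimal codons
    libraries = split_expression_libraries(indices, fraction=config.library_fraction)
    id_order = [g.gene_id for g in indices]
    # duplicate gene ids (IR copies) collapse here; first occurrence wins
    tab_of = dict(zip(id_order, gene_tables))
    high_pool = pool_tables(tab_of[g] for g in libraries.high)
    low_pool = pool_tables(tab_of[g] for g in libraries.low)
    reference = compute_rscu(high_pool)
    optimal_result = delta_rscu_optimal(
        high_pool, low_pool, threshold=config.delta_threshold
    )
    for g, tab in zip(indices, gene_tables):
        g.cai = codon_adaptation_index(tab, reference)
        if optimal_result.optimal_set:
            g.cbi, g.fop = cbi_fop(tab, optimal_result.optimal_set)

    rfsc = compute_rfsc(pooled)
    rscu = compute_rscu(pooled)
    hi_freq = high_frequency_codons(rfsc)

    enc_points = enc_plot_points(indices)
    pr2_gene = [
        pr2_point(tab, codon_set=config.pr2_codon_set, gene_id=g.gene_id)
        for g, tab in zip(indices, gene_tables)
    ]
    pr2_mean = species_pr2(pr2_gene)
    neut = neutrality_fit(
        gene_tables,
        indices,
        exclude_met_trp=config.neutrality_exclude_met_trp,
        exclude_stops=config.neutrality_exclude_stops,
        exclude_ile=config.neutrality_exclude_ile,
    )
    gc_corr = pairwise_gc_correlations(indices)

    matrix = coa_mod.rscu_matrix(kept)
    ca = coa_mod.correspondence_analysis(matrix, n_axes=config.n_axes)
    # CA rows are indexed by gene_id; duplicate ids (IR copies) would collide,
    # so correlations fall back gracefully when ids are not unique.
    if matrix.index.is_unique and len(indices) == len(set(id_order)):
        corr_rows = coa_mod.axis_correlations(ca, indices)
    else:
        log.warning("duplicate gene ids; axis correlations use first occurrences")
        seen: dict[str, GeneIndices] = {}
        for g in indices:
            seen.setdefault(g.gene_id, g)
        dedup_matrix = matrix[~matrix.index.duplicated()]
        ca = coa_mod.correspondence_analysis(dedup_matrix, n_axes=config.n_axes)
        corr_rows = coa_mod.axis_correlations(ca, list(seen.values()))

    syn_rscu = {
        c: rscu.values[c]
        for c in SYNONYMOUS_CODONS
        if CODON_TO_AA[c] not in rscu.unobserved
    }
    summary = {
        "species": species,
        "cds_before_filter": report.n_input,
        "cds_after_filter": len(kept),
        "rejection_counts": report.rule_counts,
        "l_aa": int(sum(g.l_aa for g in indices)),
        "gc1": round(pooled_gc.gc1, 3),
        "gc2": round(pooled_gc.gc2, 3),
        "gc3": round(pooled_gc.gc3, 3),
        "gc123": round(pooled_gc.gc123, 3),
        "rscu_min": round(min(syn_rscu.values()), 2),
        "rscu_max": round(max(syn_rscu.values()), 2),
        "rscu_gt1_codons": sorted(c for c, v in rscu.values.items() if v > 1.0),
        "high_frequency_codons": sorted(hi_freq),
        "optimal_codons": sorted(optimal_result.optimal_set),
        "n_optimal_codons": len(optimal_result.optimal_set),
        "expression_libraries": {"high": libraries.high, "low": libraries.low},
        "enc_mean": round(
            sum(p.enc for p in enc_points) / len(enc_points), 3
        )
        if enc_points
        else None,
        "enc_fraction_below_curve": round(fraction_below_curve(enc_points), 3),
        "pr2_at_bias": round(pr2_mean.at_bias, 3),
        "pr2_gc_bias": round(pr2_mean.gc_bias, 3),
        "neutrality": {
            "slope": round(neut.slope, 4) if not math.isnan(neut.slope) else None,
            "intercept": round(neut.intercept, 4)
            if not math.isnan(neut.intercept)
            else None,
            "pearson_r": round(neut.pearson_r, 4)
            if not math.isnan(neut.pearson_r)
            else None,
            "p_value": neut.p_value if not math.isnan(neut.p_value) else None,
        },
        "gc_correlations": {
            f"{a}_{b}": {"r": round(r, 4), "p": p}
            if not math.isnan(r)
            else None
            for (a, b), (r, p) in gc_corr.items()
        },
        "axis_inertia_fractions": [round(float(v), 4) for v in ca.inertia_fraction],
        "axis1_correlations": {
            row.index_name: {
                "r": round(row.pearson_r, 4) if not math.isnan(row.pearson_r) else None,
                "p": row.p_value if not math.isnan(row.p_value) else None,
                "mark": row.mark,
            }
            for row in corr_rows
        },
    }

    result = SpeciesReport(
        species=species,
        n_raw=report.n_input,
        n_kept=len(kept),
        pooled=pooled,
        gene_indices=indices,
        high_frequency=hi_freq,
        optimal=optimal_result.optimal_set,
        summary=summary,
    )

    if out_dir is None:
        return result
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_tsv(out / "filter_report.tsv")
    with open(out / "codon_counts.tsv", "w") as fh:
        fh.write("gene_id\t" + "\t".join(CODONS) + "\n")
        for g, tab in zip(indices, gene_tables):
            fh.write(g.gene_id + "\t" + "\t".join(str(tab.counts[c]) for c in CODONS) + "\n")
    rscu_rfsc_tsv(pooled, out / "rscu_rfsc.tsv", high_frequency=hi_freq)
    with open(out / "gene_indices.tsv", "w") as fh:
        fh.write(
            "gene_id\tT3s\tC3s\tA3s\tG3s\tCAI\tCBI\tFop\tNc\tGC3s\tGC\tL_aa\n"
        )
        for g in indices:
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        _fmt(g.gc.t3s),
                        _fmt(g.gc.c3s),
                        _fmt(g.gc.a3s),
                        _fmt(g.gc.g3s),
                        _fmt(g.cai),
                        _fmt(g.cbi),
                        _fmt(g.fop),
                        _fmt(g.enc),
                        _fmt(g.gc.gc3s),
                        _fmt(g.gc.gc123),
                        str(g.l_aa),
                    ]
                )
                + "\n"
            )
    optimal_result.to_tsv(out / "delta_rscu.tsv")
    with open(out / "enc_plot.tsv", "w") as fh:
        fh.write("gene_id\tgc3s\tenc\tenc_expected\tdeviation\n")
        for p in enc_points:
            fh.write(
                f"{p.gene_id}\t{_fmt(p.gc3s)}\t{_fmt(p.enc)}\t"
                f"{_fmt(p.enc_expected)}\t{_fmt(p.deviation)}\n"
            )
    with open(out / "pr2.tsv", "w") as fh:
        fh.write("gene_id\tat_bias\tgc_bias\n")
        for p in pr2_gene:
            fh.write(f"{p.gene_id}\t{_fmt(p.at_bias)}\t{_fmt(p.gc_bias)}\n")
        fh.write(f"mean\t{_fmt(pr2_mean.at_bias)}\t{_fmt(pr2_mean.gc_bias)}\n")
    with open(out / "neutrality.tsv", "w") as fh:
        fh.write("gene_id\tgc12\tgc3\n")
        for g, g12, g3 in zip(indices, neut.gc12_per_gene, neut.gc3_per_gene):
            fh.write(f"{g.gene_id}\t{_fmt(g12)}\t{_fmt(g3)}\n")
    ca.gene_coords.to_csv(out / "coa_genes.tsv", sep="\t", float_format="%.6f")
    ca.codon_coords.to_csv(out / "coa_codons.tsv", sep="\t", float_format="%.6f")
    with open(out / "coa_inertia.tsv", "w") as fh:
        fh.write("axis\tinertia_fraction\n")
        for i, v in enumerate(ca.inertia_fraction, start=1):
            fh.write(f"axis{i}\t{float(v):.6f}\n")
    with open(out / "axis1_correlations.tsv", "w") as fh:
        fh.write("index\tpearson_r\tp_value\tmark\n")
        for row in corr_rows:
            fh.write(
                f"{row.index_name}\t{_fmt(row.pearson_r)}\t"
                f"{_fmt(row.p_value)}\t{row.mark}\n"
            )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if make_plots:
        from . import plots

        plots.plot_enc(enc_points, out / "enc_plot.png")
        plots.plot_pr2(pr2_gene, out / "pr2_plot.png")
        plots.plot_neutrality(neut, out / "neutrality_plot.png")
    return result


def run_comparison(
    reports: list[SpeciesReport],
    host_tables: list[FrequencyTable] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Cross-species summaries and heterologous-host comparison counts."""
    if len(reports) < 2:
        raise ValueError("need >= 2 species reports")
    shared_hi = set.intersection(*(r.high_frequency for r in reports))
    rscu_gt1_sets = [
        {c for c, v in compute_rscu(r.pooled).values.items() if v > 1.0}
        for r in reports
    ]
    shared_gt1 = set.intersection(*rscu_gt1_sets)
    at_ending = {c for c in shared_gt1 if c[2] in "AT"}
    result = {
        "species": [r.species for r in reports],
        "shared_high_frequency_codons": sorted(shared_hi),
        "n_shared_high_frequency": len(shared_hi),
        "shared_rscu_gt1_codons": sorted(shared_gt1),
        "n_shared_rscu_gt1": len(shared_gt1),
        "n_shared_rscu_gt1_at_ending": len(at_ending),
        "host_comparison": {},
    }
    comparisons = []
    for host in host_tables or []:
        per_species = {}
        for r in reports:
            query = frequency_per_thousand(r.pooled, source_label=r.species)
            cmp_result = compare_hosts(query, host)
            comparisons.append(cmp_result)
            per_species[r.species] = cmp_result.n_significant
        result["host_comparison"][host.source_label] = {
            "n_significant_per_species": per_species,
            "max_n_significant": max(per_species.values()),
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "comparison.json", "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
            fh.write("\n")
        for cmp_result in comparisons:
            cmp_result.to_tsv(
                out / f"host_{cmp_result.host_label}_{cmp_result.query_label}.tsv"
            )
        with open(out / "shared_codons.tsv", "w") as fh:
            fh.write("codon\thigh_frequency_shared\trscu_gt1_shared\n")
            for c in CODONS:
                fh.write(f"{c}\t{int(c in shared_hi)}\t{int(c in shared_gt1)}\n")
    return result
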