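"""ENC-plot, PR2-plot and neutrality diagnostics."""

import math

import numpy as np
import pytest

from cpcodon.codon_stats import count_codons, gc_by_position
from cpcodon.genetic_code import CODONS, FOURFOLD_CODONS
from cpcodon.mutation_selection import (
    enc_plot_points,
    fraction_below_curve,
    neutrality_fit,
    neutrality_gc3,
    pairwise_gc_correlations,
    pr2_point,
    species_pr2,
)
from cpcodon.synthetic_data import UsageProfile, generate_genome, generate_neutrality_set
from cpcodon.usage_indices import GeneIndices, effective_number_of_codons, gene_l_aa

from conftest import make_gc, make_indices, make_table


def indices_for(records):
    tables = count_codons(records, pool=False)
    idx = [
        GeneIndices(r.gene_id, effective_number_of_codons(t), gc_by_position(t), gene_l_aa(t))
        for r, t in zip(records, tables)
    ]
    return idx, tables


class TestEncPlot:
    def test_uniform_gene_sits_near_the_curve_top(self):
        counts = {c: 170 for c in CODONS if c not in ("TAA", "TAG", "TGA")}
        table = make_table(counts)
        gc = gc_by_position(table)
        point = enc_plot_points(
            [GeneIndices("g", effective_number_of_codons(table), gc, 1)]
        )[0]
        assert point.enc > 60.4
        assert abs(point.deviation) < 1.0  # estimator noise only

    def test_mutation_only_genes_track_expected_curve(self):
        # usage driven purely by third-position composition: points stay
        # within ~2 ENC units of the expected curve at 10^3 codons per gene
        profile = UsageProfile(
            gene_count=20,
            length_range=(3000, 3000),
            gc3_gradient=(0.20, 0.55),
            seed=42,
        )
        idx, _ = indices_for(generate_genome(profile))
        points = enc_plot_points(idx)
        assert len(points) == 20
        mean_abs_dev = np.mean([abs(p.deviation) for p in points])
        assert mean_abs_dev < 2.0

    def test_selection_skewed_genes_fall_below(self):
        profile = UsageProfile(
            gene_count=20,
            length_range=(3000, 3000),
            bias_concentration=0.3,
            seed=42,
        )
        idx, _ = indices_for(generate_genome(profile))
        assert fraction_below_curve(enc_plot_points(idx)) > 0.8


class TestPr2:
    def test_balanced_usage_hits_center(self):
        counts = {c: 4 for c in FOURFOLD_CODONS}
        p = pr2_point(make_table(counts))
        assert (p.at_bias, p.gc_bias) == (0.5, 0.5)

    def test_hand_arithmetic_in_fourfold_family(self):
        # Ala third positions: A=3, T=1, G=1, C=1
        p = pr2_point(make_table({"GCA": 3, "GCT": 1, "GCG": 1, "GCC": 1}))
        assert p.at_bias == pytest.approx(0.75)
        assert p.gc_bias == pytest.approx(0.5)

    def test_non_fourfold_codons_ignored_by_default(self):
        p = pr2_point(make_table({"GCA": 3, "GCT": 1, "TAT": 50}))  # Tyr not 4-fold
        assert p.at_bias == pytest.approx(0.75)
        q = pr2_point(
            make_table({"GCA": 3, "GCT": 1, "TAT": 4}), codon_set="all_synonymous"
        )
        assert q.at_bias == pytest.approx(3 / 8)

    def test_scaling_invariance(self, random_count_table):
        table = random_count_table(9, low=1)
        scaled = make_table({c: 7 * n for c, n in table.counts.items()})
        a, b = pr2_point(table), pr2_point(scaled)
        assert a.at_bias == pytest.approx(b.at_bias)
        assert a.gc_bias == pytest.approx(b.gc_bias)

    def test_zero_denominator_is_nan(self):
        p = pr2_point(make_table({"GCA": 2, "GCT": 1}))  # no G/C third positions
        assert math.isnan(p.gc_bias)
        assert p.at_bias == pytest.approx(2 / 3)

    def test_species_value_is_unweighted_mean(self):
        points = [
            pr2_point(make_table({"GCA": 3, "GCT": 1, "GCG": 1, "GCC": 1}), gene_id="a"),
            pr2_point(make_table({"GCA": 1, "GCT": 1, "GCG": 1, "GCC": 1}), gene_id="b"),
        ]
        mean = species_pr2(points)
        assert mean.at_bias == pytest.approx((0.75 + 0.5) / 2)


class TestNeutrality:
    def test_constant_gc12_gives_zero_slope(self):
        # pure-Ala genes: GC12 pinned at 1 while GC3 varies
        tables = [make_table({"GCA": 10 - i, "GCG": i}) for i in (1, 3, 5, 7)]
        idx = [
            GeneIndices(f"g{i}", 50.0, gc_by_position(t), 10)
            for i, t in enumerate(tables)
        ]
        fit = neutrality_fit(tables, idx)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_complete_neutrality_recovers_slope_one(self):
        records = generate_neutrality_set(
            slope=1.0, intercept=0.0, noise_sd=0.0, gene_count=100, seed=42,
            gc3_range=(0.15, 0.60),
        )
        idx, tables = indices_for(records)
        fit = neutrality_fit(tables, idx)
        assert fit.slope == pytest.approx(1.0, abs=0.05)
        assert fit.pearson_r > 0.95

    def test_planted_slope_recovered(self):
        records = generate_neutrality_set(
            slope=0.2, intercept=0.35, noise_sd=0.01, gene_count=60, seed=42
        )
        idx, tables = indices_for(records)
        fit = neutrality_fit(tables, idx)
        assert 0.15 <= fit.slope <= 0.25

    def test_zero_variance_gc3_is_nan(self):
        tables = [make_table({"GCA": 5, "AAA": i}) for i in (1, 2, 3)]
        idx = [
            GeneIndices(f"g{i}", 50.0, gc_by_position(t), 10)
            for i, t in enumerate(tables)
        ]
        assert math.isnan(neutrality_fit(tables, idx).slope)

    def test_order_invariance(self):
        records = generate_neutrality_set(0.2, 0.35, 0.01, 30, seed=1)
        idx, tables = indices_for(records)
        fit = neutrality_fit(tables, idx)
        rev = neutrality_fit(tables[::-1], idx[::-1])
        assert fit.slope == pytest.approx(rev.slope)

    def test_slope_equals_r_times_sd_ratio(self):
        records = generate_neutrality_set(0.2, 0.35, 0.01, 30, seed=2)
        idx, tables = indices_for(records)
        fit = neutrality_fit(tables, idx)
        x = np.array(fit.gc3_per_gene)
        y = np.array(fit.gc12_per_gene)
        assert fit.slope == pytest.approx(
            fit.pearson_r * y.std(ddof=1) / x.std(ddof=1)
        )

    def test_gc3_exclusions_toggle(self):
        table = make_table({"ATG": 10, "ATC": 10, "GCG": 10, "TAA": 1})
        full = neutrality_gc3(
            table, exclude_met_trp=False, exclude_stops=False, exclude_ile=False
        )
        assert full == pytest.approx(30 / 31)  # ATG+ATC+GCG third-base G/C
        default = neutrality_gc3(table)  # drops ATG, ATC, TAA
        assert default == pytest.approx(1.0)


class TestPairwiseGcCorrelations:
    def test_duplicated_series_correlates_perfectly(self):
        rng = np.random.default_rng(0)
        idx = []
        for i in range(20):
            v = rng.uniform(0.3, 0.6)
            idx.append(
                make_indices(f"g{i}", gc1=v, gc2=v, gc3=rng.uniform(0.2, 0.5))
            )
        corr = pairwise_gc_correlations(idx)
        r, p = corr[("GC1", "GC2")]
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_independent_draws_are_uncorrelated(self):
        rng = np.random.default_rng(42)
        idx = [
            make_indices(
                f"g{i}",
                gc1=rng.uniform(0, 1),
                gc2=rng.uniform(0, 1),
                gc3=rng.uniform(0, 1),
            )
            for i in range(10_000)
        ]
        corr = pairwise_gc_correlations(idx)
        for r, _ in corr.values():
            assert abs(r) < 0.05

    def test_zero_variance_is_nan(self):
        idx = [make_indices(f"g{i}", gc1=0.4, gc2=0.1 * i, gc3=0.2 * i) for i in range(5)]
        corr = pairwise_gc_correlations(idx)
        assert math.isnan(corr[("GC1", "GC2")][0])
        assert not math.isnan(corr[("GC2", "GC3")][0])
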