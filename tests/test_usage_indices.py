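"""ENC, the expected-ENC curve, CAI and CBI/Fop."""

import math

import numpy as np
import pytest

from cpcodon.codon_stats import compute_rscu
from cpcodon.genetic_code import AA_TO_CODONS, SENSE_FAMILIES
from cpcodon.usage_indices import (
    cbi_fop,
    codon_adaptation_index,
    effective_number_of_codons,
    expected_enc,
    gene_l_aa,
    relative_adaptiveness,
)

from conftest import make_table


def brute_force_enc(table) -> float:
    """Independent direct evaluation of Wright's formulas.

    Per family with total n >= 2: F = (n * sum p^2 - 1)/(n - 1); class
    means over degeneracy 2/3/4/6; ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6,
    with F3 imputed as (F2+F4)/2 when missing or non-positive, other
    empty classes dropped with rescaling to the 20-amino-acid basis.
    """
    per_class = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in SENSE_FAMILIES.items():
        if aa in ("M", "W"):
            continue
        counts = [table.counts[c] for c in codons]
        n = sum(counts)
        if n < 2:
            continue
        f = (n * sum((x / n) ** 2 for x in counts) - 1) / (n - 1)
        per_class[len(codons)].append(f)
    means = {k: (np.mean(v) if v else None) for k, v in per_class.items()}
    if (means[3] is None or means[3] <= 0) and means[2] and means[4]:
        means[3] = (means[2] + means[4]) / 2
    n_fam = {2: 9, 3: 1, 4: 5, 6: 3}
    enc, n_aa = 2.0, 2
    for k, nf in n_fam.items():
        if means[k] is not None and means[k] > 0:
            enc += nf / means[k]
            n_aa += nf
    if n_aa < 20:
        enc *= 20 / n_aa
    return min(61.0, max(20.0, enc))


class TestEnc:
    def test_single_codon_per_amino_acid_gives_20(self, degenerate_table):
        assert effective_number_of_codons(degenerate_table) == pytest.approx(20.0)

    def test_uniform_usage_approaches_61(self, uniform_table):
        # exactly equal usage at ~10^4 codons: only the finite-n correction
        # keeps the estimator below the 61 ceiling
        assert effective_number_of_codons(uniform_table) == pytest.approx(
            61.0, abs=0.5
        )

    def test_toy_table_matches_brute_force_oracle(self):
        # one 2-fold family (3,1), one 4-fold (1,1,1,1); classes 3, 6 absent
        table = make_table({"TAT": 3, "TAC": 1, "GCT": 1, "GCC": 1, "GCA": 1, "GCG": 1})
        assert effective_number_of_codons(table) == pytest.approx(
            brute_force_enc(table), abs=1e-9
        )

    def test_random_tables_match_brute_force_oracle(self, random_count_table):
        for seed in range(5):
            table = random_count_table(seed, low=0, high=30)
            assert effective_number_of_codons(table) == pytest.approx(
                brute_force_enc(table), abs=1e-9
            )

    def test_scaling_counts_converges_to_infinite_sample_value(self):
        counts = {"TAT": 3, "TAC": 1, "GGT": 2, "GGC": 1, "GGA": 1, "GGG": 4}
        # infinite-sample ENC: F = sum p^2 without the finite-n correction
        f2 = (3 / 4) ** 2 + (1 / 4) ** 2
        f4 = (2 / 8) ** 2 + (1 / 8) ** 2 + (1 / 8) ** 2 + (4 / 8) ** 2
        f3 = (f2 + f4) / 2
        inf_enc = min(61.0, (2 + 9 / f2 + 1 / f3 + 5 / f4) * 20 / 17)
        deviations = []
        for m in (1, 10, 100):
            table = make_table({c: m * v for c, v in counts.items()})
            deviations.append(abs(effective_number_of_codons(table) - inf_enc))
        assert deviations[0] > deviations[1] > deviations[2]
        assert deviations[2] < 0.1

    def test_concentration_lowers_enc(self):
        # majorization within a 2-fold family: more concentrated -> lower ENC
        encs = [
            effective_number_of_codons(make_table({"TAT": a, "TAC": 100 - a}))
            for a in (50, 70, 90)
        ]
        assert encs[0] > encs[1] > encs[2]

    def test_no_usable_family_is_nan(self):
        assert math.isnan(effective_number_of_codons(make_table({"TAT": 1})))

    def test_split_sixfold_option(self):
        counts = {c: 10 for cods in AA_TO_CODONS.values() for c in cods}
        whole = effective_number_of_codons(make_table(counts))
        split = effective_number_of_codons(make_table(counts), split_sixfold=True)
        assert whole == pytest.approx(split, abs=1.0)  # both near 61
        assert split >= whole  # splitting never sees cross-box imbalance


class TestExpectedEnc:
    def test_closed_form_values(self):
        assert expected_enc(0.5) == pytest.approx(60.5)
        assert expected_enc(0.1) == pytest.approx(2.1 + 29 / (0.01 + 0.81))

    def test_symmetry_identity(self):
        for s in np.linspace(0.05, 0.95, 19):
            assert expected_enc(s) == pytest.approx(
                expected_enc(1 - s) - (1 - 2 * s)
            )

    @pytest.mark.parametrize("s", [0.0, 1.0, -0.1, 1.5])
    def test_domain_is_open_unit_interval(self, s):
        with pytest.raises(ValueError):
            expected_enc(s)


class TestCai:
    @pytest.fixture
    def reference(self, random_count_table):
        return compute_rscu(random_count_table(11, low=1, high=60))

    def test_gene_of_preferred_codons_scores_one(self, reference):
        w = relative_adaptiveness(reference)
        best = {}
        for aa, codons in AA_TO_CODONS.items():
            if aa in ("M", "W", "*"):
                continue
            best[max(codons, key=lambda c: w[c])] = 5
        assert codon_adaptation_index(make_table(best), reference) == pytest.approx(1.0)

    def test_matches_log_space_oracle(self, reference, random_count_table):
        gene = random_count_table(12, low=0, high=20)
        w = relative_adaptiveness(reference)
        logs = []
        for aa, codons in AA_TO_CODONS.items():
            if aa in ("M", "W", "*"):
                continue
            for c in codons:
                logs.extend([math.log(w[c])] * gene.counts[c])
        expected = math.exp(np.mean(logs))
        assert codon_adaptation_index(gene, reference) == pytest.approx(
            expected, abs=1e-12
        )

    def test_bounded_in_unit_interval(self, reference, random_count_table):
        for seed in range(5):
            cai = codon_adaptation_index(random_count_table(seed), reference)
            assert 0.0 < cai <= 1.0

    def test_no_eligible_codons_is_nan(self, reference):
        assert math.isnan(
            codon_adaptation_index(make_table({"ATG": 3, "TAA": 1}), reference)
        )


class TestCbiFop:
    def test_all_optimal_usage(self):
        table = make_table({"TAT": 10, "GCT": 5})
        cbi, fop = cbi_fop(table, {"TAT", "GCT"})
        assert fop == pytest.approx(1.0)
        assert cbi == pytest.approx(1.0)

    def test_random_usage_scores_zero_cbi(self):
        # exactly uniform within families: N_opt equals the random expectation
        table = make_table({c: 6 for c in AA_TO_CODONS["L"] + AA_TO_CODONS["Y"]})
        cbi, fop = cbi_fop(table, {"TTA", "TAT"})
        assert cbi == pytest.approx(0.0, abs=1e-9)
        assert fop == pytest.approx((6 + 6) / (36 + 12))

    def test_two_family_hand_case(self):
        # Tyr TAT=8, TAC=2 (TAT optimal); Ala GCT=1,GCC=1,GCA=1,GCG=1 (GCT optimal)
        table = make_table({"TAT": 8, "TAC": 2, "GCT": 1, "GCC": 1, "GCA": 1, "GCG": 1})
        n_opt, n_tot = 8 + 1, 10 + 4
        n_rand = 10 * (1 / 2) + 4 * (1 / 4)
        cbi, fop = cbi_fop(table, {"TAT", "GCT"})
        assert fop == pytest.approx(n_opt / n_tot)
        assert cbi == pytest.approx((n_opt - n_rand) / (n_tot - n_rand))

    def test_families_without_optimal_codon_ignored(self):
        table = make_table({"TAT": 4, "TAC": 6, "GGG": 100})
        _, fop = cbi_fop(table, {"TAT"})
        assert fop == pytest.approx(0.4)  # Gly plays no part

    def test_empty_optimal_set_is_error(self):
        with pytest.raises(ValueError):
            cbi_fop(make_table({"TAT": 1}), set())


def test_gene_l_aa_excludes_terminal_stop():
    assert gene_l_aa(make_table({"ATG": 1, "AAA": 10, "TAA": 1})) == 11
    assert gene_l_aa(make_table({"AAA": 5})) == 5
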