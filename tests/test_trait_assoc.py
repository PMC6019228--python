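"""Genotype-trait models, LD, and the four-locus miniature classifier."""

import itertools

import numpy as np
import pytest

from miniscan.genomics_io import TraitRecord
from miniscan.trait_assoc import (
    ceiling_check,
    fit_joint_additive,
    fit_single_locus,
    ld_r2,
    miniature_classifier,
)

LOCI = ["ADAMTS17", "OSTN", "GH1", "HMGA2"]


def records_from(genos, heights, loci=("L",)):
    out = []
    for i, (g, h) in enumerate(zip(genos, heights)):
        codes = dict(zip(loci, g if isinstance(g, (tuple, list)) else (g,)))
        out.append(TraitRecord(f"s{i}", float(h), genotypes=codes))
    return out


class TestSingleLocus:
    def test_zero_residual_class_means(self):
        genos = [0, 0, 1, 1, 2, 2]
        heights = [107, 107, 100, 100, 91, 91]
        res = fit_single_locus(records_from(genos, heights), "L")
        assert res.r_square == pytest.approx(1.0)
        assert np.isinf(res.f_value)
        assert res.p_value == 0.0
        assert res.lsmeans == {0: 107.0, 1: 100.0, 2: 91.0}
        assert all(se == 0.0 for se in res.lsmean_se.values())

    def test_known_anova_against_statsmodels(self, rng):
        """Cross-check R2/F/p against an independent OLS fit."""
        import statsmodels.formula.api as smf
        import pandas as pd

        genos = rng.choice([0, 1, 2], size=60)
        heights = 100 - 4 * genos + rng.normal(0, 3, size=60)
        res = fit_single_locus(records_from(genos, heights), "L")
        df = pd.DataFrame({"g": genos.astype(str), "y": heights})
        fit = smf.ols("y ~ C(g)", data=df).fit()
        assert res.r_square == pytest.approx(fit.rsquared, rel=1e-9)
        assert res.f_value == pytest.approx(fit.fvalue, rel=1e-9)
        assert res.p_value == pytest.approx(fit.f_pvalue, rel=1e-9)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="no variance"):
            fit_single_locus(records_from([1, 1, 1], [100, 101, 99]), "L")

    def test_null_type_one_error_rate(self):
        """Trait independent of genotype: p < 0.05 in roughly 5% of
        replicates."""
        rng = np.random.default_rng(12345)
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            genos = rng.choice([0, 1, 2], size=60)
            heights = rng.normal(100, 5, size=60)
            if len(np.unique(genos)) < 2:
                continue
            res = fit_single_locus(records_from(genos, heights), "L")
            if res.p_value < 0.05:
                rejections += 1
        rate = rejections / n_reps
        assert 0.02 < rate < 0.09  # 3 binomial SDs around 0.05

    def test_table_like_lsmean_recovery(self):
        """Cohort built with class means ~ (107.1, 100.4, 91.3), sd 5,
        n = 243: class means recovered within 1.5 cm (~2.6 class-mean
        standard errors) in >= 90% of replicates."""
        rng = np.random.default_rng(777)
        true_means = {0: 107.14, 1: 100.39, 2: 91.27}
        ok = 0
        n_reps = 40
        for _ in range(n_reps):
            genos = rng.choice([0, 1, 2], p=[0.3, 0.3, 0.4], size=243)
            heights = np.array([true_means[g] for g in genos]) + rng.normal(0, 5, 243)
            res = fit_single_locus(records_from(genos, heights), "L")
            if all(abs(res.lsmeans[g] - true_means[g]) < 1.5 for g in (0, 1, 2)):
                ok += 1
        assert ok / n_reps >= 0.9


class TestJointAdditive:
    def test_single_locus_additive_nesting(self, rng):
        genos = rng.choice([0, 1, 2], size=80)
        heights = 100 - 5 * (genos - 1) + rng.normal(0, 2, size=80)
        recs = records_from(genos, heights)
        model = fit_joint_additive(recs, ["L"])
        assert model.additive_cm["L"] == pytest.approx(-5, abs=1.0)
        single = fit_single_locus(recs, "L")
        assert model.r_square <= single.r_square + 1e-9

    def test_joint_r2_at_least_max_single(self, rng):
        n = 120
        G = rng.choice([0, 1, 2], size=(n, 4))
        heights = 100 + G @ np.array([-2.0, -1.5, -3.0, -2.74]) + rng.normal(0, 3, n)
        recs = records_from([tuple(r) for r in G], heights, loci=LOCI)
        joint = fit_joint_additive(recs, LOCI)
        singles = [fit_single_locus(recs, l).r_square for l in LOCI]
        assert joint.r_square >= max(singles) - 1e-9

    def test_effect_sum_recovery(self):
        from miniscan.evaluation import joint_model_recovery

        rate, estimate = joint_model_recovery(n_reps=50, seed=99)
        assert rate >= 0.9
        assert estimate == pytest.approx(18.48, abs=1.5)

    def test_null_effects_within_three_se(self, rng):
        n = 300
        G = rng.choice([0, 1, 2], size=(n, 4))
        heights = rng.normal(100, 3, size=n)
        recs = records_from([tuple(r) for r in G], heights, loci=LOCI)
        model = fit_joint_additive(recs, LOCI)
        for l in LOCI:
            assert abs(model.additive_cm[l]) < 3 * model.additive_se[l] + 1e-9

    def test_dominance_term_recovered(self, rng):
        n = 400
        g = rng.choice([0, 1, 2], size=n)
        heights = 100 - 4 * (g - 1) + 2.0 * (g == 1) + rng.normal(0, 1, n)
        recs = records_from(g, heights)
        model = fit_joint_additive(recs, ["L"], dominance_for=["L"])
        assert model.dominance_cm["L"] == pytest.approx(2.0, abs=0.5)

    def test_collinear_loci_raise(self):
        genos = [(0, 0), (1, 1), (2, 2), (1, 1), (0, 0), (2, 2)]
        recs = records_from(genos, [100, 98, 96, 99, 101, 95], loci=["A", "B"])
        with pytest.raises(ValueError, match="collinear|rank"):
            fit_joint_additive(recs, ["A", "B"])


class TestLdR2:
    def test_locus_against_itself_is_one(self):
        recs = records_from([(0, 0), (1, 1), (2, 2)], [100, 99, 98], loci=["A", "B"])
        assert ld_r2(recs, "A", "A") == pytest.approx(1.0)
        assert ld_r2(recs, "A", "B") == pytest.approx(1.0)

    def test_hand_computed_six_samples(self):
        a = [0, 1, 2, 2, 1, 0]
        b = [0, 1, 1, 2, 0, 0]
        recs = records_from(list(zip(a, b)), [100] * 6, loci=["A", "B"])
        cov = np.cov(a, b, ddof=1)
        expected = cov[0, 1] ** 2 / (cov[0, 0] * cov[1, 1])
        assert ld_r2(recs, "A", "B") == pytest.approx(expected)
        assert expected == pytest.approx(0.675, abs=0.001)

    def test_symmetric_and_coding_invariant(self, rng):
        g = rng.choice([0, 1, 2], size=(50, 2))
        recs = records_from([tuple(r) for r in g], [100] * 50, loci=["A", "B"])
        flipped = records_from(
            [(2 - r[0], r[1]) for r in g], [100] * 50, loci=["A", "B"]
        )
        assert ld_r2(recs, "A", "B") == pytest.approx(ld_r2(recs, "B", "A"))
        assert ld_r2(recs, "A", "B") == pytest.approx(ld_r2(flipped, "A", "B"))

    def test_independent_loci_near_zero(self, rng):
        g = rng.choice([0, 1, 2], size=(1000, 2))
        recs = records_from([tuple(r) for r in g], [100] * 1000, loci=["A", "B"])
        assert ld_r2(recs, "A", "B") < 0.01

    def test_monomorphic_locus_is_none(self):
        recs = records_from([(1, 0), (1, 1), (1, 2)], [1, 2, 3], loci=["A", "B"])
        assert ld_r2(recs, "A", "B") is None


class TestMiniatureClassifier:
    @pytest.mark.parametrize(
        "codes,expected",
        [
            ((2, 2, 2, 2), True),
            ((2, 2, 2, 1), True),
            ((1, 2, 2, 2), True),
            ((2, 2, 1, 1), False),
            ((2, 2, 2, 0), False),
            ((0, 0, 0, 0), False),
        ],
    )
    def test_rule(self, codes, expected):
        assert miniature_classifier(codes) is expected

    def test_truth_table_has_five_positive_cells(self):
        """Exhaustive enumeration of all 3^4 = 81 genotype combinations:
        exactly 5 are classified miniature (1 all-hom + 4 het placements)."""
        table = {c: miniature_classifier(c) for c in itertools.product((0, 1, 2), repeat=4)}
        positives = [c for c, v in table.items() if v]
        assert len(table) == 81
        assert len(positives) == 5
        assert tuple([2] * 4) in positives
        for i in range(4):
            c = [2] * 4
            c[i] = 1
            assert tuple(c) in positives

    def test_missing_code_raises(self):
        with pytest.raises(ValueError):
            miniature_classifier((2, 2, 2, -1))
        with pytest.raises(ValueError):
            miniature_classifier((2, 2, 2))


class TestCeilingCheck:
    def _rec(self, codes, height):
        return TraitRecord("x", height, genotypes=dict(zip(LOCI, codes)))

    def test_no_violation_below_ceiling(self):
        assert ceiling_check([self._rec((2, 2, 2, 2), 85.0)], LOCI) == []

    def test_violation_above_ceiling(self):
        out = ceiling_check([self._rec((2, 2, 2, 2), 90.0)], LOCI)
        assert len(out) == 1

    def test_non_miniature_tall_record_ignored(self):
        assert ceiling_check([self._rec((0, 0, 0, 0), 107.0)], LOCI) == []

    def test_synthetic_cohort_consistent_with_ceiling(self):
        """A cohort generated under a ceiling-consistent additive model
        (all-mutant mean far below 87 cm, small residual sd) produces no
        violations."""
        from miniscan.synthetic_data import CausalLocus, simulate_trait

        rng = np.random.default_rng(31415)
        loci = [CausalLocus(l, a) for l, a in zip(LOCI, (-2.0, -1.5, -3.0, -2.74))]
        genos = {
            f"p{i}": {l.name: int(rng.choice(3)) for l in loci} for i in range(400)
        }
        # mean chosen so the tallest classifier-positive combination
        # (three hom-mutant plus one het) sits >3 sd below the ceiling
        recs = simulate_trait(genos, loci, trait_mean=90.0, trait_sd=1.0, seed=11)
        assert ceiling_check(recs, LOCI) == []
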