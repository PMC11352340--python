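"""FPKM significance, tri-class functional classification, DE summary, fusions."""

from __future__ import annotations

import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import oligosig as og
from oligosig.expression import (
    DEThresholds,
    ExpressionClass,
    classify_variant_expression,
    compute_significance,
    de_summary,
    filter_cancer_fusions,
)
from oligosig.model import ExpressionProfile, FusionCandidate


def profile(gene="g", t=1.0, n=1.0, c=1.0, **p):
    return ExpressionProfile(gene, fpkm_t=t, fpkm_n=n, fpkm_c_mean=c, **p)


class TestSignificance:
    def test_matches_closed_form_t(self):
        """p for a tumor value far below tight controls equals the
        prediction-interval t formula computed independently."""
        controls = [19.0, 20.0, 21.0, 20.0, 20.0]
        prof = profile(t=0.1, n=20.0, c=20.0)
        compute_significance([prof], {"g": controls})
        ps = 0.1
        logs = [math.log2(v + ps) for v in controls]
        t_stat = (math.log2(0.1 + ps) - statistics.mean(logs)) / (
            statistics.stdev(logs) * math.sqrt(1 + 1 / 5)
        )
        expected = 2 * stats.t.sf(abs(t_stat), df=4)
        assert prof.p_t_vs_c == pytest.approx(expected)
        assert prof.p_t_vs_c < 0.05

    def test_value_equal_to_all_controls_has_p_one_under_permutation(self):
        prof = profile(t=20.0, n=20.0, c=20.0)
        compute_significance([prof], {"g": [20.0] * 6}, method="permutation")
        assert prof.p_t_vs_c == 1.0
        assert prof.p_t_vs_n == 1.0

    def test_identical_controls_give_degenerate_p(self):
        prof = profile(t=5.0, n=20.0, c=20.0)
        compute_significance([prof], {"g": [20.0, 20.0, 20.0]})
        assert prof.p_t_vs_c == 0.0  # zero spread, any deviation is extreme

    def test_too_few_controls_names_gene(self):
        with pytest.raises(ValueError, match="g1"):
            compute_significance([profile(gene="g1")], {"g1": [1.0]})

    def test_permutation_p_super_uniform_under_null(self):
        """Null permutation p-values are (super-)uniform: the fraction below
        alpha stays within Monte-Carlo error of alpha."""
        rng = np.random.default_rng(2024)
        n_genes, m = 2000, 60
        profs = []
        controls = {}
        for i in range(n_genes):
            base = float(rng.lognormal(3.0, 1.0))
            values = base * rng.lognormal(0.0, 0.3, size=m + 2)
            g = f"n{i}"
            profs.append(profile(gene=g, t=float(values[0]), n=float(values[1]),
                                 c=float(values[2:].mean())))
            controls[g] = [float(v) for v in values[2:]]
        compute_significance(profs, controls, method="permutation")
        frac = sum(p.p_t_vs_c < 0.05 for p in profs) / n_genes
        se = math.sqrt(0.05 * 0.95 / n_genes)
        assert frac <= 0.05 + 3 * se


class TestClassification:
    TH = DEThresholds()

    def classify(self, t, n, c, p_tn=1.0, p_tc=1.0, p_nc=1.0):
        prof = profile(t=t, n=n, c=c, p_t_vs_n=p_tn, p_t_vs_c=p_tc, p_n_vs_c=p_nc)
        return classify_variant_expression(prof, self.TH)

    def test_tumor_down_second_hit_pattern(self):
        assert self.classify(2, 20, 20, p_tn=0.01) is ExpressionClass.TUMOR_DOWN

    def test_tumor_up_oncogene_pattern(self):
        assert self.classify(30, 3, 3, p_tn=0.01) is ExpressionClass.TUMOR_UP

    def test_both_down_transcript_instability_pattern(self):
        assert self.classify(1, 1.2, 20, p_tc=0.01, p_nc=0.01) is ExpressionClass.BOTH_DOWN

    def test_no_change_pattern(self):
        assert self.classify(19, 20, 20) is ExpressionClass.NO_CHANGE

    def test_both_down_pre_empts_tumor_down(self):
        """When N is itself depressed, the T-vs-N contrast is uninformative."""
        cls = self.classify(1, 4, 40, p_tn=0.01, p_tc=0.01, p_nc=0.01)
        assert cls is ExpressionClass.BOTH_DOWN

    def test_fold_without_significance_is_no_change(self):
        assert self.classify(2, 20, 20, p_tn=0.2) is ExpressionClass.NO_CHANGE

    def test_missing_significance_is_error(self):
        with pytest.raises(ValueError, match="significance"):
            classify_variant_expression(profile(t=1, n=1, c=1))

    def test_classification_total_and_unique(self, example, example_report):
        """Every profiled candidate maps to exactly one class; counts sum."""
        counts = example_report.class_counts()
        profiled = [e for e in example_report.entries if e.expression_class]
        distinct = {e.key for e in profiled}
        assert sum(counts.values()) == len(distinct)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(scale=st.floats(0.5, 500.0), seed=st.integers(0, 10**6))
    def test_scale_invariance(self, scale, seed):
        """Multiplying all of a gene's FPKM values by a constant leaves its
        class unchanged (pseudocount small relative to the values, away
        from the significance decision boundary)."""
        from hypothesis import assume

        rng = np.random.default_rng(seed)
        t, n = float(rng.uniform(1, 50)), float(rng.uniform(1, 50))
        controls = [float(rng.uniform(5, 50)) for _ in range(5)]
        th = DEThresholds()

        def run(factor):
            prof = profile(t=t * factor, n=n * factor,
                           c=sum(controls) * factor / len(controls))
            compute_significance([prof], {"g": [c * factor for c in controls]}, th=th)
            return prof, classify_variant_expression(prof, th)

        base, base_cls = run(1.0)
        # borderline p-values flip with the (finite) pseudocount distortion
        assume(all(
            abs(p - th.alpha) > 0.02
            for p in (base.p_t_vs_n, base.p_t_vs_c, base.p_n_vs_c)
        ))
        assert base_cls == run(scale)[1]


class TestDeSummary:
    def test_fold_and_significance_rules(self):
        profs = [
            profile(gene="up", t=25, n=10, c=10, p_t_vs_n=0.01),
            profile(gene="weak", t=19, n=10, c=10, p_t_vs_n=0.01),  # below fold
            profile(gene="down", t=4, n=10, c=10, p_t_vs_n=0.01),
            profile(gene="ns", t=40, n=10, c=10, p_t_vs_n=0.2),     # not significant
        ]
        up, down = de_summary(profs)
        assert up == ["up"]
        assert down == ["down"]

    def test_recovers_planted_de_truth(self):
        cfg = og.SimulationConfig(
            seed=9, n_pairs=1, n_background_variants=50,
            n_private_deleterious=0, n_loh=0, n_somatic=5,
            n_de_up=50, n_de_down=40, n_expression_null=910,
            log_sigma=0.0, expression_fold=4.0,
        )
        _, expression, truth = og.simulate_cohort(cfg)
        compute_significance(expression.profiles, expression.controls)
        up, down = de_summary(expression.profiles)
        want_up = {g for g, d in truth.de_direction.items() if d == "up"}
        want_down = {g for g, d in truth.de_direction.items() if d == "down"}
        assert set(up) == want_up
        assert set(down) == want_down


class TestFusions:
    @pytest.mark.parametrize(
        "tumor_reads,normal_reads,kept",
        [(12, 0, True), (12, 11, False), (8, 0, False), (10, 9, True)],
    )
    def test_cancer_specific_rule(self, tumor_reads, normal_reads, kept):
        fusion = FusionCandidate("A", "B", tumor_reads, normal_reads)
        assert bool(filter_cancer_fusions([fusion])) is kept
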