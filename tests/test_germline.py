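"""Prioritization cascade: stage rules, audit trace, brute-force equivalence."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oligosig as og
from oligosig.germline import (
    FilterConfig,
    filter_benign_and_inhouse,
    filter_cancer_genes,
    filter_coverage,
    filter_deleterious,
    filter_discordant,
    filter_exonic_rare,
    run_cascade,
)
from oligosig.model import EXONIC_CONSEQUENCES, TRUNCATING_CONSEQUENCES, GenotypeCall, SibPairDataset, VariantRecord

from conftest import random_pair


def make_variant(**kw) -> VariantRecord:
    defaults = dict(
        chrom="chr1",
        pos=100,
        ref="G",
        alt="A",
        gene="MEN1",
        consequence="nonsynonymous_snv",
        genotype=GenotypeCall("het", alt_depth=10, ref_depth=10),
        depth=25,
        maf=0.001,
        cadd_phred=30.0,
        metasvm="D",
    )
    defaults.update(kw)
    return VariantRecord(**defaults)


CFG = FilterConfig(cancer_genes=frozenset({"MEN1", "TP73"}))


def brute_force_keep(v: VariantRecord, cfg: FilterConfig, unaffected_by_key) -> bool:
    """Single-pass conjunction of all six default predicates (oracle)."""
    if v.depth < cfg.min_depth:
        return False
    if v.consequence not in EXONIC_CONSEQUENCES:
        return False
    if v.maf is None:
        if not cfg.keep_absent_maf:
            return False
    elif v.maf > cfg.max_maf:
        return False
    if v.clinsig in ("benign", "likely_benign") or v.key in cfg.inhouse_db:
        return False
    if v.consequence == "synonymous":
        return False
    if v.consequence not in TRUNCATING_CONSEQUENCES:
        if v.consequence != "nonsynonymous_snv":
            return False
        if v.cadd_phred is None or v.cadd_phred < cfg.cadd_min:
            return False
        if cfg.require_metasvm_d and v.metasvm != "D":
            return False
    match = unaffected_by_key.get(v.key)
    if match is not None and not (
        match.genotype.state == "hom_ref" and match.depth >= cfg.min_depth
    ):
        return False
    return v.gene.upper() in cfg.cancer_genes


class TestStages:
    @pytest.mark.parametrize(
        "depth,min_depth,kept",
        [(9, 10, False), (10, 10, True), (0, 0, True)],
    )
    def test_coverage_threshold_inclusive(self, depth, min_depth, kept):
        cfg = FilterConfig(min_depth=min_depth)
        gt = GenotypeCall("het", alt_depth=0, ref_depth=0)
        out = filter_coverage([make_variant(depth=depth, genotype=gt)], cfg)
        assert bool(out) is kept

    @pytest.mark.parametrize(
        "maf,consequence,kept",
        [
            (0.02, "nonsynonymous_snv", False),   # above rarity threshold
            (None, "nonsynonymous_snv", True),    # unreported frequency counts as rare
            (0.001, "noncoding", False),          # exonic requirement
            (0.01, "synonymous", True),           # boundary inclusive, exonic
        ],
    )
    def test_exonic_rare(self, maf, consequence, kept):
        out = filter_exonic_rare([make_variant(maf=maf, consequence=consequence)], CFG)
        assert bool(out) is kept

    def test_absent_maf_dropped_when_disabled(self):
        cfg = FilterConfig(keep_absent_maf=False)
        assert filter_exonic_rare([make_variant(maf=None)], cfg) == []

    @pytest.mark.parametrize("clinsig,kept", [("likely_benign", False), ("benign", False), ("other", True), (None, True)])
    def test_benign_filter(self, clinsig, kept):
        out = filter_benign_and_inhouse([make_variant(clinsig=clinsig)], CFG)
        assert bool(out) is kept

    def test_inhouse_db_hit_removed(self):
        v = make_variant()
        cfg = FilterConfig(inhouse_db=frozenset({v.key}))
        assert filter_benign_and_inhouse([v], cfg) == []

    @pytest.mark.parametrize(
        "consequence,cadd,svm,kept",
        [
            ("nonsense", None, None, True),          # truncating passes without scores
            ("frameshift_indel", None, None, True),
            ("nonsynonymous_snv", 25.0, "D", True),  # both scores pass
            ("nonsynonymous_snv", 25.0, "T", False), # conjunction fails
            ("nonsynonymous_snv", 15.0, "D", False),
            ("synonymous", 35.0, "D", False),        # synonymous never retained
            ("other_exonic", 35.0, "D", False),
        ],
    )
    def test_deleterious_default_rule(self, consequence, cadd, svm, kept):
        v = make_variant(consequence=consequence, cadd_phred=cadd, metasvm=svm)
        assert bool(filter_deleterious([v], CFG)) is kept

    def test_deleterious_partition(self):
        variants = [
            make_variant(pos=i, consequence=c, cadd_phred=cadd, metasvm=svm)
            for i, (c, cadd, svm) in enumerate(
                [
                    ("nonsense", None, None),
                    ("frameshift_indel", None, None),
                    ("nonsynonymous_snv", 30.0, "D"),
                    ("nonsynonymous_snv", 10.0, "T"),
                    ("synonymous", 30.0, "D"),
                ],
                start=1,
            )
        ]
        kept = filter_deleterious(variants, CFG)
        trunc = [v for v in kept if v.consequence in TRUNCATING_CONSEQUENCES]
        nonsyn = [v for v in kept if v.consequence == "nonsynonymous_snv"]
        assert len(kept) == len(trunc) + len(nonsyn)
        assert not set(v.key for v in trunc) & set(v.key for v in nonsyn)

    def test_alternate_score_rules(self):
        v = make_variant(cadd_phred=25.0, metasvm="T")
        assert filter_deleterious([v], FilterConfig(deleterious_rule="cadd_or_svm"))
        assert not filter_deleterious([v], FilterConfig(deleterious_rule="cadd_and_svm"))


class TestDiscordance:
    def pair(self, affected, unaffected):
        return SibPairDataset("c", affected, unaffected)

    def test_private_variant_retained(self):
        v = make_variant()
        assert filter_discordant(self.pair([v], []), CFG) == [v]

    def test_shared_het_removed(self):
        v = make_variant()
        assert filter_discordant(self.pair([v], [v]), CFG) == []

    def test_confident_hom_ref_counts_as_absent(self):
        v = make_variant()
        ref_call = v.with_genotype(GenotypeCall("hom_ref", 0, 20), depth=20)
        assert filter_discordant(self.pair([v], [ref_call]), CFG) == [v]

    def test_shallow_hom_ref_cannot_confirm_absence(self):
        v = make_variant()
        ref_call = v.with_genotype(GenotypeCall("hom_ref", 0, 5), depth=5)
        assert filter_discordant(self.pair([v], [ref_call]), CFG) == []

    def test_protective_direction_screens_unaffected(self):
        v = make_variant()
        cfg = FilterConfig(direction="unaffected_only")
        assert filter_discordant(self.pair([], [v]), cfg) == [v]


class TestCascade:
    def test_trace_counts_consistent(self):
        pair = random_pair(7)
        cfg = FilterConfig(cancer_genes=frozenset(f"G{i}" for i in range(20)))
        _, trace = run_cascade(pair, cfg)
        assert [s.stage for s in trace.stages] == [
            "coverage", "exonic_rare", "benign_inhouse",
            "deleterious", "discordant", "cancer_panel",
        ]
        for stage in trace.stages:
            assert stage.n_in - stage.n_out == len(stage.removed)
        outs = [s.n_out for s in trace.stages]
        ins = [s.n_in for s in trace.stages]
        assert ins[1:] == outs[:-1]
        assert all(a >= b for a, b in zip(ins, outs))

    def test_candidates_sorted_and_deterministic(self):
        pair = random_pair(11)
        cfg = FilterConfig(cancer_genes=frozenset(f"G{i}" for i in range(40)))
        c1, _ = run_cascade(pair, cfg)
        c2, _ = run_cascade(pair, cfg)
        assert [v.key for v in c1] == [v.key for v in c2]
        assert c1 == sorted(c1, key=lambda v: (int(v.chrom[3:]), v.pos, v.alt))

    def test_empty_panel_is_configuration_error(self):
        pair = random_pair(3)
        with pytest.raises(ValueError, match="panel"):
            run_cascade(pair, FilterConfig())

    def test_nothing_planted_nothing_found(self, example):
        """A pair whose affected table is all decoys yields no candidates."""
        clean = SibPairDataset("c", [], [])
        cfg = FilterConfig(cancer_genes=frozenset({"MEN1"}))
        candidates, _ = run_cascade(clean, cfg)
        assert candidates == []

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_cascade_equals_brute_force(self, seed):
        """The staged funnel equals a single-pass predicate conjunction."""
        pair = random_pair(seed)
        cfg = FilterConfig(
            cancer_genes=frozenset(f"G{i}" for i in range(25)),
            inhouse_db=frozenset(v.key for v in pair.affected_variants[::17]),
        )
        unaffected = {r.key: r for r in pair.unaffected_variants}
        expected = {
            v.key
            for v in pair.affected_variants
            if brute_force_keep(v, cfg, unaffected)
        }
        candidates, _ = run_cascade(pair, cfg)
        assert {v.key for v in candidates} == expected

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_commuting_stage_order(self, seed):
        """Coverage / exonic-rare / benign stages commute arbitrarily."""
        pair = random_pair(seed)
        cfg = FilterConfig(cancer_genes=frozenset(f"G{i}" for i in range(25)))
        stages = [filter_coverage, filter_exonic_rare, filter_benign_and_inhouse]
        results = []
        import itertools

        for order in itertools.permutations(stages):
            current = list(pair.affected_variants)
            for fn in order:
                current = fn(current, cfg)
            results.append({v.key for v in current})
        assert all(r == results[0] for r in results)
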