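"""Shared fixtures: the worked example, its cascade output, random tables."""

from __future__ import annotations

import numpy as np
import pytest

import oligosig as og
from oligosig.model import GenotypeCall, SibPairDataset, VariantRecord

CONSEQUENCE_POOL = (
    "nonsynonymous_snv",
    "frameshift_indel",
    "nonsense",
    "synonymous",
    "other_exonic",
    "noncoding",
)


@pytest.fixture(scope="session")
def example():
    return og.load_worked_example()


@pytest.fixture(scope="session")
def example_filter_cfg(example):
    return og.FilterConfig(
        cancer_genes=frozenset(example.cancer_genes),
        inhouse_db=frozenset(example.inhouse_db),
    )


@pytest.fixture(scope="session")
def example_candidates(example, example_filter_cfg):
    """Per-case cascade output on the worked example."""
    return {
        pair.case_id: og.run_cascade(pair, example_filter_cfg)[0]
        for pair in example.cohort
    }


@pytest.fixture(scope="session")
def example_report(example, example_candidates):
    og.compute_significance(example.profiles, example.control_samples)
    report = og.integrate_candidates(
        example_candidates,
        example.profiles,
        retain_no_change=example.retain_no_change,
    )
    loh = {}
    for pair in example.cohort:
        calls = og.detect_loh(example_candidates[pair.case_id], pair.tumor_variants)
        loh[pair.case_id] = [c.key for c in calls if c.is_loh]
    report.attach_loh(loh)
    return report


def random_variant(rng: np.random.Generator, index: int, genes: list[str]) -> VariantRecord:
    """A variant with attributes drawn across all filter-relevant ranges."""
    consequence = CONSEQUENCE_POOL[int(rng.integers(len(CONSEQUENCE_POOL)))]
    depth = int(rng.integers(0, 60))
    alt = int(rng.binomial(depth, 0.5)) if depth else 0
    state = ("het", "hom_alt", "hom_ref", "missing")[int(rng.integers(4))]
    ref_base, alt_base = ("A", "T") if rng.random() < 0.5 else ("G", "C")
    return VariantRecord(
        chrom=f"chr{int(rng.integers(1, 23))}",
        pos=1000 + index,
        ref=ref_base,
        alt=alt_base,
        gene=genes[int(rng.integers(len(genes)))],
        consequence=consequence,
        genotype=GenotypeCall(state, alt_depth=alt, ref_depth=max(depth - alt, 0)),
        depth=depth,
        maf=None if rng.random() < 0.3 else float(rng.uniform(0, 0.05)),
        cadd_phred=None if rng.random() < 0.3 else float(rng.uniform(0, 40)),
        metasvm=(None, "D", "T")[int(rng.integers(3))],
        clinsig=(None, "benign", "likely_benign", "other")[int(rng.integers(4))],
    )


def random_pair(seed: int, n: int = 300) -> SibPairDataset:
    """A random sib pair whose tables overlap roughly half the time."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(40)]
    affected = [random_variant(rng, i, genes) for i in range(n)]
    unaffected = []
    for i, rec in enumerate(affected):
        if rng.random() < 0.5:
            unaffected.append(rec)
        elif rng.random() < 0.2:
            state = ("hom_ref", "het")[int(rng.integers(2))]
            depth = int(rng.integers(0, 40))
            unaffected.append(
                rec.with_genotype(GenotypeCall(state, 0, min(depth, rec.depth)),
                                  depth=depth)
            )
    # some sib-private extras
    unaffected.extend(random_variant(rng, n + i, genes) for i in range(n // 10))
    return SibPairDataset("rnd", affected, unaffected)
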