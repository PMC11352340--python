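"""Germline variant prioritization cascade for discordant sib pairs.

The cascade reduces a patient's raw annotated exome table to private, rare,
deleterious candidates in cancer-predisposition genes, in six stages:

1. coverage      — drop calls below a minimum read depth
2. exonic_rare   — keep exonic consequences with MAF <= threshold or unreported
3. benign_inhouse— drop benign/likely-benign calls and in-house database hits
4. deleterious   — keep truncating variants, and missense passing CADD+MetaSVM
5. discordant    — keep variants absent (or confidently hom-ref) in the sibling
6. cancer_panel  — keep variants in a cancer-predisposition gene panel

Every stage records input/output counts and the removed keys in a
:class:`FilterTrace`, reproducing the funnel a reviewer audits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from .model import (
    EXONIC_CONSEQUENCES,
    TRUNCATING_CONSEQUENCES,
    SibPairDataset,
    VariantRecord,
)

__all__ = ["FilterConfig", "FilterStage", "FilterTrace", "run_cascade",
           "filter_coverage", "filter_exonic_rare", "filter_benign_and_inhouse",
           "filter_deleterious", "filter_discordant", "filter_cancer_genes",
           "pool_candidates", "shared_candidates"]

Key = tuple[str, int, str, str]


@dataclass(slots=True)
class FilterConfig:
    """Thresholds and resources driving the cascade.

    min_depth:
        Minimum total read depth for a trustworthy call (default 10).
    max_maf:
        Rarity threshold on population minor allele frequency (default 0.01).
    keep_absent_maf:
        Treat an unreported MAF as rare (default True).
    cadd_min:
        CADD scaled-score cutoff for missense variants (default 20, the
        conventional top-1% deleteriousness band).
    require_metasvm_d:
        Additionally require a MetaSVM "D" call for missense (default True).
    deleterious_rule:
        ``truncating_or_scores`` (default): truncating variants pass
        unconditionally, missense must pass the score rule(s);
        ``cadd_or_svm`` / ``cadd_and_svm``: apply the score disjunction /
        conjunction to all non-synonymous exonic variants.
    direction:
        ``affected_only`` keeps variants private to the patient;
        ``unaffected_only`` is the symmetric protective screen.
    """

    min_depth: int = 10
    max_maf: float = 0.01
    keep_absent_maf: bool = True
    cadd_min: float = 20.0
    require_metasvm_d: bool = True
    deleterious_rule: str = "truncating_or_scores"
    direction: str = "affected_only"
    inhouse_db: frozenset[Key] = field(default_factory=frozenset)
    cancer_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_maf <= 1.0:
            raise ValueError("max_maf must lie in [0,1]")
        if self.deleterious_rule not in ("truncating_or_scores", "cadd_or_svm", "cadd_and_svm"):
            raise ValueError(f"unknown deleterious_rule {self.deleterious_rule!r}")
        if self.direction not in ("affected_only", "unaffected_only"):
            raise ValueError(f"unknown direction {self.direction!r}")
        self.inhouse_db = frozenset(self.inhouse_db)
        self.cancer_genes = frozenset(g.upper() for g in self.cancer_genes)


@dataclass(slots=True)
class FilterStage:
    """Audit record for one cascade stage."""

    stage: str
    n_in: int
    n_out: int
    removed: list[Key]
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_in - self.n_out != len(self.removed):
            raise ValueError(
                f"stage {self.stage}: {self.n_in} - {self.n_out} != {len(self.removed)} removed"
            )


@dataclass(slots=True)
class FilterTrace:
    """Ordered per-stage audit trail of the funnel."""

    stages: list[FilterStage] = field(default_factory=list)

    def record(self, stage: str, before: Sequence[VariantRecord],
               after: Sequence[VariantRecord], **detail) -> None:
        kept = {r.key for r in after}
        removed = [r.key for r in before if r.key not in kept]
        self.stages.append(FilterStage(stage, len(before), len(after), removed, dict(detail)))

    def as_rows(self) -> list[dict]:
        return [
            {"stage": s.stage, "n_in": s.n_in, "n_out": s.n_out, "n_removed": len(s.removed)}
            for s in self.stages
        ]

    def to_json_obj(self) -> list[dict]:
        return [
            {
                "stage": s.stage,
                "n_in": s.n_in,
                "n_out": s.n_out,
                "removed": [list(k) for k in s.removed],
                "detail": s.detail,
            }
            for s in self.stages
        ]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def filter_coverage(variants: Iterable[VariantRecord], cfg: FilterConfig) -> list[VariantRecord]:
    """Keep calls with total read depth >= cfg.min_depth (boundary inclusive)."""
    return [v for v in variants if v.depth >= cfg.min_depth]


def filter_exonic_rare(variants: Iterable[VariantRecord], cfg: FilterConfig) -> list[VariantRecord]:
    """Keep exonic variants that are rare or have no reported frequency."""

    def rare(v: VariantRecord) -> bool:
        if v.maf is None:
            return cfg.keep_absent_maf
        return v.maf <= cfg.max_maf

    return [v for v in variants if v.consequence in EXONIC_CONSEQUENCES and rare(v)]


def filter_benign_and_inhouse(
    variants: Iterable[VariantRecord], cfg: FilterConfig
) -> list[VariantRecord]:
    """Drop benign / likely-benign calls and in-house database hits."""
    return [
        v
        for v in variants
        if v.clinsig not in ("benign", "likely_benign") and v.key not in cfg.inhouse_db
    ]


def _passes_scores(v: VariantRecord, cfg: FilterConfig, rule: str) -> bool:
    has_cadd = v.cadd_phred is not None and v.cadd_phred >= cfg.cadd_min
    has_svm = v.metasvm == "D"
    if rule == "cadd_or_svm":
        return has_cadd or has_svm
    # conjunction; MetaSVM leg can be disabled
    if cfg.require_metasvm_d:
        return has_cadd and has_svm
    return has_cadd


def is_deleterious(v: VariantRecord, cfg: FilterConfig) -> bool:
    """Predicate behind the deleterious stage (exposed for oracle tests)."""
    if v.consequence == "synonymous" or v.consequence not in EXONIC_CONSEQUENCES:
        return False
    if cfg.deleterious_rule == "truncating_or_scores":
        if v.consequence in TRUNCATING_CONSEQUENCES:
            return True
        if v.consequence != "nonsynonymous_snv":
            return False
        return _passes_scores(v, cfg, "cadd_and_svm")
    return _passes_scores(v, cfg, cfg.deleterious_rule)


def filter_deleterious(variants: Iterable[VariantRecord], cfg: FilterConfig) -> list[VariantRecord]:
    """Keep predicted-deleterious variants; synonymous never survive.

    Under the default rule, protein-truncating variants (frameshift indels
    and nonsense) pass unconditionally — ensemble missense scores are
    undefined for them — while missense variants need CADD >= cadd_min and,
    when required, a MetaSVM "D" call.
    """
    return [v for v in variants if is_deleterious(v, cfg)]


def filter_discordant(
    pair: SibPairDataset,
    cfg: FilterConfig,
    variants: Optional[Sequence[VariantRecord]] = None,
) -> list[VariantRecord]:
    """Keep variants private to one sib.

    With direction ``affected_only`` (default) a variant survives when its
    key is absent from the unaffected table, or present there as a hom-ref
    call whose site depth is >= cfg.min_depth (a confident reference call).
    A hom-ref record below that depth cannot confirm absence and the
    variant is dropped. ``unaffected_only`` is the symmetric screen for
    putative protective alleles.
    """
    if cfg.direction == "affected_only":
        query = pair.affected_variants if variants is None else list(variants)
        other = pair.unaffected_variants
        if other is None:
            raise ValueError(f"case {pair.case_id}: unaffected table missing")
    else:
        query = pair.unaffected_variants if variants is None else list(variants)
        other = pair.affected_variants
        if other is None:
            raise ValueError(f"case {pair.case_id}: affected table missing")
    other_by_key = {r.key: r for r in other}

    def private(v: VariantRecord) -> bool:
        match = other_by_key.get(v.key)
        if match is None:
            return True
        if match.genotype.state == "hom_ref":
            return match.depth >= cfg.min_depth
        return False

    return [v for v in query if private(v)]


def filter_cancer_genes(variants: Iterable[VariantRecord], cfg: FilterConfig) -> list[VariantRecord]:
    """Keep variants in panel genes (case-insensitive symbol match)."""
    if not cfg.cancer_genes:
        raise ValueError("cancer gene panel is empty; configure cfg.cancer_genes")
    return [v for v in variants if v.gene.upper() in cfg.cancer_genes]


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

_CHROM_ORDER = {f"chr{i}": i for i in range(1, 23)} | {"chrX": 23, "chrY": 24, "chrM": 25}


def _sort_key(v: VariantRecord) -> tuple:
    return (_CHROM_ORDER.get(v.chrom, 99), v.chrom, v.pos, v.alt)


def run_cascade(
    pair: SibPairDataset, cfg: FilterConfig
) -> tuple[list[VariantRecord], FilterTrace]:
    """Run all six stages on one sib pair; returns sorted candidates + trace."""
    trace = FilterTrace()
    current = list(
        pair.affected_variants if cfg.direction == "affected_only" else pair.unaffected_variants
    )

    nxt = filter_coverage(current, cfg)
    trace.record("coverage", current, nxt, min_depth=cfg.min_depth)
    current = nxt

    nxt = filter_exonic_rare(current, cfg)
    trace.record("exonic_rare", current, nxt, max_maf=cfg.max_maf)
    current = nxt

    nxt = filter_benign_and_inhouse(current, cfg)
    trace.record("benign_inhouse", current, nxt, inhouse_db_size=len(cfg.inhouse_db))
    current = nxt

    nxt = filter_deleterious(current, cfg)
    n_trunc = sum(1 for v in nxt if v.consequence in TRUNCATING_CONSEQUENCES)
    trace.record(
        "deleterious",
        current,
        nxt,
        rule=cfg.deleterious_rule,
        n_truncating=n_trunc,
        n_nonsynonymous=len(nxt) - n_trunc,
    )
    current = nxt

    nxt = filter_discordant(pair, cfg, variants=current)
    trace.record("discordant", current, nxt, direction=cfg.direction)
    current = nxt

    nxt = filter_cancer_genes(current, cfg)
    trace.record("cancer_panel", current, nxt, panel_size=len(cfg.cancer_genes))

    return sorted(nxt, key=_sort_key), trace


def pool_candidates(per_case: dict[str, Sequence[VariantRecord]]) -> dict[Key, set[str]]:
    """Map each distinct candidate key to the set of cases carrying it."""
    pooled: dict[Key, set[str]] = {}
    for case_id, records in per_case.items():
        for rec in records:
            pooled.setdefault(rec.key, set()).add(case_id)
    return pooled


def shared_candidates(per_case: dict[str, Sequence[VariantRecord]], min_cases: int = 2) -> dict[Key, set[str]]:
    """Candidate keys observed in at least ``min_cases`` different cases."""
    return {k: cases for k, cases in pool_candidates(per_case).items() if len(cases) >= min_cases}
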