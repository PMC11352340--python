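"""Domain types for the sib-pair oligogenic-signature analysis.

The analysis compares annotated germline exome variant tables between an
affected patient and an unaffected full sibling, adds the patient's tumor
variant table for somatic/LOH work, and a per-gene FPKM expression table
with tumor (T), matched normal (N) and control-normal-group (C) roles.

Missing annotations are modelled as ``None`` (an explicit absent state),
never as 0: an unreported population frequency must stay distinguishable
from a rare one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "CONSEQUENCES",
    "EXONIC_CONSEQUENCES",
    "TRUNCATING_CONSEQUENCES",
    "GenotypeCall",
    "VariantRecord",
    "SibPairDataset",
    "ExpressionProfile",
    "FusionCandidate",
    "variant_key",
]

#: Recognized functional consequence labels for a variant call.
CONSEQUENCES = frozenset(
    {
        "nonsynonymous_snv",
        "frameshift_indel",
        "nonsense",
        "synonymous",
        "other_exonic",
        "noncoding",
    }
)

#: Consequences located in coding exons (retained by the exonic filter).
EXONIC_CONSEQUENCES = frozenset(
    {"nonsynonymous_snv", "frameshift_indel", "nonsense", "synonymous", "other_exonic"}
)

#: Protein-truncating consequences (frameshifting indels and stop gains).
TRUNCATING_CONSEQUENCES = frozenset({"frameshift_indel", "nonsense"})

_GT_STATES = frozenset({"hom_ref", "het", "hom_alt", "missing"})
_METASVM = frozenset({"D", "T"})
_CLINSIG = frozenset({"benign", "likely_benign", "other"})


@dataclass(frozen=True, slots=True)
class GenotypeCall:
    """Zygosity of one variant in one sample, with supporting read depths."""

    state: str
    alt_depth: int = 0
    ref_depth: int = 0

    def __post_init__(self) -> None:
        if self.state not in _GT_STATES:
            raise ValueError(f"unknown genotype state {self.state!r}")
        if self.alt_depth < 0 or self.ref_depth < 0:
            raise ValueError("allele depths must be non-negative")

    @property
    def alt_fraction(self) -> Optional[float]:
        """Alt allele fraction, or None when no allele-depth reads exist."""
        total = self.alt_depth + self.ref_depth
        if total == 0:
            return None
        return self.alt_depth / total


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One annotated variant call in one subject.

    Coordinates are 1-based, VCF convention; ``maf``, ``cadd_phred``,
    ``metasvm`` and ``clinsig`` may be None when the annotation source did
    not report them. ``hgvs`` optionally carries a human-readable mutation
    label (cDNA/protein notation) used in reports.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    genotype: GenotypeCall
    depth: int = 0
    maf: Optional[float] = None
    cadd_phred: Optional[float] = None
    metasvm: Optional[str] = None
    clinsig: Optional[str] = None
    hgvs: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"maf out of [0,1]: {self.maf}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"cadd_phred must be >= 0: {self.cadd_phred}")
        if self.metasvm is not None and self.metasvm not in _METASVM:
            raise ValueError(f"metasvm must be D/T/None, got {self.metasvm!r}")
        if self.clinsig is not None and self.clinsig not in _CLINSIG:
            raise ValueError(f"unknown clinsig {self.clinsig!r}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.genotype.alt_depth + self.genotype.ref_depth > self.depth:
            raise ValueError(
                f"allele depths exceed total depth at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Site/allele identity used for cross-table comparison."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def with_genotype(self, genotype: GenotypeCall, depth: Optional[int] = None) -> "VariantRecord":
        return replace(self, genotype=genotype, depth=self.depth if depth is None else depth)


def variant_key(record: VariantRecord) -> tuple[str, int, str, str]:
    return record.key


@dataclass(slots=True)
class SibPairDataset:
    """Paired germline tables for one discordant sib pair, plus tumor table.

    ``affected_variants`` and ``unaffected_variants`` come from blood DNA of
    the patient and the healthy sibling; ``tumor_variants`` (optional) from
    the patient's tumor tissue.
    """

    case_id: str
    affected_variants: list[VariantRecord]
    unaffected_variants: list[VariantRecord]
    tumor_variants: Optional[list[VariantRecord]] = None

    def __post_init__(self) -> None:
        for name in ("affected_variants", "unaffected_variants", "tumor_variants"):
            table = getattr(self, name)
            if table is None:
                continue
            seen: set[tuple[str, int, str, str]] = set()
            for rec in table:
                if rec.key in seen:
                    raise ValueError(
                        f"duplicate variant key {rec.key} in {name} of case {self.case_id}"
                    )
                seen.add(rec.key)


@dataclass(slots=True)
class ExpressionProfile:
    """Per-gene FPKM for tumor / matched normal / control-normal group.

    p-values are filled by :func:`oligosig.expression.compute_significance`
    and are None straight after reading a table.
    """

    gene: str
    fpkm_t: float
    fpkm_n: float
    fpkm_c_mean: float
    p_t_vs_n: Optional[float] = None
    p_n_vs_c: Optional[float] = None
    p_t_vs_c: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("fpkm_t", "fpkm_n", "fpkm_c_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 for gene {self.gene}")
        for name in ("p_t_vs_n", "p_n_vs_c", "p_t_vs_c"):
            p = getattr(self, name)
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} out of [0,1] for gene {self.gene}: {p}")


@dataclass(frozen=True, slots=True)
class FusionCandidate:
    """A candidate gene fusion with spanning-read support in T and N."""

    gene5: str
    gene3: str
    spanning_reads_tumor: int
    spanning_reads_normal: int

    def __post_init__(self) -> None:
        if self.gene5 == self.gene3:
            raise ValueError("fusion partners must differ")
        if self.spanning_reads_tumor < 0 or self.spanning_reads_normal < 0:
            raise ValueError("spanning read counts must be non-negative")
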