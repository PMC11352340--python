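"""Blood-vs-tumor comparison: somatic calls, class tallies, and LOH.

Somatic extraction is deliberate table subtraction, not probabilistic
calling: a tumor variant is somatic when its key is absent from the blood
table (or hom-ref there). Loss of heterozygosity is called at germline
candidate loci that are heterozygous in blood but effectively homozygous
for the alternate allele in tumor — either by genotype state or, when
allele depths are available, by a tumor alt-allele fraction at or above
``min_hom_af`` (default 0.8, tolerating some normal-cell contamination).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import GenotypeCall, VariantRecord

__all__ = ["SomaticTally", "LohCall", "call_somatic", "tally_somatic", "detect_loh"]

#: Consequences counted as coding in the tally.
_CODING = frozenset(
    {"nonsynonymous_snv", "frameshift_indel", "nonsense", "synonymous", "other_exonic"}
)


@dataclass(frozen=True, slots=True)
class SomaticTally:
    """Counts of somatic variants overall and by coding mutation class."""

    total: int
    coding: int
    missense: int
    frameshift_indel: int
    nonsense: int

    def __post_init__(self) -> None:
        if self.coding > self.total:
            raise ValueError("coding count exceeds total")
        if self.missense + self.frameshift_indel + self.nonsense > self.coding:
            raise ValueError("class counts exceed coding count")

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "coding": self.coding,
            "missense": self.missense,
            "frameshift_indel": self.frameshift_indel,
            "nonsense": self.nonsense,
        }


@dataclass(frozen=True, slots=True)
class LohCall:
    """Zygosity comparison at one germline candidate locus."""

    key: tuple[str, int, str, str]
    gene: str
    blood_state: GenotypeCall
    tumor_state: GenotypeCall
    is_loh: bool
    tumor_alt_fraction: Optional[float]


def call_somatic(
    blood: Sequence[VariantRecord], tumor: Sequence[VariantRecord]
) -> list[VariantRecord]:
    """Tumor variants not attributable to the germline.

    A tumor record is somatic when its (chrom, pos, ref, alt) key is absent
    from the blood table or present only as a hom-ref call.
    """
    germline_keys = {
        r.key for r in blood if r.genotype.state in ("het", "hom_alt", "missing")
    }
    return [t for t in tumor if t.key not in germline_keys]


def tally_somatic(somatic: Iterable[VariantRecord]) -> SomaticTally:
    """Count somatic variants by coding mutation class."""
    total = coding = missense = fs = nonsense = 0
    for v in somatic:
        total += 1
        if v.consequence in _CODING:
            coding += 1
        if v.consequence == "nonsynonymous_snv":
            missense += 1
        elif v.consequence == "frameshift_indel":
            fs += 1
        elif v.consequence == "nonsense":
            nonsense += 1
    return SomaticTally(total, coding, missense, fs, nonsense)


def detect_loh(
    candidates: Sequence[VariantRecord],
    tumor: Sequence[VariantRecord],
    min_hom_af: float = 0.8,
) -> list[LohCall]:
    """Zygosity-shift LOH at germline candidate loci.

    ``is_loh`` is True iff the blood genotype is heterozygous and the tumor
    genotype is homozygous-alt — satisfied by the recorded genotype state or
    by a tumor alt-allele fraction >= min_hom_af when allele depths exist.
    A candidate with no matching tumor record yields is_loh False with a
    ``missing`` tumor state.
    """
    if not 0.5 < min_hom_af <= 1.0:
        raise ValueError(f"min_hom_af must lie in (0.5, 1], got {min_hom_af}")
    tumor_by_key = {t.key: t for t in tumor}
    calls: list[LohCall] = []
    for cand in candidates:
        match = tumor_by_key.get(cand.key)
        if match is None:
            calls.append(
                LohCall(cand.key, cand.gene, cand.genotype, GenotypeCall("missing"), False, None)
            )
            continue
        af = match.genotype.alt_fraction
        hom_in_tumor = match.genotype.state == "hom_alt" or (af is not None and af >= min_hom_af)
        calls.append(
            LohCall(
                key=cand.key,
                gene=cand.gene,
                blood_state=cand.genotype,
                tumor_state=match.genotype,
                is_loh=cand.genotype.state == "het" and hom_in_tumor,
                tumor_alt_fraction=af,
            )
        )
    return calls
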