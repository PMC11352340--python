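"""Packaged worked-example cohort of four discordant sib pairs.

This curated demonstration dataset carries 40 rare deleterious germline
variants in cancer-related genes, private to the affected sib of each pair
(three of them shared by exactly two cases), together with tumor variant
tables (nine planted het->hom LOH conversions and a few somatic decoys)
and T/N/C FPKM expression profiles realizing the three functional-effect
classes (8 tumor-down, 3 tumor-up, 5 both-down) plus one retained
no-change truncating variant (URI1).

The cDNA/protein mutation notations and gene symbols are authentic
identifiers of the worked example; genomic coordinates, alleles, read
depths and FPKM values are synthetic placeholders constructed so that the
prioritization cascade, LOH caller and expression classifier reproduce the
cohort-level results exactly. Each affected table additionally contains
background decoy variants engineered to fail exactly one cascade stage, so
the full funnel is exercised.

Known transcription ambiguities of the source material (alternate case
assignments of the three shared variants, and a companion ESRRA notation)
are recorded in ``WorkedExample.metadata``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .model import ExpressionProfile, GenotypeCall, SibPairDataset, VariantRecord

__all__ = ["WorkedExample", "load_worked_example"]

CASES = ("case1", "case2", "case3", "case4")

# gene, cDNA:protein notation, consequence, cases carrying it, RNA-effect flag
_VARIANTS: list[tuple[str, str, str, tuple[str, ...], bool]] = [
    ("ACAP2", "c.C976T:p.R326X", "nonsense", ("case1",), True),
    ("ACTL6A", "c.T673A:p.S225T", "nonsynonymous_snv", ("case1",), False),
    ("BUB1B", "c.T2609C:p.V870A", "nonsynonymous_snv", ("case1",), True),
    ("DDX11", "c.G814A:p.V272M", "nonsynonymous_snv", ("case1",), False),
    ("EPB41", "c.G1264A:p.E422K", "nonsynonymous_snv", ("case1",), False),
    ("MEN1", "c.G301A:p.V101I", "nonsynonymous_snv", ("case1",), True),
    ("ANGPTL4", "c.637delC:p.P213fs", "frameshift_indel", ("case1", "case4"), True),
    ("ESRRA", "c.C1162T:p.L388F", "nonsynonymous_snv", ("case1", "case4"), False),
    ("ACACA", "c.C1948T:p.R650W", "nonsynonymous_snv", ("case2",), True),
    ("AMIGO3", "c.C669A:p.C223X", "nonsense", ("case2",), True),
    ("AVL9", "c.37_38del:p.R13fs", "frameshift_indel", ("case2",), False),
    ("CTBP2", "c.C2149T:p.R717C", "nonsynonymous_snv", ("case2",), False),
    ("CTSZ", "c.G358A:p.V120M", "nonsynonymous_snv", ("case2",), False),
    ("DEPTOR", "c.A631T:p.R211X", "nonsense", ("case2",), True),
    ("ENO3", "c.C642G:p.Y214X", "nonsense", ("case2",), True),
    ("GRM1", "c.C2185A:p.P729T", "nonsynonymous_snv", ("case2",), False),
    ("MYO10", "c.C5690T:p.S1897F", "nonsynonymous_snv", ("case2",), False),
    ("PFKP", "c.G311A:p.R104Q", "nonsynonymous_snv", ("case2",), False),
    ("PSCA", "c.G326A:p.W109X", "nonsense", ("case2",), True),
    ("ROCK1", "c.C727T:p.P243S", "nonsynonymous_snv", ("case2",), False),
    ("WWTR1", "c.1199_1200insTTTA:p.L400_X401delinsLX", "frameshift_indel", ("case2",), True),
    ("CARS", "c.G775A:p.G259S", "nonsynonymous_snv", ("case3", "case4"), True),
    ("CUX1", "c.2413dupC:p.G804fs", "frameshift_indel", ("case3",), False),
    ("EPHB6", "c.840delC:p.S280fs", "frameshift_indel", ("case3",), False),
    ("FBN2", "c.G3883A:p.D1295N", "nonsynonymous_snv", ("case3",), True),
    ("GANAB", "c.C583T:p.R195C", "nonsynonymous_snv", ("case3",), False),
    ("KDM4C", "c.3110delG:p.S1037fs", "frameshift_indel", ("case3",), False),
    ("MMP14", "c.C609A:p.Y203X", "nonsense", ("case3",), True),
    ("PTPN23", "c.G4189T:p.G1397C", "nonsynonymous_snv", ("case3",), False),
    ("RNASEL", "c.G793T:p.E265X", "nonsense", ("case3",), True),
    ("TP73", "c.G749T:p.G250V", "nonsynonymous_snv", ("case3",), True),
    ("ABHD5", "c.G341T:p.R114L", "nonsynonymous_snv", ("case4",), False),
    ("ACAD9", "c.G976A:p.A326T", "nonsynonymous_snv", ("case4",), False),
    ("EPHA7", "c.A2009C:p.Q670P", "nonsynonymous_snv", ("case4",), False),
    ("EPN3", "c.879delA:p.L293fs", "frameshift_indel", ("case4",), False),
    ("FAM188A", "c.1107delT:p.F369fs", "frameshift_indel", ("case4",), False),
    ("IQGAP2", "c.G1135C:p.E379Q", "nonsynonymous_snv", ("case4",), True),
    ("ITIH5", "c.1063delG:p.D355fs", "frameshift_indel", ("case4",), False),
    ("PSAT1", "c.G511C:p.A171P", "nonsynonymous_snv", ("case4",), False),
    ("URI1", "c.G1303T:p.E435X", "nonsense", ("case4",), True),
]

#: Expression classes realized by the packaged FPKM profiles.
CLASS_TUMOR_DOWN = ("ACACA", "ANGPTL4", "BUB1B", "FBN2", "MEN1", "MMP14", "TP73", "WWTR1")
CLASS_TUMOR_UP = ("ACAP2", "ENO3", "PSCA")
CLASS_BOTH_DOWN = ("AMIGO3", "CARS", "DEPTOR", "IQGAP2", "RNASEL")
#: No-change truncating variant retained on the RNA-effect panel by judgment.
RETAIN_NO_CHANGE = ("URI1",)

#: Nine planted blood-het -> tumor-hom conversions, (gene, case) pairs.
LOH_EVENTS: tuple[tuple[str, str], ...] = (
    ("MEN1", "case1"),
    ("BUB1B", "case1"),
    ("ANGPTL4", "case1"),
    ("ACACA", "case2"),
    ("WWTR1", "case2"),
    ("FBN2", "case3"),
    ("MMP14", "case3"),
    ("TP73", "case3"),
    ("RNASEL", "case3"),
)

#: Synthetic protein-interaction toy edge list (provenance labels as in
#: curated interaction databases). The main component spans all four cases.
TOY_EDGES: tuple[tuple[str, str, str], ...] = (
    ("EPHB6", "ACACA", "curated"),
    ("ACACA", "ENO3", "experimental"),
    ("ENO3", "CARS", "curated"),
    ("CARS", "ACAP2", "co-expression"),
    ("BUB1B", "ROCK1", "experimental"),
    ("TP73", "EPHA7", "predicted"),
    ("PRKAA1", "ACACA", "curated"),
    ("PRKAA1", "ENO3", "predicted"),
    ("RAD51", "CARS", "predicted"),
    ("RAD51", "BRCA1", "curated"),
)

#: Small demonstration gene sets (GMT-style) over the candidate genes.
TOY_GENE_SETS: dict[str, set[str]] = {
    "ECM_RECEPTOR_INTERACTION": {
        "MMP14", "FBN2", "ANGPTL4", "WWTR1", "TP73", "RNASEL", "IQGAP2",
    },
    "CELL_CYCLE": {"BUB1B", "TP73", "MEN1", "ROCK1"},
    "METABOLISM": {"ACACA", "ENO3", "PFKP", "PSAT1", "ABHD5", "ACAD9"},
}

_SNV = re.compile(r"^c\.([ACGT])(\d+)([ACGT]):")


def _alleles(hgvs: str) -> tuple[str, str]:
    """Synthetic ref/alt alleles keyed to the cDNA notation."""
    m = _SNV.match(hgvs)
    if m:
        return m.group(1), m.group(3)
    cdna = hgvs.split(":")[0]
    if "dup" in cdna:
        base = cdna[-1] if cdna[-1] in "ACGT" else "C"
        return base, base + base
    if "ins" in cdna:
        inserted = cdna.split("ins")[1]
        return "C", "C" + inserted
    if "del" in cdna:
        tail = cdna.split("del")[1]
        deleted = tail if tail and all(b in "ACGT" for b in tail) else "CA"
        return "A" + deleted, "A"
    raise ValueError(f"cannot derive alleles from {hgvs!r}")


def _germline_record(i: int, gene: str, hgvs: str, consequence: str) -> VariantRecord:
    ref, alt = _alleles(hgvs)
    truncating = consequence in ("frameshift_indel", "nonsense")
    return VariantRecord(
        chrom=f"chr{(i % 22) + 1}",
        pos=1_000_000 + i * 10_000,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        genotype=GenotypeCall("het", alt_depth=30, ref_depth=30),
        depth=60,
        maf=0.001,
        cadd_phred=None if truncating else 30.0,
        metasvm=None if truncating else "D",
        clinsig=None,
        hgvs=hgvs,
    )


def _decoys(case_index: int, inhouse: set[tuple[str, int, str, str]]) -> tuple[
    list[VariantRecord], list[VariantRecord]
]:
    """Background variants failing exactly one cascade stage each.

    Returns (affected decoys, unaffected-table records). The unaffected
    table gets the shared deleterious decoy, a low-depth hom-ref echo of
    one affected variant, and one private protective decoy (a rare
    truncating panel-gene variant only the healthy sib carries).
    """
    base = 50_000_000 + case_index * 1_000_000

    def rec(offset: int, gene: str, consequence: str, **kw) -> VariantRecord:
        defaults = dict(
            chrom=f"chr{case_index + 1}",
            pos=base + offset,
            ref="G",
            alt="A",
            gene=gene,
            consequence=consequence,
            genotype=GenotypeCall("het", alt_depth=25, ref_depth=25),
            depth=50,
            maf=0.001,
            cadd_phred=30.0,
            metasvm="D",
        )
        defaults.update(kw)
        return VariantRecord(**defaults)

    low_depth = rec(1, "TP53", "nonsense", depth=6,
                    genotype=GenotypeCall("het", alt_depth=3, ref_depth=3))
    common = rec(2, "EGFR", "nonsynonymous_snv", maf=0.15)
    noncoding = rec(3, "KRAS", "noncoding", maf=None, cadd_phred=None, metasvm=None)
    silent = rec(4, "BRCA1", "synonymous")
    benign = rec(5, "TP53", "nonsynonymous_snv", clinsig="likely_benign")
    inhouse_hit = rec(6, "EGFR", "nonsynonymous_snv")
    inhouse.add(inhouse_hit.key)
    weak_scores = rec(7, "KRAS", "nonsynonymous_snv", cadd_phred=5.0, metasvm="T")
    shared_delet = rec(8, "BRCA1", "nonsense", cadd_phred=None, metasvm=None)
    off_panel = rec(9, "OR4F5", "nonsense", cadd_phred=None, metasvm=None)
    weak_ref_sib = rec(10, "RAD51", "nonsense", cadd_phred=None, metasvm=None)

    affected = [
        low_depth, common, noncoding, silent, benign,
        inhouse_hit, weak_scores, shared_delet, off_panel, weak_ref_sib,
    ]
    unaffected = [
        shared_delet,  # het in both sibs -> fails discordance
        weak_ref_sib.with_genotype(GenotypeCall("hom_ref", alt_depth=0, ref_depth=5), depth=5),
        rec(11, "MEN1", "nonsense", cadd_phred=None, metasvm=None),  # protective screen
    ]
    return affected, unaffected


def _expression_tables() -> tuple[list[ExpressionProfile], dict[str, list[float]]]:
    profiles: list[ExpressionProfile] = []
    controls: dict[str, list[float]] = {}
    genes = [v[0] for v in _VARIANTS]
    high = [18.0, 19.0, 20.0, 21.0, 22.0]
    low = [2.6, 2.8, 3.0, 3.2, 3.4]
    for i, gene in enumerate(genes):
        f = 0.8 + 0.05 * (i % 9)  # per-gene scale jitter, deterministic
        if gene in CLASS_TUMOR_DOWN:
            c, t, n = high, 2.0, 20.0
        elif gene in CLASS_TUMOR_UP:
            c, t, n = low, 30.0, 3.0
        elif gene in CLASS_BOTH_DOWN:
            c, t, n = high, 1.0, 1.2
        else:
            c, t, n = high, 19.0, 20.0
        c_scaled = [v * f for v in c]
        controls[gene] = c_scaled
        profiles.append(
            ExpressionProfile(
                gene=gene,
                fpkm_t=t * f,
                fpkm_n=n * f,
                fpkm_c_mean=sum(c_scaled) / len(c_scaled),
            )
        )
    return profiles, controls


@dataclass(slots=True)
class WorkedExample:
    """The packaged demonstration cohort with every companion resource."""

    cohort: list[SibPairDataset]
    profiles: list[ExpressionProfile]
    control_samples: dict[str, list[float]]
    expected: pd.DataFrame
    cancer_genes: set[str]
    inhouse_db: set[tuple[str, int, str, str]]
    edges: list[tuple[str, str, str]]
    gene_sets: dict[str, set[str]]
    retain_no_change: set[str]
    metadata: dict = field(default_factory=dict)


def load_worked_example() -> WorkedExample:
    """Build the worked-example cohort deterministically (no I/O)."""
    germline = {
        case: [] for case in CASES
    }  # type: dict[str, list[VariantRecord]]
    records_by_gene: dict[str, VariantRecord] = {}
    for i, (gene, hgvs, consequence, cases, _bold) in enumerate(_VARIANTS):
        rec = _germline_record(i, gene, hgvs, consequence)
        records_by_gene[gene] = rec
        for case in cases:
            germline[case].append(rec)

    loh_lookup = {(case, gene) for gene, case in LOH_EVENTS}
    inhouse: set[tuple[str, int, str, str]] = set()
    pairs: list[SibPairDataset] = []
    for ci, case in enumerate(CASES):
        decoys_aff, unaffected = _decoys(ci, inhouse)
        tumor: list[VariantRecord] = []
        for rec in germline[case]:
            if (case, rec.gene) in loh_lookup:
                tumor.append(rec.with_genotype(GenotypeCall("hom_alt", alt_depth=58, ref_depth=2)))
            else:
                tumor.append(rec.with_genotype(GenotypeCall("het", alt_depth=30, ref_depth=30)))
        # somatic decoys: 3 missense, 1 frameshift, 1 nonsense per tumor
        somatic_specs = [
            ("nonsynonymous_snv", 1), ("nonsynonymous_snv", 2), ("nonsynonymous_snv", 3),
            ("frameshift_indel", 4), ("nonsense", 5),
        ]
        for consequence, j in somatic_specs:
            tumor.append(
                VariantRecord(
                    chrom=f"chr{ci + 10}",
                    pos=90_000_000 + j * 1_000,
                    ref="G" if consequence != "frameshift_indel" else "GT",
                    alt="T" if consequence != "frameshift_indel" else "G",
                    gene=f"SOM{ci}{j}",
                    consequence=consequence,
                    genotype=GenotypeCall("het", alt_depth=15, ref_depth=35),
                    depth=50,
                    maf=None,
                )
            )
        pairs.append(
            SibPairDataset(
                case_id=case,
                affected_variants=germline[case] + decoys_aff,
                unaffected_variants=unaffected,
                tumor_variants=tumor,
            )
        )

    profiles, controls = _expression_tables()

    expected = pd.DataFrame(
        [
            {
                "gene": gene,
                "mutation": hgvs,
                "cases": ",".join(cases),
                "consequence": consequence,
                "expression_class": (
                    "TUMOR_DOWN" if gene in CLASS_TUMOR_DOWN
                    else "TUMOR_UP" if gene in CLASS_TUMOR_UP
                    else "BOTH_DOWN" if gene in CLASS_BOTH_DOWN
                    else "NO_CHANGE"
                ),
                "rna_panel": bold,
                "loh": any(g == gene for g, _ in LOH_EVENTS),
            }
            for gene, hgvs, consequence, cases, bold in _VARIANTS
        ]
    )

    panel = {v[0] for v in _VARIANTS} | {"TP53", "EGFR", "KRAS", "BRCA1", "RAD51", "MEN1"}

    metadata = {
        "description": "curated four-pair demonstration cohort; coordinates, "
        "alleles, depths and FPKM values are synthetic placeholders",
        "shared_variants": {
            "ANGPTL4:c.637delC:p.P213fs": ["case1", "case4"],
            "ESRRA:c.C1162T:p.L388F": ["case1", "case4"],
            "CARS:c.G775A:p.G259S": ["case3", "case4"],
        },
        "alternate_case_assignments": {
            # alternate transcription of the source table's checkmarks
            "ANGPTL4:c.637delC:p.P213fs": ["case3"],
            "ESRRA:c.C1162T:p.L388F": ["case3", "case4"],
            "CARS:c.G775A:p.G259S": ["case2", "case3"],
        },
        "esrra_companion_notation": "c.C1165T:p.R389C",
        "somatic_decoys_per_tumor": {"missense": 3, "frameshift_indel": 1, "nonsense": 1},
        "protective_decoys_per_pair": 1,
    }

    return WorkedExample(
        cohort=pairs,
        profiles=profiles,
        control_samples=controls,
        expected=expected,
        cancer_genes=panel,
        inhouse_db=inhouse,
        edges=list(TOY_EDGES),
        gene_sets={k: set(v) for k, v in TOY_GENE_SETS.items()},
        retain_no_change=set(RETAIN_NO_CHANGE),
        metadata=metadata,
    )
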