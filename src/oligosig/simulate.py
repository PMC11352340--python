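"""Synthetic sib-pair cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* background heterozygous germline variants shared between sibs with a
  per-variant Bernoulli probability (0.5, the expected fraction of the
  genome shared by full sibs; no linkage structure, because the analysis
  uses none);
* a private signature of rare deleterious variants in cancer-panel genes
  planted in the affected sib only, annotated with wide margins past every
  default filter threshold, while every background variant violates at
  least one threshold by construction — recovery tests are therefore exact;
* tumor tables carrying all affected-sib germline variants plus somatic
  draws whose coding classes follow configurable proportions
  (default 1092 missense : 374 frameshift indel : 43 nonsense);
* planted het->hom LOH conversions whose tumor alt fraction reflects an
  optional tumor purity (allele depths at LOH sites use expected counts,
  so truth recovery is deterministic at purity 1);
* log-normal FPKM with planted per-class fold changes for expression
  classification and differential-expression recovery.

All randomness flows from one seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io import write_expression_table, write_variant_table, write_vcf
from .model import ExpressionProfile, GenotypeCall, SibPairDataset, VariantRecord

__all__ = ["SimulationConfig", "SimulationTruth", "SimulatedExpression",
           "simulate_cohort", "emit_files"]

_CLASS_CYCLE = ("TUMOR_DOWN", "TUMOR_UP", "BOTH_DOWN", "NO_CHANGE")
_SOMATIC_CLASSES = ("nonsynonymous_snv", "frameshift_indel", "nonsense")
_BASES = ("A", "C", "G", "T")


@dataclass(slots=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    n_pairs: int = 4
    seed: int = 0
    n_background_variants: int = 5000
    sib_share_prob: float = 0.5
    #: fixed per-case signature size; None draws Poisson(private_mean)
    n_private_deleterious: Optional[int] = None
    private_mean: float = 10.0
    somatic_class_weights: tuple[float, float, float] = (1092.0, 374.0, 43.0)
    n_somatic: int = 100
    #: planted het->hom conversions, cohort-wide
    n_loh: int = 9
    tumor_purity: float = 1.0
    expression_fold: float = 4.0
    n_controls: int = 5
    log_sigma: float = 0.25
    #: extra null genes in the expression table beyond the signature genes
    n_expression_null: int = 100
    #: planted genome-wide DE genes (tumor vs normal)
    n_de_up: int = 0
    n_de_down: int = 0
    panel_size: int = 200

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not 0.0 <= self.sib_share_prob <= 1.0:
            raise ValueError("sib_share_prob must lie in [0,1]")
        if any(w <= 0 for w in self.somatic_class_weights):
            raise ValueError("somatic class weights must be positive")
        if not 0.0 < self.tumor_purity <= 1.0:
            raise ValueError("tumor_purity must lie in (0,1]")
        if self.expression_fold <= 1:
            raise ValueError("expression_fold must exceed 1")
        if self.n_controls < 2:
            raise ValueError("need >= 2 control samples")


@dataclass(slots=True)
class SimulationTruth:
    """Planted ground truth of one simulated cohort."""

    signature_keys: dict[str, list[tuple[str, int, str, str]]] = field(default_factory=dict)
    somatic_keys: dict[str, dict[tuple[str, int, str, str], str]] = field(default_factory=dict)
    loh_keys: dict[str, list[tuple[str, int, str, str]]] = field(default_factory=dict)
    expression_class: dict[str, str] = field(default_factory=dict)
    de_direction: dict[str, str] = field(default_factory=dict)
    cancer_genes: set[str] = field(default_factory=set)
    shared_background: dict[str, int] = field(default_factory=dict)
    n_background: dict[str, int] = field(default_factory=dict)

    def to_json_obj(self) -> dict:
        return {
            "signature_keys": {c: [list(k) for k in ks] for c, ks in self.signature_keys.items()},
            "somatic_keys": {
                c: {"|".join(map(str, k)): cls for k, cls in ks.items()}
                for c, ks in self.somatic_keys.items()
            },
            "loh_keys": {c: [list(k) for k in ks] for c, ks in self.loh_keys.items()},
            "expression_class": self.expression_class,
            "de_direction": self.de_direction,
            "cancer_genes": sorted(self.cancer_genes),
            "shared_background": self.shared_background,
            "n_background": self.n_background,
        }


@dataclass(slots=True)
class SimulatedExpression:
    """Expression profiles plus the raw control-group samples behind them."""

    profiles: list[ExpressionProfile]
    controls: dict[str, list[float]]


class _Coords:
    """Unique synthetic genomic coordinates."""

    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng
        self.counter = 0

    def next(self) -> tuple[str, int]:
        self.counter += 1
        chrom = f"chr{(self.counter % 22) + 1}"
        return chrom, 100_000 + self.counter * 100


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    i = int(rng.integers(4))
    j = (i + 1 + int(rng.integers(3))) % 4
    return _BASES[i], _BASES[j]


def _het(rng: np.random.Generator, depth: int) -> GenotypeCall:
    alt = int(rng.binomial(depth, 0.5))
    return GenotypeCall("het", alt_depth=alt, ref_depth=depth - alt)


# background variants each violate one default threshold by construction
_VIOLATIONS = ("common_maf", "synonymous", "noncoding", "benign", "weak_scores", "low_depth")


def _background_variant(
    rng: np.random.Generator, coords: _Coords, gene: str
) -> VariantRecord:
    chrom, pos = coords.next()
    ref, alt = _snv_alleles(rng)
    violation = _VIOLATIONS[int(rng.integers(len(_VIOLATIONS)))]
    consequence = "nonsynonymous_snv"
    maf: Optional[float] = float(rng.uniform(0, 0.005))
    cadd: Optional[float] = float(rng.uniform(25, 40))
    metasvm: Optional[str] = "D"
    clinsig: Optional[str] = None
    depth = int(rng.integers(20, 80))
    if violation == "common_maf":
        maf = float(rng.uniform(0.05, 0.5))
    elif violation == "synonymous":
        consequence = "synonymous"
    elif violation == "noncoding":
        consequence = "noncoding"
    elif violation == "benign":
        clinsig = "likely_benign" if rng.random() < 0.5 else "benign"
    elif violation == "weak_scores":
        cadd = float(rng.uniform(0, 10))
        metasvm = "T"
    elif violation == "low_depth":
        depth = int(rng.integers(1, 10))
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        consequence=consequence, genotype=_het(rng, depth), depth=depth,
        maf=maf, cadd_phred=cadd, metasvm=metasvm, clinsig=clinsig,
    )


def _signature_variant(
    rng: np.random.Generator, coords: _Coords, gene: str
) -> VariantRecord:
    chrom, pos = coords.next()
    ref, alt = _snv_alleles(rng)
    truncating = rng.random() < 0.5
    consequence = ("nonsense" if rng.random() < 0.5 else "frameshift_indel") if truncating \
        else "nonsynonymous_snv"
    if consequence == "frameshift_indel":
        ref, alt = ref + alt, ref
    depth = int(rng.integers(40, 100))
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        consequence=consequence, genotype=_het(rng, depth), depth=depth,
        maf=None if rng.random() < 0.3 else float(rng.uniform(0, 0.005)),
        cadd_phred=None if truncating else float(rng.uniform(25, 40)),
        metasvm=None if truncating else "D",
        clinsig=None,
    )


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[list[SibPairDataset], SimulatedExpression, SimulationTruth]:
    """Generate a cohort, its expression tables, and the planted truth.

    Deterministic given ``cfg.seed``: running twice yields identical
    objects (and byte-identical files through :func:`emit_files`).
    """
    rng = np.random.default_rng(cfg.seed)
    coords = _Coords(rng)
    truth = SimulationTruth()

    panel = [f"CPG{i:04d}" for i in range(cfg.panel_size)]
    truth.cancer_genes = set(panel)
    background_genes = [f"BG{i:05d}" for i in range(2000)]

    # per-case signature sizes first, so the n_loh consistency check is early
    sizes = [
        int(cfg.n_private_deleterious)
        if cfg.n_private_deleterious is not None
        else int(rng.poisson(cfg.private_mean))
        for _ in range(cfg.n_pairs)
    ]
    if cfg.n_loh > sum(sizes):
        raise ValueError(
            f"n_loh={cfg.n_loh} exceeds total planted signature size {sum(sizes)}"
        )

    pairs: list[SibPairDataset] = []
    signature_records: dict[str, list[VariantRecord]] = {}
    for ci in range(cfg.n_pairs):
        case = f"sim{ci + 1}"
        affected: list[VariantRecord] = []
        unaffected: list[VariantRecord] = []
        n_shared = 0
        for _ in range(cfg.n_background_variants):
            gene_pool = panel if rng.random() < 0.3 else background_genes
            gene = gene_pool[int(rng.integers(len(gene_pool)))]
            rec = _background_variant(rng, coords, gene)
            affected.append(rec)
            if rng.random() < cfg.sib_share_prob:
                unaffected.append(rec)
                n_shared += 1
        truth.shared_background[case] = n_shared
        truth.n_background[case] = cfg.n_background_variants

        genes = list(rng.choice(panel, size=sizes[ci], replace=False)) if sizes[ci] else []
        planted = [_signature_variant(rng, coords, g) for g in genes]
        affected.extend(planted)
        signature_records[case] = planted
        truth.signature_keys[case] = [p.key for p in planted]

        pairs.append(SibPairDataset(case, affected, unaffected, tumor_variants=None))

    # distribute LOH conversions round-robin over cases with capacity
    loh_assignment: dict[str, set[tuple[str, int, str, str]]] = {p.case_id: set() for p in pairs}
    ci = 0
    remaining = cfg.n_loh
    order = [p.case_id for p in pairs]
    while remaining > 0:
        case = order[ci % len(order)]
        pool = [r.key for r in signature_records[case] if r.key not in loh_assignment[case]]
        if pool:
            loh_assignment[case].add(pool[0])
            remaining -= 1
        ci += 1
        if ci > 10 * cfg.n_loh * max(1, len(order)):  # all pools exhausted
            raise ValueError("could not place all LOH conversions")
    truth.loh_keys = {c: sorted(ks) for c, ks in loh_assignment.items()}

    weights = np.asarray(cfg.somatic_class_weights, dtype=float)
    probs = weights / weights.sum()
    loh_af = cfg.tumor_purity * 1.0 + (1.0 - cfg.tumor_purity) * 0.5
    for pair in pairs:
        tumor: list[VariantRecord] = []
        for rec in pair.affected_variants:
            if rec.key in loh_assignment[pair.case_id]:
                depth = rec.depth
                alt = int(round(depth * loh_af))  # expected counts: exact at purity 1
                state = "hom_alt" if alt == depth else "het"
                tumor.append(
                    rec.with_genotype(GenotypeCall(state, alt_depth=alt, ref_depth=depth - alt))
                )
            else:
                tumor.append(rec.with_genotype(_het(rng, rec.depth), depth=rec.depth))
        somatic: dict[tuple[str, int, str, str], str] = {}
        classes = rng.choice(len(_SOMATIC_CLASSES), size=cfg.n_somatic, p=probs)
        for k in classes:
            consequence = _SOMATIC_CLASSES[int(k)]
            chrom, pos = coords.next()
            ref, alt_a = _snv_alleles(rng)
            if consequence == "frameshift_indel":
                ref, alt_a = ref + alt_a, ref
            depth = int(rng.integers(30, 90))
            alt_reads = int(rng.binomial(depth, 0.25)) or 1
            rec = VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt_a, gene=f"SOMG{coords.counter}",
                consequence=consequence,
                genotype=GenotypeCall("het", alt_depth=alt_reads, ref_depth=depth - alt_reads),
                depth=depth, maf=None,
            )
            tumor.append(rec)
            somatic[rec.key] = consequence
        truth.somatic_keys[pair.case_id] = somatic
        pair.tumor_variants = tumor

    expression = _simulate_expression(cfg, rng, signature_records, truth)
    return pairs, expression, truth


def _simulate_expression(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    signature_records: dict[str, list[VariantRecord]],
    truth: SimulationTruth,
) -> SimulatedExpression:
    fold = cfg.expression_fold

    def noisy(mu: float) -> float:
        if cfg.log_sigma == 0:
            return mu
        return float(mu * rng.lognormal(0.0, cfg.log_sigma))

    genes: list[tuple[str, str]] = []  # (gene, planted class or DE direction)
    seen: set[str] = set()
    i = 0
    for planted in signature_records.values():
        for rec in planted:
            if rec.gene in seen:
                continue
            seen.add(rec.gene)
            genes.append((rec.gene, _CLASS_CYCLE[i % len(_CLASS_CYCLE)]))
            i += 1
    for j in range(cfg.n_de_up):
        genes.append((f"DEU{j:04d}", "de_up"))
    for j in range(cfg.n_de_down):
        genes.append((f"DED{j:04d}", "de_down"))
    for j in range(cfg.n_expression_null):
        genes.append((f"NULL{j:04d}", "null"))

    profiles: list[ExpressionProfile] = []
    controls: dict[str, list[float]] = {}
    for gene, label in genes:
        base = float(rng.lognormal(np.log(20.0), 1.0))
        t_mu, n_mu = base, base
        if label == "TUMOR_DOWN":
            t_mu = base / fold
        elif label == "TUMOR_UP":
            t_mu = base * fold
        elif label == "BOTH_DOWN":
            t_mu = n_mu = base / fold
        elif label == "de_up":
            t_mu = base * fold
        elif label == "de_down":
            t_mu = base / fold
        c_values = [noisy(base) for _ in range(cfg.n_controls)]
        controls[gene] = c_values
        profiles.append(
            ExpressionProfile(
                gene=gene,
                fpkm_t=noisy(t_mu),
                fpkm_n=noisy(n_mu),
                fpkm_c_mean=sum(c_values) / len(c_values),
            )
        )
        if label in _CLASS_CYCLE:
            truth.expression_class[gene] = label
        elif label == "de_up":
            truth.de_direction[gene] = "up"
        elif label == "de_down":
            truth.de_direction[gene] = "down"
        else:
            truth.de_direction[gene] = "null"
    return SimulatedExpression(profiles, controls)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def emit_files(
    cohort: list[SibPairDataset],
    expression: SimulatedExpression,
    truth: SimulationTruth,
    out_dir: str | Path,
) -> dict:
    """Write the cohort to disk in the dialects the readers consume.

    Per subject: a TSV variant table and an equivalent VCF. Plus the long
    expression TSV, the cancer panel, the truth JSON and a manifest with
    sha256 checksums. Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    for pair in cohort:
        tables = {
            f"{pair.case_id}_affected": pair.affected_variants,
            f"{pair.case_id}_unaffected": pair.unaffected_variants,
        }
        if pair.tumor_variants is not None:
            tables[f"{pair.case_id}_tumor"] = pair.tumor_variants
        for name, records in tables.items():
            tsv = out / f"{name}.tsv"
            write_variant_table(records, tsv)
            files.append(tsv)
            vcf = out / f"{name}.vcf"
            write_vcf(records, vcf, sample=name)
            files.append(vcf)

    expr_path = out / "expression.tsv"
    write_expression_table(expression.profiles, expression.controls, expr_path)
    files.append(expr_path)

    panel_path = out / "cancer_panel.txt"
    panel_path.write_text("".join(f"{g}\n" for g in sorted(truth.cancer_genes)))
    files.append(panel_path)

    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth.to_json_obj(), indent=2, sort_keys=True))
    files.append(truth_path)

    manifest = {
        "files": {f.name: _sha256(f) for f in files},
        "n_pairs": len(cohort),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
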