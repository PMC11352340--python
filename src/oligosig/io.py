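"""Readers and writers for variant tables, expression tables and gene lists.

Two variant-table dialects are supported:

* **VCF 4.x** (read), one sample per file, with annotations in INFO fields.
  The INFO keys are configurable through a key map; the defaults are
  ``GENE``, ``CONSEQ``, ``MAF``, ``CADD_PHRED``, ``METASVM``, ``CLNSIG``.
  Genotype, allele depths and total depth come from the ``GT``/``AD``/``DP``
  FORMAT fields. Multi-allelic sites are decomposed into one record per
  alternate allele.
* **TSV** (read/write), one record per row with header
  ``chrom pos ref alt gene consequence maf cadd_phred metasvm clinsig
  gt alt_depth ref_depth depth hgvs`` and ``.`` for absent values.

Expression tables are long-format TSV with header ``gene sample role fpkm``
where role is ``T`` (tumor), ``N`` (matched normal) or ``C`` (control
normal group).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    CONSEQUENCES,
    ExpressionProfile,
    FusionCandidate,
    GenotypeCall,
    VariantRecord,
)

__all__ = [
    "DEFAULT_INFO_KEYS",
    "TSV_COLUMNS",
    "read_variant_table",
    "write_variant_table",
    "write_vcf",
    "read_expression_table",
    "read_expression_controls",
    "read_gene_list",
    "read_gmt",
    "read_edge_list",
    "read_variant_keys",
    "read_fusion_table",
]

#: Default mapping of annotation concept -> VCF INFO key.
DEFAULT_INFO_KEYS: Mapping[str, str] = {
    "gene": "GENE",
    "consequence": "CONSEQ",
    "maf": "MAF",
    "cadd_phred": "CADD_PHRED",
    "metasvm": "METASVM",
    "clinsig": "CLNSIG",
}

TSV_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "maf",
    "cadd_phred",
    "metasvm",
    "clinsig",
    "gt",
    "alt_depth",
    "ref_depth",
    "depth",
    "hgvs",
)

_MISSING = "."


class ParseError(ValueError):
    """Malformed input file; the message names the offending location."""


def _fmt(value: object) -> str:
    if value is None:
        return _MISSING
    return str(value)


def _opt_float(text: str, where: str) -> Optional[float]:
    if text in ("", _MISSING):
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise ParseError(f"{where}: not a number: {text!r}") from exc


def _opt_str(text: str) -> Optional[str]:
    return None if text in ("", _MISSING) else text


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------


def read_variant_table(
    path: str | Path,
    dialect: str = "tsv",
    info_keys: Mapping[str, str] = DEFAULT_INFO_KEYS,
) -> list[VariantRecord]:
    """Read one subject's annotated variant table.

    Parameters
    ----------
    path:
        Input file. Must exist.
    dialect:
        ``"vcf"`` or ``"tsv"``.
    info_keys:
        For VCF input, mapping of annotation concept (``gene``,
        ``consequence``, ``maf``, ``cadd_phred``, ``metasvm``, ``clinsig``)
        to the INFO key carrying it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path, info_keys)
    raise ValueError(f"unknown variant-table dialect {dialect!r} (use 'vcf' or 'tsv')")


def _read_tsv(path: Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = [c for c in TSV_COLUMNS if c not in reader.fieldnames and c != "hgvs"]
        if missing:
            raise ParseError(f"{path}: header lacks columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            try:
                genotype = GenotypeCall(
                    state=row["gt"],
                    alt_depth=int(row["alt_depth"] or 0),
                    ref_depth=int(row["ref_depth"] or 0),
                )
                records.append(
                    VariantRecord(
                        chrom=row["chrom"],
                        pos=int(row["pos"]),
                        ref=row["ref"],
                        alt=row["alt"],
                        gene=row["gene"],
                        consequence=row["consequence"],
                        genotype=genotype,
                        depth=int(row["depth"] or 0),
                        maf=_opt_float(row["maf"], where),
                        cadd_phred=_opt_float(row["cadd_phred"], where),
                        metasvm=_opt_str(row["metasvm"]),
                        clinsig=_opt_str(row["clinsig"]),
                        hgvs=_opt_str(row.get("hgvs", _MISSING)),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{where}: {exc}") from exc
    return records


def _scalar_or_index(value: object, index: int) -> object:
    if isinstance(value, (tuple, list)):
        return value[index] if index < len(value) else None
    if isinstance(value, str) and "," in value:
        parts = value.split(",")
        return parts[index] if index < len(parts) else None
    return value


def _read_vcf(path: Path, info_keys: Mapping[str, str]) -> list[VariantRecord]:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad input
        raise ParseError(f"{path}: not a readable VCF ({exc})") from exc

    records: list[VariantRecord] = []
    for variant in vcf:
        where = f"{path}: {variant.CHROM}:{variant.POS}"
        try:
            ad = variant.format("AD")
            dp = variant.format("DP")
            depth = int(dp[0][0]) if dp is not None else 0
            alleles = variant.genotypes[0][:-1] if variant.genotypes else []
            for i, alt in enumerate(variant.ALT):
                allele_number = i + 1
                if not alleles or -1 in alleles:
                    state = "missing"
                else:
                    n_alt = sum(1 for a in alleles if a == allele_number)
                    state = {0: "hom_ref", 1: "het", 2: "hom_alt"}[n_alt]
                ref_depth = int(ad[0][0]) if ad is not None else 0
                alt_depth = (
                    int(ad[0][allele_number])
                    if ad is not None and ad.shape[1] > allele_number
                    else 0
                )
                info = variant.INFO

                def get(concept: str) -> object:
                    return _scalar_or_index(info.get(info_keys[concept]), i)

                maf = get("maf")
                cadd = get("cadd_phred")
                consequence = get("consequence")
                if consequence is None or consequence not in CONSEQUENCES:
                    consequence = "other_exonic" if consequence else "noncoding"
                records.append(
                    VariantRecord(
                        chrom=variant.CHROM,
                        pos=variant.POS,
                        ref=variant.REF,
                        alt=alt,
                        gene=str(get("gene") or ""),
                        consequence=str(consequence),
                        genotype=GenotypeCall(state, alt_depth=alt_depth, ref_depth=ref_depth),
                        depth=max(depth, alt_depth + ref_depth),
                        maf=None if maf is None else float(maf),
                        cadd_phred=None if cadd is None else float(cadd),
                        metasvm=_opt_str(str(get("metasvm") or _MISSING)),
                        clinsig=_opt_str(str(get("clinsig") or _MISSING)),
                    )
                )
        except ParseError:
            raise
        except Exception as exc:
            raise ParseError(f"{where}: {exc}") from exc
    return records


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records in the TSV dialect (round-trips through the reader)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.chrom,
                    rec.pos,
                    rec.ref,
                    rec.alt,
                    rec.gene,
                    rec.consequence,
                    _fmt(rec.maf),
                    _fmt(rec.cadd_phred),
                    _fmt(rec.metasvm),
                    _fmt(rec.clinsig),
                    rec.genotype.state,
                    rec.genotype.alt_depth,
                    rec.genotype.ref_depth,
                    rec.depth,
                    _fmt(rec.hgvs),
                ]
            )


_VCF_GT = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID={gene},Number=1,Type=String,Description="Gene symbol">
##INFO=<ID={consequence},Number=A,Type=String,Description="Functional consequence">
##INFO=<ID={maf},Number=A,Type=Float,Description="Population minor allele frequency">
##INFO=<ID={cadd_phred},Number=A,Type=Float,Description="CADD scaled deleteriousness score">
##INFO=<ID={metasvm},Number=A,Type=String,Description="MetaSVM call (D damaging, T tolerated)">
##INFO=<ID={clinsig},Number=A,Type=String,Description="Clinical significance">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    sample: str = "SAMPLE",
    info_keys: Mapping[str, str] = DEFAULT_INFO_KEYS,
) -> None:
    """Serialize biallelic records as a single-sample VCF 4.2 file."""
    path = Path(path)
    ordered = sorted(records, key=lambda r: (r.chrom, r.pos, r.alt))
    contigs = "".join(
        f"##contig=<ID={c}>\n" for c in sorted({r.chrom for r in ordered})
    )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(sample=sample, contigs=contigs, **info_keys))
        for rec in ordered:
            info_parts = [f"{info_keys['gene']}={rec.gene}", f"{info_keys['consequence']}={rec.consequence}"]
            if rec.maf is not None:
                info_parts.append(f"{info_keys['maf']}={rec.maf:g}")
            if rec.cadd_phred is not None:
                info_parts.append(f"{info_keys['cadd_phred']}={rec.cadd_phred:g}")
            if rec.metasvm is not None:
                info_parts.append(f"{info_keys['metasvm']}={rec.metasvm}")
            if rec.clinsig is not None:
                info_parts.append(f"{info_keys['clinsig']}={rec.clinsig}")
            fh.write(
                "\t".join(
                    [
                        rec.chrom,
                        str(rec.pos),
                        ".",
                        rec.ref,
                        rec.alt,
                        ".",
                        "PASS",
                        ";".join(info_parts),
                        "GT:AD:DP",
                        ":".join(
                            [
                                _VCF_GT[rec.genotype.state],
                                f"{rec.genotype.ref_depth},{rec.genotype.alt_depth}",
                                str(rec.depth),
                            ]
                        ),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


def _read_expression_rows(path: Path) -> dict[str, dict[str, list[tuple[str, float]]]]:
    by_gene: dict[str, dict[str, list[tuple[str, float]]]] = {}
    seen: set[tuple[str, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return {}
        for col in ("gene", "sample", "role", "fpkm"):
            if col not in reader.fieldnames:
                raise ParseError(f"{path}: expression header lacks column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            gene, sample, role = row["gene"], row["sample"], row["role"]
            if role not in ("T", "N", "C"):
                raise ParseError(f"{where}: role must be T/N/C, got {role!r}")
            if (gene, sample) in seen:
                raise ParseError(f"{where}: duplicate (gene, sample) row ({gene}, {sample})")
            seen.add((gene, sample))
            try:
                fpkm = float(row["fpkm"])
            except ValueError as exc:
                raise ParseError(f"{where}: not a number: {row['fpkm']!r}") from exc
            if fpkm < 0:
                raise ParseError(f"{where}: negative FPKM {fpkm}")
            by_gene.setdefault(gene, {"T": [], "N": [], "C": []})[role].append((sample, fpkm))
    return by_gene


def read_expression_table(path: str | Path) -> list[ExpressionProfile]:
    """Read a long-format FPKM table into one profile per gene.

    Each gene needs exactly one T row, one N row and at least two C rows;
    ``fpkm_c_mean`` is the arithmetic mean over the C samples. p-values are
    left unset (filled later by the expression module).
    """
    path = Path(path)
    profiles: list[ExpressionProfile] = []
    for gene, roles in _read_expression_rows(path).items():
        for role in ("T", "N"):
            if len(roles[role]) != 1:
                raise ParseError(
                    f"{path}: gene {gene} needs exactly one {role} sample, has {len(roles[role])}"
                )
        if len(roles["C"]) < 2:
            raise ParseError(f"{path}: gene {gene} needs >= 2 control samples")
        c_values = [v for _, v in roles["C"]]
        profiles.append(
            ExpressionProfile(
                gene=gene,
                fpkm_t=roles["T"][0][1],
                fpkm_n=roles["N"][0][1],
                fpkm_c_mean=sum(c_values) / len(c_values),
            )
        )
    return profiles


def read_expression_controls(path: str | Path) -> dict[str, list[float]]:
    """Per-gene raw control-group FPKM values from the same long TSV."""
    return {
        gene: [v for _, v in roles["C"]]
        for gene, roles in _read_expression_rows(Path(path)).items()
    }


def write_expression_table(
    profiles: Sequence[ExpressionProfile],
    controls: Mapping[str, Sequence[float]],
    path: str | Path,
) -> None:
    """Write profiles plus raw control samples back to the long TSV format."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", "sample", "role", "fpkm"])
        for prof in profiles:
            writer.writerow([prof.gene, "tumor", "T", f"{prof.fpkm_t:g}"])
            writer.writerow([prof.gene, "normal", "N", f"{prof.fpkm_n:g}"])
            for j, value in enumerate(controls[prof.gene], start=1):
                writer.writerow([prof.gene, f"control{j}", "C", f"{value:g}"])


# ---------------------------------------------------------------------------
# gene lists, gene sets, edges, fusion tables
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    symbols: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.add(line)
    return symbols


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if line.strip():
                    raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 fields")
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def read_edge_list(path: str | Path) -> list[tuple[str, str, str]]:
    """Two/three-column TSV edge list: geneA, geneB[, provenance label]."""
    edges: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: edge line needs >= 2 fields")
            label = parts[2] if len(parts) > 2 and parts[2] else "unknown"
            edges.append((parts[0], parts[1], label))
    return edges


def read_variant_keys(path: str | Path) -> set[tuple[str, int, str, str]]:
    """In-house database: TSV of chrom, pos, ref, alt (header optional)."""
    keys: set[tuple[str, int, str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: key line needs 4 fields")
            if lineno == 1 and parts[0] == "chrom":
                continue
            keys.add((parts[0], int(parts[1]), parts[2], parts[3]))
    return keys


def read_fusion_table(path: str | Path) -> list[FusionCandidate]:
    """TSV with header gene5, gene3, spanning_reads_tumor, spanning_reads_normal."""
    fusions: list[FusionCandidate] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                fusions.append(
                    FusionCandidate(
                        gene5=row["gene5"],
                        gene3=row["gene3"],
                        spanning_reads_tumor=int(row["spanning_reads_tumor"]),
                        spanning_reads_normal=int(row["spanning_reads_normal"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return fusions
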