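"""End-to-end orchestration: cascade -> somatic/LOH -> expression -> network.

A run takes its inputs from one of three modes:

* ``fixture``  — the packaged worked-example cohort;
* ``simulate`` — a synthetic cohort from :mod:`oligosig.simulate`;
* ``files``    — user-supplied variant/expression tables listed in a YAML
  config (keys documented in :class:`PipelineConfig`).

Artifacts written to the output directory: ``report.tsv`` / ``report.json``
(the per-patient signature), ``trace.json`` (the per-case filter funnel),
``loh.tsv``, ``somatic.json``, ``enrichment.tsv`` and ``network.json``
when resources allow, and ``run_manifest.json`` recording package version,
seed, parameters and a config hash. Progress is logged to stderr.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .enrichment import CandidateNetwork, EnrichmentResult, build_candidate_network, enrich, expand_network
from .expression import DEThresholds, compute_significance, integrate_candidates
from .germline import FilterConfig, FilterTrace, run_cascade, shared_candidates
from .io import (
    read_edge_list,
    read_expression_controls,
    read_expression_table,
    read_gene_list,
    read_gmt,
    read_variant_keys,
    read_variant_table,
)
from .model import SibPairDataset, VariantRecord
from .report import SignatureReport
from .simulate import SimulationConfig, simulate_cohort
from .somatic import LohCall, SomaticTally, call_somatic, detect_loh, tally_somatic
from .worked_example import load_worked_example

logger = logging.getLogger("oligosig")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass(slots=True)
class PipelineConfig:
    """Parsed run configuration.

    YAML layout (all threshold keys optional, defaults shown in
    :class:`~oligosig.germline.FilterConfig` and
    :class:`~oligosig.expression.DEThresholds`)::

        mode: files            # fixture | simulate | files
        out_dir: results/run1
        seed: 1                # simulate mode
        simulate: {n_pairs: 4, n_somatic: 100}
        cases:                 # files mode
          - {case_id: case1, affected: a.tsv, unaffected: u.tsv,
             tumor: t.tsv, dialect: tsv}
        expression: expr.tsv
        panel: panel.txt
        inhouse: inhouse.tsv
        edges: edges.tsv
        gene_sets: sets.gmt
        retain_no_change: [URI1]
        filter: {min_depth: 10, max_maf: 0.01, cadd_min: 20}
        thresholds: {min_fold: 2, alpha: 0.05, pseudocount: 0.1}
        min_hom_af: 0.8
        expand_k: 20
    """

    mode: str = "fixture"
    out_dir: Path = Path("oligosig_out")
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    cases: list[dict] = field(default_factory=list)
    expression: Optional[Path] = None
    panel: Optional[Path] = None
    inhouse: Optional[Path] = None
    edges: Optional[Path] = None
    gene_sets: Optional[Path] = None
    retain_no_change: list[str] = field(default_factory=list)
    filter: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    min_hom_af: float = 0.8
    expand_k: int = 20

    def __post_init__(self) -> None:
        if self.mode not in ("fixture", "simulate", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.out_dir = Path(self.out_dir)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML key-value config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("expression", "panel", "inhouse", "edges", "gene_sets"):
        if data.get(key) is not None:
            data[key] = Path(data[key])
    return PipelineConfig(**data)


@dataclass(slots=True)
class PipelineResult:
    """Everything one run computed, plus where the artifacts went."""

    report: SignatureReport
    traces: dict[str, FilterTrace]
    candidates: dict[str, list[VariantRecord]]
    loh_calls: dict[str, list[LohCall]]
    somatic_tallies: dict[str, SomaticTally]
    enrichment: list[EnrichmentResult]
    network: Optional[CandidateNetwork]
    expanded_network: Optional[CandidateNetwork]
    out_dir: Path


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(
        {k: str(getattr(cfg, k)) for k in sorted(PipelineConfig.__dataclass_fields__)},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(cfg: PipelineConfig):
    """Resolve cohort, expression and resources for the configured mode."""
    if cfg.mode == "fixture":
        ex = load_worked_example()
        return (
            ex.cohort, ex.profiles, ex.control_samples, ex.cancer_genes,
            ex.inhouse_db, ex.edges, ex.gene_sets, set(ex.retain_no_change),
        )
    if cfg.mode == "simulate":
        sim_cfg = SimulationConfig(seed=cfg.seed, **cfg.simulate)
        cohort, expression, truth = simulate_cohort(sim_cfg)
        return (
            cohort, expression.profiles, expression.controls, truth.cancer_genes,
            frozenset(), [], {}, set(cfg.retain_no_change),
        )
    # files mode
    if not cfg.cases:
        raise ValueError("files mode: config lists no cases")
    if cfg.panel is None:
        raise ValueError("files mode: config names no cancer gene panel")
    cohort = []
    for entry in cfg.cases:
        dialect = entry.get("dialect", "tsv")
        tumor = entry.get("tumor")
        cohort.append(
            SibPairDataset(
                case_id=entry["case_id"],
                affected_variants=read_variant_table(entry["affected"], dialect),
                unaffected_variants=read_variant_table(entry["unaffected"], dialect),
                tumor_variants=read_variant_table(tumor, dialect) if tumor else None,
            )
        )
    profiles = read_expression_table(cfg.expression) if cfg.expression else []
    controls = read_expression_controls(cfg.expression) if cfg.expression else {}
    panel = read_gene_list(cfg.panel)
    inhouse = read_variant_keys(cfg.inhouse) if cfg.inhouse else frozenset()
    edges = read_edge_list(cfg.edges) if cfg.edges else []
    gene_sets = read_gmt(cfg.gene_sets) if cfg.gene_sets else {}
    return (cohort, profiles, controls, panel, inhouse, edges, gene_sets,
            set(cfg.retain_no_change))


def run_pipeline(config: PipelineConfig | str | Path) -> PipelineResult:
    """Execute the full analysis and write artifacts to ``cfg.out_dir``."""
    cfg = load_config(config) if not isinstance(config, PipelineConfig) else config
    (cohort, profiles, controls, panel, inhouse, edges, gene_sets,
     retain) = _load_inputs(cfg)

    filter_cfg = FilterConfig(
        inhouse_db=frozenset(inhouse), cancer_genes=frozenset(panel), **cfg.filter
    )
    if not filter_cfg.cancer_genes:
        raise ValueError("cancer gene panel is empty; aborting before any output")
    th = DEThresholds(**cfg.thresholds)

    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)

    candidates: dict[str, list[VariantRecord]] = {}
    traces: dict[str, FilterTrace] = {}
    loh_calls: dict[str, list[LohCall]] = {}
    tallies: dict[str, SomaticTally] = {}
    for pair in cohort:
        logger.info("case %s: running cascade on %d variants",
                    pair.case_id, len(pair.affected_variants))
        cands, trace = run_cascade(pair, filter_cfg)
        candidates[pair.case_id] = cands
        traces[pair.case_id] = trace
        logger.info("case %s: %d candidates", pair.case_id, len(cands))
        if pair.tumor_variants is not None:
            somatic = call_somatic(pair.affected_variants, pair.tumor_variants)
            tallies[pair.case_id] = tally_somatic(somatic)
            loh_calls[pair.case_id] = detect_loh(
                cands, pair.tumor_variants, min_hom_af=cfg.min_hom_af
            )

    if profiles:
        compute_significance(profiles, controls, th=th)
        report = integrate_candidates(candidates, profiles, th, retain_no_change=retain)
    else:
        report = integrate_candidates(candidates, [], th)
    report.attach_loh(
        {case: [c.key for c in calls if c.is_loh] for case, calls in loh_calls.items()}
    )

    enrichment_results: list[EnrichmentResult] = []
    if gene_sets and profiles:
        universe = {p.gene.upper() for p in profiles}
        query = {e.gene.upper() for e in report.entries if e.functional} & universe
        if query:
            enrichment_results = enrich(query, gene_sets, universe)

    network = expanded = None
    if edges:
        per_case_genes = {c: [v.gene for v in records] for c, records in candidates.items()}
        network = build_candidate_network(per_case_genes, edges)
        expanded = expand_network(network, edges, k=cfg.expand_k)

    _write_artifacts(cfg, report, traces, loh_calls, tallies, enrichment_results,
                     network, expanded)
    return PipelineResult(
        report=report, traces=traces, candidates=candidates, loh_calls=loh_calls,
        somatic_tallies=tallies, enrichment=enrichment_results,
        network=network, expanded_network=expanded, out_dir=out,
    )


def _write_artifacts(cfg, report, traces, loh_calls, tallies, enrichment,
                     network, expanded) -> None:
    out = cfg.out_dir
    report.to_tsv(out / "report.tsv")
    report.to_json(out / "report.json")
    (out / "trace.json").write_text(
        json.dumps({c: t.to_json_obj() for c, t in traces.items()}, indent=2)
    )
    with open(out / "loh.tsv", "w") as fh:
        fh.write("case\tchrom\tpos\tref\talt\tgene\tblood_state\ttumor_state\t"
                 "tumor_alt_fraction\tis_loh\n")
        for case, calls in loh_calls.items():
            for c in calls:
                af = "" if c.tumor_alt_fraction is None else f"{c.tumor_alt_fraction:.4f}"
                fh.write(
                    f"{case}\t{c.key[0]}\t{c.key[1]}\t{c.key[2]}\t{c.key[3]}\t"
                    f"{c.gene}\t{c.blood_state.state}\t{c.tumor_state.state}\t"
                    f"{af}\t{c.is_loh}\n"
                )
    (out / "somatic.json").write_text(
        json.dumps({c: t.as_dict() for c, t in tallies.items()}, indent=2)
    )
    if enrichment:
        with open(out / "enrichment.tsv", "w") as fh:
            fh.write("set_name\toverlap\tset_size\tlist_size\tuniverse_size\t"
                     "p_value\tq_value\n")
            for r in enrichment:
                fh.write(f"{r.set_name}\t{r.overlap}\t{r.set_size}\t{r.list_size}\t"
                         f"{r.universe_size}\t{r.p_value:.6g}\t{r.q_value:.6g}\n")
    if network is not None:
        (out / "network.json").write_text(json.dumps(
            {
                "nodes": {g: sorted(cases) for g, cases in network.nodes.items()},
                "edges": [list(e) for e in network.edges],
                "components": [sorted(c) for c in network.components],
                "expanded": {
                    "nodes": {g: sorted(cases) for g, cases in expanded.nodes.items()},
                    "edges": [list(e) for e in expanded.edges],
                    "components": [sorted(c) for c in expanded.components],
                },
            },
            indent=2,
        ))
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "mode": cfg.mode,
        "config_hash": _config_hash(cfg),
        "parameters": {
            "filter": cfg.filter,
            "thresholds": cfg.thresholds,
            "min_hom_af": cfg.min_hom_af,
            "expand_k": cfg.expand_k,
        },
        "summary": report.summary(),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
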