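"""WES/RNA-seq integration on FPKM expression values.

Significance model
------------------
FPKM values are compared on the log2 scale after adding a small pseudocount.
The control-normal group (C, >= 2 samples) calibrates the variance:

* ``p_t_vs_c`` / ``p_n_vs_c`` — one-sample location test of the single
  tumor / normal observation against the control distribution, using the
  prediction-interval statistic (x - mean_C) / (s_C * sqrt(1 + 1/m)) with
  m - 1 degrees of freedom.
* ``p_t_vs_n`` — the tumor-vs-matched-normal contrast treats both as single
  observations with C-calibrated variance: (x_T - x_N) / (s_C * sqrt(2)).

The ``permutation`` alternative is a two-sided rank test of the observation
among the pooled control values (exchangeability under the null makes it
exactly super-uniform), with the T-vs-N contrast ranked against all
pairwise control differences.

Functional classification of a candidate variant's gene distinguishes
three patterns against a no-change background, checked in this order:

* BOTH_DOWN  — T and N each at most C/fold below the control group
  (transcript instability in the carrier);
* TUMOR_DOWN — T at most N/fold (second hit silencing a tumor suppressor);
* TUMOR_UP   — T at least N*fold (oncogene-like activation);
* NO_CHANGE  — otherwise.

BOTH_DOWN pre-empts the tumor-vs-normal comparisons because those are
uninformative when the matched normal is itself depressed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

from .model import TRUNCATING_CONSEQUENCES, ExpressionProfile, FusionCandidate, VariantRecord
from .report import SignatureEntry, SignatureReport

__all__ = [
    "ExpressionClass",
    "DEThresholds",
    "compute_significance",
    "classify_variant_expression",
    "integrate_candidates",
    "de_summary",
    "filter_cancer_fusions",
]


class ExpressionClass(enum.Enum):
    """Functional-effect class of a candidate variant's gene."""

    TUMOR_DOWN = "TUMOR_DOWN"
    TUMOR_UP = "TUMOR_UP"
    BOTH_DOWN = "BOTH_DOWN"
    NO_CHANGE = "NO_CHANGE"


@dataclass(frozen=True, slots=True)
class DEThresholds:
    """Fold-change / significance thresholds for differential calls.

    min_fold is a linear fold change (2 means a two-fold change in either
    direction); pseudocount is the FPKM offset protecting log-ratios from
    zeros.
    """

    min_fold: float = 2.0
    alpha: float = 0.05
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        if self.min_fold <= 1:
            raise ValueError("min_fold must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


def _one_sample_p(x: float, controls: Sequence[float], ps: float) -> float:
    """Two-sided prediction-interval t test of one log2 value vs controls."""
    logs = [math.log2(c + ps) for c in controls]
    m = len(logs)
    mean = sum(logs) / m
    var = sum((v - mean) ** 2 for v in logs) / (m - 1)
    sd = math.sqrt(var)
    diff = math.log2(x + ps) - mean
    if sd == 0.0:
        return 1.0 if diff == 0.0 else 0.0
    t = diff / (sd * math.sqrt(1.0 + 1.0 / m))
    return float(2.0 * stats.t.sf(abs(t), df=m - 1))


def _paired_single_p(x: float, y: float, controls: Sequence[float], ps: float) -> float:
    """Two-sided test of log2(x) - log2(y), variance calibrated on controls."""
    logs = [math.log2(c + ps) for c in controls]
    m = len(logs)
    mean = sum(logs) / m
    var = sum((v - mean) ** 2 for v in logs) / (m - 1)
    sd = math.sqrt(var)
    diff = math.log2(x + ps) - math.log2(y + ps)
    if sd == 0.0:
        return 1.0 if diff == 0.0 else 0.0
    t = diff / (sd * math.sqrt(2.0))
    return float(2.0 * stats.t.sf(abs(t), df=m - 1))


def _rank_p(x: float, controls: Sequence[float]) -> float:
    """Two-sided rank of x among pooled {x} + controls; exact under the null."""
    m = len(controls)
    k_low = sum(1 for c in controls if c <= x)
    k_high = sum(1 for c in controls if c >= x)
    return min(1.0, 2.0 * (min(k_low, k_high) + 1) / (m + 1))


def _rank_diff_p(x: float, y: float, controls: Sequence[float], ps: float) -> float:
    """Rank |log2 x - log2 y| against all pairwise control differences."""
    logs = [math.log2(c + ps) for c in controls]
    obs = abs(math.log2(x + ps) - math.log2(y + ps))
    diffs = [abs(a - b) for i, a in enumerate(logs) for j, b in enumerate(logs) if i != j]
    if not diffs:
        return 1.0
    extreme = sum(1 for d in diffs if d >= obs)
    return (1 + extreme) / (1 + len(diffs))


def compute_significance(
    profiles: Iterable[ExpressionProfile],
    c_samples: Mapping[str, Sequence[float]],
    method: str = "log_t",
    th: DEThresholds | None = None,
) -> list[ExpressionProfile]:
    """Fill the three p-value slots of each profile in place.

    c_samples maps gene symbol to the raw control-group FPKM values
    (>= 2 per gene). Returns the same profile objects for chaining.
    """
    if method not in ("log_t", "permutation"):
        raise ValueError(f"unknown significance method {method!r}")
    th = th or DEThresholds()
    ps = th.pseudocount
    out: list[ExpressionProfile] = []
    for prof in profiles:
        controls = c_samples.get(prof.gene)
        if controls is None or len(controls) < 2:
            raise ValueError(f"gene {prof.gene}: need >= 2 control samples")
        if method == "log_t":
            prof.p_t_vs_c = _one_sample_p(prof.fpkm_t, controls, ps)
            prof.p_n_vs_c = _one_sample_p(prof.fpkm_n, controls, ps)
            prof.p_t_vs_n = _paired_single_p(prof.fpkm_t, prof.fpkm_n, controls, ps)
        else:
            prof.p_t_vs_c = _rank_p(prof.fpkm_t, controls)
            prof.p_n_vs_c = _rank_p(prof.fpkm_n, controls)
            prof.p_t_vs_n = _rank_diff_p(prof.fpkm_t, prof.fpkm_n, controls, ps)
        out.append(prof)
    return out


def classify_variant_expression(
    profile: ExpressionProfile, th: DEThresholds | None = None
) -> ExpressionClass:
    """Assign one of the four functional-effect classes to a profiled gene."""
    th = th or DEThresholds()
    if profile.p_t_vs_n is None or profile.p_t_vs_c is None or profile.p_n_vs_c is None:
        raise ValueError(f"gene {profile.gene}: significance not computed")
    fold = th.min_fold
    if (
        profile.fpkm_t <= profile.fpkm_c_mean / fold
        and profile.fpkm_n <= profile.fpkm_c_mean / fold
        and profile.p_t_vs_c <= th.alpha
        and profile.p_n_vs_c <= th.alpha
    ):
        return ExpressionClass.BOTH_DOWN
    if profile.fpkm_t <= profile.fpkm_n / fold and profile.p_t_vs_n <= th.alpha:
        return ExpressionClass.TUMOR_DOWN
    if profile.fpkm_t >= profile.fpkm_n * fold and profile.p_t_vs_n <= th.alpha:
        return ExpressionClass.TUMOR_UP
    return ExpressionClass.NO_CHANGE


def integrate_candidates(
    candidates: Mapping[str, Sequence[VariantRecord]],
    profiles: Iterable[ExpressionProfile],
    th: DEThresholds | None = None,
    retain_no_change: Iterable[str] = (),
) -> SignatureReport:
    """Annotate each case's candidates with their gene's expression class.

    candidates maps case id -> prioritized variant list (cascade output).
    A candidate is *functional* when its class is not NO_CHANGE. The
    ``retain_no_change`` gene list additionally flags NO_CHANGE truncating
    variants in putative tumor suppressors for the RNA-effect panel — an
    explicit opt-in, not an automatic rule.
    """
    th = th or DEThresholds()
    by_gene = {p.gene.upper(): p for p in profiles}
    retain = {g.upper() for g in retain_no_change}
    entries: list[SignatureEntry] = []
    for case_id, records in candidates.items():
        for rec in records:
            prof = by_gene.get(rec.gene.upper())
            if prof is None:
                entries.append(
                    SignatureEntry(
                        case_id=case_id,
                        gene=rec.gene,
                        key=rec.key,
                        hgvs=rec.hgvs,
                        consequence=rec.consequence,
                        expression_class=None,
                        functional=False,
                        rna_panel=False,
                    )
                )
                continue
            cls = classify_variant_expression(prof, th)
            functional = cls is not ExpressionClass.NO_CHANGE
            retained = (
                cls is ExpressionClass.NO_CHANGE
                and rec.gene.upper() in retain
                and rec.consequence in TRUNCATING_CONSEQUENCES
            )
            entries.append(
                SignatureEntry(
                    case_id=case_id,
                    gene=rec.gene,
                    key=rec.key,
                    hgvs=rec.hgvs,
                    consequence=rec.consequence,
                    expression_class=cls.value,
                    functional=functional,
                    rna_panel=functional or retained,
                )
            )
    return SignatureReport(entries=entries)


def de_summary(
    all_profiles: Iterable[ExpressionProfile], th: DEThresholds | None = None
) -> tuple[list[str], list[str]]:
    """Genome-wide differential-expression lists (up, down), tumor vs normal.

    up: fpkm_t >= fpkm_n * min_fold with p_t_vs_n <= alpha;
    down: fpkm_t <= fpkm_n / min_fold with p_t_vs_n <= alpha.
    Each list is ranked by significance then magnitude.
    """
    th = th or DEThresholds()
    up: list[tuple[float, float, str]] = []
    down: list[tuple[float, float, str]] = []
    for prof in all_profiles:
        if prof.p_t_vs_n is None:
            raise ValueError(f"gene {prof.gene}: significance not computed")
        if prof.p_t_vs_n > th.alpha:
            continue
        ratio = (prof.fpkm_t + th.pseudocount) / (prof.fpkm_n + th.pseudocount)
        if prof.fpkm_t >= prof.fpkm_n * th.min_fold:
            up.append((prof.p_t_vs_n, -ratio, prof.gene))
        elif prof.fpkm_t <= prof.fpkm_n / th.min_fold:
            down.append((prof.p_t_vs_n, ratio, prof.gene))
    return [g for _, _, g in sorted(up)], [g for _, _, g in sorted(down)]


def filter_cancer_fusions(
    fusions: Iterable[FusionCandidate], min_span: int = 10
) -> list[FusionCandidate]:
    """Keep tumor-specific fusions: supported in tumor, not in normal.

    A fusion survives with >= min_span spanning reads in tumor and fewer
    than min_span in the matched normal tissue.
    """
    return [
        f
        for f in fusions
        if f.spanning_reads_tumor >= min_span and f.spanning_reads_normal < min_span
    ]
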