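"""Per-patient predisposing-signature report and cohort summaries."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = ["SignatureEntry", "SignatureReport"]

Key = tuple[str, int, str, str]


@dataclass(frozen=True, slots=True)
class SignatureEntry:
    """One candidate variant in one case, with its functional annotation.

    expression_class is None when the gene had no expression profile;
    ``functional`` means the class is an actual change (not NO_CHANGE);
    ``rna_panel`` flags membership of the RNA-effect candidate panel
    (functional variants plus explicitly retained no-change truncating
    variants); ``loh`` marks a blood-het / tumor-hom zygosity shift.
    """

    case_id: str
    gene: str
    key: Key
    hgvs: Optional[str]
    consequence: str
    expression_class: Optional[str]
    functional: bool
    rna_panel: bool
    loh: bool = False


@dataclass(slots=True)
class SignatureReport:
    """Candidate variants across the cohort plus derived summaries.

    Shared variants (same key in several cases) are de-duplicated in every
    pooled count; per-case counts keep them in each owning case.
    """

    entries: list[SignatureEntry] = field(default_factory=list)

    # -- construction helpers ------------------------------------------------

    def attach_loh(self, loh_keys_by_case: Mapping[str, Iterable[Key]]) -> None:
        """Mark entries whose (case, key) is an LOH call."""
        lookup = {
            (case, key) for case, keys in loh_keys_by_case.items() for key in keys
        }
        self.entries = [
            replace(e, loh=(e.case_id, e.key) in lookup) for e in self.entries
        ]

    # -- views ---------------------------------------------------------------

    @property
    def case_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.case_id)
        return list(seen)

    def per_case(self) -> dict[str, list[SignatureEntry]]:
        out: dict[str, list[SignatureEntry]] = {c: [] for c in self.case_ids}
        for e in self.entries:
            out[e.case_id].append(e)
        return out

    def _distinct(self) -> dict[Key, SignatureEntry]:
        by_key: dict[Key, SignatureEntry] = {}
        for e in self.entries:
            prev = by_key.get(e.key)
            # keep the flagged view of a shared variant if any case flags it
            if prev is None:
                by_key[e.key] = e
            elif (e.functional, e.rna_panel, e.loh) > (prev.functional, prev.rna_panel, prev.loh):
                by_key[e.key] = e
        return by_key

    def class_counts(self) -> dict[str, int]:
        """Distinct-variant counts per expression class (profiled only)."""
        counts: dict[str, int] = {}
        for e in self._distinct().values():
            if e.expression_class is not None:
                counts[e.expression_class] = counts.get(e.expression_class, 0) + 1
        return counts

    def summary(self) -> dict:
        distinct = self._distinct()
        per_case = self.per_case()
        case_counts = {c: len(v) for c, v in per_case.items()}
        functional_counts = {
            c: sum(1 for e in v if e.functional) for c, v in per_case.items()
        }
        shared = sum(
            1
            for key in distinct
            if len({e.case_id for e in self.entries if e.key == key}) >= 2
        )

        def stats(counts: dict[str, int]) -> dict:
            values = list(counts.values()) or [0]
            return {
                "per_case": counts,
                "mean": sum(values) / len(values),
                "min": min(values),
                "max": max(values),
            }

        return {
            "total_candidates": len(distinct),
            "shared_variants": shared,
            "class_counts": self.class_counts(),
            "rna_panel_size": sum(1 for e in distinct.values() if e.rna_panel),
            "functional_variants": sum(1 for e in distinct.values() if e.functional),
            "loh_count": sum(1 for e in distinct.values() if e.loh),
            "candidates": stats(case_counts),
            "functional": stats(functional_counts),
        }

    # -- export --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "case": e.case_id,
                "gene": e.gene,
                "chrom": e.key[0],
                "pos": e.key[1],
                "ref": e.key[2],
                "alt": e.key[3],
                "mutation": e.hgvs or "",
                "consequence": e.consequence,
                "expression_class": e.expression_class or "unprofiled",
                "functional": e.functional,
                "rna_panel": e.rna_panel,
                "loh": e.loh,
            }
            for e in self.entries
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "case", "gene", "chrom", "pos", "ref", "alt", "mutation",
                "consequence", "expression_class", "functional", "rna_panel", "loh",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json_obj(self) -> dict:
        return {
            "cases": {
                case: [
                    {
                        "gene": e.gene,
                        "key": list(e.key),
                        "mutation": e.hgvs,
                        "consequence": e.consequence,
                        "expression_class": e.expression_class,
                        "functional": e.functional,
                        "rna_panel": e.rna_panel,
                        "loh": e.loh,
                    }
                    for e in entries
                ]
                for case, entries in self.per_case().items()
            },
            "summary": self.summary(),
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_obj(), fh, indent=2)
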