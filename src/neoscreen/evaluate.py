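"""Screening comparison statistics and report tables.

All rates are computed from counts and rounded half-up at the printed
precision (one decimal for the recall rate, two elsewhere), so that a rate
recomputed from a published count column reproduces the published cell
exactly.  The consistent rate between the model and the physician,
100 x (ai_pos - ai_pos_first_neg) / phys_pos, treats "AI-positive among
first-screen-negative" as the samples only the model flagged; a negative
false-positive reduction means the physician baseline flagged fewer.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

import pandas as pd

__all__ = [
    "ComparisonRow",
    "IncidenceReport",
    "MutationTable",
    "recall_rate",
    "positive_rate",
    "consistent_rate",
    "fp_reduction",
    "overall_fp_reduction",
    "incidence_string",
    "allele_frequency_table",
    "build_comparison_table",
]


def _round_half_up(value: Decimal, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def _percent(numerator, denominator, decimals: int) -> float:
    return _round_half_up(Decimal(numerator) * 100 / Decimal(denominator), decimals)


def recall_rate(n_flagged: int, n_screened: int, decimals: int = 1) -> float:
    """Initial-screen flag rate, %: 100 x n_flagged / n_screened."""
    if n_screened <= 0:
        raise ValueError("n_screened must be > 0")
    return _percent(n_flagged, n_screened, decimals)


def positive_rate(n_pos: int, n_screened: int, decimals: int = 2) -> float:
    if n_screened <= 0:
        raise ValueError("n_screened must be > 0")
    return _percent(n_pos, n_screened, decimals)


def consistent_rate(ai_pos: int, ai_pos_first_neg: int, phys_pos: int,
                    decimals: int = 2) -> float | None:
    """Share of physician positives also flagged by the model, %:
    100 x (ai_pos - ai_pos_first_neg) / phys_pos.  None when undefined."""
    if phys_pos <= 0:
        return None
    return _percent(ai_pos - ai_pos_first_neg, phys_pos, decimals)


def fp_reduction(phys_pos: int, ai_pos: int, decimals: int = 2) -> float | None:
    """Relative reduction in flags, %: 100 x (phys_pos - ai_pos) / phys_pos.
    Negative when the model flags more; None when undefined."""
    if phys_pos <= 0:
        return None
    return _percent(phys_pos - ai_pos, phys_pos, decimals)


def overall_fp_reduction(total_phys_pos: int, excluded_outside_panel: int,
                         total_ai_pos: int, decimals: int = 2) -> float:
    """Cohort-level reduction after excluding flags for disorders outside
    the model's panel: 100 x ((phys - excluded) - ai) / (phys - excluded)."""
    denom = total_phys_pos - excluded_outside_panel
    if denom <= 0:
        raise ValueError("physician positives after exclusion must be > 0")
    return _percent(denom - total_ai_pos, denom, decimals)


def incidence_string(n_screened: int, n_cases: int) -> str:
    """Frequency in '1:N' form with thousands separators; a dash when
    there are no cases."""
    if n_cases < 0 or n_screened < 0:
        raise ValueError("counts must be non-negative")
    if n_cases == 0:
        return "–"
    n = int(_round_half_up(Decimal(n_screened) / Decimal(n_cases), 0))
    return f"1:{n:,}"


@dataclass(frozen=True)
class IncidenceReport:
    label: str
    n_cases: int
    n_screened: int

    @property
    def frequency_string(self) -> str:
        return incidence_string(self.n_screened, self.n_cases)


@dataclass(frozen=True)
class MutationTable:
    """Per-variant allele counts with relative (within-gene) and overall
    percentage shares, plus per-gene totals."""

    variants: pd.DataFrame  # gene, variant, allele_count, relative_frequency, portion_of_total
    genes: pd.DataFrame     # gene, allele_count, portion_of_total


def allele_frequency_table(counts_by_gene: Mapping[str, Mapping[str, int]]) -> MutationTable:
    """relative_frequency = 100 x count / gene total;
    portion_of_total = 100 x count / grand total of alleles."""
    variant_rows = []
    gene_rows = []
    grand_total = sum(sum(v.values()) for v in counts_by_gene.values())
    for gene, variants in counts_by_gene.items():
        gene_total = sum(variants.values())
        for variant, count in variants.items():
            if count < 1:
                raise ValueError(f"{gene} {variant}: allele counts must be >= 1")
            variant_rows.append({
                "gene": gene,
                "variant": variant,
                "allele_count": int(count),
                "relative_frequency": _percent(count, gene_total, 2),
                "portion_of_total": _percent(count, grand_total, 2),
            })
        gene_rows.append({
            "gene": gene,
            "allele_count": int(gene_total),
            "portion_of_total": _percent(gene_total, grand_total, 2),
        })
    columns_v = ["gene", "variant", "allele_count", "relative_frequency", "portion_of_total"]
    columns_g = ["gene", "allele_count", "portion_of_total"]
    return MutationTable(
        variants=pd.DataFrame(variant_rows, columns=columns_v),
        genes=pd.DataFrame(gene_rows, columns=columns_g),
    )


@dataclass(frozen=True)
class ComparisonRow:
    group_id: str
    ai_pos: int
    phys_pos: int
    ai_pos_first_neg: int
    consistent_rate: float | None
    ai_rate: float
    phys_rate: float
    fp_reduction: float | None


@dataclass(frozen=True)
class ComparisonSummary:
    rows: tuple
    ai_total: int          # distinct samples flagged by the model
    phys_total: int        # distinct samples flagged by the baseline
    both: int              # flagged by both
    ai_only: int           # model-only flags (baseline-negative)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def build_comparison_table(
    ai_flags: Mapping[str, set],
    phys_flags: Mapping[str, set],
    truth: Mapping[str, str | None],
    n_screened: int,
) -> ComparisonSummary:
    """Per-group model-vs-baseline counts and derived rates.

    ``ai_pos_first_neg`` counts model flags on samples negative on the
    baseline's initial screen overall (any group).  Samples flagged but
    absent from the cohort raise ValueError.
    """
    known = set(truth)
    for source, mapping in (("model", ai_flags), ("baseline", phys_flags)):
        for group, ids in mapping.items():
            stray = set(ids) - known
            if stray:
                raise ValueError(f"{source} flags for {group!r} include unknown samples: "
                                 f"{sorted(stray)[:3]}")
    phys_any = set().union(*phys_flags.values()) if phys_flags else set()
    rows = []
    groups = sorted(set(ai_flags) | set(phys_flags))
    for g in groups:
        ai = set(ai_flags.get(g, set()))
        phys = set(phys_flags.get(g, set()))
        first_neg = len(ai - phys_any)
        rows.append(ComparisonRow(
            group_id=g,
            ai_pos=len(ai),
            phys_pos=len(phys),
            ai_pos_first_neg=first_neg,
            consistent_rate=consistent_rate(len(ai), first_neg, len(phys)),
            ai_rate=positive_rate(len(ai), n_screened),
            phys_rate=positive_rate(len(phys), n_screened),
            fp_reduction=fp_reduction(len(phys), len(ai)),
        ))
    ai_any = set().union(*ai_flags.values()) if ai_flags else set()
    return ComparisonSummary(
        rows=tuple(rows),
        ai_total=len(ai_any),
        phys_total=len(phys_any),
        both=len(ai_any & phys_any),
        ai_only=len(ai_any - phys_any),
    )
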