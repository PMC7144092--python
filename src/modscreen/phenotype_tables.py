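"""Penetrance, viability and fertility tables for the modifier screen.

A screen row records how many flies of a genotype were scored and how many
showed each morphological trait (down-turned wings, indented thorax).  Each
row is compared against the no-deficiency control with Fisher's exact test,
and significance is called against the Bonferroni-adjusted threshold
alpha / m where m is the number of deficiency rows.

Published tables print n and a 1-decimal percentage rather than raw counts;
``reconstruct_counts`` inverts that rounding and flags cells whose printed
percentage is not consistent with any integer count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from . import core_stats

__all__ = [
    "PhenotypeRecord",
    "ViabilityRecord",
    "penetrance",
    "reconstruct_counts",
    "screen_report",
    "viability_fertility_summary",
]

TRAITS = ("wings", "thorax")


@dataclass(frozen=True)
class PhenotypeRecord:
    """Scored flies of one genotype with per-trait affected counts."""

    label: str
    flies_scored: int
    affected: dict[str, int] = field(default_factory=dict)
    deleted_segment: str = ""
    deleted_genes: str = ""

    def __post_init__(self) -> None:
        if self.flies_scored < 1:
            raise ValueError("flies_scored must be >= 1")
        for trait, count in self.affected.items():
            if not 0 <= count <= self.flies_scored:
                raise ValueError(
                    f"{self.label}/{trait}: affected count {count} outside [0, {self.flies_scored}]"
                )


@dataclass(frozen=True)
class ViabilityRecord:
    """Male progeny classes of one cross plus the fertility assay counts."""

    genotype: str
    total_male: int
    balancer_class: int
    mutant_class: int
    fertility_tested: int
    sterile: int
    fertile: int

    def __post_init__(self) -> None:
        if self.balancer_class + self.mutant_class != self.total_male:
            raise ValueError(
                f"{self.genotype}: class counts {self.balancer_class}+{self.mutant_class} "
                f"do not sum to total {self.total_male}"
            )
        if self.sterile + self.fertile != self.fertility_tested:
            raise ValueError(
                f"{self.genotype}: sterile+fertile must equal the number tested"
            )
        if min(self.total_male, self.fertility_tested) < 1:
            raise ValueError("totals must be >= 1")


def penetrance(record: PhenotypeRecord, trait: str) -> float:
    """Percentage of scored flies showing the trait, to 1 decimal."""
    if trait not in record.affected:
        raise KeyError(f"trait {trait!r} not scored for {record.label!r}")
    return round(100.0 * record.affected[trait] / record.flies_scored, 1)


def reconstruct_counts(n: int, percent: float) -> tuple[int, bool]:
    """Invert a printed 1-decimal percentage back to an integer count.

    Returns ``(count, valid)`` where ``count = round(n * percent / 100)``
    (half away from zero, matching how printed percentages are produced) and
    ``valid`` records whether re-deriving the 1-decimal percentage from that
    count recovers the input — False flags a printed value inconsistent with
    every integer count.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= percent <= 100.0:
        raise ValueError("percent must lie in [0, 100]")
    count = math.floor(n * percent / 100.0 + 0.5)
    valid = round(100.0 * count / n, 1) == round(percent, 1)
    return count, valid


def screen_report(
    records: list[PhenotypeRecord],
    control: PhenotypeRecord,
    *,
    alpha: float = 0.05,
    m: int | None = None,
    traits: tuple[str, ...] = TRAITS,
) -> pd.DataFrame:
    """Fisher's exact test of every record against the control, per trait.

    The significance flag compares each raw p against the Bonferroni
    threshold ``alpha / m`` with ``m`` defaulting to the number of records
    (deficiency rows)."""
    if not records:
        raise ValueError("need at least one record")
    if m is None:
        m = len(records)
    threshold = core_stats.bonferroni_threshold(alpha, m)
    rows = []
    for rec in records:
        for trait in traits:
            affected = rec.affected[trait]
            ctrl_affected = control.affected[trait]
            result = core_stats.fisher_exact(
                [
                    [affected, rec.flies_scored - affected],
                    [ctrl_affected, control.flies_scored - ctrl_affected],
                ]
            )
            rows.append(
                {
                    "label": rec.label,
                    "trait": trait,
                    "n": rec.flies_scored,
                    "affected": affected,
                    "penetrance_pct": penetrance(rec, trait),
                    "odds_ratio": result.odds_ratio,
                    "p_value": result.p_value,
                    "significant": result.p_value < threshold,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["family_size"] = m
    return out


def viability_fertility_summary(record: ViabilityRecord) -> tuple[float, float]:
    """(% mutant-class males among total male progeny, % fertile among
    tested), each to 1 decimal."""
    pct_mutant = round(100.0 * record.mutant_class / record.total_male, 1)
    pct_fertile = round(100.0 * record.fertile / record.fertility_tested, 1)
    return pct_mutant, pct_fertile
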