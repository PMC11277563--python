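"""Simultaneous target-coverage scoring against a panel.

A miRNA's target score for a panel is the count (and fraction) of panel
genes it is recorded to target at the same time. The selection rule keeps
miRNAs whose fraction strictly exceeds a threshold (default 75%): for an
8-gene panel that means at least 7 genes, since 6/8 = 75% exactly is
excluded by strictness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .errors import ValidationError
from .network import PanelNetwork
from .panels import PanelKey

__all__ = [
    "TargetScore",
    "ThresholdRule",
    "compute_target_score",
    "min_required_count",
    "filter_by_score",
]


@dataclass(frozen=True)
class TargetScore:
    """Coverage of one panel by one miRNA, kept as an exact rational."""

    mirna_id: str
    panel_key: PanelKey
    targeted_genes: tuple[str, ...]
    panel_size: int

    def __post_init__(self) -> None:
        if len(set(self.targeted_genes)) != len(self.targeted_genes):
            raise ValidationError("targeted_genes contains duplicates")
        if self.count > self.panel_size:
            raise ValidationError(
                f"count {self.count} exceeds panel size {self.panel_size}"
            )

    @property
    def count(self) -> int:
        return len(self.targeted_genes)

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.count, self.panel_size)

    @property
    def percent(self) -> float:
        """Percentage rounded to one decimal (87.5, 77.8, 100.0, …)."""
        return round(100 * self.count / self.panel_size, 1)

    @property
    def percent_str(self) -> str:
        """Display form: integer percentages drop the decimal ("100%", "80%")."""
        pct = self.percent
        return f"{pct:.0f}%" if pct == int(pct) else f"{pct}%"

    @property
    def ratio_str(self) -> str:
        return f"{self.count}/{self.panel_size}"


@dataclass(frozen=True)
class ThresholdRule:
    """Coverage-fraction threshold; strict means the fraction must exceed it."""

    min_fraction: float = 0.75
    strict: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction <= 1:
            raise ValidationError(
                f"min_fraction must be in (0, 1], got {self.min_fraction}"
            )


def compute_target_score(net: PanelNetwork, mirna: str) -> TargetScore:
    """Score one miRNA against the network's panel (0 coverage if absent)."""
    targeted = tuple(g for g in net.panel.genes if (mirna, g) in net.edges)
    return TargetScore(
        mirna_id=mirna,
        panel_key=net.panel.key,
        targeted_genes=targeted,
        panel_size=net.panel.size,
    )


def min_required_count(panel_size: int, rule: ThresholdRule = ThresholdRule()) -> int:
    """Smallest targeted-gene count that satisfies the threshold rule.

    With ``strict=True`` this is the least k with k > min_fraction * n;
    otherwise the least k with k >= min_fraction * n. Computed exactly on
    rationals so boundary cases (e.g. 6/8 at 75%) are never lost to
    floating point.
    """
    if panel_size < 1:
        raise ValidationError(f"panel_size must be >= 1, got {panel_size}")
    bound = Fraction(*float(rule.min_fraction).as_integer_ratio()) * panel_size
    if rule.strict:
        return math.floor(bound) + 1
    return math.ceil(bound)


def filter_by_score(
    net: PanelNetwork, rule: ThresholdRule = ThresholdRule()
) -> list[TargetScore]:
    """Scores of every miRNA meeting the threshold, best first.

    Sorted by descending count, ties broken lexicographically by miRNA id.
    The result depends only on the edge set, so row order and duplicate
    input rows cannot change it.
    """
    needed = min_required_count(net.panel.size, rule)
    scores = [compute_target_score(net, m) for m in net.mirnas]
    passing = [s for s in scores if s.count >= needed]
    return sorted(passing, key=lambda s: (-s.count, s.mirna_id))
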