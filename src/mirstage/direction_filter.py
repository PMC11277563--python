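"""Reverse-expression consistency filter and per-stage result assembly.

A miRNA that passes the coverage threshold for a panel qualifies only if
the literature reports it dysregulated in the direction opposite to the
panel (a repressor of upregulated genes should itself be downregulated,
and vice versa) in an allowed biospecimen source. Score-passing miRNAs
that fail this check are retained in a rejected list with reasons, so the
filter is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .curation import DirectionVerdict, DysregulationDB, query_direction
from .enums import DEFAULT_ALLOWED_SOURCES, Direction, Source, Stage
from .errors import ValidationError
from .network import InteractionTable, panel_subnetwork
from .panels import PanelKey, StagePanel, panels_for_stage
from .scoring import TargetScore, ThresholdRule, filter_by_score

__all__ = [
    "required_direction",
    "StageCandidate",
    "RejectedCandidate",
    "PanelCounts",
    "StageResult",
    "run_stage",
]


def required_direction(panel_direction: Direction) -> Direction:
    """Dysregulation direction a candidate must show: the panel's opposite."""
    return panel_direction.opposite


@dataclass(frozen=True)
class StageCandidate:
    """A qualified stage-specific miRNA with full provenance."""

    mirna_id: str
    panel_direction: Direction
    required_mirna_direction: Direction
    score: TargetScore
    verdict: DirectionVerdict

    def __post_init__(self) -> None:
        if self.required_mirna_direction is not self.panel_direction.opposite:
            raise ValidationError("required_mirna_direction must oppose panel_direction")
        if not self.verdict.passes:
            raise ValidationError("candidate verdict must pass the direction filter")


@dataclass(frozen=True)
class RejectedCandidate:
    """A score-passing miRNA that failed the direction filter."""

    mirna_id: str
    panel_direction: Direction
    required_mirna_direction: Direction
    score: TargetScore
    verdict: DirectionVerdict
    reason: str


@dataclass(frozen=True)
class PanelCounts:
    """Filter-funnel sizes for one panel: network -> score -> direction."""

    panel_key: PanelKey
    n_network_mirnas: int
    n_score_passing: int
    n_direction_passing: int


@dataclass
class StageResult:
    """Filtered miRNA sets for one stage, across all of its panels."""

    stage: Stage
    candidates: list[StageCandidate] = field(default_factory=list)
    rejected: list[RejectedCandidate] = field(default_factory=list)
    counts: list[PanelCounts] = field(default_factory=list)

    def candidate_mirnas(self, mirna_direction: Direction | None = None) -> frozenset[str]:
        """Candidate ids, optionally restricted to one miRNA dysregulation direction."""
        return frozenset(
            c.mirna_id
            for c in self.candidates
            if mirna_direction is None or c.required_mirna_direction is mirna_direction
        )


def run_stage(
    stage: Stage,
    panels: Mapping[PanelKey, StagePanel],
    table: InteractionTable,
    db: DysregulationDB,
    rule: ThresholdRule = ThresholdRule(),
    allowed_sources: frozenset[Source] = DEFAULT_ALLOWED_SOURCES,
) -> StageResult:
    """Run subnetwork -> coverage filter -> direction filter for one stage.

    Raises
    ------
    ValidationError
        If no panel is defined for ``stage``.
    """
    stage_panels = panels_for_stage(panels, stage)
    if not stage_panels:
        raise ValidationError(f"no panels defined for stage {stage.value!r}")

    result = StageResult(stage=stage)
    for panel in stage_panels:
        net = panel_subnetwork(table, panel)
        passing = filter_by_score(net, rule)
        needed = required_direction(panel.direction)
        n_qualified = 0
        for score in passing:
            verdict = query_direction(db, score.mirna_id, needed, allowed_sources)
            if verdict.passes:
                n_qualified += 1
                result.candidates.append(
                    StageCandidate(
                        mirna_id=score.mirna_id,
                        panel_direction=panel.direction,
                        required_mirna_direction=needed,
                        score=score,
                        verdict=verdict,
                    )
                )
            else:
                reason = (
                    f"no {needed.value}regulation evidence in allowed sources "
                    f"({', '.join(sorted(s.value for s in allowed_sources))})"
                )
                result.rejected.append(
                    RejectedCandidate(
                        mirna_id=score.mirna_id,
                        panel_direction=panel.direction,
                        required_mirna_direction=needed,
                        score=score,
                        verdict=verdict,
                        reason=reason,
                    )
                )
        result.counts.append(
            PanelCounts(
                panel_key=panel.key,
                n_network_mirnas=len(net.mirnas),
                n_score_passing=len(passing),
                n_direction_passing=n_qualified,
            )
        )
    return result
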