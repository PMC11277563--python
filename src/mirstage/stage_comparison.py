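"""Cross-stage set algebra: shared core, distinguishing sets, disease overlap."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .direction_filter import StageResult
from .enums import Direction, Stage
from .errors import ValidationError

__all__ = [
    "DiseaseEntry",
    "DISEASE_LEVEL_MIRNAS",
    "ComparisonReport",
    "compare_stages",
]

DiseaseEntry = tuple[str, Direction]

#: Default disease-level reference list: the five most disease-specific
#: miRNAs from the prior whole-disease analysis, with their reported
#: dysregulation directions.
DISEASE_LEVEL_MIRNAS: frozenset[DiseaseEntry] = frozenset(
    {
        ("hsa-miR-34a-5p", Direction.DOWN),
        ("hsa-miR-155-5p", Direction.UP),
        ("hsa-miR-124-3p", Direction.DOWN),
        ("hsa-miR-1-3p", Direction.DOWN),
        ("hsa-miR-16-5p", Direction.DOWN),
    }
)


@dataclass(frozen=True)
class ComparisonReport:
    """Decomposition of ordered stage results.

    ``shared_core`` is the set of miRNAs downregulated in every stage.
    ``distinguishing`` maps each stage to the (miRNA, direction) elements it
    adds relative to the shared core plus all earlier stages with the same
    direction; on stage-monotone inputs the core plus the cumulative added
    sets reconstructs each stage's candidate sets exactly. The full
    per-stage sets are retained in ``stage_sets`` so nothing is lost when
    inputs are not monotone. A miRNA appearing in both directions is two
    distinct elements throughout.
    """

    stage_order: tuple[Stage, ...]
    stage_sets: Mapping[Stage, Mapping[Direction, frozenset[str]]]
    shared_core: frozenset[str]
    distinguishing: Mapping[Stage, Mapping[str, frozenset[str]]]
    disease_overlap: frozenset[DiseaseEntry]


def compare_stages(
    results: Sequence[StageResult],
    disease_list: frozenset[DiseaseEntry] = DISEASE_LEVEL_MIRNAS,
) -> ComparisonReport:
    """Compare ordered stage results (earliest stage first).

    Raises
    ------
    ValidationError
        If fewer than two stage results are supplied.
    """
    if len(results) < 2:
        raise ValidationError("stage comparison requires at least two stages")

    order = tuple(r.stage for r in results)
    if len(set(order)) != len(order):
        raise ValidationError("duplicate stages in comparison input")

    stage_sets: dict[Stage, dict[Direction, frozenset[str]]] = {
        r.stage: {d: r.candidate_mirnas(d) for d in Direction} for r in results
    }

    # shared core: downregulated in every stage (order-invariant)
    core = frozenset.intersection(*(stage_sets[s][Direction.DOWN] for s in order))

    distinguishing: dict[Stage, dict[str, frozenset[str]]] = {}
    earlier: dict[Direction, frozenset[str]] = {
        Direction.DOWN: core,
        Direction.UP: frozenset(),
    }
    for stage in order:
        added = {
            "added_down": stage_sets[stage][Direction.DOWN] - earlier[Direction.DOWN],
            "added_up": stage_sets[stage][Direction.UP] - earlier[Direction.UP],
        }
        distinguishing[stage] = added
        earlier = {
            Direction.DOWN: earlier[Direction.DOWN] | stage_sets[stage][Direction.DOWN],
            Direction.UP: earlier[Direction.UP] | stage_sets[stage][Direction.UP],
        }

    all_elements: set[DiseaseEntry] = set()
    for stage in order:
        for direction in Direction:
            all_elements.update((m, direction) for m in stage_sets[stage][direction])
    overlap = frozenset(all_elements & set(disease_list))

    return ComparisonReport(
        stage_order=order,
        stage_sets={s: dict(v) for s, v in stage_sets.items()},
        shared_core=core,
        distinguishing=distinguishing,
        disease_overlap=overlap,
    )


def report_to_dict(report: ComparisonReport) -> dict:
    """JSON-friendly rendering of a comparison report."""
    return {
        "stage_order": [s.value for s in report.stage_order],
        "shared_core": sorted(report.shared_core),
        "stage_sets": {
            s.value: {d.value: sorted(report.stage_sets[s][d]) for d in Direction}
            for s in report.stage_order
        },
        "distinguishing": {
            s.value: {k: sorted(v) for k, v in report.distinguishing[s].items()}
            for s in report.stage_order
        },
        "disease_overlap": sorted([m, d.value] for m, d in report.disease_overlap),
    }


def render_markdown(report: ComparisonReport) -> str:
    """Stage-by-stage summary table with arrows marking miRNA directions."""
    arrow = {Direction.DOWN: "v", Direction.UP: "^"}
    columns: list[list[str]] = []
    headers = [s.value.replace("_", " ") for s in report.stage_order]
    for stage in report.stage_order:
        cells = [
            f"{m} {arrow[d]}"
            for d in (Direction.DOWN, Direction.UP)
            for m in sorted(report.stage_sets[stage][d])
        ]
        columns.append(cells)
    height = max(len(c) for c in columns) if columns else 0
    lines = ["| " + " | ".join(headers) + " |", "|" + "---|" * len(headers)]
    for i in range(height):
        row = [c[i] if i < len(c) else "" for c in columns]
        lines.append("| " + " | ".join(row) + " |")
    lines.append("")
    lines.append(f"Shared downregulated core: {', '.join(sorted(report.shared_core)) or '(none)'}")
    return "\n".join(lines) + "\n"
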