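"""Stage-specific directional gene panels.

Each panel names the genes whose expression is characteristically up- or
downregulated in one histological stage; panels are direction-homogeneous
and identified by the (stage, direction) pair. Gene identity is by human
symbol; a small alias table maps common protein names onto symbols.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .enums import Direction, Stage
from .errors import ValidationError

__all__ = ["StagePanel", "PanelKey", "builtin_panels", "load_panels", "GENE_ALIASES"]

PanelKey = tuple[Stage, Direction]

#: Protein-name aliases accepted in panel configs.
GENE_ALIASES: dict[str, str] = {
    "KI-67": "MKI67",
    "KI67": "MKI67",
    "P16": "CDKN2A",
    "P53": "TP53",
    "C-FOS": "FOS",
}


def _canonical_symbol(symbol: str) -> str:
    clean = str(symbol).strip().upper()
    if not clean:
        raise ValidationError("empty gene symbol")
    return GENE_ALIASES.get(clean, clean)


@dataclass(frozen=True)
class StagePanel:
    """A named directional gene panel for one stage."""

    stage: Stage
    direction: Direction
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"panel {self.key} has an empty gene list")
        seen: set[str] = set()
        for gene in self.genes:
            if gene != gene.upper() or not gene:
                raise ValidationError(f"gene symbols must be uppercase, got {gene!r}")
            if gene in seen:
                raise ValidationError(f"duplicate gene {gene!r} in panel {self.key}")
            seen.add(gene)

    @property
    def key(self) -> PanelKey:
        return (self.stage, self.direction)

    @property
    def size(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def _make(stage: Stage, direction: Direction, genes: Iterable[str]) -> StagePanel:
    return StagePanel(stage, direction, tuple(_canonical_symbol(g) for g in genes))


def builtin_panels() -> dict[PanelKey, StagePanel]:
    """The five default panels of the early-oncogenesis staging signature.

    Hyperplasia has no downregulated panel: no gene shows significantly
    diminished expression at that stage.
    """
    panels = [
        _make(
            Stage.HYPERPLASIA,
            Direction.UP,
            ["EGFR", "ERBB2", "JUN", "ETS1", "MYC", "MKI67", "CDKN2A", "TP53"],
        ),
        _make(
            Stage.DYSPLASIA,
            Direction.UP,
            ["EGFR", "ERBB2", "FGFR2", "FGFR3", "ETS1", "JUN", "MYC", "MKI67", "TP53"],
        ),
        _make(Stage.DYSPLASIA, Direction.DOWN, ["CDKN2A", "NRAS", "BCL2"]),
        _make(Stage.EARLY_INVASION, Direction.UP, ["EGFR", "FGFR2", "FGFR3", "ETS1", "JUN"]),
        _make(Stage.EARLY_INVASION, Direction.DOWN, ["CDKN2A", "BCL2"]),
    ]
    return {p.key: p for p in panels}


def load_panels(path: str | Path) -> dict[PanelKey, StagePanel]:
    """Load panels from a YAML or JSON list of {stage, direction, genes}.

    Symbols are uppercased and alias-resolved; duplicate symbols within one
    panel and duplicate (stage, direction) pairs are rejected.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, list) or not raw:
        raise ValidationError(f"{path}: panel config must be a non-empty list")

    panels: dict[PanelKey, StagePanel] = {}
    for entry in raw:
        if not isinstance(entry, Mapping):
            raise ValidationError(f"{path}: each panel entry must be a mapping")
        for field in ("stage", "direction", "genes"):
            if field not in entry:
                raise ValidationError(f"{path}: panel entry missing {field!r}")
        panel = _make(
            Stage.parse(str(entry["stage"])),
            Direction.parse(str(entry["direction"])),
            entry["genes"],
        )
        if panel.key in panels:
            raise ValidationError(f"{path}: duplicate panel for {panel.key}")
        panels[panel.key] = panel
    return panels


def panels_for_stage(
    panels: Mapping[PanelKey, StagePanel], stage: Stage
) -> list[StagePanel]:
    """Panels belonging to one stage, UP before DOWN."""
    found = [p for p in panels.values() if p.stage is stage]
    return sorted(found, key=lambda p: p.direction.value, reverse=True)
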