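"""Accessors for the packaged fixture data files.

Three TSVs and one YAML ship with the package: the interaction edges
behind the published stage-result tables, the 2023-2024 literature-update
records, the directional evidence set used by the direction filter, and
the default stage panel config.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .curation import DysregulationDB, load_dysregulation
from .network import InteractionTable, load_interactions
from .panels import PanelKey, StagePanel, load_panels

__all__ = [
    "fixture_path",
    "load_fixture_edges",
    "load_fixture_directions",
    "load_literature_update",
    "load_fixture_panels",
]

_FILES = {
    "edges": "oscc_edges.tsv",
    "directions": "oscc_mirna_directions.tsv",
    "literature_update": "literature_update_2024.tsv",
    "panels": "stage_panels.yaml",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture (keys: edges, directions,
    literature_update, panels)."""
    try:
        filename = _FILES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FILES)}") from None
    return Path(str(resources.files("mirstage").joinpath("data", filename)))


def load_fixture_edges() -> InteractionTable:
    return load_interactions(fixture_path("edges"))


def load_fixture_directions() -> DysregulationDB:
    return load_dysregulation(fixture_path("directions"))


def load_literature_update() -> DysregulationDB:
    return load_dysregulation(fixture_path("literature_update"))


def load_fixture_panels() -> dict[PanelKey, StagePanel]:
    return load_panels(fixture_path("panels"))
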