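"""Seeded synthetic bipartite networks with planted candidates and decoys.

The generator plants three separable miRNA classes around one panel:

* ``planted`` — coverage at or above the threshold AND a dysregulation
  record in the required (reverse) direction from an allowed source;
* ``decoy_score`` — threshold-passing coverage but wrong-direction, absent,
  or disallowed-source dysregulation;
* ``decoy_direction`` — correct dysregulation but sub-threshold coverage.

All remaining miRNAs are background: independent Bernoulli edges into
panel and background genes, and no dysregulation records, so their chance
of passing the coverage filter follows the binomial tail while the
direction filter removes them with certainty. By construction exactly the
planted miRNAs survive the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curation import DysregulationDB, EvidenceRecord, write_dysregulation
from .direction_filter import StageResult, required_direction
from .enums import Direction, Source
from .errors import ValidationError
from .network import InteractionTable, write_interactions
from .panels import StagePanel
from .scoring import ThresholdRule, min_required_count

__all__ = ["SimulationConfig", "SimulatedTruth", "simulate", "recovery_metrics", "write_simulation"]


@dataclass(frozen=True)
class SimulationConfig:
    n_mirnas: int
    panel: StagePanel
    n_background_genes: int = 0
    edge_probability: float = 0.1
    n_planted: int = 0
    n_decoy_score: int = 0
    n_decoy_direction: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1:
            raise ValidationError("n_mirnas must be positive")
        if self.n_background_genes < 0:
            raise ValidationError("n_background_genes must be non-negative")
        if not 0 <= self.edge_probability <= 1:
            raise ValidationError("edge_probability must be in [0, 1]")
        if min(self.n_planted, self.n_decoy_score, self.n_decoy_direction) < 0:
            raise ValidationError("class counts must be non-negative")
        if self.n_planted + self.n_decoy_score + self.n_decoy_direction > self.n_mirnas:
            raise ValidationError(
                "n_planted + n_decoy_score + n_decoy_direction exceeds n_mirnas"
            )


@dataclass(frozen=True)
class SimulatedTruth:
    config: SimulationConfig
    planted: frozenset[str]
    decoy_score: frozenset[str]
    decoy_direction: frozenset[str]
    background: frozenset[str]
    table: InteractionTable
    db: DysregulationDB
    labels: dict[str, str] = field(compare=False, default_factory=dict)


def _mirna_name(i: int) -> str:
    # zero-padded so lexicographic and numeric order agree
    return f"hsa-miR-9{i:05d}-5p"


def simulate(config: SimulationConfig, rule: ThresholdRule = ThresholdRule()) -> SimulatedTruth:
    """Draw one synthetic dataset; deterministic for a given seed."""
    rng = np.random.default_rng(config.seed)
    panel_genes = list(config.panel.genes)
    k = min_required_count(config.panel.size, rule)
    mirna_direction = required_direction(config.panel.direction)

    names = [_mirna_name(i) for i in range(config.n_mirnas)]
    n_special = config.n_planted + config.n_decoy_score + config.n_decoy_direction
    planted = names[: config.n_planted]
    decoy_score = names[config.n_planted : config.n_planted + config.n_decoy_score]
    decoy_direction = names[config.n_planted + config.n_decoy_score : n_special]
    background = names[n_special:]

    bg_genes = [f"BGENE{i:04d}" for i in range(config.n_background_genes)]
    rows: list[tuple[str, str, str]] = []
    records: list[EvidenceRecord] = []

    def add_panel_coverage(mirna: str, count: int) -> None:
        chosen = rng.choice(len(panel_genes), size=count, replace=False)
        for idx in sorted(chosen):
            rows.append((mirna, panel_genes[idx], "simulated"))

    def add_background_edges(mirna: str) -> None:
        if not bg_genes or config.edge_probability == 0:
            return
        hits = rng.random(len(bg_genes)) < config.edge_probability
        for gene, hit in zip(bg_genes, hits):
            if hit:
                rows.append((mirna, gene, "simulated"))

    for mirna in planted:
        add_panel_coverage(mirna, int(rng.integers(k, config.panel.size + 1)))
        add_background_edges(mirna)
        records.append(
            EvidenceRecord(
                mirna_id=mirna,
                direction=mirna_direction,
                source=Source(rng.choice([Source.TISSUE.value, Source.SALIVA.value])),
                reference="planted",
            )
        )

    for mirna in decoy_score:
        add_panel_coverage(mirna, int(rng.integers(k, config.panel.size + 1)))
        add_background_edges(mirna)
        mode = rng.integers(3)
        if mode == 0:
            pass  # no dysregulation evidence at all
        elif mode == 1:  # wrong direction, allowed source
            records.append(
                EvidenceRecord(
                    mirna_id=mirna,
                    direction=mirna_direction.opposite,
                    source=Source.TISSUE,
                    reference="decoy_score",
                )
            )
        else:  # right direction, disallowed source
            records.append(
                EvidenceRecord(
                    mirna_id=mirna,
                    direction=mirna_direction,
                    source=Source(rng.choice([Source.BLOOD.value, Source.CELL_LINE.value])),
                    reference="decoy_score",
                )
            )

    for mirna in decoy_direction:
        count = int(rng.integers(0, k))  # strictly below threshold
        if count:
            add_panel_coverage(mirna, count)
        add_background_edges(mirna)
        records.append(
            EvidenceRecord(
                mirna_id=mirna,
                direction=mirna_direction,
                source=Source.TISSUE,
                reference="decoy_direction",
            )
        )

    for mirna in background:
        if config.edge_probability > 0:
            hits = rng.random(len(panel_genes)) < config.edge_probability
            for gene, hit in zip(panel_genes, hits):
                if hit:
                    rows.append((mirna, gene, "simulated"))
        add_background_edges(mirna)

    labels = {m: "planted" for m in planted}
    labels.update({m: "decoy_score" for m in decoy_score})
    labels.update({m: "decoy_direction" for m in decoy_direction})
    labels.update({m: "background" for m in background})

    return SimulatedTruth(
        config=config,
        planted=frozenset(planted),
        decoy_score=frozenset(decoy_score),
        decoy_direction=frozenset(decoy_direction),
        background=frozenset(background),
        table=InteractionTable.from_rows(rows),
        db=DysregulationDB(records),
        labels=labels,
    )


def recovery_metrics(result: StageResult, truth: SimulatedTruth) -> dict[str, float]:
    """Precision and recall of pipeline candidates against the planted set.

    Empty candidate sets count as perfectly precise (no false positives);
    an empty planted set counts as fully recalled.
    """
    candidates = result.candidate_mirnas()
    tp = len(candidates & truth.planted)
    precision = tp / len(candidates) if candidates else 1.0
    recall = tp / len(truth.planted) if truth.planted else 1.0
    return {"precision": precision, "recall": recall}


def write_simulation(truth: SimulatedTruth, outdir: str | Path) -> dict[str, Path]:
    """Write the simulated inputs in the formats the main pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": outdir / "interactions.tsv",
        "dysregulation": outdir / "dysregulation.tsv",
        "panels": outdir / "panels.yaml",
        "truth": outdir / "truth_labels.tsv",
    }
    write_interactions(truth.table, paths["interactions"])
    write_dysregulation(truth.db, paths["dysregulation"])
    panel = truth.config.panel
    paths["panels"].write_text(
        yaml.safe_dump(
            [
                {
                    "stage": panel.stage.value,
                    "direction": panel.direction.value,
                    "genes": list(panel.genes),
                }
            ]
        ),
        encoding="utf-8",
    )
    pd.DataFrame(
        sorted(truth.labels.items()), columns=["mirna_id", "label"]
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
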