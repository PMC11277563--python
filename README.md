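# mirstage

Stage-specific miRNA prioritization for early oral squamous cell carcinoma
(OSCC) oncogenesis. Given a bipartite miRNA–gene interaction table, a set of
directional stage gene panels (hyperplasia, dysplasia, early invasion), and a
database of experimentally reported miRNA dysregulation, the pipeline:

1. restricts the interaction network to each panel's genes,
2. keeps miRNAs that simultaneously target **more than 75%** of a panel's
   genes (strict threshold: 6/8 = 75% exactly does not qualify),
3. keeps, of those, only miRNAs with **reverse** dysregulation evidence in
   tissue/saliva specimens (a repressor of upregulated genes must itself be
   downregulated, and vice versa), and
4. decomposes the per-stage candidate sets into a shared downregulated core,
   stage-distinguishing additions, and the overlap with a disease-level
   reference list.

Packaged fixtures ship the interaction edges and directional evidence behind
the published stage tables, plus the 2023–2024 literature-update records, so
the whole analysis runs offline.

## Modules

| module | purpose |
|---|---|
| `mirstage.curation` | miRNA name normalization, dysregulation TSV parsing, direction queries with consistency qualifiers |
| `mirstage.panels` | builtin and configurable directional stage gene panels |
| `mirstage.network` | interaction-table loading/dedup, panel subnetworks, GraphML / node-link JSON export |
| `mirstage.scoring` | exact rational target-coverage scores and the strict >75% threshold |
| `mirstage.direction_filter` | reverse-expression filter and per-stage result assembly (with rejected-candidate audit trail) |
| `mirstage.stage_comparison` | shared core / distinguishing sets / disease-level overlap |
| `mirstage.synthetic_data` | seeded simulations with planted candidates and two decoy classes |
| `mirstage.seedscan` | optional canonical seed-site scanner (8mer / 7mer-m8 / 7mer-A1 / 6mer) emitting interaction tables |
| `mirstage.cli` | `mirstage` command-line entry point |

## CLI

```bash
# full pipeline on the packaged fixtures (default inputs)
mirstage run --out results/

# custom inputs and threshold
mirstage run --interactions edges.tsv --panels panels.yaml \
    --dysregulation evidence.tsv --min-fraction 0.75 --sources tissue,saliva

# synthetic data with planted candidates + recovery metrics
mirstage simulate --seed 7 --out sim/

# seed-site scan producing a pipeline-compatible edge table
mirstage seedscan mirnas.fasta utrs.fasta --out seed_edges.tsv

# copy the packaged fixture files
mirstage export-fixtures --out fixtures/
```

`run` writes per-stage candidate TSVs, a combined `stages.json`
(up/down candidates, rejected miRNAs with reasons, and the filter funnel
network → score-passing → direction-passing), GraphML exports per panel, and
`comparison.{json,tsv,md}` with the cross-stage decomposition.

### Input formats

- interactions: TSV with columns `mirna_id`, `gene`, `source_db`
- dysregulation: TSV with columns `mirna_id`, `direction` (up/down),
  `source` (tissue/saliva/blood/cell_line/saliva_exosome), `reference`
- panels: YAML/JSON list of `{stage, direction, genes}`

miRNA names are normalized automatically (`miR124-3p` → `hsa-miR-124-3p`);
gene symbols are uppercased, with common protein-name aliases resolved
(Ki-67 → MKI67, p16 → CDKN2A, p53 → TP53).

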