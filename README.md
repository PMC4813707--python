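# bnpcp

Protein correlation profiling of blue-native PAGE AP-MS fractionation data.

An affinity-purified protein complex separated on a blue-native gel and cut
into fractions (bottom = low mass) yields one quantitation table per
experiment, with per-fraction intensity and iBAQ values for every identified
protein. `bnpcp` turns such tables into:

- **migration profiles** — each protein's per-fraction intensities normalized
  to its total intensity (sums to 1), with apparent-mass annotation from a
  marker ladder (log-linear interpolation) and replicate alignment by the
  bait's apex fraction;
- **co-migration clusters** — pairwise Manhattan distances, deterministic
  average-linkage (UPGMA) hierarchical clustering, heatmap leaf ordering,
  Newick export, and extraction of the bait's co-cluster;
- **complex entities** — peak detection on the bait profile (moving-average
  smoothing + prominence threshold) defines non-overlapping fraction regions
  ("I", "II", …); every protein gets a per-entity profile-mass share and a
  threshold call (one entity, both, or outside);
- **stoichiometry trends** — per-fraction iBAQ ratios to the bait inside a
  configurable window (default fractions 26–36), OLS slope with a t-test:
  *flat* (constant relative amount across assemblies) vs *ascending* /
  *descending* (entity-biased). Optional log-ratio fitting and a minimum
  fold-change floor (the pipeline's defaults) make the calls robust to
  multiplicative noise and dropout;
- **target-gene co-occupancy** — gene-list intersections (complex proxy
  sets), pairwise overlap percentages, 3-way Venn partitions, the shared
  fraction of partner-bound loci, and a partition → filter chain;
- **a synthetic data generator** — ground-truthed two-assembly fixtures
  (48 fractions, bimodal bait, flat / enriched / entity-specific / contaminant
  proteins, log-normal noise, dropout, replicate fraction shifts) so every
  stage is testable without external data.

## CLI

```sh
bnpcp demo --seed 1 --out demo_out          # synthetic end-to-end run + checks
bnpcp simulate --seed 0 --out fixture       # write a ground-truthed fixture
bnpcp run --config config.yaml              # full pipeline from a YAML config
bnpcp profiles --table t.tsv --out profiles.tsv
bnpcp cluster  --table t.tsv --bait SYN0001 --out clust
bnpcp stoich   --table t.tsv --bait SYN0001 --window 26 36 --out slopes.tsv
bnpcp entities --table t.tsv --bait SYN0001 --ladder marker.tsv --out ent
bnpcp overlap  --proxy a.txt --proxy b.txt --partner p1.txt --partner p2.txt --out venn.json
```

A minimal `config.yaml`:

```yaml
replicate_tables: [fixture/quant_replicate1.tsv, fixture/quant_replicate2.tsv]
bait_id: SYN0001
marker_ladder: fixture/marker_ladder.tsv
out_dir: results
window: [26, 36]
alpha: 0.05
```

Input tables are tab-delimited with `Protein IDs`, `Gene names`, one
`Intensity <k>` and one `iBAQ <k>` column per fraction, and optional
`+`-convention flag columns (`Reverse`, `Potential contaminant`,
`Only identified by site`). Fraction indices are 1-based; fraction 1 is the
gel bottom.

## Layout

| module | contents |
|---|---|
| `bnpcp.io_tables` | table/ladder/control-list dialects, QC filtering |
| `bnpcp.synthetic_data` | ground-truthed fixture generator |
| `bnpcp.profiles` | normalization, MW calibration, replicate alignment |
| `bnpcp.pcp_clustering` | Manhattan distances, UPGMA, co-cluster, heatmap order |
| `bnpcp.stoichiometry` | bait-normalized iBAQ ratio regression and trends |
| `bnpcp.entities` | bait peak detection and per-entity membership |
| `bnpcp.cooccupancy` | gene-set overlaps, Venn partitions, filter chain |
| `bnpcp.pipeline` / `bnpcp.cli` | orchestration, report bundle, CLI |
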