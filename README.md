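# hipnet

A headless Python toolkit for integrating huntingtin (HTT) protein–protein
interaction catalogs with Huntington's-disease omics data, and for scoring
IP-MS (immunoaffinity purification–mass spectrometry) interaction
experiments.

Huntington's disease is caused by CAG-repeat (polyglutamine, "polyQ")
expansion in the huntingtin gene. Hundreds of studies have reported
candidate huntingtin-interacting proteins (HIPs) across wildly different
model systems, tissues, HTT construct lengths and detection methods, and
large knock-in mouse panels ("allelic series", Q20 control vs Q50–Q175
disease alleles) have profiled the polyQ-dependent transcriptome and
proteome. `hipnet` merges these resources into one human-gene-centric
catalog and makes them queryable:

- **Catalog building** — per-observation interaction reports are merged,
  deduplicated, mapped to human orthologs via static lookup tables, and
  combined with bulk (tissue × age × Q-length), single-nucleus and
  single-cell omics into one catalog flagging each gene as a HIP and
  counting its distinct supporting studies.
- **Metadata filtering** — interaction-level boolean filters (AND / OR /
  NOT per metadata field, fields combined conjunctively), a minimum-study
  filter and a case-insensitive gene-list search. Selecting
  {Mice, Human} with AND returns genes identified at least once in mice
  *and* at least once in humans; "Mice" + "brain" across two filters
  requires a single observation that is both.
- **Network construction** — STRING-dialect alias/links files provide
  undirected functional edges with combined scores on the 0–1000 scale,
  thresholded from a 0–1 confidence (0.4 = medium confidence); isolated
  nodes are retained and reported. Node/edge TSV export is
  Cytoscape-ready.
- **Overrepresentation analysis** — one-sided Fisher's exact test of a
  query gene set against GMT annotation sets relative to a background
  list, with Benjamini–Hochberg FDR.
- **User datasets** — TSV upload with `QUANT_`-prefixed annotation columns
  (quantitative when all values are numeric, else categorical with
  comma-separated multi-values), registered as new studies with a
  known-vs-novel overlap report.
- **IP-MS scoring** — the downstream statistics of a bait-IP experiment:
  per-group SAINT specificity (mean of the two highest scores, specific at
  ≥ 0.8), bait normalization, a quantified-protein filter, minimum-CV
  replicate selection, differential interaction calls
  (|log2 FC(Q140/Q20)| ≥ 1 and Student's-t p < 0.05 on log2 abundances),
  isotope stability ratios light/(light+heavy) (≈1 stable, ≈0.5
  fast-exchanging), specific-and-stable quadrant assignment, and Venn
  partitioning of interactor sets.
- **Synthetic fixtures** — seeded generators for every input (interaction
  tables, STRING files, omics tables, spiked IP-MS matrices with known
  truth), so the full pipeline runs and is tested offline.

## Worked example

Generate a synthetic input set, filter it, build the network and score the
IP-MS design:

```bash
hipnet simulate --seed 7 --out fx
# fixtures written to fx

printf 'filters:\n- field: model_species\n  values: [Mice]\n  operator: OR\n- field: tissue\n  values: [brain, striatum]\n  operator: OR\n' > filters.yaml
hipnet filter --ppi fx/ppi_catalog.tsv --orthologs fx/ortholog_map.tsv \
    --spec filters.yaml --out filtered
# 11 genes -> filtered/genes.txt

hipnet network --genes filtered/genes.txt --entrez entrez.tsv \
    --string-aliases fx/protein.aliases.synthetic.txt \
    --string-links fx/protein.links.synthetic.txt \
    --score-threshold 0.4 --out net
# 11 nodes, 3 edges, 6 unconnected -> net

hipnet ipms --abundances fx/ipms_abundances.tsv --saint fx/ipms_saint.tsv \
    --isotopes fx/ipms_isotopes.tsv --bait HTT --out ipms
# results -> ipms
```

The filter step kept the 11 genes with at least one confirmed mouse
brain/striatum observation; 3 STRING edges passed the 0.4 confidence
cutoff, leaving 6 of the 11 nodes unconnected. In `ipms/differential.tsv`
exactly 20 proteins are called differential per age comparison — the 20
spiked 4-fold interactors of the generator — and
`ipms/spec_stable.tsv` classifies each (protein, group) pair by SAINT
specificity and isotope stability, e.g.:

```
protein    group     saint_avg  stability  class
PROT0000   Q140-2M   0.986      0.495      specific_only
```

(a specific but fast-exchanging interactor: SAINT average 0.99 ≥ 0.8, but
stability 0.495 ≈ the 0.5 exchange anchor). Every subcommand writes a
`run_manifest.json` recording its inputs and thresholds.

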