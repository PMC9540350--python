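# Methods

## Catalog model

The catalog is observation-centric: one row of the interaction table is
one experimental detection of a candidate huntingtin interactor, carrying
the metadata fields `model_species`, `tissue`, `htt_length`,
`detection_method`, `common_name`, `cell_culture_comment` and `study_id`.
The raw `model` and `model_organism` columns are partially redundant and
are collapsed into `model_species`: when both are present and unequal the
organism string wins, otherwise the non-empty one passes through, and two
empty fields yield `"unspecified"` rather than an error. Only
observations whose interaction-result flag equals `Y` (after whitespace
trim, case-sensitive) count as confirmed; unconfirmed rows are carried but
never participate in filtering or network construction.

Merging deduplicates on the full tuple (source symbol, study, model
species, tissue, HTT length, detection method). This keeps repeated
detections of the same gene across studies or methods — which is the
signal the study-count annotation summarizes — while removing literal
duplicates. The operation is idempotent and observation ids are assigned
in input order, so rebuilding from identical inputs is byte-stable.

Ortholog mapping is a static table lookup keyed on (organism, source
symbol), case-insensitive. Human records pass through with upper-cased
symbols; non-human records without an entry are excluded and counted, per
the rule that a gene without a human ortholog cannot enter the
human-centric catalog. Ties between candidate orthologs must be resolved
upstream in the table; the library never guesses. Gene identity is the
human symbol; the Entrez id is carried as an attribute, and symbol
collisions across Entrez ids merge under the symbol.

`is_hip` is equivalent to `study_count >= 1`, where `study_count` counts
distinct study ids with a confirmed observation (not raw observations):
the minimum-study filter and node annotations are defined at the study
level. Bulk omics values are sex-averaged (arithmetic mean over the sexes
present) before storage.

## Filter semantics

Filters act at the interaction level. OR- and NOT-filters constrain the
observation set: an observation survives when its field value is in (OR)
or not in (NOT) the selected values, and the base gene set is every gene
with at least one surviving observation. An AND-filter then imposes
gene-level per-value existence *within the constrained observations*: for
each selected value the gene must retain at least one surviving
observation carrying it. This is the strictest reading consistent with
both canonical behaviors — {Mice, Human} AND returns genes seen at least
once in each organism, while Mice + brain across two filters requires a
single observation that is simultaneously mouse and brain. Consequences
worth knowing: filters commute, adding values to an OR-filter is
monotone non-decreasing, adding a NOT-filter is monotone non-increasing,
and a single-valued AND-filter equals the same OR-filter. Value matching
is exact string equality after whitespace trim and case-fold — no
substring or ontology matching, by design, so results are auditable.

One open choice: "identified only with full-length HTT" is implemented as
inclusion filtering (`htt_length = full-length`), not as exclusion of
genes also seen with fragments. Exclusion is expressible by combining an
OR-filter on full-length with a NOT-filter, so no expressiveness is lost.

The minimum-study filter uses the *global* distinct-study count, not the
count within the current filtered view; the interactive equivalent is a
slider over how often a gene has ever been reported.

## Network construction

STRING-dialect inputs: an aliases table (string protein id, alias,
source) and a links table (protein1 protein2 combined_score,
space-separated, scores integer 0–1000). Entrez ids resolve to STRING ids
through the aliases file; any alias row whose alias equals the Entrez id
string is accepted regardless of its source tag, since source vocabularies
vary across releases. Unresolvable genes are reported, not fatal. The
links dialect is directed-symmetric; duplicate pairs collapse to one
undirected edge keeping the maximum score. User thresholds are on the 0–1
scale and compared as `combined_score >= round(1000 * t)`. Isolated nodes
stay in the network — unconnected interactors are a reported result, not
an artifact — and the exporter round-trips node annotations (including
multi-valued ones, flattened as comma-joined sets) through the loader
losslessly. Gzip-compressed STRING files are accepted transparently.

## Omics views

Aggregation over a gene set is the median for the log2-ratio modalities
(bulk RNA, bulk protein, single-nucleus fold change) and the sum for
single-cell expression fractions, overridable per call. The assignment is
a design choice: a median of log2 ratios is a robust central tendency,
whereas a sum of log ratios has no such reading; a sum of expression
fractions is a cell-weighted expression mass. The 90% bounding envelope
is the (5th, 95th) percentile pair, linear interpolation between closest
order statistics (numpy's `linear` method), computed per
(tissue, age, Q-length) stratum across all genes in the omics table —
the per-Q reading of "outside the bounds means upper or lower 5% at that
Q-length". Highlight rules are inclusive at their thresholds:
single-nucleus |log2(Q175/WT)| ≥ 0.15 (a >10% change, since
2^0.15 − 1 ≈ 11%) and single-cell expressing fraction ≥ 0.8.

## Enrichment

Overrepresentation is the one-sided (greater) Fisher exact p-value,
computed as the hypergeometric upper tail P(X ≥ k) on the table
[[k, n−k], [K−k, N−n−K+k]] with query size n, term size K and background
size N; the test suite checks it against exhaustive enumeration for every
table with N ≤ 60. FDR control is Benjamini–Hochberg (the conventional
choice where only "FDR correction" is specified). Query genes outside the
background are dropped and counted; annotation input order never affects
results. Term membership files are GMT. A thin adapter
(`enrichment.panther_request`) shapes the same query for a hosted
annotation service but is never exercised offline.

## User datasets

The gene column is `gene_symbol` (configurable alias list). A `QUANT_x`
column becomes annotation label `x`; it is quantitative iff every
non-missing value parses as a finite number, else categorical, with
categorical values split on commas so multi-compartment localizations
survive. Missing tokens are the empty string and `NA`/`nan`
(case-insensitive). Integration registers the records as confirmed
observations under the new study id (duplicate ids are an error),
recomputes study counts, and reports the dataset's genes partitioned into
known (≥1 prior confirmed observation) and novel; the two counts always
sum to the dataset's distinct gene count.

## IP-MS scoring

The study design is four sample groups (Q20 and Q140 knock-in at 2 and
10 months) with three biological replicates. Per group, SAINT specificity
is the mean of the two highest per-sample scores, specific at ≥ 0.8
inclusive. Bait normalization divides each sample by its bait (HTT)
abundance and rescales by the across-sample mean bait abundance, so the
bait row becomes constant (to 1e-9) and units are preserved; a missing or
non-positive bait value in any sample is a structured error naming the
sample. Proteins are retained when ≥2 replicates are quantified in at
least one group. Replicate selection evaluates every size-k subset of a
group's replicates and keeps the subset minimizing the *median* per-protein
CV (sd/mean, ddof=1, over proteins complete in the subset); the median is
our aggregate choice, robust to a few high-CV proteins, with ties broken
lexicographically.

Differential calls: log2 FC is the group-mean ratio of bait-normalized
abundances; the p-value is the classical equal-variance two-sample
Student's t on log2 abundances; a protein is differential when
|log2 FC| ≥ 1 (inclusive — thresholds describe the rendered calls) and
p < 0.05. Both thresholds are configurable, and the comparison may be run
on the full 3-replicate groups or on the min-CV-selected subsets.
Degenerate zero-variance comparisons yield p = 1 (equal means, no call)
or p = 0 (unequal means) instead of an exception. Swapping the groups
negates log2 FC and preserves p.

The isotope stability ratio is light/(light+heavy) after mixing an
unlabeled lysate with a heavy-labeled reference: ≈1 means little
in-solution exchange (stable), ≈0.5 fast exchange. The ratio is
scale-invariant; both intensities zero is an error. Specific-and-stable
assignment is the upper-right quadrant of the specificity × stability
plane: SAINT average ≥ 0.8 and stability ≥ a configurable threshold. No
canonical stability cutoff exists; the default 0.75 is the midpoint of
the stable (1.0) and fast-exchange (0.5) anchors, must lie in (0.5, 1.0),
and is echoed in all outputs. Venn partitioning over 2–4 named interactor
sets enumerates all membership regions; counts always sum to the union.

## Synthetic data

The generators are pure functions of a `FixtureSpec` (identical spec →
byte-identical files) and emit, alongside each data file, a truth
manifest that tests verify by re-scanning the emitted files — never by
trusting generator internals. What they emulate, and what they do not:

- Interaction tables draw metadata uniformly from realistic vocabularies
  with a Poisson observation count per gene (mean 3) and an 85%
  confirmation rate; real catalogs have heavily skewed study sizes and
  correlated metadata, so passing filter tests shows the boolean algebra
  is right, not that any particular biological subset is.
- STRING files are Erdős–Rényi graphs (edge probability 0.15, scores
  uniform on [150, 999]) with a 10% alias dropout to exercise unresolved
  handling; no topology realism is intended.
- Bulk omics follow a per-gene linear polyQ trend,
  slope·(Q−20)/155 + N(0, 0.1), per sex, tissue ∈ six tissues, age ∈
  {2, 6, 10} months, Q ∈ {50, 80, 92, 111, 140, 175} with the Q50×2-month
  cell absent as in the real allelic-series design; single-nucleus fold
  changes are N(cell-type mean, 0.1) and single-cell fractions
  Beta(2, 2).
- IP-MS matrices are log-normal with σ(log2) = 0.2 around per-protein
  baselines, multiplied by a per-sample bait factor (so bait
  normalization is non-trivial), with 20 of 200 proteins spiked by
  log2 FC = 2 in the Q140 groups; SAINT scores are N(0.95, 0.05) for
  spiked and N(0.2, 0.05) for decoy proteins, clipped to [0, 1]; 20% of
  proteins are stable (ratio ≈ 1) and the rest fast-exchanging
  (ratio ≈ 0.5) with noise 0.02. Under these conditions the differential
  pipeline recovers the spike set exactly with zero false calls, which
  validates the statistics at a realistic noise level — not the FDR
  behavior on real spectra, which sit upstream of this package.

Problem sizes in the test suite (40-gene catalogs, 200-protein matrices,
10^4-point envelope samples, the exhaustive N ≤ 60 Fisher sweep) were
chosen so every property is checked at full strength while the suite
stays fast enough to run on every change.

## Known limitations

No isoform-level modeling; no ontology-aware tissue matching; no live
ortholog or annotation services (all mappings are input tables); no
peptide/PSM-level processing — the IP-MS module consumes protein-level
abundance and SAINT score tables; no graph layout or rendering.
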