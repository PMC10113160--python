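# Methods

This note documents the statistical models, parameter choices and
limitations of `terveg`.

## Permutation enrichment model

For a peak set *P* and a repeat family *f* with copies *E_f*, the observed
statistic is the number of peaks overlapping (≥1 bp, half-open
coordinates) at least one copy of *f*; each peak counts once per family
regardless of how many copies it touches. The null redistributes every
peak independently and uniformly at random on its own chromosome, keeping
its exact length, over all positions where it fits entirely inside a
single mappable segment. Mappable segments are the per-chromosome
complement of a merged exclusion mask ("unmappable regions"); with no mask
the whole chromosome is mappable.

Choices worth noting:

- **Empirical p** uses the add-one estimator `(1 + r)/(N + 1)` with `r`
  the number of null counts ≥ observed. It is never 0 and attains exactly
  `1/(N+1)` on a maximally enriched input; `N` defaults to 1000
  permutations.
- **Fold** is observed over the *mean* of the null counts (the
  conventional expectation estimator; the median would be far more
  discrete at low counts), with the mean floored at `1/N` so families
  never hit under the null get a finite, conservative fold.
- **Per-chromosome shuffling** preserves each chromosome's peak density —
  the more conservative null when peak density varies across chromosomes.
  Shuffled peaks may overlap each other (no collision rule), and a
  shuffled peak may not straddle a masked region (strict reading of
  "avoiding unmappable regions").
- **Significance rule**: `p < 0.05`, `fold > 2`, `≥ 10` copies overlapped
  by peaks — all strict on p and fold. BH q-values across families are
  computed and reported but are informational; the rule uses the raw
  empirical p.
- **Reproducibility**: a single root seed drives a run; permutation *i*
  draws from the *i*-th spawned substream, so results do not depend on
  evaluation order and are bit-reproducible.
- When the annotation's elements are globally non-overlapping (always true
  for simulated genomes), null counting uses a vectorized interval join
  across all permutations at once; otherwise a per-family fallback path is
  used. Both paths implement the same statistic.

### Calibration and the discreteness of the empirical p

Permutation p-values are valid but conservative on discrete statistics:
`P(p < 0.05)` equals ~0.049 only when null counts are effectively
continuous, and drops sharply when the per-family expected overlap count
is small (many ties at low integers). The null-calibration check therefore
uses a dense genome — 300 families with heterogeneous copy numbers
(40–100) and element lengths (700–1,300 bp) on a 40-Mb chromosome with
9,000 1-kb peaks, giving per-family expected null counts of roughly
15–55 — where theory puts the attainable type-I fraction near 0.038–0.044.
The observed fraction is pooled over four independent peak draws to keep
the binomial noise of a 300-family sample small relative to the
[0.03, 0.07] acceptance band. These sizes were fixed from this analysis,
not fitted to outcomes.

## Candidate-family selection

Stage 1 intersects the significant family sets of two cell contexts.
Stage 2 applies the DNase tissue-specificity rule per family: pass iff
the fraction of placental datasets with fold > 2 exceeds 0.8 **and** the
median placental fold minus the median over the pooled kidney/liver/lung
datasets exceeds 2. Both thresholds are strict, medians of even-sized
groups are midpoint averages, and the non-placental datasets are pooled
into one group (per-tissue medians are reported as diagnostics). The
per-dataset DNase folds come from the same enrichment machinery with DNase
hypersensitive sites as the peak set; no separate statistic is introduced.
The decision is anti-monotone in all three thresholds (raising any
threshold can only shrink the candidate list), which the tests verify over
a threshold grid.

## Chromatin-state combinations

Element × mark overlap calls (≥1 bp) are turned into combination labels
over whatever mark panel is provided ("K27ac+K4me1", "K4me1_only",
"none", ...), rather than a fixed ontology — mark panels differ between
cell types. Repressive marks (H3K9me3, H3K27me3) join combinations with no
precedence over active marks. Per-family proportions can be computed over
all copies or restricted to copies bearing a chosen mark (e.g. the
fraction of H3K27ac-marked copies also carrying H3K4me1 — the
active-enhancer signature); both denominators are exposed because either
is a defensible summary and they answer different questions.

## Distance-stratified expression association

Per-gene log2 fold changes are
`log2((mean_A + c)/(mean_B + c))` on condition means of linear-scale
normalized abundances, after dropping genes below a minimal expression
threshold in *both* conditions. The pseudocount `c` defaults to 1 on the
normalized scale; the minimal threshold is a required, logged parameter
(it depends on the dataset and normalization and has no universal
default). Swapping conditions negates every value exactly.

Gene-to-element distance is the unsigned edge gap from the gene *body*
(span) by default; a TSS-anchored mode is available. Upstream and
downstream are not distinguished. Default bins are
overlap / ≤10 kb / 10–50 kb / 50–100 kb / >100 kb with the open >100-kb
bin as the reference group; edges are configurable. Group tests: one-way
ANOVA plus Tukey HSD contrasts against the reference, or rank-sum tests
per bin with BH correction in two-group mode. Bins with fewer than two
genes are excluded from testing with a warning.

TE-promoter detection intersects the TSS (a single base, strand-aware:
span start on +, span end − 1 on −) of multi-exonic transcripts
(exon_count ≥ 2) with active TE intervals. Per-family target-gene tests
collect the log2FC of genes within 100 kb (default) of any marked copy of
the family and apply the Wilcoxon signed-rank test against 0, BH-corrected
across families.

## Cross-species comparison

Coordinate maps are consumed as aligned equal-length block pairs
(a liftOver-chain abstraction; UCSC chain parsing is out of scope and
precomputed block TSVs are the supported input). An interval lifts when at
least `min_frac` (default 0.5, inspired by liftOver's remap threshold) of
its bases map into one contiguously-merged region on a single target
chromosome. A copy has a reciprocal ortholog when the lifted interval
lifts back onto a span overlapping the original element; optionally the
lifted interval must also overlap an annotated same-family element in the
target species (both modes exposed, since either reading is plausible).

Cross-species expression ratios use per-gene means of each matrix's own
normalized units, rescaled so both matrix-wide medians meet at their
geometric mean before the log-ratio (the pseudocount then stays small
relative to typical abundances). Note the scaling constant shifts *all*
ratios equally, so when a large fraction of genes carries a real shift the
absolute group means move but the group *difference* — the statistic under
test — is unaffected. Gene grouping: a gene within the window
(100 kb default; 50 kb for the three-group species-activity mode) of any
marked TE is assigned "non-orthologous" if *any* such TE lacks an
ortholog — a single species-specific element suffices to hypothesize
species-specific regulation. The three-group mode (active near the gene in
species A only / B only / neither) sets genes near marked TEs in both
species aside and runs ANOVA with Tukey contrasts.

## Synthetic data

The generators emulate the statistical structure the analyses assume:

- **Genome**: TE copies with per-family copy numbers and
  normal-distributed lengths placed uniformly without overlapping each
  other or the mask; the mask covers a configured fraction of the genome
  in ~50-kb segments; genes (default 2-kb spans, 1–5 exons) placed
  uniformly with strand-aware TSS. Defaults: two chromosomes (12 + 8 Mb),
  ten ERV-like families with copy numbers 30–100 and mean lengths
  300–1,200 bp, 5% masked.
- **Peaks**: a planted fraction per family is placed to overlap a
  uniformly chosen copy by ≥1 bp (matching the ≥1-bp enrichment rule;
  containment is not forced); the rest are uniform over mappable space.
  Defaults: 500 peaks of ~300 bp, 25%/15% planted into two families.
- **Expression**: log-normal baselines (normal on the log2 scale, mean 6,
  sd 1, i.e. typical abundances ~64 in linear units) with additive
  Gaussian noise (sd 0.5) on the log2 scale; condition A gains a planted
  log2 effect (default 1.0) iff the gene lies within the effect window
  (default 50 kb) of a marked TE. Values are emitted on the linear scale
  so the pseudocount in the fold-change formula behaves as it would on
  RPKM-like data.
- **Two species**: species B is species A with a recorded subset of TE
  copies deleted (per-family shared fraction, default 0.5); coordinate
  maps list the retained segments as aligned blocks, genes are conserved
  one-to-one. Species-B expression lacks the TE-linked effect (default
  0.8 log2 units) for genes with an A-specific marked copy within the
  window — mirroring the analysis-side rule that a single
  species-specific element dominates — so the planted group difference
  equals the configured effect exactly. Deletions (not substitutions)
  model species specificity; sequence divergence is not modeled, which is
  sufficient because every statistic under test depends only on
  presence/absence and coordinates.

All generators are pure functions of the config: one root seed, one
spawned substream per stage, bit-identical outputs across runs. Truth
records (per-peak provenance, per-gene planted effect and distance,
per-element shared flag) are sufficient to score every downstream call.

What the synthetic data does **not** emulate — and hence what passing
tests do not show about real data: sequence content and mappability
structure correlated with repeat age, overlapping/nested repeat copies,
GC- or replication-timing-biased peak placement, unbalanced designs,
count-level noise (expression noise here is homoskedastic on the log
scale), and cross-species assembly/annotation asymmetries.

## Numerical and degenerate-input conventions

- Coordinates are 0-based half-open everywhere internally; GTF and
  RepeatMasker readers convert at the boundary; chromosome names match by
  exact string equality (no alias table — real data may need
  harmonization first).
- Bookended intervals do not overlap but have distance 0.
- Empty peak sets yield p = 1 and fold = 0 for every family; an empty
  annotation yields an empty record set. Families with no targets or
  empty denominators are recorded as empty/omitted with warnings rather
  than errors.
- Proportion tables sum to 1 within 1e−9 per row; enrichment TSVs are
  written with fixed column order and `%.10g` floats so identical runs are
  byte-identical.

## Problem sizes used in the checks

Oracle equivalence runs ~1,000 randomized instances of up to a few
hundred intervals; null calibration uses 300 families × 999 permutations
× four peak draws of 9,000 peaks; planted recovery uses 20 seeded
replicates of 500 peaks over 12 families; distance recovery uses 3,500
genes against 60 marked copies on 20 Mb; the two-species check uses 120
copies and 1,500 genes on 24 Mb. These sizes keep every planted effect
many standard errors from its acceptance tolerance while completing in
minutes on one CPU.

## Known limitations

- The null model is uniform within mappable space; GC-matched,
  distance-constrained or block-bootstrap nulls are out of scope.
- Fold enrichment uses the null mean; families with near-zero null means
  produce large but floored folds — interpret folds jointly with p and
  copy counts (as the significance rule does).
- The DNase filter pools non-placental tissues; a family specifically
  accessible in exactly one comparison tissue could pass the pooled
  median test.
- Cross-species ratios assume comparable normalized units up to a single
  multiplicative factor per matrix.
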