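# Methods

`terroirseq` re-implements, as a tested pipeline with a synthetic-data
generator, an analysis workflow for inoculated wine fermentations: grape
musts from vineyard sites in several growing regions are profiled by 16S
(bacterial) and ITS (fungal) amplicon sequencing before inoculation, and
the fermentations are then followed by 3′ tag RNA sequencing over a time
series. The workflow asks three questions: do microbial communities and
fermentation transcriptomes carry vineyard-site and region signatures;
does DNA abundance in the must predict transcriptional activity during
fermentation; and which genes make up a reproducible site/region
signature.

## Data model and conventions

Count tables are features × samples on disk (TSV, feature id first,
optional `taxonomy`/`organism` columns) and samples × features in memory
for statistics. Counts are non-negative integers; validation rejects
duplicates, ragged rows, negatives and non-integers, naming the
offending row or column. Each site belongs to exactly one region, and
(site, vintage, tank[, timepoint]) identifies a sample.

Before any 16S statistic, ASVs whose lineage starts with the plant
chloroplast (`Bacteria;Cyanobacteria;Cyanobacteriia;Chloroplast`) or
mitochondrial (`Bacteria;Proteobacteria;Alphaproteobacteria;
Rickettsiales;Mitochondria`) prefix are removed. Matching is
case-sensitive on the comma/semicolon-normalized lineage, so both
delimiter dialects are accepted; filtering always precedes
normalization.

## Compositional statistics

Sequencing depth is an artifact, so community analyses work on
relative abundances or the centered log-ratio (CLR) scale. The CLR of a
sample is log(xᵢ/g(x)) with g the geometric mean; zeros are replaced,
by default, with half the smallest nonzero relative abundance in the
table (applied multiplicatively per sample, then re-closed). A fixed
+1-count alternative is selectable; the default is pinned for
reproducibility. Aitchison distance is Euclidean distance between CLR
vectors. Shannon diversity is reported in nats; Chao1 uses the
bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), defined even without
doubletons. The core microbiome is the set of features at ≥ 1% relative
abundance in ≥ 90% of samples; abundance is assessed per sample (the
per-site-mean alternative is a config choice away, but per-sample is
the default and is what the tests pin).

## Permutation tests

ANOSIM, single-factor PERMANOVA and the Mantel test are implemented
from their definitions on the distance matrix, with label permutations
vectorized. Sampled p-values use p = (b+1)/(m+1) with b the number of
permuted statistics ≥ the observed, so p is never 0; an exact mode
enumerates all n! relabelings for small n and is what the oracle tests
compare against. Ties in ranks use average ranks; all three tests are
one-sided (≥ observed). PERMANOVA reports R² = (SS_T − SS_W)/SS_T and
flags the degenerate SS_W = 0 case as infinite F rather than erroring.
Mantel defaults to Spearman correlation of the lower-triangle vectors,
drops missing entries pairwise, and returns a flagged (NaN, p = 1)
result for constant matrices instead of propagating NaN. BH FDR
adjustment (reporting threshold 0.1) is delegated to statsmodels.

NMDS minimizes non-metric SMACOF stress (scikit-learn) over a
configurable number of random restarts; Kruskal stress-1 is recomputed
from the final configuration via isotonic regression. Samples at
exactly zero dissimilarity are collapsed before embedding and share
coordinates afterwards, and configurations are centered, rotated to
principal axes and sign-fixed so output is orientation-stable.
Geographic distances use the haversine formula with Earth radius
6371.0088 km; mixed-unit covariate matrices are standardized
(mean 0, sd 1, n−1 denominator) before distance computation, with
constant columns dropped.

## DNA–RNA concordance

The pre-inoculation must sample of each tank is paired with that
fermentation's RNA samples, and per organism and timepoint the RNA
relative abundance is regressed (OLS) on the DNA relative abundance
across fermentations. Adjusted R² is reported: with a weak or absent
relationship it is legitimately negative, which plain R² cannot be.
Species are matched across assays on normalized binomial names
(lower-case, abbreviation dots stripped, whitespace collapsed);
DNA features resolved only to genus are reported as genus-level
candidates rather than matches.

## Random forests and consensus signatures

Gene time series are first summarized per fermentation into five
attributes — mean, min, max, total, and sample standard deviation (n−1)
of library-size-normalized counts — because the classifier expects
independent rows and the timepoints of one fermentation are not
independent samples. Amplicon models instead use per-sample ASV
relative abundances directly; both entry points share one model core.

The forest is a seeded bagging loop over sklearn decision trees with
explicit bootstrap/out-of-bag (OOB) bookkeeping, majority vote, and
ties broken toward the lowest class index. Hyperparameters (mtry ∈
{√p, p/5, p/2}, sample fraction ∈ {0.632, 0.8, 1.0}, minimum node size
∈ {1, 5, 10}) are tuned by OOB error over that grid when requested;
consensus runs use fixed defaults (mtry = √p, 0.632, 1) for speed and
determinism. The full-scale tree count default is 10,000; desk-scale
runs in the tests and acceptance script use 150–500 trees, which the
casewise-consistency checks show is sufficient for stable importance.

Casewise (local) permutation importance: entry (i, j) is the mean, over
trees where training sample i is OOB, of the correct-vote indicator
before minus after permuting feature j among that tree's OOB samples.
Its per-feature column mean reconciles with the global OOB permutation
importance (correlation > 0.99 in the consistency checks). Only
features a tree actually splits on are permuted for that tree;
permuting an unused feature provably leaves predictions unchanged, so
this is an exact shortcut, not an approximation.

Variable selection follows the vita idea: hold-out (cross-validated)
permutation importance over 5 folds, a null distribution formed by
mirroring the non-positive importances around zero, and selection at
p < 0.05. Two implementation choices matter in small designs. First,
the cross-validation is repeated (3 independent fold assignments,
importance averaged): with only ~3 training fermentations per class,
fold-assignment noise otherwise dominates and makes selection of
genuinely informative genes unstable from seed to seed, which a strict
intersection then amplifies. Second, when the mirrored null is too
small for p < 0.05 to be attainable (low-dimensional inputs), features
whose importance strictly exceeds every null value are retained.
Selection always runs on training data only, to avoid leakage into the
held-out evaluation.

A consensus signature intersects, per class, the genes with positive
class-average casewise importance across all S seeded models
(selection, partition and forest all re-seeded per model; negative
casewise values are kept through the averaging and only the class
average's sign is thresholded). A gene qualifies if any of its five
attributes qualifies, since the attributes are strongly correlated.
An empty intersection is a valid outcome. Organism attribution
truncates negative importances to zero and reports each organism's
percentage of the summed importance.

Two validation schemes are provided: a stratified 70:30 split and
leave-one-vintage-out (train on the other vintages, test on the
held-out one); every class must appear in training.

## The synthetic-study generator

The generator produces complete studies with the structure the analysis
assumes; its defaults mirror the emulated study design: 15 sites in 8
regions, 4 tanks per site, must DNA in vintages 2016/2017/2019 (one
tank unfermented in 2019 in the study-design preset), RNA in 2017/2019
with 2 tanks per site at 2/6/16/64/112 h.

*Communities.* Per-taxon baseline log-abundances (N(0, 1.5)) receive
additive region, site and vintage effects (log-sd configurable);
sample compositions are Dirichlet draws around the exponentiated
effect vector with concentration `dm_concentration` (overdispersion,
as real amplicon data show), and counts are multinomial at a Poisson
depth (default 5×10⁴). The designated dominant taxon (a
Hanseniaspora/Tatumella analogue) is boosted `dominance_alpha`-fold
above the most abundant background taxon, so it leads every must.
Curated lineage strings (including chloroplast/mitochondrial ASVs in
the 16S table) make the taxonomy filters and species matching
exercisable.

*Transcriptomes.* The inoculant (S. cerevisiae) takes ~90% of reads —
its share absorbs the slack so other organisms' relative abundances
are exact by construction — with a fixed grape (V. vinifera) organism,
a small set of RNA-only organisms the amplicon assay misses, and
`frac_active_taxa` of the DNA-detected fungal taxa transcriptionally
active. For an active taxon, the latent RNA share is a linear function
of the fermentation's must DNA relative abundance plus Gaussian noise
sized from the observed DNA variance so the population R² equals
`dna_rna_r2` (at target 0 the share is independent of DNA with the
same spread). Site-informative genes (default 30 of 200) carry
site-specific log-fold effects constant across vintages and
timepoints; all inoculant genes get timepoint trajectories and
Dirichlet overdispersion.

*Environment.* Site coordinates are drawn in a Pacific-coast box;
precipitation and growing degree days are latitude-trended Gaussian
process draws (squared-exponential kernel, range `env_spatial_range`
km, default 300) per vintage, so geographic and climate distances
co-vary by construction — the latitudinal trend reflects that
west-coast growing-season climate is strongly latitude-structured, and
it is what makes the geography–climate Mantel association reliable at
n = 15 sites. An infinite range collapses each field to one shared
value. Must chemistry (pH, TA, malic acid, NOPA, NH₃) has site-level
means plus tank noise.

All randomness descends from one master seed via fixed substream
offsets, so the study is byte-identical given (config, seed) and each
generator is reproducible in isolation. The truth record (informative
taxa, active taxa and species, planted genes, organelle ASVs) is
sufficient to score recovery without reading generator internals.

Presets: `study_design` (the emulated layout), `large_effect`
(site/region/vintage log-sd 1.2/0.8/0.2, gene effect sd 1.5,
concentration 200 — the high-signal condition for power and recovery
checks), and `null_effect` (all effects zero, dominance off — the
exchangeable condition for type-I calibration).

### What the generator does not emulate

No read-level simulation (no FASTQ, chimeras or error models), no
bacterial transcriptome (3′ tag chemistry captures polyadenylated
eukaryotic mRNA), no taxonomic misannotation, no batch effects, and
compositional coupling beyond closure. Passing recovery tests shows the
inference machinery is correct and calibrated under the stated
statistical structure; it does not certify performance on real
sequencing data, where effect sizes, dispersion and annotation quality
are unknown.

## Numerical and design choices

* Permutation tie handling: statistics compared with a 1e-12 tolerance
  so exact-mode p-values match enumeration bit-for-bit.
* Dirichlet concentrations are floored at 1e-8 to keep the sampler
  defined when a component's expected share underflows.
* Tree predictions inside the permutation-importance loops skip
  sklearn's per-call input validation (verified identical output).
* Problem sizes in the test-suite recovery checks: the large-effect
  preset study (60 RNA fermentations, 200 genes → 1,400 summarized
  features), S = 20 seeds with 500-tree forests and 200-tree vita
  folds; type-I calibration uses 400 null datasets of 16 samples at
  999 permutations. These sizes make the whole suite a desk-scale run
  while leaving the assertions' Monte-Carlo margins comfortable.
* The consensus signature's per-class average is taken over training
  rows of that class (one row per fermentation); with amplicon inputs
  (one sample per tank) rows are samples, which is the same averaging.

## Known limitations

* The DNA–RNA linkage clips negative latent shares at zero; for rare
  active taxa with high noise this attenuates the realized R² slightly
  below target (the dominant-taxon regression used in the recovery
  checks is essentially unaffected).
* The vita p-value is granular (mirrored empirical null), so very
  small feature sets fall back to a max-null cutoff.
* PERMANOVA is single-factor by design; no multi-factor partitioning,
  no partial Mantel, no rarefaction.
* NMDS stress is reported for the embedding of distinct samples;
  degenerate all-equal inputs embed with positive stress, as they
  must.
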