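# Methods

`phyloturn` implements a two-step null-model workflow that partitions the
turnover between pairs of microbial communities among five assembly
processes — homogeneous selection, heterogeneous selection, homogenising
dispersal, dispersal limitation and ecological drift — together with the
niche-conservatism diagnostic that justifies the phylogenetic step, the
supporting diversity/turnover metrics, and a synthetic-data generator that
produces communities under each process so the whole inference chain can
be validated by parameter recovery.

## The two-step framework

**Step 1 — phylogenetic turnover.** For a pair of communities *a*, *b*
with within-sample relative abundances *f* and patristic (cophenetic)
distances *D(i, j)*, the between-community mean nearest taxon distance is

    βMNTD(a,b) = ½ [ Σ_{i∈a} f_ia · min_{j∈b} D(i,j)
                   + Σ_{j∈b} f_jb · min_{i∈a} D(i,j) ],

the abundance-weighted average distance from each taxon to its closest
relative in the other community (a shared taxon contributes 0). An
unweighted presence/absence variant is available (`weighted=False`).
The observed value is standardised against a null distribution obtained
by shuffling the taxon↔tip assignment `reps` times (default 999):

    βNTI = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null,

with the sd using the `reps − 1` denominator. βNTI < −2 is read as
homogeneous selection (turnover lower than chance: consistent
environmental filtering), βNTI > +2 as heterogeneous selection (turnover
higher than chance: divergent filtering).

Two null schemes are provided:

* `null_scheme="shared"` (default) — one tip permutation per
  randomisation, applied to the whole table, the convention of the
  framework this package implements. Because a single relabelling maps a
  taxon present in both communities onto the *same* tip on both sides, a
  shared taxon contributes 0 to every null draw as well; the null
  measures clustering of the *unshared* turnover only. Its statistical
  power therefore grows with the size of the unshared tail — large in
  real amplicon data (thousands of ASVs), small in compact tables. A
  pair with exactly identical membership has an all-zero null under this
  scheme and is flagged undefined.
* `null_scheme="independent"` — each sample's taxa are relabelled by an
  independent permutation per randomisation, in the spirit of the
  phylogeny-pool / richness null models of the phylogenetic-community
  literature. Shared taxa no longer self-match, so the null is dispersed
  even for duplicated communities; this is the scheme under which βNTI of
  an identical pair is well defined (and strongly negative).

Pairs whose null standard deviation falls below 1e-12 (star phylogenies,
exact duplicates under the shared scheme) are flagged `undefined`,
excluded from classification, and reported in a separate column rather
than silently coerced to drift.

**Step 2 — taxonomic turnover.** Pairs not resolved by selection
(|βNTI| ≤ 2) are classified with an abundance-based Raup–Crick metric on
Bray–Curtis. For each randomisation a null community is assembled per
sample from the group's metacommunity: taxa are recruited without
replacement with probability proportional to occupancy (number of
samples occupied) until the observed richness is reached, each recruit
receiving one read; the remaining reads are drawn with probability
proportional to the taxon's pooled relative abundance, restricted to the
recruits, until the observed depth is reached. With BC_obs the observed
Bray–Curtis of the pair (computed on relative abundances so that pairs of
unequal depth are comparable with their nulls),

    RCbray = 2 · [ (#{BC_null < BC_obs} + ½·#{BC_null = BC_obs}) / reps ] − 1 ∈ [−1, 1].

RCbray < −0.95 → homogenising dispersal (turnover below the drift
expectation); RCbray > +0.95 → dispersal limitation (above it);
|RCbray| ≤ 0.95 → drift. All threshold comparisons are strict, so exact
boundary values fall through to the next rule. Ties are counted half,
which keeps a self-comparison finite at exactly −1.

The weighted-sampling-without-replacement step uses Gumbel keys
(Efraimidis–Spirakis), which is exact for successive weighted draws.
`rcbray_pair` draws fresh nulls per pair; `rcbray_all_pairs` draws one
null community per sample per randomisation and shares it across the
pairs of that randomisation (mirroring the shared tip shuffle of step 1);
per-pair marginal null distributions are identical.

**Grouping.** The framework runs separately within each substrate ×
sampling-time group; the group itself is the metacommunity for step 2.
Both steps run on raw (unrarefied, unnormalised) counts restricted to
samples with at least `min_reads` (default 1000) reads, because the
Raup–Crick null explicitly reconstructs observed read depth; a rarefied
table can be passed instead. Per-group percentages of pairs assigned to
each process (`summarize`) exclude undefined pairs from the denominator
and sum to 100.

**Environmental correlates.** `median_bnti` pools, for every sample of a
site, the βNTI values of all its within-group pairwise comparisons across
all sampling times and reports the per-(site, substrate) median;
`env_correlation` regresses these medians on one environmental variable
(OLS slope, Pearson r, two-tailed t-test p).

## Niche-conservatism precondition

The phylogenetic step is only meaningful if close relatives share habitat
preferences. `niche_optima` estimates each taxon's niche optimum as the
read-weighted mean of each environmental variable over the samples where
it occurs (variables standardised to zero mean / unit variance across
sites first, so Euclidean distances are not unit-dominated; a raw-scale
flag exists). `mantel_correlogram` relates the Euclidean niche-distance
matrix to patristic distance: phylogenetic distances are cut into
equal-width classes (Sturges' rule on the number of pairs by default),
each class's 0/1 model matrix is correlated with the niche distances, and
significance comes from permutations of the niche matrix shared across
classes, with the add-one p-value convention.

Sign convention: the raw Pearson correlation with the model matrix is
negated so that *positive r at short distances means clustering* (close
relatives have more similar niches). The default test is one-tailed in
that direction, which keeps the nominal level exact under the null;
`alternative="less"`/`"two-sided"` detect overdispersion. Classes whose
lower bound exceeds half the maximum phylogenetic distance (the standard
correlogram validity domain; configurable) are computed but flagged
untested. Multiplicity is handled by progressive Holm: the k-th class is
corrected within the first k tested classes, the convention for
correlograms read in order of increasing distance.

## Synthetic data: what the generator emulates

The generator mimics a 12-orchard × 5-replicate amplicon survey: one
count table of 60 samples at fixed read depth per dataset, a rooted
ultrametric phylogeny over 200 taxa, a per-site environment table and a
truth manifest naming the generating regime.

* **Tree** — pure-birth (Yule) with exponential waiting times,
  ultrametrised and scaled to unit root-to-tip depth so branch-length,
  niche and selection scales are mutually comparable.
* **Niche** — `n_niche_traits = 8` independent traits evolved by Brownian
  motion (rate 1) along the tree. Multivariate niches matter: any single
  Brownian trait takes similar values in many unrelated clades (every
  lineage's random walk crosses any given value), so a one-dimensional
  "habitat window" is phylogenetically incoherent; requiring proximity in
  all eight dimensions at once makes a niche neighbourhood nearly
  coincide with a clade, which is exactly the conserved-niche premise the
  framework tests for. Real niches are likewise multivariate (soil
  chemistry plus climate).
* **Pool** — log-normal relative abundances (σ = 0.5). The Raup–Crick
  null reconstructs membership by occupancy; for strongly uneven pools at
  this depth/taxon count the null systematically omits more abundance
  mass than multinomial sampling does, which would push even neutral
  pairs below −0.95. A moderately even pool keeps the drift baseline
  calibrated (|RCbray| ≤ 0.95 for ~90% of neutral pairs).
* **Selection** (homogeneous / heterogeneous) — a site's environment is a
  point in niche space; selection admits the `guild_window = 35` taxa
  nearest that point, and a neutral colonisation + demographic lottery
  (uniform membership draw of `guild_richness = 20`, Dirichlet-even
  shares, concentration 150) decides which members dominate each
  replicate. Selection picks the clade; drift picks the members. The
  resulting replicate-to-replicate membership turnover *within* a
  coherent clade is what gives βNTI its power at this scale. Under
  homogeneous selection every site shares one environment, anchored at
  the densest point of niche space (the modal niche — an anchor at the
  trait mean would lie equally near every clade and select no coherent
  guild); under heterogeneous selection the 12 site environments are
  placed by greedy farthest-point traversal of the taxon niches, so
  different sites host well-separated guilds. Setting `sigma_sel`
  replaces the fixed window with a 2σ niche-distance ball (σ = 0 admits
  only the single best-matching taxon).
* **Dispersal limitation** — no selection; each site's pool is restricted
  to `founder_pool_size = 80` founders drawn uniformly, then a site-level
  Dirichlet lottery (concentration 30 × founder abundances) lets each
  site develop its own dominance structure before multinomial sampling —
  limitation acts by amplifying drift. Smaller founder pools make
  cross-site turnover statistically indistinguishable from the
  Raup–Crick null's own assembly; the defaults give cross-site pairs that
  are reliably *more* dissimilar than the null.
* **Homogenising dispersal** — sites have distinct environments (the
  heterogeneous-selection anchors), but a fraction `migration_rate = 0.95`
  of every community is one shared *realised* regional draw: a single
  multinomial of 0.95 × depth from the pool added to every sample, plus a
  site-specific guild component for the rest. Mixing *expected*
  compositions would be indistinguishable from drift at high migration —
  mass effects make communities share realised composition, not just
  expectation, and that is what drives turnover below the null.
* **Drift** — pure multinomial sampling from the common pool, the
  weakest-structure baseline.
* Counts are multinomial at `read_depth = 1000` per sample (a
  depth-jitter option exists for robustness checks). The environment
  table carries the niche coordinates that actually drove selection plus
  two decoy variables with no effect, so null behaviour of the
  environmental-correlation step can be tested.

**What the generator does not emulate.** Sequencing error, chimeras,
taxonomy, variable library sizes (by default), the leaf/fruit/soil
source-tracking structure, and temporal autocorrelation between sampling
occasions. Passing the recovery tests shows the inference machinery is
sound under the stated generative assumptions, not that real communities
satisfy those assumptions. Datasets generated under homogeneous selection
have no between-site environmental contrast, so the niche-conservatism
diagnostic is uninformative there; the precondition test is exercised on
heterogeneous-selection datasets, where optima differ among sites.

## Numerical choices

* Permutation p-values use (count + 1)/(permutations + 1); the exhaustive
  Mantel mode enumerates all n! relabellings (n ≤ 8) and reports the
  exact tail fraction with the identity included.
* βNTI nulls with sd < 1e-12 are undefined (flagged, excluded, warned).
* Raup–Crick ties BC_null = BC_obs are detected at 1e-12 tolerance and
  counted half.
* Equal-width correlogram classes over [0, max distance]; zero distances
  fall in the first class; empty classes are skipped with a warning.
* Unrooted Newick input is midpoint-rooted — patristic distances, the
  only tree quantity used, are rooting-invariant.
* CSS normalisation uses a fixed quantile (default 0.5) rather than the
  adaptive rule, for determinism; the global scale constant is the median
  of the per-sample scaling sums, keeping values on a count-like scale.
* Rarefaction is multivariate-hypergeometric (without replacement), so an
  absent taxon can never gain reads.
* All stochastic stages take an integer seed, a `SeedSequence` or a
  `Generator`; the pipeline derives per-stage seeds from one master seed
  via fixed `spawn_key` tags, so adding a stage never perturbs the
  streams of earlier stages. Identical seeds give bitwise-identical
  output.

## Problem sizes used in validation

The regime-recovery benchmark runs the full design (12 × 5 samples, 200
taxa, depth 1000) with 199 null randomisations per step; published
analyses typically use 999, and the Monte-Carlo stability checks show
βNTI at 999 and 9999 randomisations agree within 0.2. Null-calibration
checks use 199–999 permutations over 100–200 simulated datasets of small
size. These sizes were chosen so the whole validation suite completes in
a few minutes on one core while keeping every Monte-Carlo margin wide
relative to its tolerance.

## Known limitations

* The shared-shuffle βNTI has little power when communities share most
  of their membership and the taxon pool is small; the independent
  scheme measures a different (membership-sensitive) null. Both are
  documented; users of compact tables should prefer the independent
  scheme or interpret shared-scheme βNTI near 0 cautiously.
* RCbray calibration depends on the metacommunity's evenness and on
  per-sample richness relative to pool richness; the ±0.95 thresholds
  are conventions, not significance levels.
* The per-pair process labels are the *dominant* process per comparison;
  percentages are descriptive summaries, not a variance decomposition.
* Classification treats βNTI and RCbray thresholds as hard rules; no
  uncertainty propagates from the finite number of randomisations into
  the class labels.
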