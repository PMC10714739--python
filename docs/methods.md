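# Methods

`microweb` analyses seasonal microbial food webs at the processed-data
level: genus-resolved protist communities (18S-style), phylum-resolved
bacterial communities (16S-style), a guild annotation, and a
literature-compiled predator–prey catalog. This note records the models,
conventions, parameter choices and known limitations behind the
implementation.

## Web construction

A seasonal web contains one node per protist genus detected in that
season's samples (summed counts ≥ `min_count`, default 1 — presence),
plus five standing aggregate compartments: algae, bacteria, fungi,
detritus and dissolved organic carbon (DOC). The adjacency matrix uses
the convention `a[i, j] = 1` when node *j* preys on node *i* (prey on
rows, predators on columns; energy flows row → column). Catalog edges
with an absent endpoint are excluded and tallied in the build report —
literature catalogs routinely reference taxa a given season lacks.
Aggregates are retained even when isolated because they are standing
compartments; genus nodes without any trophic link are dropped, so the
species count S counts interacting trophic species. Cannibalistic
self-loops are rejected at parse time and the diagonal is forced to
zero: none of the metrics used here is defined with self-loops in mind.

Bacteria appear twice, deliberately. The seasonal topology web carries
one bulk `bacteria` compartment. The per-sample feature analysis uses an
*expanded* view in which the bulk node is replaced by the detected
bacterial phyla, because the bacterivory feature `Int` (below) is about
which bacterial taxa are grazed, not that bacteria exist.

## Metrics

* **Complexity** — S, L, linkage density `LD = L/S`, and directed
  connectance `C = L/S²`. The directed form is used because it
  reproduces the published seasonal values from their own (S, L) pairs
  in three of four seasons; the remaining cells (summer LD, winter C)
  are internally inconsistent in the source and are reported as
  computed, flagged, never silently corrected.
* **Clustering (CC)** — mean local clustering on the symmetrized graph;
  degree-<2 nodes contribute 0. Trophic direction carries no meaning for
  neighbourhood closure, hence the symmetrization.
* **Characteristic path length (CPL)** — mean shortest-path length over
  reachable unordered pairs of the symmetrized graph; unreachable pairs
  are excluded from the mean and counted in a side report. An entirely
  disconnected web is an error, not a number.
* **Modularity (Mod)** — Newman's Q under greedy agglomerative
  (Clauset–Newman–Moore) merging of the symmetrized graph. The greedy
  algorithm is deterministic for a fixed node order, so repeated runs
  give identical partitions — reproducibility was preferred over the
  (stochastic) Louvain/Leiden family. An edgeless web scores Q = 0 on
  the singleton partition.
* **Trophic levels (TL)** — prey-averaged: basal nodes (no prey) sit at
  TL 1 and a consumer sits at one plus the mean TL of its diet. The
  definition is solved as the linear system `(I − W)·TL = 1` with W the
  row-stochastic diet matrix, so feeding loops are handled exactly. The
  system is singular precisely when some consumer has no path down to a
  basal resource; by default this is an error naming the offending
  nodes, while ensemble code uses the minimum-norm least-squares
  fallback (`on_singular="lstsq"`), since degree-preserving shuffles
  occasionally manufacture such basal-free loops.
* **Omnivory (O)** — the fraction of species feeding at more than one
  trophic level: at least two prey whose TLs differ by more than 1e-9.
  The denominator is all S species (matching a "percentage of omnivory"
  reading); a consumers-only denominator is available via a flag.
* **Degrees** — per-node prey, predator and total degrees; the average
  degree is `AD = 2L/S`.

## Quasi sign-stability (QSS)

The web's sign pattern is held fixed while interaction magnitudes are
redrawn: for each trophic link prey *i* → predator *j*, a single draw
`u ~ Uniform(0, 10)` sets the prey's loss `M[i, j] = −u` and the
predator's gain `M[j, i] = +e·u` with trophic efficiency `e = 0.1`;
every diagonal entry is `−d`, `d ~ Uniform(0, 1)` (self-limitation on
all compartments by default, toggleable to basal-only). Both the
proportion of draws whose leading eigenvalue real part is strictly
negative (`prop_stable`, with a Wilson 95% CI) and the mean leading real
part (`mean_max_eig`) are reported. A leading real part of exactly zero
counts as unstable; it is a measure-zero event. The magnitude
distributions are conventional choices, exposed as parameters — the
sign structure, not the scale, is the object of study. For realistic
webs of ~70 nodes and ~800 links `prop_stable` is essentially 0 (the
classic dense-random-matrix regime), so `mean_max_eig` is the
informative summary there: lower means closer to stability, and it is
the quantity used when the package says one web is "more stable" than
another.

## Curveball null models

Degree-preserving randomization trades, between a random pair of rows,
the entries held by exactly one of the two; every node keeps its exact
number of prey and predators. On the square trophic matrix the two
diagonal cells of a traded row pair are pinned so no trade creates a
self-loop; the raw matrix routine also runs unpinned for bipartite
incidence matrices. A degenerate trade counts toward the trade budget,
bounding runtime. Null ensembles run a single Markov chain from the
empirical web with `5·S` trades between retained snapshots (burn-in =
thinning = `5·S`; the choice is a standard mixing heuristic, exposed as
a parameter). The ensemble yields empirical 2.5/97.5 percentile bands
and a range-based `within` flag — the acceptance rule is "the observed
value falls inside the simulated range". Seasonal ensembles of the same
metric are compared by the two-sample two-sided Kolmogorov–Smirnov test
(asymptotic p); both ensemble-vs-ensemble and ensemble-vs-scalar
comparisons are possible since `ks_compare` takes plain vectors.
Benjamini–Hochberg adjustment is applied within each test family
(KS family, regression family) and reported alongside raw p values.

## Per-sample features

Each sample induces a sub-network of its season's expanded web on the
taxa the sample contains; the five standing compartments are always
retained, phylum nodes follow the sample's own detections. Features per
sample: Shannon diversity H (natural log) of the protist counts;
sub-network S, L and average degree `AD = 2L/S`; and `Int`, the
proportion of the sub-network's links that run from a bacterivorous
protist predator to a bacterial node. `Int`'s denominator is all links
of the sub-network by default (a protist-predator-only denominator is a
flag). Simple OLS with a two-sided t-test on the slope relates `Int` to
sub-network metrics across samples, and Spearman rank correlations
(tie-corrected) relate complexity columns (L, LD, C) to structure and
stability columns (meanTL, O, Mod, QSS). Per-sample QSS uses 200 draws
by default — a tractability compromise; the seasonal webs use 1000.

## Synthetic data generator

The generator emulates the survey design: four seasons × 9 samples,
seasonal detected-genus richness hit *exactly* (defaults 64/65/56/54,
giving webs of 69/70/61/59 nodes once the five aggregates join), a
phototroph-dominated guild mix with bacterivores the leading predator
guild, and a single global catalog. Specifics:

* **Guilds.** A pool of 75 genera receives primary guilds by
  largest-remainder apportionment of configured proportions (phototrophs
  0.34, bacterivores 0.32, parasites 0.06, algivores 0.09, nonselective
  omnivores 0.08, raptors 0.05, mycophagous/saprotroph/unknown 0.06).
  Eukaryvorous consumers (A/N/R) each gain one secondary guild among
  {A, N, R}; bacterivores stay specialist grazers. With these
  proportions the bacterivore share of predators lands in the 0.45–0.78
  band by construction.
* **Catalog.** Per guild membership, prey are sampled without
  replacement from the guild's prey class (bacterivores: the bulk
  bacteria pool always, plus preferred phyla; algivores: phototroph
  genera + algae; nonselective omnivores: anything; raptors: other
  genera; mycophagous → fungi; saprotrophs → detritus; parasites attach
  to 1–3 host genera as predators — the energy-flow convention treats a
  parasite as consumer of its host). Prey counts follow a geometric law
  with per-guild means (B 3.5, A 38, N 78, R 62), truncated at the class
  size and at 1.5× the mean; the cap keeps total link counts, and hence
  connectance, inside the study's band (seasonal C ≈ 0.12–0.18 across
  seeds) without letting single predators dominate. A per-season patch
  pass guarantees no detected genus is trophically isolated, so realized
  web sizes equal the richness targets exactly.
* **Abundances.** Presence is stratified by primary guild crossed with
  small catalog-degree bins, modulated by a per-sample detection-effort
  multiplier (SD 0.08) — samples differ mainly in which, not how many,
  members of each stratum they caught. Counts are rounded log-normal
  (μ = 5, σ = 1.2); the analysis uses presence and proportions only, so
  the abundance law is a free choice. Bacterial phyla are near-ubiquitous
  (presence 0.9).
* **Planted effects.** `plant_association` tilts each sample's guild
  balance along a latent gradient: high-gradient samples keep
  bacterivores and shed broad-diet generalists, raising `Int` while
  thinning links; `strength` 0 is the identity, and one protected sample
  per genus keeps season-level richness intact. The requested
  sign/metric pair only orients the gradient.

**What the generator does not emulate**, hence what passing tests do not
show about real data: sequencing and OTU-clustering noise, abundance–
interaction coupling, environmental drivers of composition, seasonal
turnover structure beyond stratified subsetting, and interaction
strengths. One further caveat matters for interpretation: in webs of
this architecture, per-sample `Int` and sub-network modularity are
intrinsically positively coupled — bacterivory links are
module-coherent, so any presence churn moves the two statistics the
same way, and removing *any* coherent edge bundle lowers both Q and
`Int`'s numerator while sparsification raises both. Extensive
experiments (stratified guild counts, degree balancing, effort
gradients, specialist vs. mixed bacterivores, phylum-only churn) all
left within-season Spearman ρ(Int, Mod) at roughly +0.4–0.95. A
positive observed Int–Mod association in such webs therefore cannot by
itself be read as an independent ecological effect; the package's
planted-effect machinery measures *recovery* of a known perturbation,
not detection against a clean independence null, because that null does
not exist here.

## Numerical and design choices

* Seed handling: one global seed fans out to stage seeds via
  `numpy.random.SeedSequence(entropy=seed, spawn_key=(k,))` with a fixed
  stage counter k, so any stage reruns in isolation bit-identically.
* All TSV output uses 6 significant digits; integer counts are written
  as integers, making write→read round-trips bit-exact.
* Ties and degeneracies: omnivory's TL-difference tolerance is 1e-9;
  exactly-zero leading eigenvalues count unstable; degenerate curveball
  trades are no-ops that consume budget; the modularity of an edgeless
  graph is 0 by convention.
* Problem sizes in the test-suite and the acceptance script — 1000
  curveball replicates per ensemble, 1000 QSS draws per seasonal web,
  200 per sample sub-network, 100 replicates for parameter recovery —
  are the package's working defaults for a ~70-node web and complete in
  minutes on a single core.

## Known limitations

* Binary webs only: no interaction strengths, no flow-based trophic
  levels, no quantitative (weighted) metrics.
* The greedy modularity partition is one deterministic heuristic; its Q
  values are comparable within this package but not across algorithms.
* QSS here is local asymptotic stability of sign-constrained random
  Jacobians; it says nothing about permanence, press perturbations or
  transient behaviour.
* The curveball chain length (5·S between snapshots) is a mixing
  heuristic, not a proven mixing time for every degree sequence.
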