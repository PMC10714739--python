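# microweb

Seasonal microbial food-web analysis for community-survey data: build
genus-level trophic networks from abundance tables and a predator–prey
catalog, quantify their complexity, topology, trophic structure and
stability, place the observed values inside degree-preserving null
ensembles, and relate per-sample bacterivore–bacteria interactions to
the web metrics.

The package is aimed at microbial ecologists working with processed
amplicon surveys — a genus-resolved protist table (18S), a
phylum-resolved bacterial table (16S), a trophic-guild annotation in the
style of the Protist Interaction Database, and a literature-compiled
edge list of who eats whom. Raw-read processing, ordination and
structural-equation modelling are out of scope.

## The model

A seasonal web has one node per detected protist genus plus standing
aggregate compartments (algae, bacteria, fungi, detritus, DOC), and a
binary adjacency matrix with $a_{ij} = 1$ when taxon $j$ preys on taxon
$i$. From each web the package computes:

* **Complexity** — links $L$, linkage density $LD = L/S$, directed
  connectance $C = L/S^2$.
* **Topology** — mean clustering coefficient $CC$, characteristic path
  length $CPL$, and Newman modularity $Q$ under deterministic greedy
  agglomeration (all on the symmetrized graph).
* **Trophic structure** — prey-averaged trophic levels
  $TL_j = 1 + \frac{1}{|D_j|}\sum_{i \in D_j} TL_i$ (basal $TL = 1$),
  solved as the linear system $(I - W)\,TL = \mathbf{1}$ so feeding
  loops are exact; omnivory $O$ = fraction of species feeding at more
  than one trophic level.
* **Quasi sign-stability** — Monte-Carlo sampling of community matrices
  constrained to the web's sign pattern (prey loss $-u$,
  $u \sim U(0,10)$; predator gain $+0.1u$; self-limitation
  $-d$, $d \sim U(0,1)$), reporting the proportion of locally stable
  draws and the mean leading eigenvalue real part.
* **Null models** — curveball randomization (trades of non-shared prey
  between row pairs; every species keeps its exact number of prey and
  predators), metric ensembles with 95% bands, and two-sided
  Kolmogorov–Smirnov comparisons between seasonal ensembles.
* **Per-sample features** — Shannon diversity, sub-network average
  degree $AD = 2L/S$, and $Int$, the proportion of sub-network links
  running from bacterivorous protists to bacterial taxa, with OLS
  regressions of sub-network metrics on $Int$ and Spearman
  complexity–stability correlations.

A bundled synthetic-data generator reproduces the survey's statistical
shape (four seasons × 9 samples, webs of 59–70 nodes, connectance
≈ 0.12–0.18, phototroph-dominated guilds with bacterivores the leading
predators) so the whole pipeline runs with no download; it can also
plant a feature–metric association of chosen sign and strength for
parameter-recovery studies. See `docs/methods.md` for definitions,
conventions and caveats.

## Worked example

```python
import microweb as mw

study = mw.FoodWebStudy.from_synthetic(seed=1)   # or .from_directory(...)
res = study.fit(seed=1, n_random=200, n_draws=500, sample_qss_draws=50)
print(res.summary())
```

prints (abridged):

```
Seasonal web metrics
----------------------------------------------------------------
         S    L     LD     C    CC   CPL   Mod  meanTL     O
spring  69  808 11.710 0.170 0.805 1.697 0.050   2.197 0.203
summer  70  858 12.257 0.175 0.813 1.690 0.036   2.192 0.200
autumn  61  591  9.689 0.159 0.787 1.719 0.060   2.177 0.197
winter  59  606 10.271 0.174 0.801 1.693 0.054   2.171 0.203

Null-model placement (curveball ensembles)
----------------------------------------------------------------
    spring       meanTL: empirical=2.197 null 95% [0.997, 3.231] within=yes
    ...
    summer   modularity: empirical=0.036 null 95% [0.034, 0.046] within=yes

Int regressions across samples
----------------------------------------------------------------
feature metric      slope  r_squared      p  n
    Int    Mod     1.3085     0.6046 0.0000 36
    Int      L -9702.4196     0.3614 0.0001 36
    Int      C    -0.7525     0.4177 0.0000 36
```

Reading it: the four seasonal webs carry 59–70 interacting nodes at
connectance 0.16–0.18; every empirical structure metric sits inside its
curveball null range (`within=yes`), so the degree-matched ensembles are
valid references; and across the 36 samples the bacterivory share of
links is positively associated with sub-network modularity and
negatively with link count and connectance. `res.samples`,
`res.null`, `res.qss`, `res.ks` and `res.correlations` hold the full
tables; `res.save(outdir)` writes them as TSV/JSON, and
`res.plot_null("summer", "modularity")` draws the ensemble histogram
with the empirical value marked.

The same pipeline is scriptable from the shell:

```sh
microweb simulate --seed 1 --out data/
microweb all --data data/ --out results/ --seed 1 --n-random 1000
```

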