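# Methods

`xdevo` implements a cross-species, cross-platform analysis of developmental
time-course transcriptomes: one species measured by a counting platform
(bulk RNA-seq, one animal per developmental age) is compared with a second
species measured by a continuous-intensity platform (expression microarray,
replicate animals per age).  The pipeline screens each species for
temporally differential genes, clusters temporal profiles, joins the two
species over one-to-one orthologs, summarises joint structure by PCA, scores
clade stability by multiscale bootstrap, and classifies each ortholog pair's
temporal conservation by the Pearson correlation of phase-averaged profiles.
Everything is exercised against a synthetic generator that plants known
structure, so every stage has ground truth.

## Synthetic data generator

The generator (`xdevo.simulate`) emulates the data layout described above.
Each gene belongs to exactly one class: three *conserved* temporal programs
(monotone up, monotone down, unimodal peak) shared by both species after
rank-based alignment of ages; a *species-A-late* program (silent until a
transition point, then rising — e.g. contractile-protein activation during
alveolar maturation); a *birth-linked* program elevated only in a window at
the earliest postnatal ages of species B; and *flat* genes.

Key modelling choices:

* **Time mapping by rank.**  Templates are functions of the normalised rank
  position of an age within its species, not of chronological age —
  cross-species comparisons align developmental stages, which unfold at
  different absolute rates.
* **Templates are zero-mean deviations.**  Per-gene baselines (uniform on
  log2 6–12, i.e. genes above the detection floor of a filtered expression
  matrix) are *mean* expression; temporal programs redistribute expression
  around them.  This keeps a gene's intensity rank independent of its
  temporal class, which is also the operating assumption of the
  intensity-difference screen (see below).  Without it the intensity
  extremes become majority-one-class and any local-null method breaks
  there.
* **One noise source per platform.**  Species A's variability is carried
  entirely by the negative-binomial count noise with dispersion 0.05
  (variance `mu + 0.05 mu^2`), whose implied log2-scale SD
  (`sqrt(0.05)/ln 2 ~ 0.32`) is a realistic single-animal bulk figure;
  species B's is lognormal with `noise_sd = 0.3` (SD of log2 intensity)
  plus an additive background floor (default 32 intensity units).
  Per-sample library sizes for A are lognormal (sigma = 0.2).
* **Defaults** (1000 genes; 7 ages per species; 3 replicate animals per age
  in B; class mixture 7% up / 7% down / 6% peak / 10% species-A-late /
  5% birth / 65% flat; effect size 2 on the log2 scale; ortholog map
  covering 90% of genes) define the study conditions used throughout the
  tests and the acceptance script.  Class counts are `round(fraction x
  n_genes)` with the remainder assigned to flat.  Species-level offsets
  (SD `species_offset_sd`) are applied, in species B, to the divergent
  classes.

What the generator does **not** model: probe-level microarray physics,
read-level sequencing, batch effects beyond the platform background, and
correlated gene modules (genes are independent given their class).  Passing
tests therefore demonstrate correctness of the algorithms under a clean
generative model, not performance on any particular real dataset.

## Normalisation chain

`raw -> log2(x + 1) -> per-sample background subtraction -> per-sample mean
centering -> per-gene per-species mean centering`, enforced through a
`scale` tag so steps cannot run out of order.  Background correction
subtracts each sample's 5th-percentile log value — a location shift that
aligns platform floors without disturbing rank order; the quantile uses
linear interpolation between order statistics so results are
bit-reproducible.  The per-gene per-species centering is what makes count
and intensity platforms jointly analysable: each gene is reduced to its
temporal deviation from its own species mean.  Both centerings are exact
(means vanish to 1e-9) and idempotent.  Replicate averaging is the
arithmetic mean of a metadata-defined group.

## Intensity-difference differential expression

A gene's between-group difference of mean log expression is judged against
the empirical distribution of the same difference among the `w =
max(50, 0.01 n)` genes nearest in overall mean intensity (a contiguous rank
window centred on the gene, clipped at the ends).  This respects the strong
mean–variance relationship of expression data without fitting a count
model.

**Robust window null.**  The window inevitably contains some of the very
differential genes the screen is after; at a non-trivial signal fraction a
plain window SD is inflated several-fold and power collapses.  The window
null is therefore estimated robustly: start from the window median and MAD,
trim beyond 2.0 scaled SDs with a monotone non-increasing trim radius
(3 iterations, normal-consistency variance correction at each step) so the
scale converges down onto the null bulk rather than re-admitting the fringe
of a separated signal cluster, then make a final pass at 2.5 SDs for
estimator efficiency.  Finally the per-window variances are smoothed along
the intensity ranking with a centred running median spanning five window
lengths: the true scale varies smoothly with intensity, while the raw
per-window estimates are strongly correlated between overlapping windows
and their occasional collective dips would otherwise inflate the far z
tail.  `robust=False` selects the plain mean/SD for comparison.  Both
variants are checked against independent per-gene loop implementations to
1e-9.

**Evidence combination.**  Per gene the statistic is the extreme pairwise
z-score across all group pairs (a gene differential anywhere in the course
is of interest).  Its p-value is *not* the raw minimum p — with k groups
that is anticonservative by roughly the number of effective comparisons —
but the exact tail of the maximum absolute pairwise z for equal-size
groups: `max |z| = range(group effects)/sqrt(2)`, referred to the
studentized-range distribution of k iid normals (computed by quadrature and
cached per k).  For two groups this reduces exactly to the two-sided normal
p.  The `vs-rest` mode (each group against the pooled remainder) uses a
Sidak correction instead, since those comparisons are not exchangeable
pairs.  Benjamini–Hochberg adjustment across genes at alpha = 0.05 gives
the significant set.

Measured operating points (fixed-seed Monte Carlo, also recomputed by
`scripts/acceptance.py`): under a 2-groups-of-3 Gaussian null with 2000
genes the raw p < 0.05 rate is ~0.054 and BH yields ~0.3 discoveries per
run; planted four-SD group shifts are recovered with ~93% sensitivity.

## Clustering and bootstrap support

Sample (or gene) dendrograms use correlation distance `1 - r` with complete
linkage (scipy's implementation; an O(n^3) brute-force reference with
lowest-index tie-breaking is kept in the test suite and agrees exactly on
tie-free data — with continuous distances ties have measure zero).
Temporal profile classes are extracted by Lloyd k-means (default k = 4) on
per-gene z-scored profiles, best of 10 seeded restarts; centroids are
recomputed as exact member means after fitting.

Clade support uses the multiscale bootstrap.  Features (the non-clustered
axis) are resampled with replacement at sizes `round(r x n_features)` for
`r` in 0.5–1.4 (step 0.1); each replicate is re-clustered and a clade
counts as recovered when its exact leaf set reappears.  The replicate
stream is fully determined by `(seed, scale index, replicate index)`, so
scales are independent yet reproducible, and a naive re-implementation can
replay the identical stream (asserted in tests).  BP is the raw recovery
fraction at r = 1.  For AU, `psi_r = Phi^-1(1 - BP_r)` is fitted against
`(sqrt(r), 1/sqrt(r))` by weighted least squares with binomial variance
weights, giving signed distance `v` and curvature `c`;
`AU = 1 - Phi(v - c)`.  BP values are clipped to
`[1/(n_boot+1), 1 - 1/(n_boot+1)]`; clades at the boundary at every scale
short-circuit to AU = 1 (or 0) with a degenerate-fit flag, as does a fit
with fewer than two usable scales (AU falls back to BP at r = 1).  `AU >=
model BP` whenever `c > 0`, and an exact synthetic BP curve reproduces
`(v, c)` to 1e-6.

Defaults: n_boot = 1000 for the standalone operation; the pipeline default
is 200 per scale (2000 reclusterings in total), which bounds the BP
Monte-Carlo SE at ~3.5% — adequate for the annotated trees it draws.

## Cross-species integration and conservation

After per-species gene centering, ortholog pairs (one-to-one by
construction: any identifier appearing in more than one candidate pair is
dropped entirely) are stacked into a combined matrix with row identity
`GENEA|GENEB`.  PCA treats samples as observations (SVD without further
centering — per-species gene centering already implies global gene
centering); variance explained is `sigma_k^2 / sum sigma^2`, components
below 1e-12 of the leading singular value are dropped, and the sign
convention makes each component's largest-magnitude loading positive.
Loadings have unit column norm, which fixes the scale of the
loading-threshold gene retrieval (default: component 2, |loading| > 0.04).

Conservation is scored on phase-averaged profiles: each species' samples
are assigned to early / intermediate / late development (by explicit config
or by splitting each species' ordered ages into thirds), profiles collapse
to the three phase means, and each ortholog pair gets the Pearson
correlation of its two 3-point profiles.  Classes: `conserved_strict`
(r > 0.9) subset of `conserved` (r > 0.8); zero-variance profiles are
`undefined`.

**DE prefilter.**  With only three phase points the null correlation is
arcsine-distributed — for two independent noise triples P(r > 0.8) is
about 0.2 — so the raw correlation screen cannot separate flat genes from
conserved ones.  The screen is therefore restricted to genes temporally
differential in *both* species.  A gene counts as temporally differential
if flagged by the per-age screen or by a phase-grouped screen (ages pooled
into the three phases): with one animal per age the per-age groups are
singletons and underpowered for gradual trends, while phase pooling loses
narrow peaks straddling a phase boundary — the two are complementary.  At
the default generator settings this screen attains ~0.93 sensitivity and
~0.998 specificity for planted conserved genes (mean over seeds).

## Pipeline and reproducibility

`run_pipeline` executes simulate → normalise → DE → k-means → ortholog
join → PCA → bootstrap clustering → conservation from one `RunConfig`
(YAML-serialisable, dataclass-validated).  A single global seed is expanded
into named per-stage substreams (`SeedSequence([seed, stage_index])`), so
stages can be re-run in isolation with identical randomness.  All artifacts
are plain text (TSV with `#` header comments naming the stage and
parameters, annotated Newick, JSON with sorted keys); two runs with the
same config are byte-identical.  Figures are rendered only by the separate
`report` step so computational outputs stay byte-comparable.

Problem sizes used by the test suite and `scripts/acceptance.py` (1000–2000
genes, 7 ages, 100–1000 bootstrap replicates, 3–20 Monte-Carlo seeds per
quantity) are the package's default desk-scale study conditions; all
reported operating points above are recomputed from scratch at run time.

## Known limitations

* The studentized-range combination is exact only for equal-size groups;
  mildly unequal groups (e.g. a trailing singleton age) are handled
  approximately.
* AU p-values inherit the usual caveats of the curve-fit construction:
  they are undefined (and flagged) for clades never or always recovered,
  and with n_boot = 100 the BP resolution limits AU accuracy.
* The conservation classifier uses exactly three phase means, following
  the phase-matched design it reproduces; a full-profile correlation mode
  exists for sensitivity analysis but is not the default.
* Ortholog inference, functional enrichment, and platform-specific
  preprocessing (probe summarisation, count normalisation) are out of
  scope; the pipeline consumes expression matrices and a one-to-one
  ortholog map.
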