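# Methods

This note documents the models, rules and numerical choices behind
`ceconet`, and what the synthetic-data studies do and do not demonstrate.

## Capability model

The knowledge base is a set of flat tables: organisms (with genus label and
annotation source — KEGG-coded, UniProt-annotated, or BLAST-assigned
orthologs), organism→KO and organism→EC assignments, KO→reaction and
EC→reaction links, reaction→primary substrate–product compound pairs, and
compound monoisotopic masses. An organism *carries* a reaction when any of
its KO **or** EC assignments links to it (set union; requiring both routes
would make coverage hostage to whichever annotation happens to be missing,
and the two routes are redundant encodings of the same enzymology). Genus
columns are the union of their member organisms, with per-entry provenance
retained so a reviewer can see which annotation source contributed each 1.

Manual curation of organisms implausible in the habitat (e.g. soil dwellers
sharing a genus name with gut taxa) is a judgment call, not a computation;
it enters as an explicit organism exclusion list.

The genus→metabolite capability map takes, for each reaction a genus
carries, **both** sides of each primary substrate–product pair: an enzyme
acting on a compound is evidence of interaction regardless of direction, and
edge classification ("can this genus metabolize this compound?") is
direction-free. Reactions without pair records contribute nothing and are
counted in diagnostics. Coverage reporting gives the fraction of total
genus-level counts carried by genera with at least one nonzero matrix entry,
the genera-per-reaction distribution (reactions private to one genus versus
ubiquitous), and per-compound genus-ubiquity fractions.

## Community profiles

* Singleton OTUs (total count exactly 1 across all samples) are removed
  before any statistics.
* Rarefaction is a single multivariate-hypergeometric draw per sample to a
  common depth (the minimum sample total by default), seeded and
  reproducible. One draw, not an average over repeated draws: averaging
  produces non-integer counts and obscures the sampling variance the
  downstream t-tests assume.
* Genus aggregation sums OTU counts sharing a genus label **before**
  normalizing to relative abundance, so counts are conserved. Lineages
  unclassified at genus rank get the stable label
  `unclassified_<parent-rank>_<parent-name>`, which keeps them distinct
  across parents instead of pooling them into one meaningless bin.
* "Detected on both days" for the abundance filters is operationalized as
  mean relative abundance above the threshold within **every** required day
  group. Per-sample presence was rejected: with n = 5 replicates a single
  dropout sample would evict a genus. Defaults: 0.0001 (0.01 %) for
  capability-model inclusion, 0.0005 (0.05 %) for correlation eligibility.

## LC-MS features

* **Alignment** is greedy single-linkage in (m/z, RT), seeded by descending
  intensity: the most intense unassigned peak founds a feature and absorbs
  peaks within 10 ppm (relative to the lower m/z) and 0.5 min. Each sample
  contributes at most one peak per feature (most intense wins). Consensus
  m/z and RT are intensity-weighted means. Peaks are canonically sorted
  first, so the result is independent of input order.
* **Intensity filter**: features whose maximum intensity is below 100 cps
  are dropped; a feature exactly at the threshold is kept (≥ semantics).
* **Isotopologue collapse**: co-eluting features (within 0.1 min) on the
  ladder m0 + k·1.00336 Da (k ≤ 3, 10 ppm per rung, charge 1 assumed) are
  collapsed onto the lowest-mass member, which is flagged monoisotopic.
  Ladders are treated as contiguous — a missing rung ends the series. The
  summed group intensity is recorded rather than discarded.
* **Temporal classes** use an explicit rule table over signed two-tailed
  t-tests of inoculated versus medium-blank intensities at day 1 and day 7:
  (−,−) fast substrate, (0,−) slow substrate, (+,+) fast product, (0,+)
  slow product, (+,0) or (+,−) intermediate (elevated early, gone later),
  anything else unclassified. Hierarchical clustering finds these same five
  patterns in real data, but a rule table is deterministic, auditable, and
  directly testable against planted classes. Zero-variance groups make the
  test undefined; such features are reported unclassified with a diagnostic.
* **RT correction** maps observed RT onto the pure-standard scale by local
  linear regression: an ordinary least-squares line through the k = 3
  anchors nearest in observed RT, with extrapolation from the nearest window
  outside the anchor range. k = 3 is the smallest window that still
  averages anchor noise while following piecewise-linear drift exactly.
* **Annotation** matches feature m/z to compound adduct masses (M+1.007276
  in positive mode, M−1.007276 in negative; other adducts are out of scope
  by default) within 10 ppm, then scores each candidate by how many of its
  distinct reaction-pair neighbors (graph distance 1) have adduct masses
  matching any detected feature. Ranking is score-descending, ties broken by
  absolute ppm error. Depth-1 neighborhoods keep the score interpretable (a
  count of corroborating detections); deeper neighborhoods dilute the signal
  with hub compounds.

## Correlation network

* `pearson_with_p` uses the exact two-tailed t-test:
  t = r·√(n−2)/√(1−r²), df = n−2; |r| = 1 maps to p = 0. Constant vectors
  are an error for the caller to handle — the screen excludes such pairs
  *before* forming the BH family, so m counts only testable pairs.
* `bh_adjust` is the step-up procedure: sort ascending,
  q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j, capped at 1. The family is **all** testable
  genus × metabolite pairs in one screen (not per-genus families, which
  would trade false-discovery control across genera of different sizes).
* Edges require |r| ≥ 0.76 **and** adjusted p < 0.05 by default; a config
  switch substitutes the raw p-value for sensitivity analyses. Both
  thresholds are configuration, not constants.
* Node fold change (day 1 → day 7) uses
  log₂((mean₇ + ε)/(mean₁ + ε)) with a ±0.26 dead zone (about 1.2-fold)
  defining "unchanged"; a binary up/down call with no dead zone would flip
  on noise for flat nodes.
* Which samples enter the screen (days, treatments, inoculated-only) is an
  explicit configuration choice; the default pools both days and all
  treatment arms of the inoculated cultures.
* Export: SIF, edge/node attribute TSVs and GraphML with fixed field order
  and formatting, so identical runs are byte-identical.

## Synthetic data

The generators emulate the study design the pipeline targets: 5 replicate
cultures × days {1, 7} × {control, 10 µM, 100 µM} plus per-day medium
blanks. Genus abundances are log-normal with genus-specific day-7 shifts
(some genera rise, some collapse between days); OTU counts are multinomial
draws at 50,000 reads over ~2 OTUs per genus. Planted metabolite signals are
linear transforms of the latent genus abundance plus Gaussian noise scaled
by √(1/r² − 1), so the population correlation equals the requested r
(default 0.95) and `noise_sd = 0` degenerates to an exact linear transform.
Empirical (non-mechanistic) plants are rejection-sampled so the compound is
verifiably outside the genus's capability set. Feature emission adds
1.5 ppm m/z and 0.01 min RT jitter, five temporal classes at 5-SD effects,
decaying isotopologue ladders, a dose-scaled parent/monoester pair, and
unstructured noise features.

What the synthetic studies show: the statistics are exact, FDR is
controlled, planted structure at study-like effect sizes is recovered, and
the pipeline is deterministic end to end. What they do not show: robustness
to compositional artifacts of relative abundances (the screen is plain
Pearson by design, not CLR/SparCC), to heavy-tailed or structurally missing
real LC-MS intensities, to chimeric or misclassified lineages, or to
incomplete genome annotation in real databases — on real data the empirical
edge class absorbs those gaps rather than the model correcting them.

Problem sizes in the test suite and acceptance studies (100-seed screens of
600 pairs at n = 10; 50 random knowledge bases of ≤ 50 organisms; 100
planted ladders) were chosen so each property is measured with comfortable
Monte-Carlo margins while the whole suite stays interactive.

## Known limitations

* Annotation scoring is a deliberately simple stand-in for full
  evidence-combination annotators: depth-1, two adducts, count score.
* Reaction-pair "primary" status is taken as given by the knowledge-base
  tables; no filtering of cofactor pairs is attempted.
* Temporal classification assumes two time points with matched blanks;
  richer designs need a different rule table.
* The correlation screen treats relative abundances as ordinary covariates;
  compositional effects can induce spurious negative correlations among
  dominant genera.
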