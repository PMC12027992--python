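# Methods

## The model and its assumptions

The package models the inhibition of human DPP III by 36 amidino-substituted
2-aryl benzimidazoles as a linear function of four 2D graph descriptors,

    log10(% inh at 30 µM) = b0 + b1·Rww + b2·Mats3e + b3·BELe4 + b4·nCs,

fitted by ordinary least squares on a 29-compound training set.  The
underlying assumptions are the usual ones for small-set QSAR: the response
is adequately described on the log scale (it spans 0.1–100 %, i.e. −1 to 2
log units), descriptor–activity relationships are approximately linear over
the sampled chemical space, and the 36 compounds are representative of the
benzimidazole-amidine series (the applicability domain makes this
assumption checkable per compound).

## Descriptor conventions

All descriptors are computed on the hydrogen-suppressed molecular graph;
aromatic perception follows RDKit.

* **Distance matrix** — BFS shortest-path edge counts.
* **Detour matrix** — longest simple-path edge counts.  The default
  algorithm decomposes the graph over its biconnected components (any
  simple path crosses the same sequence of cut vertices, so detour
  distances add along the block–cut tree) and enumerates paths only inside
  blocks; a naive whole-graph enumeration is retained as the oracle and the
  two are property-tested for equality.  On acyclic graphs the detour and
  distance matrices coincide.
* **Rww** — the hyper-detour entry for a pair is ½(Δ²+Δ) and Rww sums its
  reciprocal over unordered pairs.  The vendor normalisation of this index
  is not public; this convention is fixed here and isolated so that an
  externally supplied reference descriptor table can calibrate it
  (`reciprocal_hyper_detour` accepts a precomputed Δ, and the constants sit
  in one module).  Supporting evidence for the convention: refitting the
  model on these Rww values reproduces the published Rww coefficient almost
  exactly (+0.058 vs the printed +0.06).
* **Mats3e** — Moran I at lag 3 with carbon-scaled Sanderson
  electronegativities (w_C = 1), the convention used for "e"-weighted
  autocorrelations.  Empty lag classes and zero-variance weights return 0
  by convention.
* **BELe4** — 4th smallest signed eigenvalue (ascending sort) of the Burden
  matrix: diagonal = carbon-scaled Sanderson weight; bonded off-diagonal =
  0.1 × conventional bond order (aromatic 1.5 → 0.15) plus 0.01 when either
  endpoint is terminal; non-bonded = 0.001.  These constants follow the
  original Burden scheme and are configurable (`BurdenConstants`).  All
  packaged compounds give positive BELe4, consistent with the published
  observation.
* **nCs** — non-aromatic carbon, all bonds single, exactly two heavy
  neighbours, both carbon.  In the study set this matches only the C5
  methylene of the tetrahydropyrimidine ring, so nCs = 1 for every group-c
  compound and 0 elsewhere — exactly the published pattern.

One marginal deviation from the published qualitative description: under
these conventions the quinoline derivative b9 has Mats3e = +0.01 (the
source reports all compounds except b13 negative).  b13 remains the clear
positive maximum.

## Packaged data and its reconstruction

The activity table quotes roughly two thirds of the % inhibition values
verbatim; the rest are only described qualitatively ("strong, ≥ 90 %",
"complete inhibition", "approximately 50 %", "reduced by ~90 % vs c2") plus
IC₅₀ values.  The packaged CSV transcribes every quoted number exactly and
reconstructs the remaining twelve from those statements; a provenance
column separates `reported` from `reconstructed` rows.  Consequences:

* band memberships and the ≥50 % group counts (8/12, 8/13, 4/11) are exact;
* the group relative occupancies computed from the packaged table are
  0.60 (a), 0.63 (b), 0.39 (c).  The printed summaries (0.56/0.59/0.36) are
  arithmetically unreachable by *any* table consistent with the quoted
  per-compound values and band definitions — e.g. the quoted group-b
  members alone sum to 385 and the five remaining members are constrained
  to ≥ 90 (four "strong" compounds) and ≈ 50, forcing an occupancy ≥ 0.6.
  The per-compound statements were taken as primary; the ranking
  b > a > c is reproduced either way.

## Model refit vs the published fit

Refitting the four descriptors as computed here gives a training R² of
~0.43–0.65 depending on the split seed (median ≈ 0.5), against the
published 0.82.  Three observations locate the gap:

* the coefficient signs all agree with the published equation, and the Rww
  coefficient agrees numerically, so the descriptor implementations capture
  the same directional structure;
* the published values were produced by a closed-source descriptor engine
  whose exact normalisations are not printed, and the model was selected by
  GA from a 450-descriptor pool — a selection that optimistically biases
  the in-sample fit of the chosen quadruple;
* compound c5 (% inh = 0.1, log = −1) dominates the unexplained variance:
  excluding it raises the full-set R² from 0.45 to 0.64.  c5 is precisely
  the compound the original Williams-plot analysis flags as its outlier.

The applicability-domain findings are reproduced exactly: h\* = 3·5/29 =
0.517, no compound above h\*, and c5 the unique |standardized CV residual| >
2 outlier.  The Y-scrambling means behave as theory predicts for refitted
nulls (mean scrambled R² ≈ p/(n−1) ≈ 0.14, mean scrambled Q² < 0).

## Statistical procedures and numerical choices

* **Splitting** — compounds ranked by log activity, cut into 5 contiguous
  bins (sizes differing by ≤ 1); the test set takes 1–2 per bin, totalling
  round(n/5) (7 of 36), with the double-contributing bins chosen by the
  seeded RNG.  The published 29/7 membership is unpublished, so
  split-dependent statistics are reported across seeds.
* **Q²_LOO** — 1 − PRESS/SS_tot with LOO residuals via the exact hat-matrix
  identity e/(1−h); tested against explicit row-deletion refits.
* **Q²_LMO** — mean over seeded 30 %-exclusion refits (default 1000
  iterations, stable to ±0.01); each iteration scores the excluded rows
  against the full-training mean, which makes the single-row case collapse
  to Q²_LOO exactly.
* **Y-scrambling** — 500 seeded permutations, refit each (the hat matrix is
  reused since X is fixed), means reported.  A correlation-based variant
  (mean r² between original and permuted y) is provided because the
  published scrambled statistics (< 0.02) are below the refit-null
  expectation p/(n−1); which definition the original software reports is
  not documented, so both are available and the refit default is used
  throughout.
* **GA selection** — k-subset chromosomes, tournament selection (size 2),
  uniform membership crossover repaired to size k, per-gene swap mutation
  (p = 0.1), single elitism, Q²_LOO fitness, fully seeded.  For pools with
  C(p, k) ≤ 2000 the exhaustive scan is used outright; the GA is
  property-tested to match it above that size on planted-signal pools.
* **IC₅₀** — 2-parameter log-logistic (asymptotes fixed at 0/100, since %
  inhibition is already normalised) fitted in log-concentration space;
  a 4PL variant frees the asymptotes.  Non-convergence is reported via a
  flag, flat responses are rejected.  At 3 % response noise on a 7-point
  triplicate design the IC₅₀ is recovered within 15 %.
* **Degenerate inputs** — single-atom graphs give Rww = 0; empty Moran lag
  classes and constant weights give 0; BELe_k is undefined (error) below k
  atoms; non-positive % inhibition is excluded from the log transform with
  a warning; rank-deficient designs raise naming the collinearity.

## Synthetic-data generators

`synthdata` emulates (i) the regression geometry (standard-normal X,
planted β, Gaussian noise — defaults mirror the study: n = 29, four
informative descriptors, the published coefficients), (ii) random
valence-legal molecular graphs (uniform random trees with an optional
single ring closure; element alphabet C/N/O/S/F/Cl), and (iii) logistic
dose–response curves with replicate noise.  What they deliberately do not
emulate: real descriptor distributions (packaged-table moments can be used
instead of standard normals if desired), chemistry-realistic structures
beyond valence legality, and heteroscedastic assay noise.  Green synthetic
tests therefore demonstrate estimator correctness, not real-data
performance.

## Design decisions

* Library-first shape: the public surface is the importable API plus the
  narrative scripts in `examples/`; no console entry point is installed,
  since the intended use is from Python.
* Structures as neutral free bases, 5-substituted regioisomer, NH on N1,
  neutral amidine tautomers — one documented convention for the whole set.
  Descriptor sensitivity to the 5- vs 6- drawing can be probed directly by
  parsing the alternative SMILES and recomputing.
* Analogue screening restricts substitution to the carbocyclic positions
  4–7 and reports every (site, substituent) proposal with its leverage and
  in-domain flag; nothing is suppressed.

## Known limitations

* Rww/BELe4 normalisations are package conventions, not a byte-level
  reproduction of the original descriptor engine; absolute predictions of
  the published coefficients on these descriptors are therefore on a
  different scale, and the refit coefficients should be used for new
  predictions.
* Twelve packaged activities are reconstructed (flagged); statistics that
  sum over groups inherit that uncertainty, bounded by the band
  constraints.
* The detour computation is exact but exponential in block size; it is
  limited (configurably) to 64 heavy atoms and is intended for drug-sized
  molecules.
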