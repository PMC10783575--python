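# Methods

## Quantification model

Reporter intensities are treated as relative abundances on a multiplicative
scale; all statistics operate on `log2` intensities.  An intensity of exactly
0 means "not observed" and becomes missing — it is never imputed and never
treated as zero abundance.  A feature needs at least `min_per_group` (default
2) finite values in each group to be tested; below that it is flagged
`insufficient_replicates` and carried through reporting but excluded from
statistics.

Channel normalization defaults to per-channel median-centering in log2 space
(every channel's median is shifted to the grand median of channel medians).
This removes TMT loading differences that would otherwise masquerade as
effects; `none` is available to reproduce analyses that used raw log2 ratios.
Median centering is exactly invariant to a uniform rescaling of all
intensities and removes a per-channel multiplicative artifact exactly.

The group effect is the **difference of group means of log2 intensities**
(not the log2 of mean intensities).  The distinction matters with noise; the
difference-of-means form is the one consistent with per-channel log
transformation and is the module's single documented definition.

## The joint statistic

For tested features, with `e` the log2 effect:

* `p_t`: two-sided unpaired t-test on the per-channel log2 intensities.
  Pooled variance is the default; Welch is available (`equal_var=False`).
  Degenerate inputs follow explicit conventions: zero variance in both groups
  with equal means → `p_t = 1`; with unequal means → `p_t = 0` (logged).
* `σ_global`: the sample SD (ddof = 1) of `e` over all tested features of the
  same table, computed separately for the phosphosite and the protein tables.
* `Z = e / σ_global`; the Gaussian tail `1 − Φ(|Z|)` is computed via the
  complementary error function and is accurate beyond |Z| = 30.
* `p_joint = p_t · (1 − Φ(|Z|))`.

No multiple-testing correction is applied; the stringent raw threshold
`α = 0.0005` plays that role.  By construction `p_joint ≤ min(p_t, tail)`,
the tail equals 0.5 exactly at Z = 0, and negating every effect leaves all
`p_joint` values unchanged while swapping the up/down classification.

**Calibration caveat.**  `p_joint` is a *ranking* statistic, not a calibrated
p-value.  Under an all-null simulation the standardized effect is ~N(0,1), so
the tail factor alone satisfies P(tail < u) = 2u, and the product with the
(positively correlated) t-test p-value crosses 5·10⁻⁴ for roughly 3% of null
sites — about 60× the nominal α.  (Even for two *independent* uniform
p-values, P(product < α) = α(1 − ln α) > α.)  The acceptance suite measures
this honestly; interpret the threshold as a selectivity dial, and rely on the
effect-size and motif criteria — which in simulation hold the realized
false-discovery proportion of *direct calls* near zero — rather than on the
nominal α for error control.

**Ordering of exclusion and σ.**  By default σ_global is computed over all
tested phosphosites and the protein-change exclusion applies only to
classification; `exclude_before_sigma=True` computes σ after removing sites
on significantly changed proteins.  The two differ negligibly when few
proteins change, but the choice is explicit because the definition of "all
log2(KO/Control) values" is ambiguous in practice.

## Classification and exclusion

Statuses partition the input sites: `up`, `down`, `not_significant`,
`excluded_protein_change` (parent protein has protein-level
`p_joint < α`), and `insufficient_replicates`.  A site whose accession is
absent from the protein table is *not* excluded (logged).  Excluded and
under-quantified sites are ineligible for direct-target calls.

## Direct-target criteria and comparison modes

`strict` mode (default, for full-precision pipeline output) requires
`p_joint < α` and `e < −t` with `t = 0.3`.  `table_replication` mode exists
for replaying *printed* tables whose values are rounded to four decimals: it
uses `p_joint ≤ α` and `|e| > t` with `e < 0`.  The `≤` admits rows whose
printed p equals the threshold exactly (a printed `0.0005` stands for a value
below it before rounding), while the strict `>` on |effect| keeps a printed
`0.275` out and a `0.31` in — together these reproduce the published
catalog's membership without loosening the underlying criteria.

## Position-specific motif enrichment

Per (relative position, residue) a 2×2 chi-square (1 df, no Yates correction)
compares foreground vs background counts; `enriched` requires
`p < 0.001` *and* foreground frequency above background.  Padded (`_`)
positions contribute to neither count.  Against a residue-frequency model
(rather than a background sequence set) a 1-df goodness-of-fit chi-square is
used.  Pooled residue classes ({R,K}, {D,E}) can be tested the same way.  The
natural background is the full set of quantified sites — "preference among
regulated sites" — with uniform and user-frequency models available.  The
per-cell 2×2 formulation matches logo-style displays; a signed-log2-fold
matrix is emitted for external logo rendering.

## Synthetic data

The generator emulates the study design: 5 KO vs 3 control channels,
log-normal noise (Gaussian in log2, default SD 0.25 — the study reports no
within-group variance, so this is a free parameter chosen as a typical TMT
between-replicate spread), base intensity 2²⁰, ~1% direct sites at −0.8 log2,
~2% proline-directed up-sites at +0.8, and ~3% of proteins with a +0.5 log2
total-abundance shift that propagates into their phosphosites.  Direct-site
sequences get R/K at −3 and D/E at +2 imposed; indirect sites get P at +1;
backgrounds are uniform over the 20 amino acids (configurable residue
frequencies), center S:T at 4:1.  Protein-level shifts are planted only on
proteins hosting no planted site, so each ground-truth class has a single
meaning (a "direct" site is always one the pipeline *should* recover; the
shifted proteins exist to exercise the exclusion rule).

A single root `SeedSequence` is split into independent streams for class
assignment, sequences, site noise and protein noise: identical config + seed
gives byte-identical tables, and enlarging one dimension does not reshuffle
the others.

What the generator does **not** emulate: peptide-level identification,
missingness mechanisms beyond intensity zero, TMT isotopic impurity
(assumed corrected upstream), correlated noise across sites of one protein,
and the real mouse-proteome residue composition.  Passing recovery tests
therefore demonstrate statistical correctness of the pipeline, not expected
sensitivity on real data.

## Problem sizes and numerics

The test and acceptance analyses use 1,000–20,000 simulated sites — large
enough for stable empirical fractions (20,000 null sites give a binomial SE
of ~0.1% on the null-calibration fraction) while keeping a full run in
seconds.  The t-test is vectorized over features; tolerance choices:
pipeline-vs-oracle agreement is asserted at 1e−8 per site (the oracle uses
closed-form pooled t and quadrature of the normal density), and the Gaussian
tail is asserted against quadrature at 1e−7.

## Known limitations

* `p_joint`'s null calibration (above) — thresholds are selectivity dials.
* Monophosphosite collapsing from search-engine output is delegated to the
  MaxQuant import adapter's column choice (`___1` multiplicity columns); the
  pipeline itself assumes one row per monophosphosite.
* No empirical-Bayes variance moderation; with 2–5 replicates per group the
  t-test variance estimates are noisy, which the global-Z factor only partly
  offsets.
* Annotation-based reports (kinase/phosphatase subsets, term enrichment) use
  user-supplied gene lists; no database is bundled, so results depend on the
  supplied annotation's coverage.
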