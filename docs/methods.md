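# Methods

## Natural-abundance correction

Only carbon isotopes are corrected.  The instruments this workflow targets
resolve isotopologues at unit mass, where the dominant interference for
organic acids and amino acids is natural ¹³C; multi-element
(H/N/O/S/Si) correction would require resolution-dependent bookkeeping
that unit-mass data cannot support.  The forward smearing matrix for an
n-carbon metabolite is therefore exactly binomial: a molecule with j
tracer-labelled carbons appears at m+i with probability
C(n−j, i−j)·p^(i−j)·(1−p)^(n−j−(i−j)).  Parameters:

- `p13c` — natural ¹³C abundance, default 0.0107 (the IUPAC representative
  value; the exact terrestrial value varies in the 4th decimal and the
  choice is configurable).
- `tracer_purity` — isotopic enrichment of the labelled substrate,
  default 1.0.  When < 1 a second binomial over the j labelled positions
  is composed into the matrix.  Commercial U-¹³C substrates are ≥ 99 %
  enriched, so the default ignores purity.
- `nonneg` — default on.  The exact linear solve is used first; if it
  returns fractions below −10⁻¹⁰ (relative), the solve is repeated with a
  non-negative least-squares constraint.  Noisy, low-abundance m+1/m+2
  channels otherwise routinely produce small negative fractions that
  violate the MID invariants.  Results are always renormalised to sum 1.

Missing isotopologue rows are zero-filled with a warning rather than
rejected: sparse detection at low abundance is routine in primary-cell
LC-MS, and rejecting the whole metabolite would bias analyses toward
abundant species.

## Labelling statistics

- Fractional enrichment is Σ_{i≥2} m_i, applied uniformly — including to
  2-carbon glycine, where it reduces to the fully-labelled fraction.  The
  any-label companion 1 − m₀ is exposed (`labelled_fraction`) for
  sensitivity checks, since m+1 is dominated by residual natural abundance
  and single-carbon exchange.
- The PC/PDH ratio m+3/m+2 is computed for malate, citrate and aspartate.
  A zero m+2 denominator yields NaN ("undefined"), never 0 or infinity;
  downstream paired tests drop undefined pairs and report the count.  The
  degenerate case does not arise in realistically labelled data, but the
  explicit flag keeps it from silently poisoning fold changes.
- Carbon-pool contribution weights each isotopologue by the share of
  carbons it labels, Σ_i (i/n)·m_i.  Contributions from the three tracers
  are merged at the condition level (the tracers are parallel cultures,
  never the same physical sample); per-patient merging is available when
  pair ids align.  If the tracer sum exceeds 1 — possible through
  cross-talk and noise, and expected when a high palmitate concentration
  suppresses apparent glucose contribution — the unassigned remainder is
  clamped to 0 and the overshoot surfaced in an `excess` QC column rather
  than hidden.

## Differential testing

Two-sided t-tests on log₁₀-transformed values, paired within patient for
control/treated designs, unpaired for disease/normal comparisons.
Non-positive or missing values are dropped (pairwise in paired mode) with
counts reported; metabolites with fewer than two complete pairs are
excluded from the FDR family with a warning.

Zero-variance degenerate cases are resolved explicitly: identically zero
paired differences give p = 1; identical nonzero differences (t
undefined) give the exact two-sided sign-test bound p = 2^(1−n), flagged
`degenerate` — the most conservative exact p-value consistent with n
same-direction observations.  Constant unpaired arms use the analogous
exhaustive-permutation bound 2/C(n₁+n₂, n₁).

Multiple testing uses the two-stage step-up adaptive FDR at Q = 0.10
(configurable): stage 1 is a linear step-up at q′ = Q/(1+Q); with
0 < r₁ < m rejections the null count is estimated as m₀ = m − r₁ and
stage 2 reruns the step-up with m₀ in the denominator.  Per-test q-values
hold m₀ fixed and invert the stage-2 threshold: with the step-up
transform c_i = min_{j≥i} m₀·p_(j)/j, q_i = c_i/(1−c_i) capped at 1, so
"rejected at level Q" and "q ≤ Q" coincide and q-values are monotone in
p.  This matches the q-value semantics under which volcano tiers
(q < 0.05 strong, q < 0.1 weak) are read.  Note the adaptive procedure is
guaranteed at least as powerful as the plain step-up at its working level
q′ (stage 1), not at Q itself: when few tests reject, the 1/(1+Q)
shrinkage can outweigh the adaptivity gain.  The test suite asserts the
true superset property and cross-checks rejection sets against both a
brute-force scan of the definition and an independent library
implementation.  A plain Benjamini–Hochberg step-up is also exposed and
is the default for the steady-state analysis, matching the correction
historically used for total-pool comparisons.

## Steady-state preprocessing

Per batch, every sample is divided by the batch's first-acquired sample
(acquisition order must be explicit in metadata — it is never inferred
from file order); the variance-stabilising transform is the generalised
log, glog(x) = log₂((x + √(x² + λ²))/2), with λ the minimum positive
value of the matrix.  λ is a data-driven pseudo-count standing in for a
regularised-log transform whose shrinkage parameter is not identifiable
from the published description; it is recorded in the run log, and a
per-metabolite λ mode is exposed as a configuration knob since either
convention exists in the wild.  Columns are then mean-centred, and for
multi-batch dose-series designs each batch is centred on its own no-drug
controls, which removes additive batch offsets exactly (verified by
inject-and-recover tests).  Effect sizes reported from this pipeline are
post-transform mean differences rescaled by log₁₀2, exact as log₁₀ fold
changes for abundances well above λ.

## The simulator

A single-turn model of TCA labelling: ¹³C₆ glucose labels a fraction
`g_label` of pyruvate at m+3; acetyl-CoA is m+2 with probability
`f_pdh·g_label` (or `f_fao` under the palmitate tracer); oxaloacetate is
m+3 with probability `f_pc·g_label`; citrate is the convolution of the
two moieties, so its m+5 class exists only when PC-m+3 and PDH-m+2
condense — ablating PC (f_pc = 0) zeroes citrate m+3 and m+5 exactly.
Each decarboxylation removes one uniformly chosen carbon (from m+k the
product is m+(k−1) with probability k/n), deliberately agnostic to
positional (isotopomer) information the analysis never uses.  The
malate/aspartate pool mixes fresh PC-derived oxaloacetate (weight f_pc)
with oxidatively derived carbon (1 − f_pc), preserving m+3 ≈ f_pc·g_label
as the PC readout; glutamate is AKG diluted by an unlabelled-exchange
fraction `d_exch`; under the glutamine tracer AKG is seeded m+5 with
probability `f_gln` and the label runs one turn forward into
malate/aspartate and citrate.

No multi-turn recycling is modelled: the interpretive identities the
analysis relies on (m+2 = PDH, m+3 = PC, m+5 = condensation) are
first-turn statements, and the single-turn closure keeps every statistic
available in closed form for exact verification.  Kinetics, positional
isotopomers and peak shapes are out of scope.

Default scenario (`FluxScenario()`): g_label 0.7, f_pdh 0.55, f_fao 0.25,
f_pc 0.25, f_gln 0.6, d_exch 0.2, measurement CV 0.10 — an actively
glucose-oxidising progenitor-like state after 24 h in 11 mM U-¹³C glucose
medium, with a visible but minority anaplerotic flux.  The default
treated-arm effect multiplies f_pdh by 0.6 and g_label by 0.8 with f_pc
unchanged, emulating a kinase-inhibitor response that suppresses
oxidative glucose entry but spares anaplerosis.  Cohorts draw
subject-level log-normal jitter (CV 0.15) of all fractions, apply the
effect within subject (paired design, default 4 pairs), and emit matched
cell counts (controls ≈ quadruple in 48 h, treated slower) and
spent-medium concentrations whose glucose/glutamine consumption scales
with the subject's g_label and f_gln.  All randomness descends from one
seed through named substreams; regeneration is bit-identical.

What passing simulator-anchored tests does and does not show: the
generator reproduces the *structure* of real tracing data (condensation
mass classes, natural-abundance smearing, multiplicative noise, pairing,
batch assignment) but not chromatographic artefacts, missingness
correlated with abundance, heavy-tailed patient heterogeneity, or
multi-turn label scrambling — so green tests certify the arithmetic and
inferential machinery, not instrument-level robustness.

## Exchange rates and growth

Exchange rate per cell per 48 h is (amount_spent − amount_cellfree) /
mean(cells_d0, cells_d2), positive for secretion.  The published form of
this quantity is ambiguous between concentration and amount; the package
converts concentrations to amounts with the culture volume (default
1 mL) before normalising.  The growth read-out is emitted in two forms:
the assay-idiosyncratic 4·seeding/density ("fold of quadruple", 1.0 for a
culture that quadruples) exactly as conventionally computed, and standard
doublings log₂(density/seeding), because the former is self-contradictory
as described at source and downstream users need an unambiguous quantity.

## Numerical choices and verification scales

Correction solves are exact triangular systems (condition number ~1 for
p ≈ 0.01); round-trip error is < 10⁻¹⁵ against the matrix-product
oracle, tested at 10⁻⁶ over 500 random MIDs.  Closed-form flux recovery
through the full observe → correct → enrich path is tested at 10⁻⁹ over
a 5×5×5 grid of (f_pc, f_pdh, g_label).  FDR calibration uses 500
fully-null replicates of 2000 paired tests (n = 4 pairs of log-normal
values, where the log-t is exact); the treatment-signature power check
uses 100 cohorts of 8 pairs at 5 % measurement CV.  These problem sizes
keep the whole suite and the acceptance script each under a minute on a
single core while leaving Monte-Carlo error well inside the asserted
margins.

## Known limitations

- Carbon-only correction; not suitable for Si-derivatised GC-MS data.
- Single-turn ground truth: real multi-turn labelling inflates m+1/m+2
  classes in ways the simulator does not emulate.
- The PC/PDH ratio inherits the usual caveat that cytosolic malic-enzyme
  activity can also produce m+3 TCA metabolites; the package computes the
  readout and leaves that interpretive control (e.g. mitochondrial
  pyruvate carrier inhibition) to the experiment.
- `mode` covers paired and unpaired two-condition designs; multi-level
  dose series should be analysed condition-pair-wise or with external
  ANOVA tooling.
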