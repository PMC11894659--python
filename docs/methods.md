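# Methods

## The validation model

The protocol rests on three premises. First, quality filtering on the
full-search top score can enrich spectra whose correct peptide is present in
the search space (identifiable spectra), because unidentifiable spectra draw
their top score from the null of best-of-|Ω| random matches, which is
stochastically below the correct-match score distribution of identifiable
spectra. Second, when the search space is split at random into k disjoint
subsets, a spectrum whose correct peptide is *not* in the selected subset γ
receives a genuinely incorrect best match from γ, so the subset search
manufactures incorrect PSMs whose scores follow the true null. Third, a
subset top hit that coincides with the full-search top hit of a
quality-filtered spectrum is correct with high probability. Labels follow:
*correct* iff subset top = full top. The proxy FDP computed from these
labels estimates the FDP of the subset-search results, and its agreement
with the FDR estimates under evaluation (TDC, Storey variants) is the
validation readout.

The one systematic error mode is an unidentifiable spectrum that survives
filtering: its full top candidate lands in γ with probability ≈ 1/k, in
which case the subset top equals the full top and the PSM is mislabeled
correct. pFDP therefore *underestimates* FDP at permissive QF thresholds,
and the discrepancy decays as the threshold rises — the behavior the
convergence test measures. At the other end, an over-stringent threshold
leaves too few spectra for stable curves; a floor of 1000 labeled PSMs
(`min_retained_psms`) separates the two regimes, and curves below it are
drawn dashed rather than dropped.

## Estimators

* TDC: FDR(x) = (N_D(x) + 1)/N_T(x), counts with ≥, clipped to [0, 1]; the
  +1 gives the corrected (non-anti-conservative) estimator. q-values are the
  running minimum over thresholds at or below a PSM's score, so acceptance
  sets nest. Inside the pipeline, each (score-adjusted) subset target
  competes per spectrum with its decoy before counting — the concatenated
  search semantics; losers get q = 1.
* Decoy p-values: p(x) = (n_D(x) + 1)/(N_D + 1), guaranteed in (0, 1] and
  super-uniform under the null.
* Storey q-values: π₀ = #{p > λ}/((1 − λ)m) at λ = 0.5 by default (a
  spline-smoother variant is provided), capped into (0, 1]; q is the usual
  min-scan. With π₀ = 1 the output is exactly Benjamini–Hochberg, which the
  tests verify against statsmodels.
* Šidák: p′ = 1 − (1 − p)^n for best-of-n candidate tests, computed via
  expm1/log1p for small p.
* TEV(e) = a·ln(e/N₀) with a = −0.02, N₀ = 1000: strictly decreasing,
  log-linear in e, and chosen so that typical engine e-values land in the
  score range where the tabulated empirical nulls are defined.
* Tabulated empirical null: right-tail probabilities interpolated linearly
  between knots; out-of-range scores clamp (to 1 below, to the smallest
  tabulated tail above) with a warning. The table is consumed, never re-fit.

## Subset-size score adjustment

A subset search sees |Ω|/k candidates, which moves the null of
space-dependent scores. Two distinct conversions are exposed through
`score_kind`, and they are *not* the same map:

* `e_value` (×k): an e-value reported by a search over the subset counts
  k-fold fewer candidates; multiplying by k restores the full-space
  per-match expectation. This is the per-match significance conversion
  appropriate when the subset search recomputes e-values against its own
  space (presearch re-search).
* `tev` / `gumbel` (+|a|·ln k resp. +β·ln k): the best incorrect match over
  m i.i.d. Gumbel(μ₀, β) candidate scores is Gumbel(μ₀ + β·ln m, β), so a
  k-fold smaller space lowers the top-hit null by exactly β·ln k. Adding it
  back matches the subset top-hit null to full-space references (decoy score
  sets, tabulated nulls built from full searches) — the right conversion in
  postsearch mode, where candidate scores are inherited from the full
  search. Under the simulator this identity is exact, which makes the
  adjustment test sharp.

`space_independent` scores (dot products and similar) pass through
unchanged.

## Simulator

`simulate()` emulates a database search without modeling spectra: Ω is a
set of random 8–15-mer peptides; each spectrum's incorrect candidate scores
are i.i.d. Gumbel(μ₀, β) of which only the top-N order statistics are
generated (exactly, via the Rényi exponential-spacing representation, so
cost is independent of |Ω|); identifiable spectra add a correct score from a
configurable model that competes for rank 1; unidentifiable spectra are
"foreign", their true peptide kept outside Ω by construction (longer
sequences). The optional decoy channel draws an independent best-of-|Ω|
Gumbel per spectrum — exchangeable with the incorrect-target best, the TDC
assumption, exactly. Derived e-values follow the per-candidate null, so
TEV-based paths can be exercised.

Default conditions (the "separated" fixture): 20,000 spectra, |Ω| = 10,000,
top-N = 10, 85% identifiable, correct scores Normal(16, 2) against
Gumbel(0, 1) candidate nulls. The best-of-10⁴ null then sits near 9.2 ± 1.3
while correct matches sit near 16, giving a clear but overlapping
separation: QF thresholds below ~12 admit measurable mislabeling,
thresholds of 12 and above (≈3 null scale units past the null top location)
essentially eliminate it — so a QF grid spanning 10–20.5 exhibits the full
phenomenology (biased labels → converged labels → starved subset search) in
one scan. Sample sizes in tests and the acceptance script (20k spectra ×
3 seeds for convergence, 50 × 3k for coverage, 10⁵ for the exclusion law)
were chosen to keep Monte-Carlo error well inside the asserted tolerances.

What the simulator does *not* capture: fragmentation and spectral detail,
score correlations between candidates of the same spectrum, imperfect decoy
construction, chimeric spectra, and engine-specific score pathologies.
Passing tests therefore establish the protocol's statistical correctness
under its own assumptions, not the behavior of any particular engine on
real data.

## Numerical and design choices

* Scores are oriented internally to higher-is-better by negation of
  declared lower-is-better scores; every comparison (QF, validation
  thresholds, estimator counts) uses ≥.
* Partition sizes differ by at most 1, remainder to the lowest-indexed
  subsets after a seeded shuffle; peptides are sorted before shuffling so
  the result is independent of set iteration order. The selected subset
  defaults to index 0 (uniform over contents after the shuffle) and is
  overridable.
* Subset-scan ties cannot arise in postsearch mode (ranks are unique); in
  presearch re-scoring, equal scores go to the lexicographically smaller
  peptide, for determinism.
* Peptide-level rollup keeps the best-scoring PSM per peptide, ties broken
  by smaller spectrum id.
* Peptide equality across engines strips modification annotations by
  default (`keep_modifications` flips this), since engines annotate
  modifications heterogeneously.
* Bootstrap bands are percentile bands (16th/84th) over B ≥ 100 resamples
  of the labeled PSMs, the symmetric realization of a 68% pointwise
  interval; grid points with empty acceptance in more than half the
  resamples are masked. Observed coverage of the true FDP runs slightly
  above nominal because the point estimate and the truth share the accepted
  set's sampling noise.
* The "most stable" QF threshold minimizes the mean band width among curves
  retaining at least `min_retained_psms` labeled PSMs; ties take the larger
  threshold.
* The KS diagnostic (two-sample, two-sided, asymptotic p) compares
  partition-labeled incorrect scores with a reference null sample. With
  labels of perfect provenance (simulation) the paired comparison within a
  scan measures label bias, while comparison against a large independent
  null sample measures small-sample instability at over-stringent
  thresholds; the diagnostic falls then rises across a QF scan.
* FDR grid default: 50 log-spaced thresholds in [0.001, 0.5]; QF grid
  default: deciles 0.5–0.99 of the rank-1 score distribution, both
  overridable in the TOML configuration.
* Degenerate inputs: empty acceptance returns NaN with a warning (pFDP) or
  skips the grid point (curves); a QF threshold retaining zero spectra
  warns and yields an empty table rather than an error.

## Limitations

Presearch mode with a real engine requires the user to run the subset
search out-of-band (the CLI writes partitioned FASTA files) and feed the
results back as canonical TSV; the built-in re-scorer only restricts an
existing deeper candidate list. Protein-level FDR, posterior error
probabilities, chimeric spectra and semi-supervised rescoring are out of
scope. The intersection protocol's precursor-shift re-search is likewise
consumed, not executed.
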