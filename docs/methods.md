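# Methods

## The kinetic model

Reverse transcription of each transcript is modelled as rate-limited by
hybridization of its gene-specific reverse primer, a second-order reaction
between primer and template. Because every attenuated primer (final
concentrations 2.5×10⁻¹¹ – 5×10⁻⁸ M after diluting the 0.00025–0.5 μM
stocks 1:10 into the reaction) is in large excess over its transcript
(average single-gene mRNA ≈ 7×10⁻¹⁵ M in 20 ng of total RNA), the primer
concentration is treated as constant and the template obeys the pseudo
first-order empirical law `-d[RNA]/dt = k'·[RNA]^n` with
`k' = k·[Primer]`. Closed forms: exponential decay for `n = 1`, the
power-law solution `(k't(n−1) + [RNA]₀^(1−n))^(1/(1−n))` otherwise. For
`n < 1` the closed form reaches zero in finite time; the implementation
clamps at zero (template exhaustion) rather than raising, and also clamps
above at `[RNA]₀` so mass conservation
`[RNA] + [cDNA¹ˢᵗ] = [RNA]₀` holds exactly.

PCR multiplies the first strand by `α = (1 + e)^(c−1)` with per-cycle
efficiency `e ∈ (0,1]`; `e = 1` gives the theoretical bound `2^(c−1)`
(the first cycle only makes the second strand). Primer pools are never
decremented — the excess argument above — and no plateau phase is
modelled; the model targets the calibration-relevant regime, not end-point
PCR yield.

Units: concentrations in molar, time in whatever unit makes `k'·t`
dimensionless. Nothing depends on the absolute time unit. The
per-nucleotide molar mass in the average-transcript estimate defaults to
340 g/mol (330 g/mol shifts the average concentration from 6.9×10⁻¹⁵ to
7.1×10⁻¹⁵ M); it is an explicit parameter.

### Reaction orders below one and scale

The power law with `n ≠ 1` is not scale-invariant: the dimensionless
conversion driver is `k'·t·(1−n)·[RNA]₀^(n−1)`. At femtomolar template
concentrations this quantity is enormous for any appreciable `k'·t`, the
template is exhausted, and the dilution response collapses back to slope 1.
The empirically observed regime — parallel log–log lines of common slope
below 1 — is the *partial-conversion* regime. Two consequences for this
package:

* the parallel-lines property (slopes of all genes equal regardless of
  per-gene `k'`) is exact only in the low-conversion limit; the slope of a
  gene deviates from `n` by roughly `0.4 × conversion` at `n = 0.8`, so
  tests of the 10⁻⁶-level parallelism use `k'·t` small enough that
  conversion is ≲ 10⁻⁵;
* the synthetic generator, when asked for `n ≠ 1`, rescales concentrations
  to dimensionless relative units and maps the attenuation range onto
  `k'·t ∈ [0.0025, 0.05]` (parameter `kt_max = 0.05`, 20-fold spread), so
  every gene stays partially converted across the whole 128-fold dilution
  range. For `n = 1` the generator works directly in molar units with
  `k'` from the primer concentrations; attenuation then acts through the
  saturating factor `1 − exp(−k't)`.

## Calibration

First regression per gene: OLS of `log₁₀ F` on `log₁₀ [RNA]_tot`,
implemented by the covariance/variance closed form, with R² reported.
Points with non-positive or below-floor NPA are excluded (log domain).
The common slope `ā` is the **unweighted arithmetic mean** of the per-gene
slopes — no R² weighting, since no principled weights are available — and
each gene's shared-slope intercept is the closed form
`b_{i,ā} = mean(log F) − ā·mean(log R)`, which minimizes that gene's
residual sum of squares at the fixed slope (verified against grid search
in the tests). The spike-in gene is excluded from the slope average: its
NPA is identically 1 and carries no calibration information.

Replicates: by default every replicate point enters the fit individually
(`replicate_mode="points"`); a `"means"` mode averages NPAs per
concentration before taking logs. The mode used is recorded in the model
file. Logarithms are base 10 throughout.

Detection limits: the instrument's peak-calling floor is not observable
downstream, so the limit is a policy. Default: a configurable minimum
trustworthy peak area (50 fluorescence-area units) divided by the run's
spike-in area, giving a per-run NPA floor; alternatively a fixed NPA floor.
The floor maps through each gene's calibration line,
`limit = 10^((log₁₀ floor − b_{i,ā})/ā)`, so doubling the floor multiplies
every limit by `2^(1/ā)`. Measurements at or below the floor are flagged
and reported *as the limit value*, never as zero. The policy in force is
serialized with the model.

Model files are TSV with a structured `#` header (mean slope, replicate
mode, floor policy, provenance including input checksums) so a
kit-specific standard curve can be stored and reused; serialization is
bit-exact round-trip.

## Fragment tables and normalization

The canonical dialect is a header + tab-separated table with columns
`fragment_index, length_nt, peak_height, peak_area`; a dialect mapping
renames alternative headers. Rows failing numeric parsing or carrying
negative areas are rejected with the line number logged. Peaks are
assigned to panel genes by nearest sized length within a tolerance
(default 2.0 nt — ladder sizing is fractional, so integer equality would
be wrong); the tolerance must stay below half the minimum spacing of
expected lengths, which makes assignment unambiguous and independent of
row order. Equidistant candidates resolve toward the larger peak area
(peak-splitting artifact), logged. NPA is the peak area divided by the
spike-in area of the same run; genes without a matched fragment are
carried as below-floor with missing NPA, so log-domain code never sees
zeros.

## Quality control

*Mixing linearity* fits NPA against the mixing fraction of two RNA pools
on linear axes; the slope sign classifies regulation direction and a
near-zero R² marks genes with no abundance difference between the pools
(a flat response is reported with R² = 0).

*Replicate concordance* histograms `log₂(value₁/value₂)` over pairs of
independent measurements, excluding any pair with a value below the
detection limit. Bins are 0.2 log₂ units wide, centred on multiples of the
bin width; the distribution is shifted so the most populated bin centres at
zero (ties break toward zero shift), absorbing global between-run scale
effects. Fractions use inclusive boundaries: within two-fold means
|log₂| ≤ 1, beyond four-fold |log₂| ≥ 2. Because it is unstated whether
such fractions should be computed before or after centering, both are
reported (`frac_*` centered, `raw_frac_*` uncentered).

*Max-normalization* rescales a per-gene time series to its maximal
quantifiable value for comparative display, carrying below-limit entries
as flagged missing values rather than zeros.

## Synthetic data

The generator emulates the statistical structure the method assumes: peak
areas are the kinetic model's amplified amounts times a detector gain,
a per-run uniform scale factor (0.8–1.25; injection/pipetting variation
that spike-in normalization must cancel), and multiplicative lognormal
noise (σ of the natural log, default 0.05 ≈ 5% CV); sized lengths get
Gaussian jitter (σ = 0.3 nt); the spike-in area is constant before noise;
peaks below a detection area (10 units) are absent from the table, as an
uncalled peak would be. Defaults mirror a realistic assay: 35 genes plus
one spike-in, distinct fragment lengths across 114–357 nt, primer stocks
log-uniform over 0.00025–0.5 μM, transcript abundances log-uniform over
two orders of magnitude around 10⁻¹⁴ M, an 8-point two-fold dilution
series from 100 ng to 0.78 ng measured in duplicate, and up-/down-/
non-regulated genes (30%/30%/40%, four-fold changes) for mixing and
time-series designs. The replicate time-series generator draws two
lognormal measurements per sample around a shared true trajectory
(default σ = 0.7 log₂ units, 26 cells × 5 time points).

What the generator does **not** emulate: electropherogram traces, ladder
mis-sizing beyond Gaussian jitter, PCR plateau/competition effects,
carry-over contamination, or biologically structured co-regulation.
Passing tests therefore demonstrate the correctness of the calibration
and QC machinery under the method's own statistical assumptions, not the
behaviour of any particular real dataset.

## Numerical and statistical choices

* Power-law branch continuous at `n → 1` (verified to 10⁻⁴ at
  `n = 1 ± 10⁻⁶`); results clamped to `[0, [RNA]₀]`.
* Degenerate fits (fewer than two distinct abscissae) raise rather than
  return NaNs; model building fails loudly listing unfittable genes so the
  caller drops them explicitly.
* Under the default noise condition (σ = 0.05) a quantified dilution
  level's estimate carries an irreducible ≈4% standard deviation from the
  spike-in normalization (noise shared by all genes of a run, two runs per
  level); end-to-end recovery is therefore summarized as the RMS relative
  error across levels rather than a pointwise maximum, which would be an
  extreme-value statistic of that noise floor.
* Simulation sizes in the test suite (35 genes, 16 runs, 4000 concordance
  pairs) are the assay's own natural scale; the whole suite runs in a few
  seconds.

## Known limitations

The method yields *relative* amounts only; no absolute copy numbers. The
reaction order `n` is reported descriptively through the fitted common
slope, not estimated by fitting the power-law model. The detection-limit
policy is a documented substitute for instrument-specific behaviour.
The `.ceqfrag` byte layout of the original instrument software is
proprietary; the canonical dialect reconstructs its documented fields
(index, length, height, area) as plain TSV.
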