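# Methods

## Charge model

Residues are classified at physiological-pH convention: K and R positive,
D and E negative, everything else neutral. Histidine is neutral (its side
chain is mostly unprotonated at pH 7.4); phosphomimetics and pH-dependent
protonation are out of scope. Ambiguity codes (B, J, O, U, X, Z) are accepted
by default and treated as neutral, non-F, non-G residues; a strict mode
rejects them.

## LCR definition and span convention

A like-charge region is a maximal run of same-sign charged residues. Two
span conventions exist in the field's informal usage:

1. **first-to-last charge (default)** — the LCR spans from its first to its
   last same-sign charged residue, inclusive. Neutral residues between the
   run's last charge and the next opposite charge are not part of the LCR.
2. **extend-to-opposite** (`extend_to_opposite=True`) — the span continues
   up to the residue immediately before the next opposite-sign charge (or
   the sequence terminus).

The default reproduces the canonical worked example (positive LCR of length
8 / charge count 4 followed by a negative LCR of length 7 / charge count 3
on `KAKGSKTKGDNADQSDP`). The switch is provided for comparability but the
two conventions must never be mixed within one analysis; every dataset-level
routine takes the convention as a single parameter.

Length-1 and length-2 LCRs are always produced by the scanner so that
conservation invariants hold (summed charge counts per sign equal the
sequence's charge totals); they are removed only by explicit filtering. The
inclusion rule used by all dataset statistics is *strictly greater than* a
minimum length, default 2 — i.e., lengths ≥ 3 are kept.

## Per-protein metrics

- **FG-motif density**: exact `FG` dipeptide occurrences per residue. FG
  cannot self-overlap, so a substring count is exact. FxFG/GLFG variants are
  not counted separately; the selection filter is stated purely as FG/AA.
- **FG-Nup candidacy**: disorder fraction > 0.30 AND FG density > 0.15,
  both strict, mirroring the ">" filters used to assemble FG-Nup datasets.
  The disorder fraction is the union of merged disordered-region annotations
  divided by the full-protein length when full sequences are supplied
  (otherwise the analyzed record's own length is the denominator).
- **LCR-covered percentage**: 100 × (summed lengths of sign-matching LCRs
  passing the min-length filter) / sequence length. Non-increasing in the
  minimum length; positive + negative coverage ≤ 100% at min length 1
  because spans are disjoint.
- **Ranked LCRs**: per sign, sorted by length descending with ties broken by
  earlier start (the literature is silent on ties; the tie-break makes
  output deterministic). Rank gaps and ratios are absent (None) rather than
  errors when a protein has fewer than 2 or 3 LCRs of the sign.
- **lpLCR**: two explicit modes, because no single formal definition exists.
  DETECT returns the longest positive LCR only if it reaches a length
  threshold (default 200 residues, the empirical boundary above which
  longest LCRs are essentially absent from generic disordered material) and
  optionally stays below a charge-content ceiling. LONGEST returns the
  per-protein longest positive LCR unconditionally — the unit removed in
  exclusion re-analyses and ranked in rank-gap statistics. The 200-residue
  boundary is a parameter, never hard-coded into conclusions.

## Dataset statistics

Boxplot statistics follow the Tukey convention: quartiles by linear
interpolation (numpy's default; the method name is recorded in comparison
output), whiskers at the most extreme observations within 1.5·IQR of the
quartiles, outliers beyond. Standard deviation is the sample estimate
(ddof = 1; 0 for a single observation). Scatter points are per-protein
longest positive and negative LCRs after the > 2-residue filter; a protein
whose LCRs all fail the filter contributes no point. Covered-percentage
histograms bin [0, 100] in half-open bins with the last bin closed, so
counts always sum to the number of proteins. Comparisons are descriptive
only (side-by-side tables and deltas); no hypothesis tests are produced
because the analysis's claims are about distribution shape, not significance.

Exclusion re-analysis removes each protein's longest positive LCR (LONGEST
mode) from the pooled lengths — exactly one value per protein that has at
least one positive LCR. A DETECT-mode variant removes only maxima passing
the length threshold.

Multi-region proteins are analyzed per region by default (each disordered
region is its own analysis unit), with `extract_regions(..., concatenate=True)`
available to pool a protein's regions into one unit; the choice is visible
in the record ids.

## Synthetic data generator

The generator emulates the two sequence architectures the analysis
distinguishes; it is a statistical emulation, not a biological claim.

- **DisProt-like**: each position is independently positive with probability
  f₊ and negative with probability f₋ (defaults 0.10/0.10, a typical
  charged-residue density for disordered regions), otherwise neutral filler
  drawn uniformly from the 16 neutral canonical residues. Independent
  Bernoulli placement is the simplest model consistent with a stated density;
  it has no charge-patterning correlations. Sequence lengths are normal
  (default 300 ± 30, rounded, floored).
- **FG-Nup-like**: a planted N-terminal segment (length normal, default
  150 ± 20) containing only positive charges at a low density (default 0.03),
  concatenated with a DisProt-like charge-rich segment at the same f₊/f₋
  defaults. FG dipeptides are written into random adjacent neutral filler
  pairs until the whole sequence reaches the target FG/AA density (default
  0.2, above the 0.15 selection filter).

Two constructions make the planted truth exactly recoverable under the
default span convention: the planted segment's first and last positions are
forced to be charged, and the charge-rich segment opens with a negative
charge, terminating the planted run at the segment boundary. Without the
boundary charge, the planted run would extend a random distance into the
charge-rich segment (until its first negative charge), blurring the planted
span by a geometrically distributed offset; with it, the scanner's longest
positive LCR coincides with the planted span whenever no longer positive run
arises by chance in the charge-rich segment (negligible at the defaults).
Recovery metrics (length bias, intersection-over-union span overlap,
DETECT-mode flag rates, observed charge fractions) are computed by
`recovery_report`.

Randomness: one global seed spawns one independent substream per sequence
(numpy `SeedSequence.spawn`), so datasets are byte-reproducible and stable
under parallel generation.

What passing tests on synthetic data do **not** show: real FG Nups have
motif grammars (FxFG/GLFG spacing), compositional biases beyond charge and
FG content, and evolutionary correlations none of which the generator
models; recovery results validate the pipeline's correctness, not the
biological prevalence of lpLCRs.

## Numerical and design choices

- Coordinates are 1-based inclusive everywhere.
- Overlapping or adjacent disordered-region annotations are merged before
  any coverage computation (idempotent interval union).
- `outlier_fraction` uses a strict `length > threshold` comparison.
- Degenerate inputs: empty datasets, empty value lists and empty scatter
  collections raise errors rather than returning NaN; missing ranks in rank
  statistics yield absent fields.
- Problem sizes in the test suite (hundreds of sequences of length ~300,
  ~1000 random sequences for oracle equivalence) were chosen as the smallest
  sizes at which the stochastic claims are statistically stable.

## Known limitations

- No κ (charge-patterning mixedness) or sequence-charge-decoration moments;
  only f₊/f₋ and run-length statistics are computed.
- Disorder annotations are consumed, not predicted; the package does not run
  a disorder predictor.
- The comparison module is descriptive; users needing inference should
  export the TSVs and model the data directly.
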