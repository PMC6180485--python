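# Methods

This note documents the models, parameter choices, and numerical decisions
behind `polterm`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinate conventions

Gene models are stored 0-based half-open. The TSS and PAS are the interval
boundaries oriented by strand: a '+' gene has `tss < pas`; a '−' gene has
`tss > pas`. Strand-oriented offsets around an anchor `a` map to genomic
`a + d` on '+' and `a − 1 − d` on '−', so offset 0 is the first base past
the 3′ end on both strands and all windows are mirror-symmetric. All
analysis windows are half-open in oriented coordinates: B1 = [0, 50),
B2 = [350, 400), denominator = [−500, 500) around the PAS; boundary-touching
intervals do not count as overlap anywhere in the package.

## Gene selection

A gene is kept iff (a) the nearest same-strand downstream TSS lies strictly
more than 275 nt past its PAS, measured in the gene's transcription
direction, with "downstream" meaning a non-negative gap (a gene with no
downstream neighbor passes vacuously); and (b) no opposite-strand annotated
unit (TSS-to-PAS extent) intersects [PAS − 250, PAS + 500) oriented. The
alternative reading of the distances in absolute genome coordinates would
differ only for '−' genes; the oriented form was chosen because the
criterion exists to protect the post-PAS signal window, which is a
strand-oriented object. The implementation is checked against a naive
all-pairs oracle on 50 seeded annotations.

## Spike-in calibration

The scale factor is `alpha = 1e6 * m_hat / N_spike_IP` with
`m_hat = N_spike_input / N_pombe_input`. Only the two correction inputs are
dictated by the assay design (spike-in IP depth; input mixture ratio); this
particular algebra is a package choice in the ChIP-Rx style. The 1e6 is
cosmetic and cancels in every between-strain ratio, as does `alpha` itself
in the termination index (a within-sample ratio) — asserted by test.
Duplicates are defined as identical (chromosome, 5′ position, strand);
multi-mappers are identified by NH > 1 (SAM) or an `n_hits` column.

### Duplicate collapse at desk scale

The toy genome (600 kb) with 2e5 reads/sample puts per-(position, strand)
read rates at 0.2–0.4, so positional duplicate collapse also removes
coincidental collisions and compresses density-dependent ratios by 5–15%
(more under overdispersed noise). Real experiments (~1e7 reads over ~25 Mb)
sit in the collision-free regime where the rule removes PCR artifacts
almost exclusively. Consequently: occupancy tracks and termination indices
use the positional rule as published (the within-sample index is barely
affected); the mixing-fraction estimator and the calibration-recovery
checks use raw species counts (`dedup=False`), since the generator plants
no PCR duplicates by default and those quantities are exactly the
density-dependent ratios the collision artifact distorts. The duplicate
rule itself is tested on a fixture with planted duplicates.

## Synthetic-data generator

The generator emulates the study conditions: 15% spike-in cell fraction;
two fission-yeast-like chromosomes of 250 kb plus one 100 kb spike-in
chromosome; 300 genes; 2e5 single-end 50 nt reads per sample; wild-type
post-PAS readthrough decay 50 nt versus 400 nt in the defective strain.

* **Occupancy.** Each gene draws a lognormal body level (sigma 0.4).
  A mark-shape function modulates the body: flat for total Pol II and
  Ser5P; a logistic 3′ rise for Ser2P/Tyr1P (centered 400–500 nt before
  the PAS, scale 150 nt); a Gaussian bump centered 300 nt past the PAS
  (sd 150 nt) on a low baseline for Thr4P. Past the PAS everything is
  multiplied by `exp(-d / decay)`. Shape parameters live in the
  configuration, not in code.
* **Reads.** Expected read-midpoint density is the occupancy plus a
  uniform background (0.05 of the unit body level); per-base counts are
  Poisson or gamma-mixed Poisson (negative binomial, dispersion 0.1 — the
  default, since overdispersion is the realistic regime; Poisson is kept
  for closed-form checks). Reads are 50 nt point intervals; fragment-size
  and mappability effects are not modeled, and no sequence is generated.
* **Species mixing.** IP samples allocate reads between fission-yeast
  chromatin (occupancy-weighted) and spike-in chromatin (uniform, weighted
  by the realized mixing ratio); input samples allocate by genomic DNA
  content (genome size × cell ratio). The realized ratio is shared between
  an IP and its input — they come from the same culture — and can be
  jittered per strain × mark (lognormal, `mixing_jitter_sd`). The default
  jitter is 0 so that the default input sample estimates the nominal 15%;
  the calibration-recovery tests enable jitter (sd 0.2) explicitly.
* **IP efficiency** acts as a per-strain sequencing-yield multiplier.
  Under fixed sequencing depth, a uniform change in IP efficiency scales
  both species' immunoprecipitated material equally and cancels in read
  allocation; yield is the observable nuisance.
* **Planted effects.** `occupancy_scale` multiplies a strain's entire
  chromatin occupancy (background included), making "a planted 2× increase"
  well-defined: calibrated coverage should double everywhere.
* **Annotation.** Genes are packed left to right; clean genes get ≥ 520 nt
  clearance on both sides (sufficient for all selection criteria), and a
  configurable fraction (default 0.2) is emitted as deliberate failures:
  tandem same-strand pairs with a ≤ 250 nt TSS gap, and antisense pairs
  overlapping the PAS window. Infeasible packing raises with the
  constraint named.

Determinism: every randomized operation seeds `numpy` generators from
`(seed, stream-id[, sample-index])`, so identical configurations reproduce
outputs bit for bit, file level included.

What passing tests show: the estimators recover planted truths under
count noise, nuisance variation, and the published filtering rules, at
desk scale. What they do not show: robustness to mappability artifacts,
fragment-length effects, antibody cross-reactivity, or annotation error —
none of which the generator models.

## Termination statistics

Indices are computed per gene as coverage mass ratios (read-midpoint
counting is available behind a flag at the coverage step). Genes whose
windows leave the chromosome or whose denominator is zero are excluded and
reported. Median-of-B1 scaling uses the numpy median (even-length = mean of
the central pair), so `median(scaled_B1) == 1` exactly.

`compare_strains` uses the two-sided Wilcoxon rank-sum (Mann–Whitney) test:
exact enumeration when both groups have ≤ 20 values without ties, otherwise
the tie-corrected normal approximation; the Hodges–Lehmann estimate
(median of pairwise differences) summarizes the shift.

Two statistical facts about the design, measured during development and
worth knowing when interpreting output:

* Comparing the two strains of one simulation is a *matched-gene* design —
  both groups share the per-gene true indices — which makes the rank-sum
  test conservative under the null (observed type-I ≈ 0.02 at α = 0.05).
  Reported p-values for matched comparisons are therefore honest but not
  tight.
* Median-of-B1 scaling divides each group by a noisy shared factor; for
  *independent* groups this inflates the type-I rate (observed ≈ 0.09).
  The nominal-rate property test therefore uses unscaled B2 indices from
  independent replicate simulations whose genes are spaced > 1000 nt so
  that PAS ± 500 windows are disjoint (observed 0.058, uniform p-values by
  KS). In the matched between-strain comparison the shared-factor noise is
  dwarfed by the matched-gene conservatism.

## Metagene profiles

Default windows: PAS anchor [−500, +1000), TSS anchor [−250, +1000), 10 nt
bins (the bin size is a package choice; it must tile the window exactly).
Bin value is the mean per-base signal, so summed mass is conserved.
Replicates are averaged at the profile level, not pooled at the read level.
The upstream-equalized overlay applies an additive vertical offset so each
strain's mean over a pre-PAS window matches the reference; "level matching
by horizontal translation" is not well defined for profiles of this shape,
so the additive reading was implemented, with a multiplicative option
behind a flag. Heatmap rows are min-max scaled for display only; the TSV
written beside every figure carries the unscaled numbers and is the test
surface.

## Cross-link structural validation

Filtering keeps E strictly below 1e-5 and collapses unordered residue
pairs, summing spectral counts and keeping the best E-value. Distances are
Cα–Cα; the 30 Å satisfiability bound reflects the BS3 spacer plus side
chains. The 15 Å "close contact" extraction also uses Cα (the minimal
heavy-atom variant is a flag away) for consistency. First model only;
altlocs resolve to highest occupancy; insertion codes raise. Cross-species
transfer uses global Needleman–Wunsch (BLOSUM62, open 10, extend 0.5,
Biopython `PairwiseAligner`); positions opposite gaps are reported
untransferable rather than dropped, and transfers below 20% identity raise.
Contacts and distances are verified against an O(n²) brute-force scan on
structures of up to 400 residues.

## Binding fits

The quadratic depletion isotherm is evaluated in the rationalized form
`f = 2P / (s + sqrt(s² − 4PL))`, `s = P + L + Kd`, which is stable when the
discriminant is small. Fits optimize log Kd from an 8-point start grid
spanning one decade beyond the sampled concentrations on both sides, with
Levenberg–Marquardt least squares; standard errors come from the Jacobian
(delta method for Kd). A fit is flagged non-identifiable when the fitted
curve is ≥ 95% saturated at the lowest nonzero concentration — the data
then only bound Kd from above. 1:1 stoichiometry is fixed; Hill or
competition models are out of scope. Noiseless round trips recover Kd to
1e-6 relative; at 2% of the dynamic range the recovery is within 10%.

## Problem sizes

Defaults run the full pipeline in ~3 s and the complete test suite in
~1 min on one CPU: 300 genes / 600 kb / 2e5 reads per sample for
pipeline-level checks, 30–40 genes and 1e4–3e4 reads for property suites
that repeat hundreds of simulations, ≤ 400 residues for structure oracles.
These sizes were chosen so that Monte-Carlo assertions retain power while
the suite stays fast; all of them are configuration, not constants.
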