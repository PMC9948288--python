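# Methods

`dropdel` simulates the statistics of activity-based DNA-encoded library
(DEL) screening in microfluidic droplets and provides the estimators used to
analyze such screens.  This note records the models, the defaults and why
they were chosen, the numerical decisions, and the limits of what the
simulations demonstrate.

## Library model and aliquot sampling

A split-and-pool design is an ordered list of cycles, each a set of building
blocks; diversity is the product of per-cycle block counts.  Members are
indexed 0..N-1 in mixed radix over the cycles (cycle 1 most significant),
which makes the index↔building-block mapping bijective and trivially
invertible during decoding.

Aliquot size is measured in **equivalents** (ε): one equivalent is a bead
count equal to the diversity.  We model the per-member replicate count
(k class) as independent Poisson(ε) draws — the infinite-pool limit of
sampling beads with replacement.  The alternative (multinomial draws of a
fixed bead total) differs only at order 1/N and does not admit the
closed-form coverage used throughout:

    coverage(k; ε) = P(K ≥ k) = 1 − Σ_{i<k} e^{−ε} ε^i / i!

implemented via `scipy.stats.poisson.sf`.  Monte-Carlo coverage from sampled
aliquots is tested against this closed form within 3 binomial standard
errors, and sampled k-class histograms against the Poisson pmf by chi-square
at α = 0.01.

## Tag encoding and decoding

Tags are `headpiece + opening primer + one codon per cycle + closing
primer`.  The constant regions are documented placeholder sequences (real
platforms use proprietary constructs); they carry no information and are
validated only for presence.  Codebooks are built by seeded greedy random
search subject to a minimum pairwise Hamming distance `d` (default 3, codon
length 6), so nearest-codon decoding corrects up to `(d−1)//2` substitutions
per codon.  Greedy search is not optimal packing — at codon length 6 and
d = 3 it reliably yields ~90 codons of the 256 Hamming-bound — but it is
simple, reproducible, and ample at simulation scale.  Reads are modeled
substitution-only: this keeps the codon region at fixed offsets, so decoding
needs no alignment and indel tolerance is deliberately out of scope.
Decoding failures are flagged (`ambiguous` for distance ties, `unrecognized`
when the distance budget is exceeded) and dropped with a logged count rather
than imputed.

## Droplet encapsulation and assay signals

Per-droplet bead and cell counts are independent Poisson draws with mean
occupancies λ_bead and λ_cell.  The default λ_bead = −ln(0.9) ≈ 0.105 puts a
bead in ~10 % of droplets, keeping coencapsulation rare but present.  Beads
are drawn without replacement from the shuffled aliquot; exhaustion leaves
later droplets beadless with a warning rather than an error.  At unit
occupancy for both beads and cells the exact probability of a one-bead,
one-cell droplet is e^−2 ≈ 13.5 %, which is what the simulator reports
(figures quoting "~10 %" for this configuration are approximate).

A photocleaved bead releases `release_fraction × loading` into the droplet;
with loading in fmol and volume in pL the concentration in mM is simply
`release_fraction × loading / volume` (100 fmol fully released into 100 pL
= 1 mM).  Lowering `release_fraction` emulates attenuated UV photocleavage.

Baseline signals are i.i.d. Normal(μ_neg, σ_neg).  An active member at
concentration c inhibits by a fraction f(c): either a fixed effect or a
Hill curve `effect · c^h / (c^h + IC50^h)`.  Coencapsulated actives compose
multiplicatively (simple, monotone, reduces to the single-bead case).  Under
the default "proportional" noise mode the whole noisy signal is scaled by
(1 − f) — appropriate for fluorogenic readouts whose noise tracks intensity
— so full inhibition gives identically zero signal; an "additive" mode that
scales only the mean is available via configuration.

Fluorescence polarization readouts use the standard definition
`(I∥ − I⊥)/(I∥ + I⊥)`.  Raw detector traces are reduced to per-droplet
scalars by moving-average smoothing, baseline segmentation, and taking the
peak height of each sufficiently wide segment; this is a deliberately simple
plumbing reduction, not a model of detector physics.

## The rolling-window sorter

The sorter is single-pass and order-dependent: for droplet i ≥ `window`
(default 1000) the mean μ and sample standard deviation σ (ddof = 1) of the
prior `window` signals set the instantaneous threshold μ − zσ (default
z = 4; μ + zσ for gain-of-signal assays).  A droplet is sorted iff its
signal is strictly beyond the threshold; ties are not hits.  Design
decisions, each testable:

- **Burn-in**: the first `window` droplets are never sorted, avoiding
  ill-defined statistics at startup.
- **No exclusion**: sorted hits stay in subsequent windows; at ppm-level hit
  rates their contamination of μ and σ is negligible.
- **Affine invariance**: sorting decisions are invariant to common shifts
  and positive rescalings of the signal stream.

The asymptotic null sort probability is the one-tailed normal tail
`expected_outlier_rate(z) = Φ(−z)`: 32 ppm at z = 4, i.e. ~32 expected hits
per million null droplets, the threshold used by the productivity verdict.
Because μ and σ are *estimated* from a finite window, the exact null rate of
the implemented sorter is the Student-t tail
`t_{n−1}.sf(z / √(1 + 1/n))` (`finite_window_outlier_rate`): 34.3 ppm at
z = 4 with n = 1000, converging to Φ(−z) as the window grows.  Tests oracle
the exact finite-window rate; at z = 4 the two agree well inside the 3
Poisson-standard-error band of a million-droplet run.

Rolling statistics are computed with pandas' rolling mean/std shifted by one
droplet, which reproduces the streaming definition exactly while remaining
vectorized (a million droplets sort in about a second).

## Hit deconvolution and FDR

Sorted beads are decoded and aggregated per distinct structure; `k_hit` is
the number of sorted beads carrying a member.  Triage retains rows with
`k_hit ≥ k_min`; the FDR is the fraction of *distinct retained structures*
that are inactive (per-structure, matching the triage narrative, not
per-bead).  Stratification beyond the binary triage is reported but not used
for ranking: Poisson sampling and synthesis noise make finer k distinctions
uninformative.  A warning is emitted when a hit collection exceeds ~30000
beads, the practical PCR amplification constraint.

`screen_fdr_simulation` runs the full pipeline (sample → encapsulate →
signal → sort → sequence → decode → aggregate → triage) with stage seeds
derived from one master seed via `numpy.random.SeedSequence`.  The default
acceptance-scale conditions — a 2000-member 2-cycle design, 5 fully
inhibiting actives, ε = 3, λ_bead = 0.05, 1.2 × 10^5 droplets, 20
replicates — were chosen so that actives are deeply sampled (k ≈ 3),
coencapsulation is rare but non-zero, and the FDR at k_min = 1 is materially
positive while triage at k_min = 2 removes essentially every false
discovery, the regime the method is designed for.  Building-block
enrichment is reported as raw k-weighted counts per cycle with a chi-square
test against uniformity; no field-standard enrichment statistic exists for
activity screens, so this is explicitly an artifact convention.

## Z′ assay quality

Z′ = 1 − 3(σ_neg + σ_pos)/|μ_neg − μ_pos| from labeled control populations;
1 for a statistically perfect assay, > 0.5 (strict) for a screenable one.
Population moments are sample mean and SD (ddof = 1) — identical in effect
to Gaussian fits for Gaussian populations, without an optimizer.
Populations must be supplied pre-labeled; splitting a mixed flow-injection
trace into components is out of scope.

## What the simulations do and do not show

The generator reproduces the *statistical* structure of droplet DEL
screening: Poisson sampling and occupancy, Gaussian assay noise, threshold
sorting, decoding errors, and replicate-based triage.  It does not model
synthesis yields or truncation products, bead-to-bead loading variance,
droplet volume polydispersity, detector drift or saturation, PCR bias, or
indels in sequencing — so passing tests validate the statistical framework,
not the behavior of any particular wet-lab assay.  Problem sizes in the test
suite (10^6-droplet null screens, 10^5-member aliquots, 10^4-member decode
round trips, 20-replicate FDR curves) were picked as the smallest scales at
which the targeted statistics are resolvable at 3-standard-error precision.
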