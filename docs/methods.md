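# Methods

## Derivative chromosomes and observables

A rearranged haplotype is an ordered list of oriented reference segments
(`DerivativeChromosome`); all coordinates are 0-based, half-open. Two
observables are derived from it:

* **Junctions.** Each derivative adjacency whose reference coordinates are
  not contiguous in reference orientation implies a junction of two
  breakends. A breakend records the retained terminal base and the side on
  which reference sequence is retained: `R` = retained at coordinates
  ≤ pos, `L` = retained at ≥ pos (BEDPE strands `+`/`-`). Junctions are
  canonically ordered and **deduplicated**: the mirrored arms of a BFB
  palindrome repeat the same fusion junction, and a sequencing pipeline
  would report it once. An *n*-cycle BFB therefore yields exactly *n*
  fold-back junctions.
* **Copy number.** Per-base depth is the number of derivative segments
  covering a base plus `baseline_cn − 1` intact homolog copies (default
  baseline 2: events on one haplotype of a diploid; the ploidy of
  immortalized fibroblast lines is not modeled further). Depth is averaged
  per bin (default 1 kb in clone simulations), rounded half-up to an
  integer, and equal neighbors are merged. With `bin_size=1` this equals
  per-base counting exactly, which the tests verify against a brute-force
  oracle.

Junction side rules per event class: a deletion of [s, e) leaves
{(s−1, R), (e, L)}; a tandem duplication {(e−1, R), (s, L)}; an inversion a
head-to-head {(s−1, R), (e−1, R)} plus tail-to-tail {(s, L), (e, L)} pair.

## Event models

**Templated insertion.** A copy of the template [t0, t0+len) replaces
`site_deletion_len` bases at the insertion site, inverted with default
probability 0.8 (insertions are typically, not always, inverted; no
proportion is published, so 0.8 is this package's choice). Default sampling
bounds encode the reported ranges: template length log-uniform 2–100 kb,
site deletion uniform 6–1000 bp, insertion distance uniform from the
template midpoint over [10 kb, 5 Mb] — with the lower bound raised to half
the template plus the site when needed, since a distance measured from the
midpoint cannot be smaller than the template's own half-width without
overlap. The event leaves +1 copy over the template, −1 over the replaced
site, and two junctions: an (RR, LL) pair when inverted, an (RL, RL) pair
when direct.

**Breakage-fusion-bridge.** The distal telomere is lost by a break drawn
uniformly in the terminal `window_frac` (default 10%) of the chromosome;
each cycle fuses the retained arm to its reverse-complement sister copy
(one fold-back junction at the current tip) and re-breaks the palindromic
dicentric. Break positions erode inward — break *k+1* is uniform in
[p_k·(1−w), p_k) in reference coordinates, implemented by truncating the
trailing mirrored arm at that coordinate. This geometry was chosen over a
literal "break near the derivative end" rule because the palindrome's two
derivative ends alternate between the two reference extremes; the
reference-frame erosion gives the canonical BFB signature: fold-back
junctions clustered toward the lost end with alternating R/R / L/L sides
and a copy-number staircase that is monotone non-decreasing toward the
fusion point (1, 2, 4, … on the affected haplotype), with copy loss distal
to the first break.

**Chromothripsis.** A region is cut at `n_fragments − 1` uniform positions;
fragments survive independently with `retain_prob` and are re-ligated in
random order and orientation. Copy number inside the region oscillates
between baseline and baseline−1, and junction sides are near-uniform over
the four categories (verified by Monte Carlo over 200 seeds).

## Clone simulation (the study conditions)

Two genotype profiles define the simulated conditions on a single
195 Mb chromosome (mouse chromosome 1 scale), baseline copy number 2:

| parameter | wild_type | rtel1_null |
|---|---|---|
| events per clone | uniform 8–12 | uniform 15–35 |
| class mix | del .50 / tdup .35 / inv .15 | del .35 / tdup .20 / inv .10 / TI .25 / bfb .05 / chromothripsis .05 |
| deletion size | log-uniform 0.5–10 kb | log-uniform 0.5–300 kb |
| BFB | — | ≤ 1 per clone, 2–4 cycles |
| chromothripsis | — | ≤ 1 per clone, 10–20 fragments, retain 0.6, region 2–4 Mb |

These encode the reported contrasts: wild-type subclones carry 8–12 simple,
mostly sub-10 kb SVs; mutant subclones carry 15–35 events with many
deletions above 100 kb and the complex classes. The per-clone caps on BFB
and chromothripsis reflect that these present as single regional patterns
per profile.

Placement is uniform with rejection against previously occupied intervals
(max 1000 retries), with a 1.05 Mb minimum spacing between independently
placed events. The margin emulates genome-wide sparsity: tens of subclonal
SVs scattered over a ~2.5 Gb genome are compressed here onto one modeled
chromosome, and without the spacing they would co-cluster far more densely
than real inter-event distances allow. A templated insertion's site may
approach its own template (distances start at 10 kb) but keeps the full
margin to every other event. When a BFB is drawn it is applied first, to
the pristine distal end; all other events then stay 6 Mb proximal of its
realized erosion zone, and the chromothripsis region keeps a 1.5 Mb clear
buffer, so the three regional signatures remain separable. The generator
does **not** emulate: inter-chromosomal translocations, microhomology or
untemplated bases at junctions (insert length defaults to 0), subclonal
mixtures, sequencing noise in junction positions, or CN noise — so passing
round-trip tests demonstrate internal consistency of simulator and
classifier at call level, not robustness to caller noise in real WGS data.

## Classifier

Greedy hierarchical assignment — chromothripsis, then BFB, then templated
insertions, then simple junction types — so complex calls consume their
constituent junctions and every junction lands in exactly one class
(asserted at run time). Thresholds (all in `ClassifierConfig`; none are
published for the original in-house calling, so these are this package's
defaults): fold-back gap 10 kb, chromothripsis ≥ 8 clustered breakends with
gap-clustering at 1 Mb, ≤ 2 CN states inside the region, junction-side
uniformity not rejected by a χ² goodness-of-fit at α = 0.05; BFB requires a
fold-back junction with a monotone, amplified CN staircase proximal and
sub-baseline CN distal to the chromosome end, absorbing all fold-backs
inside the contiguous amplified run (cycle estimate = their count);
templated insertions require a junction pair flanking a CN+1 template with
a 6–1000 bp site deletion at the configured distance, ties broken by
minimal site deletion then leftmost template. The chromothripsis
orientation test rejects ~5% of true shattered regions by construction
(α = 0.05); with chromothripsis ~5% of mutant events this costs ~0.25% in
round-trip recovery. Head-to-head/tail-to-tail pairs spanning the same
interval (±50 bp) are merged into balanced inversions; unpaired short
inverted junctions remain `fold_back`.

Nested insertions into another rearrangement's breakpoint are not resolved
beyond the greedy order; such configurations surface as separate simple
calls rather than a combined event.

## Worm segregation model

Chromosome types N = normal(dpy-25), B = mIn1(rol-1, GFP), and reciprocal
crossover products R1 = (dpy-25, GFP), R2 = (rol-1). Each parental meiosis
yields a recombinant gamete with probability *r* (R1 or R2 with r/2 each);
double crossovers are not modeled since they would not exchange flanking
markers. Phenotypes are resolved by marker dosage (semi-dominant markers
distinguishable at 1 vs 2 copies; recessives visible only when homozygous);
genotypes with identical dosage signatures share a label, so the double
recombinant R1/R2 is indistinguishable from the balanced heterozygote and
is **not** counted as scoreable exchange — one reason the assay
under-detects, alongside viability loss of recombinant genotypes (both
directions verified by tests). Viabilities default to 1 and renormalize the
distribution over surviving classes.

Frequency estimates report 100·k/n rounded to two decimals with exact
Clopper–Pearson 95% CIs. Group comparison uses Fisher's exact test when
either group total is ≤ 1000 and χ² without continuity correction
otherwise. Fold changes are ratios of the 2-decimal rounded percentages;
because published figures use both conventions (27.33 → 27 by rounding,
110.67 → 110 by truncation), the operation reports both `rounded` and
`truncated` and flags disagreement. Map distances offer the direct
estimator (100·R scaled by a design detectability factor) and the
self-cross correction p = 1 − √(1 − 2R); which the original interval
figures used is not stated, so neither is asserted as canonical. The
corrected estimator rejects R > 0.5, where it is undefined.

## Numerical choices

* Copy-number binning integrates the exact piecewise-constant depth over
  each bin and rounds half-up — deterministic and independent of bin
  iteration order.
* Wilcoxon rank-sum: exact null when the pooled sample is ≤ 20 without
  ties, tie-corrected normal approximation (no continuity correction)
  otherwise; exactness is cross-checked against full enumeration in tests.
* Fisher's two-sided p uses the point-probability method; the tests verify
  it against direct hypergeometric enumeration.
* All simulation entry points accept a seed or `numpy` Generator; identical
  seed + configuration reproduces observables exactly.

## Problem sizes used in the shipped checks

Round-trip recovery runs 100 clones (50 per genotype) on the 195 Mb
default genome; cohort power uses 100 replicates of 4-vs-4 cohorts
compared on junction counts; estimator-recovery checks use 100 seeds at
n = 10⁵ progeny (frequency) and n = 5×10³ (map distance). These sizes give
Monte-Carlo errors comfortably inside the 3-SE acceptance bands while the
whole suite stays in the half-minute range.

## Known limitations

* Single-chromosome model: fold-back fusions are bookkept intra-
  chromosomally; translocations are out of scope.
* The BFB final state is the post-bridge intermediate of the last cycle;
  real clones may carry further resolved derivatives.
* Chromothripsis regions whose lost-fragment runs exceed the 1 Mb
  clustering gap can split below the breakend threshold and go uncalled
  (~2–3% of shattered regions under defaults).
* Classifier thresholds are tuned to the simulator's call-level cleanliness
  and would need recalibration for noisy junction/CN calls from real reads.
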